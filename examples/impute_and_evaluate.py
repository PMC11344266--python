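"""Train a tiny model, impute a truncated phantom, and score the result.

A deliberately small configuration (two training phantoms, 60 steps per
generator) so the whole script runs in about a minute: simulate, train
the four generators, cut 6 mm off the top of a held-out phantom, impute
it, and report imputed-region PSNR/SSIM against the ground truth next to
the zero-filled input.  Expect modest numbers — the point is the shape
of the pipeline, not peak quality.
"""

from dwifov.evaluation import evaluate_imputation
from dwifov.gan import GeneratorSpec
from dwifov.inference import impute_study
from dwifov.normalization import simulate_cutoff
from dwifov.phantom import PhantomSpec, make_cases
from dwifov.training import TrainConfig, prepare_case, train_bundle

spec = PhantomSpec(shape=(32, 32, 32), n_weighted=4)
raw_train = make_cases(spec, 2, master_seed=1)
raw_val = make_cases(spec, 1, master_seed=1, offset=2)
raw_test = make_cases(spec, 1, master_seed=1, offset=3)

train = [prepare_case(s, t, b) for s, t, b, _ in raw_train]
val = [prepare_case(s, t, b) for s, t, b, _ in raw_val]

config = TrainConfig(n=1, steps=60, batch_size=4, val_interval=30, seed=1,
                     generator_spec=GeneratorSpec(n=1, width=8, n_blocks=1,
                                                  n_down=1),
                     discriminator_width=8)
print("training the four (shell group x view) generators ...")
bundle, states = train_bundle(train, val, config)
for key, st in states.items():
    print(f"  {key}: final L1 {st.g_l1[-1]:.4f}, "
          f"best val MSE {st.best_score:.5f} @ step {st.best_step}")

study, t1, brain, _ = raw_test[0]
truncated, fov = simulate_cutoff(study, brain, 6.0, "top")
print(f"\ncut {len(fov.missing_z_slices())} axial slices from the top; "
      "imputing ...")
imputed, _ = impute_study(bundle, truncated, t1, fov=fov, brain=brain, n=1)

for name, test in (("zero-filled input", truncated), ("imputed", imputed)):
    res = evaluate_imputation(study, test, fov, brain)
    line = "  ".join(f"{g}: PSNR {m['psnr']:5.2f} dB SSIM {m['ssim']:.3f}"
                     for g, m in res.items())
    print(f"{name:<18} {line}")

print("\nThe imputed volume should clearly beat the zero-filled input in "
      "the missing region; acquired voxels are untouched by construction.")
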