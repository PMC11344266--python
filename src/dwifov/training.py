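"""Adversarial training loop with cutoff augmentation and model selection.

Each of the four generators (shell group × view) is trained
independently: per step a study and a volume of the generator's shell
group are drawn, the volume is truncated by a random 0–50 mm cut from the
top or bottom of the brain, a mini-batch of 2.5D patches is extracted,
and the discriminator and generator take alternating Adam steps on the
minimax value plus the λ-weighted L1 term.  Checkpoints are compared by
their imputation error on the missing region only of validation studies
truncated by a fixed cut, and the best checkpoint (argmin) is returned.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import _autograd as ag
from ._autograd import Adam, Tensor
from .core_io import DWIStudy
from .errors import TrainingDiverged
from .gan import (DiscriminatorSpec, GeneratorSpec, ModelBundle, PatchDiscriminator,
                  ResnetGenerator, build_discriminator, build_generator,
                  default_generator_spec, forward_generate,
                  generator_adversarial_term, l1_loss, to_internal,
                  total_generator_objective, adversarial_loss_from_logits)
from .normalization import (BrainMask, FOVMask, compute_normalization,
                            apply_normalization, draw_cutoff, simulate_cutoff)
from .patches import brain_slice_range, extract_patch, view_axis

log = logging.getLogger(__name__)


@dataclass
class TrainingCase:
    """One normalized, grid-aligned study ready for training or validation."""

    dwi: np.ndarray              # (x, y, z, v) in [0, 1]
    structural: np.ndarray       # (x, y, z) in [0, 1]
    brain: BrainMask
    gradients: "object"
    voxel_size: float = 1.0


def prepare_case(study: DWIStudy, structural, brain: BrainMask) -> TrainingCase:
    """Normalize a grid-aligned study + structural pair for training."""
    dwi_params = compute_normalization(study)
    t1_data = structural.data if hasattr(structural, "data") else structural
    t1_params = compute_normalization(np.asarray(t1_data))
    return TrainingCase(
        dwi=apply_normalization(study.data, dwi_params),
        structural=apply_normalization(np.asarray(t1_data), t1_params),
        brain=brain, gradients=study.gradients,
        voxel_size=float(study.voxel_size[2]))


@dataclass
class TrainConfig:
    """Hyperparameters for one generator's training run."""

    shell_group: str = "bweighted"
    view: str = "sagittal"
    n: int = 1                       # neighbor half-width
    lam: float = 100.0               # L1 weight λ
    batch_size: int = 24
    steps: int = 400
    cutoff_range_mm: tuple[float, float] = (0.0, 50.0)
    # augmentation draws never exceed this fraction of the brain's z-extent,
    # so the 0-50 mm range stays valid on small phantom grids
    max_cut_brain_fraction: float = 0.4
    val_cut_mm: float | None = None  # default: 30 mm scaled by grid_z/256
    val_interval: int = 50
    val_max_volumes: int = 2
    lr: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    seed: int = 0
    ablate_structural: bool = False  # baseline: zero the structural channels
    generator_spec: GeneratorSpec | None = None
    discriminator_width: int = 16
    margin: int = 0


@dataclass
class TrainState:
    """Loss traces and the best validation checkpoint seen."""

    step: int = 0
    d_loss: list = field(default_factory=list)
    g_adv: list = field(default_factory=list)
    g_l1: list = field(default_factory=list)
    val_steps: list = field(default_factory=list)
    val_scores: list = field(default_factory=list)
    best_score: float = float("inf")
    best_step: int = -1


class ModelSelector:
    """Keeps the checkpoint with the minimum validation error."""

    def __init__(self):
        self.best_score = float("inf")
        self.best_step = -1
        self.best_state = None

    def update(self, step: int, score: float, state_dict: dict | None = None):
        if not np.isfinite(score):
            return False
        if score < self.best_score:
            self.best_score = score
            self.best_step = step
            if state_dict is not None:
                self.best_state = copy.deepcopy(state_dict)
            return True
        return False


def _default_val_cut(case: TrainingCase) -> float:
    """30 mm on the full 256-slice grid, scaled to the actual axial extent."""
    grid_z = case.dwi.shape[2]
    return 30.0 * grid_z / 256.0 * case.voxel_size


def validation_score(generator_or_bundle, val_cases, cut_mm: float,
                     cut_side: str = "top", view: str | None = None,
                     shell_group: str | None = None, n: int | None = None,
                     max_volumes: int | None = None,
                     ablate_structural: bool = False) -> float:
    """Mean imputation MSE on the missing region only (brain ∩ missing).

    Accepts either a single generator (scored with its own view) or a
    complete :class:`ModelBundle` (scored with merged views).  The cutoff
    is fixed so scores are comparable across checkpoints.
    """
    from .inference import predict_volume_view, merge_views  # cycle guard

    single = not isinstance(generator_or_bundle, ModelBundle)
    if single and (view is None or shell_group is None or n is None):
        raise ValueError("view, shell_group and n are required for a "
                         "single-generator validation score")
    errors = []
    for case in val_cases:
        truncated, fov = simulate_cutoff(case.dwi, case.brain, cut_mm,
                                         cut_side, voxel_size=case.voxel_size)
        region = case.brain.mask.astype(bool) & ~fov.mask.astype(bool)
        if not region.any():
            raise ValueError("empty missing region at the validation cutoff")
        structural = (np.zeros_like(case.structural) if ablate_structural
                      else case.structural)
        groups = ([shell_group] if single else ["b0", "bweighted"])
        for group in groups:
            idx = case.gradients.group_indices(group)
            if max_volumes is not None:
                idx = idx[:max_volumes]
            for v in idx:
                truth = case.dwi[..., v]
                inp = truncated[..., v]
                if single:
                    pred = predict_volume_view(generator_or_bundle, inp,
                                               structural, view, n,
                                               brain=case.brain)
                else:
                    gs = generator_or_bundle.get(group, "sagittal")
                    gc = generator_or_bundle.get(group, "coronal")
                    nn = (gs.spec.in_channels // 2 - 1) // 2
                    pred = merge_views(
                        predict_volume_view(gs, inp, structural, "sagittal",
                                            nn, brain=case.brain),
                        predict_volume_view(gc, inp, structural, "coronal",
                                            nn, brain=case.brain))
                diff = truth[region] - pred[region]
                errors.append(float(np.mean(diff * diff)))
    return float(np.mean(errors))


def _sample_batch(case: TrainingCase, config: TrainConfig,
                  rng: np.random.Generator):
    """One augmented mini-batch of (input stack, target slice) arrays."""
    idx = case.gradients.group_indices(config.shell_group)
    v = int(rng.choice(idx))
    lo_mm, hi_mm = config.cutoff_range_mm
    z_lo, z_hi = case.brain.z_extent()
    brain_mm = (z_hi - z_lo + 1) * case.voxel_size
    hi_mm = min(hi_mm, config.max_cut_brain_fraction * brain_mm)
    cut_mm = float(rng.uniform(lo_mm, max(lo_mm, hi_mm)))
    side = "top" if rng.random() < 0.5 else "bottom"
    truth = case.dwi[..., v]
    truncated, _ = simulate_cutoff(truth, case.brain, cut_mm, side,
                                   voxel_size=case.voxel_size)
    structural = (np.zeros_like(case.structural)
                  if config.ablate_structural else case.structural)
    extent = truth.shape[view_axis(config.view)]
    lo, hi = brain_slice_range(case.brain, config.view, extent, config.margin)
    indices = rng.integers(lo, hi + 1, size=config.batch_size)
    stacks, targets = [], []
    for i in indices:
        s = extract_patch(truncated, structural, config.view, int(i),
                          config.n, target_volume=truth)
        stacks.append(s.input_stack)
        targets.append(s.target_slice)
    return np.stack(stacks), np.stack(targets)


def train_generator(train_cases, val_cases, config: TrainConfig):
    """Train one generator; returns ``(generator, TrainState)``.

    The returned generator carries the weights of the checkpoint with the
    lowest fixed-cutoff validation error (missing region only), never a
    later checkpoint that scored worse.
    """
    if not train_cases or not val_cases:
        raise ValueError("need at least one training and one validation study")
    rng = np.random.default_rng(config.seed)
    slice_hw = [s for a, s in enumerate(train_cases[0].dwi.shape[:3])
                if a != view_axis(config.view)]
    gspec = config.generator_spec or default_generator_spec(
        config.n, min(slice_hw))
    if gspec.n != config.n:
        gspec = replace(gspec, n=config.n)
    gen = build_generator(gspec, seed=int(rng.integers(2 ** 31)))
    disc = build_discriminator(
        DiscriminatorSpec(cond_channels=gspec.in_channels,
                          width=config.discriminator_width),
        seed=int(rng.integers(2 ** 31)))
    opt_g = Adam(gen.params(), lr=config.lr, betas=config.betas)
    opt_d = Adam(disc.params(), lr=config.lr, betas=config.betas)

    val_cut = config.val_cut_mm
    if val_cut is None:
        val_cut = _default_val_cut(val_cases[0])

    state = TrainState()
    selector = ModelSelector()

    def validate(step):
        score = validation_score(
            gen, val_cases, val_cut, "top", view=config.view,
            shell_group=config.shell_group, n=config.n,
            max_volumes=config.val_max_volumes,
            ablate_structural=config.ablate_structural)
        state.val_steps.append(step)
        state.val_scores.append(score)
        selector.update(step, score, gen.state_dict())
        log.info("step %d: val MSE %.5f (best %.5f @ %d)",
                 step, score, selector.best_score, selector.best_step)

    for step in range(1, config.steps + 1):
        case = train_cases[int(rng.integers(len(train_cases)))]
        x, y = _sample_batch(case, config, rng)
        cond = Tensor(to_internal(x))
        real = Tensor(to_internal(y))

        fake = gen(cond)

        # discriminator ascends E[log D(real)] + E[log(1 − D(fake))]
        d_loss = -adversarial_loss_from_logits(
            disc(cond, real), disc(cond, fake.detach()))
        opt_d.zero_grad()
        opt_g.zero_grad()
        d_loss.backward()
        opt_d.step()

        # generator descends E[log(1 − D(fake))] + λ·L1
        adv = generator_adversarial_term(disc(cond, fake))
        l1 = l1_loss(real, fake)
        g_loss = total_generator_objective(adv, l1, config.lam)
        opt_d.zero_grad()
        opt_g.zero_grad()
        g_loss.backward()
        opt_g.step()

        dl, ga, gl = d_loss.item(), adv.item(), l1.item()
        if not (np.isfinite(dl) and np.isfinite(ga) and np.isfinite(gl)):
            raise TrainingDiverged(
                f"non-finite loss at step {step}: d={dl} adv={ga} l1={gl}")
        state.step = step
        state.d_loss.append(dl)
        state.g_adv.append(ga)
        state.g_l1.append(gl)

        if step % config.val_interval == 0 or step == config.steps:
            validate(step)

    if selector.best_state is not None:
        gen.load_state_dict(selector.best_state)
    state.best_score = selector.best_score
    state.best_step = selector.best_step
    return gen, state


def train_bundle(train_cases, val_cases, base_config: TrainConfig,
                 shell_groups=("b0", "bweighted"),
                 views=("sagittal", "coronal")) -> tuple[ModelBundle, dict]:
    """Train the four (shell group × view) generators of the pipeline."""
    bundle = ModelBundle()
    states = {}
    for g_i, group in enumerate(shell_groups):
        for v_i, view in enumerate(views):
            cfg = replace(base_config, shell_group=group, view=view,
                          seed=base_config.seed + 17 * g_i + 31 * v_i)
            gen, st = train_generator(train_cases, val_cases, cfg)
            bundle.add(group, view, gen,
                       meta={"best_score": st.best_score,
                             "best_step": st.best_step,
                             "steps": cfg.steps, "n": cfg.n,
                             "lam": cfg.lam, "seed": cfg.seed,
                             "ablate_structural": cfg.ablate_structural})
            states[(group, view)] = st
            log.info("trained %s/%s: best val MSE %.5f", group, view,
                     st.best_score)
    return bundle, states
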