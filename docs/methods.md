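# Methods

## Problem and model

Clinical brain diffusion MRI is frequently acquired with an incomplete
field of view (FOV): a contiguous block of axial slices at the superior
or inferior end of the brain is simply never scanned. `dwifov` imputes
those missing slices for every volume of a diffusion-weighted series,
conditioning on (a) the acquired portion of the volume itself and (b) a
co-registered structural (T1w-like) image whose FOV is complete.

The mapping is learned as a 2.5D conditional adversarial model. Working
on an isotropic normalized grid, a deterministic generator `G` receives,
for one target slice in the sagittal or coronal view, the stack of its
`2n+1` neighboring DWI slices concatenated with the `2n+1` structural
slices at the same indices — `2·(2n+1)` input channels in total — and
predicts the single target slice. Four generators are trained, one per
(shell group × view) cell: b0 and diffusion-weighted volumes have very
different intensity statistics, and the two in-plane views provide
complementary continuity constraints. The axial view is excluded by
construction: axial slices inside the missing region contain no signal
at all, so there is nothing to condition on in that view.

The objective per generator is the classic minimax value plus an L1
reconstruction term:

    L_GAN(G, D) = E_y[log D(y)] + E_x[log(1 − D(G(x)))]
    L_L1(G)     = E[‖y − G(x)‖₁]
    G*          = arg min_G max_D  L_GAN(G, D) + λ·L_L1(G)

with `λ = 100` by default — the reconstruction term dominates, which is
what one wants for medical image synthesis, and the discriminator mainly
sharpens local texture. `D` is a patch-level convolutional classifier on
the conditioning stack concatenated with the candidate slice. The
adversarial value is implemented in logit space
(`log D = −softplus(−logit)`), which equals the probability-space
formula but is stable for confident discriminators. The literal minimax
sign convention is used for the generator step; because `λ·L1` dominates
the gradient, the well-known saturation of this form is immaterial here.

At inference every slice of both views is predicted, the two predicted
volumes are merged by unweighted voxel averaging, only the slices in the
missing region are kept, resampled back to subject space, and combined
with the acquired data as `m ⊙ x + (1 − m) ⊙ ỹ` where `m` is the binary
acquired-region mask. Acquired voxels are therefore bit-identical in the
output — a hard guarantee, tested voxel-wise.

## Preprocessing conventions

* **Intensity normalization.** One scale per DWI study: the 99.9th
  percentile of all voxels across all volumes jointly maps to 1, the
  minimum to 0 (values clipped to [0, 1]); the structural image gets its
  own scale. The percentile is computed over all voxels including
  background by default; a flag restricts it to positive voxels, since
  the fraction of background air changes the percentile slightly.
* **Grid.** All learning happens on an isotropic axis-aligned grid
  (default 256³ at 1 mm; 48³ in the desk-scale study), with centered
  pad/crop and trilinear (intensities) or nearest (masks) resampling.
  When the input already lies on the grid the resampler short-circuits
  to an exact integer shift, so full-grid phantoms round-trip exactly.
  Registration between the structural image and the DWI is consumed, not
  computed: inputs must already share a world space.
* **Brain mask.** Median filter → Otsu threshold → largest connected
  component → hole filling. It restricts metric computation, locates the
  brain's z-extent for cutoff simulation, and (optionally, default on)
  masks imputed slices to the brain to suppress halo artifacts outside
  it.
* **b0 / weighted split.** A volume is b0 if `bval ≤ 50 s/mm²`; real
  bval files jitter around nominal zero, so an exact-zero test is too
  brittle.

## Training procedure

Per optimization step: draw a study, draw a volume from the generator's
shell group, truncate the volume by a random cut of 0–50 mm from the top
or bottom of the brain (uniform cut length, equal side probability),
then draw a mini-batch of slice indices within the brain's bounding box
along the view axis. Inputs come from the truncated data, targets from
the untruncated ground truth, for *all* brain slices — not only missing
ones — so the model also learns the identity regime and stays usable on
complete-FOV inputs. On small phantom grids the random cut is capped at
40% of the brain's z-extent so the draw always respects the brain; at
full scale this cap (≈60 mm for an adult brain) leaves the 0–50 mm
range untouched.

Optimization is Adam at learning rate 2e-4 with momentum parameters
(0.5, 0.999), alternating one discriminator and one generator step.
Checkpoints are compared by their mean squared error *on the missing
region only* (within the brain mask) of validation studies truncated by
a fixed cut — 30 mm at full scale, scaled by `grid_z/256` on smaller
grids — and the returned model is the argmin over validated checkpoints,
never a later, worse one. A fixed validation cut is essential: scoring
against freshly randomized cuts would make checkpoint scores
incomparable.

The structural-ablation baseline trains the same architecture with the
structural channels zeroed (rather than removed), keeping checkpoints
shape-compatible with the full model.

All randomness — phantom geometry and noise, weight initialization,
sampling order — flows from one seed through `numpy.random.Generator`,
and the implementation is single-threaded numpy, so training traces are
exactly reproducible.

## Networks

The generator is a residual encoder–decoder: a 3×3 input convolution,
`n_down` stride-2 convolutions (channel-doubling), a stack of residual
blocks at the bottleneck, nearest-neighbor ×2 upsampling with 3×3
convolutions back to full resolution, and a tanh output head. Weights
are initialized N(0, 0.02). Intensities cross the module boundary in
[0, 1] and are mapped affinely to the internal tanh range [−1, 1]. The
full-scale configuration (slices ≥ 128²) uses width 64, 9 residual
blocks and two downsampling stages; below that a narrow variant (width
16, 1 block, 1 stage) is used — small slices neither need nor can
support the deep stack. The networks run on a purpose-built numpy
reverse-mode autodiff engine (`dwifov._autograd`) with im2col GEMM
convolutions; input gradients are computed as dilated convolutions with
the flipped kernel, and gradients are verified against finite
differences in the test suite.

## Evaluation

All metrics are computed on normalized intensities with `data_range = 1`
within the evaluation region (brain ∩ missing):

* masked MSE and PSNR `10·log10(range²/MSE)` (PSNR reports `+inf` when
  the MSE is exactly zero);
* 3-D SSIM with a uniform 7³ window and unbiased covariance
  normalization. For whole-volume scores only valid window centers are
  averaged (the usual convention); for mask-restricted scores the SSIM
  map is computed with reflect-padded windows so that thin missing
  regions touching the grid boundary remain scoreable.
* distance-stratified metrics: each fully missing axial slice is
  assigned its distance in mm to the nearest acquired slice, measured
  along the axial axis, and PSNR/SSIM are aggregated per distance bin;
* per-direction ADC maps, `ADC = −ln(S/S0)/b` with `S0` the mean b0
  volume and non-positive signals excluded as invalid, feeding a
  tie-corrected Kruskal–Wallis test for gradient-direction bias
  (identical-value degenerate input returns H = 0, p = 1);
* method comparison tables aggregate per-study metrics first, then
  report mean ± sd across studies.

## Phantom simulator

The phantom stands in for clinical data: nested superellipsoids (thin
CSF rim, gray shell, tall white core; exponent 3 flattens the top and
bottom as in a real head, so axial cross-sections stay large until just
below the apex; proportions jittered ±8% with ±15° rotation across
cases) on a 48³ @ 1 mm grid, one b0 plus six b = 1300 s/mm² directions
laid out on a golden spiral. Signals follow the single-tensor model
`S = S0·exp(−b·gᵀDg)`: CSF isotropic 3.0e-3 mm²/s, gray isotropic
0.8e-3, white prolate (0.9, 0.5, 0.5)e-3 with its principal axis on a
smooth tangential swirl — so diffusion-weighted contrast is genuinely
direction-dependent, which the per-direction ADC analysis needs. The S0
map and the tensor field are Gaussian-smoothed (σ = 0.5 voxels) *before*
signal synthesis, emulating partial-volume mixing at compartment
boundaries while keeping the forward model exact for the returned
fields. DWI magnitudes receive Rician noise (σ = 0.02·max S0), the
standard magnitude-MRI model, whose background noise floor is asserted
statistically in the tests.

Two features deliberately decouple the DWI from the structural channel,
because they decide where imputation is *hard*:

* a DWI-only smooth multiplicative S0 field (rms amplitude 0.25,
  correlation length ≈ 4 voxels) standing in for bias-field and
  physiological variability. It is invisible in the structural channel,
  so in the missing region the model can only infer it by propagating
  in-plane from the acquired rows — information that decays with
  distance from the acquired region, which is the mechanism behind the
  characteristic worsening of imputation with slice distance. It
  multiplies `S0`, so it cancels exactly in ADC ratios.
* residual T1w→DWI misregistration: the structural channel is shifted by
  a random sub-voxel offset (up to 1.5 mm per axis), as left over by
  affine registration in real pipelines. Tissue-boundary placement must
  then be corrected from the DWI itself, which again is only possible
  near the acquired region.

The structural channel encodes the compartments with a T1w-like ordering
(white 0.90, gray 0.55, CSF 0.12) plus independent Gaussian noise:
informative about tissue boundaries, not a copy of the DWI contrast.

What the phantom does *not* emulate: real anatomy (gyri, ventricles),
susceptibility/eddy/motion artifacts, multi-shell schemes, spatially
varying coil sensitivity. Passing the desk-scale study therefore shows
that the pipeline's mechanics and learning signal work end-to-end, not
that clinical-grade quality is reached on real scans.

## Desk-scale study conditions

The bundled experiment (`dwifov.benchmark.run_study`, also behind
`scripts/acceptance.py`) uses 12 training / 3 validation / 5 test
phantoms at 48³, trains each of the four generators (and four ablated
baselines) for 400 steps at batch size 8 with n = 1, truncates test
phantoms by 10 mm from the top, and evaluates the imputed studies
against the ground truth plus two reference-free baselines: zero filling
and nearest-acquired-slice replication. These sizes were chosen once as
a single-CPU desk-scale configuration of the same pipeline that would
run at 256³ with n = 7, batch 24 and the deep generator on a GPU.

## Known limitations and open choices

* The paper-scale intensity convention for MSE is ambiguous in the
  literature this follows; this package standardizes all reported
  metrics on normalized [0, 1] intensities and states the data range in
  every report.
* Equal weighting is used when merging sagittal and coronal predictions,
  and equal loss weight for missing vs acquired target slices; both are
  uncommitted choices in the source design.
* Out-of-volume neighbor slices in a 2.5D stack are zero-filled,
  consistent with the zero padding of the normalized grid.
* The FOV-mask derivation heuristic (all-zero axial slice runs adjacent
  to the brain's z-extremes) assumes truncation is the only source of
  fully zero slices inside the brain's extent.
* At desk scale the adversarial term contributes little before L1
  convergence; the discriminator mostly acts as a regularizer. This
  mirrors the λ = 100 design intent but means desk-scale results probe
  the conditional-regression pathway more than the adversarial one.
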