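# Methods

`sctsynth` implements an MR-to-synthetic-CT (sCT) translation study as a
self-contained, seeded pipeline: a synthetic pelvic phantom cohort stands in
for clinical MRI/CT pairs, three adversarial translation models are trained
and compared, and the resulting sCTs are judged by image, structure and
dosimetric agreement. This note records the models, the assumptions behind
them, and the design choices made where the design was genuinely open.

## Synthetic cohort

Each case is a pair of co-registered 3-D volumes built from one ellipsoid
geometry: body with a subcutaneous fat rim, two femoral heads and a sacrum
block, bladder, prostate, and a rectal balloon (air- or water-filled) wrapped
in a rectal wall. CT values are a per-tissue Hounsfield lookup plus Gaussian
voxel noise, clipped to [−1024, 3071] HU; MR values are a T2-TSE-like lookup
(fluid and fat bright, cortical bone near void) modulated by a smooth
multiplicative bias field (default amplitude 0.15, correlation length 80 mm)
plus noise, clipped at 0. A couch-like slab of ≈0 HU lies outside the body so
body extraction has something to remove.

Default tissue means (HU / MR a.u.): air −1000/20, soft tissue 40/350, fat
−90/750, trabecular bone 700/100, cortical rim 1200/50, bladder 0/900,
prostate 45/430, rectal wall 40/300, balloon fill −1000/20 (air) or 0/880
(water), couch 0/20. The cortical rim and the couch carry their own label
ids so that with all noise switched off the CT is an *exact* per-label
lookup — several tests rely on that property. MR intensity levels are chosen
so that tissues mapping to different HU are separable in MR, i.e. a perfect
translator exists; what makes the task non-trivial is noise, the bias field,
boundary partial-volume mixing and (optionally) misalignment.

Misregistration emulates imperfect MR↔CT alignment: a random rigid motion
(defaults: ≤5 mm translation, ≤3° rotation per axis) composed with a
band-limited elastic displacement (≤3 mm, 40 mm correlation length) is
applied to the MR by resampling; the exact sampling map is stored as ground
truth, and a validity mask tracks which voxels came from inside the original
field of view. Everything is a pure function of (spec, seed).

What the phantom does *not* emulate: anatomically realistic shapes, MR
physics (k-space, T2 decay blurring), metal or motion artifacts,
inter-patient anatomy beyond ellipsoid size/position jitter. Passing tests
therefore demonstrate that the algorithms are implemented correctly and that
the comparison logic behaves as designed — not that any clinical performance
level would be reached on real data.

## Preprocessing

Fixed order, recorded in provenance: resample to a common spacing →
affine-register MR to CT → body mask → intensity normalization → slice
filter → central crop.

- **Resampling** is trilinear (nearest for labels/masks), origin-preserving,
  with out-of-field values −1024 HU (CT) or 0 (MR).
- **Registration** maximizes mutual information (32×32 joint histogram) of
  the CT and the moved MR over the CT body mask, with Powell descent over a
  rigid parameterization on a multi-resolution pyramid (down-sampling
  factors 4 and 2), seeded by the body-centroid offset. Matched-intensity
  MSE is unusable here because T2 contrast is not a monotone function of HU
  (fat and urine are MR-bright at ≤0 HU; bone is MR-dark at +700 HU).
  Volumes are pre-smoothed by 0.7 voxels per level, which suppresses the
  well-known grid-aligned local minima of histogram MI under linear
  interpolation. The elastic residual is deliberately left uncorrected;
  if the optimum fails to improve on identity the result is flagged and
  identity used.
- **Body extraction**: largest 3-D connected component above −300 HU, holes
  filled per slice. −300 HU separates tissue from air robustly and removes
  the couch.
- **Normalization**: CT maps [−1024, 3071] → [−1, 1] affinely (clip first);
  MR subtracts the body mean and divides by 2.5 body standard deviations,
  clipped to [−1, 1]. The CT map is exactly invertible; sCTs are produced by
  the inverse.
- **Slice filter**: a slice is dropped iff strictly more than 5% of its CT
  body voxels lack valid MR data (voxels mapped from inside the original MR
  field of view). Slices without body voxels carry no body information and
  are kept.
- **Crop**: central in-plane crop to the configured size; training uses
  random crops of the same ratio.

## Translation models

All three variants use the same building blocks, written directly on numpy:
a residual encoder–decoder generator (7×7 stem, two stride-2 stages,
residual blocks at 1/4 resolution, nearest-upsample + convolution decoder,
tanh output) and a patch discriminator (four 4×4 convolution stages emitting
a spatial realness map). At full scale (base width 64, 9 blocks) the
generator has ≈11.37 M and the discriminator ≈2.76 M parameters; a `scale`
parameter shrinks width and depth for desk-scale runs. Initialization is
N(0, 0.02), seeded.

Objectives are least-squares adversarial losses. For the CT-domain
discriminator, `E_x (D_CT(x) − 1)² + E_y (D_CT(G_MRI(y)))²`, with the
mirrored MR-domain pair added for the cycle variants; generators minimize
`E_y (D_CT(G_MRI(y)) − 1)²` (+ mirrored term). The variants differ only in
the generator's weighted total:

| variant | total generator objective |
|---|---|
| GAN | 15 · paired MAE + adversarial |
| CycGAN | 10 · cycle consistency + adversarial |
| RgGAN | 10 · cycle + adversarial + 100 · paired (reference) MAE |

The cycle term is the mean absolute reconstruction error averaged over the
two directions (CT→MR→CT and MR→CT→MR). With the reference weight at 0,
RgGAN's update rule degenerates exactly to CycGAN's — a property the tests
assert iteration-for-iteration.

Training is Adam (β₁ = 0.5, β₂ = 0.999), batch 2, learning rate 2·10⁻⁴ held
constant then decayed linearly to 0 (full-scale schedule: 10 + 30 epochs;
desk presets shorten both phases). One discriminator and one generator step
per batch, discriminator first; the generator forward passes are computed
once per iteration and their tapes reused in both updates (the D step does
not touch G parameters, so this is exact). CycGAN consumes the MR and CT
slice pools through independent shuffles (unpaired contract); the paired
terms use the registered pairing with a shared crop per pair. No image pool
and no identity loss, since the objective lists only the terms above.
Training is bit-reproducible for a fixed seed on a fixed platform.

Inference mirrors the protocol: per axial slice, central crop to the
training size → generator → zero-pad back → reassemble the volume →
resample to the reference CT spacing → invert the CT normalization.

## Evaluation

- **Image quality**: ME, MAE (HU) and PSNR over the body mask, PSNR with a
  fixed 4095 HU dynamic range (∞ sentinel for identical images) so values
  are comparable across cases.
- **Structures**: threshold-based auto-contours on CT-like volumes — bone at
  ≥200 HU within the body (small speckle dropped, holes filled), rectal
  balloon as the largest air cavity (≤−400 HU) or, for water fill, the
  largest near-water pocket in the posterior central region; soft tissue is
  the set identity body − bone − balloon. Agreement via Dice and the
  maximum symmetric surface distance (Hausdorff; 6-connectivity surfaces,
  distances in mm via the distance transform; a percentile argument allows
  the 95th-percentile variant, the maximum is the default report).
- **Dose**: a deliberately simple arc surrogate — N equispaced coplanar
  parallel beams shaped to the PTV projection plus margin, each attenuated
  as exp(−μ · water-equivalent depth) with depth from a piecewise-linear
  HU→density map (ρ = 1 + HU/1000 below 100 HU, reduced slope reaching 2.0
  at 1600 HU). Defaults: 24 angles, μ = 0.005/mm, 5 mm margin. The computed
  dose is normalized so the mean PTV dose equals the prescription; an
  explicit scale can be passed instead to emulate fixed monitor units. The
  pipeline's CT-vs-sCT comparison uses the contract's per-volume
  normalization by default (`fixed_plan_scale` switches to the fixed-scale
  recalculation). The engine is deterministic and strictly HU-sensitive; it
  makes no claim of clinical validity (no scatter, no optimization).
- **DVH**: exact sorted-voxel quantiles, no histogram binning. D_x% is the
  dose at descending rank ⌈x/100 · N⌉ (1-based) — the minimum dose of the
  hottest x% of the structure.
- **Gamma**: 3-D global analysis; dose differences normalized to the
  reference maximum, voxels below 10% of it excluded. The search runs over
  the evaluated dose refined trilinearly 3× per axis within a radius of
  3 × DTA, taking the minimum of √((Δdose/(DD%·D_max))² + (d/DTA)²). On
  small grids an exhaustive search over the same candidate set is the test
  oracle and matches exactly. Supported criteria include 3%/2 mm and
  2%/2 mm (defaults) and 3%/3 mm.
- **Statistics**: one-way ANOVA across variants with Bonferroni-adjusted
  pairwise pooled-variance t-tests (α = 0.05 two-sided, p capped at 1;
  degenerate all-equal input reports p = 1 by convention).

## Experiment orchestration and problem sizes

`run_experiment` derives one seed per stage (phantom generation,
misregistration, split, training, evaluation) from a master seed via
`SeedSequence`, so the whole report is a pure function of its config. Splits
are disjoint by construction. Per-case evaluation caches the reference
structures and reference dose so variants are compared against identical
references.

Desk-scale defaults were fixed once as a compute budget, not tuned:
phantom grids of 64–96 voxels in-plane (2.5–4.5 mm voxels, 16–24 slices),
cohorts of 8/2/4 (main comparison) or 4/1/2 (clean parameter recovery),
networks at scale 0.125–0.15 (base width 8–10, 2 residual blocks), 4–12 desk
epochs split evenly between the constant and decay phases, training crops of
56–76 pixels. The optimizer
settings, loss ratios and batch size are never scaled. The full-scale
configuration (86/7/20 cohort, 1.3×1.3×2.5 mm spacing, 384/356 crops,
scale 1 networks, 40 epochs) is expressible through the same configs but is
not exercised by the test suite.

At these sizes the unpaired variant is the slowest learner: CycGAN must
infer the HU mapping through the discriminators and cycle alone, and a few
hundred updates leave visibly more residual error than the paired variants —
which is itself the qualitative ordering the comparison is designed to show.

## Known limitations

- The numpy training engine is single-threaded and desk-scale; it is the
  package's own implementation, exact but not fast, and full-scale training
  is supported in interface only.
- The registration recovers rigid motion (the generator produces rigid +
  elastic); shear/scale components of a general affine are not
  parameterized.
- The dose surrogate ignores scatter, penumbra and inverse optimization;
  gamma and DVH comparisons are meaningful relative to this engine only.
- Slice-axis translations are weakly observable when the body spans the
  whole imaged slab (near-constant cross-section); in-plane components
  recover to a fraction of a voxel.
- The water-filled balloon contour on CT relies on a positional prior (the
  posterior central region), since near-water HU is not unique to it.
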