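# Methods

This note records the model behind `stonect`, the numerical and design
choices that were genuinely open, and what the synthetic validation does
and does not demonstrate.

## The feature pair

A urinary stone on non-enhanced CT is characterized by two point
measurements:

* `maxHU`: the attenuation of the highest-attenuating voxel inside the
  stone mask. Ties are broken toward the lexicographically smallest voxel
  index in `(slice, row, column)` order, so extraction is deterministic.
* `ppLapl`: the output of the scaled Laplacian filter at that voxel. The
  filter computes, at every voxel, the centre value minus a weighted mean
  of the 26 neighbours of the 3×3×3 neighbourhood, with weights normalized
  to sum to one. A constant field therefore maps to 0 HU, and the filter is
  linear with any global offset removed: `L(aV + b) = a·L(V)`.

The neighbour weighting of the filter is not uniquely fixed by its verbal
definition, so two schemes are implemented:

* `inverse_distance` (default): weights proportional to 1, 1/√2, 1/√3 for
  face, edge, and corner neighbours — the standard 27-point discrete
  Laplacian family;
* `uniform`: all 26 neighbours equal.

Neither scheme is claimed to be bit-identical to the original clinical
implementation, whose kernel is unpublished; the filter contract (centre
minus normalized weighted neighbour mean, replicate padding at the volume
border) is what the tests pin down, for both schemes. The neighbourhood is
taken from the full volume, never restricted to the stone mask, which is
what makes `ppLapl` segmentation-independent. Neighbourhoods are evaluated
in voxel units; the features are defined on a 1/1 mm axial reformat, so
anisotropic volumes trigger a warning and can be resampled to 1 mm
isotropic first (`resample_isotropic`).

## Segmentation and size

`segment_stone` grows the 26-connected component of voxels ≥ 130 HU (a
conventional minimum stone attenuation, configurable) around a seed,
clipped to a 40 mm cube centred on the seed; a component touching the clip
boundary is flagged as possibly truncated. Because the features are point
estimates, the exact boundary hardly matters — the mask only determines
where the peak is searched.

Stone size is the largest axial diameter: per slice, the maximum pairwise
distance between member-voxel footprint extremes (voxel centre ± half a
voxel along each in-plane axis), maximized over slices. A single voxel at
1 mm spacing measures 1.0 mm, matching how a caliper measurement of one
voxel would read.

## Predictors

* Rigid cutoffs: non-UA iff `maxHU ≥ 1000` or `ppLapl ≥ 195` (both HU). On
  the lines the call is non-UA; the UA region is the open rectangle below
  both cutoffs.
* maxHU-only: UA iff `maxHU < 745` (strict).
* kNN: majority vote among the k = 9 Euclidean-nearest training points in
  the raw (maxHU, ppLapl) plane. k is required to be odd, so a binary vote
  cannot tie; exact distance ties at the k-th rank are broken by training-
  point insertion order (a stable sort), making the vote deterministic.
  Feature standardization before the distance is available but off by
  default: both axes are in HU, and the reference behaviour uses raw
  distances. The annotated clinical training set behind the published kNN
  model is not public, so the package ships a CSV loader for user-supplied
  training data and a surrogate generator (below); results on the surrogate
  are plausible stand-ins, not reproductions of the clinical model.

## Evaluation statistics

UA is the positive class. Mixed-composition reference stones are excluded
before counting (they have no reliable reference standard); predictors
never output MIXED. Sensitivity, specificity, and accuracy carry exact
Clopper–Pearson binomial confidence intervals (the "exact" choice keeps
coverage at or above the nominal level for every true proportion, which a
test verifies by simulation). Reported percentages are rounded half-up
through an intermediate one-decimal step (81.47 → 81.5 → 82), the
convention of common clinical-statistics software; raw proportions are kept
internally.

Paired predictors are compared with McNemar's test on the discordant
counts b and c; the default is the exact two-sided binomial form
`p = min(1, 2·P(X ≤ min(b,c)))` with `X ~ Bin(b+c, ½)` (p = 1 when
b = c = 0), with mid-p and continuity-corrected χ² variants available.
AUC is the Mann–Whitney statistic with midrank tie handling; the natural
scores are the kNN UA vote fraction and the negated maxHU. The rigid
two-cutoff rule has no continuous score, so no AUC is defined for it.

## Synthetic phantoms

`generate_phantom` renders one ellipsoidal stone into a soft-tissue
background (30 HU): a **flat** profile at the target peak (the low
peak-to-neighbourhood contrast typical of UA stones) or a **peaked**
quadratic cap `v(x) = peak − a·|x − x₀|²` clipped to the background. The
curvature is calibrated analytically: for a quadratic profile the filter
response at the peak is `a · Σₙ wₙ|dₙ|²`, so a target ppLapl maps directly
to a curvature. The stone is convolved with a Gaussian PSF (σ = 0.6 mm,
a realistic reconstruction-kernel width for a 1 mm abdominal reformat) and
Gaussian noise is added (σ = 15 HU, typical for thin-slice low-dose
abdominal CT). Everything is driven by one seed; identical specs give
bit-identical volumes.

`generate_training_set` draws labelled (maxHU, ppLapl) pairs from truncated
bivariate normal distributions (rejection sampling) whose class-wise means,
SDs, ranges, and default counts (22 UA, 104 non-UA) emulate published
clinical stone cohorts: UA maxHU 537 ± 155 HU in [223, 794], ppLapl
122 ± 39 HU in [47, 212]; non-UA maxHU 1286 ± 292 HU in [536, 1796], ppLapl
282 ± 96 HU in [51, 546]. The within-class feature correlation is not
published; 0.6 is the default (both features grow with mineral density) and
is varied in tests. Truncation shifts the realized means by a few HU from
the nominal values; the tests account for this.

`simulate_cohort` ties everything together: per stone it samples feature
and size targets from the class distributions (sizes: UA 7.3 ± 4.1 mm in
[3, 19], non-UA 6.3 ± 2.5 mm in [3, 15]), renders a quadratic-cap phantom
whose curvature encodes the sampled ppLapl (UA stones come out nearly
flat), applies a two-iteration render → measure → correct calibration so
the noise-free extracted features hit the targets, adds noise, re-segments
the stone from a central seed, and extracts the features. Default cohort
size is 37 UA + 106 non-UA. At the boundary of the feasible range (a very
low-attenuation stone cannot support an arbitrarily large peak contrast
over a 30 HU background) the calibration saturates; the affected draws
remain far from the decision cutoffs.

### What the simulation shows — and does not

The phantoms demonstrate that the pipeline is self-consistent: features
extracted from rendered, blurred, noisy, re-segmented stones recover the
generating distributions well enough that the rigid-cutoff predictor
attains ≥ 90% accuracy against generator truth (typically 92–96% across
seeds), and the score-based predictors reach AUC ≈ 0.99. They are
feature-level emulations: real stones have irregular shapes, internal
laminations, partial-volume and beam-hardening effects, and a joint
(maxHU, ppLapl) distribution known only through its first two moments.
Passing the synthetic tests validates the implementation and the
plausibility of the decision geometry, not clinical performance on any
scanner.

## Numerical choices and edge cases

* Replicate padding everywhere a neighbourhood leaves the volume; a peak on
  the volume border is legal but flagged.
* Segmentation requires the seed to sit at or above the threshold,
  otherwise it errors with an instruction to re-seed.
* Zero metric denominators (e.g. sensitivity with no positive stones) are
  flagged as undefined, never silently dropped.
* AUC with a single class present is rejected rather than returned as NaN.
* All generators take explicit seeds; no global random state is used or
  mutated.
* CLI exit codes: 0 success, 2 validation error, 3 I/O error. Machine-
  readable outputs are byte-identical across reruns with the same inputs
  and configuration; every report logs a hash of the configuration.

## Known limitations

* The original filter kernel and training data are unpublished; both weight
  schemes and the surrogate training set are documented approximations.
* The quadratic-cap stone model cannot represent hollow or laminated
  stones, and the truncated-normal feature model is an approximation of an
  unknown empirical joint distribution.
* Classification is strictly binary (UA vs non-UA); mixed stones are out of
  scope by design, mirroring the lack of a reliable in vivo reference for
  them.
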