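"""Synthetic CT phantoms and surrogate feature data with known ground truth.

Three generators make the whole pipeline testable without clinical images:

* :func:`generate_phantom` renders a single ellipsoidal stone into a small
  HU volume — a flat internal profile (typical of uric acid stones, whose
  peak-to-neighbourhood contrast is low) or a centre-peaked quadratic-cap
  profile (calcium-like stones, high contrast) — convolves it with a
  Gaussian point-spread function and adds Gaussian noise;
* :func:`generate_training_set` draws surrogate labelled (maxHU, ppLapl)
  points from truncated bivariate normal distributions whose class-wise
  moments and ranges follow published clinical stone cohorts;
* :func:`simulate_cohort` combines the two: it samples per-stone feature
  targets, renders a phantom calibrated to hit them, and runs segmentation
  and feature extraction end to end, returning a labelled feature table.

Everything is seed-deterministic; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .classify import StoneLabel, TrainingSet
from .errors import ValidationError
from .features import extract_features
from .filters import LaplacianKernel
from .segment import segment_stone
from .volume import CTVolume, StoneMask

__all__ = [
    "StonePhantomSpec",
    "ClassFeatureSpec",
    "FeatureDistributionSpec",
    "UA_FEATURES",
    "NON_UA_FEATURES",
    "generate_phantom",
    "generate_training_set",
    "simulate_cohort",
]


# ------------------------------------------------------------------ phantoms
@dataclass(frozen=True)
class StonePhantomSpec:
    """Everything needed to render one stone phantom deterministically.

    ``profile`` is ``"flat"`` (constant ``peak_hu`` inside the stone) or
    ``"peaked"`` (quadratic cap falling from ``peak_hu`` at the centre with
    a curvature chosen so the noise-free, unblurred filter response at the
    peak equals ``pp_lapl_hu``). ``None`` picks flat for UA and peaked for
    non-UA. Attenuations in HU, lengths in mm.
    """

    composition: StoneLabel = StoneLabel.NON_UA
    peak_hu: float | None = None  # default: class-typical peak
    pp_lapl_hu: float | None = None  # target peak contrast for "peaked"
    profile: str | None = None
    diameter_mm: float = 8.0
    background_hu: float = 30.0  # soft tissue
    blur_sigma_mm: float = 0.6  # reconstruction PSF width
    noise_sigma_hu: float = 15.0
    shape: tuple[int, int, int] | None = None  # default: diameter + 12 mm margin
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axis_ratio: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.composition not in (StoneLabel.UA, StoneLabel.NON_UA):
            raise ValidationError("phantom composition must be UA or NON_UA")
        if not 3.0 <= self.diameter_mm <= 20.0:
            raise ValidationError(
                f"diameter {self.diameter_mm} mm outside the 3-20 mm inclusion range"
            )
        if self.profile not in (None, "flat", "peaked"):
            raise ValidationError("profile must be 'flat' or 'peaked'")
        if self.blur_sigma_mm < 0 or self.noise_sigma_hu < 0:
            raise ValidationError("blur and noise sigmas must be >= 0")
        if any(r <= 0 or r > 1.0 for r in self.axis_ratio):
            raise ValidationError("axis_ratio entries must be in (0, 1]")
        if self.resolved_peak_hu() <= self.background_hu:
            raise ValidationError("peak attenuation must exceed the background")

    def resolved_peak_hu(self) -> float:
        if self.peak_hu is not None:
            return self.peak_hu
        return 537.0 if self.composition is StoneLabel.UA else 1286.0

    def resolved_profile(self) -> str:
        if self.profile is not None:
            return self.profile
        return "flat" if self.composition is StoneLabel.UA else "peaked"

    def resolved_pp_lapl(self) -> float:
        if self.pp_lapl_hu is not None:
            return self.pp_lapl_hu
        return 122.0 if self.composition is StoneLabel.UA else 282.0

    def resolved_shape(self) -> tuple[int, int, int]:
        if self.shape is not None:
            return self.shape
        return tuple(
            int(np.ceil(self.diameter_mm / s)) + 2 * int(np.ceil(6.0 / s))
            for s in self.spacing
        )


def _render_noise_free(
    spec: StonePhantomSpec, peak_hu: float, curvature: float
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic part of the phantom: profile, ellipsoid support, PSF blur."""
    shape = spec.resolved_shape()
    semi = [
        (spec.diameter_mm / 2.0) * r for r in spec.axis_ratio
    ]  # semi-axes in mm
    if any(2 * a < s for a, s in zip(semi, spec.spacing)) or any(
        int(np.ceil(2 * a / s)) > dim for a, s, dim in zip(semi, spec.spacing, shape)
    ):
        raise ValidationError("stone does not fit the phantom volume")
    centre = [dim // 2 for dim in shape]
    grids = np.meshgrid(
        *[(np.arange(dim) - c) * s for dim, c, s in zip(shape, centre, spec.spacing)],
        indexing="ij",
    )
    d2_mm = sum(g**2 for g in grids)
    rho2 = sum((g / a) ** 2 for g, a in zip(grids, semi))
    inside = rho2 <= 1.0

    values = np.full(shape, spec.background_hu, dtype=np.float64)
    profile = peak_hu - curvature * d2_mm
    values[inside] = np.maximum(profile[inside], spec.background_hu)

    if spec.blur_sigma_mm > 0:
        sigma_vox = [spec.blur_sigma_mm / s for s in spec.spacing]
        values = ndimage.gaussian_filter(values, sigma=sigma_vox, mode="nearest")
    return values, inside


def generate_phantom(
    spec: StonePhantomSpec, kernel: LaplacianKernel | None = None
) -> tuple[CTVolume, StoneMask, StoneLabel]:
    """Render one stone phantom; returns (volume, ground-truth mask, label).

    The ground-truth mask is the noise-free ellipsoid support. Identical
    specs yield bit-identical volumes.
    """
    kernel = kernel or LaplacianKernel()
    peak = spec.resolved_peak_hu()
    if spec.resolved_profile() == "flat":
        curvature = 0.0
    else:
        # HU/mm^2 curvature whose filter response at the peak voxel equals
        # the ppLapl target (before blur): a = ppLapl / sum_n w_n |d_n|^2.
        curvature = spec.resolved_pp_lapl() / kernel.mean_sq_neighbor_distance(spec.spacing)
    values, inside = _render_noise_free(spec, peak, curvature)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma_hu > 0:
        values = values + rng.normal(0.0, spec.noise_sigma_hu, size=values.shape)
    volume = CTVolume(values=values, spacing=spec.spacing)
    mask = StoneMask(mask=inside, truncated=False, spacing=spec.spacing)
    return volume, mask, spec.composition


# ----------------------------------------------------- feature distributions
@dataclass(frozen=True)
class ClassFeatureSpec:
    """Truncated-normal moments of (maxHU, ppLapl) for one stone class."""

    mean_max_hu: float
    sd_max_hu: float
    range_max_hu: tuple[float, float]
    mean_pp_lapl: float
    sd_pp_lapl: float
    range_pp_lapl: tuple[float, float]
    mean_size_mm: float = 6.5
    sd_size_mm: float = 3.0
    range_size_mm: tuple[float, float] = (3.0, 19.0)
    n: int = 1

    def __post_init__(self) -> None:
        for mean, (lo, hi), what in (
            (self.mean_max_hu, self.range_max_hu, "maxHU"),
            (self.mean_pp_lapl, self.range_pp_lapl, "ppLapl"),
            (self.mean_size_mm, self.range_size_mm, "size"),
        ):
            if not lo < hi:
                raise ValidationError(f"empty truncation range for {what}")
            if not lo <= mean <= hi:
                raise ValidationError(f"{what} truncation range must contain the mean")
        if self.n < 1:
            raise ValidationError("class count must be >= 1")


#: Class-wise feature moments emulating clinical UA / non-UA stone cohorts.
UA_FEATURES = ClassFeatureSpec(
    mean_max_hu=537.0,
    sd_max_hu=155.0,
    range_max_hu=(223.0, 794.0),
    mean_pp_lapl=122.0,
    sd_pp_lapl=39.0,
    range_pp_lapl=(47.0, 212.0),
    mean_size_mm=7.3,
    sd_size_mm=4.1,
    range_size_mm=(3.0, 19.0),
    n=22,
)
NON_UA_FEATURES = ClassFeatureSpec(
    mean_max_hu=1286.0,
    sd_max_hu=292.0,
    range_max_hu=(536.0, 1796.0),
    mean_pp_lapl=282.0,
    sd_pp_lapl=96.0,
    range_pp_lapl=(51.0, 546.0),
    mean_size_mm=6.3,
    sd_size_mm=2.5,
    range_size_mm=(3.0, 15.0),
    n=104,
)


@dataclass(frozen=True)
class FeatureDistributionSpec:
    """Joint feature model: one :class:`ClassFeatureSpec` per class plus the
    within-class maxHU-ppLapl correlation (both features grow with mineral
    density, hence the positive default)."""

    ua: ClassFeatureSpec = field(default_factory=lambda: UA_FEATURES)
    non_ua: ClassFeatureSpec = field(default_factory=lambda: NON_UA_FEATURES)
    correlation: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not -0.999 <= self.correlation <= 0.999:
            raise ValidationError("correlation must lie in (-1, 1)")


def _sample_truncated_bivariate(
    rng: np.random.Generator, cls: ClassFeatureSpec, rho: float, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample n correlated (maxHU, ppLapl) pairs within their ranges."""
    chol = np.linalg.cholesky([[1.0, rho], [rho, 1.0]])
    out_mh = np.empty(n)
    out_pl = np.empty(n)
    got = 0
    for _ in range(10_000):
        batch = max(4 * (n - got), 64)
        z = rng.standard_normal((batch, 2)) @ chol.T
        mh = cls.mean_max_hu + cls.sd_max_hu * z[:, 0]
        pl = cls.mean_pp_lapl + cls.sd_pp_lapl * z[:, 1]
        ok = (
            (mh >= cls.range_max_hu[0])
            & (mh <= cls.range_max_hu[1])
            & (pl >= cls.range_pp_lapl[0])
            & (pl <= cls.range_pp_lapl[1])
        )
        take = min(int(ok.sum()), n - got)
        out_mh[got : got + take] = mh[ok][:take]
        out_pl[got : got + take] = pl[ok][:take]
        got += take
        if got == n:
            return out_mh, out_pl
    raise ValidationError("truncation ranges reject nearly all draws")


def _sample_truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    out = np.empty(n)
    got = 0
    for _ in range(10_000):
        x = rng.normal(mean, sd, size=max(4 * (n - got), 64))
        x = x[(x >= lo) & (x <= hi)]
        take = min(x.size, n - got)
        out[got : got + take] = x[:take]
        got += take
        if got == n:
            return out
    raise ValidationError("truncation range rejects nearly all draws")


def generate_training_set(
    spec: FeatureDistributionSpec | None = None,
) -> TrainingSet:
    """Surrogate labelled training set for the kNN predictor.

    Stands in for the annotated reference dataset (22 UA + 104 non-UA
    stones by default), which is not public; claims plausibility, not
    identity.
    """
    spec = spec or FeatureDistributionSpec()
    rng = np.random.default_rng(spec.seed)
    mh_ua, pl_ua = _sample_truncated_bivariate(rng, spec.ua, spec.correlation, spec.ua.n)
    mh_non, pl_non = _sample_truncated_bivariate(
        rng, spec.non_ua, spec.correlation, spec.non_ua.n
    )
    labels = [StoneLabel.UA] * spec.ua.n + [StoneLabel.NON_UA] * spec.non_ua.n
    return TrainingSet(
        max_hu=np.concatenate([mh_ua, mh_non]),
        pp_lapl=np.concatenate([pl_ua, pl_non]),
        labels=labels,
        provenance="surrogate",
    )


# ------------------------------------------------------------------- cohorts
def _calibrated_phantom(
    target_mh: float,
    target_pl: float,
    size_mm: float,
    composition: StoneLabel,
    seed: int,
    kernel: LaplacianKernel,
    blur_sigma_mm: float,
    noise_sigma_hu: float,
) -> tuple[CTVolume, StoneMask]:
    """Render a quadratic-cap stone whose extracted noise-free features hit
    the sampled targets, then add noise.

    The PSF blur lowers the rendered peak and flattens the cap, so a fixed
    number of render -> measure -> correct iterations adjusts the rendered
    peak and curvature before the noisy realization is produced.
    """
    base = StonePhantomSpec(
        composition=composition,
        peak_hu=target_mh,
        pp_lapl_hu=target_pl,
        profile="peaked",
        diameter_mm=size_mm,
        blur_sigma_mm=blur_sigma_mm,
        noise_sigma_hu=0.0,
        seed=seed,
    )
    peak, pplapl = target_mh, target_pl
    for _ in range(2):
        spec = replace(base, peak_hu=peak, pp_lapl_hu=pplapl)
        vol, mask, _ = generate_phantom(spec, kernel)
        feats = extract_features(vol, mask, kernel, with_size=False)
        peak += target_mh - feats.max_hu
        if feats.pp_lapl > 1e-6:
            pplapl = min(5.0 * target_pl, pplapl * target_pl / feats.pp_lapl)
        if peak <= base.background_hu + 1.0:
            peak = base.background_hu + 1.0
            break
    final = replace(base, peak_hu=peak, pp_lapl_hu=pplapl, noise_sigma_hu=noise_sigma_hu)
    vol, mask, _ = generate_phantom(final, kernel)
    return vol, mask


def simulate_cohort(
    n_ua: int = 37,
    n_non_ua: int = 106,
    seed: int = 0,
    features: FeatureDistributionSpec | None = None,
    kernel: LaplacianKernel | None = None,
    blur_sigma_mm: float = 0.6,
    noise_sigma_hu: float = 15.0,
    segmentation_threshold_hu: float = 130.0,
) -> pd.DataFrame:
    """End-to-end simulated stone cohort: phantoms -> segmentation ->
    feature extraction -> labelled feature table.

    Per stone, (maxHU, ppLapl, size) targets are drawn from the class
    feature distributions, a calibrated phantom is rendered, the stone is
    re-segmented from a central seed, and the measured features are
    tabulated next to the generator's ground truth. Fully reproducible from
    ``seed``.
    """
    if n_ua < 1 or n_non_ua < 1:
        raise ValidationError("both classes need at least one stone")
    features = features or FeatureDistributionSpec()
    kernel = kernel or LaplacianKernel()
    rng = np.random.default_rng(seed)

    plan: list[tuple[StoneLabel, ClassFeatureSpec, int]] = [
        (StoneLabel.UA, features.ua, n_ua),
        (StoneLabel.NON_UA, features.non_ua, n_non_ua),
    ]
    rows = []
    stone_idx = 0
    for label, cls, n in plan:
        mh, pl = _sample_truncated_bivariate(rng, cls, features.correlation, n)
        size = _sample_truncated_normal(
            rng, cls.mean_size_mm, cls.sd_size_mm, *cls.range_size_mm, n
        )
        for i in range(n):
            phantom_seed = int(rng.integers(0, 2**31 - 1))
            vol, _truth_mask = _calibrated_phantom(
                float(mh[i]),
                float(pl[i]),
                float(size[i]),
                label,
                phantom_seed,
                kernel,
                blur_sigma_mm,
                noise_sigma_hu,
            )
            centre = tuple(dim // 2 for dim in vol.shape)
            mask = segment_stone(vol, centre, threshold=segmentation_threshold_hu)
            feats = extract_features(vol, mask, kernel)
            rows.append(
                {
                    "stone_id": f"S{stone_idx:04d}",
                    "reference": label.value,
                    "max_hu": feats.max_hu,
                    "pp_lapl": feats.pp_lapl,
                    "size_mm": feats.size_mm,
                    "target_max_hu": float(mh[i]),
                    "target_pp_lapl": float(pl[i]),
                    "target_size_mm": float(size[i]),
                }
            )
            stone_idx += 1
    return pd.DataFrame(rows)
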