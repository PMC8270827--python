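"""The three UA / non-UA predictors on the (maxHU, ppLapl) plane.

* rigid cutoffs: non-UA iff maxHU >= 1000 HU or ppLapl >= 195 HU — the UA
  region is the open axis-aligned rectangle below both cutoffs;
* maxHU only: UA iff maxHU < 745 HU;
* k-nearest-neighbours (k = 9, Euclidean distance) majority vote against a
  labelled training set, which yields a smooth curved decision boundary
  instead of the rectangle.

Stones sitting exactly on a cutoff line classify as non-UA (the ``>=``
convention). All predictors are deterministic; kNN breaks exact distance
ties at the k-th rank by training-point insertion order.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError
from .features import StoneFeatures

__all__ = [
    "StoneLabel",
    "CutoffConfig",
    "KnnConfig",
    "TrainingSet",
    "classify_cutoff",
    "classify_maxhu",
    "classify_knn",
    "knn_ua_fraction",
    "decision_map",
]


class StoneLabel(str, Enum):
    """Reference / predicted stone composition.

    ``MIXED`` (20-80% uric acid fraction) is only meaningful as a reference
    label; predictors never output it and evaluation excludes it.
    """

    UA = "UA"
    NON_UA = "NON_UA"
    MIXED = "MIXED"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


def _as_pair(features: StoneFeatures | Sequence[float]) -> tuple[float, float]:
    if isinstance(features, StoneFeatures):
        return features.as_pair()
    pair = tuple(float(v) for v in features)
    if len(pair) != 2:
        raise ValidationError("expected StoneFeatures or a (max_hu, pp_lapl) pair")
    if not all(np.isfinite(pair)):
        raise ValidationError(f"non-finite feature values {pair}")
    return pair


@dataclass(frozen=True)
class CutoffConfig:
    """Decision thresholds of the two rigid-cutoff predictors, in HU."""

    pp_lapl_cut: float = 195.0
    max_hu_cut: float = 1000.0
    max_hu_only_cut: float = 745.0

    def __post_init__(self) -> None:
        for name in ("pp_lapl_cut", "max_hu_cut", "max_hu_only_cut"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class KnnConfig:
    """k-nearest-neighbour settings.

    ``k`` must be odd so a binary majority vote can never tie.
    ``standardize`` z-scores both features with the training moments before
    computing distances (off by default: both features are in HU, so raw
    Euclidean distance is already meaningful).
    """

    k: int = 9
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValidationError(f"k must be a positive odd integer, got {self.k}")


@dataclass
class TrainingSet:
    """Labelled (maxHU, ppLapl) points backing the kNN predictor."""

    max_hu: np.ndarray
    pp_lapl: np.ndarray
    labels: np.ndarray  # array of StoneLabel
    provenance: str = "user-supplied"  # or "surrogate"

    def __post_init__(self) -> None:
        self.max_hu = np.asarray(self.max_hu, dtype=np.float64)
        self.pp_lapl = np.asarray(self.pp_lapl, dtype=np.float64)
        self.labels = np.asarray(
            [StoneLabel(l) for l in np.ravel(self.labels)], dtype=object
        )
        n = len(self.labels)
        if self.max_hu.shape != (n,) or self.pp_lapl.shape != (n,):
            raise ValidationError("training feature/label lengths differ")
        if not (np.all(np.isfinite(self.max_hu)) and np.all(np.isfinite(self.pp_lapl))):
            raise ValidationError("training set contains non-finite features")
        if any(l is StoneLabel.MIXED for l in self.labels):
            raise ValidationError("MIXED labels are not allowed in a training set")
        present = {l for l in self.labels}
        if present != {StoneLabel.UA, StoneLabel.NON_UA}:
            raise ValidationError("training set must contain both UA and NON_UA points")

    def __len__(self) -> int:
        return len(self.labels)

    # ----------------------------------------------------------------- I/O
    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "user-supplied") -> "TrainingSet":
        try:
            df = pd.read_csv(path)
        except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise InputError(f"cannot read training CSV {path!s}: {exc}") from exc
        missing = {"max_hu", "pp_lapl", "label"} - set(df.columns)
        if missing:
            raise ValidationError(f"training CSV {path!s} lacks columns {sorted(missing)}")
        return cls(
            max_hu=df["max_hu"].to_numpy(),
            pp_lapl=df["pp_lapl"].to_numpy(),
            labels=df["label"].to_numpy(),
            provenance=provenance,
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "max_hu": self.max_hu,
                "pp_lapl": self.pp_lapl,
                "label": [l.value for l in self.labels],
            }
        ).to_csv(path, index=False)


# ---------------------------------------------------------------- predictors
def classify_cutoff(
    features: StoneFeatures | Sequence[float], config: CutoffConfig = CutoffConfig()
) -> StoneLabel:
    """Rigid two-cutoff rule: non-UA iff maxHU >= cut or ppLapl >= cut."""
    max_hu, pp_lapl = _as_pair(features)
    if max_hu >= config.max_hu_cut or pp_lapl >= config.pp_lapl_cut:
        return StoneLabel.NON_UA
    return StoneLabel.UA


def classify_maxhu(
    features: StoneFeatures | Sequence[float] | float,
    config: CutoffConfig = CutoffConfig(),
) -> StoneLabel:
    """Single-feature rule: UA iff maxHU < the maxHU-only cutoff (strict)."""
    if isinstance(features, (int, float, np.floating)):
        max_hu = float(features)
        if not np.isfinite(max_hu):
            raise ValidationError("non-finite maxHU")
    else:
        max_hu, _ = _as_pair(features)
    return StoneLabel.UA if max_hu < config.max_hu_only_cut else StoneLabel.NON_UA


def _knn_votes(
    max_hu: float, pp_lapl: float, train: TrainingSet, config: KnnConfig
) -> np.ndarray:
    if config.k > len(train):
        raise ValidationError(
            f"k={config.k} exceeds the training set size {len(train)}"
        )
    mh, pl = train.max_hu, train.pp_lapl
    q = np.array([max_hu, pp_lapl])
    if config.standardize:
        mu = np.array([mh.mean(), pl.mean()])
        sd = np.array([mh.std(ddof=0), pl.std(ddof=0)])
        sd[sd == 0] = 1.0
        d2 = ((mh - mu[0]) / sd[0] - (q[0] - mu[0]) / sd[0]) ** 2 + (
            (pl - mu[1]) / sd[1] - (q[1] - mu[1]) / sd[1]
        ) ** 2
    else:
        d2 = (mh - q[0]) ** 2 + (pl - q[1]) ** 2
    order = np.argsort(d2, kind="stable")  # stable: insertion order breaks ties
    return train.labels[order[: config.k]]


def classify_knn(
    features: StoneFeatures | Sequence[float],
    train: TrainingSet,
    config: KnnConfig = KnnConfig(),
) -> StoneLabel:
    """Majority vote among the k nearest training stones (Euclidean)."""
    max_hu, pp_lapl = _as_pair(features)
    votes = _knn_votes(max_hu, pp_lapl, train, config)
    n_ua = sum(1 for v in votes if v is StoneLabel.UA)
    return StoneLabel.UA if n_ua * 2 > len(votes) else StoneLabel.NON_UA


def knn_ua_fraction(
    features: StoneFeatures | Sequence[float],
    train: TrainingSet,
    config: KnnConfig = KnnConfig(),
) -> float:
    """Fraction of UA votes among the k nearest neighbours (a UA score in [0, 1])."""
    max_hu, pp_lapl = _as_pair(features)
    votes = _knn_votes(max_hu, pp_lapl, train, config)
    return sum(1 for v in votes if v is StoneLabel.UA) / len(votes)


# ---------------------------------------------------------------- maps
def decision_map(
    predictor: Callable[[tuple[float, float]], StoneLabel],
    max_hu_values: Sequence[float],
    pp_lapl_values: Sequence[float],
) -> np.ndarray:
    """Evaluate a predictor on a rectangular feature grid.

    Returns an object array of :class:`StoneLabel` with shape
    ``(len(max_hu_values), len(pp_lapl_values))``; entry ``[i, j]`` is the
    prediction at ``(max_hu_values[i], pp_lapl_values[j])``. Suitable for
    rendering the decision regions of any of the three predictors.
    """
    mh = np.asarray(max_hu_values, dtype=float)
    pl = np.asarray(pp_lapl_values, dtype=float)
    if mh.size == 0 or pl.size == 0:
        raise ValidationError("decision_map: empty grid")
    out = np.empty((mh.size, pl.size), dtype=object)
    for i, x in enumerate(mh):
        for j, y in enumerate(pl):
            out[i, j] = predictor((float(x), float(y)))
    return out
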