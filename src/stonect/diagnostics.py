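"""Diagnostic-accuracy statistics for the UA / non-UA predictors.

Cross-tabulation against the reference standard (UA is the positive
class; MIXED reference stones are excluded before counting), sensitivity /
specificity / accuracy with exact Clopper-Pearson binomial confidence
intervals, an exact McNemar test for paired predictor comparison, and
ROC / AUC over a continuous UA score.

Reported percentages are rounded half-up in two stages (raw value -> one
decimal -> integer), the convention of common clinical-statistics output;
raw proportions are kept unrounded internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats

from .classify import StoneLabel
from .errors import ValidationError

__all__ = [
    "ConfusionMatrix2x2",
    "Proportion",
    "DiagnosticReport",
    "cross_tabulate",
    "diagnostic_metrics",
    "exact_binomial_ci",
    "mcnemar_exact",
    "mcnemar_between",
    "roc_auc",
    "round_percent",
]


def round_percent(proportion: float) -> int:
    """Proportion -> integer percent, half-up via an intermediate decimal.

    E.g. 0.8147 -> 81.47 -> 81.5 -> 82.
    """
    if not np.isfinite(proportion):
        raise ValidationError("cannot round a non-finite proportion")
    one_dp = Decimal(repr(float(100.0 * proportion))).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return int(one_dp.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Counts of a binary classification, with UA as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def _coerce_labels(values: Sequence, what: str) -> list[StoneLabel]:
    try:
        return [StoneLabel(v) for v in values]
    except ValueError as exc:
        raise ValidationError(f"invalid {what} label: {exc}") from exc


def cross_tabulate(predictions: Sequence, references: Sequence) -> ConfusionMatrix2x2:
    """Count the 2x2 table of predictions against references.

    Inputs are aligned per stone. MIXED reference stones are removed before
    counting; a MIXED prediction is a contract violation.
    """
    preds = _coerce_labels(predictions, "prediction")
    refs = _coerce_labels(references, "reference")
    if len(preds) != len(refs):
        raise ValidationError(
            f"{len(preds)} predictions vs {len(refs)} references"
        )
    if any(p is StoneLabel.MIXED for p in preds):
        raise ValidationError("predictors never output MIXED")
    tp = fn = fp = tn = 0
    for p, r in zip(preds, refs):
        if r is StoneLabel.MIXED:
            continue
        if r is StoneLabel.UA:
            tp += p is StoneLabel.UA
            fn += p is StoneLabel.NON_UA
        else:
            fp += p is StoneLabel.UA
            tn += p is StoneLabel.NON_UA
    return ConfusionMatrix2x2(tp=int(tp), fn=int(fn), fp=int(fp), tn=int(tn))


def exact_binomial_ci(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Clopper-Pearson exact confidence interval for a binomial proportion."""
    if trials < 1 or not 0 <= successes <= trials:
        raise ValidationError(f"invalid counts {successes}/{trials}")
    if not 0 < confidence < 1:
        raise ValidationError("confidence must be in (0, 1)")
    ci = stats.binomtest(successes, trials).proportion_ci(
        confidence_level=confidence, method="exact"
    )
    return (float(ci.low), float(ci.high))


@dataclass(frozen=True)
class Proportion:
    """A proportion with its counts and exact confidence interval."""

    numerator: int
    denominator: int
    ci_low: float
    ci_high: float

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def value(self) -> float:
        return self.numerator / self.denominator if self.defined else float("nan")

    @property
    def percent(self) -> int:
        if not self.defined:
            raise ValidationError("metric undefined: zero denominator")
        return round_percent(self.value)

    @property
    def ci_percent(self) -> tuple[int, int]:
        if not self.defined:
            raise ValidationError("metric undefined: zero denominator")
        return (round_percent(self.ci_low), round_percent(self.ci_high))


@dataclass(frozen=True)
class DiagnosticReport:
    """Sensitivity / specificity / accuracy of UA prediction with exact CIs."""

    sensitivity: Proportion
    specificity: Proportion
    accuracy: Proportion
    confusion: ConfusionMatrix2x2
    confidence: float = 0.95

    def to_dict(self) -> dict:
        def prop(p: Proportion) -> dict:
            d = {
                "numerator": p.numerator,
                "denominator": p.denominator,
                "defined": p.defined,
            }
            if p.defined:
                d.update(
                    value=p.value,
                    percent=p.percent,
                    ci=[p.ci_low, p.ci_high],
                    ci_percent=list(p.ci_percent),
                )
            return d

        cm = self.confusion
        return {
            "confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
            "confidence": self.confidence,
            "sensitivity": prop(self.sensitivity),
            "specificity": prop(self.specificity),
            "accuracy": prop(self.accuracy),
        }


def _proportion(num: int, den: int, confidence: float) -> Proportion:
    if den == 0:
        return Proportion(num, den, float("nan"), float("nan"))
    lo, hi = exact_binomial_ci(num, den, confidence)
    return Proportion(num, den, lo, hi)


def diagnostic_metrics(
    cm: ConfusionMatrix2x2, confidence: float = 0.95
) -> DiagnosticReport:
    """Sensitivity tp/(tp+fn), specificity tn/(tn+fp), accuracy, with CIs.

    A zero denominator leaves that metric flagged undefined rather than
    silently dropped.
    """
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    return DiagnosticReport(
        sensitivity=_proportion(cm.tp, cm.tp + cm.fn, confidence),
        specificity=_proportion(cm.tn, cm.tn + cm.fp, confidence),
        accuracy=_proportion(cm.tp + cm.tn, cm.total, confidence),
        confusion=cm,
        confidence=confidence,
    )


def mcnemar_exact(b: int, c: int, method: str = "exact") -> float:
    """McNemar test p-value from the two discordant-pair counts.

    ``b`` and ``c`` count stones classified differently by the two paired
    predictors. Methods: ``exact`` (two-sided binomial, p = min(1,
    2 P(X <= min(b, c))) with X ~ Bin(b+c, 1/2)), ``midp`` (exact minus half
    the central term), ``chi2_cc`` (continuity-corrected chi-square).
    """
    if b < 0 or c < 0:
        raise ValidationError("discordant counts must be >= 0")
    n = b + c
    if n == 0:
        return 1.0
    m = min(b, c)
    if method == "exact":
        return min(1.0, 2.0 * float(stats.binom.cdf(m, n, 0.5)))
    if method == "midp":
        p = 2.0 * float(stats.binom.cdf(m, n, 0.5)) - float(stats.binom.pmf(m, n, 0.5))
        return min(1.0, p)
    if method == "chi2_cc":
        statistic = (abs(b - c) - 1) ** 2 / n
        return float(stats.chi2.sf(statistic, df=1))
    raise ValidationError(f"unknown McNemar method {method!r}")


def mcnemar_between(
    pred_a: Sequence, pred_b: Sequence, references: Sequence, method: str = "exact"
) -> tuple[int, int, float]:
    """Discordant counts and McNemar p for two predictors on the same stones.

    ``b`` counts stones predictor A gets right and B wrong, ``c`` the
    reverse; MIXED reference stones are excluded.
    """
    pa = _coerce_labels(pred_a, "prediction")
    pb = _coerce_labels(pred_b, "prediction")
    refs = _coerce_labels(references, "reference")
    if not (len(pa) == len(pb) == len(refs)):
        raise ValidationError("prediction/reference lengths differ")
    b = c = 0
    for a, bb, r in zip(pa, pb, refs):
        if r is StoneLabel.MIXED:
            continue
        b += (a is r) and (bb is not r)
        c += (a is not r) and (bb is r)
    return int(b), int(c), mcnemar_exact(int(b), int(c), method=method)


def roc_auc(
    scores: Sequence[float], references: Sequence, higher_is_ua: bool = True
) -> float:
    """Trapezoidal AUC for discriminating UA stones by a continuous score.

    Equal to the Mann-Whitney statistic (ties contribute with midranks).
    For the kNN predictor the natural score is the UA vote fraction; for
    the maxHU predictor it is the negated attenuation (lower attenuation is
    more UA-like). MIXED reference stones are excluded; with only one class
    left the AUC is undefined and rejected.
    """
    from sklearn.metrics import roc_auc_score

    refs = _coerce_labels(references, "reference")
    s = np.asarray(scores, dtype=float)
    if len(refs) != s.size:
        raise ValidationError("scores/references length mismatch")
    keep = np.array([r is not StoneLabel.MIXED for r in refs])
    y = np.array([r is StoneLabel.UA for r in refs])[keep]
    s = s[keep] if higher_is_ua else -s[keep]
    if y.all() or not y.any():
        raise ValidationError("AUC undefined: only one class present")
    return float(roc_auc_score(y, s))
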