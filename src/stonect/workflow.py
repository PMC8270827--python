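"""Pipeline-level operations binding imaging, classification, and statistics.

These are the functions the command-line interface wraps: per-volume
feature extraction, per-table classification, and the full evaluation
report (per-method confusion matrices, metrics with exact CIs, pairwise
McNemar tests, AUCs where a continuous score exists).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .classify import (
    StoneLabel,
    TrainingSet,
    classify_cutoff,
    classify_knn,
    classify_maxhu,
    knn_ua_fraction,
)
from .config import RunConfig
from .diagnostics import diagnostic_metrics, cross_tabulate, mcnemar_between, roc_auc
from .errors import ValidationError
from .features import StoneFeatures, extract_features
from .segment import segment_stone
from .volume import CTVolume, StoneMask

__all__ = ["run_features", "classify_table", "run_full_report", "render_report_text"]

METHODS = ("cutoff", "maxhu", "knn")


def run_features(
    volume: CTVolume,
    stones: Mapping[str, StoneMask | Sequence[int]],
    config: RunConfig | None = None,
) -> dict[str, StoneFeatures]:
    """Extract the feature pair for each stone in one volume.

    ``stones`` maps stone ids to either a ready mask or a seed index triple
    (which is segmented first with the configured threshold and clip cube).
    """
    config = config or RunConfig()
    out: dict[str, StoneFeatures] = {}
    for sid in sorted(stones):
        entry = stones[sid]
        if isinstance(entry, StoneMask):
            mask = entry
        else:
            mask = segment_stone(
                volume,
                tuple(entry),
                threshold=config.segmentation.threshold_hu,
                max_extent_mm=config.segmentation.max_extent_mm,
            )
        out[sid] = extract_features(volume, mask, config.kernel)
    return out


def classify_table(
    features: pd.DataFrame,
    methods: Sequence[str] = METHODS,
    config: RunConfig | None = None,
    train: TrainingSet | None = None,
) -> pd.DataFrame:
    """Add one prediction column per requested method to a feature table."""
    config = config or RunConfig()
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValidationError(f"unknown methods {sorted(unknown)}; choose from {METHODS}")
    if "knn" in methods and train is None:
        raise ValidationError("kNN classification needs a training set")
    out = features.copy()
    pairs = list(zip(out["max_hu"].astype(float), out["pp_lapl"].astype(float)))
    if "cutoff" in methods:
        out["pred_cutoff"] = [classify_cutoff(p, config.cutoffs).value for p in pairs]
    if "maxhu" in methods:
        out["pred_maxhu"] = [classify_maxhu(p, config.cutoffs).value for p in pairs]
    if "knn" in methods:
        out["pred_knn"] = [classify_knn(p, train, config.knn).value for p in pairs]
        out["knn_ua_fraction"] = [knn_ua_fraction(p, train, config.knn) for p in pairs]
    return out


def run_full_report(
    features: pd.DataFrame,
    references: pd.DataFrame,
    config: RunConfig | None = None,
    train: TrainingSet | None = None,
    mcnemar: bool = True,
) -> dict:
    """Evaluate every available method against the reference labels.

    Joins the two tables on ``stone_id`` (mismatched ids are an error
    naming the offenders), classifies, excludes MIXED reference stones from
    the counts, and returns a machine-readable report.
    """
    config = config or RunConfig()
    f_ids, r_ids = set(features["stone_id"]), set(references["stone_id"])
    if f_ids != r_ids:
        only_f, only_r = sorted(f_ids - r_ids), sorted(r_ids - f_ids)
        raise ValidationError(
            f"stone id mismatch: only in features {only_f[:10]}, only in references {only_r[:10]}"
        )
    feats = features.drop(columns=["reference"], errors="ignore")
    merged = feats.merge(references[["stone_id", "reference"]], on="stone_id").sort_values(
        "stone_id", kind="stable"
    )
    methods = list(METHODS) if train is not None else ["cutoff", "maxhu"]
    table = classify_table(merged, methods, config, train)

    refs = [StoneLabel(r) for r in table["reference"]]
    n_mixed = sum(r is StoneLabel.MIXED for r in refs)
    report: dict = {
        "n_stones": int(len(table)),
        "n_mixed_excluded": int(n_mixed),
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
        "methods": {},
    }
    for m in methods:
        preds = list(table[f"pred_{m}"])
        cm = cross_tabulate(preds, refs)
        report["methods"][m] = diagnostic_metrics(cm, config.confidence).to_dict()

    keep = [r is not StoneLabel.MIXED for r in refs]
    y = [r for r, k in zip(refs, keep) if k]
    both_classes = StoneLabel.UA in y and StoneLabel.NON_UA in y
    aucs: dict[str, float] = {}
    if both_classes:
        mh = -table["max_hu"].to_numpy(dtype=float)[keep]
        aucs["maxhu"] = roc_auc(mh, y)
        if train is not None:
            score = table["knn_ua_fraction"].to_numpy(dtype=float)[keep]
            aucs["knn"] = roc_auc(score, y)
    report["auc"] = aucs

    if mcnemar and len(methods) > 1:
        pairs = {}
        for i, a in enumerate(methods):
            for b in methods[i + 1 :]:
                db, dc, p = mcnemar_between(table[f"pred_{a}"], table[f"pred_{b}"], refs)
                pairs[f"{a}_vs_{b}"] = {"b": db, "c": dc, "p_value": p}
        report["mcnemar"] = pairs
    return report


def render_report_text(report: dict) -> str:
    """Human-readable cross-tabulations and metric lines."""
    lines: list[str] = []
    lines.append(
        f"Stones: {report['n_stones']} ({report['n_mixed_excluded']} mixed excluded)  "
        f"config {report['config_hash']}"
    )
    for m, r in report["methods"].items():
        cm = r["confusion"]
        lines.append("")
        lines.append(f"[{m}]  prediction rows x reference columns (UA positive)")
        lines.append(f"              ref UA   ref non-UA")
        lines.append(f"  pred UA     {cm['tp']:6d}   {cm['fp']:10d}")
        lines.append(f"  pred non-UA {cm['fn']:6d}   {cm['tn']:10d}")
        for name in ("sensitivity", "specificity", "accuracy"):
            p = r[name]
            if not p["defined"]:
                lines.append(f"  {name}: undefined (0 denominator)")
                continue
            lo, hi = p["ci_percent"]
            lines.append(
                f"  {name}: {p['percent']}% ({p['numerator']}/{p['denominator']}) "
                f"{int(round(100 * r['confidence']))}%CI {lo}-{hi}%"
            )
    if report.get("auc"):
        lines.append("")
        for m, a in report["auc"].items():
            lines.append(f"AUC {m}: {a:.2f}")
    if report.get("mcnemar"):
        lines.append("")
        for pair, d in report["mcnemar"].items():
            lines.append(
                f"McNemar {pair}: b={d['b']} c={d['c']} p={d['p_value']:.3f}"
            )
    return "\n".join(lines) + "\n"
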