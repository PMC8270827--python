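"""CSV and JSON readers/writers for feature, label, and report tables.

Dialect is fixed: UTF-8, comma separator, header row, decimal point.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import InputError, ValidationError
from .features import StoneFeatures

__all__ = [
    "FEATURE_COLUMNS",
    "write_features_csv",
    "read_features_csv",
    "read_labels_csv",
    "write_report_json",
]

FEATURE_COLUMNS = ["stone_id", "max_hu", "pp_lapl", "peak_i", "peak_j", "peak_k", "size_mm"]


def write_features_csv(
    features: Mapping[str, StoneFeatures] | Sequence[tuple[str, StoneFeatures]],
    path: str | Path,
) -> None:
    """One row per stone, ordered by stone id for stable output."""
    items = sorted(dict(features).items())
    rows = [
        {
            "stone_id": sid,
            "max_hu": f.max_hu,
            "pp_lapl": f.pp_lapl,
            "peak_i": f.peak_index[0],
            "peak_j": f.peak_index[1],
            "peak_k": f.peak_index[2],
            "size_mm": "" if f.size_mm is None else f.size_mm,
        }
        for sid, f in items
    ]
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(path, index=False)


def _read_csv(path: str | Path, required: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read CSV {path!s}: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path!s} lacks required columns {sorted(missing)}")
    if df.empty:
        raise ValidationError(f"{path!s} contains no rows")
    return df


def read_features_csv(path: str | Path) -> pd.DataFrame:
    """Feature table with at least stone_id, max_hu, pp_lapl."""
    return _read_csv(path, {"stone_id", "max_hu", "pp_lapl"})


def read_labels_csv(path: str | Path) -> pd.DataFrame:
    """Reference labels: stone_id, reference (UA|NON_UA|MIXED)."""
    df = _read_csv(path, {"stone_id", "reference"})
    bad = set(df["reference"]) - {"UA", "NON_UA", "MIXED"}
    if bad:
        raise ValidationError(f"{path!s}: invalid reference labels {sorted(bad)}")
    return df


def write_report_json(report: dict, path: str | Path) -> None:
    """Deterministic (sorted keys) machine-readable report."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
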