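"""Dispensing-claims and demographics data model and CSV I/O.

Claims carry a calendar month rather than a date: the source reimbursement
feed collates dispensings monthly, so a month is the native resolution for
both chronicity and cost aggregation.  Files are comma-delimited UTF-8
with a header row and ``.`` decimal separator.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLAIMS_COLUMNS = ["patient_id", "month", "atc_code", "ingredient_cost"]
DEMOGRAPHICS_COLUMNS = ["patient_id", "sex", "age_band"]

SEXES = ("male", "female")
AGE_BANDS = ("65-69", "70-74", "75+")
_AGE_BAND_ALIASES = {
    "65-69": "65-69", "65 - 69": "65-69",
    "70-74": "70-74", "70 - 74": "70-74",
    "75+": "75+", ">=75": "75+", "≥75": "75+", "≥ 75": "75+", "75 +": "75+",
}

_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})$")


class ClaimsFormatError(ValueError):
    """Raised for rows that violate the claims/demographics schema."""


def parse_month(month: str) -> int:
    """Parse an ISO ``YYYY-MM`` string into a linear month index."""
    m = _MONTH_RE.match(str(month).strip())
    if not m:
        raise ClaimsFormatError(f"unparseable month {month!r} (expected YYYY-MM)")
    year, mon = int(m.group(1)), int(m.group(2))
    if not 1 <= mon <= 12:
        raise ClaimsFormatError(f"unparseable month {month!r} (month out of range)")
    return year * 12 + (mon - 1)


def format_month(index: int) -> str:
    """Inverse of :func:`parse_month`."""
    return f"{index // 12:04d}-{index % 12 + 1:02d}"


@dataclass(frozen=True)
class StudyWindow:
    """Inclusive month window for chronicity plus the costing year."""

    start_month: str = "2009-11"
    end_month: str = "2011-02"
    cost_year: int = 2010

    def __post_init__(self) -> None:
        if parse_month(self.start_month) > parse_month(self.end_month):
            raise ValueError("start_month must not be after end_month")

    @property
    def start_index(self) -> int:
        return parse_month(self.start_month)

    @property
    def end_index(self) -> int:
        return parse_month(self.end_month)

    @property
    def n_months(self) -> int:
        return self.end_index - self.start_index + 1

    def months(self) -> list[str]:
        return [format_month(i) for i in range(self.start_index, self.end_index + 1)]

    def contains(self, month: str) -> bool:
        return self.start_index <= parse_month(month) <= self.end_index


DEFAULT_WINDOW = StudyWindow()


def read_claims(
    path: str | Path,
    window: StudyWindow = DEFAULT_WINDOW,
    *,
    strict: bool = True,
) -> pd.DataFrame:
    """Read a claims CSV, dropping (and counting) records outside *window*.

    Returns a frame with columns ``patient_id, month, atc_code,
    ingredient_cost`` sorted by (patient_id, month, atc_code); codes are
    uppercased.  In strict mode an unparseable month or a negative cost
    raises :class:`ClaimsFormatError` with the offending line number; with
    ``strict=False`` such rows are skipped and counted.  The number of
    dropped rows is logged and exposed as ``df.attrs``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CLAIMS_COLUMNS if c not in df.columns]
    if missing:
        raise ClaimsFormatError(f"claims file {path} missing column(s): {missing}")
    df = df[CLAIMS_COLUMNS].copy()

    month_idx = np.empty(len(df), dtype=int)
    cost = np.empty(len(df), dtype=float)
    bad_rows = []
    for i, (mon, raw_cost) in enumerate(zip(df["month"], df["ingredient_cost"])):
        line_no = i + 2  # header is line 1
        try:
            month_idx[i] = parse_month(mon)
            cost[i] = float(raw_cost)
            if not np.isfinite(cost[i]) or cost[i] < 0:
                raise ClaimsFormatError(f"negative or non-finite ingredient_cost {raw_cost!r}")
        except (ClaimsFormatError, ValueError) as exc:
            if strict:
                raise ClaimsFormatError(f"{path}, line {line_no}: {exc}") from exc
            bad_rows.append(i)
            month_idx[i] = -1
            cost[i] = np.nan

    df["ingredient_cost"] = np.round(cost, 2)
    df["atc_code"] = df["atc_code"].str.strip().str.upper()
    df["patient_id"] = df["patient_id"].str.strip()

    keep = (month_idx >= window.start_index) & (month_idx <= window.end_index)
    if bad_rows:
        keep[bad_rows] = False
    n_dropped_window = int((~keep).sum()) - len(bad_rows)
    out = df.loc[keep].sort_values(CLAIMS_COLUMNS[:3], kind="mergesort").reset_index(drop=True)
    if n_dropped_window or bad_rows:
        logger.info(
            "read_claims(%s): dropped %d record(s) outside %s..%s, skipped %d bad row(s)",
            path, n_dropped_window, window.start_month, window.end_month, len(bad_rows),
        )
    out.attrs["n_dropped_outside_window"] = n_dropped_window
    out.attrs["n_skipped_bad_rows"] = len(bad_rows)
    return out


def write_claims(df: pd.DataFrame, path: str | Path) -> None:
    """Write claims in the same dialect :func:`read_claims` accepts."""
    out = df[CLAIMS_COLUMNS].copy()
    out["ingredient_cost"] = out["ingredient_cost"].astype(float).map(lambda v: f"{v:.2f}")
    out.to_csv(path, index=False)


def read_demographics(path: str | Path) -> pd.DataFrame:
    """Read and validate a demographics CSV (one row per patient)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DEMOGRAPHICS_COLUMNS if c not in df.columns]
    if missing:
        raise ClaimsFormatError(f"demographics file {path} missing column(s): {missing}")
    df = df[DEMOGRAPHICS_COLUMNS].copy()
    df["patient_id"] = df["patient_id"].str.strip()
    df["sex"] = df["sex"].str.strip().str.lower()
    df["age_band"] = df["age_band"].str.strip().map(lambda s: _AGE_BAND_ALIASES.get(s, s))

    dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].unique()
    if len(dupes):
        raise ClaimsFormatError(f"duplicate patient_id(s) in demographics: {sorted(dupes)[:5]}")
    bad_sex = sorted(set(df["sex"]) - set(SEXES))
    if bad_sex:
        raise ClaimsFormatError(f"unknown sex value(s): {bad_sex}")
    bad_band = sorted(set(df["age_band"]) - set(AGE_BANDS))
    if bad_band:
        raise ClaimsFormatError(
            f"unknown age_band value(s): {bad_band} (population is >=65: {list(AGE_BANDS)})"
        )
    return df.reset_index(drop=True)


def write_demographics(df: pd.DataFrame, path: str | Path) -> None:
    df[DEMOGRAPHICS_COLUMNS].to_csv(path, index=False)


def month_run_length(months) -> int:
    """Length of the longest run of adjacent calendar months.

    Accepts ``YYYY-MM`` strings or linear month indices; duplicates are
    ignored; the empty set maps to 0.  Year boundaries are adjacent
    (December precedes the following January).
    """
    idx = sorted({parse_month(m) if isinstance(m, str) else int(m) for m in months})
    if not idx:
        return 0
    best = cur = 1
    for prev, nxt in zip(idx, idx[1:]):
        cur = cur + 1 if nxt == prev + 1 else 1
        best = max(best, cur)
    return best
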