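"""Annual ingredient-cost aggregation and bootstrap comparison of means.

A dispensing contributes cost only when (a) it falls in the costing
year, (b) its code resolves (post priority-resolution) to a condition
category, and (c) that category is in the patient's assigned condition
set.  Anti-diabetic dispensings (A10A/A10B) match no catalog category
and therefore never contribute — diabetes is not an index condition.
Confidence intervals use the seeded percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import Catalog
from .claims import StudyWindow, DEFAULT_WINDOW, parse_month
from .scoring import BANDS, capped_band
from .stats import round_half_up


def annual_costs(
    claims: pd.DataFrame,
    profiles: pd.DataFrame,
    catalog: Catalog,
    window: StudyWindow = DEFAULT_WINDOW,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient annual ingredient cost over assigned condition categories.

    Returns ``(totals, breakdown)``: *totals* has one row per profile row
    (``patient_id, total_cost``, zero-condition patients cost 0.00);
    *breakdown* is long form ``patient_id, category, cost``.
    """
    unknown = set(claims["patient_id"]) - set(profiles["patient_id"])
    if unknown:
        raise ValueError(
            f"claims reference patient(s) missing from profiles: {sorted(unknown)[:5]}"
        )
    d = claims.copy()
    d["mi"] = d["month"].map(parse_month)
    year_start = parse_month(f"{window.cost_year}-01")
    d = d[(d["mi"] >= year_start) & (d["mi"] < year_start + 12)]

    code_map = {}
    for code in d["atc_code"].unique():
        try:
            code_map[code] = catalog.resolve_code(code) if len(code) == 7 else None
        except ValueError:  # ungrammatical code: treat as unmatched
            code_map[code] = None
    d["category"] = d["atc_code"].map(code_map)
    d = d.dropna(subset=["category"])

    assigned = (
        profiles.loc[profiles["conditions"] != "", ["patient_id", "conditions"]]
        .assign(category=lambda f: f["conditions"].str.split(";"))
        .explode("category")[["patient_id", "category"]]
    )
    d = d.merge(assigned, on=["patient_id", "category"], how="inner")

    breakdown = (
        d.groupby(["patient_id", "category"], sort=True)["ingredient_cost"]
        .sum()
        .round(2)
        .rename("cost")
        .reset_index()
    )
    totals = (
        profiles[["patient_id"]]
        .merge(
            breakdown.groupby("patient_id")["cost"].sum().rename("total_cost"),
            on="patient_id",
            how="left",
        )
        .fillna({"total_cost": 0.0})
    )
    totals["total_cost"] = totals["total_cost"].round(2)
    return totals, breakdown


@dataclass(frozen=True)
class BootstrapCI:
    mean: float
    ci95: tuple[float, float]
    replicates: int
    seed: int


def bootstrap_mean(costs, replicates: int = 2000, seed: int = 0) -> BootstrapCI:
    """Percentile-bootstrap mean: point estimate is the sample mean, the CI
    the empirical 2.5th/97.5th percentiles of resampled means."""
    x = np.asarray(costs, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("bootstrap_mean requires a non-empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(replicates, n))
    means = x[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return BootstrapCI(float(x.mean()), (float(lo), float(hi)), replicates, seed)


def cost_ratio(t2dm_mean: float, non_mean: float) -> float:
    """T2DM / non-T2DM mean cost ratio, half-up to two decimals.

    Both means zero (e.g. the zero-condition stratum) gives ratio 1.
    """
    if non_mean == 0:
        return 1.0 if t2dm_mean == 0 else float("inf")
    return round_half_up(t2dm_mean / non_mean, 2)


def cost_table(
    totals: pd.DataFrame,
    profiles: pd.DataFrame,
    replicates: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap mean cost with 95% CI per stratum × group, plus cost ratios.

    Strata: each sex × age band, then each capped comorbidity band.  Each
    stratum×group cell is bootstrapped within stratum with its own
    deterministic sub-seed.  Ratios divide unrounded point means.  Empty
    cells are left blank (NaN).
    """
    d = profiles.merge(totals, on="patient_id")
    d["group"] = np.where(d["t2dm"], "t2dm", "non_t2dm")

    seeds = iter(np.random.SeedSequence(seed).generate_state(4 * (6 + len(BANDS))).tolist())
    rows = []

    def add_row(kind: str, label: str, sub: pd.DataFrame) -> None:
        cells = {}
        for group in ("t2dm", "non_t2dm"):
            s = next(seeds)
            x = sub.loc[sub["group"] == group, "total_cost"].to_numpy()
            if len(x) == 0:
                cells[group] = None
            else:
                cells[group] = bootstrap_mean(x, replicates, s)
        t2, non = cells["t2dm"], cells["non_t2dm"]
        rows.append(
            {
                "stratum_kind": kind,
                "stratum": label,
                "t2dm_mean": t2.mean if t2 else np.nan,
                "t2dm_ci_low": t2.ci95[0] if t2 else np.nan,
                "t2dm_ci_high": t2.ci95[1] if t2 else np.nan,
                "non_t2dm_mean": non.mean if non else np.nan,
                "non_t2dm_ci_low": non.ci95[0] if non else np.nan,
                "non_t2dm_ci_high": non.ci95[1] if non else np.nan,
                "cost_ratio": cost_ratio(t2.mean, non.mean) if t2 and non else np.nan,
            }
        )

    for sex in ("male", "female"):
        for band in ("65-69", "70-74", "75+"):
            add_row("sex_age", f"{sex} {band}",
                    d[(d["sex"] == sex) & (d["age_band"] == band)])
    for band in BANDS:
        add_row("n_conditions", band, d[d["capped_band"] == band])
    return pd.DataFrame(rows)
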