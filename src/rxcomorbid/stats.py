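"""Stratified prevalence, comorbidity-distribution and adjusted-OR analytics.

Reporting conventions: percentages are rounded half-up to one decimal,
odds ratios and their confidence bounds to two decimals; quartiles use
lower interpolation so medians and IQRs of integer scores stay integers;
p-values below 1e-4 print as ``<0.0001``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .claims import AGE_BANDS, SEXES
from .scoring import BANDS


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (5 rounds away from zero), unlike banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_p(p: float) -> str:
    return "<0.0001" if p < 1e-4 else f"{p:.4f}"


# ---------------------------------------------------------------------------
# prevalence

def prevalence_from_counts(counts: pd.DataFrame) -> dict:
    """Prevalence report from stratified counts.

    *counts* has columns ``sex, age_band, group, n`` with group in
    ``{"t2dm", "non_t2dm"}``.  Returns overall/by-sex/by-age prevalence
    (percent, one decimal, half-up), exact counts, and marginal shares.
    Also verifies count conservation: strata sum to group and cohort totals.
    """
    required = {"sex", "age_band", "group", "n"}
    if not required <= set(counts.columns):
        raise ValueError(f"counts must have columns {sorted(required)}")
    n_total = int(counts["n"].sum())
    if n_total == 0:
        raise ValueError("empty cohort")
    by_group = counts.groupby("group")["n"].sum()
    n_t2dm = int(by_group.get("t2dm", 0))
    n_non = int(by_group.get("non_t2dm", 0))
    assert n_t2dm + n_non == n_total  # count conservation

    def prev(sub: pd.DataFrame) -> float:
        tot = sub["n"].sum()
        t2 = sub.loc[sub["group"] == "t2dm", "n"].sum()
        return round_half_up(100.0 * t2 / tot, 1) if tot else 0.0

    report = {
        "n_total": n_total,
        "n_t2dm": n_t2dm,
        "n_non_t2dm": n_non,
        "overall_prevalence_pct": round_half_up(100.0 * n_t2dm / n_total, 1),
        "by_sex": {},
        "by_age_band": {},
        "counts_by_sex": {},
        "share_by_age_band_pct": {},
    }
    for sex in SEXES:
        sub = counts[counts["sex"] == sex]
        if len(sub):
            report["by_sex"][sex] = prev(sub)
            report["counts_by_sex"][sex] = int(sub["n"].sum())
    for band in AGE_BANDS:
        sub = counts[counts["age_band"] == band]
        if len(sub):
            report["by_age_band"][band] = prev(sub)
            report["share_by_age_band_pct"][band] = round_half_up(
                100.0 * sub["n"].sum() / n_total, 1
            )
    return report


def stratum_counts(profiles: pd.DataFrame) -> pd.DataFrame:
    """Collapse profiles to ``sex × age_band × group`` counts."""
    d = profiles.assign(group=np.where(profiles["t2dm"], "t2dm", "non_t2dm"))
    return (
        d.groupby(["sex", "age_band", "group"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )


def prevalence_table(profiles: pd.DataFrame) -> dict:
    """Prevalence report computed from scored profiles."""
    if profiles.empty:
        raise ValueError("empty cohort")
    return prevalence_from_counts(stratum_counts(profiles))


# ---------------------------------------------------------------------------
# medians / IQR

def _q(scores: np.ndarray, q: float) -> int:
    """Type-1 (inverse-CDF, lower-interpolation) quantile on integer scores."""
    return int(np.percentile(scores, q, method="inverted_cdf"))


@dataclass(frozen=True)
class StratumSummary:
    sex: str | None
    age_band: str | None
    group: str
    n: int
    median_score: int | None
    iqr: tuple[int, int] | None


def median_iqr_table(profiles: pd.DataFrame) -> list[StratumSummary]:
    """Median [q1, q3] of raw scores per sex × age band × group, plus pooled rows.

    Empty strata are reported with ``n=0`` and no summary, not an error.
    """
    d = profiles.assign(group=np.where(profiles["t2dm"], "t2dm", "non_t2dm"))
    out: list[StratumSummary] = []

    def summarize(sub: pd.DataFrame, sex, band, group) -> StratumSummary:
        scores = sub["raw_score"].to_numpy()
        if len(scores) == 0:
            return StratumSummary(sex, band, group, 0, None, None)
        return StratumSummary(
            sex, band, group, len(scores),
            _q(scores, 50), (_q(scores, 25), _q(scores, 75)),
        )

    for sex in SEXES:
        for band in AGE_BANDS:
            for group in ("t2dm", "non_t2dm"):
                sub = d[(d["sex"] == sex) & (d["age_band"] == band) & (d["group"] == group)]
                out.append(summarize(sub, sex, band, group))
    for group in ("t2dm", "non_t2dm"):
        out.append(summarize(d[d["group"] == group], None, None, group))
    return out


# ---------------------------------------------------------------------------
# chi-square

@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame

    @property
    def p_text(self) -> str:
        return format_p(self.p_value)


def _pearson_chi2(table: pd.DataFrame) -> tuple[float, int, float]:
    obs = table.to_numpy(dtype=float)
    chi2, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)


def distribution_chi_square(profiles: pd.DataFrame) -> ChiSquareResult:
    """Pearson chi-square over the capped-band × group contingency table.

    Bands unoccupied in both groups are dropped, so df = occupied bands − 1.
    """
    d = profiles.assign(group=np.where(profiles["t2dm"], "t2dm", "non_t2dm"))
    if d["group"].nunique() < 2:
        raise ValueError("both T2DM and non-T2DM groups must be non-empty")
    table = (
        d.groupby(["capped_band", "group"]).size().unstack(fill_value=0)
        .reindex(BANDS, fill_value=0)[["t2dm", "non_t2dm"]]
    )
    table = table.loc[table.sum(axis=1) > 0]
    chi2, df, p = _pearson_chi2(table)
    return ChiSquareResult(chi2, df, p, table)


# ---------------------------------------------------------------------------
# logistic regression

@dataclass(frozen=True)
class ORResult:
    condition: str
    prevalence_t2dm_pct: float
    prevalence_non_pct: float
    odds_ratio: float | None
    ci95: tuple[float, float] | None
    p_value: float | None
    flagged: str | None = None

    adjusted_for: tuple[str, ...] = ("age_band (ref 65-69)", "sex (ref female)")


def _design_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(
        {
            "const": 1.0,
            "t2dm": profiles["t2dm"].astype(float),
            "age_70_74": (profiles["age_band"] == "70-74").astype(float),
            "age_75_plus": (profiles["age_band"] == "75+").astype(float),
            "male": (profiles["sex"] == "male").astype(float),
        },
        index=profiles.index,
    )
    # adjustment columns with no variation (single-stratum cohorts) would
    # make the information matrix singular; drop them
    for col in ("age_70_74", "age_75_plus", "male"):
        if X[col].nunique() == 1:
            X = X.drop(columns=col)
    return X


def fit_adjusted_logit(profiles: pd.DataFrame, outcome: np.ndarray):
    """Logit of *outcome* on T2DM + age-band + sex; returns the fit result.

    Reference levels: age 65-69, female, non-T2DM.
    """
    X = _design_matrix(profiles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(np.asarray(outcome, dtype=float), X)
        return model.fit(disp=0, maxiter=100)


def _or_from_fit(fit, term: str = "t2dm") -> tuple[float, tuple[float, float], float]:
    coef = fit.params[term]
    se = fit.bse[term]
    lo, hi = coef - 1.959963984540054 * se, coef + 1.959963984540054 * se
    return float(np.exp(coef)), (float(np.exp(lo)), float(np.exp(hi))), float(fit.pvalues[term])


def adjusted_odds_ratios(
    profiles: pd.DataFrame,
    min_prevalence_pct: float = 10.0,
    conditions: list[str] | None = None,
) -> list[ORResult]:
    """Per-condition age/sex-adjusted odds ratio of condition presence on T2DM.

    Conditions are filtered at *min_prevalence_pct* computed over the whole
    cohort (both groups pooled) unless an explicit list is given.  A model
    that fails to converge (e.g. perfect separation) yields a flagged
    result with no estimate.
    """
    cond_sets = profiles["conditions"].map(lambda s: set(s.split(";")) if s else set())
    all_conditions = sorted(set().union(*cond_sets)) if len(cond_sets) else []
    n = len(profiles)
    t2dm = profiles["t2dm"].to_numpy(dtype=bool)
    n_t2, n_non = int(t2dm.sum()), int((~t2dm).sum())

    results = []
    for cond in conditions if conditions is not None else all_conditions:
        has = cond_sets.map(lambda s: cond in s).to_numpy(dtype=bool)
        prev_all = 100.0 * has.sum() / n
        if conditions is None and prev_all < min_prevalence_pct:
            continue
        prev_t2 = round_half_up(100.0 * (has & t2dm).sum() / n_t2, 1) if n_t2 else 0.0
        prev_non = round_half_up(100.0 * (has & ~t2dm).sum() / n_non, 1) if n_non else 0.0
        if has.all() or not has.any():
            results.append(ORResult(cond, prev_t2, prev_non, None, None, None,
                                    flagged="degenerate outcome"))
            continue
        try:
            fit = fit_adjusted_logit(profiles, has)
            if not fit.mle_retvals.get("converged", True) or not np.isfinite(fit.bse["t2dm"]):
                raise ValueError("non-converged fit")
            or_, ci, p = _or_from_fit(fit)
        except Exception:
            results.append(ORResult(cond, prev_t2, prev_non, None, None, None,
                                    flagged="separation or non-convergence"))
            continue
        results.append(ORResult(cond, prev_t2, prev_non, or_, ci, p))
    return results


# ---------------------------------------------------------------------------
# low vs high comorbidity split

@dataclass(frozen=True)
class HighLowReport:
    threshold: int
    table: pd.DataFrame  # low/high × group counts
    chi_square: ChiSquareResult | None
    odds_ratio: float | None
    ci95: tuple[float, float] | None
    p_value: float | None
    degenerate: bool = False


def high_low_split(profiles: pd.DataFrame) -> HighLowReport:
    """Low (<T2DM-group median) vs high (>=median) comorbidity association.

    The threshold is the T2DM group's median raw score.  Reports the 2×2
    contingency table, the Pearson chi-square (no continuity correction)
    and the age/sex-adjusted odds ratio of high comorbidity on T2DM.
    """
    t2_scores = profiles.loc[profiles["t2dm"], "raw_score"].to_numpy()
    if len(t2_scores) == 0:
        raise ValueError("T2DM group is empty; threshold not computable")
    threshold = _q(t2_scores, 50)
    high = profiles["raw_score"].to_numpy() >= threshold
    d = profiles.assign(
        group=np.where(profiles["t2dm"], "t2dm", "non_t2dm"),
        level=np.where(high, "high", "low"),
    )
    table = (
        d.groupby(["level", "group"]).size().unstack(fill_value=0)
        .reindex(["low", "high"], fill_value=0)
        .reindex(columns=["t2dm", "non_t2dm"], fill_value=0)
    )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return HighLowReport(threshold, table, None, None, None, None, degenerate=True)
    chi2, df, p = _pearson_chi2(table)
    chi_res = ChiSquareResult(chi2, df, p, table)
    try:
        fit = fit_adjusted_logit(profiles, high)
        or_, ci, p_or = _or_from_fit(fit)
    except Exception:
        return HighLowReport(threshold, table, chi_res, None, None, None, degenerate=True)
    return HighLowReport(threshold, table, chi_res, or_, ci, p_or)
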