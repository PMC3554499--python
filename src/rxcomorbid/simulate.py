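"""Seed-deterministic synthetic dispensing claims with known ground truth.

Patients are sampled stratum-first (sex, age band), the treated-T2DM flag
by per-sex prevalence, and each condition independently from a logistic
model with a planted odds ratio on the T2DM flag.  A treated condition
emits a run of monthly dispensings of its representative code(s): a
chronic run (at least as long as the chronicity threshold) with
probability ``persistence``, otherwise a sub-chronic 1-2 month run that
must be filtered out by the scoring engine.  Per-dispensing ingredient
costs are gamma distributed (right-skewed, non-negative).

Because conditions are conditionally independent given T2DM, the implied
distribution of the comorbidity count in each group is Poisson-binomial
and can be computed exactly (:func:`implied_count_pmf`), which gives
closed-form ground truth for medians and for the odds ratio of any
high-comorbidity split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .catalog import Catalog, load_catalog
from .claims import StudyWindow, DEFAULT_WINDOW

#: a grammatical full code matching no catalog category: keeps every
#: patient past the cohort-inclusion filter without adding a condition
BACKGROUND_CODE = "B05AA01"
OAH_CODE = "A10BA02"


@dataclass(frozen=True)
class ConditionSpec:
    """Planted parameters for one condition category."""

    baseline_prevalence: float          # P(condition | non-T2DM)
    t2dm_odds_ratio: float
    codes: tuple[str, ...]              # representative full ATC code(s), all emitted
    cost_shape: float = 2.0             # gamma shape of per-dispensing cost
    cost_scale: float = 10.0            # gamma scale (EUR)

    def prevalence(self, t2dm: bool) -> float:
        if not t2dm:
            return self.baseline_prevalence
        return float(expit(logit(self.baseline_prevalence) + np.log(self.t2dm_odds_ratio)))


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int = 10_000
    male_share: float = 0.43
    age_band_probs: dict = field(
        default_factory=lambda: {"65-69": 0.228, "70-74": 0.269, "75+": 0.503}
    )
    t2dm_prevalence_by_sex: dict = field(
        default_factory=lambda: {"male": 0.121, "female": 0.079}
    )
    conditions: dict = field(default_factory=dict)  # name -> ConditionSpec
    persistence: float = 1.0            # P(chronic run | treated condition)
    chronic_run_months: tuple[int, int] = (3, 6)
    subchronic_run_months: tuple[int, int] = (1, 2)
    window: StudyWindow = DEFAULT_WINDOW
    background_cost: tuple[float, float] = (1.5, 4.0)

    def __post_init__(self) -> None:
        if not 0 <= self.male_share <= 1 or not 0 <= self.persistence <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.age_band_probs.values()) - 1.0) > 1e-9:
            raise ValueError("age_band_probs must sum to 1")
        for name, spec in self.conditions.items():
            if not 0 < spec.baseline_prevalence < 1:
                raise ValueError(f"{name}: baseline prevalence must be in (0, 1)")
            if spec.t2dm_odds_ratio <= 0:
                raise ValueError(f"{name}: odds ratio must be positive")

    def validate_against(self, catalog: Catalog) -> None:
        """Check every condition exists in *catalog* and its codes resolve to it."""
        for name, spec in self.conditions.items():
            if name not in catalog.names:
                raise ValueError(f"condition {name!r} not in catalog")
            for code in spec.codes:
                resolved = catalog.resolve_code(code)
                # a code matching no category at all is allowed (it can be
                # used deliberately to exercise exclusion rules), but a code
                # attributed to a different category would corrupt the
                # planted ground truth
                if resolved is not None and resolved != name:
                    raise ValueError(
                        f"representative code {code} of {name!r} resolves to {resolved!r}"
                    )


def reference_marginals_config(n_patients: int = 100_000) -> GeneratorConfig:
    """Defaults mirroring the marginal structure of the national elderly
    claims cohort the modified index was developed on.

    Marginals: male share 43%; age shares 22.8 / 26.9 / 50.3%; treated-T2DM
    prevalence 12.1% (male) / 7.9% (female), i.e. 9.7% overall.  The ten
    conditions with >=10% published prevalence carry their published
    non-T2DM prevalence and age/sex-adjusted odds ratio.  The remaining
    entries are lower-prevalence filler conditions whose parameters were
    chosen so that the implied comorbidity-count distributions have
    medians 5 (T2DM) and 3 (non-T2DM) and a high-comorbidity (>=5) split
    odds ratio close to 2.8.
    """
    published = {
        "Hyperlipidemia": (0.426, 4.95, ("C10AA05",)),
        "Anti-platelet therapy": (0.398, 3.84, ("B01AC06",)),
        "Heart disease": (0.394, 2.44, ("C07AB02",)),
        "Hypertension": (0.217, 1.79, ("C03AA03",)),
        "Gastric-oesophageal reflux disorder & Peptic ulcer": (0.345, 1.67, ("A02BC01",)),
        "Depression": (0.160, 1.46, ("N06AB05",)),
        "Chronic airways disease": (0.144, 1.35, ("R03AC02",)),
        "Osteoporosis": (0.143, 0.73, ("M05BA04",)),
        "Pain - Anti-inflammatory agents": (0.130, 1.14, ("M01AE01",)),
        "Pain - Opiates": (0.100, 1.42, ("N02AA01",)),
    }
    # Filler parameters tuned (exact Poisson-binomial) so that, jointly with
    # the published conditions above, implied count medians are 5 (T2DM) and
    # 3 (non-T2DM) and the implied odds ratio of (count >= 5) is 2.83.
    # Chronic heart failure emits both component codes to exercise the
    # all-of rule (loop diuretic + ACE inhibitor).
    fillers = {
        "Chronic Heart failure": (0.090, 0.80, ("C03CA01", "C09AA02")),
        "Anti-coagulation therapy": (0.100, 0.85, ("B01AA03",)),
        "Anxiety": (0.090, 0.75, ("N05BA01",)),
        "Gout": (0.060, 0.80, ("M04AA01",)),
        "Hypothyroidism": (0.080, 0.80, ("H03AA01",)),
        "Glaucoma": (0.070, 0.85, ("S01EA01",)),
        "Dementia": (0.060, 0.75, ("N06DA02",)),
        "Arrhythmia": (0.070, 0.80, ("C01BD01",)),
        "Epilepsy": (0.080, 0.75, ("N03AA01",)),
        "Angina": (0.050, 0.85, ("C01DA02",)),
        "Psychotic illness": (0.090, 0.85, ("N05AA01",)),
        "Allergies": (0.070, 0.75, ("R01AC01",)),
        "Steroid responsive disease": (0.100, 0.80, ("H02AB01",)),
        "Migraine": (0.080, 0.85, ("N02CA01",)),
    }
    conditions = {
        name: ConditionSpec(p0, or_, codes)
        for name, (p0, or_, codes) in {**published, **fillers}.items()
    }
    return GeneratorConfig(n_patients=n_patients, conditions=conditions)


def _emit_runs(rng, patient_idx, chronic_mask, window, run_lo_hi, sub_lo_hi):
    """Sample a dispensing run per patient; returns (row_patient, row_month)."""
    k = len(patient_idx)
    lo, hi = run_lo_hi
    slo, shi = sub_lo_hi
    run_len = np.where(
        chronic_mask,
        rng.integers(lo, hi + 1, size=k),
        rng.integers(slo, shi + 1, size=k),
    )
    start = rng.integers(0, window.n_months - run_len + 1)
    total = int(run_len.sum())
    row_pid = np.repeat(patient_idx, run_len)
    pos = np.arange(total) - np.repeat(np.cumsum(run_len) - run_len, run_len)
    row_month = np.repeat(start, run_len) + pos
    return row_pid, row_month


def generate(
    config: GeneratorConfig,
    seed: int,
    catalog: Catalog | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate ``(claims, demographics, ground_truth)`` frames.

    Fully deterministic for a given ``(config, seed)``.  If *catalog* is
    given the config is validated against it first.
    """
    if catalog is None:
        catalog = load_catalog()
    config.validate_against(catalog)
    rng = np.random.default_rng(seed)
    n = config.n_patients
    window = config.window
    month_labels = np.array(window.months())

    pids = np.array([f"P{i:07d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.male_share, "male", "female")
    bands = list(config.age_band_probs)
    age = rng.choice(bands, size=n, p=[config.age_band_probs[b] for b in bands])
    prev = np.where(
        sex == "male",
        config.t2dm_prevalence_by_sex["male"],
        config.t2dm_prevalence_by_sex["female"],
    )
    t2dm = rng.random(n) < prev

    pid_parts, month_parts, code_parts, cost_parts = [], [], [], []
    truth_pid_parts, truth_name_parts = [], []
    code_names: list[str] = []

    def emit(patient_idx, chronic_mask, code, shape, scale):
        row_pid, row_month = _emit_runs(
            rng, patient_idx, chronic_mask, window,
            config.chronic_run_months, config.subchronic_run_months,
        )
        if code not in code_names:
            code_names.append(code)
        pid_parts.append(row_pid)
        month_parts.append(row_month)
        code_parts.append(np.full(len(row_pid), code_names.index(code), dtype=np.int64))
        cost_parts.append(np.round(rng.gamma(shape, scale, size=len(row_pid)), 2))

    for name in sorted(config.conditions):
        spec = config.conditions[name]
        p = expit(logit(spec.baseline_prevalence) + np.log(spec.t2dm_odds_ratio) * t2dm)
        has = rng.random(n) < p
        idx = np.flatnonzero(has)
        truth_pid_parts.append(idx)
        truth_name_parts.append(np.full(len(idx), name, dtype=object))
        chronic = rng.random(len(idx)) < config.persistence
        for code in spec.codes:
            emit(idx, chronic, code, spec.cost_shape, spec.cost_scale)

    # treated-T2DM patients: oral anti-hyperglycaemic runs (flag only, no cost
    # relevance — anti-diabetics resolve to no index category)
    t2_idx = np.flatnonzero(t2dm)
    emit(t2_idx, rng.random(len(t2_idx)) < config.persistence, OAH_CODE, 1.5, 12.0)

    # background dispensing: guarantees cohort inclusion for every patient
    bshape, bscale = config.background_cost
    emit(np.arange(n), np.ones(n, dtype=bool), BACKGROUND_CODE, bshape, bscale)

    pid_all = np.concatenate(pid_parts)
    month_all = np.concatenate(month_parts)
    code_all = np.concatenate(code_parts)
    cost_all = np.concatenate(cost_parts)
    # sort by (patient, month, code) using integer keys; code rank follows
    # lexicographic order of the code strings
    code_rank = np.argsort(np.argsort(code_names))
    order = np.lexsort((code_rank[code_all], month_all, pid_all))
    claims = pd.DataFrame(
        {
            "patient_id": pids[pid_all[order]],
            "month": month_labels[month_all[order]],
            "atc_code": np.array(code_names, dtype=object)[code_all[order]],
            "ingredient_cost": cost_all[order],
        }
    )

    demographics = pd.DataFrame({"patient_id": pids, "sex": sex, "age_band": age})
    true_conditions = np.full(n, "", dtype=object)
    if truth_pid_parts:
        joined = (
            pd.DataFrame(
                {
                    "i": np.concatenate(truth_pid_parts),
                    "name": np.concatenate(truth_name_parts),
                }
            )
            .sort_values(["i", "name"], kind="mergesort")
            .groupby("i")["name"]
            .agg(";".join)
        )
        true_conditions[joined.index.to_numpy()] = joined.to_numpy()
    truth = pd.DataFrame(
        {"patient_id": pids, "t2dm_true": t2dm, "true_conditions": true_conditions}
    )
    return claims, demographics, truth


# ---------------------------------------------------------------------------
# exact implied ground truth (Poisson-binomial over independent conditions)

def implied_count_pmf(config: GeneratorConfig, t2dm: bool) -> np.ndarray:
    """Exact pmf of the comorbidity count in one group, by convolution."""
    pmf = np.array([1.0])
    for spec in config.conditions.values():
        p = spec.prevalence(t2dm)
        new = np.zeros(len(pmf) + 1)
        new[: len(pmf)] += pmf * (1 - p)
        new[1:] += pmf * p
        pmf = new
    return pmf


def implied_median(config: GeneratorConfig, t2dm: bool) -> int:
    cdf = np.cumsum(implied_count_pmf(config, t2dm))
    return int(np.searchsorted(cdf, 0.5))


def implied_split_odds_ratio(config: GeneratorConfig, threshold: int) -> float:
    """True odds ratio of (count >= threshold) between T2DM and non-T2DM."""
    p_hi = implied_count_pmf(config, True)[threshold:].sum()
    p_lo = implied_count_pmf(config, False)[threshold:].sum()
    return float((p_hi / (1 - p_hi)) / (p_lo / (1 - p_lo)))


def overall_t2dm_prevalence(config: GeneratorConfig) -> float:
    m = config.male_share
    by_sex = config.t2dm_prevalence_by_sex
    return m * by_sex["male"] + (1 - m) * by_sex["female"]
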