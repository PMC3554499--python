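"""Chronic-condition assignment, T2DM proxy flag and comorbidity scoring.

A patient is assigned a condition category when dispensings of codes
attributed to that category cover at least ``min_consecutive`` adjacent
calendar months.  Each distinct code a patient receives is attributed to
a single category — the highest-priority category whose patterns match —
so a multi-indication drug never contributes to two scores.  Categories
with ``all_of_groups`` (chronic heart failure: loop diuretic plus ACE
inhibitor) are assessed on raw pattern matches before single-category
attribution, and require every component group to be chronic on its own.

Medication-treated type-2 diabetes is flagged by proxy: chronic
dispensing of oral anti-hyperglycaemic agents (any ``A10B`` code,
pooled at class level), alone or alongside insulin (``A10A``).
Insulin without an oral agent does not raise the flag, and neither
drug class contributes to the comorbidity score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import Catalog
from .claims import month_run_length, parse_month

OAH_PREFIX = "A10B"   # oral anti-hyperglycaemic agents (T2DM proxy)
INSULIN_PREFIX = "A10A"

CAPPED_BAND_MAX = 10
BANDS = [str(i) for i in range(CAPPED_BAND_MAX)] + [f">={CAPPED_BAND_MAX}"]

INCLUSION_MODES = ("chronic_any", "any_dispensing")


@dataclass(frozen=True)
class ChronicityRule:
    """Minimum number of consecutive monthly dispensings for chronicity."""

    min_consecutive: int = 3

    def __post_init__(self) -> None:
        if self.min_consecutive < 1:
            raise ValueError("min_consecutive must be >= 1")


def capped_band(raw_score: int) -> str:
    """Render a raw condition count as a capped band label (``>=10`` at 10+)."""
    return BANDS[min(int(raw_score), CAPPED_BAND_MAX)]


@dataclass(frozen=True)
class ComorbidityProfile:
    patient_id: str
    conditions: frozenset[str]
    t2dm: bool

    @property
    def raw_score(self) -> int:
        return len(self.conditions)

    @property
    def capped_band(self) -> str:
        return capped_band(self.raw_score)


def _code_tables(catalog: Catalog, codes) -> pd.DataFrame:
    """Per unique code: resolved category and all-of group memberships."""
    codes = pd.Index(codes).unique()
    all_of = [
        (cat.name, gi, group)
        for cat in catalog.categories
        for gi, group in enumerate(cat.all_of_groups)
    ]
    rows = []
    for code in codes:
        if len(code) != 7:
            rows.append((code, None, None))
            continue
        try:
            resolved = catalog.resolve_code(code)
        except ValueError:
            resolved = None
        groups = tuple(
            (name, gi)
            for name, gi, group in all_of
            if any(p.matches(code) for p in group)
        )
        rows.append((code, resolved, groups or None))
    return pd.DataFrame(rows, columns=["atc_code", "category", "all_of_hits"]).set_index(
        "atc_code"
    )


def _longest_runs_flat(keys: np.ndarray, months: np.ndarray, span: int) -> tuple[np.ndarray, np.ndarray]:
    """Longest consecutive-month run per integer key.

    *months* are offsets in ``[0, span)``; duplicates allowed.  Returns
    ``(unique_keys, max_run_length)``.  Packing keys and months into one
    integer keeps the whole computation in numpy.
    """
    if len(keys) == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    width = span + 1  # +1 gap so runs never continue across keys
    packed = np.unique(keys.astype(np.int64) * width + months)
    k, m = packed // width, packed % width
    new_run = np.empty(len(packed), dtype=bool)
    new_run[0] = True
    new_run[1:] = (k[1:] != k[:-1]) | (m[1:] != m[:-1] + 1)
    run_id = np.cumsum(new_run) - 1
    run_len = np.bincount(run_id)
    run_key = k[new_run]
    ukeys, inv = np.unique(run_key, return_inverse=True)
    best = np.zeros(len(ukeys), dtype=np.int64)
    np.maximum.at(best, inv, run_len)
    return ukeys, best


def identify_t2dm(patient_claims: pd.DataFrame, rule: ChronicityRule = ChronicityRule()) -> bool:
    """T2DM proxy for one patient: chronic OAH (A10B) dispensing, class-pooled."""
    months = patient_claims.loc[
        patient_claims["atc_code"].str.startswith(OAH_PREFIX), "month"
    ]
    return month_run_length(months) >= rule.min_consecutive


def assign_conditions(
    patient_claims: pd.DataFrame,
    catalog: Catalog,
    rule: ChronicityRule = ChronicityRule(),
) -> frozenset[str]:
    """Chronic-condition category set for a single patient's claims."""
    if patient_claims.empty:
        return frozenset()
    if patient_claims["patient_id"].nunique() > 1:
        raise ValueError("assign_conditions expects claims for a single patient")
    codes = _code_tables(catalog, patient_claims["atc_code"])
    months_by_code: dict[str, set[int]] = {}
    for code, month in zip(patient_claims["atc_code"], patient_claims["month"]):
        months_by_code.setdefault(code, set()).add(parse_month(month))

    assigned = set()
    months_by_category: dict[str, set[int]] = {}
    months_by_group: dict[tuple[str, int], set[int]] = {}
    for code, months in months_by_code.items():
        row = codes.loc[code]
        if row["category"] is not None:
            months_by_category.setdefault(row["category"], set()).update(months)
        for hit in row["all_of_hits"] or ():
            months_by_group.setdefault(hit, set()).update(months)

    for cat in catalog.categories:
        if cat.all_of_groups:
            ok = all(
                month_run_length(months_by_group.get((cat.name, gi), ()))
                >= rule.min_consecutive
                for gi in range(len(cat.all_of_groups))
            )
        else:
            ok = (
                month_run_length(months_by_category.get(cat.name, ()))
                >= rule.min_consecutive
            )
        if ok:
            assigned.add(cat.name)
    return frozenset(assigned)


def score_cohort(
    claims: pd.DataFrame,
    demographics: pd.DataFrame,
    catalog: Catalog,
    rule: ChronicityRule = ChronicityRule(),
    *,
    inclusion: str = "chronic_any",
) -> pd.DataFrame:
    """Score every cohort member; returns one profile row per included patient.

    Output columns: ``patient_id, sex, age_band, t2dm, raw_score,
    capped_band, conditions`` (semicolon-joined sorted category names).
    The default inclusion rule keeps patients with at least
    ``rule.min_consecutive`` consecutive months of any dispensing;
    ``inclusion="any_dispensing"`` keeps anyone with at least one record.
    """
    if inclusion not in INCLUSION_MODES:
        raise ValueError(f"inclusion must be one of {INCLUSION_MODES}")
    unknown = set(claims["patient_id"]) - set(demographics["patient_id"])
    if unknown:
        raise ValueError(
            f"claims reference patient(s) missing from demographics: {sorted(unknown)[:5]}"
        )
    if demographics.empty or claims.empty:
        return _empty_profiles()

    pid_codes, pid_labels = pd.factorize(claims["patient_id"])
    month_map = {m: parse_month(m) for m in claims["month"].unique()}
    mi = claims["month"].map(month_map).to_numpy()
    mi_off = mi - mi.min()
    span = int(mi_off.max()) + 1
    min_run = rule.min_consecutive

    # inclusion filter
    if inclusion == "any_dispensing":
        included_pids = set(pid_labels)
    else:
        keys, runs = _longest_runs_flat(pid_codes, mi_off, span)
        included_pids = set(pid_labels[keys[runs >= min_run]])

    # per unique ATC code: attributed category and all-of group memberships
    code_inv, code_labels = pd.factorize(claims["atc_code"])
    code_labels = np.asarray(code_labels)
    code_info = _code_tables(catalog, code_labels)
    cat_names = [c.name for c in catalog.categories]
    cat_index = {name: i for i, name in enumerate(cat_names)}
    all_of_cats = [c for c in catalog.categories if c.all_of_groups]
    all_of_keys = [
        (c.name, gi) for c in all_of_cats for gi in range(len(c.all_of_groups))
    ]
    group_index = {key: i for i, key in enumerate(all_of_keys)}

    code_cat = np.full(len(code_labels), -1, dtype=np.int64)
    code_groups: list[tuple[int, ...]] = []
    code_is_oah = np.zeros(len(code_labels), dtype=bool)
    for j, code in enumerate(code_labels):
        info = code_info.loc[code]
        if info["category"] is not None:
            code_cat[j] = cat_index[info["category"]]
        code_groups.append(
            tuple(group_index[h] for h in (info["all_of_hits"] or ()))
        )
        code_is_oah[j] = code.startswith(OAH_PREFIX)

    # plain categories via single-category attribution
    row_cat = code_cat[code_inv]
    mask = row_cat >= 0
    n_cat = len(cat_names)
    keys, runs = _longest_runs_flat(
        pid_codes[mask] * n_cat + row_cat[mask], mi_off[mask], span
    )
    chronic_keys = keys[runs >= min_run]
    chronic = pd.DataFrame(
        {
            "patient_id": pid_labels[chronic_keys // n_cat],
            "category": np.array(cat_names, dtype=object)[chronic_keys % n_cat],
        }
    )

    # all-of categories assessed on raw group matches
    if all_of_cats:
        chronic = chronic[~chronic["category"].isin([c.name for c in all_of_cats])]
        n_grp = len(all_of_keys)
        rep_rows_list, rep_grp_list = [], []
        for j, groups in enumerate(code_groups):
            if not groups:
                continue
            rows_j = np.flatnonzero(code_inv == j)
            for g in groups:
                rep_rows_list.append(rows_j)
                rep_grp_list.append(np.full(len(rows_j), g, dtype=np.int64))
        if rep_rows_list:
            rep_rows = np.concatenate(rep_rows_list)
            rep_grp = np.concatenate(rep_grp_list)
            gkeys, gruns = _longest_runs_flat(
                pid_codes[rep_rows] * n_grp + rep_grp, mi_off[rep_rows], span
            )
            ok = gkeys[gruns >= min_run]
            chronic_group_pairs = {(int(k // n_grp), int(k % n_grp)) for k in ok}
        else:
            chronic_group_pairs = set()
        extra = []
        for cat in all_of_cats:
            need = [group_index[(cat.name, gi)] for gi in range(len(cat.all_of_groups))]
            pids_ok = set.intersection(
                *[
                    {p for p, g in chronic_group_pairs if g == gi}
                    for gi in need
                ]
            ) if need else set()
            extra.extend((pid_labels[p], cat.name) for p in pids_ok)
        if extra:
            chronic = pd.concat(
                [chronic, pd.DataFrame(extra, columns=["patient_id", "category"])],
                ignore_index=True,
            )

    cond_lists = (
        chronic.sort_values(["patient_id", "category"])
        .groupby("patient_id")["category"]
        .agg(list)
    )

    # T2DM flag: pooled A10B months
    oah_mask = code_is_oah[code_inv]
    okeys, oruns = _longest_runs_flat(pid_codes[oah_mask], mi_off[oah_mask], span)
    t2dm_ids = set(pid_labels[okeys[oruns >= min_run]])

    profiles = demographics[demographics["patient_id"].isin(included_pids)].copy()
    if profiles.empty:
        return _empty_profiles()
    profiles = profiles.reset_index(drop=True)
    conds = profiles["patient_id"].map(cond_lists)
    conds = conds.apply(lambda v: v if isinstance(v, list) else [])
    profiles["t2dm"] = profiles["patient_id"].isin(t2dm_ids)
    profiles["raw_score"] = conds.str.len().astype(int)
    profiles["capped_band"] = profiles["raw_score"].map(capped_band)
    profiles["conditions"] = conds.str.join(";")
    return profiles.sort_values("patient_id", kind="mergesort").reset_index(drop=True)


def _empty_profiles() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": pd.Series(dtype=str),
            "sex": pd.Series(dtype=str),
            "age_band": pd.Series(dtype=str),
            "t2dm": pd.Series(dtype=bool),
            "raw_score": pd.Series(dtype=int),
            "capped_band": pd.Series(dtype=str),
            "conditions": pd.Series(dtype=str),
        }
    )


PROFILE_COLUMNS = list(_empty_profiles().columns)


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles[PROFILE_COLUMNS].to_csv(path, index=False)


def read_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "conditions": str, "capped_band": str},
        keep_default_na=False,
    )
    df["t2dm"] = df["t2dm"].astype(str).str.lower().isin(["true", "1"])
    df["raw_score"] = df["raw_score"].astype(int)
    return df[PROFILE_COLUMNS]
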