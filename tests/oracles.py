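"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written with plain strings, loops and
enumeration — no reuse of the package's vectorized code paths.
"""

from __future__ import annotations

import re

import numpy as np

# standalone ATC grammar oracle (letter from the 14 anatomical groups,
# two digits, optional letter, letter, two digits)
ATC_ORACLE_RE = re.compile(r"^[ABCDGHJLMNPRSV][0-9][0-9]([A-Z]([A-Z]([0-9][0-9])?)?)?$")


def oracle_is_valid_atc(code: str) -> bool:
    return len(code) in (3, 4, 5, 7) and ATC_ORACLE_RE.match(code) is not None


def oracle_match(includes: list[str], excludes: list[str], code: str) -> bool:
    """Prefix scan with exclusion dominance."""
    for pat in excludes:
        if code[: len(pat)] == pat:
            return False
    for pat in includes:
        if code[: len(pat)] == pat:
            return True
    return False


def oracle_categories_for_code(catalog, code: str) -> list[str]:
    """Brute-force scan of every category's patterns, priority order."""
    hits = []
    for cat in catalog.categories:
        inc = [p.code for p in cat.includes]
        exc = [p.code for p in cat.excludes]
        if oracle_match(inc, exc, code):
            hits.append((cat.priority_rank, cat.name))
    return [name for _, name in sorted(hits)]


def oracle_longest_run(month_indices) -> int:
    """Enumerate every candidate window instead of a single linear pass."""
    months = set(month_indices)
    best = 0
    for start in months:
        length = 0
        while start + length in months:
            length += 1
        best = max(best, length)
    return best


def oracle_assign_conditions(records, catalog, min_consecutive=3) -> set[str]:
    """records: iterable of (month_index, full_code) for one patient."""
    months_by_code: dict[str, set[int]] = {}
    for mi, code in records:
        months_by_code.setdefault(code, set()).add(mi)

    # single-category attribution: each code to its top matching category
    months_by_category: dict[str, set[int]] = {}
    for code, months in months_by_code.items():
        cats = oracle_categories_for_code(catalog, code)
        if cats:
            months_by_category.setdefault(cats[0], set()).update(months)

    assigned = set()
    for cat in catalog.categories:
        if cat.all_of_groups:
            ok = True
            for group in cat.all_of_groups:
                pats = [p.code for p in group]
                months = set()
                for code, mset in months_by_code.items():
                    if oracle_match(pats, [], code):
                        months |= mset
                if oracle_longest_run(months) < min_consecutive:
                    ok = False
            if ok:
                assigned.add(cat.name)
        else:
            months = months_by_category.get(cat.name, set())
            if oracle_longest_run(months) >= min_consecutive:
                assigned.add(cat.name)
    return assigned


def oracle_identify_t2dm(records, min_consecutive=3) -> bool:
    months = {mi for mi, code in records if code.startswith("A10B")}
    return oracle_longest_run(months) >= min_consecutive


def oracle_pearson_chi2(table: np.ndarray) -> tuple[float, int]:
    """Textbook Pearson chi-square by explicit summation."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            expected = table[i].sum() * table[:, j].sum() / total
            chi2 += (table[i, j] - expected) ** 2 / expected
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return chi2, df


def oracle_logistic_irls(X: np.ndarray, y: np.ndarray, n_iter: int = 50):
    """Newton-Raphson logistic regression; returns (beta, standard errors)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        H = X.T @ (X * W[:, None])
        grad = X.T @ (y - mu)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    H = X.T @ (X * (mu * (1 - mu))[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, se
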