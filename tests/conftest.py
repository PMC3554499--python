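from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rxcomorbid import load_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_catalog("rxriskv_mod_2010")


@pytest.fixture(scope="session")
def code_pool(catalog):
    """Full ATC codes exercising the catalog: pattern-derived, excluded,
    anti-diabetic and unmatched codes."""
    pool = set()
    for cat in catalog.categories:
        for p in sorted(pat.code for pat in cat.includes):
            pool.add(pad_to_full(p))
        for p in sorted(pat.code for pat in cat.excludes):
            pool.add(p)
    pool.update({"A10BA02", "A10BB01", "A10AB01", "V01AA01", "B05AA01", "J01CA04"})
    return sorted(pool)


def pad_to_full(pattern: str) -> str:
    """Deterministically extend a truncated pattern to a full 7-char code."""
    suffix = "AA01"
    return pattern + suffix[len(pattern) - 3 :] if len(pattern) < 7 else pattern


def make_claims(rows):
    """rows: iterable of (patient_id, month, code, cost)."""
    return pd.DataFrame(
        rows, columns=["patient_id", "month", "atc_code", "ingredient_cost"]
    )


def make_demo(rows):
    """rows: iterable of (patient_id, sex, age_band)."""
    return pd.DataFrame(rows, columns=["patient_id", "sex", "age_band"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
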