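import numpy as np
import pandas as pd
import pytest

from rxcomorbid.scoring import capped_band
from rxcomorbid.stats import (
    adjusted_odds_ratios,
    distribution_chi_square,
    fit_adjusted_logit,
    format_p,
    high_low_split,
    median_iqr_table,
    prevalence_from_counts,
    prevalence_table,
    round_half_up,
    stratum_counts,
)

from oracles import oracle_logistic_irls, oracle_pearson_chi2


def profiles_from_scores(t2dm_scores, non_scores, rng=None):
    """Build a profile frame with mixed strata from two score lists."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for i, (score, flag) in enumerate(
        [(s, True) for s in t2dm_scores] + [(s, False) for s in non_scores]
    ):
        rows.append(
            {
                "patient_id": f"P{i:06d}",
                "sex": rng.choice(["male", "female"]),
                "age_band": rng.choice(["65-69", "70-74", "75+"]),
                "t2dm": flag,
                "raw_score": int(score),
                "capped_band": capped_band(int(score)),
                "conditions": "",
            }
        )
    return pd.DataFrame(rows)


class TestRounding:
    @pytest.mark.parametrize(
        "x,nd,expected",
        [(9.65, 1, 9.7), (9.64, 1, 9.6), (0.05, 1, 0.1), (1.005, 2, 1.01), (2.5, 0, 3.0)],
    )
    def test_half_up(self, x, nd, expected):
        assert round_half_up(x, nd) == expected

    def test_p_format(self):
        assert format_p(0.00005) == "<0.0001"
        assert format_p(0.0234) == "0.0234"


class TestPrevalence:
    def test_simple_counts(self):
        counts = pd.DataFrame(
            [
                ("male", "65-69", "t2dm", 10),
                ("male", "65-69", "non_t2dm", 90),
                ("female", "70-74", "t2dm", 5),
                ("female", "70-74", "non_t2dm", 95),
            ],
            columns=["sex", "age_band", "group", "n"],
        )
        rep = prevalence_from_counts(counts)
        assert rep["n_total"] == 200
        assert rep["overall_prevalence_pct"] == 7.5
        assert rep["by_sex"]["male"] == 10.0
        assert rep["by_age_band"]["70-74"] == 5.0

    def test_zero_t2dm(self):
        counts = pd.DataFrame(
            [("male", "65-69", "non_t2dm", 50)], columns=["sex", "age_band", "group", "n"]
        )
        assert prevalence_from_counts(counts)["overall_prevalence_pct"] == 0.0

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            prevalence_table(profiles_from_scores([], []))

    def test_from_profiles_matches_counts(self):
        prof = profiles_from_scores([5, 4], [3, 2, 1])
        rep = prevalence_table(prof)
        assert rep["n_t2dm"] == 2
        assert rep["overall_prevalence_pct"] == 40.0
        counts = stratum_counts(prof)
        assert counts["n"].sum() == 5


class TestMedianIqr:
    def test_three_scores(self):
        prof = profiles_from_scores([3, 5, 6], [])
        pooled = [s for s in median_iqr_table(prof) if s.sex is None and s.group == "t2dm"][0]
        assert pooled.median_score == 5
        assert pooled.iqr == (3, 6)

    def test_single_patient(self):
        prof = profiles_from_scores([4], [])
        pooled = [s for s in median_iqr_table(prof) if s.sex is None and s.group == "t2dm"][0]
        assert pooled.median_score == 4
        assert pooled.iqr == (4, 4)

    def test_empty_stratum_reported_not_error(self):
        prof = profiles_from_scores([4], [])
        rows = median_iqr_table(prof)
        empties = [s for s in rows if s.n == 0]
        assert empties and all(s.median_score is None for s in empties)

    def test_integer_quartiles(self):
        prof = profiles_from_scores([1, 2, 3, 4, 5, 6], [])
        pooled = [s for s in median_iqr_table(prof) if s.sex is None and s.group == "t2dm"][0]
        # lower-interpolation quartiles stay on the integer grid
        assert pooled.median_score in (3, 4)
        assert all(isinstance(v, int) for v in pooled.iqr)


class TestChiSquare:
    def test_uniform_table_zero(self):
        prof = profiles_from_scores([0] * 10 + [1] * 10, [0] * 10 + [1] * 10)
        res = distribution_chi_square(prof)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_hand_2x3_matches_textbook_formula(self):
        table = np.array([[10, 20, 30], [15, 10, 35]])
        from rxcomorbid.stats import _pearson_chi2

        chi2, df, _ = _pearson_chi2(pd.DataFrame(table))
        ochi2, odf = oracle_pearson_chi2(table)
        assert chi2 == pytest.approx(ochi2, rel=1e-12)
        assert df == odf

    def test_permutation_invariance(self):
        from rxcomorbid.stats import _pearson_chi2

        t = pd.DataFrame([[12, 7], [5, 20], [9, 9]])
        a = _pearson_chi2(t)[0]
        b = _pearson_chi2(t.iloc[::-1])[0]
        c = _pearson_chi2(t[t.columns[::-1]])[0]
        assert a == pytest.approx(b) == pytest.approx(c)

    def test_all_eleven_bands_gives_df_10(self):
        rng = np.random.default_rng(8)
        scores = list(range(12)) * 20  # covers bands 0..9 and >=10 in both groups
        prof = profiles_from_scores(scores, scores, rng)
        res = distribution_chi_square(prof)
        assert res.df == 10
        assert len(res.table) == 11

    def test_one_group_empty_errors(self):
        with pytest.raises(ValueError):
            distribution_chi_square(profiles_from_scores([1, 2], []))


class TestHighLowSplit:
    def test_null_case(self):
        rng = np.random.default_rng(42)
        scores = rng.poisson(3, size=4000)
        prof = profiles_from_scores(scores[:2000], scores[2000:], rng)
        rep = high_low_split(prof)
        assert rep.odds_ratio == pytest.approx(1.0, abs=0.25)
        assert rep.chi_square.statistic < 10

    def test_threshold_is_t2dm_median(self):
        prof = profiles_from_scores([5, 5, 5], [1, 1, 1])
        assert high_low_split(prof).threshold == 5

    def test_degenerate_all_below(self):
        prof = profiles_from_scores([2, 2, 2], [2, 2, 2])
        rep = high_low_split(prof)
        # threshold 2, everyone high -> one empty margin
        assert rep.degenerate

    def test_empty_t2dm_group_errors(self):
        with pytest.raises(ValueError):
            high_low_split(profiles_from_scores([], [1, 2]))

    def test_or_equals_cross_product_without_covariates(self):
        # single-stratum cohort: adjustment columns drop, model is const+t2dm
        rows = []
        counts = {(True, True): 30, (True, False): 20, (False, True): 25, (False, False): 40}
        i = 0
        for (t2, high), k in counts.items():
            for _ in range(k):
                score = 5 if high else 1
                rows.append(
                    {
                        "patient_id": f"P{i:04d}", "sex": "female", "age_band": "65-69",
                        "t2dm": t2, "raw_score": score,
                        "capped_band": capped_band(score), "conditions": "",
                    }
                )
                i += 1
        prof = pd.DataFrame(rows)
        rep = high_low_split(prof)
        cross = (30 * 40) / (20 * 25)
        assert rep.odds_ratio == pytest.approx(cross, rel=1e-5)


class TestAdjustedOddsRatios:
    def _profiles_with_condition(self, has, t2dm, sex, age):
        return pd.DataFrame(
            {
                "patient_id": [f"P{i:05d}" for i in range(len(has))],
                "sex": sex,
                "age_band": age,
                "t2dm": t2dm,
                "raw_score": has.astype(int),
                "capped_band": [capped_band(int(h)) for h in has],
                "conditions": np.where(has, "Hyperlipidemia", ""),
            }
        )

    def test_eight_patient_fixture_matches_irls_oracle(self):
        t2dm = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        a70 = np.array([0, 0, 1, 1, 0, 1, 1, 0], bool)
        male = np.array([1, 1, 0, 0, 1, 1, 1, 0], bool)
        y = np.array([1, 0, 0, 1, 0, 0, 1, 1], float)
        prof = self._profiles_with_condition(
            y.astype(bool), t2dm,
            np.where(male, "male", "female"), np.where(a70, "70-74", "65-69"),
        )
        fit = fit_adjusted_logit(prof, y)
        X = np.column_stack([np.ones(8), t2dm, a70, male]).astype(float)
        beta, se = oracle_logistic_irls(X, y)
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-5)
        assert np.allclose(fit.bse.to_numpy(), se, atol=1e-4)

    def test_null_ci_covers_one(self):
        rng = np.random.default_rng(3)
        n = 5000
        t2dm = rng.random(n) < 0.3
        has = rng.random(n) < 0.4  # independent of everything
        prof = self._profiles_with_condition(
            has, t2dm, rng.choice(["male", "female"], n),
            rng.choice(["65-69", "70-74", "75+"], n),
        )
        results = adjusted_odds_ratios(prof)
        assert len(results) == 1
        lo, hi = results[0].ci95
        assert lo <= 1.0 <= hi

    def test_prevalence_filter(self):
        rng = np.random.default_rng(4)
        n = 1000
        t2dm = rng.random(n) < 0.3
        has = rng.random(n) < 0.05  # below the 10% default threshold
        prof = self._profiles_with_condition(
            has, t2dm, rng.choice(["male", "female"], n),
            rng.choice(["65-69", "70-74", "75+"], n),
        )
        assert adjusted_odds_ratios(prof) == []
        assert len(adjusted_odds_ratios(prof, min_prevalence_pct=1.0)) == 1

    def test_separation_flagged(self):
        # condition present iff T2DM: perfect separation
        t2dm = np.array([1, 1, 1, 0, 0, 0], bool)
        prof = self._profiles_with_condition(
            t2dm.copy(), t2dm,
            np.array(["male", "female"] * 3), np.array(["65-69"] * 6),
        )
        results = adjusted_odds_ratios(prof, min_prevalence_pct=0.0)
        assert results[0].flagged is not None
        assert results[0].odds_ratio is None
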