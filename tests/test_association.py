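"""Odds ratios, chi-square, Fisher exact and logistic regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmaquant import association as assoc

TABLE2 = assoc.ContingencyTable2x2(a=124, b=2, c=118, d=14)


def fisher_enumeration(t: assoc.ContingencyTable2x2) -> float:
    """Independent oracle: sum hypergeometric probabilities of every table
    with the observed margins whose probability does not exceed the
    observed table's."""
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    N = t.total
    lo, hi = max(0, c1 - r2), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, N, r1, c1)
    pobs = stats.hypergeom.pmf(t.a, N, r1, c1)
    return float(pmf[pmf <= pobs * (1 + 1e-9)].sum())


class TestOddsRatio:
    def test_published_cross_tab(self):
        """The 126-low/132-high vs CNS-relapse table gives OR 7.36 with
        Woolf 95% CI (1.64, 33.06)."""
        res = assoc.odds_ratio(TABLE2)
        assert round(res.or_, 2) == 7.36
        assert round(res.ci_low, 2) == 1.64
        assert round(res.ci_high, 2) == 33.06
        assert res.method == "woolf"

    def test_symmetric_table_is_unity(self):
        res = assoc.odds_ratio(assoc.ContingencyTable2x2(10, 10, 10, 10))
        assert res.or_ == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_haldane_correction_hand_value(self):
        """(5,0,5,5): +0.5 to every cell gives (5.5*5.5)/(0.5*5.5) = 11."""
        res = assoc.odds_ratio(assoc.ContingencyTable2x2(5, 0, 5, 5))
        assert res.method == "haldane_corrected"
        assert res.or_ == pytest.approx(11.0)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            assoc.odds_ratio(assoc.ContingencyTable2x2(0, 0, 5, 5))

    def test_ci_symmetric_on_log_scale(self):
        res = assoc.odds_ratio(TABLE2)
        assert np.log(res.or_) - np.log(res.ci_low) == pytest.approx(
            np.log(res.ci_high) - np.log(res.or_)
        )

    def test_woolf_ci_narrows_as_counts_scale_up(self):
        widths = []
        for k in (1, 2, 5, 10):
            r = assoc.odds_ratio(
                assoc.ContingencyTable2x2(12 * k, 3 * k, 9 * k, 7 * k)
            )
            widths.append(np.log(r.ci_high) - np.log(r.ci_low))
        assert all(a > b for a, b in zip(widths, widths[1:]))


class TestPearsonChi2:
    def test_published_table_p(self):
        stat, p = assoc.pearson_chi2(TABLE2)
        assert round(p, 3) == 0.003

    def test_identical_rows_give_null(self):
        stat, p = assoc.pearson_chi2(assoc.ContingencyTable2x2(8, 4, 8, 4))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_definitional_sum_over_cells(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(1, 40, 4)
        t = assoc.ContingencyTable2x2(int(a), int(b), int(c), int(d))
        arr = t.as_array()
        exp = np.outer(arr.sum(1), arr.sum(0)) / t.total
        oracle = ((arr - exp) ** 2 / exp).sum()
        stat, _ = assoc.pearson_chi2(t)
        assert stat == pytest.approx(oracle, rel=1e-12)

    def test_invariant_under_transpose_and_swaps(self):
        t = TABLE2
        stat, _ = assoc.pearson_chi2(t)
        for other in [
            assoc.ContingencyTable2x2(t.a, t.c, t.b, t.d),  # transpose
            assoc.ContingencyTable2x2(t.c, t.d, t.a, t.b),  # row swap
            assoc.ContingencyTable2x2(t.b, t.a, t.d, t.c),  # column swap
        ]:
            assert assoc.pearson_chi2(other)[0] == pytest.approx(stat)


class TestFisherExact:
    def test_small_table_against_enumeration(self):
        t = assoc.ContingencyTable2x2(2, 1, 1, 2)
        assert assoc.fisher_exact(t) == pytest.approx(fisher_enumeration(t), abs=1e-12)

    def test_zero_margin_is_one(self):
        assert assoc.fisher_exact(assoc.ContingencyTable2x2(3, 0, 5, 0)) == 1.0

    def test_published_table_matches_enumeration(self):
        assert assoc.fisher_exact(TABLE2) == pytest.approx(
            fisher_enumeration(TABLE2), abs=1e-10
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_random_tables_match_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        cells = rng.multinomial(int(rng.integers(4, 61)), [0.25] * 4)
        t = assoc.ContingencyTable2x2(*map(int, cells))
        assert assoc.fisher_exact(t) == pytest.approx(
            fisher_enumeration(t), abs=1e-10
        )


class TestLogisticFit:
    def test_saturated_2x2_equals_cross_product_or(self):
        """exp(slope) of the one-covariate logistic model equals the
        cross-product odds ratio, and the Wald CI equals the Woolf CI."""
        t = TABLE2
        x = np.r_[np.zeros(t.a + t.b), np.ones(t.c + t.d)]
        y = np.r_[np.zeros(t.a), np.ones(t.b), np.zeros(t.c), np.ones(t.d)]
        fit = assoc.logistic_fit(pd.DataFrame({"high": x}), y)
        res = assoc.odds_ratio(t)
        assert fit.or_["high"] == pytest.approx(res.or_, abs=1e-6)
        assert fit.ci_low["high"] == pytest.approx(res.ci_low, abs=1e-4)
        assert fit.ci_high["high"] == pytest.approx(res.ci_high, abs=1e-4)

    def test_quasi_separated_level_is_flagged(self):
        x = np.r_[np.zeros(30), np.ones(10)]
        y = np.r_[(np.arange(30) < 5).astype(float), np.ones(10)]
        fit = assoc.logistic_fit(pd.DataFrame({"g": x}), y)
        assert fit.separation_flags["g"]
        assert np.isnan(fit.summary_frame().loc["g", "odds_ratio"])

    def test_intercept_only_recovers_prevalence(self):
        y = np.r_[np.ones(7), np.zeros(13)]
        fit = assoc.logistic_fit(pd.DataFrame(index=range(20)), y)
        p = 1 / (1 + np.exp(-fit.params["const"]))
        assert p == pytest.approx(0.35, abs=1e-8)

    def test_single_class_outcome_raises(self):
        with pytest.raises(ValueError):
            assoc.logistic_fit(pd.DataFrame({"x": [1.0, 2.0]}), [1, 1])


@pytest.fixture(scope="module")
def null_cohort():
    from tmaquant import synthetic as syn

    cfg = syn.SimConfig(
        n_patients=500,
        cells_per_core_mean=80.0,
        relapse=syn.RelapseModel(baseline_logit=-2.2, beta_density=0.0),
        seed=31,
    )
    clin = syn.patient_level_cohort(cfg)
    med = clin["true_nrf2_ck_density"].median()
    labels = pd.DataFrame(
        {"nrf2_ck_density_whole": clin["true_nrf2_ck_density"] > med}
    )
    return labels, clin


class TestRelapseScreens:

    def test_null_density_ci_covers_one(self, null_cohort):
        labels, clin = null_cohort
        report = assoc.relapse_screens(labels, clin)
        uni = report["univariate"]
        row = uni[
            (uni["outcome"] == "cns_relapse")
            & (uni["variable"] == "nrf2_ck_density_whole")
        ].iloc[0]
        assert row["ci_low"] <= 1.0 <= row["ci_high"]

    def test_age_is_a_single_continuous_coefficient(self, null_cohort):
        labels, clin = null_cohort
        report = assoc.relapse_screens(labels, clin)
        uni = report["univariate"]
        age_rows = uni[(uni["outcome"] == "cns_relapse") & (uni["variable"] == "age")]
        assert len(age_rows) == 1
        assert age_rows.iloc[0]["term"] == "age"

    def test_multivariate_includes_stage_indicators_against_ia(self, null_cohort):
        labels, clin = null_cohort
        report = assoc.relapse_screens(labels, clin)
        idx = report["multivariate"].params.index
        assert "stage_IA" not in idx
        assert {"stage_IB", "stage_IIIB"} <= set(idx)
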