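"""Fisher/chi-square dispatch, t tests, logistic fits and diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from _oracles import auc_mann_whitney, fisher_enumerate, logit_grid_search
from actipat import reference as ref
from actipat.stats import (
    categorical_test,
    chi_square,
    diagnostics,
    fisher_exact,
    hosmer_lemeshow,
    logistic_fit,
    reverse_model,
    t_test,
    t_test_from_stats,
)


class TestFisher:
    @pytest.mark.parametrize(
        "key,digits",
        [("age", 3), ("sex", 2), ("risk_factors", 2), ("pa_change", 2)],
    )
    def test_reference_cohort_tables_reproduce_printed_p(self, key, digits):
        t = ref.GROUP_TABLES[key]["counts"]
        p = fisher_exact(t).p_value
        assert round(p, digits) == ref.PRINTED_P[key]

    def test_degenerate_diagonal_table(self):
        assert fisher_exact([[1, 0], [0, 1]]).p_value == 1.0

    def test_empty_margin_convention(self):
        assert fisher_exact([[0, 0], [3, 4]]).p_value == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(200):
            t = rng.integers(0, 16, size=(2, 2))
            if t.sum() == 0 or t.sum() > 60:
                continue
            assert fisher_exact(t).p_value == pytest.approx(
                fisher_enumerate(t), abs=1e-9
            )

    def test_invariant_under_row_and_column_swaps(self, rng):
        for _ in range(50):
            t = rng.integers(0, 12, size=(2, 2)) + 1
            p = fisher_exact(t).p_value
            assert fisher_exact(t[::-1]).p_value == pytest.approx(p)
            assert fisher_exact(t[:, ::-1]).p_value == pytest.approx(p)
            assert fisher_exact(t.T).p_value == pytest.approx(p)


class TestChiSquareAndDispatch:
    def test_perfect_independence(self):
        res = chi_square([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_computed_statistic(self):
        res = chi_square([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(6.6667, abs=1e-4)
        assert res.df == 1

    def test_zero_expected_cell_directs_to_fisher(self):
        with pytest.raises(ValueError, match="[Ff]isher"):
            chi_square([[0, 0], [5, 5]])

    def test_small_count_dispatches_to_fisher(self):
        res = categorical_test(ref.GROUP_TABLES["age"]["counts"])  # cell 3 < 5
        assert res.method == "fisher"

    def test_large_counts_dispatch_to_chi_square(self):
        assert categorical_test([[10, 20], [20, 10]]).method == "chi_square"

    def test_null_type_one_error_at_most_nominal(self, rng):
        """Fisher dispatch on small-n null tables rejects at <= 5%."""
        rejections = 0
        reps = 2000
        for _ in range(reps):
            row = rng.binomial(1, 0.5, size=20)
            col = rng.binomial(1, 0.5, size=20)
            t = pd.crosstab(row, col).reindex(
                index=[0, 1], columns=[0, 1], fill_value=0
            ).to_numpy()
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            if categorical_test(t).p_value <= 0.05:
                rejections += 1
        assert rejections / reps <= 0.05


class TestTTest:
    def test_identical_groups(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_pooled_example(self):
        res = t_test([1, 2, 3], [2, 3, 4])
        assert abs(res.statistic) == pytest.approx(1.2247, abs=1e-4)
        assert res.df == 4

    def test_summary_and_raw_paths_agree(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, size=int(rng.integers(3, 15)))
            b = rng.normal(0.5, 2, size=int(rng.integers(3, 15)))
            for variant in ("pooled", "welch"):
                raw = t_test(a, b, variant)
                summ = t_test_from_stats(
                    a.mean(), a.std(ddof=1), a.size,
                    b.mean(), b.std(ddof=1), b.size, variant,
                )
                assert summ.statistic == pytest.approx(raw.statistic)
                assert summ.p_value == pytest.approx(raw.p_value)

    def test_reference_ee_rows_significant_under_pooled_t(self):
        for seg, printed_bound in (("weekday", 0.001), ("weekend", 0.003)):
            s = ref.EE_SUMMARY[seg]
            res = t_test_from_stats(*s["stable"], *s["shifting"])
            assert res.p_value <= printed_bound + 5e-4


class TestLogistic:
    def test_balanced_predictor_gives_unit_odds_ratio(self):
        df = pd.DataFrame({"x": [0, 0, 1, 1] * 5})
        y = [0, 1, 0, 1] * 5
        fit = logistic_fit(df[["x"]], y)
        assert fit.odds_ratio[1] == pytest.approx(1.0, abs=1e-6)

    def test_or_equals_cross_product_ratio(self, rng):
        for _ in range(20):
            t = rng.integers(1, 20, size=(2, 2))
            x = np.repeat([0, 0, 1, 1], t.flatten())
            y = np.repeat([0, 1, 0, 1], t.flatten())
            fit = logistic_fit(pd.DataFrame({"x": x}), y)
            cpr = (t[1, 1] * t[0, 0]) / (t[1, 0] * t[0, 1])
            assert fit.odds_ratio[1] == pytest.approx(cpr, rel=1e-4)

    def test_matches_grid_search_likelihood_maximizer(self, rng):
        x = rng.binomial(1, 0.5, size=20).astype(float)
        y = rng.binomial(1, 0.3 + 0.4 * x)
        if y.sum() in (0, y.size):
            y[0] = 1 - y[0]
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        _, b0, b1 = logit_grid_search(x, y, (-4, 4), (-4, 4), steps=161)
        assert fit.coef[0] == pytest.approx(b0, abs=0.06)
        assert fit.coef[1] == pytest.approx(b1, abs=0.06)

    def test_wald_ci_brackets_or(self, rng):
        x = rng.binomial(1, 0.5, 60)
        y = rng.binomial(1, 0.2 + 0.5 * x)
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        assert (fit.ci_low <= fit.odds_ratio).all()
        assert (fit.odds_ratio <= fit.ci_high).all()

    def test_separation_flagged_not_silent(self):
        df = pd.DataFrame({"x": [0] * 10 + [1] * 10})
        y = [0] * 10 + [1] * 10
        fit = logistic_fit(df[["x"]], y)
        assert fit.separation

    def test_all_event_outcome_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(pd.DataFrame({"x": [0, 1]}), [1, 1])

    def test_wald_ci_coverage_near_nominal(self, rng):
        """95% CI covers the true log-odds in about 95% of replicates."""
        beta = 1.0
        covered = 0
        reps = 500
        for _ in range(reps):
            x = rng.binomial(1, 0.5, 150).astype(float)
            p = 1 / (1 + np.exp(-(-1.0 + beta * x)))
            y = rng.binomial(1, p)
            if y.sum() in (0, y.size):
                continue
            fit = logistic_fit(pd.DataFrame({"x": x}), y)
            if fit.ci_low[1] <= np.exp(beta) <= fit.ci_high[1]:
                covered += 1
        assert covered / reps == pytest.approx(0.95, abs=0.03)


class TestDiagnostics:
    def test_intercept_only_pseudo_r2_zero(self, rng):
        y = rng.binomial(1, 0.4, 50)
        fit = logistic_fit(pd.DataFrame(index=range(50)), y)
        d = diagnostics(fit, groups=3)
        assert d["pseudo_r2"] == pytest.approx(0.0, abs=1e-9)

    def test_perfectly_calibrated_groups_hl_zero(self):
        # fitted risk exactly matches group event rates
        probs = np.repeat([0.2, 0.5, 0.8], 10)
        y = np.concatenate([[1, 1] + [0] * 8, [1] * 5 + [0] * 5, [1] * 8 + [0, 0]])
        res = hosmer_lemeshow(probs, y, groups=3)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_auc_agrees_with_mann_whitney(self, rng):
        for _ in range(20):
            y = rng.binomial(1, 0.5, 40)
            if y.sum() in (0, y.size):
                continue
            x = rng.normal(size=40) + y
            fit = logistic_fit(pd.DataFrame({"x": x}), y)
            d = diagnostics(fit, groups=5)
            assert d["auc"] == pytest.approx(auc_mann_whitney(y, fit.fitted), abs=1e-9)


class TestReverseModel:
    def test_null_association_rarely_significant(self):
        """Independent draws: the pattern-group term rejects at ~nominal rate."""
        local = np.random.default_rng(424242)
        n, rejections, reps = 200, 0, 20
        for _ in range(reps):
            data = pd.DataFrame(
                {
                    "participant_id": [str(i) for i in range(n)],
                    "female": local.binomial(1, 0.5, n),
                    "age_ge40": local.binomial(1, 0.4, n),
                    "multi_risk": local.binomial(1, 0.5, n),
                    "group": local.choice(["stable", "shifting"], n),
                }
            )
            fit = reverse_model(data)
            if fit.table().set_index("term").loc["shifting", "p"] <= 0.05:
                rejections += 1
        assert rejections <= 4  # binomial(20, 0.05) exceeds 4 with p < 1e-3
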