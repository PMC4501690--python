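"""Pooled-assay likelihood, MLE, LRT, BH, bootstrap, association tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from flyvirome.prevalence import (
    bh_adjust,
    estimate_by_group,
    global_mean_prevalence,
    loglik,
    lrt_bulk_vs_single,
    mle,
    prevalence_correlation,
    uniform_bulk_closed_form,
    wolbachia_association,
)
from flyvirome.simulate import SurveySpec, gen_survey


def product_oracle(p, assays):
    """Direct product of per-assay probabilities."""
    total = 1.0
    for k, outcome in assays:
        pr_pos = 1.0 - (1.0 - p) ** k
        total *= pr_pos if outcome == "positive" else 1.0 - pr_pos
    return math.log(total) if total > 0 else -math.inf


class TestLoglik:
    def test_matches_product_oracle_for_mixed_bulks(self):
        assays = [(1, "positive"), (1, "negative"), (5, "positive"),
                  (10, "negative"), (3, "positive")]
        for p in (0.01, 0.1, 0.37, 0.9):
            assert loglik(p, assays) == pytest.approx(product_oracle(p, assays))

    def test_impossible_configurations(self):
        assert loglik(0.0, [(1, "positive")]) == -math.inf
        assert loglik(1.0, [(4, "negative")]) == -math.inf

    def test_out_of_range_p_raises(self):
        with pytest.raises(ValueError):
            loglik(1.2, [(1, "positive")])

    def test_unimodal_on_grid(self):
        assays = [(1, "positive")] * 3 + [(1, "negative")] * 7 + \
                 [(5, "positive")] * 2 + [(5, "negative")] * 4
        grid = np.linspace(0.001, 0.999, 999)
        ll = np.array([loglik(p, assays) for p in grid])
        sign_changes = np.sum(np.abs(np.diff(np.sign(np.diff(ll)))) > 0)
        assert sign_changes <= 1  # one interior maximum, no secondary modes


class TestMLE:
    def test_all_negative_pins_zero(self):
        est = mle([(1, "negative")] * 10)
        assert est.p_hat == 0.0 and est.ci_lower == 0.0
        assert est.ci_upper > 0

    def test_all_positive_pins_one(self):
        est = mle([(1, "positive")] * 10)
        assert est.p_hat == 1.0 and est.ci_upper == 1.0
        assert est.ci_lower < 1

    def test_singles_equal_sample_fraction(self):
        for x, n in ((1, 10), (8, 20), (13, 40)):
            assays = [(1, "positive")] * x + [(1, "negative")] * (n - x)
            assert mle(assays).p_hat == pytest.approx(x / n, abs=1e-6)

    def test_uniform_bulks_match_closed_form(self):
        est = mle([(5, "positive")] * 8 + [(5, "negative")] * 12)
        assert est.p_hat == pytest.approx(uniform_bulk_closed_form(8, 20, 5), abs=1e-6)
        assert est.p_hat == pytest.approx(0.0971, abs=5e-4)

    def test_interval_contains_estimate_and_orders(self):
        est = mle([(1, "positive")] * 5 + [(1, "negative")] * 45 + [(10, "positive")] * 3)
        assert 0 <= est.ci_lower <= est.p_hat <= est.ci_upper <= 1
        drop = est.logL_max - loglik(est.ci_lower + 1e-9, list(
            [(1, "positive")] * 5 + [(1, "negative")] * 45 + [(10, "positive")] * 3))
        assert drop == pytest.approx(2.0, abs=1e-3)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mle([])

    def test_interval_coverage_near_nominal(self):
        # 2-logL drop corresponds to ~95.4% asymptotic coverage (chi2(1))
        p_true, n, covered = 0.2, 500, 0
        reps = 200
        rng = np.random.default_rng(7)
        for _ in range(reps):
            x = rng.binomial(n, p_true)
            est = mle([(1, "positive")] * x + [(1, "negative")] * (n - x))
            covered += est.ci_lower <= p_true <= est.ci_upper
        assert 0.90 <= covered / reps <= 0.99

    def test_parameter_recovery_mixed_designs(self):
        rng = np.random.default_rng(11)
        for p_true in (0.05, 0.2, 0.5):
            for design in ("singles", "bulks", "mixed"):
                if design == "bulks" and p_true > 0.2:
                    # bulks of 10 saturate (almost all positive) at high
                    # prevalence and carry no information; skip that cell
                    continue
                estimates = []
                for _ in range(40):
                    assays = []
                    if design in ("singles", "mixed"):
                        x = rng.binomial(200, p_true)
                        assays += [(1, "positive")] * x + [(1, "negative")] * (200 - x)
                    if design in ("bulks", "mixed"):
                        q = 1 - (1 - p_true) ** 10
                        y = rng.binomial(40, q)
                        assays += [(10, "positive")] * y + [(10, "negative")] * (40 - y)
                    estimates.append(mle(assays, grid_resolution=1e-3).p_hat)
                bias = np.mean(estimates) - p_true
                assert abs(bias) < 0.03, (p_true, design, bias)


class TestLRT:
    def test_single_stratum_raises(self):
        with pytest.raises(ValueError):
            lrt_bulk_vs_single([(1, "positive")] * 4 + [(1, "negative")] * 6)

    def test_statistic_nonnegative_and_zero_when_fits_agree(self):
        # bulk data whose closed-form MLE equals the singles MLE exactly:
        # singles 36/100 -> 0.36; bulks k=2 with x/n = 1-(0.64)^2 = 0.5904
        q = 1 - 0.64 ** 2
        assert q == pytest.approx(0.5904)
        assays = ([(1, "positive")] * 36 + [(1, "negative")] * 64
                  + [(2, "positive")] * 5904 + [(2, "negative")] * 4096)
        stat, p = lrt_bulk_vs_single(assays)
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-3)

    def test_power_against_strong_difference(self):
        rng = np.random.default_rng(3)
        x_singles = rng.binomial(400, 0.05)
        q = 1 - 0.5 ** 5
        x_bulks = rng.binomial(100, q)
        assays = ([(1, "positive")] * x_singles + [(1, "negative")] * (400 - x_singles)
                  + [(5, "positive")] * x_bulks + [(5, "negative")] * (100 - x_bulks))
        stat, p = lrt_bulk_vs_single(assays)
        assert p < 1e-3

    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(19)
        rejections = 0
        reps = 300
        for _ in range(reps):
            x = rng.binomial(250, 0.2)
            q = 1 - 0.8 ** 5
            y = rng.binomial(50, q)
            assays = ([(1, "positive")] * x + [(1, "negative")] * (250 - x)
                      + [(5, "positive")] * y + [(5, "negative")] * (50 - y))
            _, p = lrt_bulk_vs_single(assays)
            rejections += p < 0.05
        # binomial 3 SD band around 5% at 300 reps
        assert abs(rejections / reps - 0.05) < 3 * math.sqrt(0.05 * 0.95 / reps) + 0.005


class TestBH:
    def test_all_ones_nothing_significant(self):
        assert not bh_adjust([1.0, 1.0, 1.0]).any()

    def test_hand_stepped_example(self):
        flags = bh_adjust([0.001, 0.9], q=0.05)
        assert flags.tolist() == [True, False]

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=12), st.data())
    @settings(max_examples=50, deadline=None)
    def test_lowering_one_p_never_deselects_others(self, pvals, data):
        idx = data.draw(st.integers(0, len(pvals) - 1))
        before = bh_adjust(pvals)
        lowered = list(pvals)
        lowered[idx] = lowered[idx] / 2
        after = bh_adjust(lowered)
        others = [i for i in range(len(pvals)) if i != idx]
        assert all(after[i] >= before[i] for i in others)


class TestGlobalMean:
    def test_single_location_collapses(self):
        mean, (lo, hi) = global_mean_prevalence([0.3], seed=1)
        assert mean == lo == hi == pytest.approx(0.3)

    def test_identical_estimates_zero_width(self):
        mean, (lo, hi) = global_mean_prevalence([0.2] * 8, seed=1)
        assert lo == hi == pytest.approx(0.2)

    def test_matches_independent_bootstrap_oracle(self):
        est = np.arange(10) / 10
        mean, (lo, hi) = global_mean_prevalence(est, n_boot=5000, seed=123)
        rng = np.random.default_rng(99)
        boot = np.array([est[rng.integers(0, 10, 10)].mean() for _ in range(5000)])
        olo, ohi = np.percentile(boot, [2.5, 97.5])
        assert mean == pytest.approx(est.mean())
        assert lo == pytest.approx(olo, abs=0.02) and hi == pytest.approx(ohi, abs=0.02)


class TestWolbachiaAssociation:
    def test_fisher_combination_arithmetic(self):
        # two locations each with p = 0.05 -> X = -2(ln .05 + ln .05) ~ 11.98, df 4
        x = -2 * (math.log(0.05) + math.log(0.05))
        assert x == pytest.approx(11.983, abs=1e-3)
        assert stats.chi2.sf(x, 4) == pytest.approx(0.01747, abs=1e-4)

    def test_independent_tables_give_large_p(self):
        tables = {"loc1": [[25, 25], [25, 25]], "loc2": [[10, 10], [10, 10]]}
        res = wolbachia_association(tables)
        assert res.df == 4
        assert all(p == pytest.approx(1.0) for _, _, p in res.per_location)
        assert res.combined_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.combined_p == pytest.approx(1.0)

    def test_zero_margin_tables_excluded(self):
        tables = {"good": [[5, 5], [5, 5]], "bad": [[0, 0], [10, 10]]}
        res = wolbachia_association(tables)
        assert res.excluded == ["bad"] and res.df == 2

    def test_all_degenerate_raises(self):
        with pytest.raises(ValueError):
            wolbachia_association({"a": [[0, 0], [1, 1]]})

    def test_null_rejection_rate_on_simulated_surveys(self):
        rejections, reps = 0, 120
        for rep in range(reps):
            spec = SurveySpec(
                [(f"loc{i}", "melanogaster", 120, []) for i in range(4)],
                {(f"loc{i}", "melanogaster", "V"): 0.3 for i in range(4)},
                {(f"loc{i}", "melanogaster"): 0.5 for i in range(4)},
                wolbachia_virus_odds_ratio=1.0, seed=rep)
            _, truth = gen_survey(spec)
            res = wolbachia_association(
                {loc: t for (loc, _, _), t in truth["tables"].items()})
            rejections += res.combined_p < 0.05
        # Fisher's exact is conservative in small tables; allow [0, ~9%]
        assert rejections / reps <= 0.09


class TestPrevalenceCorrelation:
    def test_monotone_pairs(self):
        out = prevalence_correlation([0.1, 0.2, 0.3, 0.4], [0.2, 0.3, 0.5, 0.9])
        assert out["rho"] == pytest.approx(1.0)
        out = prevalence_correlation([0.4, 0.3, 0.2, 0.1], [0.2, 0.3, 0.5, 0.9])
        assert out["rho"] == pytest.approx(-1.0)

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            prevalence_correlation([0.1, 0.2], [0.3, 0.4])

    def test_null_mean_rho_near_zero(self):
        rng = np.random.default_rng(5)
        rhos = []
        for _ in range(500):
            v = rng.permutation(16)
            w = np.arange(16)
            rhos.append(prevalence_correlation(v / 16, w / 16)["rho"])
        assert abs(np.mean(rhos)) < 3 / math.sqrt(15 * 500)


class TestEstimateByGroup:
    def test_groups_and_estimates(self):
        spec = SurveySpec(
            [("loc1", "melanogaster", 100, [5, 5]), ("loc2", "simulans", 80, [])],
            {("loc1", "melanogaster", "V"): 0.25, ("loc2", "simulans", "V"): 0.0},
            seed=2)
        df, _ = gen_survey(spec)
        est = estimate_by_group(df, grid_resolution=1e-3)
        assert len(est) == 2
        zero_row = est[est["location"] == "loc2"].iloc[0]
        assert zero_row["p_hat"] == 0.0
        loc1 = est[est["location"] == "loc1"].iloc[0]
        assert 0.05 < loc1["p_hat"] < 0.5
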