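"""Differential machinery: NB interaction test, BH, Fisher meta-p, rescue calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import _oracles as oracles
from splicerescue.differential import (
    bh_adjust,
    classify_rescue,
    gene_de_test,
    ir_difftest,
    meta_p,
    nb_ratio_test,
    size_factors,
)


class TestNbRatioTest:
    def test_identical_counts_give_null_result(self):
        s = np.array([50, 60, 55])
        u = np.array([20, 25, 22])
        effect, p = nb_ratio_test(s, u, s, u)
        assert effect == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_all_zero_event_untestable(self):
        z = np.zeros(3)
        assert nb_ratio_test(z, z, z, z) == (0.0, 1.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            nb_ratio_test([5], [5], [5, 6], [5, 6])

    def test_effect_sign_and_magnitude_on_clean_shift(self):
        # odds 4:1 -> 1:4 is a -4 log2-odds change; large counts, tiny noise
        s_a, u_a = np.array([800, 800, 800]), np.array([200, 200, 200])
        s_b, u_b = np.array([200, 200, 200]), np.array([800, 800, 800])
        effect, p = nb_ratio_test(s_a, u_a, s_b, u_b)
        assert effect == pytest.approx(-4.0, abs=0.01)
        assert p < 1e-6

    def test_loglik_route_agrees_with_statsmodels(self, rng):
        """The in-package IRLS reduced-model fit matches statsmodels' NB GLM
        log-likelihood on random events (independent implementation)."""
        import statsmodels.api as sm

        from splicerescue.differential import _irls_nb, _moment_dispersion, _nb_loglik

        for _ in range(25):
            cells = [rng.poisson(rng.integers(5, 200), 3) for _ in range(4)]
            alpha = _moment_dispersion(cells)
            y = np.concatenate(cells).astype(float)
            read_class = np.array([0.0] * 3 + [1.0] * 3 + [0.0] * 3 + [1.0] * 3)
            condition = np.array([0.0] * 6 + [1.0] * 6)
            X = np.column_stack([np.ones(12), read_class, condition])
            _, mu, converged = _irls_nb(y, X, alpha)
            assert converged
            fit = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
            assert _nb_loglik(y, mu, alpha) == pytest.approx(fit.llf, abs=1e-4)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.poisson(50, 100).astype(float) + 1
        mat = np.column_stack([col, col, col])
        assert np.allclose(size_factors(mat), 1.0)

    def test_doubled_column_gives_proportional_factors(self, rng):
        col = rng.poisson(50, 200).astype(float) + 1
        mat = np.column_stack([col, 2 * col])
        sf = size_factors(mat)
        assert sf[1] / sf[0] == pytest.approx(2.0)
        assert np.prod(sf) == pytest.approx(1.0)  # geometric mean 1

    def test_global_scaling_leaves_factors_unchanged(self, rng):
        """Median-of-ratios is invariant to a global count rescaling because
        the geometric-mean reference rescales identically."""
        mat = rng.poisson(40, (50, 4)).astype(float) + 1
        assert np.allclose(size_factors(mat), size_factors(7.0 * mat))

    def test_no_universally_expressed_gene_rejected(self):
        mat = np.array([[0.0, 5.0], [5.0, 0.0]])
        with pytest.raises(ValueError):
            size_factors(mat)


class TestGeneDeTest:
    def test_duplicated_columns_give_unit_pvalues(self, rng):
        """When condition b's columns literally duplicate condition a's, every
        gene's effect estimate is exactly zero and p = 1."""
        half = rng.poisson(100, (100, 3))
        counts = pd.DataFrame(np.hstack([half, half]))
        res = gene_de_test(counts, ["a"] * 3 + ["b"] * 3)
        assert np.allclose(res["log2_effect"], 0.0)
        assert np.allclose(res["p_value"], 1.0)

    def test_null_simulation_not_anticonservative(self, rng):
        """Null rejection rate at alpha=0.05 stays at or below the binomial
        99% upper bound (slight conservatism from per-gene dispersion
        estimation is acceptable; inflation is not)."""
        counts = pd.DataFrame(
            rng.poisson(100, (600, 6)), index=[f"g{i}" for i in range(600)]
        )
        res = gene_de_test(counts, ["a"] * 3 + ["b"] * 3)
        rejections = int((res["p_value"] < 0.05).sum())
        _, hi = stats.binom.interval(0.99, 600, 0.05)
        assert 0 < rejections <= hi

    def test_strong_injected_change_detected(self, rng):
        base = rng.poisson(500, (80, 6)).astype(int)
        base[0, 3:] *= 10
        res = gene_de_test(pd.DataFrame(base), ["a"] * 3 + ["b"] * 3)
        assert res.loc[0, "padj"] < 0.05
        assert res.loc[0, "log2_effect"] == pytest.approx(np.log2(10), abs=0.3)

    def test_single_replicate_rejected(self, rng):
        counts = pd.DataFrame(rng.poisson(10, (5, 3)))
        with pytest.raises(ValueError):
            gene_de_test(counts, ["a", "b", "b"])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])

    def test_padj_never_below_p(self, rng):
        p = rng.random(100)
        assert np.all(bh_adjust(p) >= p - 1e-12)

    def test_matches_brute_force_oracle_random_vectors(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 40))
            p = np.round(rng.random(m), 4)
            assert bh_adjust(p) == pytest.approx(oracles.bh_brute_force(p), abs=1e-12)


class TestMetaP:
    def test_unit_pvalues_combine_to_one(self):
        assert meta_p(1.0, 1.0) == pytest.approx(1.0)

    def test_closed_form_worked_example(self):
        assert meta_p(0.01, 0.02) == pytest.approx(0.0019, abs=2e-4)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(p=st.floats(min_value=1e-12, max_value=1.0))
    def test_combining_with_one_never_decreases_evidence_against(self, p):
        assert meta_p(p, 1.0) >= p - 1e-12

    def test_zero_p_clamped_not_crashing(self):
        assert 0.0 <= meta_p(0.0, 0.5) <= 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            meta_p(1.5, 0.5)


def _results_frame(event_ids, effects, ps):
    return pd.DataFrame(
        {
            "event_id": event_ids,
            "log2_effect": effects,
            "p_value": ps,
            "padj": bh_adjust(ps),
        }
    )


class TestClassifyRescue:
    def test_perfect_mirror_rescues_everything(self):
        ids = [f"e{i}" for i in range(10)]
        effects = np.linspace(-3, -1, 10)
        ps = np.full(10, 1e-6)
        kd = _results_frame(ids, effects, ps)
        rescue = _results_frame(ids, -effects, ps)
        table, summary = classify_rescue(kd, rescue, top_n=10, alpha=0.05)
        assert summary.frac_rescued == 1.0
        assert summary.n_down == 10

    def test_flat_rescue_comparison_rescues_nothing(self):
        ids = [f"e{i}" for i in range(10)]
        kd = _results_frame(ids, np.linspace(-3, -1, 10), np.full(10, 1e-6))
        rescue = _results_frame(ids, np.zeros(10), np.ones(10))
        _, summary = classify_rescue(kd, rescue, top_n=10, alpha=0.05)
        assert summary.frac_rescued == 0.0

    def test_down_up_split_counts_significant_events(self):
        ids = [f"e{i}" for i in range(6)]
        effects = np.array([-2.0, -2.0, -2.0, 2.0, 1.0, 0.5])
        ps = np.array([1e-8, 1e-8, 1e-8, 1e-8, 0.9, 0.9])
        kd = _results_frame(ids, effects, ps)
        rescue = _results_frame(ids, -effects, ps)
        _, summary = classify_rescue(kd, rescue, top_n=6, alpha=0.05)
        assert summary.n_down + summary.n_up == summary.n_significant
        assert summary.n_down == 3 and summary.n_up == 1

    def test_unmatched_event_sets_rejected(self):
        kd = _results_frame(["a", "b"], [1.0, 2.0], [0.1, 0.2])
        rescue = _results_frame(["a", "c"], [1.0, 2.0], [0.1, 0.2])
        with pytest.raises(ValueError, match="unmatched"):
            classify_rescue(kd, rescue, top_n=2)

    def test_top_n_larger_than_events_rejected(self):
        kd = _results_frame(["a"], [1.0], [0.1])
        with pytest.raises(ValueError):
            classify_rescue(kd, kd, top_n=5)


class TestIrDifftest:
    def test_pipeline_is_deterministic_and_oriented(self):
        from splicerescue.synthetic import SimConfig, simulate_ir_counts

        cfg = SimConfig(
            n_events=40, frac_dependent=1.0, frac_direction_down=1.0,
            effect_log2_mean=3.0, mean_depth=300, seed=8,
        )
        counts, truth = simulate_ir_counts(cfg)
        res = ir_difftest(counts, "ctrl", "kd")
        res2 = ir_difftest(counts, "ctrl", "kd")
        pd.testing.assert_frame_equal(res, res2)
        # every event loses splicing efficiency: fitted effects overwhelmingly negative
        assert (res["log2_effect"] < 0).mean() > 0.95
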