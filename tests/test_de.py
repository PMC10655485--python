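"""Single-sample NB test, grid approximation, adjustment, calls, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import nbinom

from dgd.de import (
    adjust_pvalues,
    call_degs,
    enrichment_score,
    exact_pvalue,
    exact_pvalue_batch,
    grid_pvalue,
    log2_fold_change,
)


def brute_force_pvalue(x, m, r, K):
    """Literal two-tailed sum over every count 0..K."""
    k = np.arange(K + 1)
    pmf = nbinom.pmf(k, r, r / (r + m))
    return min(pmf[pmf <= pmf[x] * (1 + 1e-12)].sum(), 1.0)


class TestExactPvalue:
    def test_mode_has_pvalue_one(self):
        # m chosen so the mode is unique (no exact pmf tie at the mode)
        m, r = 19.5, 5.0
        k = np.arange(0, 2000)
        mode = int(k[np.argmax(nbinom.pmf(k, r, r / (r + m)))])
        assert exact_pvalue(mode, m, r, 2000) == pytest.approx(1.0, abs=1e-9)

    def test_zero_observation_against_summation_oracle(self):
        p = exact_pvalue(0, 5.0, 2.0, 500)
        assert p == pytest.approx(brute_force_pvalue(0, 5.0, 2.0, 500), abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_instances_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(50, 1000))
        m = rng.uniform(0.5, 80)
        r = rng.uniform(0.3, 25)
        x = int(rng.integers(0, K + 1))
        assert exact_pvalue(x, m, r, K) == pytest.approx(
            brute_force_pvalue(x, m, r, K), abs=1e-12)

    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(5)
        xs = rng.integers(0, 400, size=50)
        batch = exact_pvalue_batch(xs, 50.0, 2.0, 400)
        for x, p in zip(xs, batch):
            assert p == pytest.approx(exact_pvalue(int(x), 50.0, 2.0, 400),
                                      abs=1e-12)

    def test_observation_beyond_library_rejected(self):
        with pytest.raises(ValueError):
            exact_pvalue(11, 5.0, 2.0, 10)

    def test_result_is_positive(self):
        # extremely improbable observation still yields p > 0
        assert exact_pvalue(10_000, 1.0, 20.0, 10_000) > 0.0


class TestGridPvalue:
    def test_saturated_grid_equals_exact(self):
        for x in (0, 3, 40, 160):
            exact = exact_pvalue(x, 20.0, 4.0, 200)
            assert grid_pvalue(x, 20.0, 4.0, 200, grid_points=201) == exact
            assert grid_pvalue(x, 20.0, 4.0, 200, grid_points=500) == exact

    def test_error_shrinks_with_grid_size(self):
        # fixed hard instance; truncated-exact oracle sums the region
        # holding >= 1 - 1e-12 of the mass
        K, m, r, x = 1_000_000, 1000.0, 2.0, 2000
        upper = int(nbinom.ppf(1 - 1e-13, r, r / (r + m))) + 100
        k = np.arange(upper + 1)
        pmf = nbinom.pmf(k, r, r / (r + m))
        oracle = pmf[pmf <= nbinom.pmf(x, r, r / (r + m))].sum()
        errors = [abs(grid_pvalue(x, m, r, K, g) - oracle)
                  for g in (100, 1000, 10_000)]
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 1e-3

    def test_two_sided_monotonicity_away_from_mode(self):
        m, r, K = 100.0, 3.0, 100_000
        k = np.arange(3000)
        mode = int(k[np.argmax(nbinom.pmf(k, r, r / (r + m)))])
        ups = [grid_pvalue(x, m, r, K) for x in range(mode, mode + 400, 40)]
        assert all(a >= b - 1e-12 for a, b in zip(ups, ups[1:]))
        downs = [grid_pvalue(x, m, r, K) for x in range(mode, -1, -10)]
        assert all(a >= b - 1e-12 for a, b in zip(downs, downs[1:]))

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            grid_pvalue(1, 5.0, 2.0, 100, grid_points=1)


class TestLog2FoldChange:
    def test_identity_at_equal_counts(self):
        assert log2_fold_change(20, 20.0) == 0.0

    def test_exact_two_with_pseudocount_algebra(self):
        m = 7.0
        x = 4 * m + 3  # x + 1 = 4 (m + 1)
        assert log2_fold_change(x, m) == pytest.approx(2.0, abs=1e-12)

    def test_zero_count_stays_finite(self):
        assert log2_fold_change(0, 1.0) == pytest.approx(-1.0, abs=1e-12)

    def test_vectorized(self):
        out = log2_fold_change(np.array([0, 7]), np.array([1.0, 7.0]))
        np.testing.assert_allclose(out, [-1.0, 0.0], atol=1e-12)


class TestAdjustPvalues:
    def test_constant_vector_is_fixed_point(self):
        np.testing.assert_allclose(adjust_pvalues([0.2] * 5), 0.2)

    def test_hand_executed_step_up(self):
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(adjust_pvalues([0.04]), [0.04])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, size=100)
        assert (adjust_pvalues(p) >= p - 1e-15).all()

    def test_bonferroni_option(self):
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.2], "bonferroni"),
                                   [0.02, 0.4])

    def test_empty_and_invalid(self):
        with pytest.raises(ValueError):
            adjust_pvalues([])
        with pytest.raises(ValueError):
            adjust_pvalues([0.0, 0.5])


class TestCallDegs:
    def _table(self, padj, lfc):
        n = len(padj)
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "observed": np.ones(n, dtype=int),
            "predicted_mean": np.ones(n),
            "dispersion": np.ones(n),
            "p": padj, "padj": padj, "log2fc": lfc,
        })

    def test_both_gates_must_pass(self):
        res = call_degs(self._table([0.009, 0.009, 0.05], [1.5, 0.9, 1.5]))
        assert res.table["called"].tolist() == [True, False, False]

    def test_direction_labels(self):
        res = call_degs(self._table([0.001, 0.001], [2.0, -2.0]))
        assert res.table["direction"].tolist() == ["up", "down"]
        assert res.n_up == 1 and res.n_down == 1

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            call_degs(self._table([0.5], [0.0]), alpha=1.5)


class TestEnrichmentScore:
    def test_whole_universe_has_no_enrichment(self):
        universe = [f"g{i}" for i in range(100)]
        assert enrichment_score(universe, universe[:10], 100) == 1.0

    def test_direct_arithmetic(self):
        sig = [f"s{i}" for i in range(20)]
        markers = [f"m{i}" for i in range(50)]
        sig[:5] = markers[:5]
        assert enrichment_score(sig, markers, 1000) == 5.0

    def test_relabeling_invariance(self):
        sig = ["a", "b", "c"]
        markers = ["b", "c", "d"]
        base = enrichment_score(sig, markers, 50)
        ren = {n: f"x_{n}" for n in "abcd"}
        assert enrichment_score([ren[s] for s in sig],
                                [ren[m] for m in markers], 50) == base

    def test_random_sets_average_to_one(self):
        rng = np.random.default_rng(12)
        total, n_sig, n_mark = 1000, 20, 50
        markers = set(range(n_mark))
        draws = 10_000
        es = np.empty(draws)
        for i in range(draws):
            sig = rng.choice(total, size=n_sig, replace=False)
            es[i] = len(markers.intersection(sig)) * total / (n_sig * n_mark)
        mc_sd = es.std(ddof=1) / np.sqrt(draws)
        assert abs(es.mean() - 1.0) <= 3 * mc_sd

    def test_empty_sets_not_computable(self):
        with pytest.raises(ValueError):
            enrichment_score([], ["m"], 10)
        with pytest.raises(ValueError):
            enrichment_score(["s"], [], 10)


class TestNullCalibration:
    def test_discrete_test_is_conservative(self):
        # null draws from the same NB the test assumes
        rng = np.random.default_rng(77)
        m, r, K, n = 50.0, 2.0, 10_000, 4000
        xs = np.clip(rng.negative_binomial(r, r / (r + m), size=n), 0, K)
        p = exact_pvalue_batch(xs, m, r, K)
        rate = float((p <= 0.05).mean())
        mc_sd = np.sqrt(0.05 * 0.95 / n)
        assert rate <= 0.05 + 3 * mc_sd
        # empirical CDF dominated by the uniform CDF
        for t in (0.01, 0.05, 0.1, 0.25, 0.5):
            ecdf = float((p <= t).mean())
            assert ecdf <= t + 3 * np.sqrt(t * (1 - t) / n)


class TestFullPipeline:
    def test_spiked_sample_recovery_exceeds_null_calls(
        self, toy_study, de_inference_config
    ):
        """Positive-control spikes produce many calls; the matched clean
        sample produces almost none."""
        from dgd import run_de, simulate_samples, spike_sample

        model = toy_study["model"]
        truth = toy_study["truth"]
        ho, ho_truth = simulate_samples(truth, 2, seed=314)
        rng = np.random.default_rng(315)
        elig = np.flatnonzero(truth.spike_eligible[0])
        genes = rng.choice(elig, size=min(20, elig.size), replace=False)
        x_sp = spike_sample(ho.values[0], ho_truth, 0, genes, fold=4.0, seed=316)
        de_sp = run_de(x_sp, model, inference_config=de_inference_config)
        de_null = run_de(ho.values[0], model,
                         inference_config=de_inference_config)
        n_sp = int(de_sp.table["called"].sum())
        n_null = int(de_null.table["called"].sum())
        assert n_sp >= 5
        assert n_null <= max(1, int(0.01 * 100 * n_sp) // 100 + 2)

    def test_pipeline_determinism(self, toy_study, de_inference_config):
        from dgd import run_de

        model = toy_study["model"]
        x = toy_study["holdout"].values[0]
        a = run_de(x, model, inference_config=de_inference_config)
        b = run_de(x, model, inference_config=de_inference_config)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.table.to_csv() == b.table.to_csv()
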