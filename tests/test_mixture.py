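"""Binomial-mixture EM: background estimation, recovery, posteriors, layers."""

import numpy as np
import pandas as pd
import pytest

from _oracles import grid_mixture_max_loglik
from conftest import make_summaries_frame
from tlabelbench import mixture as mx
from tlabelbench.simulate import simulate_umi_counts


class TestEstimateBackground:
    def test_zero_conversions(self):
        df = pd.DataFrame({"T": [10, 20], "TC": [0, 0]})
        assert mx.estimate_background(df) == 0.0

    def test_direct_mle(self):
        df = pd.DataFrame({"T": [5000, 5000], "TC": [12, 8]})
        assert mx.estimate_background(df) == pytest.approx(0.002)

    def test_zero_coverage_raises(self):
        with pytest.raises(ValueError):
            mx.estimate_background(pd.DataFrame({"T": [0], "TC": [0]}))


class TestPosterior:
    def test_zero_prior_gives_zero(self):
        assert mx.posterior_new(3, 10, 0.001, 0.08, 0.0) == 0.0

    def test_closed_form_value(self):
        """Independent closed-form evaluation at k=0, n=10."""
        p_e, p_c, pi = 0.001, 0.08, 0.5
        a = (1 - p_e) ** 10
        b = (1 - p_c) ** 10
        expected = pi * b / (pi * b + (1 - pi) * a)
        got = mx.posterior_new(0, 10, p_e, p_c, pi)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.3049, abs=1e-4)

    def test_many_conversions_overwhelm_any_prior(self):
        for pi in (0.01, 0.1, 0.9):
            assert mx.posterior_new(5, 10, 0.001, 0.08, pi) > 0.999

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mx.posterior_new(5, 3, 0.001, 0.08, 0.5)  # k > n
        with pytest.raises(ValueError):
            mx.posterior_new(1, 3, 0.001, 1.5, 0.5)


class TestEmFit:
    def test_no_signal_gives_zero_pi(self):
        """p_e = 0 and all k = 0: the labeled component has no support."""
        fit = mx.fit_binomial_mixture([0] * 50, [10] * 50, p_e=0.0)
        assert fit.pi == pytest.approx(0.0, abs=1e-6)

    def test_rejects_all_zero_content(self):
        with pytest.raises(ValueError):
            mx.fit_binomial_mixture([0, 0], [0, 0], p_e=0.002)

    def test_loglik_trace_monotone(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            df = simulate_umi_counts(
                500, pi=rng.uniform(0.2, 0.8), p_c=0.08, p_e=0.002, seed=seed
            )
            fit = mx.fit_binomial_mixture(df["k"], df["n"], 0.002)
            assert np.all(np.diff(fit.loglik_trace) >= -1e-7)

    def test_em_beats_grid_oracle(self):
        """On small instances, EM attains at least the exhaustive
        (pi, p_c) grid maximum (step 0.001)."""
        rng = np.random.default_rng(5)
        for _ in range(4):
            n_umis = int(rng.integers(50, 200))
            pi = rng.uniform(0.1, 0.9)
            p_c = rng.uniform(0.02, 0.15)
            p_e = rng.uniform(0.0, 0.01)
            df = simulate_umi_counts(
                n_umis, pi, p_c, p_e, seed=int(rng.integers(1 << 30))
            )
            fit = mx.fit_binomial_mixture(df["k"], df["n"], p_e)
            grid = grid_mixture_max_loglik(df["k"], df["n"], p_e, step=0.001)
            assert fit.loglik_trace[-1] >= grid - 1e-6

    def test_parameter_recovery_at_scale(self):
        df = simulate_umi_counts(50_000, 0.4, 0.08, 0.002, seed=17)
        fit = mx.fit_binomial_mixture(df["k"], df["n"], 0.002)
        assert fit.pi == pytest.approx(0.4, abs=0.02)
        assert fit.p_c == pytest.approx(0.08, abs=0.005)

    def test_recovery_error_shrinks_with_umi_count(self):
        """Median |pi_hat - pi| strictly decreases as UMIs grow."""
        medians = []
        for n_umis in (500, 5_000, 50_000):
            errs = []
            for seed in range(20):
                df = simulate_umi_counts(n_umis, 0.4, 0.08, 0.002, seed=1000 + seed)
                fit = mx.fit_binomial_mixture(df["k"], df["n"], 0.002)
                errs.append(abs(fit.pi - 0.4))
            medians.append(np.median(errs))
        assert medians[0] > medians[1] > medians[2]

    def test_posterior_calibration(self):
        """UMIs with posterior near 0.5 are truly new about half the time.

        Uses a low T-content regime (mean 4) so that zero-conversion UMIs
        of short molecules land in the ambiguous posterior band; at the
        default content the posterior distribution is bimodal and the band
        is empty by construction.
        """
        df = simulate_umi_counts(
            100_000, 0.5, 0.08, 0.002, mean_t_content=4.0, seed=23
        )
        fit = mx.fit_binomial_mixture(df["k"], df["n"], 0.002)
        band = (fit.posterior >= 0.45) & (fit.posterior <= 0.55)
        assert band.sum() > 100
        assert abs(df["is_new"][band].mean() - 0.5) <= 0.1

    def test_collapse_flagged_non_identifiable(self):
        df = simulate_umi_counts(2_000, 0.5, 0.002, 0.002, seed=3)
        fit = mx.fit_binomial_mixture(df["k"], df["n"], 0.002)
        if not fit.identifiable:
            assert np.isnan(fit.pi)
        else:
            # EM may explain null data with pi ~ 0 instead of collapsing p_c
            assert fit.pi < 0.2 or fit.p_c < 0.01


class TestEstimateLayers:
    def _summaries(self, pi, p_c=0.08, p_e=0.002, n_genes=20, n_umis=4000, seed=0):
        df = simulate_umi_counts(n_umis, pi, p_c, p_e, seed=seed)
        rng = np.random.default_rng(seed + 1)
        gene_index = rng.integers(0, n_genes, n_umis)
        gene_ids = [f"g{i:03d}" for i in range(n_genes)]
        return make_summaries_frame(df["k"], df["n"], gene_index, gene_ids), df

    def test_layer_identities(self):
        summaries, _ = self._summaries(pi=0.4)
        adata = mx.estimate_layers(summaries, p_e=0.002)
        total = adata.layers["total"]
        np.testing.assert_allclose(
            adata.layers["labeled"] + adata.layers["unlabeled"], total
        )
        est = adata.layers["estimated_new"] + adata.layers["estimated_old"]
        ok = ~np.isnan(est)
        np.testing.assert_allclose(est[ok], total[ok])
        assert (adata.layers["labeled"] <= total).all()

    def test_null_chemistry_estimates_near_zero(self):
        """Chemistry off: estimated new fraction stays below 2%."""
        summaries, _ = self._summaries(pi=0.5, p_c=0.002, n_umis=4000, seed=5)
        adata = mx.estimate_layers(summaries, p_e=0.002)
        est = np.nansum(adata.layers["estimated_new"])
        total = adata.layers["total"].sum()
        assert est / total < 0.02

    def test_saturated_gene_estimates_near_total(self):
        """Every UMI of a gene with k >= 3 at n = 15: estimated-new ~ total."""
        gene_ids = ["gA"]
        summaries = make_summaries_frame(
            [3, 4, 5, 3, 4, 5, 3, 4, 5, 3], [15] * 10, [0] * 10, gene_ids
        )
        adata = mx.estimate_layers(summaries, p_e=0.002)
        est = np.nansum(adata.layers["estimated_new"])
        assert est == pytest.approx(adata.layers["total"].sum(), rel=0.01)

    def test_estimated_recovers_undetected_new_molecules(self):
        """Raw labeled counts miss new molecules with k = 0; the posterior
        sums recover them, so estimated-new exceeds raw labeled."""
        summaries, _ = self._summaries(pi=0.4, n_umis=8000, seed=9)
        adata = mx.estimate_layers(summaries, p_e=0.002)
        assert np.nansum(adata.layers["estimated_new"]) > adata.layers["labeled"].sum()

    def test_low_support_genes_have_missing_estimates(self):
        summaries, _ = self._summaries(pi=0.4, n_genes=2, n_umis=30, seed=2)
        # add a gene with fewer UMIs than the support threshold
        extra = make_summaries_frame([1, 0], [15, 12], [0, 0], ["rare"])
        adata = mx.estimate_layers(
            pd.concat([summaries, extra], ignore_index=True), p_e=0.002,
            min_gene_umis=10,
        )
        rare_col = list(adata.var_names).index("rare")
        assert np.isnan(adata.layers["estimated_new"][:, rare_col]).all()
        assert adata.layers["total"][:, rare_col].sum() == 2  # raw still emitted

    def test_strategy_validation(self):
        summaries, _ = self._summaries(pi=0.4, n_umis=100)
        with pytest.raises(ValueError):
            mx.estimate_layers(summaries, p_e=0.002, strategy="per_cell_per_gene")
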