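"""Consensus calling, filtering and per-cell rate computation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, chisquare

from _oracles import brute_force_consensus
from tlabelbench import quantify as q
from tlabelbench.quantify import DataIntegrityError, ReadObservation, SnpMask
from tlabelbench.simulate import (
    SimulationConfig,
    plant_snps,
    simulate_dataset,
    simulate_umi_counts,
)
from tlabelbench import mixture


def _frame(*reads):
    return ReadObservation.frame(list(reads))


class TestQualityFilter:
    def test_high_quality_input_unchanged(self):
        reads = _frame(
            ReadObservation("b1", "u1", "g1", [(0, "T", "C", 40), (1, "A", "A", 40)])
        )
        out = q.quality_filter(reads, min_phred=27)
        pd.testing.assert_frame_equal(
            out.astype(str), reads.astype(str), check_dtype=False
        )

    def test_strict_inequality_at_cutoff(self):
        """Phred 27 is reverted, 28 survives: the cutoff is strictly greater."""
        reads = _frame(
            ReadObservation("b1", "u1", "g1", [(0, "T", "C", 27), (1, "T", "C", 28)])
        )
        out = q.quality_filter(reads, min_phred=27)
        assert out.loc[out["pos"] == 0, "obs"].astype(str).item() == "T"
        assert out.loc[out["pos"] == 1, "obs"].astype(str).item() == "C"

    def test_reverted_position_still_covered(self):
        reads = _frame(ReadObservation("b1", "u1", "g1", [(0, "T", "C", 10)]))
        summ = q.consensus_umis(reads, min_phred=27)
        assert summ["T"].item() == 1  # content kept
        assert summ["TC"].item() == 0  # conversion dropped


class TestConsensus:
    def test_single_read_is_identity(self):
        reads = _frame(
            ReadObservation("b1", "u1", "g1", [(0, "T", "C", 40), (3, "G", "G", 40)])
        )
        pos = q.consensus_positions(reads)
        assert dict(zip(pos["pos"], pos["consensus"].astype(str))) == {0: "C", 3: "G"}

    def test_plurality_vote(self):
        """Three reads observing C, C, T at a ref-T position: consensus C."""
        reads = _frame(
            ReadObservation("b1", "u1", "g1", [(5, "T", "C", 40)]),
            ReadObservation("b1", "u1", "g1", [(5, "T", "C", 40)]),
            ReadObservation("b1", "u1", "g1", [(5, "T", "T", 40)]),
        )
        summ = q.consensus_umis(reads)
        assert summ["TC"].item() == 1

    def test_tie_falls_to_reference(self):
        reads = _frame(
            ReadObservation("b1", "u1", "g1", [(5, "T", "C", 40)]),
            ReadObservation("b1", "u1", "g1", [(5, "T", "T", 40)]),
        )
        summ = q.consensus_umis(reads)
        assert summ["TC"].item() == 0 and summ["T"].item() == 1

    def test_conflicting_refs_raise(self):
        reads = _frame(
            ReadObservation("b1", "u1", "g1", [(5, "T", "C", 40)]),
            ReadObservation("b1", "u1", "g1", [(5, "A", "C", 40)]),
        )
        with pytest.raises(DataIntegrityError):
            q.consensus_positions(reads)

    def test_matches_brute_force_oracle(self):
        """Vectorized consensus equals an independent per-position vote on a
        random batch of <=100 reads."""
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(100):
            bc = f"b{rng.integers(3)}"
            umi = f"u{rng.integers(10)}"
            gene = f"g{rng.integers(4)}"
            for pos in rng.choice(20, size=rng.integers(1, 6), replace=False):
                ref = "ACGT"[(pos + 1) % 4]
                obs = "ACGT"[rng.integers(4)] if rng.random() < 0.3 else ref
                rows.append((bc, umi, gene, int(pos), ref, obs, 40))
        frame = pd.DataFrame(
            rows, columns=["barcode", "umi", "gene_id", "pos", "ref", "obs", "qual"]
        )
        expected = brute_force_consensus(rows)
        got = q.consensus_positions(frame)
        assert len(got) == len(expected)
        for _, row in got.iterrows():
            key = (row["barcode"], row["umi"], row["gene_id"], row["pos"])
            assert expected[key] == (str(row["ref"]), str(row["consensus"]))


class TestSnpMask:
    def test_clean_control_gives_empty_mask(self):
        reads = _frame(ReadObservation("b1", "u1", "g1", [(0, "T", "T", 40)]))
        mask = q.detect_snps(q.consensus_positions(reads))
        assert len(mask) == 0

    def test_majority_converted_position_is_masked(self):
        reads = _frame(
            *[
                ReadObservation("b1", f"u{i}", "g1", [(4, "T", "C", 40)])
                for i in range(3)
            ],
            *[
                ReadObservation("b1", f"v{i}", "g1", [(4, "T", "T", 40)])
                for i in range(2)
            ],
        )
        mask = q.detect_snps(q.consensus_positions(reads), threshold=0.5)
        assert mask.positions == frozenset({("g1", 4)})

    def test_default_threshold(self):
        assert SnpMask(frozenset()).threshold == 0.5

    def test_empty_control_raises_with_guidance(self):
        with pytest.raises(ValueError, match="skip SNP masking"):
            q.detect_snps(q.consensus_positions(pd.DataFrame(columns=q.SUB_TYPES)))

    def test_masking_turns_snp_only_umi_unlabeled(self):
        reads = _frame(ReadObservation("b1", "u1", "g1", [(4, "T", "C", 40)]))
        mask = SnpMask(frozenset({("g1", 4)}))
        summ = q.consensus_umis(reads, snp_mask=mask)
        assert len(summ) == 1  # UMI conserved, not dropped
        assert summ["TC"].item() == 0 and summ["T"].item() == 0

    def test_empty_mask_is_identity(self):
        reads = _frame(ReadObservation("b1", "u1", "g1", [(4, "T", "C", 40)]))
        pos = q.consensus_positions(reads)
        out = q.apply_snp_mask(pos, SnpMask(frozenset()))
        pd.testing.assert_frame_equal(out, pos)

    def test_masking_restores_background_estimate(self):
        """Planted SNPs inflate the control background rate; masking brings
        the estimate back within its binomial confidence interval (a single
        95% interval misses ~1 time in 20, so a small seed panel is used)."""
        p_e = 0.002
        in_interval = 0
        for seed in (21, 22, 23):
            base = dict(
                n_cells=6,
                n_genes=40,
                mean_umis_per_cell=900,
                chemistry_preset="control",
                seq_error_rate=0.0,
                seed=seed,
            )
            snps = plant_snps(SimulationConfig(**base), n_snps=12, seed=seed)
            reads, _ = simulate_dataset(SimulationConfig(**base, snp_positions=snps))
            positions = q.consensus_positions(q.quality_filter(reads))
            mask = q.detect_snps(positions, threshold=0.5)
            assert mask.positions  # planted SNPs are found
            unmasked = mixture.estimate_background(q.summarize_umis(positions))
            masked_summ = q.summarize_umis(q.apply_snp_mask(positions, mask))
            masked = mixture.estimate_background(masked_summ)
            assert masked < unmasked
            n_t = masked_summ["T"].sum()
            half_width = 1.96 * np.sqrt(p_e * (1 - p_e) / n_t)
            in_interval += abs(masked - p_e) <= half_width
        assert in_interval >= 2


class TestCellRates:
    def test_rate_is_conversions_over_content(self):
        reads = _frame(
            *[
                ReadObservation("b1", f"u{i}", "g1", [(4 * j + 3, "T", "C" if j < 2 else "T", 40) for j in range(10)])
                for i in range(10)
            ]
        )
        # 10 UMIs x 10 T positions, 2 conversions each -> TC rate 0.2
        prof = q.cell_rates(q.consensus_umis(reads))
        assert prof["TC"].item() == pytest.approx(0.2)
        assert prof["labeled_umi_fraction"].item() == 1.0

    def test_labeled_umi_fraction(self):
        reads = _frame(
            *[
                ReadObservation("b1", f"u{i}", "g1", [(3, "T", "C" if i < 4 else "T", 40)])
                for i in range(10)
            ]
        )
        prof = q.cell_rates(q.consensus_umis(reads))
        assert prof["labeled_umi_fraction"].item() == pytest.approx(0.4)

    def test_no_mismatches_gives_zero_rates(self):
        reads = _frame(
            ReadObservation("b1", "u1", "g1", [(0, "T", "T", 40), (1, "A", "A", 40)])
        )
        prof = q.cell_rates(q.consensus_umis(reads))
        assert prof["TC"].item() == 0.0
        assert prof["AG"].item() == 0.0

    def test_zero_content_rate_is_missing_not_zero(self):
        reads = _frame(ReadObservation("b1", "u1", "g1", [(0, "T", "T", 40)]))
        prof = q.cell_rates(q.consensus_umis(reads))
        assert np.isnan(prof["AG"].item())  # no covered A positions

    def test_rates_within_bounds(self, small_summaries):
        prof = q.cell_rates(small_summaries)
        rates = prof[q.SUB_TYPES].to_numpy(dtype=float)
        finite = rates[~np.isnan(rates)]
        assert ((finite >= 0) & (finite <= 1)).all()

    def test_conversion_counts_never_exceed_content(self, small_summaries):
        for sub in q.SUB_TYPES:
            assert (small_summaries[sub] <= small_summaries[sub[0]]).all()


class TestHistogram:
    def test_trivial_histograms(self):
        df = pd.DataFrame({"TC": [0, 0, 1, 2]})
        hist = q.conversions_per_umi_histogram(df)
        assert hist.to_dict() == {0: 2, 1: 1, 2: 1}
        assert hist.sum() == 4

    def test_matches_mixture_model_distribution(self):
        """The TC-per-UMI histogram follows the two-component binomial
        mixture (chi-square goodness of fit, alpha = 0.01)."""
        pi, p_c, p_e, mean_n = 0.4, 0.08, 0.002, 15.0
        df = simulate_umi_counts(40_000, pi, p_c, p_e, mean_n, seed=13)
        hist = np.bincount(df["k"], minlength=12)[:12]
        ks = np.arange(12)
        expected = np.zeros(12)
        for n_val, cnt in df["n"].value_counts().items():
            expected += cnt * (
                pi * binom.pmf(ks, n_val, p_c) + (1 - pi) * binom.pmf(ks, n_val, p_e)
            )
        # merge sparse tail bins for a valid chi-square
        cut = np.argmax(np.cumsum(expected) > expected.sum() - 5)
        obs = np.r_[hist[:cut], hist[cut:].sum()]
        exp = np.r_[expected[:cut], expected[cut:].sum()]
        exp *= obs.sum() / exp.sum()
        _, p = chisquare(obs, exp)
        assert p > 0.01


class TestCellQc:
    def _profiles(self, rows):
        return pd.DataFrame(
            rows, columns=["mito_fraction", "n_genes", "n_umis"],
            index=[f"b{i}" for i in range(len(rows))],
        )

    def test_clean_cell_retained_by_both_presets(self):
        prof = self._profiles([(0.05, 1000, 3000)])
        assert list(q.cell_qc(prof, preset="zf4")) == ["b0"]
        assert list(q.cell_qc(prof, preset="embryo")) == ["b0"]

    def test_gene_ceiling_only_in_zf4(self):
        prof = self._profiles([(0.05, 4001, 3000)])
        assert len(q.cell_qc(prof, preset="zf4")) == 0
        assert len(q.cell_qc(prof, preset="embryo")) == 1

    def test_embryo_umi_floor(self):
        prof = self._profiles([(0.05, 1000, 799)])
        assert len(q.cell_qc(prof, preset="embryo")) == 0
        assert len(q.cell_qc(prof, preset="zf4")) == 1

    def test_mito_boundary_is_inclusive_drop(self):
        prof = self._profiles([(0.10, 1000, 3000)])
        assert len(q.cell_qc(prof, preset="zf4")) == 0

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown QC preset"):
            q.cell_qc(self._profiles([(0.0, 500, 500)]), preset="hela")


def test_pipeline_conserves_umis(small_dataset, small_summaries):
    """Quality filtering and rate computation never drop UMIs."""
    _, reads, truth = small_dataset
    assert len(small_summaries) == len(truth.umis)
    prof = q.cell_rates(small_summaries)
    assert prof["n_umis"].sum() == len(truth.umis)


def test_null_chemistry_tc_rate_matches_other_rates():
    """With p_c = p_e (control), the pooled T-to-C rate is statistically
    indistinguishable from the pooled rate of the other 11 substitution
    types (two-sided 2x2 chi-square)."""
    from scipy.stats import chi2_contingency

    cfg = SimulationConfig(
        n_cells=8,
        n_genes=60,
        mean_umis_per_cell=200,
        chemistry_preset="control",
        seed=4,
    )
    reads, _ = simulate_dataset(cfg)
    summ = q.consensus_umis(reads)
    tc_conv = summ["TC"].sum()
    tc_cov = summ["T"].sum()
    other_conv = sum(summ[s].sum() for s in q.SUB_TYPES if s != "TC")
    other_cov = sum(3 * summ[b].sum() for b in "ACG") + 2 * summ["T"].sum()
    table = [
        [tc_conv, tc_cov - tc_conv],
        [other_conv, other_cov - other_conv],
    ]
    _, p, *_ = chi2_contingency(table)
    assert p > 0.01
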