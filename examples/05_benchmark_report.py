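"""Benchmark two chemistries at a normalized sequencing depth.

Simulates the same cell population under a strong (on-beads mCPBA/TFEA)
and a weak (in-situ IAA) conversion chemistry, summarizes per-method
T-to-C rates and labeled fractions, predicts detected UMIs at a fixed read
depth, and reports the fold-difference in conversion efficiency together
with the published matched-pair reference fold.
"""

from tlabelbench import MethodRun, cell_rates, consensus_umis, fold_difference, method_summary
from tlabelbench.presets import METHOD_BENCHMARKS
from tlabelbench.simulate import SimulationConfig, simulate_dataset


def run(preset: str) -> MethodRun:
    cfg = SimulationConfig(
        n_cells=20,
        n_genes=250,
        mean_umis_per_cell=900,
        chemistry_preset=preset,
        depth_lognorm_sigma=0.3,
        seed=6,  # same seed: identical cells, only the chemistry differs
    )
    reads, truth = simulate_dataset(cfg)
    profiles = cell_rates(consensus_umis(reads))
    depth = truth.umis.groupby("barcode")["n_reads"].sum()
    return MethodRun(name=preset, profiles=profiles, reads_per_cell=depth)


runs = [run("mcpba_tfea_ph7.4"), run("insitu_iaa_ph8")]
summary = method_summary(runs, query_depth=2000)
cols = ["method", "mean_tc_rate", "mean_labeled_umi_fraction", "predicted_numi"]
print(summary[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))

fold = fold_difference(
    summary.loc[0, "mean_tc_rate"], summary.loc[1, "mean_tc_rate"]
)
ref = fold_difference(
    METHOD_BENCHMARKS["onbeads_iaa_matched"]["mean_tc_rate_pct"],
    METHOD_BENCHMARKS["insitu_iaa_matched"]["mean_tc_rate_pct"],
)
print(f"simulated fold-difference in mean T-to-C rate: {fold}")
print(f"published matched on-beads vs in-situ fold:    {ref}")
print("-> on-beads chemistry converts several-fold more efficiently than the"
      " same reaction run inside intact cells.")
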