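"""Classify maternal vs zygotic genes during genome activation.

Simulates an embryo at the maternal-to-zygotic transition: maternal-only
genes (no new RNA), zygotic-only genes (nearly all new), and a large
maternal-zygotic class in between. Genes are classified from the
new-to-total RNA ratio (NTR) on the mixture-estimated new layer, sweeping
the zygotic threshold over 70-85%, and the recovered zygotic set is
compared against the simulated truth with Fisher's exact test.
"""

from tlabelbench import (
    classify_mz,
    consensus_umis,
    estimate_layers,
    ntr_from_adata,
    overlap_test,
    threshold_sweep,
)
from tlabelbench.simulate import SimulationConfig, simulate_dataset

config = SimulationConfig(
    n_cells=15,
    n_genes=400,
    mean_umis_per_cell=1500,
    embryo_mode=True,
    p_c=0.08,
    expression_logsd=0.3,
    depth_lognorm_sigma=0.3,
    seed=4,
)
reads, truth = simulate_dataset(config)
adata = estimate_layers(consensus_umis(reads), p_e=config.background_pe)
records = ntr_from_adata(adata, use_estimated=True, min_umis=10)

sweep = threshold_sweep(records, [0.70, 0.75, 0.80, 0.85])
print(sweep.to_string(index=False))
print("-> zygotic counts shrink as the NTR cutoff rises; maternal counts don't.")

called = classify_mz(records, z_threshold=0.70)
called_z = set(called[called["mz_class"] == "Z"]["gene_id"])
true_z = set(truth.genes[truth.genes["mz_class"] == "Z"]["gene_id"])
universe = set(records["gene_id"])
res = overlap_test(called_z, true_z & universe, universe)
print(f"called Z: {len(called_z)}, true Z among retained genes: "
      f"{len(true_z & universe)}")
print(f"overlap odds ratio = {res.odds_ratio}, p = {res.p_value:.3g}")
print("-> a very large odds ratio: the called and true zygotic sets"
      " (almost) coincide.")
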