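"""Simulate a labeling experiment and quantify T-to-C conversions.

Generates a small Drop-seq-like dataset with the mCPBA/TFEA (pH 7.4)
chemistry preset, builds per-UMI consensus conversion counts, and prints
per-cell substitution rates. The T-to-C rate should sit well above the
other 11 substitution types — that excess is the labeling signal.
"""

from tlabelbench import cell_rates, consensus_umis
from tlabelbench.simulate import SimulationConfig, simulate_dataset

config = SimulationConfig(
    n_cells=10,
    n_genes=150,
    mean_umis_per_cell=500,
    chemistry_preset="mcpba_tfea_ph7.4",
    seed=1,
)
reads, truth = simulate_dataset(config)
print(f"simulated {len(truth.umis)} UMIs / {len(reads)} position observations")

summaries = consensus_umis(reads)  # Phred > 27 filter + per-UMI consensus
profiles = cell_rates(summaries)

tc = profiles["TC"].mean()
others = profiles[[c for c in profiles.columns[:12] if c != "TC"]].mean().mean()
print(f"mean T-to-C rate per cell:   {tc:.4f}")
print(f"mean of other 11 rates:      {others:.4f}")
print(f"mean labeled-UMI fraction:   {profiles['labeled_umi_fraction'].mean():.3f}")
print(
    "-> T-to-C is elevated by the chemistry acting on 4sU in new RNA; the\n"
    "   other substitution types stay at the background conversion level."
)
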