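"""Separate new from pre-existing RNA with the binomial mixture.

Each UMI contributes (k conversions out of n covered Ts). Old molecules
convert at the background rate p_e, new molecules at the induced rate p_c;
EM recovers the fraction-new pi and p_c with p_e held fixed. The per-UMI
posterior then builds *estimated* new/old expression layers that recover
new molecules showing zero conversions — the main bias of raw labeling.
"""

import numpy as np
import pandas as pd

from tlabelbench import estimate_layers, fit_binomial_mixture
from tlabelbench.quantify import SUB_TYPES
from tlabelbench.simulate import simulate_umi_counts

pi_true, p_c_true, p_e = 0.4, 0.08, 0.002
df = simulate_umi_counts(50_000, pi_true, p_c_true, p_e, seed=2)

fit = fit_binomial_mixture(df["k"], df["n"], p_e)
print(f"truth:     pi = {pi_true:.3f}, p_c = {p_c_true:.4f}")
print(f"estimated: pi = {fit.pi:.3f}, p_c = {fit.p_c:.4f} "
      f"({fit.n_iter} EM iterations)")

# wrap the UMIs into per-gene summaries and build expression layers
rng = np.random.default_rng(3)
gene_index = rng.integers(0, 50, len(df))
summaries = pd.DataFrame(
    {
        "barcode": [f"cell{i % 10}" for i in range(len(df))],
        "umi": [f"u{i}" for i in range(len(df))],
        "gene_id": [f"gene{g:02d}" for g in gene_index],
        "A": 10, "C": 10, "G": 10, "T": df["n"],
        **{s: 0 for s in SUB_TYPES},
    }
)
summaries["TC"] = df["k"]
adata = estimate_layers(summaries, p_e=p_e)

raw = adata.layers["labeled"].sum()
est = np.nansum(adata.layers["estimated_new"])
total = adata.layers["total"].sum()
print(f"raw labeled fraction:       {raw / total:.3f}")
print(f"estimated new fraction:     {est / total:.3f}")
print(
    "-> raw >=1-conversion labeling misses new molecules with k = 0; the\n"
    "   posterior-summed estimate is close to the simulated fraction-new."
)
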