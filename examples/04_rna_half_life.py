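"""Estimate RNA half-lives from a single labeling pulse.

After t hours of labeling, a gene with half-life h has turned over a
fraction 1 - 2^(-t/h) of its pool; inverting gives
h = ln(2) t / (-ln(1 - n/r)) from labeled (n) and total (r) counts.
The example draws labeled counts for genes of known half-life, recovers h,
and ranks transcript stability deciles.
"""

import numpy as np

from tlabelbench import gene_half_lives, rank_stability

rng = np.random.default_rng(5)
t = 4.0  # hours of 4sU labeling
true_h = np.array([0.5, 1, 2, 4, 6, 8, 12, 16, 24, 48], dtype=float)
r = 20_000  # UMIs per gene
labeled = rng.binomial(r, 1 - 2 ** (-t / true_h))[:, None]
total = np.full((len(true_h), 1), r)

est = gene_half_lives(labeled, total, [f"gene{i}" for i in range(len(true_h))], t=t)
est = rank_stability(est, fraction=0.1)
for h, (_, row) in zip(true_h, est.iterrows()):
    print(
        f"{row['gene_id']}: true h = {h:5.1f} h, estimated = {row['h']:6.2f} h"
        f"  [{row['stability_flag']}]"
    )
print(
    "-> the shortest-lived decile is flagged unstable, the longest stable;\n"
    "   estimates track truth to within binomial counting noise."
)
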