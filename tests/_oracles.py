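"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library's own code paths: the consensus oracle
is a per-position dictionary vote, the mixture oracle an exhaustive grid
enumeration, and the Fisher oracle a direct hypergeometric sum.
"""

from collections import Counter, defaultdict

import numpy as np
from scipy.stats import binom, hypergeom


def brute_force_consensus(rows):
    """Plurality vote per (barcode, umi, gene, pos); ties fall to reference.

    ``rows`` is an iterable of (barcode, umi, gene_id, pos, ref, obs, qual)
    tuples (qual ignored — apply filtering upstream). Returns a dict mapping
    (barcode, umi, gene_id, pos) -> (ref, consensus).
    """
    votes = defaultdict(Counter)
    refs = {}
    for barcode, umi, gene, pos, ref, obs, _qual in rows:
        key = (barcode, umi, gene, pos)
        votes[key][obs] += 1
        if key in refs and refs[key] != ref:
            raise ValueError("conflicting refs in oracle input")
        refs[key] = ref
    out = {}
    for key, counter in votes.items():
        top = max(counter.values())
        winners = [base for base, cnt in counter.items() if cnt == top]
        consensus = winners[0] if len(winners) == 1 else refs[key]
        out[key] = (refs[key], consensus)
    return out


def grid_mixture_max_loglik(k, n, p_e, step=0.001):
    """Exhaustive (pi, p_c) grid maximum of the binomial-mixture likelihood.

    The grid covers the estimator's parameter space: pi in [0, 1] and
    p_c in [p_e, 1], both at the given step (p_e itself included).
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    keep = n > 0
    k, n = k[keep], n[keep]
    pis = np.arange(0.0, 1.0 + step / 2, step)
    pcs = np.arange(0.0, 1.0 + step / 2, step)
    pcs = np.concatenate([[p_e], pcs[pcs > p_e]])
    a = binom.pmf(k, n, p_e)
    best = -np.inf
    chunk = 16
    for i in range(0, len(pcs), chunk):
        b = binom.pmf(k[None, :], n[None, :], pcs[i : i + chunk, None])
        mix = (
            pis[None, :, None] * b[:, None, :]
            + (1.0 - pis)[None, :, None] * a[None, None, :]
        )
        ll = np.log(np.clip(mix, 1e-300, None)).sum(axis=-1)
        best = max(best, float(ll.max()))
    return best


def fisher_two_sided_p(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    row1 = a + b
    n_total = a + b + c + d
    col1 = a + c
    p_obs = hypergeom.pmf(a, n_total, row1, col1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n_total), min(row1, col1) + 1):
        p = hypergeom.pmf(x, n_total, row1, col1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)
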