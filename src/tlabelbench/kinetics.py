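"""RNA half-life estimation from one-shot metabolic labeling.

A single labeling pulse of duration ``t`` turns over a fraction
``f = n/r = 1 - 2**(-t/h)`` of each gene's mRNA pool, where ``n`` is the
number of metabolically labeled molecules, ``r`` the total abundance and
``h`` the half-life. Inverting gives the closed form

    h = ln(2) * t / (-ln(1 - n/r))

which this module applies per gene to labeled/total UMI counts summed over a
caller-supplied cell subset (typically steady-state cells). Genes with no
labeled molecules map to an infinite half-life sentinel; fully labeled genes
map to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HalfLifeEstimate",
    "half_life",
    "fraction_new_from_halflife",
    "gene_half_lives",
    "rank_stability",
]

#: Labeling duration (hours) used for the cell-line workflow.
DEFAULT_LABELING_TIME_H = 4.0


@dataclass(frozen=True)
class HalfLifeEstimate:
    """Per-gene half-life record.

    ``h`` may be ``math.inf`` (no labeled molecules); such genes are excluded
    from stability ranking and flagged ``non-finite``.
    """

    gene_id: str
    n: float
    r: float
    t: float
    h: float
    stability_flag: str = "mid"


def half_life(n, r, t):
    """Closed-form half-life from labeled count ``n``, total ``r``, time ``t``.

    Accepts scalars or arrays. Boundary cases: ``n == 0`` returns ``inf``
    (nothing turned over within the pulse), ``n == r`` returns ``0``.

    Raises
    ------
    ValueError
        If ``r <= 0``, ``n < 0``, ``n > r`` or ``t <= 0``.
    """
    n_arr = np.asarray(n, dtype=float)
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("total abundance r must be > 0")
    if np.any(n_arr < 0) or np.any(n_arr > r_arr):
        raise ValueError("labeled count n must satisfy 0 <= n <= r")
    if not np.all(np.asarray(t, dtype=float) > 0):
        raise ValueError("labeling time t must be > 0")
    frac = n_arr / r_arr
    with np.errstate(divide="ignore"):
        h = np.where(
            frac >= 1.0,
            0.0,
            np.log(2.0) * t / -np.log1p(-np.where(frac >= 1.0, 0.0, frac)),
        )
    if np.isscalar(n) and np.isscalar(r):
        return float(h)
    return h


def fraction_new_from_halflife(halflife, t):
    """Inverse of :func:`half_life`: expected labeled fraction after time ``t``.

    Returns ``1 - 2**(-t/halflife)``; the monotone limit for an infinitely
    stable transcript is 0. Raises ``ValueError`` for non-positive inputs.
    """
    h_arr = np.asarray(halflife, dtype=float)
    if np.any(h_arr <= 0):
        raise ValueError("half-life must be > 0")
    if not np.all(np.asarray(t, dtype=float) > 0):
        raise ValueError("labeling time t must be > 0")
    frac = -np.expm1(-np.log(2.0) * t / h_arr)
    if np.isscalar(halflife):
        return float(frac)
    return frac


def gene_half_lives(
    labeled,
    total,
    gene_ids,
    t: float = DEFAULT_LABELING_TIME_H,
    cell_mask=None,
) -> pd.DataFrame:
    """Per-gene half-lives from labeled/total gene x cell count matrices.

    Parameters
    ----------
    labeled, total
        2D arrays of shape (n_genes, n_cells); counts are summed over the
        selected cells before the closed form is applied.
    gene_ids
        Sequence of gene identifiers, length ``n_genes``.
    t
        Labeling time in hours.
    cell_mask
        Optional boolean mask or integer index selecting the cell subset
        (e.g. steady-state cells). Cluster assignment is the caller's job.

    Returns
    -------
    DataFrame with columns ``gene_id, n, r, t, h, stability_flag``; genes
    with ``r == 0`` are dropped (no information).
    """
    labeled = np.asarray(labeled, dtype=float)
    total = np.asarray(total, dtype=float)
    if labeled.shape != total.shape:
        raise ValueError("labeled and total matrices must be aligned")
    if cell_mask is not None:
        cell_mask = np.asarray(cell_mask)
        if cell_mask.dtype == bool and not cell_mask.any():
            raise ValueError("cell subset is empty")
        if cell_mask.dtype != bool and len(cell_mask) == 0:
            raise ValueError("cell subset is empty")
        labeled = labeled[:, cell_mask]
        total = total[:, cell_mask]
    elif labeled.shape[1] == 0:
        raise ValueError("cell subset is empty")
    n = labeled.sum(axis=1)
    r = total.sum(axis=1)
    keep = r > 0
    if np.any(n[keep] > r[keep]):
        raise ValueError("labeled counts exceed totals")
    h = np.full(len(n), np.nan)
    h[keep] = half_life(n[keep], r[keep], t)
    df = pd.DataFrame(
        {
            "gene_id": np.asarray(gene_ids),
            "n": n,
            "r": r,
            "t": float(t),
            "h": h,
            "stability_flag": "mid",
        }
    )
    df = df[keep].reset_index(drop=True)
    df.loc[~np.isfinite(df["h"]), "stability_flag"] = "non-finite"
    return df


def rank_stability(estimates: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Flag the shortest- and longest-lived deciles of finite half-lives.

    Genes are sorted by ``h`` ascending (ties broken by ``gene_id`` for
    stability); the shortest ``fraction`` are flagged ``unstable-decile`` and
    the longest ``fraction`` ``stable-decile``. Non-finite estimates are
    excluded from the ranking and keep the ``non-finite`` flag.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    out = estimates.copy()
    finite = out[np.isfinite(out["h"])]
    if finite.empty:
        raise ValueError("no finite half-life estimates to rank")
    order = finite.sort_values(["h", "gene_id"], kind="mergesort")
    k = max(1, int(round(fraction * len(order))))
    out["stability_flag"] = np.where(np.isfinite(out["h"]), "mid", "non-finite")
    out.loc[order.index[:k], "stability_flag"] = "unstable-decile"
    out.loc[order.index[-k:], "stability_flag"] = "stable-decile"
    return out
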