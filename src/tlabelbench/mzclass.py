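"""Maternal / maternal-zygotic / zygotic gene classification from NTR.

During zygotic genome activation, a gene's new-to-total RNA ratio (NTR) —
labeled UMIs over total UMIs, pooled across cells — separates maternally
deposited transcripts (NTR near 0) from zygotically activated ones (NTR near
1). Genes are filtered at a minimum UMI support, ranked into equal-size NTR
bins, and classified with fixed thresholds: zygotic above the z-threshold
(swept over 70/75/80/85%), maternal below 5%, maternal-zygotic between.
Fisher's exact test quantifies overlap of zygotic gene sets against external
references.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

__all__ = [
    "OverlapResult",
    "DEFAULT_Z_THRESHOLDS",
    "compute_ntr",
    "ntr_from_adata",
    "bin_genes",
    "classify_mz",
    "threshold_sweep",
    "overlap_test",
]

DEFAULT_MIN_UMIS = 10
DEFAULT_M_THRESHOLD = 0.05
DEFAULT_Z_THRESHOLDS = (0.70, 0.75, 0.80, 0.85)


@dataclass(frozen=True)
class OverlapResult:
    """2x2 overlap of two gene sets within a universe."""

    table: tuple  # ((a, b), (c, d))
    odds_ratio: float  # sample odds ratio a*d / (b*c); inf when b*c == 0
    p_value: float


def compute_ntr(
    labeled,
    total,
    gene_ids,
    min_umis: int = DEFAULT_MIN_UMIS,
) -> pd.DataFrame:
    """Per-gene NTR from cell-summed labeled and total count matrices.

    ``labeled`` and ``total`` are (genes x cells) arrays (or already-summed
    1D vectors). Genes with fewer than ``min_umis`` total UMIs are excluded
    — low-coverage NTRs are dominated by sampling noise.
    """
    labeled = np.asarray(labeled, dtype=float)
    total = np.asarray(total, dtype=float)
    if labeled.shape != total.shape:
        raise ValueError("labeled and total matrices must be aligned")
    if labeled.ndim == 2:
        labeled = labeled.sum(axis=1)
        total = total.sum(axis=1)
    if np.any(labeled > total + 1e-9):
        raise ValueError("labeled counts exceed totals: corrupt layers")
    keep = total >= min_umis
    with np.errstate(invalid="ignore", divide="ignore"):
        ntr = np.where(total > 0, labeled / total, np.nan)
    df = pd.DataFrame(
        {
            "gene_id": np.asarray(gene_ids),
            "labeled_umis": labeled,
            "total_umis": total,
            "ntr": ntr,
        }
    )
    return df[keep].reset_index(drop=True)


def ntr_from_adata(
    adata,
    use_estimated: bool = False,
    min_umis: int = DEFAULT_MIN_UMIS,
) -> pd.DataFrame:
    """NTR records from an estimate_layers AnnData.

    By default the numerator is the raw ``labeled`` layer (the literal
    definition); ``use_estimated=True`` uses the mixture-corrected
    ``estimated_new`` layer instead, which undoes the undercounting of new
    molecules that show zero conversions. Genes without estimated support
    are dropped in estimated mode.
    """
    layer = "estimated_new" if use_estimated else "labeled"
    labeled = np.asarray(adata.layers[layer]).T  # genes x cells
    total = np.asarray(adata.layers["total"]).T
    gene_ids = np.asarray(adata.var_names)
    if use_estimated:
        ok = ~np.isnan(labeled).any(axis=1)
        labeled, total, gene_ids = labeled[ok], total[ok], gene_ids[ok]
        labeled = np.minimum(labeled, total)  # posterior sums within totals
    return compute_ntr(labeled, total, gene_ids, min_umis=min_umis)


def bin_genes(records: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Rank genes by NTR (ascending) into equal-size bins 1..n_bins.

    Bin sizes differ by at most one (earlier bins take the remainder); NTR
    ties break by gene_id lexicographically, so the binning is stable.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(records) < n_bins:
        raise ValueError(f"{len(records)} genes cannot fill {n_bins} bins")
    out = records.sort_values(["ntr", "gene_id"], kind="mergesort").reset_index(
        drop=True
    )
    splits = np.array_split(np.arange(len(out)), n_bins)
    bins = np.empty(len(out), dtype=np.int64)
    for i, idx in enumerate(splits, start=1):
        bins[idx] = i
    out["bin"] = bins
    return out


def classify_mz(
    records: pd.DataFrame,
    z_threshold: float,
    m_threshold: float = DEFAULT_M_THRESHOLD,
) -> pd.DataFrame:
    """Exhaustive, disjoint M/MZ/Z partition of the retained genes.

    Z iff ntr > z_threshold; M iff ntr < m_threshold; MZ otherwise (the
    band between the maternal and zygotic cutoffs).
    """
    for name, v in (("z_threshold", z_threshold), ("m_threshold", m_threshold)):
        if not 0 < v < 1:
            raise ValueError(f"{name} must be in (0, 1)")
    if m_threshold >= z_threshold:
        raise ValueError("m_threshold must be below z_threshold")
    out = records.copy()
    ntr = out["ntr"].to_numpy()
    cls = np.full(len(out), "MZ", dtype=object)
    cls[ntr > z_threshold] = "Z"
    cls[ntr < m_threshold] = "M"
    out["mz_class"] = cls
    return out


def threshold_sweep(
    records: pd.DataFrame,
    z_thresholds=DEFAULT_Z_THRESHOLDS,
    m_threshold: float = DEFAULT_M_THRESHOLD,
) -> pd.DataFrame:
    """Class counts per zygotic threshold; Z counts are non-increasing."""
    z_thresholds = list(z_thresholds)
    if not z_thresholds:
        raise ValueError("need at least one z threshold")
    rows = []
    for z in z_thresholds:
        classified = classify_mz(records, z, m_threshold)
        counts = classified["mz_class"].value_counts()
        rows.append(
            {
                "z_threshold": z,
                "M": int(counts.get("M", 0)),
                "MZ": int(counts.get("MZ", 0)),
                "Z": int(counts.get("Z", 0)),
            }
        )
    return pd.DataFrame(rows)


def overlap_test(set_a, set_b, universe) -> OverlapResult:
    """Fisher's exact test for overlap of two gene sets.

    Builds the 2x2 table (in A and B / A only / B only / neither) over the
    universe. The odds ratio is the sample ratio a*d / (b*c), serialized as
    inf when b*c == 0; the two-sided p-value sums hypergeometric
    probabilities no larger than the observed table's.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    sa = set(set_a) & universe
    sb = set(set_b) & universe
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    d = len(universe) - a - b - c
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = a * d / (b * c)
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return OverlapResult(table=((a, b), (c, d)), odds_ratio=odds, p_value=float(p))
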