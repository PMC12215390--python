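"""Per-UMI consensus conversion counting and per-cell substitution rates.

Reads sharing a (cell barcode, UMI, gene) triple derive from one mRNA
molecule; a per-position plurality vote across those reads (consensus
calling) prevents read-level sequencing errors from being counted as
chemical conversions. On top of the consensus this module applies the
standard filters of nucleotide-conversion pipelines:

* a Phred cutoff — mismatch calls with quality <= ``min_phred`` (default 27,
  strict inequality retained) revert to "no evidence": they still contribute
  coverage but never a conversion;
* a germline SNP mask built from an untreated control sample — positions
  converted in at least ``threshold`` (default 0.5) of covering control UMIs
  are treated as uninformative and removed from both conversion and content
  counts;
* cell-level QC on detected genes, UMIs and mitochondrial fraction.

Coordinates are 0-based transcript space throughout. Content of a multi-read
UMI is the union of covered positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReadObservation",
    "SnpMask",
    "DataIntegrityError",
    "SUB_TYPES",
    "quality_filter",
    "consensus_positions",
    "summarize_umis",
    "consensus_umis",
    "detect_snps",
    "apply_snp_mask",
    "cell_rates",
    "conversions_per_umi_histogram",
    "cell_qc",
    "QC_PRESETS",
]

#: The 12 substitution types, reference base first.
SUB_TYPES = [a + b for a in "ACGT" for b in "ACGT" if a != b]
_BASES = list("ACGT")

DEFAULT_MIN_PHRED = 27
DEFAULT_SNP_THRESHOLD = 0.5

#: Cell-QC presets: ``zf4`` mirrors the cultured-cell filters (mitochondrial
#: UMI fraction >= 10%, fewer than 400 or more than 4000 detected genes);
#: ``embryo`` the 5.5 hpf filters (mito >= 10%, < 800 UMIs, < 400 genes).
QC_PRESETS = {
    "zf4": {"mito_max": 0.10, "min_genes": 400, "max_genes": 4000},
    "embryo": {"mito_max": 0.10, "min_genes": 400, "min_umis": 800},
}


class DataIntegrityError(ValueError):
    """Inconsistent read evidence (e.g. conflicting reference bases)."""


@dataclass(frozen=True)
class ReadObservation:
    """One aligned read's per-position evidence.

    ``observations`` is a list of (pos, ref, obs, qual) tuples with 0-based
    transcript coordinates; positions must be unique within the read.
    """

    barcode: str
    umi: str
    gene_id: str
    observations: list = field(default_factory=list)

    def __post_init__(self):
        positions = [p for p, *_ in self.observations]
        if len(positions) != len(set(positions)):
            raise DataIntegrityError("positions must be unique within one read")
        for _, ref, obs, qual in self.observations:
            if ref not in _BASES or obs not in _BASES:
                raise DataIntegrityError(f"bases must be one of {_BASES}")
            if qual < 0:
                raise DataIntegrityError("Phred quality must be >= 0")

    @staticmethod
    def frame(reads: list["ReadObservation"]) -> pd.DataFrame:
        """Stack ReadObservation objects into the tabular read form."""
        rows = [
            (r.barcode, r.umi, r.gene_id, pos, ref, obs, qual)
            for r in reads
            for pos, ref, obs, qual in r.observations
        ]
        return pd.DataFrame(
            rows, columns=["barcode", "umi", "gene_id", "pos", "ref", "obs", "qual"]
        )


@dataclass(frozen=True)
class SnpMask:
    """Masked (gene_id, position) pairs plus the detection threshold used."""

    positions: frozenset
    threshold: float = DEFAULT_SNP_THRESHOLD

    def __len__(self) -> int:
        return len(self.positions)


def _base_codes(col: pd.Series) -> np.ndarray:
    codes = pd.Categorical(col, categories=_BASES).codes
    if (codes < 0).any():
        raise DataIntegrityError("bases must be A, C, G or T")
    return codes.astype(np.int8)


def quality_filter(reads: pd.DataFrame, min_phred: int = DEFAULT_MIN_PHRED) -> pd.DataFrame:
    """Revert low-quality mismatch calls to the reference base.

    A mismatch with Phred quality <= ``min_phred`` (strictly greater survives)
    is treated as carrying no conversion evidence: the position stays covered
    but the observed base becomes the reference. Matches are untouched.
    """
    if min_phred < 0:
        raise ValueError("min_phred must be >= 0")
    ref_c = _base_codes(reads["ref"])
    obs_c = _base_codes(reads["obs"])
    qual = reads["qual"].to_numpy()
    revert = (obs_c != ref_c) & (qual <= min_phred)
    out = reads.copy()
    if revert.any():
        new_obs = np.where(revert, ref_c, obs_c)
        out["obs"] = pd.Categorical.from_codes(new_obs, categories=_BASES)
    return out


def _triple_codes(df: pd.DataFrame):
    b_codes, b_cats = pd.factorize(df["barcode"], sort=True)
    u_codes, u_cats = pd.factorize(df["umi"], sort=True)
    g_codes, g_cats = pd.factorize(df["gene_id"], sort=True)
    uid = (b_codes.astype(np.int64) * len(u_cats) + u_codes) * len(g_cats) + g_codes
    return uid, (np.asarray(b_cats), np.asarray(u_cats), np.asarray(g_cats))


def consensus_positions(reads: pd.DataFrame) -> pd.DataFrame:
    """Per-position plurality vote across the reads of each UMI.

    Returns one row per (barcode, umi, gene_id, pos) with the reference base
    and the consensus call. Ties (including ties not involving the reference)
    fall to the reference base — the conservative choice that never inflates
    conversion counts. Conflicting reference bases at one position raise
    :class:`DataIntegrityError`.
    """
    if reads.empty:
        return pd.DataFrame(
            columns=["barcode", "umi", "gene_id", "pos", "ref", "consensus"]
        )
    uid, cats = _triple_codes(reads)
    pos = reads["pos"].to_numpy(dtype=np.int64)
    ref_c = _base_codes(reads["ref"]).astype(np.int64)
    obs_c = _base_codes(reads["obs"]).astype(np.int64)

    maxpos = int(pos.max()) + 1
    up = uid * maxpos + pos
    key = up * 4 + obs_c

    # one sort drives everything: rows ordered by (uid, pos, obs)
    order = np.argsort(key, kind="stable")
    key_s = key[order]
    ref_s = ref_c[order]
    up_s = key_s // 4

    # per-(uid, pos) groups over rows; reference must be constant within one
    new_up_row = np.r_[True, up_s[1:] != up_s[:-1]]
    up_starts_rows = np.flatnonzero(new_up_row)
    gid_rows = np.cumsum(new_up_row) - 1
    ref_first = ref_s[up_starts_rows]
    if np.any(ref_s != ref_first[gid_rows]):
        raise DataIntegrityError("conflicting reference bases at one position")

    # collapse rows to unique (uid, pos, obs) vote counts
    new_key_row = np.r_[True, key_s[1:] != key_s[:-1]]
    key_starts = np.flatnonzero(new_key_row)
    counts = np.diff(np.r_[key_starts, len(key_s)])
    ukey = key_s[key_starts]
    kup = ukey // 4
    kobs = ukey % 4

    # per-(uid, pos) groups over unique votes: plurality with ties -> ref
    new_group = np.r_[True, kup[1:] != kup[:-1]]
    starts = np.flatnonzero(new_group)
    gid = np.cumsum(new_group) - 1
    gmax = np.maximum.reduceat(counts, starts)
    is_max = counts == gmax[gid]
    n_max = np.add.reduceat(is_max.astype(np.int64), starts)
    cand = np.where(is_max, np.arange(len(ukey)), len(ukey))
    first_max = np.minimum.reduceat(cand, starts)
    winner = kobs[first_max]

    group_up = kup[starts]
    ref_g = ref_first
    consensus = np.where(n_max > 1, ref_g, winner)

    uid_g = group_up // maxpos
    pos_g = group_up % maxpos
    b_cats, u_cats, g_cats = cats
    g_code = uid_g % len(g_cats)
    bu = uid_g // len(g_cats)
    u_code = bu % len(u_cats)
    b_code = bu // len(u_cats)
    return pd.DataFrame(
        {
            "barcode": pd.Categorical.from_codes(b_code, categories=b_cats),
            "umi": pd.Categorical.from_codes(u_code, categories=u_cats),
            "gene_id": pd.Categorical.from_codes(g_code, categories=g_cats),
            "pos": pos_g.astype(np.int32),
            "ref": pd.Categorical.from_codes(ref_g.astype(np.int8), categories=_BASES),
            "consensus": pd.Categorical.from_codes(
                consensus.astype(np.int8), categories=_BASES
            ),
        }
    )


def summarize_umis(positions: pd.DataFrame) -> pd.DataFrame:
    """Collapse consensus positions into per-UMI content and conversion counts.

    Output columns: barcode, umi, gene_id, covered reference-base counts
    (A, C, G, T) and the 12 substitution-type counts. UMIs whose only covered
    positions were masked out disappear with their positions; UMIs with zero
    reference-T content are ordinary rows (unconvertible molecules).
    """
    cols = ["barcode", "umi", "gene_id", *_BASES, *SUB_TYPES]
    if positions.empty:
        return pd.DataFrame(columns=cols)
    uid, cats = _triple_codes(positions)
    uniq, inv = np.unique(uid, return_inverse=True)
    ref_c = _base_codes(positions["ref"])
    cons_c = _base_codes(positions["consensus"])

    content = np.zeros((len(uniq), 4), dtype=np.int64)
    np.add.at(content, (inv, ref_c), 1)

    conv = np.zeros((len(uniq), 16), dtype=np.int64)
    mism = cons_c != ref_c
    np.add.at(conv, (inv[mism], ref_c[mism] * 4 + cons_c[mism]), 1)

    b_cats, u_cats, g_cats = cats
    g_code = uniq % len(g_cats)
    bu = uniq // len(g_cats)
    out = pd.DataFrame(
        {
            "barcode": pd.Categorical.from_codes(bu // len(u_cats), categories=b_cats),
            "umi": pd.Categorical.from_codes(bu % len(u_cats), categories=u_cats),
            "gene_id": pd.Categorical.from_codes(g_code, categories=g_cats),
        }
    )
    for i, base in enumerate(_BASES):
        out[base] = content[:, i]
    for ri, rb in enumerate(_BASES):
        for oi, ob in enumerate(_BASES):
            if ri != oi:
                out[rb + ob] = conv[:, ri * 4 + oi]
    return out


def consensus_umis(
    reads: pd.DataFrame,
    min_phred: int = DEFAULT_MIN_PHRED,
    snp_mask: SnpMask | None = None,
) -> pd.DataFrame:
    """Quality filter -> consensus -> SNP mask -> per-UMI summaries.

    UMI conservation: a UMI whose every covered position is SNP-masked is
    kept as an all-zero row rather than silently dropped.
    """
    positions = consensus_positions(quality_filter(reads, min_phred))
    if snp_mask is None:
        return summarize_umis(positions)
    before = positions[["barcode", "umi", "gene_id"]].drop_duplicates()
    summaries = summarize_umis(apply_snp_mask(positions, snp_mask))
    merged = before.astype(str).merge(
        summaries.assign(
            barcode=summaries["barcode"].astype(str),
            umi=summaries["umi"].astype(str),
            gene_id=summaries["gene_id"].astype(str),
        ),
        on=["barcode", "umi", "gene_id"],
        how="left",
    )
    count_cols = [*_BASES, *SUB_TYPES]
    merged[count_cols] = (
        merged[count_cols].astype(float).fillna(0.0).astype(np.int64)
    )
    return merged.sort_values(["barcode", "umi", "gene_id"], kind="mergesort").reset_index(
        drop=True
    )


def detect_snps(
    control_positions: pd.DataFrame,
    threshold: float = DEFAULT_SNP_THRESHOLD,
    min_coverage: int = 5,
) -> SnpMask:
    """Call SNP positions from an untreated control sample.

    A (gene, position) enters the mask when at least ``min_coverage``
    control UMIs cover it and the fraction whose consensus differs from the
    reference is >= ``threshold``. With no chemical conversion in the
    control, recurrent mismatches at one position are germline variants,
    not labeling signal.

    The coverage floor matters: at 1-2x-covered positions a single chance
    background conversion clears any fraction threshold, and masking such
    positions selectively removes converted sites, biasing downstream
    background-rate estimates downward.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    if control_positions.empty:
        raise ValueError(
            "empty control dataset: pass snp_mask=None to skip SNP masking explicitly"
        )
    df = control_positions
    g_codes, g_cats = pd.factorize(df["gene_id"], sort=True)
    pos = df["pos"].to_numpy(dtype=np.int64)
    maxpos = int(pos.max()) + 1
    key = g_codes.astype(np.int64) * maxpos + pos
    mism = (_base_codes(df["consensus"]) != _base_codes(df["ref"])).astype(np.int64)
    uniq, inv, cover = np.unique(key, return_inverse=True, return_counts=True)
    n_mism = np.zeros(len(uniq), dtype=np.int64)
    np.add.at(n_mism, inv, mism)
    hit = (n_mism / cover >= threshold) & (cover >= min_coverage)
    genes = np.asarray(g_cats)[(uniq[hit] // maxpos)]
    positions = uniq[hit] % maxpos
    return SnpMask(
        positions=frozenset(zip(genes.tolist(), positions.tolist())),
        threshold=threshold,
    )


def apply_snp_mask(positions: pd.DataFrame, mask: SnpMask) -> pd.DataFrame:
    """Drop masked positions entirely (both conversion and content evidence)."""
    if not mask.positions or positions.empty:
        return positions
    pairs = pd.MultiIndex.from_arrays(
        [positions["gene_id"].astype(str), positions["pos"].astype(int)]
    )
    masked = pd.MultiIndex.from_tuples(sorted(mask.positions))
    return positions[~pairs.isin(masked)].reset_index(drop=True)


def cell_rates(summaries: pd.DataFrame, mito_prefix: str = "mt-") -> pd.DataFrame:
    """Per-cell substitution-rate profiles.

    Each of the 12 rates is (summed conversions) / (summed covered positions
    of the reference base) over the cell's UMIs; zero coverage yields NaN
    (missing), never 0. ``labeled_umi_fraction`` is the fraction of UMIs with
    at least one T-to-C conversion. ``n_genes``, ``n_umis`` and
    ``mito_fraction`` (fraction of UMIs from ``mito_prefix`` genes) feed QC.
    """
    if summaries.empty:
        raise ValueError("no UMI summaries: cannot compute cell rates")
    df = summaries
    grouped = df.groupby("barcode", observed=True)
    sums = grouped[[*_BASES, *SUB_TYPES]].sum()
    out = pd.DataFrame(index=sums.index)
    for sub in SUB_TYPES:
        denom = sums[sub[0]].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[sub] = np.where(denom > 0, sums[sub].to_numpy() / denom, np.nan)
    out["labeled_umi_fraction"] = grouped["TC"].apply(lambda s: float((s > 0).mean()))
    out["n_umis"] = grouped.size()
    out["n_genes"] = grouped["gene_id"].nunique()
    is_mito = df["gene_id"].astype(str).str.startswith(mito_prefix)
    out["mito_fraction"] = is_mito.groupby(df["barcode"], observed=True).mean()
    return out


def conversions_per_umi_histogram(summaries: pd.DataFrame) -> pd.Series:
    """Histogram of T-to-C conversions per UMI: index k, values UMI counts."""
    counts = summaries["TC"].value_counts().sort_index()
    counts.index.name = "tc_per_umi"
    counts.name = "n_umis"
    return counts


def cell_qc(
    profiles: pd.DataFrame,
    preset: str | None = None,
    thresholds: dict | None = None,
) -> pd.Index:
    """Retain barcodes passing the QC thresholds of a preset.

    ``thresholds`` keys (all optional): ``mito_max`` (cells with mito
    fraction >= this are dropped), ``min_genes``, ``max_genes``,
    ``min_umis``. Exactly one of ``preset``/``thresholds`` must be given.
    """
    if (preset is None) == (thresholds is None):
        raise ValueError("pass exactly one of preset or thresholds")
    if preset is not None:
        try:
            thresholds = QC_PRESETS[preset]
        except KeyError:
            raise ValueError(
                f"unknown QC preset {preset!r}; known: {sorted(QC_PRESETS)}"
            ) from None
    keep = pd.Series(True, index=profiles.index)
    if "mito_max" in thresholds:
        keep &= profiles["mito_fraction"] < thresholds["mito_max"]
    if "min_genes" in thresholds:
        keep &= profiles["n_genes"] >= thresholds["min_genes"]
    if "max_genes" in thresholds:
        keep &= profiles["n_genes"] <= thresholds["max_genes"]
    if "min_umis" in thresholds:
        keep &= profiles["n_umis"] >= thresholds["min_umis"]
    return profiles.index[keep]
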