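"""Synthetic 4sU metabolic-labeling scRNA-seq generator with known ground truth.

The generator emulates what the downstream pipeline actually consumes — a
stream of per-position read observations — without modeling nucleotide
sequences or alignment. The generative story, molecule by molecule:

* Each gene has a ground-truth fraction-new tied to an RNA half-life through
  ``fraction_new = 1 - 2**(-t/half_life)`` (one labeling pulse of ``t`` hours).
* Per-cell expression follows a Gamma-Poisson (negative binomial) model with
  log-normal per-cell depth factors; every drawn count is one UMI (one mRNA
  molecule).
* A UMI covers a random set of transcript positions: the number of reference-T
  positions is Poisson(``mean_t_content``), likewise for A/C/G content.
* Molecule-level conversions: a new molecule converts each covered T to C
  with probability ``p_c``; background conversions hit every substitution
  type of every molecule at rate ``background_pe`` per alternate base.
  Germline SNP positions show the alternate base in every overlapping read.
* Each UMI is sequenced by ``1 + Poisson(1)`` reads; read-level sequencing
  errors of all 12 substitution types occur at ``seq_error_rate`` per
  alternate base, and per-base Phred scores place a configurable fraction of
  calls at or below the quality cutoff used downstream.

Randomness is split hierarchically (dataset -> cell) with
``numpy.random.SeedSequence`` spawn keys, so enlarging ``n_cells`` never
perturbs the draws of earlier cells, and identical (config, seed) pairs
produce byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .kinetics import fraction_new_from_halflife, half_life
from .presets import CHEMISTRY_PRESETS, preset_conversion_probability

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ConfigurationError",
    "simulate_dataset",
    "simulate_umi_counts",
    "make_embryo_truth",
    "plant_snps",
    "fraction_new_from_halflife",
    "READ_COLUMNS",
]

BASES = np.array(list("ACGT"))
#: Columns of the read-observation table (one row per covered position per read).
READ_COLUMNS = ["barcode", "umi", "gene_id", "pos", "ref", "obs", "qual"]

# For each reference base, alternate bases in draw order. For T the first
# alternate is C so that the induced-conversion branch is the first interval
# of the shared uniform draw: raising p_c can only turn more T calls into C
# under a common seed (monotone coupling).
_ALT_ORDER = {
    "A": ("C", "G", "T"),
    "C": ("A", "G", "T"),
    "G": ("A", "C", "T"),
    "T": ("C", "A", "G"),
}
_ALT_CODES = np.array(
    [["ACGT".index(x) for x in _ALT_ORDER[b]] for b in "ACGT"], dtype=np.int8
)


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


def _check_prob(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and 0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic labeling experiment.

    Defaults describe a realistic Drop-seq-scale run: ~2500 UMIs per cell
    (matching the median transcript recovery of the benchmark datasets),
    Poisson(15) reference-T content per UMI, a top-performing on-beads
    chemistry, and a background conversion rate of 0.2%. Tests and scripts
    override the problem-size fields (``n_cells``, ``n_genes``,
    ``mean_umis_per_cell``) freely; the rate and content parameters are the
    study conditions.
    """

    n_cells: int = 200
    n_genes: int = 2000
    labeling_time_t: float = 4.0
    chemistry_preset: str = "mcpba_tfea_ph7.4"
    p_c: float | None = None  # explicit override of the preset
    background_pe: float = 0.002
    seq_error_rate: float = 0.001  # per covered position, per alternate base
    mean_t_content: float = 15.0
    mean_other_content: float = 15.0
    mean_umis_per_cell: float = 2500.0
    expression_logsd: float = 1.0
    expression_dispersion: float = 0.3
    halflife_log_mean: float = math.log(4.0)  # hours, log scale
    halflife_log_sd: float = 1.0
    embryo_mode: bool = False
    class_fractions: dict = field(
        default_factory=lambda: {"Z": 0.10, "MZ": 0.78, "M": 0.12}
    )
    class_ntr_ranges: dict = field(
        default_factory=lambda: {
            "M": (0.0, 0.02),
            "MZ": (0.05, 0.50),
            "Z": (0.85, 1.0),
        }
    )
    snp_positions: tuple = ()  # tuple of (gene_id, 0-based transcript pos)
    n_mito_genes: int | None = None
    depth_lognorm_sigma: float = 0.5
    reads_per_umi_poisson: float = 1.0
    low_quality_fraction: float = 0.05
    gene_length: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ConfigurationError("n_cells and n_genes must be positive")
        if self.labeling_time_t <= 0:
            raise ConfigurationError("labeling_time_t must be > 0")
        _check_prob("background_pe", self.background_pe)
        _check_prob("seq_error_rate", self.seq_error_rate)
        _check_prob("low_quality_fraction", self.low_quality_fraction)
        if self.p_c is not None:
            _check_prob("p_c", self.p_c)
        if self.mean_t_content <= 0 or self.mean_other_content < 0:
            raise ConfigurationError("base-content means must be positive")
        if self.expression_dispersion <= 0:
            raise ConfigurationError("expression_dispersion must be positive")
        if self.chemistry_preset not in CHEMISTRY_PRESETS:
            raise ConfigurationError(
                f"unknown chemistry preset {self.chemistry_preset!r}"
            )
        if self.conversion_probability() < self.background_pe:
            raise ConfigurationError("p_c must be >= background_pe")
        if self.embryo_mode:
            self._check_class_ranges()
        if self.n_mito_genes is None:
            self.n_mito_genes = max(1, self.n_genes // 100)
        if self.gene_length < 4 * 40:
            raise ConfigurationError("gene_length too short for realistic coverage")

    def _check_class_ranges(self) -> None:
        ranges = sorted(self.class_ntr_ranges.values())
        for (lo, hi), (lo2, _hi2) in zip(ranges, ranges[1:]):
            if hi > lo2:
                raise ConfigurationError(
                    f"class NTR ranges overlap: {(lo, hi)} vs {(lo2, _hi2)}"
                )
        for lo, hi in ranges:
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigurationError("class NTR ranges must lie in [0, 1]")
        total = sum(self.class_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError("class fractions must sum to 1")

    def conversion_probability(self) -> float:
        """Induced T-to-C probability: explicit ``p_c`` or the preset value."""
        if self.p_c is not None:
            return self.p_c
        return preset_conversion_probability(self.chemistry_preset, self.background_pe)

    def gene_ids(self) -> np.ndarray:
        names = [f"gene{i:05d}" for i in range(self.n_genes)]
        for i in range(self.n_mito_genes):
            names[i] = f"mt-{names[i]}"
        return np.array(names)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["snp_positions"] = [list(p) for p in self.snp_positions]
        return d


@dataclass
class GroundTruth:
    """What the simulator knows and the pipeline tries to recover.

    ``genes`` columns: gene_id, fraction_new, half_life, mz_class (empty when
    not in embryo mode). ``umis`` columns: barcode, umi, gene_id, is_new.
    The half-life and fraction-new columns always satisfy
    ``fraction_new == 1 - 2**(-t/half_life)`` to machine precision.
    """

    genes: pd.DataFrame
    umis: pd.DataFrame
    snp_positions: tuple
    labeling_time_t: float


def _dataset_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))

def _cell_rng(seed: int, cell_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(1, cell_index))
    )


def _encode_dna(values: np.ndarray, width: int) -> np.ndarray:
    """Deterministic base-4 encoding of integers as DNA strings."""
    values = np.asarray(values, dtype=np.int64)
    out = np.empty((len(values), width), dtype="U1")
    v = values.copy()
    for j in range(width - 1, -1, -1):
        out[:, j] = BASES[v % 4]
        v //= 4
    return np.array(["".join(row) for row in out])


def _ref_base_index(gene_index, pos):
    """Reference base at a transcript position: bases interleave every 4 nt,
    phase-shifted per gene so base pools differ between genes."""
    return (np.asarray(pos) + np.asarray(gene_index)) % 4


def make_embryo_truth(config: SimulationConfig) -> pd.DataFrame:
    """Draw per-gene M/MZ/Z classes and fraction-new from the class ranges.

    Genes are partitioned by ``class_fractions`` (default 12% maternal-only,
    78% maternal-and-zygotic, 10% zygotic-only) and fraction-new is uniform
    within each class's configured NTR range. The equivalent half-life is
    derived through the closed-form inverse so that both parameterizations
    agree exactly.
    """
    if not config.embryo_mode:
        raise ConfigurationError("make_embryo_truth requires embryo_mode=True")
    rng = _dataset_rng(config.seed)
    gene_ids = config.gene_ids()
    classes = sorted(config.class_fractions)  # deterministic order
    probs = np.array([config.class_fractions[c] for c in classes])
    assignment = rng.choice(len(classes), size=config.n_genes, p=probs)
    fraction_new = np.empty(config.n_genes)
    for ci, cname in enumerate(classes):
        lo, hi = config.class_ntr_ranges[cname]
        mask = assignment == ci
        fraction_new[mask] = rng.uniform(lo, hi, mask.sum())
    # keep fractions strictly inside (0, 1) so half-lives stay finite
    fraction_new = np.clip(fraction_new, 1e-12, 1.0 - 1e-12)
    hl = half_life(fraction_new, np.ones_like(fraction_new), config.labeling_time_t)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "fraction_new": fraction_new,
            "half_life": hl,
            "mz_class": np.array(classes)[assignment],
        }
    )


def _gene_truth(config: SimulationConfig) -> pd.DataFrame:
    if config.embryo_mode:
        return make_embryo_truth(config)
    rng = _dataset_rng(config.seed)
    hl = rng.lognormal(config.halflife_log_mean, config.halflife_log_sd, config.n_genes)
    fraction_new = fraction_new_from_halflife(hl, config.labeling_time_t)
    return pd.DataFrame(
        {
            "gene_id": config.gene_ids(),
            "fraction_new": fraction_new,
            "half_life": hl,
            "mz_class": "",
        }
    )


def plant_snps(config: SimulationConfig, n_snps: int, seed: int = 0) -> tuple:
    """Pick ``n_snps`` germline T>C SNP positions on random genes.

    Returns (gene_id, pos) pairs whose reference base is T, suitable for
    ``SimulationConfig.snp_positions``. Positions are distinct.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(9,)))
    gene_ids = config.gene_ids()
    pool = config.gene_length // 4
    chosen = set()
    out = []
    while len(out) < n_snps:
        g = int(rng.integers(config.n_genes))
        q = int(rng.integers(pool))
        pos = 4 * q + (3 - g) % 4  # reference T position of gene g
        if (g, pos) in chosen:
            continue
        chosen.add((g, pos))
        out.append((gene_ids[g], pos))
    return tuple(out)


def _expression_weights(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    w = rng.lognormal(0.0, config.expression_logsd, config.n_genes)
    return w / w.sum()


def simulate_umi_counts(
    n_umis: int,
    pi: float,
    p_c: float,
    p_e: float,
    mean_t_content: float = 15.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fast path: draw per-UMI (T content, T-to-C count) pairs directly.

    Equivalent to the conversion layer of the full generator but skipping
    reads, positions and qualities — the form consumed by the binomial
    mixture. Returns columns ``n`` (covered reference-T positions), ``k``
    (T-to-C conversions) and the ground-truth ``is_new`` flag.
    """
    for name, v in (("pi", pi), ("p_c", p_c), ("p_e", p_e)):
        _check_prob(name, v)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    n = rng.poisson(mean_t_content, n_umis)
    is_new = rng.random(n_umis) < pi
    k = rng.binomial(n, np.where(is_new, p_c, p_e))
    return pd.DataFrame({"n": n, "k": k, "is_new": is_new})


def simulate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the full read-observation table plus ground truth.

    Returns
    -------
    reads : DataFrame
        One row per covered transcript position per read, columns
        ``barcode, umi, gene_id, pos, ref, obs, qual``; string columns are
        pandas Categoricals. Every UMI has at least one read.
    truth : GroundTruth
    """
    genes = _gene_truth(config)
    gene_ids = genes["gene_id"].to_numpy()
    fraction_new = genes["fraction_new"].to_numpy()

    # expression weights use their own spawn key so they are independent of
    # the ground-truth draws that share the dataset-level seed
    expr_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(3,))
    )
    weights = _expression_weights(config, expr_rng)

    p_c = config.conversion_probability()
    p_e = config.background_pe
    snp_keys = None
    if config.snp_positions:
        gene_index = {g: i for i, g in enumerate(gene_ids)}
        snp_keys = np.array(
            sorted(
                gene_index[g] * config.gene_length + int(pos)
                for g, pos in config.snp_positions
            ),
            dtype=np.int64,
        )

    frames = []
    truth_frames = []
    shape = 1.0 / config.expression_dispersion
    pool = config.gene_length // 4

    for c in range(config.n_cells):
        rng = _cell_rng(config.seed, c)
        depth = rng.lognormal(0.0, config.depth_lognorm_sigma)
        mu = weights * config.mean_umis_per_cell * depth
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)
        n_umis = int(counts.sum())
        if n_umis == 0:
            continue
        gidx = np.repeat(np.arange(config.n_genes), counts)
        is_new = rng.random(n_umis) < fraction_new[gidx]

        # covered positions per UMI, by reference base
        content = np.empty((n_umis, 4), dtype=np.int64)
        content[:, 3] = np.minimum(rng.poisson(config.mean_t_content, n_umis), pool)
        for b in range(3):
            content[:, b] = np.minimum(
                rng.poisson(config.mean_other_content, n_umis), pool
            )

        rows_uidx = []
        rows_pos = []
        rows_ref = []
        for b in range(4):
            nb = content[:, b]
            total = int(nb.sum())
            if total == 0:
                continue
            # distinct pool indices per UMI: random keys, take the nb smallest
            keys = rng.random((n_umis, pool))
            order = np.argsort(keys, axis=1, kind="stable")
            take = np.arange(pool)[None, :] < nb[:, None]
            q = order[take]  # concatenated chosen pool slots, grouped by UMI
            uidx = np.repeat(np.arange(n_umis), nb)
            # pool slot q of base b in gene g sits at transcript position
            # 4q + ((b - g) mod 4)
            pos = 4 * q + (b - gidx[uidx]) % 4
            rows_uidx.append(uidx)
            rows_pos.append(pos)
            rows_ref.append(np.full(total, b, dtype=np.int8))

        uidx = np.concatenate(rows_uidx)
        pos = np.concatenate(rows_pos)
        ref = np.concatenate(rows_ref)

        # molecule-level base calls: first-alternate interval carries the
        # chemistry for reference-T positions of new molecules
        u = rng.random(len(uidx))
        p1 = np.where((ref == 3) & is_new[uidx], p_c, p_e)
        obs = ref.astype(np.int8).copy()
        alt = _ALT_CODES
        sel1 = u < p1
        sel2 = (~sel1) & (u < p1 + p_e)
        sel3 = (~sel1) & (~sel2) & (u < p1 + 2 * p_e)
        obs[sel1] = alt[ref[sel1], 0]
        obs[sel2] = alt[ref[sel2], 1]
        obs[sel3] = alt[ref[sel3], 2]

        if snp_keys is not None:
            key = gidx[uidx].astype(np.int64) * config.gene_length + pos
            at_snp = np.isin(key, snp_keys)
            obs[at_snp] = alt[ref[at_snp], 0]  # homozygous alternate allele

        # expand molecule positions into reads
        reads_per_umi = 1 + rng.poisson(config.reads_per_umi_poisson, n_umis)
        rep = reads_per_umi[uidx]
        ridx = np.repeat(np.arange(len(uidx)), rep)
        n_rows = len(ridx)

        u2 = rng.random(n_rows)
        err = u2 < 3 * config.seq_error_rate
        obs_read = obs[ridx].copy()
        if config.seq_error_rate > 0:
            which = np.minimum((u2 / config.seq_error_rate).astype(np.int64), 2)
            obs_read[err] = alt[obs_read[err], which[err]]

        low = rng.random(n_rows) < config.low_quality_fraction
        qual = np.where(
            low,
            rng.integers(10, 28, n_rows),
            rng.integers(28, 42, n_rows),
        ).astype(np.int16)

        barcode = _encode_dna(np.array([c]), 12)[0]
        umi_names = _encode_dna(np.arange(n_umis), 8)
        frame = pd.DataFrame(
            {
                "barcode": pd.Categorical([barcode]).repeat(n_rows),
                "umi": pd.Categorical.from_codes(uidx[ridx], categories=umi_names),
                "gene_id": pd.Categorical.from_codes(
                    gidx[uidx[ridx]], categories=gene_ids
                ),
                "pos": pos[ridx].astype(np.int32),
                "ref": pd.Categorical.from_codes(ref[ridx], categories=list("ACGT")),
                "obs": pd.Categorical.from_codes(obs_read, categories=list("ACGT")),
                "qual": qual,
            }
        )
        frames.append(frame)
        truth_frames.append(
            pd.DataFrame(
                {
                    "barcode": barcode,
                    "umi": umi_names,
                    "gene_id": gene_ids[gidx],
                    "is_new": is_new,
                    "n_reads": reads_per_umi,
                }
            )
        )

    if frames:
        # per-cell categorical columns have different category sets; union
        # them so concat keeps compact categorical dtype instead of object
        from pandas.api.types import union_categoricals

        parts = {}
        for col in ("barcode", "umi", "gene_id"):
            parts[col] = union_categoricals([f[col] for f in frames])
        reads = pd.concat(
            [f.drop(columns=["barcode", "umi", "gene_id"]) for f in frames],
            ignore_index=True,
        )
        for col in ("barcode", "umi", "gene_id"):
            reads[col] = parts[col]
        reads = reads[["barcode", "umi", "gene_id", "pos", "ref", "obs", "qual"]]
        umis = pd.concat(truth_frames, ignore_index=True)
    else:
        reads = pd.DataFrame(columns=READ_COLUMNS)
        umis = pd.DataFrame(columns=["barcode", "umi", "gene_id", "is_new", "n_reads"])
    truth = GroundTruth(
        genes=genes,
        umis=umis,
        snp_positions=tuple(config.snp_positions),
        labeling_time_t=config.labeling_time_t,
    )
    return reads, truth
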