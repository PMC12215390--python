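# Methods

This note documents the generative model behind the synthetic data, the
estimators, the numerical choices, and the limits of what the test suite
demonstrates.

## Generative model (simulate)

The simulator emits exactly what the quantification stage consumes: one row
per covered transcript position per read (`barcode, umi, gene_id, pos, ref,
obs, qual`), with no nucleotide sequences, alignment artifacts, doublets or
ambient RNA.

**Expression.** Gene relative-expression weights are log-normal
(`expression_logsd`, default 1.0, normalized to sum to one); per-cell depth
factors are log-normal (`depth_lognorm_sigma`, default 0.5); per-gene UMI
counts are Gamma-Poisson (negative binomial, dispersion
`expression_dispersion` = 0.3), the standard overdispersion model for
scRNA-seq counts. Defaults target ~2,500 UMIs per cell, matching the median
transcript recovery of typical Drop-seq-scale runs.

**Molecules.** A UMI's covered reference-T positions are
Poisson(`mean_t_content`, default 15) — a stand-in, since per-UMI T-content
distributions are not published; it must stay configurable. A/C/G content is
Poisson(15) each. UMIs with zero T content are kept: they are real,
unconvertible molecules, and dropping them would bias NTR upward. Reference
bases interleave deterministically along each transcript (period 4, phase
shifted per gene), giving every gene a 100-position T pool at the default
400-nt transcript length.

**Conversions.** Each gene has a ground-truth fraction-new tied to a
half-life via `f = 1 - 2^(-t/h)` (machine-precision consistency is a tested
invariant); each UMI is new with that probability. New molecules convert
each covered T to C with probability `p_c`; *all* molecules additionally
suffer background conversions of every substitution type at `background_pe`
(default 0.002) per alternate base. Making the background type-symmetric —
rather than T-to-C-specific — is what reproduces the control behaviour of
real data, where the eleven non-TC rates sit at the same background level as
TC when no chemistry is applied. Chemistry presets store observed per-method
T-to-C rates (8.40%, 8.11%, ... down to 2.62%) as `p_c` defaults; these are
documented approximations, since an observed raw rate conflates `p_c`, the
fraction-new and `p_e`.

**Reads.** Each UMI gets `1 + Poisson(1)` reads covering all its positions.
Read-level sequencing errors hit every position at `seq_error_rate` (default
0.001) per alternate base; per-base Phred scores place `low_quality_fraction`
(default 5%) of calls at or below the downstream cutoff of 27. Germline SNP
positions (configurable; `plant_snps` picks reference-T sites) show the
alternate base in every overlapping read, i.e. homozygous variants.

**Embryo mode.** Genes are partitioned into maternal-only / maternal-zygotic
/ zygotic-only classes (default mix 12% / 78% / 10%, the proportions typical
of vertebrate genome activation) with fraction-new uniform in per-class
ranges, default M [0, 0.02], MZ [0.05, 0.50], Z [0.85, 1.0]. The ranges are
deliberately disjoint with a gap below the 70% zygotic threshold: fixed-NTR
classification presupposes a bimodal separation between genes with and
without a dominant zygotic contribution, and these defaults encode that
biology. They are configuration, not constants.

**Randomness.** Streams are split hierarchically with seed-sequence spawn
keys (dataset truth, expression weights, one stream per cell), so enlarging
`n_cells` never perturbs earlier cells, and identical (config, seed) pairs
are byte-identical on disk. Conversion draws use a single uniform per
position with the induced-conversion branch as the first interval, so
raising `p_c` under a common seed can only increase the T-to-C rate
(monotone coupling, property-tested).

## Quantification

Reads sharing (barcode, UMI, gene) are collapsed by per-position plurality
vote; ties — including ties not involving the reference — fall to the
reference base, the conservative rule that never inflates conversions.
Conflicting reference bases raise an integrity error. The Phred filter runs
*before* consensus: a mismatch at quality ≤ 27 reverts to "no evidence",
contributing coverage but never a conversion. Content of a multi-read UMI is
the union of covered positions. A vectorized single-sort implementation is
checked against a brute-force dictionary-vote oracle.

SNP masking is control-based: positions where ≥ `snp-threshold` (default
0.5) of covering control UMIs disagree with the reference are removed from
both conversion and content counts. A minimum-coverage floor (default 5
control UMIs) is applied first: at 1–2× covered positions a single chance
background conversion clears any fraction threshold, and masking such sites
selectively removes converted positions, biasing the background-rate
estimate downward. Adequate control depth is therefore a stated requirement
of the SNP stage. UMIs whose every position is masked are retained as
all-zero rows (pipeline conservation: UMIs in = UMIs out).

Per-cell rates are pooled conversions over pooled coverage per reference
base; zero coverage serializes as missing, never 0. Cell QC presets: `zf4`
(drop mito ≥ 10%, genes < 400 or > 4000) and `embryo` (mito ≥ 10%,
UMIs < 800, genes < 400).

## Mixture estimation

`p_e` is the pooled MLE `sum(TC)/sum(T)` on the masked control. The
two-component binomial mixture is fitted by EM over `(pi, p_c)` with `p_e`
fixed; initialization `pi = 0.5`, `p_c = max(2 p_e, 0.02)`; convergence at
relative log-likelihood change < 1e-8 or 10,000 iterations. The high
iteration cap matters: weakly separated instances (`p_c` within a few-fold
of `p_e`) move along a flat likelihood ridge and need thousands of cheap
iterations; with the cap in place EM matches an exhaustive 0.001-step grid
search on every tested instance. Two guards: (i) when zero conversions are
attributed to the labeled component, `p_c` is left unchanged rather than
collapsing to zero, which yields the correct `pi -> 0` limit on
conversion-free data; (ii) if `p_c` still collapses onto `p_e`, the fit is
flagged non-identifiable, `pi` is reported missing, and estimated-new layers
are zero (no evidence of new RNA).

`p_c` is fitted once per sample — conversion efficiency is a property of
the chemistry, not of a gene — and `pi` per gene (vectorized pi-only EM),
with a global-`pi` strategy switch. Per-gene-per-cell fits are deliberately
not offered: the data are too sparse at single-cell depth. Estimated-new
entries are real-valued posterior sums, never rounded; genes under 10 total
UMIs keep raw layers but have missing estimates. Infinite half-lives and
missing rates serialize as empty fields with flag columns, never as large
numbers.

The posterior distribution under well-separated defaults (`p_c = 0.08`,
`p_e = 0.002`, n ~ 15) is strongly bimodal — zero-conversion UMIs sit below
0.4, converted UMIs above 0.9 — so posterior-calibration checks are run in
an overlapping regime (mean T content 4) where the ambiguous band is
populated.

## Classification and kinetics

NTR defaults to the literal raw labeled/total definition with a
`use_estimated` switch for the mixture-corrected layer. The correction is
not cosmetic: per-molecule detection is `1 - (1-p_c)^n` ≈ 0.71 at the
default chemistry, so a truly 95%-new zygotic gene has raw NTR ≈ 0.68 and
would *fail* a 70% threshold; recovery tests therefore classify on the
estimated layer, which is also what practitioners model before calling
zygotic genes. The band between the maternal (5%) and zygotic cutoffs is
classified MZ. Binning is rank-based with sizes differing by at most one and
ties broken by gene id. Fisher's exact test (scipy) reports the sample odds
ratio `ad/bc` (infinity serialized when `bc = 0`) and the conventional
two-sided p summing hypergeometric probabilities ≤ the observed table's; an
enumeration oracle verifies both in the tests.

Half-lives use the closed form above, with sentinels `h = inf` at `n = 0`
and `h = 0` at `n = r`; stability ranking flags the shortest and longest
10% of finite estimates. "Steady-state cell" selection is an input mask —
clustering is out of scope.

## Complexity reports

LOESS is tricube-weighted local least squares of degree 2 over the
`ceil(span N)` points nearest the query (span 0.75), with no robustness
iterations — the same family as the standard R implementation's defaults —
so it reproduces global polynomials of degree ≤ 2 exactly at interior
points (tested at 10× machine precision). nUMI uses OLS with intercept.
Cell filters before fitting: > 100 detected genes (cell line; > 200 for
embryo runs) for nGene, > 400 UMIs for nUMI. Predictions outside the
observed read range are allowed but flagged. Fold-differences round
half-up to two decimals, matching how such ratios are reported.
Pseudobulk concordance is Pearson r of `log(count + 1)` gene sums per
layer and method pair.

## Problem sizes

The shipped tests and the acceptance script run, per scenario: 50,000 UMIs
for mixture recovery (5 seeds), ≤ 200-UMI instances against the grid oracle
(20 instances), 6 × 900-UMI-per-cell controls for SNP masking (20 seeds),
a 25-cell × 1,000-gene embryo run (~60,000 UMIs) for zygotic recovery, and
12 × 50,000-count round trips for half-lives. These sizes put Monte-Carlo
error comfortably inside the asserted tolerances while keeping a full run
in minutes on one CPU.

## What passing tests do and do not show

The generator reproduces the *statistical* structure the estimators rely on
(binomial conversions, background symmetry, overdispersed counts, depth
variation, SNPs, quality noise) but not alignment errors, strand
misassignment, barcode collisions, UMI errors, intron/exon ambiguity,
chemistry-induced RNA degradation or cell-type structure. Recovery results
on simulation therefore validate the estimators against their own model
assumptions — they do not certify accuracy on real data where those
assumptions are approximate. The published per-method rates live in
`presets.py` as reference inputs; nothing in the test suite claims to
reproduce numbers that depend on the original sequencing datasets.
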