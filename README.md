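# tlabelbench

Simulation and analysis toolkit for **4sU metabolic-labeling single-cell
RNA-seq** (SLAM-seq / TimeLapse-seq-style nucleotide conversion chemistry on
droplet platforms).

## The problem

Metabolic labeling feeds cells the uridine analog 4-thiouridine (4sU), which
is incorporated into newly synthesized RNA. A chemical conversion reaction
then makes incorporated 4sU read as **C instead of T** during sequencing, so
new transcripts carry excess T-to-C substitutions while pre-existing
transcripts show only background mismatches. Downstream one can quantify RNA
synthesis and turnover per gene per cell: which transcripts are newly made
(e.g. zygotic genome activation in embryos), how fast mRNAs decay, and how
different conversion chemistries and capture platforms trade conversion
efficiency against library complexity.

This package implements the computational side of that workflow as a tested
Python library, driven by its own synthetic-data generator with known ground
truth, so no sequencing download is needed:

| module | what it does |
|---|---|
| `tlabelbench.simulate` | per-UMI read-observation generator: chemistry presets, background conversions, sequencing errors, SNPs, Phred scores, depth variation; embryo (maternal/zygotic) mode |
| `tlabelbench.quantify` | per-UMI consensus calling, Phred filter (> 27), control-based SNP masking, per-cell 12-type substitution rates, cell QC presets |
| `tlabelbench.mixture` | background rate estimation and two-component binomial-mixture EM for the fraction of new RNA; raw and estimated expression layers (AnnData) |
| `tlabelbench.mzclass` | new-to-total ratio (NTR), decile binning, maternal / maternal-zygotic / zygotic classification, threshold sweeps, Fisher overlap tests |
| `tlabelbench.kinetics` | closed-form RNA half-lives from one labeling pulse; stability-decile ranking |
| `tlabelbench.complexity` | depth-normalized library-complexity prediction (LOESS / OLS), per-method benchmark tables, fold-differences, pseudobulk concordance |

## The model

Each captured mRNA molecule (UMI) covers `n` reference-T positions of which
`k` read as C. Old molecules convert at a background rate `p_e` (estimated
from an untreated control after SNP masking); new molecules at the induced
rate `p_c`. Per gene (or globally), the count likelihood is a two-component
binomial mixture

```
L(pi, p_c) = prod_i [ (1 - pi) Binom(k_i; n_i, p_e) + pi Binom(k_i; n_i, p_c) ]
```

maximized by EM over `(pi, p_c)` with `p_e` fixed. The per-UMI posterior
probability of being new converts raw labeled/unlabeled counts (labeled =
at least one T-to-C) into *estimated* new/old layers, recovering new
molecules that happened to show zero conversions.

Two closed forms anchor the downstream biology. The new-to-total RNA ratio
`NTR = labeled / total` per gene classifies genes as zygotic (`NTR >
70–85%`), maternal (`NTR < 5%`) or maternal-zygotic (between). And a single
labeling pulse of `t` hours ties the labeled fraction `n/r` to the RNA
half-life `h`:

```
h = ln(2) * t / ( -ln(1 - n/r) )
```

## Worked example

```bash
python examples/02_estimate_new_rna.py
```

prints (50,000 simulated UMIs, truth `pi = 0.4`, `p_c = 0.08`, `p_e = 0.002`):

```
truth:     pi = 0.400, p_c = 0.0800
estimated: pi = 0.402, p_c = 0.0805 (31 EM iterations)
raw labeled fraction:       0.299
estimated new fraction:     0.402
```

The raw labeled fraction (UMIs with ≥ 1 conversion) underestimates the true
fraction-new by a third — at `p_c = 0.08` and ~15 covered Ts per molecule,
29% of new molecules show no conversion at all — while the mixture-based
estimate lands on the simulated truth. The other scripts in `examples/`
walk through quantification (`01`), maternal/zygotic classification (`03`),
half-life estimation (`04`) and chemistry benchmarking (`05`), each printing
a few numbers and what they mean.

A thin CLI mirrors the pipeline stages for shell use
(`tlabelbench simulate | quantify | estimate | classify | halflife | report`);
every stage is byte-deterministic given a seed and config.

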