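"""Library-complexity prediction and cross-method benchmark summaries.

Chemical conversion degrades reverse transcription, so methods are compared
at a *normalized* sequencing depth: per-cell detected genes (nGene) are
regressed on aligned reads per cell with LOESS (tricube-weighted local
quadratic, span 0.75, no robustness iterations) and per-cell UMIs with
ordinary least squares, then both are evaluated at a fixed query depth
(10,000 reads for cell-line runs, 4,000 for embryo runs). The module also
aggregates per-method metric rows (mean/median T-to-C rate, labeled-UMI
fraction, predicted complexity), computes fold-differences between methods,
and pairwise Pearson concordance of log-transformed pseudobulk expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DepthFit",
    "MethodRun",
    "fit_depth_curve",
    "loess_predict",
    "method_summary",
    "fold_difference",
    "pseudobulk_concordance",
    "QUERY_DEPTH_CELL_LINE",
    "QUERY_DEPTH_EMBRYO",
]

QUERY_DEPTH_CELL_LINE = 10_000
QUERY_DEPTH_EMBRYO = 4_000
DEFAULT_SPAN = 0.75
DEFAULT_DEGREE = 2


@dataclass(frozen=True)
class DepthFit:
    """Prediction of a per-cell response at a fixed sequencing depth."""

    response: str
    model: str  # "loess" or "linear"
    span: float
    degree: int
    query_depth: float
    prediction: float
    extrapolated: bool
    n_cells: int


@dataclass
class MethodRun:
    """One method's processed outputs, as consumed by the report stage.

    ``profiles`` is the per-cell rate table from ``quantify.cell_rates``;
    ``reads_per_cell`` a Series of aligned reads indexed by barcode.
    """

    name: str
    profiles: pd.DataFrame
    reads_per_cell: pd.Series


def loess_predict(
    x,
    y,
    x0: float,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
) -> float:
    """Tricube-weighted local polynomial regression evaluated at ``x0``.

    The window holds the ceil(span * N) points nearest to ``x0``; weights
    are tricube in |x - x0| scaled by the window radius, and a plain
    (non-robust) weighted least-squares polynomial of the given degree is
    fitted. A local quadratic reproduces any global degree-<=2 polynomial
    exactly at interior points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    n = len(x)
    q = max(int(np.ceil(span * n)), degree + 2)
    if n < q or n < degree + 2:
        raise ValueError("too few points for the requested span/degree")
    dist = np.abs(x - x0)
    order = np.argsort(dist, kind="stable")[:q]
    dmax = dist[order].max()
    if dmax == 0:
        raise ValueError("degenerate window: all reads identical")
    w = (1 - (dist[order] / dmax) ** 3) ** 3
    pos = w > 0
    if pos.sum() < degree + 1:
        raise ValueError("not enough points with positive weight")
    xs, ys, ws = x[order][pos], y[order][pos], w[pos]
    design = np.vander(xs - x0, degree + 1, increasing=True)
    sw = np.sqrt(ws)
    beta, *_ = np.linalg.lstsq(design * sw[:, None], ys * sw, rcond=None)
    return float(beta[0])


def fit_depth_curve(
    cells: pd.DataFrame,
    response: str,
    query_depth: float,
    model: str = "loess",
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    min_response: float | None = None,
) -> DepthFit:
    """Fit response ~ reads over cells and predict at ``query_depth``.

    ``cells`` needs columns ``reads`` and ``response``. ``min_response``
    applies the pre-fit cell filter (e.g. > 100 detected genes for
    cell-line nGene fits, > 400 UMIs for nUMI fits). Predictions outside
    the observed read range are allowed but flagged ``extrapolated``.
    """
    if model not in {"loess", "linear"}:
        raise ValueError("model must be 'loess' or 'linear'")
    df = cells[["reads", response]].dropna()
    if min_response is not None:
        df = df[df[response] > min_response]
    x = df["reads"].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    if len(x) < 10:
        raise ValueError(f"only {len(x)} cells after filtering; need >= 10")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: constant reads per cell")
    if model == "loess":
        pred = loess_predict(x, y, query_depth, span=span, degree=degree)
    else:
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        pred = float(ols.predict([1.0, query_depth])[0])
    extrapolated = not (x.min() <= query_depth <= x.max())
    return DepthFit(
        response=response,
        model=model,
        span=span if model == "loess" else float("nan"),
        degree=degree if model == "loess" else 1,
        query_depth=float(query_depth),
        prediction=pred,
        extrapolated=extrapolated,
        n_cells=len(x),
    )


def method_summary(
    runs: list[MethodRun],
    query_depth: float = QUERY_DEPTH_CELL_LINE,
    min_genes_filter: float = 100,
    min_umis_filter: float = 400,
) -> pd.DataFrame:
    """One benchmark row per method.

    Columns: mean/median T-to-C rate, mean labeled-UMI fraction, predicted
    nGene (LOESS) and nUMI (linear) at ``query_depth``, and cell count.
    Deterministic given inputs; an empty cell set is an error, not a row.
    """
    if not runs:
        raise ValueError("need at least one method run")
    rows = []
    for run in runs:
        prof = run.profiles
        if prof.empty:
            raise ValueError(f"method {run.name!r} has no cells")
        cells = pd.DataFrame(
            {
                "reads": run.reads_per_cell.reindex(prof.index),
                "nGene": prof["n_genes"],
                "nUMI": prof["n_umis"],
            }
        )
        ngene = fit_depth_curve(
            cells, "nGene", query_depth, model="loess", min_response=min_genes_filter
        )
        numi = fit_depth_curve(
            cells, "nUMI", query_depth, model="linear", min_response=min_umis_filter
        )
        rows.append(
            {
                "method": run.name,
                "mean_tc_rate": float(prof["TC"].mean()),
                "median_tc_rate": float(prof["TC"].median()),
                "mean_labeled_umi_fraction": float(
                    prof["labeled_umi_fraction"].mean()
                ),
                "predicted_ngene": ngene.prediction,
                "predicted_numi": numi.prediction,
                "query_depth": float(query_depth),
                "n_cells": len(prof),
            }
        )
    return pd.DataFrame(rows)


def fold_difference(mean_a: float, mean_b: float) -> float:
    """Ratio of two group means, rounded half-up to two decimals."""
    if mean_b == 0:
        raise ValueError("zero denominator in fold difference")
    ratio = Decimal(repr(float(mean_a) / float(mean_b)))
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def pseudobulk_concordance(pseudobulk: dict) -> pd.DataFrame:
    """Pairwise Pearson r of log-transformed pseudobulk expression.

    ``pseudobulk`` maps method name -> {layer name -> Series of gene-summed
    counts indexed by gene}. For every method pair and every shared layer,
    the correlation of log(count + 1) over the genes present in both is
    reported. Fewer than 3 shared genes is an error.
    """
    methods = sorted(pseudobulk)
    if len(methods) < 2:
        raise ValueError("need at least two methods")
    rows = []
    for i, ma in enumerate(methods):
        for mb in methods[i + 1 :]:
            shared_layers = sorted(set(pseudobulk[ma]) & set(pseudobulk[mb]))
            for layer in shared_layers:
                sa = pseudobulk[ma][layer]
                sb = pseudobulk[mb][layer]
                genes = sa.index.intersection(sb.index)
                if len(genes) < 3:
                    raise ValueError(
                        f"fewer than 3 shared genes between {ma} and {mb}"
                    )
                va = np.log1p(sa.loc[genes].to_numpy(dtype=float))
                vb = np.log1p(sb.loc[genes].to_numpy(dtype=float))
                rows.append(
                    {
                        "method_a": ma,
                        "method_b": mb,
                        "layer": layer,
                        "pearson_r": float(np.corrcoef(va, vb)[0, 1]),
                        "n_genes": len(genes),
                    }
                )
    return pd.DataFrame(rows)
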