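"""Two-component binomial mixture for the fraction of newly synthesized RNA.

Each UMI contributes a pair (k, n): n covered reference-T positions, k of
them read as C after consensus and filtering. Old molecules convert at the
background rate p_e (estimated from an untreated control), new molecules at
the chemistry-induced rate p_c >> p_e. The per-UMI likelihood is

    (1 - pi) * Binomial(k; n, p_e) + pi * Binomial(k; n, p_c)

and EM maximizes it over (pi, p_c) with p_e held fixed. The per-UMI
posterior probability of being new turns raw labeled/unlabeled counts into
*estimated* new/old expression layers: summing posteriors per gene and cell
recovers new molecules that happened to show no conversion (k = 0), the main
bias of raw >=1-T-to-C labeling at realistic conversion rates.

UMIs with n = 0 carry no information and are excluded from the likelihood
but carried through as unlabeled (posterior 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

__all__ = [
    "MixtureFit",
    "NonIdentifiableError",
    "estimate_background",
    "fit_binomial_mixture",
    "posterior_new",
    "fit_pi_per_gene",
    "estimate_layers",
]

DEFAULT_TOL = 1e-8
# weakly separated instances (p_c within a few-fold of p_e) progress along a
# flat ridge in (pi, p_c); a low iteration cap stops them before convergence
DEFAULT_MAX_ITER = 10_000
_PC_COLLAPSE_TOL = 1e-6


class NonIdentifiableError(RuntimeError):
    """The labeled component is indistinguishable from background."""


@dataclass
class MixtureFit:
    """Result of one EM fit.

    ``pi`` is NaN when the fit is non-identifiable (p_c collapsed onto p_e).
    ``posterior`` is aligned with the input UMIs; n = 0 UMIs get 0.
    """

    p_e: float
    p_c: float
    pi: float
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    posterior: np.ndarray
    identifiable: bool = True


def estimate_background(control_summaries: pd.DataFrame) -> float:
    """Maximum-likelihood background T-to-C rate from a control sample.

    Simply total conversions over total coverage: sum(TC) / sum(T) across
    the control's (SNP-masked, quality-filtered) UMI summaries.
    """
    total_t = float(control_summaries["T"].sum())
    if total_t <= 0:
        raise ValueError("control has zero reference-T coverage")
    return float(control_summaries["TC"].sum()) / total_t


def _validate_kn(k: np.ndarray, n: np.ndarray) -> None:
    if np.any(n < 0) or np.any(k < 0) or np.any(k > n):
        raise ValueError("need 0 <= k <= n for every UMI")


def posterior_new(k, n, p_e: float, p_c: float, pi: float):
    """P(new | k, n) by Bayes rule inside the mixture."""
    for name, v in (("p_e", p_e), ("p_c", p_c), ("pi", pi)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    k_arr = np.asarray(k)
    n_arr = np.asarray(n)
    _validate_kn(k_arr, n_arr)
    a = binom.pmf(k_arr, n_arr, p_e)
    b = binom.pmf(k_arr, n_arr, p_c)
    denom = pi * b + (1 - pi) * a
    if np.any(denom <= 0):
        raise ValueError("both mixture densities are zero for some UMI")
    post = pi * b / denom
    if np.isscalar(k):
        return float(post)
    return post


def fit_binomial_mixture(
    k,
    n,
    p_e: float,
    *,
    init_pi: float = 0.5,
    init_pc: float | None = None,
    fixed_pc: float | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> MixtureFit:
    """EM for (pi, p_c) with the background rate fixed.

    Initialization pi = 0.5 and p_c = max(2 p_e, 0.02) is robust on sparse
    conversion counts; convergence is declared when the relative
    log-likelihood improvement drops below ``tol``. The log-likelihood trace
    is non-decreasing (EM guarantee). When the fitted p_c collapses onto
    p_e, the mixture weight is unidentifiable: ``pi`` is reported as NaN and
    ``identifiable=False``.
    """
    k_all = np.asarray(k, dtype=np.int64)
    n_all = np.asarray(n, dtype=np.int64)
    _validate_kn(k_all, n_all)
    informative = n_all > 0
    if not informative.any():
        raise ValueError("no UMI with n > 0: mixture cannot be fitted")
    ki = k_all[informative]
    ni = n_all[informative]

    eps = 1e-12
    pi = float(np.clip(init_pi, eps, 1 - eps))
    if fixed_pc is not None:
        pc = float(fixed_pc)
    else:
        pc = init_pc if init_pc is not None else max(2 * p_e, 0.02)
    pc = float(np.clip(pc, max(p_e, eps), 1 - eps))

    la = binom.logpmf(ki, ni, p_e)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lb = binom.logpmf(ki, ni, pc)
        log_mix = logsumexp(
            np.stack([np.log1p(-pi) + la, np.log(pi) + lb]), axis=0
        )
        ll = float(log_mix.sum())
        resp = np.exp(np.log(pi) + lb - log_mix)
        trace.append(ll)
        pi = float(np.clip(resp.mean(), eps, 1 - eps))
        if fixed_pc is None:
            denom = float((resp * ni).sum())
            num = float((resp * ki).sum())
            # with no conversions attributed to the labeled component there
            # is no information about p_c; keep it rather than collapsing
            if denom > 0 and num > 0:
                pc = float(np.clip(num / denom, max(p_e, eps), 1 - eps))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * (abs(trace[-2]) + 1):
            converged = True
            break

    identifiable = fixed_pc is not None or (pc - p_e) > _PC_COLLAPSE_TOL
    posterior = np.zeros(len(k_all))
    if identifiable:
        posterior[informative] = posterior_new(ki, ni, p_e, pc, pi)
    return MixtureFit(
        p_e=float(p_e),
        p_c=pc,
        pi=pi if identifiable else float("nan"),
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
        posterior=posterior,
        identifiable=identifiable,
    )


def fit_pi_per_gene(
    k,
    n,
    gene_index,
    p_e: float,
    p_c: float,
    n_genes: int,
    *,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
):
    """Vectorized pi-only EM, one mixture weight per gene with shared rates.

    Returns (pi array of length n_genes, per-UMI posterior array). Genes
    with no informative UMI get pi = NaN and posterior 0.
    """
    k_all = np.asarray(k, dtype=np.int64)
    n_all = np.asarray(n, dtype=np.int64)
    g_all = np.asarray(gene_index, dtype=np.int64)
    _validate_kn(k_all, n_all)
    informative = n_all > 0
    ki, ni, gi = k_all[informative], n_all[informative], g_all[informative]

    eps = 1e-12
    counts = np.bincount(gi, minlength=n_genes).astype(float)
    has_data = counts > 0
    pi = np.full(n_genes, 0.5)

    la = binom.logpmf(ki, ni, p_e)
    lb = binom.logpmf(ki, ni, p_c)
    resp = np.zeros(len(ki))
    for _ in range(max_iter):
        lp = np.log(np.clip(pi[gi], eps, 1.0))
        lq = np.log(np.clip(1 - pi[gi], eps, 1.0))
        log_mix = np.logaddexp(lq + la, lp + lb)
        resp = np.exp(lp + lb - log_mix)
        new_pi = pi.copy()
        sums = np.bincount(gi, weights=resp, minlength=n_genes)
        new_pi[has_data] = np.clip(sums[has_data] / counts[has_data], eps, 1 - eps)
        if np.max(np.abs(new_pi - pi)) <= tol:
            pi = new_pi
            break
        pi = new_pi
    pi[~has_data] = np.nan

    posterior = np.zeros(len(k_all))
    posterior[informative] = resp
    return pi, posterior


def estimate_layers(
    summaries: pd.DataFrame,
    p_e: float,
    strategy: str = "per_gene",
    min_gene_umis: int = 10,
) -> ad.AnnData:
    """Build raw and model-estimated gene expression layers.

    p_c is fitted once on the pooled UMIs (the conversion chemistry is a
    property of the sample, not of a gene); the mixture weight is then
    fitted per gene (``strategy="per_gene"``, default) or shared globally
    (``strategy="global"``). Per-gene-per-cell fits are too sparse to be
    useful at single-cell depth.

    Returns an AnnData (cells x genes) with layers ``total``, ``labeled``
    (raw: >=1 T-to-C), ``unlabeled``, ``estimated_new`` (posterior sums,
    real-valued) and ``estimated_old``. Genes with fewer than
    ``min_gene_umis`` total UMIs keep their raw layers but have NaN
    estimated layers. Entrywise, labeled + unlabeled == total and
    estimated_new + estimated_old == total wherever defined.
    """
    if strategy not in {"per_gene", "global"}:
        raise ValueError("strategy must be 'per_gene' or 'global'")
    if summaries.empty:
        raise ValueError("no UMI summaries")
    k = summaries["TC"].to_numpy(dtype=np.int64)
    n = summaries["T"].to_numpy(dtype=np.int64)
    b_codes, b_cats = pd.factorize(summaries["barcode"], sort=True)
    g_codes, g_cats = pd.factorize(summaries["gene_id"], sort=True)
    n_cells, n_genes = len(b_cats), len(g_cats)

    global_fit = fit_binomial_mixture(k, n, p_e)
    p_c = global_fit.p_c
    if not global_fit.identifiable:
        # no separable labeled component (e.g. chemistry off): no evidence of
        # new RNA, so the estimated-new layer is all zero and pi is missing
        pi_gene = np.full(n_genes, np.nan)
        posterior = np.zeros(len(k))
    elif strategy == "per_gene":
        pi_gene, posterior = fit_pi_per_gene(k, n, g_codes, p_e, p_c, n_genes)
    else:
        pi_gene = np.full(n_genes, global_fit.pi)
        posterior = global_fit.posterior

    total = np.zeros((n_cells, n_genes))
    labeled = np.zeros((n_cells, n_genes))
    est_new = np.zeros((n_cells, n_genes))
    np.add.at(total, (b_codes, g_codes), 1.0)
    np.add.at(labeled, (b_codes, g_codes), (k > 0).astype(float))
    np.add.at(est_new, (b_codes, g_codes), posterior)

    gene_umis = total.sum(axis=0)
    supported = gene_umis >= min_gene_umis
    est_new[:, ~supported] = np.nan

    adata = ad.AnnData(
        X=total.copy(),
        obs=pd.DataFrame(index=pd.Index(np.asarray(b_cats), name="barcode")),
        var=pd.DataFrame(
            {
                "n_umis": gene_umis,
                "pi": pi_gene,
                "estimated_supported": supported,
            },
            index=pd.Index(np.asarray(g_cats), name="gene_id"),
        ),
    )
    adata.layers["total"] = total
    adata.layers["labeled"] = labeled
    adata.layers["unlabeled"] = total - labeled
    adata.layers["estimated_new"] = est_new
    adata.layers["estimated_old"] = total - est_new
    adata.uns["fit"] = {
        "p_e": float(p_e),
        "p_c": float(p_c),
        "identifiable": bool(global_fit.identifiable),
        "pi_global": float(global_fit.pi),
        "strategy": strategy,
        "min_gene_umis": int(min_gene_umis),
        "converged": bool(global_fit.converged),
        "n_iter": int(global_fit.n_iter),
    }
    return adata
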