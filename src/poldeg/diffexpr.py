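"""Minimal negative-binomial two-group Wald test with explicit size factors.

The model is NB with mean mu and variance mu + alpha*mu^2.  Per-gene
normalized counts q_gj = N_gj / s_j are compared between two groups;
the Wald statistic is the log2 fold change of (pseudocounted) group
means over a delta-method standard error.  Dispersion alpha is
estimated by method of moments and, by default, moderated toward the
experiment-wide value — with thousands of genes the shared component
is estimated almost exactly, which keeps the z-test calibrated at
small replicate numbers.

Deliberate divergences from the reference R workflow: no fold-change
shrinkage, no independent filtering, no outlier handling.  The
thresholding logic (2-fold, FDR < 0.05) is what downstream stages
consume, not bit-identical statistics.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import CountMatrix, PoldegError, SizeFactors

DISPERSION_FLOOR = 1e-8
DISPERSION_CEIL = 50.0
MEAN_PSEUDOCOUNT = 0.5


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, ties preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise PoldegError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _within_group_variance(q: np.ndarray, groups_idx: list) -> np.ndarray:
    n_total = sum(len(ix) for ix in groups_idx)
    df = n_total - len(groups_idx)
    ss = np.zeros(q.shape[0])
    for ix in groups_idx:
        sub = q[:, ix]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return ss / df


def _mom_dispersion(q: np.ndarray, groups_idx: list) -> Tuple[np.ndarray, float]:
    """Method-of-moments dispersion from within-group residuals.

    The model treats normalized counts as NB with variance
    mu + alpha*mu^2 (inference therefore depends on the data only
    through normalized counts, which makes results exactly invariant
    to rescaling a sample's counts and size factor together).  Per
    gene, alpha solves var_within = mu + alpha*mu^2, where var_within
    pools unbiased residual variance across both groups.  The common
    dispersion aggregates the same moment identity across expressed
    genes — sum(var - mu) / sum(mu^2) — which avoids the downward
    bias a median of noisy per-gene estimates has at few replicates.
    """
    var_within = _within_group_variance(q, groups_idx)
    mu = q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_within - mu) / np.square(mu)
    alpha[~np.isfinite(alpha)] = DISPERSION_FLOOR
    alpha = np.clip(alpha, DISPERSION_FLOOR, DISPERSION_CEIL)
    expressed = mu > 1.0
    if not expressed.any():
        return alpha, DISPERSION_FLOOR
    m, v = mu[expressed], var_within[expressed]
    # unweighted moment ratio as a starting value, then one GLS step:
    # Var(var_g) ~ 2 sigma_g^4 / df, so weights 1/(mu(1+alpha*mu))^2
    # give every well-expressed gene equal influence instead of letting
    # the few largest genes dominate through the mu^2 regressor.
    alpha_common = max(float(np.sum(v - m) / np.sum(np.square(m))), DISPERSION_FLOOR)
    for _ in range(2):
        w = 1.0 / np.square(1.0 + alpha_common * m)
        alpha_common = float(np.sum(w * (v - m)) / np.sum(w * np.square(m)))
        alpha_common = float(np.clip(alpha_common, DISPERSION_FLOOR, DISPERSION_CEIL))
    return alpha, alpha_common


def nb_wald_test(
    cm: CountMatrix,
    groups: pd.Series,
    size_factors: SizeFactors,
    dispersion_mode: str = "moderated",
    prior_df: float = 50.0,
    target_only: bool = True,
) -> pd.DataFrame:
    """Two-group NB Wald test (treated vs control).

    ``groups`` maps sample_id to 'control'/'treated'.  Returns a frame
    indexed by gene_id with columns baseMeanC, baseMeanT, log2FC, SE,
    pvalue, FDR.

    ``dispersion_mode``: 'per_gene' (raw MoM), 'common' (one pooled
    value for all genes) or 'moderated' (MoM shrunk toward the common
    value with ``prior_df`` pseudo-replicates of weight).
    """
    if dispersion_mode not in ("per_gene", "common", "moderated"):
        raise PoldegError(f"unknown dispersion mode {dispersion_mode!r}")
    labels = set(groups.unique())
    if labels != {"control", "treated"}:
        raise PoldegError(f"groups must be 'control'/'treated', got {sorted(labels)}")
    sub = cm.subset_species("target") if target_only else cm
    samples = [s for s in sub.sample_ids if s in groups.index]
    if set(samples) != set(groups.index):
        raise PoldegError("group labels must cover exactly the matrix samples")
    ctrl = [s for s in samples if groups[s] == "control"]
    trt = [s for s in samples if groups[s] == "treated"]
    if len(ctrl) < 2 or len(trt) < 2:
        raise PoldegError(
            "need >= 2 replicates per group (variance unidentifiable otherwise)"
        )
    counts = sub.counts[ctrl + trt].to_numpy(dtype=float)
    s = np.array([size_factors[x] for x in ctrl + trt])
    if counts.sum() == 0:
        raise PoldegError("count matrix is all zero")
    for name, ix in (("control", range(len(ctrl))), ("treated", range(len(ctrl), len(ctrl) + len(trt)))):
        if counts[:, list(ix)].sum() == 0:
            raise PoldegError(f"{name} group has zero counts for every gene")

    q = counts / s[None, :]
    ix_c = list(range(len(ctrl)))
    ix_t = list(range(len(ctrl), len(ctrl) + len(trt)))
    mu_c = q[:, ix_c].mean(axis=1)
    mu_t = q[:, ix_t].mean(axis=1)

    alpha_gene, alpha_common = _mom_dispersion(q, [ix_c, ix_t])
    if dispersion_mode == "per_gene":
        alpha = alpha_gene
    elif dispersion_mode == "common":
        alpha = np.full_like(alpha_gene, alpha_common)
    else:
        df_res = len(samples) - 2
        w = df_res / (df_res + prior_df)
        alpha = np.clip(
            w * alpha_gene + (1 - w) * alpha_common, DISPERSION_FLOOR, DISPERSION_CEIL
        )

    pc = MEAN_PSEUDOCOUNT
    log2fc = np.log2(mu_t + pc) - np.log2(mu_c + pc)

    def group_var(mu: np.ndarray, ix: list) -> np.ndarray:
        return (mu + alpha * np.square(mu)) / len(ix)

    ln2sq = np.log(2.0) ** 2
    var_lfc = group_var(mu_t, ix_t) / (np.square(mu_t + pc) * ln2sq) + group_var(
        mu_c, ix_c
    ) / (np.square(mu_c + pc) * ln2sq)
    se = np.sqrt(var_lfc)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval = np.clip(pval, 0.0, 1.0)
    fdr = bh_adjust(pval)

    return pd.DataFrame(
        {
            "baseMeanC": mu_c,
            "baseMeanT": mu_t,
            "log2FC": log2fc,
            "SE": se,
            "pvalue": pval,
            "FDR": fdr,
        },
        index=sub.counts.index,
    )


def call_de(
    results: pd.DataFrame,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    min_expr: Optional[float] = None,
    expr: Optional[pd.Series] = None,
) -> pd.Series:
    """Classify genes as up / down / ns / low_expr.

    A gene is 'up' iff log2FC >= lfc_threshold and FDR < fdr_threshold
    (mirrored for 'down').  When ``min_expr`` is given, genes whose
    expression summary (``expr``, e.g. max RPKM across samples) fails
    the threshold are labelled 'low_expr' and excluded from up/down.
    """
    for col in ("log2FC", "FDR"):
        if col not in results.columns:
            raise PoldegError(f"results missing column {col!r}")
    status = pd.Series("ns", index=results.index, dtype=object)
    sig = results["FDR"] < fdr_threshold
    status[sig & (results["log2FC"] >= lfc_threshold)] = "up"
    status[sig & (results["log2FC"] <= -lfc_threshold)] = "down"
    if min_expr is not None:
        if expr is None:
            raise PoldegError("min_expr given without an expression summary")
        low = expr.reindex(results.index).fillna(0.0) <= min_expr
        status[low] = "low_expr"
    status.name = "status"
    return status
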