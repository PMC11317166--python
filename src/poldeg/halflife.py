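"""4sU pulse-chase processing: scaling, filtering, first-order decay fits.

After the metabolic label is washed out, the labelled fraction of a
transcript decays as A * exp(-k t); the half-life is ln2 / k.  Before
fitting, samples are put on a common scale by the geometric mean of a
designated stable-transcript set (transcripts long-lived enough to be
constant over the chase), which cancels per-sample technical scale
distortions that would otherwise bias every fitted k.

Fits are log-linear least squares: log(value) = log(A) - k t.  Zeros
are dropped before the log (not pseudocounted), replicate values at a
timepoint are averaged on the log scale, and a fitted k <= 0 is
reported as 'nondecaying' with infinite half-life rather than an
error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import ExpressionMatrix, PoldegError, SizeFactors

LN2 = math.log(2.0)
K_EPS = 1e-10  # slopes below this (1/h) are numerically zero: nondecaying


@dataclass
class DecayFit:
    """Per-gene first-order decay fit."""

    gene_id: str
    k: float  # 1/h; 0 for nondecaying
    halflife_h: float  # ln2/k, may be inf
    intercept: float  # fitted level at t = 0 (natural scale)
    rmse_log: float
    n_timepoints: int
    n_dropped_zeros: int
    flag: str  # ok | nondecaying | insufficient_points


def stable_gene_scaling(
    em: ExpressionMatrix,
    stable_ids: Sequence[str],
    sample_sheet: pd.DataFrame,
) -> Tuple[pd.Series, ExpressionMatrix]:
    """Between-sample scale factors from stable transcripts.

    c_j = geomean over stable genes of TPM_gj / geomean of TPM at the
    reference (timepoint 0) samples; rescaled value = TPM_gj / c_j.
    Stable genes with a zero anywhere are dropped with a warning
    (their geometric mean is undefined); if all are dropped this is an
    error.  c = 1 at the reference by construction.
    """
    stable_ids = list(stable_ids)
    if not stable_ids:
        raise PoldegError("stable gene set is empty")
    missing = [g for g in stable_ids if g not in em.values.index]
    if missing:
        raise PoldegError(f"stable genes absent from matrix: {missing}")
    ref_samples = sample_sheet.index[sample_sheet["timepoint_h"] == 0]
    if len(ref_samples) == 0:
        raise PoldegError("no timepoint-0 reference sample in sheet")
    sub = em.values.loc[stable_ids]
    usable = (sub > 0).all(axis=1)
    if not usable.all():
        warnings.warn(
            f"dropping stable genes with zeros: {list(sub.index[~usable])}"
        )
    sub = sub.loc[usable]
    if sub.empty:
        raise PoldegError("no stable gene has positive expression in every sample")
    log_sub = np.log(sub.to_numpy())
    ref_log = log_sub[:, [em.values.columns.get_loc(s) for s in ref_samples]].mean(axis=1)
    c = pd.Series(
        np.exp((log_sub - ref_log[:, None]).mean(axis=0)), index=em.values.columns
    )
    rescaled = ExpressionMatrix(values=em.values.div(c, axis=1), unit=em.unit)
    return c, rescaled


def filter_expressed(
    em: ExpressionMatrix,
    sample_sheet: pd.DataFrame,
    threshold: float = 0.2,
    condition: Optional[str] = None,
) -> pd.Index:
    """Genes whose mean TPM at the (untreated) 0 h samples exceeds ``threshold``.

    The comparison is strictly greater-than: a gene sitting exactly at
    the threshold is dropped.
    """
    sheet = sample_sheet
    if condition is not None:
        sheet = sheet[sheet["condition"] == condition]
    ref = sheet.index[sheet["timepoint_h"] == 0]
    if len(ref) == 0:
        raise PoldegError("no 0 h sample available for the expression filter")
    baseline = em.values[list(ref)].mean(axis=1)
    return em.values.index[baseline > threshold]


def fit_decay(
    times: Sequence[float],
    values: Sequence[float],
    min_points: int = 3,
    gene_id: str = "",
    average_replicates: bool = True,
) -> DecayFit:
    """Log-linear least-squares fit of first-order decay.

    Non-positive values are dropped (count recorded); replicate
    observations at the same timepoint are averaged on the log scale
    before fitting so each timepoint carries equal leverage.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if np.any(t < 0):
        raise PoldegError("timepoints must be >= 0")
    pos = v > 0
    n_dropped = int((~pos).sum())
    t, v = t[pos], v[pos]
    logv = np.log(v)
    if average_replicates and len(t):
        frame = pd.DataFrame({"t": t, "logv": logv}).groupby("t")["logv"].mean()
        t, logv = frame.index.to_numpy(), frame.to_numpy()
    if len(t) < min_points or len(np.unique(t)) < 2:
        return DecayFit(gene_id, math.nan, math.nan, math.nan, math.nan,
                        len(t), n_dropped, "insufficient_points")
    slope, loga = np.polyfit(t, logv, 1)
    k = -slope
    resid = logv - (loga + slope * t)
    rmse = float(np.sqrt(np.mean(resid**2)))
    if k <= K_EPS:
        return DecayFit(gene_id, 0.0, math.inf, float(np.exp(loga)), rmse,
                        len(t), n_dropped, "nondecaying")
    return DecayFit(gene_id, float(k), LN2 / k, float(np.exp(loga)), rmse,
                    len(t), n_dropped, "ok")


def fits_to_frame(fits: Sequence[DecayFit]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "k_per_h": [f.k for f in fits],
            "halflife_h": [f.halflife_h for f in fits],
            "intercept": [f.intercept for f in fits],
            "rmse_log": [f.rmse_log for f in fits],
            "n_timepoints": [f.n_timepoints for f in fits],
            "n_dropped_zeros": [f.n_dropped_zeros for f in fits],
            "flag": [f.flag for f in fits],
        },
        index=pd.Index([f.gene_id for f in fits], name="gene_id"),
    )
    return df


def halflife_table(
    matrices: Dict[str, Tuple[ExpressionMatrix, pd.DataFrame]],
    stable_ids: Sequence[str],
    size_factors: Optional[Dict[str, SizeFactors]] = None,
    tpm_threshold: float = 0.2,
    reference_condition: Optional[str] = None,
    min_points: int = 3,
) -> Tuple[Dict[str, pd.DataFrame], Optional[pd.DataFrame]]:
    """Full pulse-chase pipeline per condition, plus a paired comparison.

    Stages per condition: optional spike-in normalization (divide each
    sample by its size factor), stable-transcript scaling, the TPM
    filter evaluated at the reference condition's 0 h samples, then a
    decay fit per kept gene.  Genes failing the filter appear with
    flag 'filtered_low_expr'.  When there are exactly two conditions,
    the second return value pairs them as
    log2(halflife_other / halflife_reference).
    """
    if not matrices:
        raise PoldegError("no conditions supplied")
    conditions = list(matrices)
    ref_cond = reference_condition or conditions[0]
    if ref_cond not in matrices:
        raise PoldegError(f"reference condition {ref_cond!r} not among {conditions}")

    processed: Dict[str, Tuple[ExpressionMatrix, pd.DataFrame]] = {}
    for cond, (em, sheet) in matrices.items():
        if size_factors is not None and cond in size_factors:
            sf = size_factors[cond]
            em = ExpressionMatrix(
                values=em.values.div(
                    pd.Series({s: sf[s] for s in em.values.columns}), axis=1
                ),
                unit=em.unit,
            )
        _, em = stable_gene_scaling(em, stable_ids, sheet)
        processed[cond] = (em, sheet)

    ref_em, ref_sheet = processed[ref_cond]
    kept = filter_expressed(ref_em, ref_sheet, threshold=tpm_threshold)

    tables: Dict[str, pd.DataFrame] = {}
    for cond, (em, sheet) in processed.items():
        times = sheet["timepoint_h"].to_numpy(dtype=float)
        fits: List[DecayFit] = []
        for gid in em.values.index:
            if gid not in kept:
                fits.append(
                    DecayFit(gid, math.nan, math.nan, math.nan, math.nan, 0, 0,
                             "filtered_low_expr")
                )
                continue
            fits.append(
                fit_decay(times, em.values.loc[gid].to_numpy(), min_points, gene_id=gid)
            )
        tables[cond] = fits_to_frame(fits)

    delta = None
    others = [c for c in conditions if c != ref_cond]
    if len(others) == 1:
        a, b = tables[ref_cond], tables[others[0]]
        common = a.index.intersection(b.index)
        ok = (a.loc[common, "flag"] == "ok") & (b.loc[common, "flag"] == "ok")
        delta = pd.DataFrame(
            {
                "halflife_ref_h": a.loc[common, "halflife_h"],
                "halflife_other_h": b.loc[common, "halflife_h"],
                "delta_log2_halflife": np.where(
                    ok,
                    np.log2(b.loc[common, "halflife_h"] / a.loc[common, "halflife_h"]),
                    np.nan,
                ),
            },
            index=common,
        )
    return tables, delta
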