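"""Spike-in normalization for tracks and count matrices, RPKM/TPM, ratio tracks.

The experimental design mixes a fixed proportion of foreign ("spike-in")
cells into every sample, so the spike-in read counts anchor absolute
normalization even when the target transcriptome changes globally —
the regime where library-size normalization silently rescales true
fold changes away.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import CountMatrix, CoverageTrack, ExpressionMatrix, PoldegError, SizeFactors


def chip_scale_factors(spike_read_counts: pd.Series) -> SizeFactors:
    """Track scale factors proportional to 1 / spike-in read count.

    Samples with more spike-in reads were sequenced deeper per cell, so
    their signal is scaled down.  Factors are rescaled to geometric
    mean 1 (a symmetric convention; only proportionality is meaningful).
    """
    counts = spike_read_counts.astype(float)
    if (counts <= 0).any() or not np.isfinite(counts).all():
        raise PoldegError("all spike-in read counts must be positive and finite")
    raw = 1.0 / counts
    factors = raw / np.exp(np.mean(np.log(raw)))
    return SizeFactors(factors=factors, method="chip_reciprocal")


def spikein_size_factors(cm: CountMatrix, min_usable: int = 5) -> SizeFactors:
    """Median-of-ratios size factors computed over spike-in genes only.

    s_j = median over spike-in genes g of N_gj / geomean_j' N_gj',
    after dropping genes with a zero count in any sample (whose
    geometric mean is zero).  Falls back to the ratio of spike-in
    column totals when fewer than ``min_usable`` genes survive.
    """
    spike = cm.subset_species("spikein")
    if spike.counts.shape[0] == 0:
        raise PoldegError("no spike-in genes in count matrix")
    arr = spike.counts.to_numpy(dtype=float)
    usable = (arr > 0).all(axis=1)
    if usable.sum() >= min_usable:
        sub = arr[usable]
        geomeans = np.exp(np.mean(np.log(sub), axis=1))
        ratios = sub / geomeans[:, None]
        factors = pd.Series(np.median(ratios, axis=0), index=cm.sample_ids)
        return SizeFactors(factors=factors, method="median_of_ratios_spikein")
    totals = arr.sum(axis=0)
    if (totals <= 0).any():
        raise PoldegError("a sample has zero spike-in reads; cannot normalize")
    warnings.warn(
        f"only {int(usable.sum())} spike-in genes usable for median-of-ratios; "
        "falling back to spike-in column totals"
    )
    factors = pd.Series(totals / np.exp(np.mean(np.log(totals))), index=cm.sample_ids)
    return SizeFactors(factors=factors, method="total_spikein")


def naive_size_factors(cm: CountMatrix, method: str = "median_of_ratios_all") -> SizeFactors:
    """Size factors ignoring the spike-in, for contrast experiments.

    ``median_of_ratios_all`` is the standard estimator a practitioner
    would apply without spike-ins; it assumes most genes are unchanged
    and is exactly the estimator that global repression defeats.
    ``total_all`` uses target-gene column totals.
    """
    target = cm.subset_species("target")
    arr = target.counts.to_numpy(dtype=float)
    if method == "median_of_ratios_all":
        usable = (arr > 0).all(axis=1)
        if usable.sum() == 0:
            raise PoldegError("no genes usable for median-of-ratios")
        sub = arr[usable]
        geomeans = np.exp(np.mean(np.log(sub), axis=1))
        factors = pd.Series(
            np.median(sub / geomeans[:, None], axis=0), index=cm.sample_ids
        )
    elif method == "total_all":
        totals = arr.sum(axis=0)
        if (totals <= 0).any():
            raise PoldegError("a sample has zero target reads")
        factors = pd.Series(totals / np.exp(np.mean(np.log(totals))), index=cm.sample_ids)
    else:
        raise PoldegError(f"unknown naive size-factor method {method!r}")
    return SizeFactors(factors=factors, method=method)


def rpkm_tpm(cm: CountMatrix, unit: str = "RPKM") -> ExpressionMatrix:
    """Length/depth-normalized expression over target genes.

    RPKM_gj = N_gj * 1e9 / (L_g * sum_g' N_g'j);
    TPM_gj = (N_gj / L_g) * 1e6 / sum_g' (N_g'j / L_g').
    Spike-in genes are excluded from the gene universe and the
    denominators: their abundance reflects the mixing ratio, not the
    transcriptome.
    """
    if unit not in ("RPKM", "TPM"):
        raise PoldegError(f"unit must be RPKM or TPM, got {unit!r}")
    target = cm.subset_species("target")
    counts = target.counts.to_numpy(dtype=float)
    lengths = target.lengths.to_numpy(dtype=float)
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        raise PoldegError("zero library size in at least one sample")
    if unit == "RPKM":
        vals = counts * 1e9 / (lengths[:, None] * libsize[None, :])
    else:
        rate = counts / lengths[:, None]
        vals = rate * 1e6 / rate.sum(axis=0)[None, :]
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=target.counts.index, columns=target.counts.columns),
        unit=unit,  # type: ignore[arg-type]
    )


def ratio_track(
    numerator: CoverageTrack,
    denominator: CoverageTrack,
    bin_size: int = 10,
    pseudocount: float = 1.0,
    chrom_sizes: Optional[dict] = None,
) -> CoverageTrack:
    """Binned signal ratio (num + pc) / (den + pc), scale factors applied.

    Used for phospho-CTD over total polymerase tracks and for nascent-RNA
    over elongating-polymerase (elongation-rate) tracks.
    """
    if bin_size < 1:
        raise PoldegError("bin size must be >= 1")
    num_chroms, den_chroms = set(numerator.chroms), set(denominator.chroms)
    if num_chroms != den_chroms:
        raise PoldegError(
            f"chromosome universes differ: {sorted(num_chroms ^ den_chroms)}"
        )
    out = CoverageTrack(strand=numerator.strand)
    for chrom in numerator.chroms:
        end = chrom_sizes[chrom] if chrom_sizes else max(
            numerator.chrom_end(chrom), denominator.chrom_end(chrom)
        )
        n_bins = int(np.ceil(end / bin_size))
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, end)
        vals = np.empty(n_bins)
        for i, (a, b) in enumerate(zip(starts, ends)):
            nm = numerator.window_mean(chrom, int(a), int(b))
            dm = denominator.window_mean(chrom, int(a), int(b))
            vals[i] = (nm + pseudocount) / (dm + pseudocount)
        out.add_runs(chrom, starts, ends, vals)
    return out
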