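"""Gene-set definitions used downstream of the quantitative stages.

* length classes: Short (<= 10 kb), Medium (10-75 kb], Long (> 75 kb);
* degradation-upregulated genes: up-called in BOTH degron RNA-seq
  contrasts (NTD and CTD) and expressed above an RPKM floor;
* control genes: short (< 10 kb), not histone genes, not upregulated;
* binding genes: genes whose extent, extended upstream by a promoter
  window in sense orientation, overlaps at least one peak.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, Sequence, Set

import numpy as np
import pandas as pd

from .models import GeneModel, PeakSet, PoldegError

SHORT_MAX_BP = 10_000
MEDIUM_MAX_BP = 75_000


def length_class(gene: GeneModel) -> str:
    """Short iff L <= 10 kb, Medium iff 10 kb < L <= 75 kb, else Long."""
    if gene.length <= SHORT_MAX_BP:
        return "Short"
    if gene.length <= MEDIUM_MAX_BP:
        return "Medium"
    return "Long"


def define_upregulated(
    de_ntd: pd.DataFrame,
    de_ctd: pd.DataFrame,
    rpkm: pd.DataFrame,
    rpkm_threshold: float = 1.0,
) -> Set[str]:
    """Genes up-called in both degron contrasts with max RPKM above threshold.

    ``de_ntd``/``de_ctd`` need a 'status' column; the RPKM filter is
    the max over the supplied samples (upregulated genes are low at
    baseline, so a baseline-only filter would empty the set).
    """
    for name, df in (("NTD", de_ntd), ("CTD", de_ctd)):
        if "status" not in df.columns:
            raise PoldegError(f"{name} DE table lacks a 'status' column")
    shared = de_ntd.index.intersection(de_ctd.index)
    if len(shared) == 0:
        raise PoldegError("DE tables have disjoint gene universes")
    up_both = set(de_ntd.index[de_ntd["status"] == "up"]) & set(
        de_ctd.index[de_ctd["status"] == "up"]
    )
    max_rpkm = rpkm.max(axis=1)
    return {g for g in up_both if max_rpkm.get(g, 0.0) > rpkm_threshold}


def control_genes(
    genes: Sequence[GeneModel],
    upregulated: Set[str],
    histone_ids: Set[str],
) -> Set[str]:
    """Short (< 10 kb) genes excluding histone genes and upregulated genes."""
    if not histone_ids:
        warnings.warn("empty histone gene list: no histone exclusion applied")
    return {
        g.gene_id
        for g in genes
        if g.length < SHORT_MAX_BP
        and g.gene_id not in histone_ids
        and g.gene_id not in upregulated
    }


def binding_genes(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    promoter_upstream: int = 3000,
) -> Set[str]:
    """Genes overlapped (>= 1 bp) by any peak over their promoter-extended span.

    The gene extent is extended ``promoter_upstream`` bp upstream in
    sense orientation (half-open arithmetic: a peak touching only the
    end coordinate does not overlap).
    """
    by_chrom: Dict[str, pd.DataFrame] = {
        str(c): sub for c, sub in peaks.intervals.groupby("chrom")
    }
    bound: Set[str] = set()
    for g in genes:
        if g.strand == "+":
            a, b = max(0, g.start - promoter_upstream), g.end
        else:
            a, b = g.start, g.end + promoter_upstream
        sub = by_chrom.get(g.chrom)
        if sub is None:
            continue
        if ((sub["start"] < b) & (sub["end"] > a)).any():
            bound.add(g.gene_id)
    return bound


def gene_labels(
    genes: Sequence[GeneModel],
    upregulated: Set[str],
    histone_ids: Set[str],
    bound: Dict[str, Set[str]] | None = None,
) -> pd.DataFrame:
    """Combined per-gene label table (length class, upregulated, control, bound)."""
    ctrl = control_genes(genes, upregulated, histone_ids)
    df = pd.DataFrame(
        {
            "length_class": [length_class(g) for g in genes],
            "upregulated": [g.gene_id in upregulated for g in genes],
            "control": [g.gene_id in ctrl for g in genes],
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )
    for factor, ids in (bound or {}).items():
        df[f"bound_{factor}"] = [g in ids for g in df.index]
    if (df["upregulated"] & df["control"]).any():
        raise PoldegError("a gene cannot be both control and upregulated")
    return df
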