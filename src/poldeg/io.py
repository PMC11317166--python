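"""Readers and writers for the text formats the pipeline exchanges.

Formats: GTF (1-based closed, converted on ingest), BED6/BED12 and
bedGraph (0-based half-open, used as-is), TSV count tables and
expression matrices.  Everything the package writes can be read back
to an identical in-memory object.
"""

from __future__ import annotations

import io as _io
import os
from typing import Dict, List, Optional, Sequence, Set

import gffutils
import numpy as np
import pandas as pd

from .models import (
    CountMatrix,
    CoverageTrack,
    ExpressionMatrix,
    GeneModel,
    PeakSet,
    PoldegError,
    SizeFactors,
)


def _check_unique_ids(genes: List[GeneModel]) -> List[GeneModel]:
    seen: Set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise PoldegError(f"duplicate gene_id {g.gene_id!r} in annotation")
        seen.add(g.gene_id)
    return genes


def read_gene_annotation(
    path: str,
    fmt: str = "gtf",
    spikein_chroms: Optional[Set[str]] = None,
) -> List[GeneModel]:
    """Load gene models from GTF, BED6 or BED12.

    GTF coordinates (1-based, closed) are converted to the internal
    0-based half-open convention.  Genes on chromosomes listed in
    ``spikein_chroms`` are tagged as spike-in species.
    """
    spikein_chroms = spikein_chroms or set()
    if fmt == "gtf":
        genes = _read_gtf(path, spikein_chroms)
    elif fmt in ("bed6", "bed12"):
        genes = _read_bed(path, spikein_chroms)
    else:
        raise PoldegError(f"unsupported annotation format {fmt!r}")
    return _check_unique_ids(genes)


def _read_gtf(path: str, spikein_chroms: Set[str]) -> List[GeneModel]:
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise PoldegError(f"failed to parse GTF {path}: {exc}") from exc
    genes: List[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.strand not in ("+", "-"):
            import warnings

            warnings.warn(
                f"skipping gene {feat.id!r}: unknown strand {feat.strand!r}"
            )
            continue
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        biotype = (
            feat.attributes.get("gene_biotype", feat.attributes.get("gene_type", [None]))
        )[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feat.seqid,
                start=feat.start - 1,  # GTF is 1-based closed
                end=feat.end,
                strand=feat.strand,
                biotype=biotype,
                species="spikein" if feat.seqid in spikein_chroms else "target",
            )
        )
    return genes


def _read_bed(path: str, spikein_chroms: Set[str]) -> List[GeneModel]:
    genes: List[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise PoldegError(
                    f"{path}:{lineno}: BED record needs >= 6 fields, got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise PoldegError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand not in ("+", "-"):
                import warnings

                warnings.warn(f"{path}:{lineno}: unknown strand {strand!r}, skipping")
                continue
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    start=s,
                    end=e,
                    strand=strand,
                    species="spikein" if chrom in spikein_chroms else "target",
                )
            )
    return genes


def write_gene_annotation_bed6(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_gene_annotation_gtf(genes: Sequence[GeneModel], path: str) -> None:
    """Write gene features as GTF (converting back to 1-based closed)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            if g.biotype:
                attrs += f' gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\tpoldeg\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_coverage_track(path: str, strand: str = ".") -> CoverageTrack:
    """Load a bedGraph file (0-based half-open) into a CoverageTrack.

    Exact duplicate runs are collapsed; partially overlapping runs are
    rejected.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    if df["value"].isna().any():
        raise PoldegError(f"{path}: malformed bedGraph (missing value field)")
    df = df.drop_duplicates()
    track = CoverageTrack(strand=strand)
    for chrom, sub in df.groupby("chrom", sort=True):
        track.add_runs(chrom, sub["start"], sub["end"], sub["value"])
    return track


def write_coverage_track(track: CoverageTrack, path: str) -> None:
    frames = []
    for chrom in track.chroms:
        s, e, v = track.runs(chrom)
        frames.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e, "value": v}))
    if not frames:
        open(path, "w").close()
        return
    pd.concat(frames).to_csv(
        path, sep="\t", header=False, index=False, float_format="%.10g"
    )


def read_count_table(path: str) -> CountMatrix:
    """Load a TSV count table.

    Expected columns: ``gene_id``, ``species``, ``length``, then one
    integer column per sample.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "species", "length"):
        if col not in df.columns:
            raise PoldegError(f"{path}: missing mandatory column {col!r}")
    df = df.set_index("gene_id")
    species = df["species"].astype(str)
    bad = set(species.unique()) - {"target", "spikein"}
    if bad:
        raise PoldegError(
            f"{path}: unknown species label(s) {sorted(bad)}; map genome names "
            "to the 'target'/'spikein' vocabulary before loading"
        )
    lengths = df["length"].astype(np.int64)
    sample_cols = [c for c in df.columns if c not in ("species", "length")]
    if not sample_cols:
        raise PoldegError(f"{path}: no sample columns found")
    counts = df[sample_cols]
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or not np.allclose(arr, np.round(arr)):
        raise PoldegError(f"{path}: counts must be integers")
    if (arr < 0).any():
        raise PoldegError(f"{path}: counts must be >= 0")
    return CountMatrix(counts=counts.astype(np.int64), species=species, lengths=lengths)


def write_count_table(cm: CountMatrix, path: str) -> None:
    out = pd.concat([cm.species.rename("species"), cm.lengths.rename("length"), cm.counts], axis=1)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_expression_matrix(path: str, unit: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ExpressionMatrix(values=df, unit=unit)  # type: ignore[arg-type]


def write_expression_matrix(em: ExpressionMatrix, path: str) -> None:
    out = em.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_sample_sheet(path: str) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, condition, timepoint_h, replicate."""
    df = pd.read_csv(path, sep="\t")
    req = {"sample_id", "condition", "timepoint_h", "replicate"}
    missing = req - set(df.columns)
    if missing:
        raise PoldegError(f"{path}: sample sheet missing columns {sorted(missing)}")
    return df.set_index("sample_id")


def read_peaks(path: str) -> PeakSet:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    return PeakSet(intervals=df)


def write_size_factors(sf: SizeFactors, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# method: {sf.method}\n")
        fh.write("sample_id\tsize_factor\n")
        for sample, val in sf.factors.items():
            fh.write(f"{sample}\t{val:.10g}\n")


def read_size_factors(path: str) -> SizeFactors:
    method = "median_of_ratios_spikein"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# method:"):
            method = first.split(":", 1)[1].strip()
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(_io.StringIO(body), sep="\t", index_col="sample_id")
    return SizeFactors(factors=df["size_factor"], method=method)
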