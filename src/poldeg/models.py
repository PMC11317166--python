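"""Core domain types shared by every analysis stage.

Coordinate convention: all intervals are 0-based half-open (BED
convention) everywhere inside the package.  GTF input (1-based,
closed) is converted on ingest and never seen again.  For a gene on
the minus strand the transcription start site (TSS) is ``end - 1``
(the last covered base) and the transcription end site (TES) is
``start``; "downstream" means decreasing genomic coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

Strand = Literal["+", "-"]
Species = Literal["target", "spikein"]

VALID_SPECIES = ("target", "spikein")


class PoldegError(ValueError):
    """Base class for domain-level validation failures."""


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene interval with derived TSS/TES anchors.

    ``start``/``end`` are 0-based half-open genomic coordinates.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: Strand
    biotype: Optional[str] = None
    species: Species = "target"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise PoldegError(
                f"gene {self.gene_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise PoldegError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if self.species not in VALID_SPECIES:
            raise PoldegError(
                f"gene {self.gene_id}: species must be one of {VALID_SPECIES}, "
                f"got {self.species!r}"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def genes_to_frame(genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Tabular view of a gene collection (one row per gene, indexed by id)."""
    return pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "species": [g.species for g in genes],
            "length": [g.length for g in genes],
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )


class CoverageTrack:
    """Piecewise-constant per-chromosome signal.

    Stored as sorted, non-overlapping ``(start, end, value)`` runs per
    chromosome.  Positions not covered by any run read as 0 — the
    depth-of-coverage convention.  A multiplicative ``scale_factor``
    (spike-in derived) is applied lazily by every query.
    """

    def __init__(
        self,
        runs: Optional[Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]] = None,
        strand: str = ".",
        scale_factor: float = 1.0,
    ) -> None:
        if scale_factor <= 0 or not math.isfinite(scale_factor):
            raise PoldegError(f"scale_factor must be finite and > 0, got {scale_factor}")
        if strand not in ("+", "-", "."):
            raise PoldegError(f"strand label must be '+', '-' or '.', got {strand!r}")
        self.strand = strand
        self.scale_factor = float(scale_factor)
        self._runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if runs:
            for chrom, (s, e, v) in runs.items():
                self.add_runs(chrom, s, e, v)

    @property
    def chroms(self) -> List[str]:
        return sorted(self._runs)

    def add_runs(
        self,
        chrom: str,
        starts: Iterable[int],
        ends: Iterable[int],
        values: Iterable[float],
    ) -> None:
        s = np.asarray(list(starts), dtype=np.int64)
        e = np.asarray(list(ends), dtype=np.int64)
        v = np.asarray(list(values), dtype=np.float64)
        if not (len(s) == len(e) == len(v)):
            raise PoldegError("starts, ends, values must have equal length")
        order = np.argsort(s, kind="stable")
        s, e, v = s[order], e[order], v[order]
        if np.any(e <= s):
            raise PoldegError(f"{chrom}: runs must satisfy start < end")
        if np.any(~np.isfinite(v)) or np.any(v < 0):
            raise PoldegError(f"{chrom}: run values must be finite and >= 0")
        if len(s) > 1 and np.any(s[1:] < e[:-1]):
            i = int(np.argmax(s[1:] < e[:-1]))
            raise PoldegError(
                f"{chrom}: overlapping runs at [{s[i]},{e[i]}) and [{s[i+1]},{e[i+1]})"
            )
        if chrom in self._runs:
            ps, pe, pv = self._runs[chrom]
            s = np.concatenate([ps, s])
            e = np.concatenate([pe, e])
            v = np.concatenate([pv, v])
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            if np.any(s[1:] < e[:-1]):
                raise PoldegError(f"{chrom}: overlapping runs after merge")
        self._runs[chrom] = (s, e, v)

    def runs(self, chrom: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._runs.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.float64)),
        )

    def value_at(self, chrom: str, pos: int) -> float:
        """Signal at a single base (scale factor applied)."""
        s, e, v = self.runs(chrom)
        i = np.searchsorted(s, pos, side="right") - 1
        if i >= 0 and pos < e[i]:
            return float(v[i]) * self.scale_factor
        return 0.0

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base signal over [start, end), scale factor applied."""
        if end <= start:
            return 0.0
        s, e, v = self.runs(chrom)
        if len(s) == 0:
            return 0.0
        lo = np.searchsorted(e, start, side="right")
        hi = np.searchsorted(s, end, side="left")
        if hi <= lo:
            return 0.0
        ov = np.minimum(e[lo:hi], end) - np.maximum(s[lo:hi], start)
        return float(np.sum(ov * v[lo:hi])) * self.scale_factor

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base signal over [start, end); uncovered bases count as 0."""
        n = end - start
        if n <= 0:
            return math.nan
        return self.window_sum(chrom, start, end) / n

    def binned_means(
        self, chrom: str, start: int, end: int, bin_size: int
    ) -> np.ndarray:
        """Mean signal in consecutive bins of ``bin_size`` covering [start, end)."""
        if (end - start) % bin_size != 0:
            raise PoldegError("bin size must divide window length")
        edges = np.arange(start, end + bin_size, bin_size)
        return np.array(
            [self.window_mean(chrom, int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]
        )

    def scaled(self, scale_factor: float) -> "CoverageTrack":
        """Same runs, different scale factor (runs are shared, not copied)."""
        t = CoverageTrack(strand=self.strand, scale_factor=scale_factor)
        t._runs = self._runs
        return t

    def chrom_end(self, chrom: str) -> int:
        s, e, v = self.runs(chrom)
        return int(e[-1]) if len(e) else 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        if self.strand != other.strand or self.chroms != other.chroms:
            return False
        for c in self.chroms:
            for a, b in zip(self.runs(c), other.runs(c)):
                if not np.array_equal(a, b):
                    return False
        return True


@dataclass
class CountMatrix:
    """Gene x sample integer read counts with per-gene species tags.

    ``counts`` is a DataFrame indexed by gene_id with sample columns;
    ``species`` and ``lengths`` are Series on the same index.
    """

    counts: pd.DataFrame
    species: pd.Series
    lengths: pd.Series

    def __post_init__(self) -> None:
        self.counts.index.name = "gene_id"
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise PoldegError(f"duplicate gene_id {dup!r} in count matrix")
        if not self.species.index.equals(self.counts.index) or not self.lengths.index.equals(
            self.counts.index
        ):
            raise PoldegError("species/lengths index must match counts index")
        bad = set(self.species.unique()) - set(VALID_SPECIES)
        if bad:
            raise PoldegError(
                f"unknown species label(s) {sorted(bad)}; use 'target' or 'spikein'"
            )
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise PoldegError("counts must be integral")
            self.counts = self.counts.round().astype(np.int64)
            arr = self.counts.to_numpy()
        if np.any(arr < 0):
            raise PoldegError("counts must be >= 0")
        if np.any(self.lengths.to_numpy() <= 0):
            raise PoldegError("gene lengths must be > 0")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.counts.columns)

    @property
    def n_spikein(self) -> int:
        return int((self.species == "spikein").sum())

    def subset_species(self, species: str) -> "CountMatrix":
        mask = self.species == species
        return CountMatrix(
            self.counts.loc[mask], self.species.loc[mask], self.lengths.loc[mask]
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.species, self.lengths)


@dataclass
class SizeFactors:
    """Per-sample positive multipliers with the estimator recorded."""

    factors: pd.Series
    method: str

    KNOWN_METHODS = (
        "median_of_ratios_spikein",
        "median_of_ratios_all",
        "total_spikein",
        "total_all",
        "chip_reciprocal",
    )

    def __post_init__(self) -> None:
        if self.method not in self.KNOWN_METHODS:
            raise PoldegError(f"unknown size-factor method {self.method!r}")
        vals = self.factors.to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
            raise PoldegError("size factors must be finite and > 0")
        if self.method == "chip_reciprocal":
            gm = float(np.exp(np.mean(np.log(vals))))
            if abs(gm - 1.0) > 1e-9:
                raise PoldegError(
                    f"chip_reciprocal factors must have geometric mean 1, got {gm}"
                )

    def __getitem__(self, sample: str) -> float:
        return float(self.factors[sample])


@dataclass
class ExpressionMatrix:
    """Gene x sample non-negative real expression values with a unit tag."""

    values: pd.DataFrame
    unit: Literal["RPKM", "TPM", "normalized-count"]

    def __post_init__(self) -> None:
        if self.unit not in ("RPKM", "TPM", "normalized-count"):
            raise PoldegError(f"unknown expression unit {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise PoldegError("expression values must be >= 0")


@dataclass
class PeakSet:
    """Genomic intervals (e.g. ChIP peaks), sorted per chromosome."""

    intervals: pd.DataFrame  # columns: chrom, start, end [, score]

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end"}
        if not req.issubset(self.intervals.columns):
            raise PoldegError(f"peak table needs columns {sorted(req)}")
        if (self.intervals["start"] >= self.intervals["end"]).any():
            raise PoldegError("peaks must satisfy start < end")
        self.intervals = self.intervals.sort_values(
            ["chrom", "start", "end"]
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)
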