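"""Strand-aware windows and the three coverage-derived transcription indices.

* pausing index (PI): mean polymerase signal in the promoter-proximal
  window (TSS-30 to TSS+300 in sense orientation) over the mean in
  the gene body (TSS+300 to TES).  High PI marks promoter-proximal
  pausing.
* readthrough index (RI): mean nascent-RNA signal in the 2 kb
  downstream of the TES over the 2 kb upstream; values near 0 mean
  clean termination, values near 1 mean full readthrough.
* elongation index (EI): nascent-RNA (TT-seq) over elongating
  polymerase (pSer2) signal across the gene body — a per-gene proxy
  for elongation output per polymerase.

"Signal" means mean per-base value over the window (sum mode is
available), making PI insensitive to the asymmetric window lengths.
All windows are sense-oriented: for a minus-strand gene "downstream"
decreases the genomic coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import CoverageTrack, GeneModel, PoldegError

TSS_UPSTREAM = 30
TSS_DOWNSTREAM = 300
TERM_SIZE = 2000

WindowRole = Literal["tss", "body", "gene_body_char", "term", "pre_term"]


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    end: int
    clipped: bool = False
    na_reason: Optional[str] = None

    @property
    def valid(self) -> bool:
        return self.na_reason is None and self.end > self.start


def build_window(
    gene: GeneModel,
    role: WindowRole,
    chrom_end: Optional[int] = None,
    tss_upstream: int = TSS_UPSTREAM,
    tss_downstream: int = TSS_DOWNSTREAM,
    term_size: int = TERM_SIZE,
) -> Window:
    """Construct one sense-oriented window for a gene.

    Plus strand: tss=[TSS-30, TSS+300), body=[TSS+300, gene end),
    term = 2 kb past the gene end, pre_term = last 2 kb of the gene
    span (the TES base belongs to pre_term, never to term).  Minus
    strand mirrors all of these.  Windows are clipped to
    [0, chrom_end) with a flag.
    """
    s, e = gene.start, gene.end
    if gene.strand == "+":
        coords = {
            "tss": (s - tss_upstream, s + tss_downstream),
            "body": (s + tss_downstream, e),
            "gene_body_char": (s + tss_downstream, e),
            "term": (e, e + term_size),
            "pre_term": (e - term_size, e),
        }[role]
    else:
        coords = {
            "tss": (e - tss_downstream, e + tss_upstream),
            "body": (s, e - tss_downstream),
            "gene_body_char": (s, e - tss_downstream),
            "term": (s - term_size, s),
            "pre_term": (s, s + term_size),
        }[role]
    a, b = coords
    if role in ("body", "gene_body_char") and b <= a:
        return Window(gene.chrom, a, max(a, b), na_reason="short_gene")
    clipped = False
    if a < 0:
        a, clipped = 0, True
    if chrom_end is not None and b > chrom_end:
        b, clipped = chrom_end, True
    if b <= a:
        return Window(gene.chrom, a, a, clipped=True, na_reason="clipped_away")
    return Window(gene.chrom, a, b, clipped=clipped)


def _window_signal(track: CoverageTrack, w: Window, mode: str) -> float:
    if mode == "mean":
        return track.window_mean(w.chrom, w.start, w.end)
    return track.window_sum(w.chrom, w.start, w.end)


def _ratio(
    num_track: CoverageTrack,
    num_w: Window,
    den_track: CoverageTrack,
    den_w: Window,
    mode: str,
) -> Tuple[float, Optional[str]]:
    for w in (num_w, den_w):
        if not w.valid:
            return math.nan, w.na_reason or "empty_window"
    den = _window_signal(den_track, den_w, mode)
    if den == 0:
        return math.nan, "zero_denominator"
    return _window_signal(num_track, num_w, mode) / den, None


def pausing_index(
    track: CoverageTrack, gene: GeneModel, mode: str = "mean", chrom_end: Optional[int] = None
) -> Tuple[float, Optional[str]]:
    """PI = signal(TSS window) / signal(gene body). Returns (value, na_reason)."""
    return _ratio(
        track,
        build_window(gene, "tss", chrom_end),
        track,
        build_window(gene, "body", chrom_end),
        mode,
    )


def readthrough_index(
    track: CoverageTrack, gene: GeneModel, mode: str = "mean", chrom_end: Optional[int] = None
) -> Tuple[float, Optional[str]]:
    """RI = signal(2 kb past TES) / signal(2 kb before TES)."""
    return _ratio(
        track,
        build_window(gene, "term", chrom_end),
        track,
        build_window(gene, "pre_term", chrom_end),
        mode,
    )


def elongation_index(
    tt_track: CoverageTrack,
    pser2_track: CoverageTrack,
    gene: GeneModel,
    mode: str = "mean",
    chrom_end: Optional[int] = None,
) -> Tuple[float, Optional[str]]:
    """EI = nascent-RNA signal over pSer2 signal across the gene body."""
    w = build_window(gene, "gene_body_char", chrom_end)
    return _ratio(tt_track, w, pser2_track, w, mode)


def select_strand_track(
    tracks: Dict[str, CoverageTrack], gene: GeneModel, strand_mode: str = "sense"
) -> CoverageTrack:
    """Pick the stranded track a gene should be read from.

    'sense' uses the gene's own strand (readthrough continues on the
    gene's strand); 'forward' always uses the plus-strand track.
    """
    if strand_mode == "sense":
        key = gene.strand
    elif strand_mode == "forward":
        key = "+"
    else:
        raise PoldegError(f"strand_mode must be 'sense' or 'forward', got {strand_mode!r}")
    if key not in tracks:
        raise PoldegError(f"no track for strand {key!r}")
    return tracks[key]


def index_table(
    genes: Sequence[GeneModel],
    polii_track=None,
    tt_tracks: Optional[Dict[str, CoverageTrack]] = None,
    pser2_track: Optional[CoverageTrack] = None,
    mode: str = "mean",
    strand_mode: str = "sense",
) -> pd.DataFrame:
    """Per-gene PI / RI / EI table with window means and NA reason codes.

    PI uses the polymerase track — either one unstranded
    CoverageTrack or a dict of stranded tracks, resolved per gene via
    ``strand_mode``.  RI uses the stranded nascent-RNA tracks; EI
    needs both nascent-RNA and pSer2 signal.  Indices whose inputs
    are absent come back as NaN with reason 'no_track'.
    """

    def resolve(tr, g: GeneModel) -> CoverageTrack:
        return select_strand_track(tr, g, strand_mode) if isinstance(tr, dict) else tr

    rows = []
    for g in genes:
        row: Dict[str, object] = {"gene_id": g.gene_id}
        if polii_track is not None:
            ptrack = resolve(polii_track, g)
            pi, reason = pausing_index(ptrack, g, mode)
            row["PI"], row["PI_na_reason"] = pi, reason
            row["tss_mean"] = _window_signal(ptrack, build_window(g, "tss"), "mean")
            bw = build_window(g, "body")
            row["body_mean"] = (
                _window_signal(ptrack, bw, "mean") if bw.valid else math.nan
            )
        else:
            row["PI"], row["PI_na_reason"] = math.nan, "no_track"
        if tt_tracks is not None:
            sense = select_strand_track(tt_tracks, g, strand_mode)
            ri, reason = readthrough_index(sense, g, mode)
            row["RI"], row["RI_na_reason"] = ri, reason
            row["term_mean"] = _window_signal(sense, build_window(g, "term"), "mean")
            row["pre_term_mean"] = _window_signal(sense, build_window(g, "pre_term"), "mean")
        else:
            row["RI"], row["RI_na_reason"] = math.nan, "no_track"
        if tt_tracks is not None and pser2_track is not None:
            sense = select_strand_track(tt_tracks, g, strand_mode)
            ei, reason = elongation_index(sense, pser2_track, g, mode)
            row["EI"], row["EI_na_reason"] = ei, reason
        else:
            row["EI"], row["EI_na_reason"] = math.nan, "no_track"
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def metagene_profile(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    upstream: int = 2000,
    downstream: int = 2000,
    bin_size: int = 50,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Binned signal matrix around TSS anchors plus its column-mean profile.

    Rows are genes, columns are bins ordered upstream-to-downstream in
    sense orientation (minus-strand rows are computed on mirrored
    coordinates so bin 0 is always the most-upstream bin).
    """
    if not genes:
        raise PoldegError("empty gene set")
    total = upstream + downstream
    if total % bin_size != 0:
        raise PoldegError("bin size must divide upstream + downstream")
    n_bins = total // bin_size
    mat = np.empty((len(genes), n_bins))
    for i, g in enumerate(genes):
        tss = g.tss
        if g.strand == "+":
            vals = track.binned_means(g.chrom, tss - upstream, tss + downstream, bin_size)
        else:
            vals = track.binned_means(
                g.chrom, tss - downstream + 1, tss + upstream + 1, bin_size
            )[::-1]
        mat[i] = vals
    cols = [f"bin_{j}" for j in range(n_bins)]
    df = pd.DataFrame(mat, index=[g.gene_id for g in genes], columns=cols)
    profile = df.mean(axis=0)
    profile.name = "mean_signal"
    return df, profile
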