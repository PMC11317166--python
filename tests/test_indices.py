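"""Window arithmetic, coverage indices, metagene profiles."""

import math

import numpy as np
import pandas as pd
import pytest

from poldeg.indices import (
    build_window,
    elongation_index,
    index_table,
    metagene_profile,
    pausing_index,
    readthrough_index,
    select_strand_track,
)
from poldeg.models import CoverageTrack, GeneModel, PoldegError


def track_from(runs, strand="."):
    t = CoverageTrack(strand=strand)
    for chrom, s, e, v in runs:
        t.add_runs(chrom, [s], [e], [v])
    return t


class TestWindows:
    def test_plus_strand_tss_window(self):
        g = GeneModel("g", "chr1", 1000, 9000, "+")
        w = build_window(g, "tss")
        assert (w.start, w.end) == (970, 1300)

    def test_minus_strand_tss_window_mirrored(self):
        g = GeneModel("g", "chr1", 1000, 5000, "-")  # TSS = 4999
        w = build_window(g, "tss")
        assert (w.start, w.end) == (4700, 5030)

    def test_body_windows_both_strands(self):
        gp = GeneModel("g", "chr1", 1000, 9000, "+")
        gm = GeneModel("g", "chr1", 1000, 9000, "-")
        assert (build_window(gp, "body").start, build_window(gp, "body").end) == (1300, 9000)
        assert (build_window(gm, "body").start, build_window(gm, "body").end) == (1000, 8700)

    def test_termination_windows_flank_gene_end(self):
        gp = GeneModel("g", "chr1", 10000, 20000, "+")
        assert (build_window(gp, "term").start, build_window(gp, "term").end) == (20000, 22000)
        assert (build_window(gp, "pre_term").start, build_window(gp, "pre_term").end) == (18000, 20000)
        gm = GeneModel("g", "chr1", 10000, 20000, "-")
        assert (build_window(gm, "term").start, build_window(gm, "term").end) == (8000, 10000)
        assert (build_window(gm, "pre_term").start, build_window(gm, "pre_term").end) == (10000, 12000)

    def test_short_gene_body_is_na(self):
        g = GeneModel("g", "chr1", 1000, 1200, "+")
        assert build_window(g, "body").na_reason == "short_gene"

    def test_clipping_flagged(self):
        g = GeneModel("g", "chr1", 10, 3000, "+")
        w = build_window(g, "tss")
        assert w.clipped and w.start == 0


class TestPausingIndex:
    def test_constructed_five(self):
        g = GeneModel("g", "chr1", 1000, 9000, "+")
        t = track_from([("chr1", 970, 1300, 10.0), ("chr1", 1300, 9000, 2.0)])
        pi, reason = pausing_index(t, g)
        assert reason is None and pi == pytest.approx(5.0)

    def test_uniform_track_gives_one(self):
        g = GeneModel("g", "chr1", 1000, 9000, "+")
        t = track_from([("chr1", 0, 20000, 3.0)])
        assert pausing_index(t, g)[0] == pytest.approx(1.0)

    def test_zero_body_is_na(self):
        g = GeneModel("g", "chr1", 1000, 9000, "+")
        t = track_from([("chr1", 970, 1300, 10.0)])
        pi, reason = pausing_index(t, g)
        assert math.isnan(pi) and reason == "zero_denominator"

    def test_scale_invariance(self):
        g = GeneModel("g", "chr1", 1000, 9000, "-")
        t = track_from([("chr1", 500, 9500, 4.0), ("chr1", 9500, 9700, 1.0)])
        assert pausing_index(t.scaled(7.5), g)[0] == pytest.approx(pausing_index(t, g)[0])


class TestReadthroughIndex:
    def test_uniform_through_tes_is_one(self):
        g = GeneModel("g", "chr1", 5000, 15000, "+")
        t = track_from([("chr1", 0, 30000, 2.0)])
        assert readthrough_index(t, g)[0] == pytest.approx(1.0)

    def test_signal_stopping_at_tes_is_zero(self):
        g = GeneModel("g", "chr1", 5000, 15000, "+")
        t = track_from([("chr1", 5000, 15000, 2.0)])
        assert readthrough_index(t, g)[0] == pytest.approx(0.0)

    def test_zero_pre_term_is_na(self):
        g = GeneModel("g", "chr1", 5000, 15000, "+")
        t = track_from([("chr1", 15000, 17000, 2.0)])
        ri, reason = readthrough_index(t, g)
        assert math.isnan(ri) and reason == "zero_denominator"

    def test_minus_strand_mirror(self):
        # same geometry reflected: readthrough tail upstream of start
        gm = GeneModel("g", "chr1", 5000, 15000, "-")
        t = track_from([("chr1", 4000, 15000, 2.0)])  # 1 kb tail past TES=5000
        ri, _ = readthrough_index(t, gm)
        assert ri == pytest.approx(0.5)  # tail covers half the term window


class TestElongationIndex:
    def test_identical_tracks_one(self):
        g = GeneModel("g", "chr1", 1000, 9000, "+")
        t = track_from([("chr1", 0, 20000, 3.0)])
        assert elongation_index(t, t, g)[0] == pytest.approx(1.0)

    def test_two_fold(self):
        g = GeneModel("g", "chr1", 1000, 9000, "+")
        tt = track_from([("chr1", 0, 20000, 6.0)])
        ps = track_from([("chr1", 0, 20000, 3.0)])
        assert elongation_index(tt, ps, g)[0] == pytest.approx(2.0)

    def test_zero_denominator_na(self):
        g = GeneModel("g", "chr1", 1000, 9000, "+")
        tt = track_from([("chr1", 0, 20000, 6.0)])
        ps = CoverageTrack()
        ei, reason = elongation_index(tt, ps, g)
        assert math.isnan(ei) and reason == "zero_denominator"


def test_strand_mirror_symmetry():
    """Reflecting gene and track through a coordinate leaves PI/RI unchanged."""
    L = 50000
    g = GeneModel("g", "chr1", 5000, 15000, "+")
    runs = [("chr1", 4970, 5300, 8.0), ("chr1", 5300, 15000, 2.0), ("chr1", 15000, 16000, 1.0)]
    t = track_from(runs)
    # mirror: x -> L - x
    mirrored = [("chr1", L - e, L - s, v) for (_, s, e, v) in runs]
    tm = track_from(mirrored)
    gm = GeneModel("g", "chr1", L - 15000, L - 5000, "-")
    assert pausing_index(t, g)[0] == pytest.approx(pausing_index(tm, gm)[0])
    assert readthrough_index(t, g)[0] == pytest.approx(readthrough_index(tm, gm)[0])


def test_select_strand_track_modes():
    plus, minus = CoverageTrack(strand="+"), CoverageTrack(strand="-")
    tracks = {"+": plus, "-": minus}
    gm = GeneModel("g", "chr1", 0, 100, "-")
    assert select_strand_track(tracks, gm, "sense") is minus
    assert select_strand_track(tracks, gm, "forward") is plus
    with pytest.raises(PoldegError):
        select_strand_track(tracks, gm, "antisense")


class TestMetagene:
    def test_uniform_track_flat_profile(self):
        genes = [
            GeneModel("a", "chr1", 10000, 30000, "+"),
            GeneModel("b", "chr1", 40000, 60000, "-"),
        ]
        t = track_from([("chr1", 0, 100000, 7.0)])
        mat, profile = metagene_profile(t, genes, 2000, 2000, 100)
        assert np.allclose(mat.to_numpy(), 7.0)
        assert np.allclose(profile.to_numpy(), 7.0)

    def test_bump_lands_in_first_body_bin(self):
        g = GeneModel("a", "chr1", 10000, 30000, "+")
        t = track_from([("chr1", 10000, 10100, 9.0)])
        _, profile = metagene_profile(t, [g], 1000, 1000, 100)
        assert profile.idxmax() == "bin_10"  # first bin at/after the TSS

    def test_minus_strand_row_reversal_involution(self):
        gm = GeneModel("m", "chr1", 40000, 60000, "-")
        t = track_from([("chr1", 59000, 61000, 3.0)])  # around the TSS at 59999
        mat, _ = metagene_profile(t, [gm], 2000, 2000, 100)
        row = mat.loc["m"].to_numpy()
        assert np.allclose(row[::-1][::-1], row)
        # signal extends 1 kb upstream and 1 kb downstream of the TSS
        assert row[10] == 3.0 and row[30] == 0.0

    def test_empty_gene_set_rejected(self):
        with pytest.raises(PoldegError):
            metagene_profile(CoverageTrack(), [], 100, 100, 10)


def test_index_recovery_on_simulated_tracks():
    """Zero-noise simulation reproduces truth exactly; CV=0.1 keeps the
    median relative error of both indices within a few percent."""
    from poldeg.simulate import SimulationConfig, simulate_annotation, simulate_tracks

    cfg0 = SimulationConfig(
        n_genes=40, n_spikein_genes=5, length_log10_range=(3.6, 4.4),
        noise_cv=0.0, seed=21,
    )
    genes = simulate_annotation(cfg0)
    target = [g for g in genes if g.species == "target"]
    tracks, truth = simulate_tracks(genes, cfg0)
    tab = index_table(target, polii_track=tracks, tt_tracks=tracks).join(truth.genes)
    np.testing.assert_allclose(tab["PI"], tab["true_pi"], rtol=1e-10)
    ok = tab.dropna(subset=["true_ri"])
    np.testing.assert_allclose(ok["RI"], ok["true_ri"], rtol=1e-10)
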