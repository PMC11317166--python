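"""Determinism, construction guarantees and truth bookkeeping of the simulators."""

import numpy as np
import pandas as pd
import pytest

from poldeg.classify import length_class
from poldeg.models import PoldegError
from poldeg.normalize import spikein_size_factors
from poldeg.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_counts,
    simulate_pulse_chase,
    simulate_tracks,
    stable_gene_ids,
)


class TestConfigValidation:
    def test_gap_constraint_enforced(self):
        with pytest.raises(PoldegError, match="gap"):
            SimulationConfig(intergenic_gap=500)

    def test_fraction_bounds(self):
        with pytest.raises(PoldegError):
            SimulationConfig(fraction_upregulated=1.0)
        with pytest.raises(PoldegError):
            SimulationConfig(fraction_upregulated=0.5, fraction_repressed=0.6)

    def test_timepoints_validated(self):
        with pytest.raises(PoldegError):
            SimulationConfig(timepoints=(0.0, -1.0))
        with pytest.raises(PoldegError):
            SimulationConfig(timepoints=(1.0, 3.0))

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(PoldegError):
            SimulationConfig(depth=0)


class TestAnnotation:
    def test_same_seed_identical(self):
        cfg = SimulationConfig(n_genes=100, n_spikein_genes=10, seed=1)
        a = simulate_annotation(cfg)
        b = simulate_annotation(SimulationConfig(n_genes=100, n_spikein_genes=10, seed=1))
        assert a == b

    def test_all_length_classes_present(self):
        cfg = SimulationConfig(n_genes=120, n_spikein_genes=5, seed=2)
        classes = {length_class(g) for g in simulate_annotation(cfg) if g.species == "target"}
        assert classes == {"Short", "Medium", "Long"}

    def test_non_overlapping_with_gaps(self):
        cfg = SimulationConfig(n_genes=80, n_spikein_genes=10, seed=3)
        genes = simulate_annotation(cfg)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for members in by_chrom.values():
            members.sort(key=lambda g: g.start)
            for a, b in zip(members, members[1:]):
                assert b.start - a.end >= cfg.intergenic_gap

    def test_both_strands_used(self):
        cfg = SimulationConfig(n_genes=50, n_spikein_genes=5, seed=4)
        strands = {g.strand for g in simulate_annotation(cfg)}
        assert strands == {"+", "-"}

    def test_infeasible_packing_rejected(self):
        cfg = SimulationConfig(
            n_genes=5, n_spikein_genes=1, chrom_length=30_000,
            length_log10_range=(4.8, 5.0),
        )
        with pytest.raises(PoldegError, match="chromosome"):
            simulate_annotation(cfg)


class TestCounts:
    def test_same_seed_identical_matrix(self):
        cfg = SimulationConfig(n_genes=50, n_spikein_genes=10, seed=5)
        genes = simulate_annotation(cfg)
        cm1, t1 = simulate_counts(genes, cfg)
        cm2, t2 = simulate_counts(genes, cfg)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
        pd.testing.assert_frame_equal(t1.genes, t2.genes)

    def test_spikein_truth_is_always_unchanged(self):
        cfg = SimulationConfig(n_genes=50, n_spikein_genes=10, seed=6)
        genes = simulate_annotation(cfg)
        _, truth = simulate_counts(genes, cfg)
        spike = [g.gene_id for g in genes if g.species == "spikein"]
        assert (truth.genes.loc[spike, "true_log2fc"] == 0).all()

    def test_spikein_means_track_depth_only(self):
        """Spike-in expected counts carry no condition effect: per-depth
        means agree across conditions within sampling error."""
        cfg = SimulationConfig(n_genes=300, n_spikein_genes=100, seed=7)
        genes = simulate_annotation(cfg)
        cm, truth = simulate_counts(genes, cfg)
        per_depth = cm.subset_species("spikein").counts.div(
            truth.samples["depth"], axis=1
        )
        ctrl = per_depth.iloc[:, :3].to_numpy().mean()
        trt = per_depth.iloc[:, 3:].to_numpy().mean()
        assert abs(np.log2(trt / ctrl)) < 0.1

    def test_null_case_exchangeable(self):
        """With no condition effects the two groups are statistically
        exchangeable: the NB test calls roughly alpha false positives."""
        from poldeg.diffexpr import nb_wald_test

        cfg = SimulationConfig(
            n_genes=2000, n_spikein_genes=100, fraction_upregulated=0.0,
            fraction_repressed=0.0, repression_factor=1.0, seed=8,
        )
        cm, _ = simulate_counts(simulate_annotation(cfg), cfg)
        groups = pd.Series(
            ["control" if s.startswith("control") else "treated" for s in cm.sample_ids],
            index=cm.sample_ids,
        )
        res = nb_wald_test(cm, groups, spikein_size_factors(cm))
        frac = float((res["pvalue"] < 0.05).mean())
        assert 0.02 < frac < 0.09

    def test_law_of_large_numbers_fold_change(self):
        """Poisson limit at high depth: a true log2FC=2 gene shows an
        empirical spike-normalized ratio near 4."""
        cfg = SimulationConfig(
            n_genes=100, n_spikein_genes=50, dispersion=0.0, depth=1e6,
            depth_jitter=0.0, fraction_repressed=0.0, fraction_upregulated=0.3,
            upregulated_log2fc=2.0, seed=9,
        )
        cm, truth = simulate_counts(simulate_annotation(cfg), cfg)
        sf = spikein_size_factors(cm)
        q = cm.counts.div(pd.Series({s: sf[s] for s in cm.sample_ids}), axis=1)
        up = truth.genes.index[truth.genes["true_log2fc"] == 2.0]
        ratio = q.loc[up].iloc[:, 3:].mean(axis=1).sum() / q.loc[up].iloc[:, :3].mean(axis=1).sum()
        assert ratio == pytest.approx(4.0, rel=0.05)


class TestPulseChase:
    def test_noise_free_closed_form(self):
        cfg = SimulationConfig(
            n_genes=20, n_spikein_genes=5, noise_cv=0.0,
            distortion_range=(1.0, 1.0), timepoints=(0.0, 1.0, 3.0), seed=10,
        )
        genes = simulate_annotation(cfg)
        em, _, truth = simulate_pulse_chase(genes, cfg)
        decaying = truth.genes[~truth.genes["is_stable"]]
        g = decaying.index[0]
        e0 = decaying.loc[g, "baseline_tpm"]
        k = decaying.loc[g, "true_k_per_h"]
        np.testing.assert_allclose(
            em.values.loc[g].to_numpy(),
            [e0, e0 * np.exp(-k), e0 * np.exp(-3 * k)],
            rtol=1e-12,
        )

    def test_stable_genes_constant_up_to_distortion(self):
        cfg = SimulationConfig(n_genes=20, n_spikein_genes=5, noise_cv=0.0, seed=11)
        genes = simulate_annotation(cfg)
        em, _, truth = simulate_pulse_chase(genes, cfg)
        d = truth.samples["true_distortion"].to_numpy()
        for g in stable_gene_ids(cfg):
            vals = em.values.loc[g].to_numpy()
            np.testing.assert_allclose(vals / d, vals[0], rtol=1e-12)

    def test_determinism(self):
        cfg = SimulationConfig(n_genes=30, n_spikein_genes=5, seed=12)
        genes = simulate_annotation(cfg)
        em1, _, _ = simulate_pulse_chase(genes, cfg)
        em2, _, _ = simulate_pulse_chase(genes, cfg)
        pd.testing.assert_frame_equal(em1.values, em2.values)


class TestTracks:
    def test_constructed_index_oracles(self):
        """p=5, b=2, r fixed, zero noise: indices equal truth exactly."""
        from poldeg.indices import index_table

        cfg = SimulationConfig(
            n_genes=10, n_spikein_genes=5, noise_cv=0.0,
            pausing_range=(5.0, 5.0), body_level_range=(2.0, 2.0),
            readthrough_range=(1.0, 1.0), length_log10_range=(3.6, 4.2), seed=13,
        )
        genes = simulate_annotation(cfg)
        target = [g for g in genes if g.species == "target"]
        tracks, _ = simulate_tracks(genes, cfg)
        tab = index_table(target, polii_track=tracks, tt_tracks=tracks)
        np.testing.assert_allclose(tab["PI"], 5.0, rtol=1e-10)
        np.testing.assert_allclose(tab["RI"], 1.0, rtol=1e-10)

    def test_zero_readthrough_gives_zero_index(self):
        from poldeg.indices import index_table

        cfg = SimulationConfig(
            n_genes=6, n_spikein_genes=5, noise_cv=0.0,
            readthrough_range=(0.0, 0.0), length_log10_range=(3.6, 4.2), seed=14,
        )
        genes = simulate_annotation(cfg)
        target = [g for g in genes if g.species == "target"]
        tracks, _ = simulate_tracks(genes, cfg)
        tab = index_table(target, tt_tracks=tracks)
        np.testing.assert_allclose(tab["RI"], 0.0, atol=1e-12)

    def test_signal_confined_to_sense_strand(self):
        cfg = SimulationConfig(
            n_genes=8, n_spikein_genes=5, noise_cv=0.0,
            length_log10_range=(3.6, 4.2), seed=15,
        )
        genes = simulate_annotation(cfg)
        tracks, _ = simulate_tracks(genes, cfg)
        for g in genes:
            if g.species != "target":
                continue
            anti = tracks["-" if g.strand == "+" else "+"]
            assert anti.window_sum(g.chrom, g.start, g.end) == 0.0

    def test_determinism(self):
        cfg = SimulationConfig(n_genes=10, n_spikein_genes=5,
                               length_log10_range=(3.6, 4.2), seed=16)
        genes = simulate_annotation(cfg)
        t1, _ = simulate_tracks(genes, cfg)
        t2, _ = simulate_tracks(genes, cfg)
        assert t1["+"] == t2["+"] and t1["-"] == t2["-"]
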