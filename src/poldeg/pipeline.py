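"""End-to-end orchestration of the synthetic analysis pipeline.

One YAML config drives: simulate -> size factors -> differential
expression -> coverage indices -> pulse-chase half-lives -> gene
classification.  Every output TSV carries a provenance header (tool
version, config hash, seed) and reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .classify import gene_labels, define_upregulated
from .diffexpr import call_de, nb_wald_test
from .halflife import halflife_table
from .indices import index_table
from .io import (
    write_count_table,
    write_coverage_track,
    write_expression_matrix,
    write_gene_annotation_bed6,
    write_size_factors,
)
from .models import PoldegError
from .normalize import naive_size_factors, rpkm_tpm, spikein_size_factors
from .simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_counts,
    simulate_pulse_chase,
    simulate_tracks,
    stable_gene_ids,
)

logger = logging.getLogger("poldeg")


@dataclass
class PipelineConfig:
    outdir: str
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    rpkm_threshold: float = 1.0
    tpm_threshold: float = 0.2
    stages: List[str] = field(
        default_factory=lambda: ["simulate", "normalize", "de", "indices", "halflife", "classify"]
    )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        if not os.path.exists(path):
            raise PoldegError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        if "outdir" not in raw:
            raise PoldegError("config must set 'outdir'")
        return cls(simulation=sim, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "simulation": self.simulation.__dict__,
                "lfc": self.lfc_threshold,
                "fdr": self.fdr_threshold,
                "rpkm": self.rpkm_threshold,
                "tpm": self.tpm_threshold,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: str, cfg: PipelineConfig) -> None:
    header = (
        f"# poldeg {__version__}; config={cfg.config_hash()}; "
        f"seed={cfg.simulation.seed}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t")


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> Dict[str, str]:
    """Run the configured stages; return a manifest of artifact checksums."""
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: Dict[str, str] = {}
    sim = cfg.simulation
    t_start = time.time()

    def produced(name: str, path: str) -> None:
        manifest[name] = _checksum(path)
        logger.info("stage artifact %s -> %s", name, path)

    def stage(name: str) -> bool:
        return name in cfg.stages

    try:
        genes = simulate_annotation(sim)
        target_genes = [g for g in genes if g.species == "target"]
        if stage("simulate"):
            ann_path = os.path.join(cfg.outdir, "annotation.bed")
            write_gene_annotation_bed6(genes, ann_path)
            produced("annotation", ann_path)

        cm, truth_counts = simulate_counts(genes, sim)
        if stage("simulate"):
            counts_path = os.path.join(cfg.outdir, "counts.tsv")
            write_count_table(cm, counts_path)
            produced("counts", counts_path)
            truth_counts.to_tsv(
                os.path.join(cfg.outdir, "truth_genes.tsv"),
                os.path.join(cfg.outdir, "truth_samples.tsv"),
            )
            produced("truth_genes", os.path.join(cfg.outdir, "truth_genes.tsv"))

        sf = spikein_size_factors(cm)
        if stage("normalize"):
            sf_path = os.path.join(cfg.outdir, "size_factors.tsv")
            write_size_factors(sf, sf_path)
            produced("size_factors", sf_path)
            rpkm = rpkm_tpm(cm, "RPKM")
            rpkm_path = os.path.join(cfg.outdir, "rpkm.tsv")
            write_expression_matrix(rpkm, rpkm_path)
            produced("rpkm", rpkm_path)

        de = None
        if stage("de"):
            groups = pd.Series(
                ["control" if s.startswith("control") else "treated" for s in cm.sample_ids],
                index=cm.sample_ids,
            )
            de = nb_wald_test(cm, groups, sf)
            rpkm = rpkm_tpm(cm, "RPKM")
            de["status"] = call_de(
                de,
                cfg.lfc_threshold,
                cfg.fdr_threshold,
                min_expr=None,
            )
            de_path = os.path.join(cfg.outdir, "de.tsv")
            _write_tsv(de, de_path, cfg)
            produced("de", de_path)

        if stage("indices"):
            tracks, truth_tracks = simulate_tracks(genes, sim)
            for strand, label in (("+", "plus"), ("-", "minus")):
                p = os.path.join(cfg.outdir, f"track_{label}.bedgraph")
                write_coverage_track(tracks[strand], p)
                produced(f"track_{label}", p)
            idx = index_table(target_genes, polii_track=tracks, tt_tracks=tracks)
            idx_path = os.path.join(cfg.outdir, "indices.tsv")
            _write_tsv(idx, idx_path, cfg)
            produced("indices", idx_path)
            truth_tracks.genes.to_csv(
                os.path.join(cfg.outdir, "truth_indices.tsv"), sep="\t"
            )
            produced("truth_indices", os.path.join(cfg.outdir, "truth_indices.tsv"))

        if stage("halflife"):
            em, sheet, truth_hl = simulate_pulse_chase(genes, sim, condition="untreated")
            stable = stable_gene_ids(sim)
            tables, _ = halflife_table(
                {"untreated": (em, sheet)}, stable, tpm_threshold=cfg.tpm_threshold
            )
            hl_path = os.path.join(cfg.outdir, "halflife_untreated.tsv")
            _write_tsv(tables["untreated"], hl_path, cfg)
            produced("halflife", hl_path)
            truth_hl.genes.to_csv(
                os.path.join(cfg.outdir, "truth_halflife.tsv"), sep="\t"
            )
            produced("truth_halflife", os.path.join(cfg.outdir, "truth_halflife.tsv"))

        if stage("classify"):
            if de is None:
                raise PoldegError("classify stage requires the de stage")
            rpkm = rpkm_tpm(cm, "RPKM")
            up = define_upregulated(de, de, rpkm.values, cfg.rpkm_threshold)
            labels = gene_labels(target_genes, up, histone_ids=set())
            labels_path = os.path.join(cfg.outdir, "gene_labels.tsv")
            _write_tsv(labels, labels_path, cfg)
            produced("gene_labels", labels_path)
    except PoldegError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PoldegError(f"pipeline stage failed: {exc}") from exc

    manifest_path = os.path.join(cfg.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline finished in %.1f s", time.time() - t_start)
    return manifest
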