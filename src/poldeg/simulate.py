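"""Synthetic data with known ground truth for every analysis stage.

The generators emulate the three data modalities the pipeline
consumes:

* dual-species count matrices in which most target genes are globally
  repressed while spike-in genes stay constant — the regime where
  library-size normalization miscalls unchanged genes and spike-in
  normalization does not;
* 4sU pulse-chase time courses obeying first-order decay, with
  per-sample multiplicative scale distortions and a designated set of
  stable transcripts used for between-sample scaling;
* stranded coverage tracks built from a promoter-proximal bump, a
  uniform gene body and a post-TES tail, so the pausing and
  readthrough indices have exact constructed values.

All randomness flows from one integer seed through
``numpy.random.SeedSequence(seed).spawn``: child 0 drives the
annotation, child 1 the counts, child 2 the pulse-chase course and
child 3 the tracks.  Identical (config, seed) pairs give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import CountMatrix, CoverageTrack, ExpressionMatrix, GeneModel, PoldegError

MIN_INTERGENIC_GAP = 2000  # keeps +-2 kb TES windows collision-free


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults mirror the study design the pipeline targets: ~2000
    target genes plus a 10%-scale spike-in gene set, 3 vs 3
    replicates at 2e6 reads each, NB dispersion 0.05, 80% of target
    genes repressed 5-fold with a 10% truly upregulated minority at
    log2FC = 2, and a 0/1/3/12 h chase with 10% lognormal noise.
    """

    n_genes: int = 2000
    n_spikein_genes: int = 200
    length_log10_range: Tuple[float, float] = (3.0, 5.3)  # 1 kb .. 200 kb
    intergenic_gap: int = 2500
    chrom_length: int = 60_000_000
    depth: float = 2e6
    depth_jitter: float = 0.05
    dispersion: float = 0.05
    n_replicates: int = 3
    fraction_upregulated: float = 0.10
    upregulated_log2fc: float = 2.0
    fraction_repressed: float = 0.80
    repression_factor: float = 0.2
    timepoints: Tuple[float, ...] = (0.0, 1.0, 3.0, 12.0)
    noise_cv: float = 0.10
    distortion_range: Tuple[float, float] = (0.7, 1.3)
    n_stable_genes: int = 7
    halflife_range_h: Tuple[float, float] = (0.5, 24.0)
    pausing_range: Tuple[float, float] = (2.0, 10.0)
    readthrough_range: Tuple[float, float] = (0.1, 1.0)
    body_level_range: Tuple[float, float] = (1.0, 10.0)
    track_bin: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fraction_upregulated < 1):
            raise PoldegError("fraction_upregulated must lie in [0, 1)")
        if self.fraction_upregulated + self.fraction_repressed > 1:
            raise PoldegError("fraction_upregulated + fraction_repressed must be <= 1")
        if self.intergenic_gap < MIN_INTERGENIC_GAP:
            raise PoldegError(
                f"intergenic_gap must be >= {MIN_INTERGENIC_GAP} bp so that "
                "post-TES windows cannot collide with neighbouring genes"
            )
        if self.depth <= 0:
            raise PoldegError("sequencing depth must be > 0")
        if any(t < 0 for t in self.timepoints):
            raise PoldegError("timepoints must be >= 0 hours")
        if 0.0 not in self.timepoints:
            raise PoldegError("timepoints must include 0")

    def rng(self, stage: int) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(4)
        return np.random.default_rng(children[stage])


@dataclass
class TruthBundle:
    """Ground truth stored alongside every simulated dataset.

    ``genes`` is indexed by gene_id and carries whichever truth
    columns the generator defines (true_log2fc, true_halflife_h,
    true_pi, true_ri, ...); ``samples`` carries per-sample truths
    (depth, condition, distortion).
    """

    genes: pd.DataFrame
    samples: pd.DataFrame
    seed: int

    def to_tsv(self, gene_path: str, sample_path: str) -> None:
        g = self.genes.copy()
        g.index.name = "gene_id"
        g.to_csv(gene_path, sep="\t")
        s = self.samples.copy()
        s.index.name = "sample_id"
        s.to_csv(sample_path, sep="\t")


def simulate_annotation(config: SimulationConfig) -> List[GeneModel]:
    """Place non-overlapping genes on toy chromosomes.

    Target genes go on chromosomes named chrT*, spike-in genes on
    chrS*; every pair of neighbouring genes is separated by the
    configured intergenic gap and both strands are used.
    """
    rng = config.rng(0)
    lo, hi = config.length_log10_range
    genes: List[GeneModel] = []

    def place(n: int, prefix: str, chrom_prefix: str, species: str) -> None:
        lengths = np.round(10 ** rng.uniform(lo, hi, size=n)).astype(np.int64)
        strands = rng.choice(["+", "-"], size=n)
        chrom_i, cursor = 1, config.intergenic_gap
        for i in range(n):
            L = int(lengths[i])
            if cursor + L + config.intergenic_gap > config.chrom_length:
                chrom_i += 1
                cursor = config.intergenic_gap
                if cursor + L + config.intergenic_gap > config.chrom_length:
                    raise PoldegError(
                        f"gene of {L} bp cannot fit on a {config.chrom_length} bp chromosome"
                    )
            genes.append(
                GeneModel(
                    gene_id=f"{prefix}{i:05d}",
                    chrom=f"{chrom_prefix}{chrom_i}",
                    start=cursor,
                    end=cursor + L,
                    strand=str(strands[i]),  # type: ignore[arg-type]
                    species=species,  # type: ignore[arg-type]
                )
            )
            cursor += L + config.intergenic_gap

    place(config.n_genes, "gene_", "chrT", "target")
    place(config.n_spikein_genes, "spike_", "chrS", "spikein")
    return genes


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_counts(
    genes: Sequence[GeneModel], config: SimulationConfig
) -> Tuple[CountMatrix, TruthBundle]:
    """Dual-species NB count matrix for a control vs treated contrast.

    Expected counts are depth_j x relative abundance x condition
    effect, with relative abundances normalized to the control pool.
    Spike-in genes carry no condition effect, so their expected counts
    differ between samples only through depth_j; under global
    repression the treated target pool (and library) shrinks while
    the spike-in anchor stays fixed — the regime where normalizing by
    target-library statistics miscalls unchanged genes.  True log2
    fold changes are recorded in the TruthBundle.
    """
    rng = config.rng(1)
    ids = [g.gene_id for g in genes]
    species = pd.Series([g.species for g in genes], index=ids)
    lengths = pd.Series([g.length for g in genes], index=ids)
    n = len(genes)
    target_ix = np.flatnonzero((species == "target").to_numpy())

    abundance = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    abundance /= abundance.sum()
    effect = np.ones(n)
    n_up = int(round(config.fraction_upregulated * len(target_ix)))
    n_rep = int(round(config.fraction_repressed * len(target_ix)))
    shuffled = rng.permutation(target_ix)
    up_ix, rep_ix = shuffled[:n_up], shuffled[n_up : n_up + n_rep]
    effect[up_ix] = 2.0 ** config.upregulated_log2fc
    effect[rep_ix] = config.repression_factor

    n_rep_samples = config.n_replicates
    samples = [f"control_{r+1}" for r in range(n_rep_samples)] + [
        f"treated_{r+1}" for r in range(n_rep_samples)
    ]
    conditions = ["control"] * n_rep_samples + ["treated"] * n_rep_samples
    j = config.depth_jitter
    depths = config.depth * rng.uniform(1 - j, 1 + j, size=len(samples))

    counts = np.empty((n, len(samples)), dtype=np.int64)
    for si, cond in enumerate(conditions):
        w = abundance * (effect if cond == "treated" else 1.0)
        mu = depths[si] * w
        counts[:, si] = _nb_sample(rng, mu, config.dispersion)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=ids, columns=samples),
        species=species,
        lengths=lengths,
    )
    truth_genes = pd.DataFrame(
        {"true_log2fc": np.log2(effect), "abundance": abundance}, index=ids
    )
    truth_samples = pd.DataFrame(
        {"condition": conditions, "depth": depths}, index=samples
    )
    return cm, TruthBundle(genes=truth_genes, samples=truth_samples, seed=config.seed)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_pulse_chase(
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    condition: str = "untreated",
    base_truth: Optional[pd.DataFrame] = None,
    halflife_scale: Optional[pd.Series] = None,
) -> Tuple[ExpressionMatrix, pd.DataFrame, TruthBundle]:
    """TPM-scale time course with first-order decay per target gene.

    Gene g at chase time t has expected signal E_g * exp(-k_g t),
    multiplied by a per-sample scale distortion d_t (d_0 = 1) and
    mean-one lognormal noise.  The first ``n_stable_genes`` target
    genes are the designated stable transcripts (k = 0).  Pass
    ``base_truth`` (a previous TruthBundle's ``genes`` frame) to reuse
    baselines across conditions, and ``halflife_scale`` to lengthen or
    shorten chosen genes' half-lives in this condition.

    Returns (matrix, sample sheet, truth).  Values are left on the
    distorted scale: correcting the distortion is the job of
    stable-transcript scaling downstream.
    """
    rng = config.rng(2)
    target = [g for g in genes if g.species == "target"]
    ids = [g.gene_id for g in target]
    n = len(ids)
    if config.n_stable_genes > n:
        raise PoldegError("more stable genes requested than target genes exist")

    if base_truth is not None:
        e0 = base_truth["baseline_tpm"].reindex(ids).to_numpy()
        hl = base_truth["true_halflife_h"].reindex(ids).to_numpy()
    else:
        e0 = 10.0 ** rng.uniform(-1.0, 2.5, size=n)
        lo, hi = config.halflife_range_h
        hl = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        hl[: config.n_stable_genes] = np.inf
    if halflife_scale is not None:
        hl = hl * halflife_scale.reindex(ids).fillna(1.0).to_numpy()
    k = np.where(np.isinf(hl), 0.0, np.log(2.0) / hl)

    tps = list(config.timepoints)
    d_lo, d_hi = config.distortion_range
    distortion = rng.uniform(d_lo, d_hi, size=len(tps))
    distortion[tps.index(0.0)] = 1.0

    sample_ids = [f"{condition}_{t:g}h" for t in tps]
    vals = np.empty((n, len(tps)))
    for ti, t in enumerate(tps):
        expected = e0 * np.exp(-k * t) * distortion[ti]
        vals[:, ti] = expected * _lognormal_noise(rng, config.noise_cv, n)

    em = ExpressionMatrix(
        values=pd.DataFrame(vals, index=ids, columns=sample_ids), unit="TPM"
    )
    sheet = pd.DataFrame(
        {
            "condition": condition,
            "timepoint_h": tps,
            "replicate": 1,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth_genes = pd.DataFrame(
        {
            "baseline_tpm": e0,
            "true_halflife_h": hl,
            "true_k_per_h": k,
            "is_stable": np.isinf(hl),
        },
        index=ids,
    )
    truth_samples = pd.DataFrame(
        {"condition": condition, "timepoint_h": tps, "true_distortion": distortion},
        index=sample_ids,
    )
    return em, sheet, TruthBundle(genes=truth_genes, samples=truth_samples, seed=config.seed)


def stable_gene_ids(config: SimulationConfig) -> List[str]:
    """Gene ids of the designated stable transcripts under the default naming."""
    return [f"gene_{i:05d}" for i in range(config.n_stable_genes)]


MIN_RI_GENE_LENGTH = 2300  # body must reach 2 kb behind the TES for RI truth to hold


def simulate_tracks(
    genes: Sequence[GeneModel], config: SimulationConfig
) -> Tuple[Dict[str, CoverageTrack], TruthBundle]:
    """Stranded coverage tracks with exact constructed pausing/readthrough.

    Each target gene contributes, on its own strand: a promoter bump
    of mean p_g*b_g over [TSS-30, TSS+300), a uniform body of mean b_g
    over [TSS+300, TES], and a post-TES tail of mean r_g*b_g over the
    2 kb past the TES.  Per-bin lognormal noise (mean one, the
    configured CV) multiplies every value.  True PI = p_g always;
    true RI = r_g for genes long enough (>= 2.3 kb) that the
    pre-termination window lies wholly inside the uniform body, NaN
    otherwise.
    """
    from .indices import build_window  # local import avoids cycle

    rng = config.rng(3)
    target = [g for g in genes if g.species == "target"]
    ids = [g.gene_id for g in target]
    n = len(ids)
    p_lo, p_hi = config.pausing_range
    r_lo, r_hi = config.readthrough_range
    b_lo, b_hi = config.body_level_range
    p = rng.uniform(p_lo, p_hi, size=n)
    r = rng.uniform(r_lo, r_hi, size=n)
    b = rng.uniform(b_lo, b_hi, size=n)

    per_strand: Dict[str, Dict[str, List[np.ndarray]]] = {
        "+": {}, "-": {}
    }

    def emit(strand: str, chrom: str, start: int, end: int, level: float) -> None:
        if end <= start or level <= 0:
            return
        nb = int(np.ceil((end - start) / config.track_bin))
        edges = np.minimum(start + np.arange(nb + 1) * config.track_bin, end)
        noise = _lognormal_noise(rng, config.noise_cv, nb)
        store = per_strand[strand].setdefault(chrom, [])
        store.append(np.column_stack([edges[:-1], edges[1:], level * noise]))

    for i, g in enumerate(target):
        tss_w = build_window(g, "tss")
        body_w = build_window(g, "body")
        term_w = build_window(g, "term")
        emit(g.strand, g.chrom, tss_w.start, tss_w.end, p[i] * b[i])
        if body_w.valid:
            emit(g.strand, g.chrom, body_w.start, body_w.end, b[i])
        emit(g.strand, g.chrom, term_w.start, term_w.end, r[i] * b[i])

    tracks: Dict[str, CoverageTrack] = {}
    for strand, chrom_map in per_strand.items():
        t = CoverageTrack(strand=strand)
        for chrom, chunks in chrom_map.items():
            arr = np.vstack(chunks)
            order = np.argsort(arr[:, 0])
            arr = arr[order]
            t.add_runs(chrom, arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
        tracks[strand] = t

    true_ri = np.where(
        np.array([g.length for g in target]) >= MIN_RI_GENE_LENGTH, r, np.nan
    )
    truth_genes = pd.DataFrame(
        {"true_pi": p, "true_ri": true_ri, "body_level": b}, index=ids
    )
    truth = TruthBundle(
        genes=truth_genes,
        samples=pd.DataFrame(index=pd.Index([], name="sample_id")),
        seed=config.seed,
    )
    return tracks, truth
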