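# Methods

## The problem the package models

Acute degron-mediated depletion of RNA polymerase II subunits (RPB1/RPB2)
suppresses transcription genome-wide. Sequencing assays only measure
relative composition, so any global shift is invisible to — and actively
distorted by — normalization schemes that assume most genes are unchanged.
The experimental designs this package serves therefore mix a fixed
proportion of cells from a second species into every sample: reads mapping
to the spike-in genome provide an anchor proportional to per-cell material,
valid regardless of what happens to the target transcriptome.

All coordinates inside the package are 0-based half-open (BED convention);
GTF input is converted on ingest. For a minus-strand gene the TSS is
`end − 1` and the TES is `start`; "downstream" means decreasing coordinate.
Uncovered track positions read as signal 0, the depth-of-coverage
convention.

## Normalization

**Track scale factors** (ChIP-style): s_j ∝ 1 / spike-in read count,
rescaled to geometric mean 1. Only proportionality is identified by the
data; the geometric-mean-1 convention is symmetric in the number of
conditions.

**Count size factors**: median-of-ratios restricted to spike-in genes,
s_j = median_g N_gj / (Π_j' N_gj')^(1/m), after dropping spike-in genes
with any zero count. With fewer than 5 usable genes the estimator falls
back to spike-in column totals (with a warning). The package also provides
the estimators one would use *without* spike-ins (`median_of_ratios_all`,
`total_all`) because the contrast between them and the spike-in route is
the central point: under global repression the all-gene median-of-ratios
reference is dominated by repressed genes, so truly unchanged genes appear
strongly upregulated.

**RPKM/TPM** are computed over target genes only; spike-in abundance
reflects the mixing ratio, not the transcriptome, so it is excluded from
denominators.

**Ratio tracks** (e.g. pSer2/RPB1, or nascent RNA/pSer2) are per-bin mean
ratios after applying each track's scale factor, with a configurable
pseudocount (default 1 signal unit) and bin (default 10 bp). Published
workflows rarely state these defaults; here they are documented and
configurable rather than hidden.

## Differential expression

A deliberately minimal two-group negative-binomial Wald test, implemented
rather than delegated, so the thresholding logic is transparent and
testable:

- normalized counts q_gj = N_gj / s_j; group means μ̂_C, μ̂_T;
- log2FC = log2((μ̂_T + ½) / (μ̂_C + ½)) — no shrinkage; the pseudocount
  only stabilizes empty means;
- variance model: normalized counts are treated as NB with
  Var = μ + αμ². Inference depends on the data only through (q, group),
  which makes results exactly invariant to rescaling a sample's counts
  and size factor together;
- dispersion: per-gene method of moments,
  α̂_g = (var_within − μ̂)/μ̂², floored at 10⁻⁸. The common dispersion is
  estimated by generalized-least-squares iterations of the same moment
  identity, weighting each expressed gene by 1/(1 + αμ)² — the inverse
  variance of its moment residual. (An unweighted ratio lets the few
  largest genes dominate; a median of per-gene estimates is biased low at
  3 vs 3 because the within-group variance is chi-square with few degrees
  of freedom. Both alternatives measurably miscalibrate the test.)
  The default mode shrinks per-gene estimates toward the common value
  with a prior weight of 50 pseudo-degrees of freedom; with thousands of
  genes the common component is nearly exact, keeping the z-test
  calibrated at small replicate numbers (measured null type-I error
  0.049–0.057 across seeds at the default design);
- Wald z = log2FC / SE with the delta-method SE, two-sided normal p,
  Benjamini–Hochberg adjustment (via statsmodels), and status calls at
  the conventional thresholds |log2FC| ≥ 1 and FDR < 0.05, with an
  optional minimum-expression (RPKM) gate that labels genes `low_expr`.

Known divergences from DESeq2: no fold-change shrinkage, no dispersion
trend fitting, no independent filtering, no outlier handling, single
two-group design only. On a spike-in fixture with pydeseq2 given the same
spike-in control genes, fold changes agree to ~10⁻³ (see the cross-check
test).

## Coverage indices

With sense-oriented windows anchored on the TSS and the gene end E
(half-open):

- tss = [TSS−30, TSS+300), body = [TSS+300, E);
- term = [E, E+2000), pre_term = [E−2000, E) — the TES base belongs to
  pre_term, never to term, so no base is double-counted;
- PI = mean(tss)/mean(body); RI = mean(term)/mean(pre_term);
  EI = mean_nascent(body)/mean_pSer2(body).

"Signal" is the mean per-base value over the window (sum mode available),
which makes PI insensitive to the very different window lengths. A zero
denominator yields NA with reason `zero_denominator`; genes whose body
window is empty yield `short_gene`. Readthrough defaults to each gene's
sense strand of the stranded nascent-RNA track — biologically, readthrough
transcription continues on the gene's own strand — with a forward-only
mode exposed for strict replication of forward-strand conventions.
Metagene matrices are binned means around the TSS; minus-strand rows are
computed on mirrored coordinates so bin 0 is always most-upstream.

## RNA half-lives

After label washout the labelled fraction decays as A·e^(−kt). The stages
are: optional spike-in normalization of the TPM matrix; between-sample
scaling by the geometric mean of a designated stable-transcript set
(c_t = 1 at the reference t = 0 by construction); a strict TPM > 0.2
filter evaluated at the untreated 0 h samples; and a per-gene log-linear
least-squares fit of log(value) = log A − k·t, with t½ = ln2/k.

Choices made where practice varies: the fit is log-linear (closed-form,
deterministic) rather than nonlinear; zeros are dropped before the log
rather than pseudocounted (pseudocounts bias k at low expression), with
the dropped count recorded; replicate observations at a timepoint are
averaged on the log scale so every timepoint has equal leverage; fitted
k ≤ 10⁻¹⁰/h is reported as `nondecaying` with t½ = ∞ rather than an
error. Genes with fewer than 3 positive points are flagged
`insufficient_points`.

## Gene classes

Length classes: Short iff L ≤ 10 kb, Medium iff 10 kb < L ≤ 75 kb, Long
iff L > 75 kb (the 10 kb boundary is assigned to Short; one convention,
stated and tested). Degradation-upregulated genes are those called `up`
in *both* degron contrasts whose maximum RPKM over the supplied samples
exceeds 1 — the maximum, because genuinely upregulated genes are low at
baseline and a baseline-only filter would empty the set; the summary
statistic is configurable. Control genes are < 10 kb, not histone genes
(caller-supplied list), and not upregulated. Peak-bound genes are those
whose span, extended 3 kb upstream in sense orientation (configurable),
overlaps any peak by ≥ 1 bp under half-open arithmetic.

## Strand-specific gene-body counting

Nascent-RNA/chromatin-RNA libraries are read-strand specific. The package
ingests stranded coverage tracks, and a protocol tag maps gene strand to
read-strand track: under `reverse_stranded` (the common dUTP convention)
a plus-strand gene is quantified from the minus track and vice versa.
The counting window is the sense gene body from TSS+300 to the gene end,
and the statistic is the summed per-base signal.

## Synthetic data and what it does (not) show

All generators draw from one seed via `numpy.random.SeedSequence.spawn`
(child 0 annotation, 1 counts, 2 pulse-chase, 3 tracks); identical
configs are bit-identical across runs.

**Counts.** Genes are placed non-overlapping on toy chromosomes with
≥ 2.5 kb gaps, lengths log-uniform from 1 kb to 200 kb (spanning all three
length classes). Expected counts are depth_j × relative abundance ×
condition effect; spike-in genes carry no condition effect. Defaults
mirror the targeted study design: 2 000 target + 200 spike-in genes,
3 vs 3 replicates at 2×10⁶ expected reads (±5% jitter), NB dispersion
0.05 (Var = μ + αμ²), 80% of target genes repressed 5-fold and 10%
upregulated at log2FC = 2 in the treated condition. This reproduces the
regime where all-gene normalization miscalls unchanged genes.

**Pulse-chase.** Baselines are log-uniform over ~0.1–300 TPM (so the
TPM > 0.2 filter has work to do), true half-lives log-uniform on
[0.5, 24] h, timepoints 0/1/3/12 h, per-sample scale distortions uniform
on [0.7, 1.3] (fixed to 1 at t = 0), multiplicative mean-one lognormal
noise with CV 0.1, and seven designated stable transcripts with k = 0.

**Tracks.** Each gene contributes, on its own strand, a promoter bump of
mean p·b over the TSS window, a uniform body at level b, and a post-TES
tail at r·b over the termination window, with per-25-bp-bin lognormal
noise. True PI = p by construction; true RI = r for genes ≥ 2.3 kb
(shorter genes' pre-termination window leaves the uniform body, so their
truth is recorded as NaN rather than silently wrong).

What passing recovery tests shows: the estimators invert the generative
models they were designed for, at realistic noise levels, and the
normalization contrast behaves as the spike-in logic predicts. What it
does not show: robustness to features real data have and the simulators
lack — multi-isoform structure and alternative TSS/TES usage, overlapping
and antisense transcription, mappability and GC artifacts, non-lognormal
technical noise, label-incorporation kinetics in pulse-chase data, and
batch structure. Results on real data depend on those, and the package
makes no claims about them.

## Problem sizes and numerics

Benchmark problem sizes (2 000–10 000 genes for count experiments, 500
genes for pulse-chase recovery, 200 genes for track recovery) were chosen
so each recovery metric is estimated with comfortable margin while a full
run of the suite plus the reproduction script completes in a few minutes
on one CPU. Degenerate inputs are handled by explicit flags or typed
errors (`PoldegError`) rather than NaN propagation: zero denominators,
short genes, all-zero spike-ins, missing 0 h samples, single replicates.
Pipeline outputs carry a provenance header (version, config hash, seed)
and a SHA-256 manifest; deterministic stages are byte-identical across
reruns.
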