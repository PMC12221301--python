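# Methods

## Coordinate model

Everything is transcript-space: 0-based, half-open intervals on the sense
strand, with each transcript partitioned into 5'UTR, CDS and 3'UTR tiling
`[0, L)`. The CDS must be a positive multiple of 3; transcripts violating the
partition are skipped at load time with a logged count rather than aborting a
run. Annotations are accepted as transcript-space BED12 (chrom = transcript
id, thickStart/thickEnd = CDS) or a transcript-space GTF dialect (seqname =
transcript id, CDS features); both are small enough that the package parses
them directly.

## uORF discovery and classification

Discovery is a pure sequence scan: every occurrence of an allowed start codon
(AUG, or near-cognate CUG/GUG/UUG) inside the 5'UTR opens a candidate, closed
by the first in-frame stop codon searched to the transcript end; candidates
with no stop are discarded. Candidates whose stop lies at or beyond the CDS
start are retained but flagged `overlaps_morf` and excluded from class
aggregates by default, since their footprints are not separable from mORF
signal. Nested and overlapping candidates are all reported; no deduplication
is applied, because any collapsing rule would be arbitrary at this level and
downstream consumers can group by transcript.

Kozak context uses the two classical features — purine at −3 and G at +4 —
giving `strong` (both), `medium` (exactly one), `weak` (neither); a start
within 3 nt of the cap has no −3 base and is `weak` by convention. Spacing
eligibility (used by uORF-stop metagene profiles) requires the stop-to-mORF
gap to be strictly greater than 50 nt so that initiation signal at the mORF
start does not contaminate the uORF-stop window.

## Footprint quantification

P-sites are assigned as 5' end + offset(length); the default offset is +12 nt
for all lengths 25–35, the conventional mammalian monosome choice, and is
overridable per length. Reads whose length has no offset, or whose P-site
falls past the transcript end, are discarded and tallied. A read counts for a
gene when its P-site lies in the CDS half-open interval (an any-overlap mode
exists for comparison); multi-mapping reads appear once per target and
contribute 1/multiplicity under the default fractional weighting (unit
weighting reproduces count-each behaviour). RNA-seq reads are counted over
the whole transcript, not the CDS, since RNA fragments carry no positional
meaning. The expression filter keeps genes with reads-per-kilobase-of-CDS
≥ 2.5 (boundary inclusive) in **every** library of both assays by default;
`any`-library scope is selectable. QC reports P-site fractions across
5'UTR/CDS/3'UTR and reading-frame fractions within the CDS.

## TE interaction test

Size factors are median-of-ratios (the median across all-nonzero genes of the
count-to-geometric-mean ratio), computed separately within FP and within RNA
libraries by default because the two chemistries have unrelated depths; joint
computation is available. Factors are not rescaled afterwards — only ratios
of factors within a stratum matter to the fit.

Dispersion: per gene, the pooled within-group variance s² of normalized
counts over the unique design rows gives the moment estimate
α̂ = (s² − μ̄)/μ̄². A parametric trend α(μ) = a₀ + a₁/μ is least-squares
fitted to the positive estimates, and gene values are shrunk toward the trend
on the log scale with an empirical-Bayes weight: the sampling variance of a
log variance on the residual degrees of freedom, against the excess spread of
gene estimates around the trend. With few replicates and homogeneous true
dispersion this weight approaches 1 (near-pooled estimation, which is what
keeps the Wald test calibrated at n = 3 replicates); simulated per-gene
heterogeneity relaxes it. Estimates are floored at 1e-8; all-zero genes are
excluded. No Cox–Reid adjustment is applied — the small-sample bias this
leaves is absorbed by the trend, and null calibration is verified by
simulation rather than assumed.

The NB GLM (log link, size factors as offsets, fixed per-gene α) is fitted by
iteratively reweighted least squares vectorised across genes: one batched
p×p solve per iteration, convergence at relative deviance change < 1e-8
within 100 iterations (non-converged genes are flagged and their p-values set
missing). Coefficients and standard errors (from the expected information
X'WX, W = μ/(1+αμ)) are reported in log2. The interaction Wald statistic is
referred to the standard normal; Benjamini–Hochberg adjustment runs over the
genes actually tested (post-filter), with missing p-values excluded from m.
No fold-change shrinkage is applied: the thresholds mirror an analysis that
cuts on the raw MLE. Down-calls use padj < α and log2FC < −cut (strict);
up-calls use padj < α and log2FC ≥ cut (inclusive) — the asymmetry follows
the inequalities of the mirrored analysis. "Blunted induction" genes pass the
up-call in the control-arm treatment contrast and fail it in the knockout
arm. Contrasts (`ko`, `tm-ctrl`, `tm-ko`) are fitted as separate
two-condition models rather than one four-condition model, matching pairwise
comparison semantics.

## Metagene profiles

The contributing unit is a transcript (mORF anchors) or a transcript–uORF
pair (uORF anchors); the anchor is the first base of the start or stop codon.
Each unit's windowed P-site counts are normalized per the mode — unit mean 1
over covered offsets (`per-transcript-mean`, the default, making the average
depth-invariant) or raw counts — and averaged with equal unit weight so
abundant transcripts do not dominate. Offsets outside a short transcript are
averaged over covering units only. Units with zero window reads are excluded
and counted. In raw mode, density times coverage sums exactly to the window
read total. Default windows are −30..+90 around starts and −90..+30 around
stops. Profile comparison resamples units within each profile (B = 1000,
seeded) and reports the per-offset difference with a percentile band.

## uORF-class aggregates

Genes are classified by their discovered, non-mORF-overlapping uORFs: any AUG
uORF puts a gene in the AUG class regardless of additional near-cognate uORFs
(priority rule); otherwise near-cognate; otherwise none — a partition of the
tested genes. The reported shift is the difference of median TE log2 fold
changes against the background (all tested genes by default; the uORF-free
subset selectable). The significance test is a two-sided Mann–Whitney U of
the class against its complement within the background: testing a class
against a superset that contains the class itself would be conservative and
non-uniform under label permutation, so the complement is used even when the
background is "all".

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
sequencing chemistry. Counts are gamma-Poisson: RNA ~ NB(μ_g·s_j, α), FP ~
NB(μ_g·TE_g·2^Δ·s_j, α), with gene abundances log-normal (meanlog = ln 500,
sdlog = 1), baseline TE log-normal (sdlog = 0.5), dispersion α = 0.1,
triplicates per assay×genotype×treatment, and per-sample depth factors
log-uniform in [0.5, 2] so normalization is non-trivially exercised. TE
effects multiply FP means only — an assay×condition interaction by
construction, never an RNA change. The truth table records every injected
effect. Footprints are placed per transcript: P-site codons uniform over the
CDS with ×3 multipliers on the first and last codon (start/stop accumulation;
free parameters, as no quantitative anchor exists for them), within-codon
offset from frame weights (0.7/0.15/0.15), lengths 25–35 nt peaked at
28–29, and — on transcripts carrying a usable AUG uORF — a `uorf_load`
fraction of reads moved onto a random uORF. All randomness flows through one
named generator (`numpy.random.default_rng`, PCG64), so a seed fixes the
dataset byte for byte.

What the generator does **not** model: ligation/PCR bias, sequence-dependent
cleavage, codon-level pausing, isoform mixtures, rRNA contamination, or
genome-space mapping artefacts. Passing tests therefore demonstrate that the
statistics are implemented correctly and calibrated under the assumed model,
not that the model captures every failure mode of real libraries.

## Numerical and design notes

- IRLS initialisation from least squares on log((y+0.5)/s); linear predictors
  clipped to ±30 before exponentiation; a 1e-10 ridge on X'WX guards
  degenerate weights.
- The saturated 2×2 design makes the interaction MLE equal the log2
  normalized TE ratio exactly on noise-free counts, which the tests exploit
  as a closed-form oracle; the analogous depth-rescaling invariance (scale
  one sample's counts and its size factor together) is exact only when all
  residuals are zero, and is tested on noise-free counts for that reason.
- With triplicates and α = 0.1, SE(log2FC_TE) ≈ 0.5: a 1-log2 TE shift sits
  near the per-gene detection floor. The pipeline's value in that regime is
  calibrated error control plus aggregate analyses, not per-gene sensitivity.
- Validation problem sizes (2000 genes × 20 null datasets, 10 recovery
  datasets, 1000 random UTRs, 10³ BH vectors) were chosen to give stable
  Monte-Carlo estimates at interactive runtimes.

## Known limitations

- Dispersion shrinkage has no outlier protection (no Cook's-distance
  analogue); a single wild replicate can inflate a gene's α̂ and cost power.
- The discovery scan is sequence-based; it does not call translated uORFs
  from footprint evidence.
- GTF support covers the transcript-space dialect only (seqname = transcript
  id), not genome-space annotations.
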