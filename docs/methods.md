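# Methods

## Promoter model

A gene's promoter is the window of `window` bp (default 1,000) strictly
upstream of its transcriptional start site; the TSS base itself is
excluded. The TSS is the 5' end of the gene feature (`start` on +, `end`
on −); transcript isoforms and UTRs are not resolved. Sequences are
returned in the gene's own 5'→3' orientation (reverse-complemented for −
strand genes), truncated at contig boundaries and flagged rather than
dropped (a `drop_truncated` switch discards them instead). Soft-masked
lowercase bases are uppercased; `N` is retained and can never match a
k-mer, which is conservative. Windows overlapping neighboring genes are
not masked — no masking rule is defensible without isoform-level data.

Coordinates are 1-based inclusive throughout (GFF3 convention); BED input
is converted on read, so both encodings of an interval are
indistinguishable downstream.

## Motif model and scanning

Motif sets are sets of equal-length DNA words, optionally scored (e.g.
protein-binding-microarray E-scores). Degenerate patterns with bracket
groups (`AAGAT[T/C]TT`) expand by Cartesian product. Scanning is exact
substring matching; every (possibly overlapping) window position counts,
and by default a window also matches the reverse complement of a word,
since double-stranded binding assays do not fix an orientation. A
palindromic word (e.g. `AAGATCTT`, which is its own reverse complement)
counts once per position. Enrichment uses only per-gene *presence*
(count ≥ 1), so the overlapping-occurrence convention cannot affect the
headline statistics. The position-frequency-matrix builder is descriptive
output only; scanning is never threshold-based.

## Resampling enrichment test

Given a universe of M genes of which K carry the motif, a focal set of
size n with presence fraction f_obs, and N resamples (default 1,000):
each resample draws n genes *without replacement* from the full universe
(focal genes are not excluded), and

    p_enriched = #{resamples with fraction > f_obs} / N
    p_depleted = #{resamples with fraction < f_obs} / N

with ties tallied separately, so `p_enriched + p_depleted + ties/N = 1`.
Strict inequalities make the estimator anti-conservative by half the tie
mass; the conservative variant `(r+1)/(N+1)` is reported alongside.
Because presence is a fixed binary attribute, the null hit count is
exactly Hypergeometric(M, K, n); the closed-form tails
(`p_exact_enriched/depleted`) are computed as an independent cross-check
— the Monte-Carlo route samples explicit gene indices (the n smallest of
M uniform keys per resample) and never draws hypergeometric variates.
When several gene sets are tested in one run, Benjamini–Hochberg adjusted
enrichment p-values are appended as a secondary column; raw empirical
values remain primary.

Comparisons are made in hit-count units (f_obs·n) with a 1e-9 guard, so
float division cannot misclassify ties.

### Calibration and its limits

For a focal set that is itself a uniform draw, the empirical p-value is
approximately uniform but sub-uniform by construction: the null count
distribution has point masses, and strict inequalities shift each p-value
down by the local atom. With N = 1,000 the exact probability
P(p_enriched ≤ 0.05) for a null focal set is ≈ 0.056 for any
reasonably wide universe (the continuous-p baseline is (m+1)/(N+1) =
0.051, plus atom/2). The calibration suite therefore uses a universe wide
enough (null count SD ≈ 9.5; M = 4,000, K = 2,000, n = 400) that the
largest atom is ~0.01, keeping the Kolmogorov–Smirnov distance of the
p-value distribution well inside the α = 0.01 critical band at 500
replicates. Narrow universes would fail the uniformity check for reasons
intrinsic to strict-inequality empirical p-values, not implementation
defects.

## nCounter normalization chain

Per lane: (1) background threshold B = mean + 2·sample-SD of the eight
negative-control probes; counts ≤ B are *not detected* — they are never
floored to small positive values, so absence propagates as "nd" codes.
(2) Positive-control scaling s_pos = (across-lane arithmetic mean of
per-lane positive geometric means) / (lane geometric mean); the per-lane
log-log fit of positive counts against the known six-point concentration
ladder is reported as QC (slope, R²) but not used for scaling. (3) The
same geometric-mean construction over the three reference genes, applied
after positive scaling. A normalized value is (raw − B)·s_pos·s_ref when
raw > B.

Per-gene log2 fold change is log2 of the ratio of detected-replicate
condition means (a mean-of-log-ratios alternative is behind a flag).
Genes with no detected treated replicate are coded `nd-treated`, no
detected control replicate `nd-control`, neither `ND`.

Two structural facts about this chain, verified algebraically and by
simulation, shape the tests:

- For endogenous values the positive factor cancels:
  value = corrected · T / gm(refs in lane), with T a cross-lane constant.
  The combined per-lane scale is therefore anchored by the **three
  reference probes alone**, and with multiplicative noise σ = 0.1 a
  single panel determines each lane factor only to ~σ/√3 ≈ 6%. Recovery
  accuracy is accordingly assessed as *systematic* error by averaging
  recovered factors over 10 replicate panels (SE ≈ 1.8%, checked against
  a 5% band); per-panel deviations of ~6% are expected sampling noise,
  not normalization failure.
- Because the cross-lane anchors are means over all lanes, multiplying
  every count in one lane by c rescales *all* normalized values by one
  shared global unit. Detection flags (lane-local) and all fold changes
  are exactly invariant; individual values are invariant only up to that
  common unit, and are tested as such.

## Concordance and overlap

Cross-platform concordance is Pearson r, the least-squares line, R² and
sign concordance over complete pairs. Not-detected codes are excluded by
default; an `nd_policy="zero"` treats them as fold change 0 — both are
offered because published panel R² values are sometimes consistent with
the zero convention, and neither is asserted as canonical.
Non-significant markers ("-") always drop the pair. Direction is the
sign of log2FC; zero fold change carries no direction and joins neither
the same- nor opposite-direction count. Ortholog concordance over
many-to-many maps uses the precedence same > opposite > not-DE per source
gene, with the denominator restricted to source genes having at least one
mapped ortholog.

The package bundles a small published validation dataset
(`data/nanostring_rnaseq_log2fc.tsv`): per-gene log2 fold changes for a
rice cytokinin-response panel measured by both RNA-Seq and NanoString
nCounter in roots and shoots. Its 30 numeric root pairs give Pearson
r = 0.953 with not-detected probes excluded; the desk-check test verifies
this against a sum-formula computation to 1e-12.

## Expression summaries

RPKM = count / ((length/1000) · (library_size/1e6)), with gene length the
annotated expressed-sequence length supplied by the caller and library
size the total mapped reads (not the column sum). A gene is "expressed"
at ≥ 20 reads summed over all samples. `top_share` ranks genes by raw
count (ties broken by gene id for determinism) and reports the read
fraction captured by the top quantile; it is non-decreasing in the
quantile and reaches 1 at quantile 1.

## Synthetic data

Generators are pure functions of (parameters, seed):

- **Toy genomes**: random ACGT contigs; genes on alternating strands in
  slots sized so every promoter window is complete and non-overlapping.
- **Motif planting**: each promoter is first replaced by
  rejection-sampled sequence containing no motif word on either strand,
  then receives one planted occurrence (uniform position, strand, word)
  with probability p1 (focal genes) or p0 (background). Planting
  probabilities are therefore exact, which makes enrichment recovery
  tests sharp. Defaults p0 = 0.22 and p1 = 0.278 mirror the
  presence fractions of the study design the pipeline targets; the
  sequence-free `simulate_hit_universe` plants the per-gene booleans
  directly and is statistically identical, used where the sequence layer
  only adds cost (e.g. 100 repetitions at a 30,000-gene scale).
- **nCounter panels**: counts = round(lane_factor · (background + signal)
  · noise) with log-normal(0, σ) noise per cell and an additive
  nonspecific background common to all probes — the quantity the
  negative controls estimate, which makes the σ = 0, unit-lane-factor
  case exactly invertible. Six positive probes follow a four-fold
  concentration ladder, eight negatives carry background only, three
  references are condition-independent; three treated and three control
  lanes. Endogenous baselines are log-uniform on [500, 4000] counts, lane
  factors log-uniform on [0.7, 1.4] unless supplied.
- **Paired fold changes**: bivariate normal, unit variances, correlation
  ρ (|ρ| = 1 handled as the exact degenerate case).

What the generators do *not* emulate: read-level sequencing error,
GC/composition structure, probe cross-hybridization, cartridge batch
effects, or correlated biological replicates. Passing tests demonstrate
correctness of the computations under the stated model, not robustness
to those real-data phenomena.

## Problem sizes and determinism

The acceptance suite runs the scan oracle on 1,000 random sequences up to
2 kb; the Monte-Carlo/exact comparison at N = 100,000 on a 12-gene
universe and N = 20,000 across a (M, K, n) grid; calibration with 500
replicates of N = 1,000; planted-enrichment detection over 100 runs at
the 30,000-gene / 2,890-set scale; and the end-to-end CLI pipeline on a
10,000-gene preset with 960-gene planted sets (chosen so the planted
0.278-vs-0.22 contrast is detectable by an N = 1,000 test with ~99%
power). Every stochastic step flows from one seed; reruns with identical
manifests are byte-identical.

## Known limitations

- The gene universe for enrichment defaults to all scanned genes; an
  expressed-genes-only universe is a caller decision.
- No GC- or length-matched null models; the resampling null treats genes
  as exchangeable.
- The positive-control "standard curve" is used as a scale anchor; a
  concentration-regression normalization is reported as QC only.
- Exact-match scanning deliberately ignores near-miss binding sites; a
  diverged motif instance counts as absent.
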