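# Methods

This note documents the models, parameter choices and numerical decisions
behind `senatac`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Coordinates and overlap semantics

All intervals are 0-based half-open `[start, end)`. Two intervals overlap
iff they share at least one base; adjacency is not overlap. This "literal
1 bp overlap" rule is used uniformly: peak consensus, cross-condition peak
merging (maximal unions of transitively overlapping intervals, with
membership patterns for Venn counts), region counting, consensus
intersection and volcano labels. GTF-style 1-based inputs must be
converted on read; all emitted BED/bedGraph is half-open as is.

## Peak calling

Single-end reads are extended from their 5′ position to `extsize`
(default 200 bp) and clipped at chromosome ends; reads overlapping a
blacklist interval by ≥1 bp are removed first. The per-base expected rate
is `λ_local = max(λ_genome, λ_10kb)` where `λ_genome` is total tag bases
over the effective genome size and `λ_10kb` the mean pileup in a centred
10 kb window (truncated at chromosome ends). ATAC has no input control, so
a single local window absorbs regional bias; a shorter 1 kb window adds
little on top of the fragment-scale pileup itself and is omitted. Bases
with Poisson upper-tail p below the cutoff (default 1e-5, configurable —
no canonical value exists for this style of caller) are merged into peaks
across gaps ≤ `extsize/2`; peaks narrower than `extsize/2` are dropped;
summit ties break leftmost so calling is deterministic. Reads-in-peaks
(RiP) is reported as a library-quality metric (>10% is the usual bar).
Consensus peaks are peaks supported by ≥ 2 replicates (≥1 bp), merged into
their union span.

## Invariant-gene scaling factors

Counts-per-million comparisons are compositional: if one condition's
transcriptional output shifts, every gene's CPM shifts with it. The
normalization therefore anchors on genes whose expression should not
change: expressed (logCPM strictly above the mean over all genes, with
logCPM = log2((count + 0.5)/(libsize + 1)·1e6) averaged per condition) and
stable (−0.14 < logFC < 0.14, strictly, in every contrast against the
reference). The logFC here is the difference of condition-mean logCPM —
the selection needs only condition-level summaries, not a per-sample GLM
fit. ATAC reads are counted over peaks containing a selected gene's TSS
base within `[start, end)` (strictest reading of "peaks containing TSSs"),
and the factor for condition c is `m_ref / m_c`, the direction that makes
invariant-promoter coverage equal across conditions — the stated intent of
the method. Tracks are replicate-pooled per-base coverage, binned (bin
value = mean per-base coverage × factor), written as bedGraph with equal
adjacent bins merged; bigWig emission is out of scope (text is exactly
testable).

## Exact NB differential test

The count route follows the classic exact-test construction for replicated
counts: TMM factors (M trimmed 30% per tail, A 5% per tail,
precision-weighted mean, factors scaled to geometric mean 1; reference
column = the one whose scaled upper quartile is nearest the mean);
counts mapped to the common (geometric-mean) effective library size by NB
quantile mapping (midpoint CDF at the input mean → quantile at the output
mean; Poisson branch for dispersion < 1e-8); common dispersion maximizing
the conditional log-likelihood over replicates within each group (1-D
bounded search on log φ in [log 1e-6, log 20], tolerance 1e-6, with one
adjust–estimate refinement pass); and a two-sided exact test of the group
totals conditioned on their sum (outcomes no more likely than the observed
split). logFC uses adjusted group means with a 0.5 prior count.
Benjamini–Hochberg gives the FDR; a region is "opened" when fdr < cutoff
and logFC ≥ threshold (default preset 0.05/0.58; strict preset 0.01/0.58
for the combined-condition and co-culture-style contrasts). Two-group
designs only; covariate GLMs and trended dispersion are out of scope.
Validation is by Monte-Carlo calibration (null rejection rate, power at
planted fold changes), not by matching any external tool's output.

Note an identifiability limit exercised by the power validation: when all
regions shift in one direction, count normalization absorbs the shift, so
the Monte-Carlo power design plants direction-balanced fold changes.

## HMM differential segmentation

The second, independent route segments the per-bin difference
`d = asinh(A) − asinh(B)` of two normalized condition tracks (default
100 bp bins) with a 3-state Gaussian HMM: means (+δ, 0, −δ), shared
variance, fixed sticky transitions (0.99 self, 0.005 cross). Only the
emission parameters are re-estimated by EM (≤100 iterations, relative
log-likelihood tolerance 1e-6), with δ initialised at the 90th percentile
of |d| and chromosomes treated as independent sequences sharing
parameters. A variance collapse triggers one jittered restart, then an
error. The Viterbi path is cut into maximal gain/loss runs; each segment
of m bins with mean difference d̄ is scored with the upper-tail normal
p-value of |d̄| under the fitted null (sd σ/√m), and segments below
−log10 p = 10 are dropped. The forward–backward and Viterbi kernels are
JIT-compiled with numba. The asinh transform stabilises count-like
coverage variance while remaining defined at zero.

The consensus differential set keeps count-test calls that overlap a
same-direction HMM segment by ≥1 bp; it is by construction a subset of
each single-method call set. Classification of a region set against
another contrast ("repressed" if overlapping a significantly closed
region, "enhanced" if opened, repressed taking precedence when both)
reports the repressed fraction used for the NOTCH-antagonism analyses.

## Annotation

Enhancers are the merged ≥1 bp intersections of H3K27ac and H3K4me1 peaks
within each baseline condition, unioned over conditions. Each region gets
exactly one category by fixed precedence — promoter_tss (region edge
within 500 bp of a TSS), exon, UTR, CpG island, enhancer, intron, repeat
(with family label), intergenic — because a deterministic single-label
partition is what category barplots need; the precedence is configurable.
Two TSS distances are reported: the signed midpoint distance to the
nearest TSS (negative upstream of the gene) for distance distributions,
and the unsigned region-edge distance for the 500 bp gene-assignment rule
(the permissive reading of "within 500 bp"; a region may map to several
genes). GC% is computed directly from sequence with ambiguous bases
excluded from the denominator. Expression summaries per region class
deduplicate genes (a gene hit by several regions counts once) and use the
population SD.

## Clustering and similarity

Heatmap matrices are track values in (2·flank)/bin bins centred on region
midpoints (defaults ±2.5 kb, 50 bp bins; out-of-genome bins are 0), with
one column block per condition stacked side by side, mirroring
side-by-side condition heatmaps. K-means uses k-means++ with a fixed seed
and best-of-10 restarts; clusters are renumbered by decreasing mean signal
because raw k-means indices are arbitrary. Sample similarity is Pearson
correlation of normalized per-sample counts; the dendrogram is WPGMA
(scipy's "weighted" linkage) on 1 − r, reported in newick with ultrametric
node heights = merge distance / 2; PCA operates on centred log2(count + 1)
(variance stabilization for counts) with explained-variance fractions.

## SAHF imaging

Segmentation follows the particle-analysis recipe: Otsu threshold
(between-class variance maximized over a 256-bin histogram of the
min–max-scaled image; the leftmost maximizer is taken, which matters only
on the exactly-flat plateau across an empty histogram gap where every
split induces the same partition), hole filling, connected components
(8-connectivity default), area window [200, 8000] px and border exclusion.
Measurements (area, mean, SD, max) use the original intensities inside
each mask. SAHF positivity — a manual call at the bench — is scored by an
explicit proxy: foci are components of pixels > mean + 2·SD inside the
nucleus with ≥5 px, and ≥5 foci ⇒ positive. All constants are parameters
and are reported with the output; the proxy can only be validated against
synthetic truth, not against manual scores. Population summaries flag
n < 200 cells (SAHF fractions) and n < 30 nuclei (intensity metrics).

## Cohort statistics

Pearson r with the exact t-test on n−2 df (two-sided), Bonferroni
multiplied by the caller-supplied number of tests (e.g. tumour types
scanned). Stratification is a median split with strict inequalities; ties
fall into "other", and only the two discordant strata are compared.
Kaplan–Meier is the product-limit estimator at event times; the G-rho
statistic weights each event time's observed-minus-expected vector by the
left-continuous pooled KM survival to the power ρ (ρ=0: ordinary
log-rank), with the hypergeometric covariance and a chi-square on k−1 df
(pseudo-inverse for degenerate covariance).

## Synthetic-data generator

The generator defines the package's reference conditions: four conditions
(growing, RIS, NIS, N+RIS; optionally shHMGA1-like designs via custom
condition tuples), three replicates, fragments size-selected 170–400 bp,
background GC 0.50, AT-rich RIS-open regions at GC 0.35.

- **Genome/annotation.** Sequence is i.i.d. per base with region-specific
  GC probability (no dinucleotide structure — sufficient for GC%
  analyses). Planted regions, gene bodies, CpG islands, repeats (family
  labels assigned randomly from LINE/LTR/SINE/simple — structural, not
  biological, fidelity) and decoy histone peaks are laid out
  deterministically on jittered even spacing, ≥3 kb apart and ≥6 kb from
  chromosome ends; overcrowding raises a sizing error. Housekeeping
  promoters each contain exactly one TSS of a gene flagged invariant.
  Histone-mark peaks pad the designated enhancer regions so their joint
  overlap recovers exactly the enhancer truth; decoys carry one mark only.
- **Fragments.** Background fragments are uniform over the genome; each
  planted region receives extra fragments so its density is
  max(enrichment, 1) × background under that sample's condition
  (enrichment 0 therefore leaves background placement untouched).
  Per-sample totals are Poisson around fragments_per_sample × depth
  multiplier. In the combined N+RIS condition, a configurable fraction
  (default 0.6) of RIS-open regions loses its enrichment entirely — the
  planted analogue of NOTCH antagonising RAS-driven opening.
- **RNA-seq.** NB counts (default dispersion 0.005) with invariant genes
  high and tight (lognormal around mean 1000, σ=0.3) and variable genes
  lower (median 150, σ=0.6) carrying |logFC| ≥ 0.5 in at least one
  contrast. Because CPM is relative, each condition's variable genes are
  rescaled so expected output matches the reference, and the common shift
  is folded into the recorded true logFC — without this balance the
  invariant genes' CPM would drift with the library composition and the
  ±0.14 band would be systematically missed. The low default dispersion
  emulates tightly regulated housekeeping expression; analytically,
  sd(logFC) ≈ √(2(1/μ+φ)/n)/ln 2 must stay ≤ ~0.085 for the band to hold
  at 6 replicates.
- **Images.** Elliptical nuclei (radii 16–22 px) on a jittered grid (no
  overlap, no border contact; impossible packings raise an error),
  background 15, nucleus 110, foci 220 on an 8-bit scale, Gaussian noise
  σ=6. SAHF-positive nuclei carry 5–8 disk foci of radius 2 px. The foci
  load must stay a modest fraction of the nucleus for the mean + 2·SD rule
  to sit below the focus intensity (worst case here: ~17% load ⇒ threshold
  ≈ 212 < 220); real SAHF morphology (layered rings) is not modelled, so
  imaging results validate the scoring pipeline, not biological realism.
- **Cohort.** Bivariate normal log2 expression at the target correlation;
  exponential survival with the favourable discordant stratum at hazard
  1/1000 per day, the unfavourable at hazard ratio × that, concordant
  patients at the geometric mean; Koziol–Green censoring (censored with
  the target probability, at a uniform fraction of the event time) gives
  the exact expected censoring fraction with one parameter.

Identical seeds give byte-identical outputs throughout.

## Validation conditions and their limits

The reference validation (tests/test_acceptance.py, scripts/acceptance.py)
uses: a 12 Mb genome with 200 planted RIS-open regions among 2,000
background peaks at enrichment 8 and 10⁶ fragments/sample × 3 replicates
for recovery (sensitivity ≥ 0.9, empirical FDR ≤ 0.1, and in practice
1.0/0.0); depth multipliers {1.0, 0.5, 1.7, 2.0} with 300 invariant
promoters for normalization (≤5% error); 10,000 null NB regions for
calibration and 2,000 direction-balanced regions for power; 300 nuclei at
SAHF fraction 0.4; 500–600-patient cohorts; and a 4-patient hand-checked
log-rank table. These sizes were chosen as the smallest at which the
binomial/Monte-Carlo error of each check is well inside its band.

What passing does **not** show: robustness to Tn5 insertion bias,
nucleosome periodicity, mappability, duplicate reads, GC-dependent
amplification, overlapping nuclei or real SAHF morphology, or cohort
confounding — none of which the generator models. The planted regions are
well separated and homogeneous in length; real peak landscapes are not.
Reported headline fractions from the original biological system depend on
deposited sequencing data and are deliberately not targets here.

## Known limitations

- Two-group differential designs only; no covariates, no tagwise
  dispersion.
- The HMM caller runs on pooled normalized tracks, not per-replicate
  (consistent with using pre-computed normalization factors; replicate
  variance enters through the count route of the consensus).
- `merge_peak_sets` membership assumes each input interval lies inside one
  merged region (guaranteed by construction of merged unions).
- Otsu's threshold is reported at a bin edge; thresholds inside an empty
  histogram gap are equivalent but not unique.
- The library exposes functions, not a CLI; the `examples/` scripts are
  the intended entry points for interactive use.
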