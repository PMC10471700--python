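# Methods

This note documents the models, defaults, and numerical choices behind each
stage, what the synthetic generator does and does not emulate, and the known
limitations.

## Coordinates and annotation

All internal coordinates are 0-based half-open (BED-native); GTF's 1-based
inclusive convention is converted at the parsing boundary.  The TSS is
`start` on the + strand and `end − 1` on the − strand.  Strand affects only
TSS placement — ChIP and bisulfite signals are counted unstranded.  Distance
from a region to a TSS is zero if the TSS lies inside the region and
otherwise is measured from the region edge nearest the TSS (the convention
of common peak annotators; region midpoints would systematically inflate
distances for wide regions).  Genome build labels are opaque metadata; no
liftover is attempted.

## Differential expression

The design of record pools five animals per arm into a single library per
condition, so the default test is exact and conditional: for gene totals
*a* (EDC) and *b* (VEH) with library sizes N_EDC and N_VEH, under the null
*a | a+b ~ Binomial(a+b, N_EDC/(N_EDC+N_VEH))*, and the two-sided p-value
sums the probabilities of all outcomes no more probable than the observed
one (with 1e-7 relative slack against floating-point ties).  With
replicates the test is a likelihood-ratio χ²₁ comparing a shared versus
per-condition negative-binomial mean with library-size offsets at a fixed
dispersion φ (Var = μ + φμ²), default φ = 0.01 (biological CV 0.1, a
conventional value for designs too small to estimate dispersion).  The
group rate MLE is closed-form (the count-weighted rate) when library sizes
are equal and a one-dimensional Brent optimization in log-rate otherwise.
Under a planted null with three replicates per condition the empirical
type-I error at p < 0.05 falls within [0.03, 0.07] (tested).

Fold changes add a 0.5-read pseudocount to both conditions so zero counts
give finite log2 ratios.  The detection filter keeps genes with a summed
count ≥ 10 (configurable; the original analysis reports a detected-gene
universe without stating its rule).  Calls require |log2 FC| ≥ 1 *and*
Benjamini–Hochberg q < 0.05; both cut-offs are strict inequalities on q and
non-strict on the fold change, matching a "twofold with FDR < 0.05" rule.
TMM normalization and empirical-Bayes dispersion shrinkage are deliberately
out of scope.

## Differential H3K4me3 windows

Window counts are tested with the log-likelihood-ratio G-test on the 2×2
table of (window reads, other reads) × condition; cells with zero observed
count contribute nothing to G, and p comes from the χ² distribution with
1 df.  Fold change is computed on reads-per-million with a 0.5-read
pseudocount; direction comes from the fold change and significance from the
G-test, so a significant region must pass both the ≥1.5× and q < 0.01 cuts
in the same direction.  BH adjustment runs across windows with at least one
read in either condition only — untestable windows would dilute the FDR.

Windows are non-overlapping fixed-width tiles (default 1 kb).  The
windowed scan is often run with an overlapping step; with independent
per-window counts an overlapping step only re-tests the same reads, so the
tiled scan plus merging of adjacent same-direction significant windows
gives the same merged regions with one test per read.  Merged regions keep
the extremal fold change and the minimal q among their windows; merging is
idempotent and regions of one direction are pairwise disjoint (tested).

## Chromatin states

Binarization follows the standard emission-segmentation recipe: the
background rate λ is the genome-wide mean count per bin and a bin scores 1
when the Poisson upper tail at its count falls below 1e-4.  The HMM has
Bernoulli emissions (one mark in scope), default four states — a single
mark cannot support the 15+ states of multi-mark consortium maps — and is
fitted by Baum–Welch with five seeded Dirichlet-initialized restarts
(pipeline default two restarts), tolerance 1e-6, and at most 500
iterations.  The recursions use per-step scaling, which is algebraically
identical to log-space recursion and keeps the E-step O(T·S²); EM
log-likelihood monotonicity is asserted in the tests.  States are relabeled
in decreasing emission order, so state 1 ("active-high") is always the most
signal-rich and the last state is "quiescent".  Viterbi decoding resolves
ties toward the lowest state index for determinism.  The segmentation is
fitted on the vehicle track, treating the unexposed epigenome as the
reference partition; this is configurable in code.  Per-state enrichment is
the odds ratio of differential bp inside versus outside the state against
the state's cumulative genomic size, with a 0.5-bp Haldane correction when
any cell is zero; with no differential bp at all the odds ratios are
reported as 0 and flagged undefined rather than invented.

## Methylome

A CpG site is analyzable only with ≥5× coverage in both conditions, and the
per-site difference is delta = EDC − VEH methylation fraction (hypo < 0).
Methylation fractions below 0.1% are reported as zero, mirroring the
variant-frequency floor of amplicon variant calling.  The per-site test is
the two-sided Fisher exact test on meth/unmeth × condition, computed by
conditional hypergeometric enumeration with the probability-mass ordering
definition (tables no more probable than the observed one), with 1e-7
relative slack.

The 10/33/50% thresholds are interpreted as absolute differences in
percentage points — RRBS deltas are conventionally reported that way; a
relative reading would make the threshold depend on the baseline level.
Gene promoter status uses an any-site rule: hypo requires at least one
analyzable promoter site at delta ≤ −T and none at ≥ +T (hyper symmetric,
both ⇒ mixed, otherwise none).  A mean-based rule could not represent the
"mixed directions" category.

Panel summaries call a site hypo (hyper) when the Fisher p < 0.05 and the
delta is negative (positive); the percent-hypo denominator is the full
panel size, reported to one decimal, and missing or under-covered sites are
listed rather than silently dropped.  The cross-site comparison is a
paired Wilcoxon signed-rank test: zero differences dropped, midranks for
ties, exact two-sided p for n ≤ 25 via the rank-sum distribution (computed
by dynamic programming on doubled ranks — identical to enumerating all 2ⁿ
sign patterns, verified against brute force), and a tie-corrected normal
approximation without continuity correction beyond.

The bundled panel definition file `data/erg_panels_synthetic.tsv` carries
the eight ERG promoter panels with their published sizes (Esr1 14, Ar 17,
Pgr 19; the five remaining panels sized so the total is 102 sites);
positions are synthetic placeholders, as the original site coordinates are
only distributed as a spreadsheet supplement.

## Integration

Only genes called up or down enter the concordance tables (the analysis
classifies regulated genes; "ns" genes would otherwise dominate every
denominator).  Expected/opposite/mixed/none categories partition each
direction's gene list, and percentages are recomputed from counts at two
decimals.  A gene's mark status comes from merged significant regions only;
sub-threshold windows never contribute.  Over-representation uses the
hypergeometric upper tail P(X ≥ k) with list and set clipped to the
universe; the Fisher association test builds (up, down) × (mark, no mark).

## The synthetic generator

The generator emulates the study conditions, not raw reads: no FASTQ-level
simulation, bisulfite conversion error, mappability or copy-number
artifacts, input/IgG correction, or isoform structure.  Genes sit on a
regular grid (4-kb bodies every 20 kb on two chromosomes) with alternating
strand; promoters are TSS ± 1 kb — the threshold literature never defines
"promoter" numerically, 1 kb is conventional and configurable.

Defaults define the simulated study: 2000 genes of which 50 are labeled
ERGs, 25% differentially expressed (half up, half down, ties to up) at
|log2 FC| = 1.5; single pooled library per condition at 10⁷ reads with
log-normal (σ = 1.5) base abundances and NB dispersion 0.01; ChIP
background 5 reads per 1-kb window with promoter peaks at 10× background
and a planted EDC/VEH peak ratio of 3 (inverted for reduced promoters);
14 CpGs per promoter (the size of the Esr1 panel) at Poisson 30× coverage,
vehicle levels Beta-distributed around 0.5 with concentration 30, and a
planted methylation delta of ±0.40 — comfortably above the 33-point
calling threshold after clipping to [0, 1], as a planted effect at the
threshold would conflate generator calibration with caller sensitivity.
Cross-layer agreement with the expression direction is drawn per gene at
80% (histone) and 60% (methylation).  Every stage draws from an
independent stream derived from the global seed and a stage tag, so adding
a stage never perturbs another stage's data and identical configurations
are bit-identical.

Because promoters are well-separated, effects are planted symmetrically,
and coverage is uniform, passing recovery tests demonstrates the
correctness of the statistics and plumbing — not performance on real data,
where peak widths vary, CpG density is non-uniform, and layers are
confounded.

## Determinism and output formats

TSVs are tab-separated with mandatory headers and '.' for missing values;
floating-point columns are formatted explicitly so reruns are
byte-identical.  BED scores encode −10·log₁₀(q) capped at 1000.  The
effective configuration is echoed into every output directory.  The JSON
summary uses sorted keys and stable rounding.

## Problem sizes

The bundled tests exercise the default 2000-gene study end to end, a
50,000-bin two-state HMM recovery, and thousand-instance oracle
equivalence sweeps for the exact tests; these sizes were chosen as the
smallest at which the planted-recovery tolerances are dominated by the
statistics rather than sampling noise.

## Known limitations

* The unreplicated exact test conditions on totals and cannot absorb
  biological variability; with real pooled designs its p-values are
  optimistic, as they are for any unreplicated caller.
* The NB likelihood-ratio test uses a fixed, user-supplied dispersion.
* The HMM likelihood surface is multimodal; restarts mitigate but do not
  guarantee the global optimum.
* Chromatin-state counts, binarization cut-off, and the condition used for
  segmentation are conventions, not published parameters.
* Whether the methylation thresholds are percentage-point or relative
  differences is unstated in the source analysis; percentage-point is the
  default and the alternative is a one-line change at the call site.
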