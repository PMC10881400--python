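# Methods

This note documents the models, rules and numerical choices behind
`neuromat`, what its synthetic data emulate, and the limits of what the
passing test suite demonstrates about real data.

## Expression stage

**Preprocessing.** Counts are converted to RPKM,
`RPKM[g,s] = counts[g,s] / (length_kb(g) · total(s)/10⁶)`, to make
replicate libraries comparable. A transcript is "present" when it
reaches 1 RPKM in at least one sample; only present genes enter the
differential tests. For PCA, counts are variance-stabilized as
`log2(count/sizefactor + 1)` with median-of-ratios size factors (the
per-gene reference is the geometric mean over samples, computed over
genes with no zero counts). This is a simple variance-flattening
transform rather than a full mean–variance model; because maturation
scores compare conditions *within one embedding*, only the relative
geometry matters.

**Differential test.** `naive_differential` is a deliberately
transparent stand-in: logFC is the difference of group means of
log2(RPKM+1), the p-value is Welch's unequal-variance t-test on the
same values, FDR is Benjamini–Hochberg over tested genes. Genes with no
variance and equal means in both groups get p = 1. With n = 3
replicates this test has limited power for single-transition contrasts
(raw p cannot fall far below ~0.03 for moderate effects), which is why
strict monotonic calls are rare on simulated data while relaxed calls —
driven by the powerful d100 vs d25 contrast — recover planted trends
well. `classify_monotonic` accepts externally produced tables (columns
gene/comparison/logFC/pvalue/fdr), so count-model differential results
can be dropped in unchanged.

**Monotonic rules.** The strict/relaxed boolean clauses are applied
verbatim per gene (see README); thresholds are inclusive (FDR ≤ 0.05),
fold-change sign tests strict (> 0 fails at 0), and the relaxed rule's
first OR branch is inclusive (≥ / ≤). Genes missing from any required
comparison table are labelled `none` (logged at debug level) rather
than raising, so independently filtered contrasts can be combined. One
asymmetry is inherited as printed: the relaxed "down" rule mirrors the
"up" rule with ≤ in the first OR branch.

**Marker selection** keeps labelled genes with max |logFC| > 1 over the
four contrasts, peak timepoint-mean expression > 5 RPKM and s.e.m. at
d100 strictly < 1 (a boundary value of exactly 1.0 is excluded).

## Trajectory stage

PCA is computed by SVD on gene-centred, variance-stabilized values of
the top-N (default 1000) most variable genes, or of an explicit
DE-derived gene list when one is supplied. Component signs are fixed by
making each component's largest-magnitude gene loading positive, so
embeddings are fully deterministic. The maturation score uses the raw
PC1–3 coordinates without variance weighting; since both the treatment
vector and the control vector live in the same embedding, the score is
invariant to overall rotation and translation of the point cloud, and
linear in the displacement (score(αv) = α·score(v)).

Correlation clustering uses distance 1 − Pearson r with complete
linkage; samples are pre-sorted by label so tie-breaking is
reproducible, and dendrograms export to Newick.

`kmeans_redundancy` grows k from 2, keeping the best of `nstart = 25`
random initializations per k, and stops when clusters become redundant,
returning the previous k. The redundancy rule (not uniquely determined
by the procedure's description) is: any cluster smaller than 1% of rows,
or two centroid profiles with Pearson r > 0.95; both thresholds are
parameters. Note that with only two columns the centroid-correlation
test is degenerate (any two 2-vectors correlate at ±1), so the rule is
meaningful for ≥ 3 conditions — the intended use.

## Calcium stage

**ΔF/F0.** The default baseline F0 is a running 10th percentile over a
30 s window, tracking slow drift while ignoring transients; a global
percentile is available. Under heavy additive noise a low percentile
underestimates F0, which offsets and slightly rescales ΔF/F0 — the
spike detector therefore thresholds *excursions above the trace
median*, not absolute values.

**Spike detection.** The trace is boxcar-smoothed (default 1.0 s,
`smooth_s = 0` disables), then local maxima are kept that exceed the
smoothed-trace median plus `max(min_amplitude, threshold_sd · σ)`,
where σ is the robust noise level (median absolute deviation of the
first-differenced raw trace, scaled by 0.6745·√2 and attenuated by the
boxcar). The same excursion is required as peak *prominence*: this
rejects noise bumps riding the decaying tail of an earlier transient,
which clear an absolute threshold but rise only by the noise scale.
Peaks closer than the refractory period (1 s) merge, keeping the
larger. Reported amplitude is the raw ΔF/F0 maximum within ±(half
smoothing width + 1) frames of the smoothed peak; reported time is that
frame. The 1.0 s boxcar approximates a matched filter for the
simulator's 1.5 s decay kernel; for indicators with much faster
kinetics a shorter window is appropriate.

**Synchrony.** A candidate window of width 0.5 s qualifies when at
least a `participation` fraction (default 0.8; 1.0 reproduces the
literal "all ROIs" reading) of neurons fire inside it; overlapping
qualifying windows merge into one event timed at the median participant
spike (ties: earliest). The rate is 60·events/duration. The rate is
monotone non-increasing in the participation threshold.

**NMDA/AMPA.** The NMDA component is the +40 mV current linearly
interpolated at exactly onset + 20 ms (when AMPA receptors are
desensitized); the AMPA component is the peak |−70 mV| current in the
event; the ratio divides the two. Sampling must be ≤ 1 ms for the 20 ms
read-out to be well-defined.

## Chromatin stage

Atlas construction removes peaks overlapping any blacklist interval,
pools all peak sets and transitively merges peaks whose gap is ≤ 500 bp
("within 500 bp" read inclusively; interval algebra via pyranges, with
a brute-force oracle in the tests). Coordinates are 0-based half-open.
The atlas is idempotent under rebuilding and guarantees same-chromosome
gaps > 500 bp. Depth normalization scales each sample to 10⁷ fragments,
conserving within-sample ratios exactly.

Mark presence per peak/stage uses the replicate-mean normalized signal
against a per-mark threshold — by default 2× the atlas-wide median of
that mark pooled over both stages, overridable per mark (e.g. from a
matched IgG control). This count-level criterion stands in for
read-level peak calling against IgG; users supplying real data should
prefer explicit thresholds. Transition templates: *bivalent_resolving*
(K4me3 ∧ K27me3 in NPC; K27ac ∧ ¬K27me3 in neuron), *active_gaining*
(neither active mark in NPC; K4me3 ∧ K27ac ∧ ¬K27me3 in neuron),
*immature_open* (K4me3 ∧ K27ac in NPC; no active mark in neuron),
*stable* (identical presence pattern at both stages), otherwise
*other*. The templates are mutually exclusive by construction.

Peak→gene annotation assigns intragenic peaks to the overlapped gene;
when several genes overlap, the gene whose strand-aware TSS is nearest
the peak midpoint wins, then lexicographic gene id; intergenic peaks go
to the nearest TSS on the same chromosome (midpoint anchor); peaks on
gene-less chromosomes stay unannotated. Differential peaks (union over
contrasts at FDR ≤ 5%, via the same Welch/BH stand-in on normalized
counts) are z-scored per row and clustered by Ward linkage at a
requested k or by the redundancy-stopped k-means. Cluster×timepoint
expression profiles average the per-gene z-scores (across timepoints)
of each cluster's annotated, differentially expressed genes; flat genes
are excluded with a warning.

## Enrichment stage

For each motif, K carriers among N atlas peaks and k among the n group
peaks give foreground k/n, background K/N, odds ratio fg/bg and the
upper-tail hypergeometric p-value P(X ≥ k) (enrichment only; depletion
is not tested). BH correction is applied across motifs within a group
(the correction scheme is a package choice). The expression filter
keeps motifs with odds ratio ≥ 1.2 (inclusive) whose associated factor
reaches ≥ 1 RPKM at any neuronal timepoint; results rank by descending
odds ratio, then ascending p, then motif id. Raising either threshold
can only shrink the result set. A rank-based (Kolmogorov–Smirnov)
enrichment variant is deliberately not provided: the ranking statistic
such a test would need is underdetermined, and guessing one would
invite misinterpretation.

## Synthetic data: what it emulates, and what it does not

- **Expression**: six timepoints (hPSC, NPC, d25, d50, d75, d100), two
  treatment arms, 3 replicates, negative-binomial counts
  (var = μ + αμ², one shared dispersion α = 0.05) around condition
  means. Planted mono_up genes climb by `effect_log2fc` (default 1) per
  neuronal transition from a base of 2⁶ counts; mono_down genes start
  high (base + 3 effects) and decay to base, which keeps library
  composition balanced across timepoints — without this, RPKM of null
  genes drifts with the planted genes' totals and the empirical FDR of
  any downstream test inflates. Progenitor stages sit at the d25
  baseline. Gene lengths are uniform on 0.5–10 kb. Not emulated:
  per-gene dispersion trends, GC/length biases, isoform switching,
  batch effects.
- **Calcium** (~3 min at 5 frames/s): private Poisson events per ROI
  plus network events with Bernoulli participation; instantaneous rise,
  exponential decay (τ = 1.5 s), truncated-normal amplitudes, Gaussian
  additive noise (an assumption — GCaMP noise statistics are not
  modelled beyond this), baseline 100 AU. Event times are quantized to
  the frame grid so planted amplitudes are exactly representable; an
  optional minimum event gap (default off) makes recovery runs
  separable at the cost of slightly thinning the Poisson process. Not
  emulated: indicator saturation and rise kinetics, bleaching,
  movement artefacts, ROI cross-talk.
- **Chromatin**: 2000 non-overlapping peaks (gaps > 500 bp, so the
  atlas is stable under merging) across two chromosomes; four marks ×
  two stages × two replicates; Poisson counts at `signal_high = 100` or
  `signal_low = 5` per the planted state template, scaled to library
  size (default 10⁷, making normalization the identity). The
  `immature_open` template is simulated as active marks in NPC only —
  which marks define "open" immature chromatin is a package choice.
  `simulate_gene_models` lays a gene body over each peak and assigns
  planted mono_up gene ids to bivalent-resolving peaks at rate 0.9,
  wiring the chromatin and expression truths together for end-to-end
  association tests. Not emulated: peak-width variation, overlapping
  regulatory elements, distal enhancer–gene links, copy-number effects.
- **Motifs**: Bernoulli presence at background rate 0.2, enriched
  groups at min(1, 2.5×0.2); one factor gene per motif.

Passing recovery tests on these data show the *procedures are
implemented correctly and have the expected operating characteristics
under their own assumptions*; they do not certify performance on real
sequencing or imaging data, where the stand-in differential test, the
count-level mark-presence rule and the Gaussian noise model are the
main simplifications to revisit.

## Numerical choices and degenerate inputs

- Seeds: every simulator takes an explicit seed and records it; the
  pipeline derives per-stage seeds from one master seed via
  `numpy.random.SeedSequence`, so a fixed seed yields byte-identical
  summary JSON (timings are written separately).
- NB sampling switches to the exact Poisson limit below α = 10⁻⁸.
- Zero-variance rows/samples: correlation clustering raises naming the
  sample; z-scoring excludes flat genes with a warning; k-means on
  identical rows returns k_min with a degenerate-data warning.
- Welch t on identical groups yields p = 1 via the equal-means rule.
- Hypergeometric p at k = 0 is exactly 1; odds ratio 0/positive-bg is
  0, positive-fg/zero-bg is ∞ (motif absent from atlas).
- PCA pads with zero coordinates when fewer than three informative
  components exist (rank-deficient input).
- Problem sizes for the default study (2000 genes, 30 ROIs × 180 s,
  2000 peaks, 20 motifs) were chosen to give stable recovery statistics
  while keeping a full run in seconds on one CPU.

## Known limitations

- The Welch/BH stand-in is anti-conservative for counts with n = 2–3
  replicates and underpowered for single-transition contrasts; it is a
  scaffold for exercising the rules, not a replacement for a
  count-model test on real data.
- The differential-peak step with two replicates per stage has low
  power; on simulated landscapes most truly differential peaks are
  missed at FDR 5% (the clustering itself is validated separately on
  planted archetypes).
- The spike detector assumes additive noise and a roughly constant
  baseline per 30 s window; rapidly drifting baselines would need a
  shorter window or the global-percentile mode.
- `kmeans_redundancy`'s stopping rule is a heuristic; with few
  conditions (columns) the centroid-correlation criterion saturates.
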