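# Methods

This note documents the models, defaults and numerical choices behind
`semtype`, and what its synthetic data can and cannot demonstrate.

## The analysis model

A cohort of semen samples is profiled by paired-end 16S V4 amplicon
sequencing. After demultiplexing and quality filtering, each read pair is
assigned to a reference 16S sequence; per-sample counts are aggregated at
genus and species rank and converted to proportions, because raw read counts
differ per sample for purely technical reasons. Community structure is then
summarized three ways: (i) *beta diversity* — pairwise weighted UniFrac on a
rooted reference phylogeny, hierarchically clustered into community types;
(ii) *alpha diversity* — Shannon entropy and Chao1 richness per sample; and
(iii) *association* — nonparametric tests linking taxa and community types to
a clinical normal/case dichotomy derived from seven semen-quality criteria.
Finally, a compact decision rule over five marker genera reproduces the
community-type assignment from proportions alone, making the typing usable
in settings where only targeted quantification (e.g. qPCR of a few genera) is
available.

## Read quality control

The Q30 rule is interpreted as *truncate-then-filter*: each mate is truncated
at its first base with Phred quality < `min_quality` (default 30), and the
pair is kept only if both truncated mates are at least `min_length` (default
100) nucleotides and contain no non-ACGT character. This interpretation
satisfies both a per-base truncation reading and a read-retention reading of
the Q30 rule; a mean-quality mode (`mean_quality_mode=True`, no truncation)
is available for comparison. If either mate fails, the pair is discarded,
because the assignment step downstream requires concordant mates. Phred+33
encoding only.

## Taxonomic assignment

Candidate references are found by exact k-mer seeding (k = 15, sampled at
stride k so a read with few errors is guaranteed to seed), then each
candidate is scored by a banded glocal alignment — the read aligned
end-to-end against its best-matching window of the reference, computed with
edlib and band width set by the maximum admissible edit distance. Identity is
1 − edits / read-length; the read length is the denominator deliberately,
since the competing convention (alignment-column denominator) changes
borderline calls. A hit requires identity ≥ 0.97 (inclusive, so a 120-nt read
with 3 substitutions, identity 0.975, passes and one with 4, identity 0.9667,
fails). Both orientations are tried. A pair is assigned only when both mates
hit the same reference; the shared reference with the highest mean mate
identity wins, ties broken by higher minimum mate identity then by
lexicographic sequence id. Deterministic tie-breaking (rather than LCA
promotion) keeps profiles integer-valued and runs exactly reproducible.

## Community typing

**Weighted UniFrac.** Implemented by a single postorder accumulation of
descendant mass per branch: raw distance Σᵢ bᵢ·|Aᵢ − Bᵢ|, normalized by
Σⱼ dⱼ·(pᴬⱼ + pᴮⱼ) with dⱼ the root-to-leaf depth, which bounds the distance
in [0, 1]. The normalized variant is the default (`normalized=False` gives
the raw sum). The implementation is cross-checked in the test suite against
an independent branch-enumeration oracle (dendropy traversal) on 200 random
trees and against scikit-bio's implementation.

**Clustering.** UPGMA (average linkage), chosen over neighbour joining
because cutting the dendrogram into k groups requires ultrametric heights.
Ties on the minimum inter-cluster distance are broken by the
lexicographically smallest pair of cluster labels, so the merge history is
fully deterministic. Cutting into k groups undoes the last k−1 merges, which
always yields exactly k groups.

**Choosing k.** The Calinski–Harabasz pseudo-F is computed for each candidate
k in 2..10 and the argmax taken (ties to the smallest k). Because UniFrac
matrices need not embed exactly in Euclidean space, the statistic is
evaluated on PCoA coordinates restricted to positive-eigenvalue axes
(`pseudo_f_on="distance"` switches to the sums-of-squared-distances form).
Calinski–Harabasz is known to favour very fine partitions when clusters are
nearly point-like (within-cluster dispersion → 0 inflates F at large k);
this regime does not arise at the package's default noise levels.

**PCoA.** Gower double-centering of −D²/2, symmetric eigendecomposition,
axes with eigenvalue > 1e-10 retained and scaled by √eigenvalue, each axis
oriented so its largest-magnitude coordinate is positive (a deterministic
sign convention; eigenvector signs are otherwise arbitrary).

**Alpha diversity.** Shannon entropy uses natural log (nats). Chao1 uses the
bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)) so that cohorts without
doubletons are well-defined; it requires integer counts, not proportions.

## Association statistics

Clinical thresholds (abnormal when): volume ≥ 6.4 or ≤ 1.2 ml; concentration
< 15×10⁶ cells/ml; motility < 40%; Kruger strict morphology ≤ 5%; antisperm
IgA > 30%; atypical (very small sperm heads) ≥ 1%; leukocytes observed
(≥ 10⁶ cells/ml, the WHO peroxidase-stain criterion). A sample with zero
abnormal criteria is *normal*; with at least `min_abnormal_case` (default 2)
it is a *case*; in between it is excluded from supervised comparisons. The
case threshold is a parameter because the source cohort's printed counts
(36 normal + 33 case of 96) are compatible with either a ≥ 2 or a ≥ 3
reading once excluded samples exist.

Differential abundance: taxa with cohort-mean proportion strictly above
0.25% (mean, not per-sample, proportion — the choice is config-exposed) are
tested by a two-sided Mann–Whitney U (exact enumeration when the pooled
sample is ≤ 20 without ties, otherwise tie-corrected normal approximation
with continuity correction). FDR control uses a two-stage adaptive
Benjamini–Hochberg: stage 1 runs BH at α/(1+α); with r₁ rejections the null
count is estimated as m₀ = m − r₁ (m₀ = m when r₁ = 0); stage 2 runs BH at
α·m/m₀. This exact hybrid is composed from two plain BH passes because the
library two-stage variants differ in which stage gets the 1/(1+α) factor.
Adjusted values are the stage-2 BH-adjusted p-values scaled by m₀/m, so
rejection is `q ≤ α`; the adaptive rejection set always contains the plain
BH set at the same α. Significance tiers (0.05/0.01/0.001 on the raw p) are
reported only for taxa that pass the FDR screen.

Fisher's exact test uses the minimum-likelihood two-sided convention (sum of
hypergeometric probabilities ≤ that of the observed table), which reproduces
the published group-enrichment p-values from the published counts; the odds
ratio gets a 0.5 Haldane–Anscombe correction iff a cell is zero. Co-occurrence
networks connect genera with |Spearman ρ| strictly greater than 0.4
(average-rank ties); CASA metrics are associated with taxa by Spearman
correlation under the same abundance filter and FDR procedure, a correlation
(rather than dichotomized-test) design chosen because the metrics are
continuous kinematic/morphometric measurements.

## Rule classifier

Features per sample: the proportions of the five marker genera, all 20
ordered pairwise ratios, each genus against the sum of the other four, and
the composite Lactobacillus/(Prevotella+Pseudomonas+Haemophilus) — 31
features, a superset guaranteed to represent the published rule. Ratios with
a zero denominator are encoded as a large sentinel (10⁹) and flagged rather
than dropping the sample, since absence of a genus is biologically
meaningful; a sentinel behaves correctly under threshold splits ("ratio very
large"). The tree learner is C4.5-flavoured: candidate thresholds are
midpoints of consecutive distinct sorted values, splits are scored by gain
ratio among candidates whose information gain is at least the node's average
positive gain (the C4.5 safeguard against trivial high-ratio splits), ties
break by lower feature index then lower threshold, and leaves keep class
frequencies used as prediction scores. The original J48 pruning heuristics
are not reproduced; minimum leaf size (default 2) and an optional depth cap
control complexity. Cross-validation is stratified with a fixed seed and
one-vs-rest ROC AUC is computed on scores pooled across test folds
(pooling, not per-fold averaging).

## Synthetic cohort

The generator replaces the unavailable clinical dataset and defines the
study conditions the tests run under.

* **Reference.** 14 genera × 2 species, 250-nt sequences. Genus ancestors are
  independent random sequences; species diverge from their ancestor by ~2.5%
  substitutions, so all cross-species identities stay below the 97% mapping
  ceiling (verified exhaustively at build time, with bounded retries) while
  reads at the default 0.5% error rate map back above it. The phylogeny
  groups species of a genus as a clade (species branches 0.024
  substitutions/site, genus stems 0.35), so between-genus differences
  dominate UniFrac, as they do on a real 16S tree.
* **Community types.** Three types with Dirichlet-distributed genus
  compositions (precision 25 — visible overlap between types but separable
  structure). The predominant-genus means are fixed at the published values
  (Pseudomonas 16.1% for G1, Lactobacillus 32.3% for G2, Prevotella 26.3%
  for G3); the secondary structure follows each type's published
  co-occurrence description (Enterobacter/Rhodanobacter/Corynebacterium with
  G1; Gardnerella/Atopobium/Propionibacterium with G2;
  Propionibacterium/Dietzia with G3), and the 25/55/16 weighting reproduces
  the cohort-wide means (e.g. Lactobacillus 19.9%, Pseudomonas 9.7%,
  Prevotella 7.8%). Within-genus species splits are fixed (∝ 1/rank).
* **Reads.** Default 5,000 pairs/sample — a desk-scale stand-in for the tens
  of thousands of reads per participant in a real MiSeq run; read length 150
  nt from opposite amplicon ends; i.i.d. substitution errors (default 0.5%);
  per-base qualities from a two-state model (good Q38, absorbing bad Q15)
  with hazard 10⁻⁴ early and 0.02 beyond position 110, so Q30 truncation is
  exercised while >95% of pairs survive default QC. No chimeras, PCR
  duplicates, indels, or length variation.
* **Clinical records.** A sample is fully normal with the type's planted
  probability (0.20 / 0.527 / 0.125 for G1/G2/G3); otherwise 2 + Poisson(0.8)
  criteria (capped at 7) are drawn abnormal, so every non-normal sample is a
  case under the default rule. Raw values are uniform within flag-consistent
  ranges, since only the thresholds, not the value distributions, are
  specified by the study design. CASA metrics are Gaussian around textbook
  values; head elongation carries a planted monotone dependence on the
  sample's Lactobacillus proportion (slope 0.6, noise SD 0.08), giving the
  CASA association test a recoverable signal.
* **Seeding.** One master seed is fanned out via `numpy.random.SeedSequence`
  (reference, barcodes, then one stream per sample), so cohorts are
  byte-identical per seed and stages are individually reproducible.

**What passing tests show — and don't.** Recovery of the planted three types
(ARI ≥ 0.9), of the planted 2× case-enrichment (≥ 80% of replicates), and of
the planted decision rule demonstrates that the pipeline's inference is
correct *under its own generative assumptions*: Dirichlet compositional
noise, substitution-only errors, a small balanced reference, and a clean
genus-clade tree. Real 16S data violate several of these (chimeras,
copy-number variation, database incompleteness, non-clade-like reference
trees, compositional effects of unobserved taxa), so synthetic performance
bounds, but does not estimate, real-world performance.

## Problem sizes and runtime defaults

The default cohort is 96 samples (25/55/16) at 5,000 read pairs per sample;
a full pipeline run takes about a minute on one CPU. Power and calibration
studies run at the profile level (no read simulation): 50 replicates for
planted-signal power, 200 for null calibration. The UniFrac oracle suite uses
200 random trees of up to 8 leaves, where exhaustive branch enumeration is
cheap.

## Known limitations

* UPGMA and pseudo-F inherit the usual failure modes of centroid-style
  criteria: outlier samples can claim singleton clusters, and very tight
  clusters inflate F at large k.
* The Mann–Whitney exact path is limited to pooled n ≤ 20 without ties;
  beyond that the normal approximation is used even when an exact test would
  be feasible.
* The gain-ratio tree does not reproduce J48's pruning, missing-value
  handling, or subtree raising; learned trees can differ from Weka's on the
  same data even when the decision regions agree.
* The taxonomic assigner is a reference-window mapper, not a full aligner:
  indel-heavy reads (absent from the generator) would be penalized through
  edit distance rather than realigned.
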