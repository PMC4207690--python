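# semtype

**Seminal-microbiome community typing and semen-quality association analysis.**

Bacteria in semen are a suspected contributor to male-factor infertility, but
culture- and PCR-based assays only see a handful of species. `semtype`
reimplements, as a tested Python package, a whole-community 16S V4 amplicon
analysis of semen samples: from paired-end reads to taxonomic profiles,
phylogeny-aware community types, and statistical associations with clinical
semen quality. It is aimed at bioinformaticians who want a reproducible,
end-to-end reference implementation of this analysis style — including a fully
synthetic cohort generator, so every result in the test suite is computable
without access to clinical data.

## What it computes

1. **Read QC** (`semtype.readqc`) — demultiplexing by barcode, 3′ truncation
   at the first base below Q30, discarding of reads shorter than 100 nt or
   containing ambiguous characters.
2. **Taxonomic profiles** (`semtype.taxprof`) — read pairs map to a 16S
   reference when alignment identity ≥ 97% *and* both mates agree on the
   reference; counts aggregate to genus/species proportion matrices.
3. **Community types** (`semtype.commtype`) — pairwise weighted UniFrac

   $$d_{WU}(A,B) = \frac{\sum_i b_i\,|A_i - B_i|}{\sum_j d_j\,(p^A_j + p^B_j)}$$

   (branch length $b_i$, fraction of each community descending through branch
   $i$, root-to-leaf depth $d_j$), UPGMA clustering, and selection of the
   number of community types $k$ by the Calinski–Harabasz pseudo-F

   $$F = \frac{(\mathrm{TSS}-\mathrm{WSS})/(k-1)}{\mathrm{WSS}/(n-k)}$$

   on principal-coordinate embeddings; Shannon and bias-corrected Chao1 alpha
   diversity; PCoA.
4. **Association statistics** (`semtype.assoc`) — seven clinical criteria
   (volume, concentration, motility, Kruger morphology, IgA, atypical heads,
   leukocytes) flagged against reference thresholds; samples with 0 abnormal
   criteria are *normal*, with ≥ 2 are *cases*; per-taxon Mann–Whitney tests
   behind a 0.25% mean-abundance filter with two-stage adaptive
   Benjamini–Hochberg FDR control; Fisher exact tests with odds ratios for
   group enrichment; Spearman co-occurrence networks (|ρ| > 0.4).
5. **Rule classifier** (`semtype.ruleclf`) — community type predicted from
   five marker genera (*Lactobacillus*, *Gardnerella*, *Prevotella*,
   *Pseudomonas*, *Haemophilus*) via ratio features. Ships both the fixed
   published two-step rule — Lactobacillus/(Prevotella+Pseudomonas+Haemophilus)
   > 0.57 ⇒ G2, else Prevotella/Pseudomonas > 1.37 ⇒ G3, else G1 — and a
   C4.5-style gain-ratio decision tree that can relearn it, evaluated by
   stratified 5-fold CV with one-vs-rest ROC AUC.
6. **Synthetic cohorts** (`semtype.syndata`) — a self-contained generator
   (reference sequences + phylogeny, Dirichlet compositions around three
   community-type means, error-bearing paired reads with realistic Phred
   decay, clinical records whose abnormality rates depend on community type)
   that stands in for the original 96-sample cohort.

`CommunityTyper`, `GainRatioTreeClassifier` and `FixedRuleClassifier` are
scikit-learn estimators and compose with sklearn model selection.

## Worked example

```python
import warnings
from semtype import pipeline, syndata, ruleclf

cfg = pipeline.PipelineConfig(
    cohort=syndata.CohortConfig(group_sizes={"G1": 8, "G2": 18, "G3": 6},
                                n_pairs_per_sample=1000),
    seed=7,
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = pipeline.run(cfg)          # simulate -> qc -> profile -> cluster -> assoc -> classify

print("community types:", report.typing["group_sizes"])
print("normal fraction per group:",
      {g: round(f, 3) for g, f in report.typing["normal_fraction"].items()})
print("ARI vs planted types:", round(report.ari_vs_truth, 3))
print("cross-validated AUC:", {g: round(a, 3) for g, a in report.classifier["auc"].items()})

sample = {"Lactobacillus": 0.60, "Prevotella": 0.10,
          "Pseudomonas": 0.10, "Haemophilus": 0.10}
print("fixed rule:", ruleclf.fixed_rule_classify(sample))
```

prints

```
community types: {'G1': 8, 'G2': 18, 'G3': 6}
normal fraction per group: {'G1': 0.625, 'G2': 0.556, 'G3': 0.0}
ARI vs planted types: 1.0
cross-validated AUC: {'G1': 0.979, 'G2': 1.0, 'G3': 0.917}
fixed rule: G2
```

The pseudo-F criterion selected three community types and the cut recovered
the planted type of every sample (adjusted Rand index 1.0). The
Lactobacillus-dominated group (18 samples) retains a high fraction of
clinically normal samples while the Prevotella-dominated group has none, the
pattern the clinical coupling plants. The composite ratio for the example
sample is 0.6/0.3 = 2.0 > 0.57, so the fixed rule assigns the
Lactobacillus-predominant type G2.

The same stages are exposed on the command line:

```bash
semtype run --seed 1 --outdir out/          # full pipeline, writes out/report.json
semtype simulate --seed 1 --outdir cohort/  # just the synthetic cohort
semtype qc --r1 R1.fastq --r2 R2.fastq --barcodes barcodes.tsv --out qc/
```

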