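# rfsubtype

Severity-subtype discovery for case/control clinical cohorts, with
multi-omic biomarker validation of the subtypes.

## The problem and the method

Psychiatric disorders such as military-related PTSD are heterogeneous:
cases meeting one diagnosis can differ widely in symptom profile and
severity, and subgroups may have distinct biological correlates. This
package implements a stratification pipeline for a discovery cohort of
diagnosed cases and healthy controls (HC) assessed on the individual items
of a battery of clinical scales (a CAPS-like clinician severity scale plus
self-report instruments) and profiled on a panel of blood-based multi-omic
biomarkers (methylation, miRNA, metabolites, proteins, endocrine and
routine-lab measures):

1. **Forest distance.** A bootstrap ensemble of classification trees
   (random forest, default 4000 trees) is grown to classify cases vs HC on
   the clinical items. The *proximity* of two subjects is the fraction of
   trees in which they fall in the same terminal node; `1 - proximity` is
   a dissimilarity tuned to the clinical distinctions the forest learned.
2. **PAM subtyping.** Partitioning around medoids (deterministic
   multi-start BUILD + best-improvement SWAP) clusters the cases on this
   distance, `k = 2` by default. Clusters are named S1/S2 in order of mean
   severity-scale total. Internal validation: silhouettes (with HC kept as
   a third group) and a 2-D diffusion-map / classical-MDS embedding;
   external validation: the case-vs-HC forest is scored on a held-out
   validation cohort (all-tree vote fraction, AUC-ROC).
3. **Clinical profiling.** Summary scales are compared across HC/S1/S2
   with one-way ANOVA and pairwise Wilcoxon rank-sum tests under a
   family-wise threshold (default p < 1e-4), plus a PCA of the summary
   scales whose first component acts as a one-number severity index.
4. **Biomarker classification with shaving.** For each intergroup contrast
   (S1 vs HC, S2 vs HC, S2 vs S1, cases vs HC) and each feature class, a
   forest is grown and iteratively *shaved*: the least Gini-important
   features are dropped, the forest refit, and the smallest feature set
   whose out-of-bag (OOB) AUC is within a tolerance of the best AUC is
   selected. The reported AUC comes from an independent refit on the
   selected set. Top markers per contrast get Welch-t mean-difference
   tests under a Bonferroni threshold (`alpha / #tests`, e.g. 0.05/20 =
   0.0025) and up/down direction-of-dysregulation calls in the more severe
   group.
5. **Panel comparison.** Canonical correlation analysis (whitening + SVD
   of the cross-covariance) compares two marker panels after removing
   their overlap.

Because cohorts of this kind are not publicly depositable, the package
ships a first-class synthetic cohort generator (`rfsubtype.synthetic`)
whose defaults emulate the study-scale structure: 71/74 discovery HC/cases
with planted subtypes of 26 and 48 cases, a 36/26 validation sample,
graded-response ordinal items on 16 scales driven by a latent severity
factor, 342 biomarkers with a minority of graded group shifts (mostly
down-regulated with severity, a lactate-like up-regulated minority), and
five weaker auxiliary feature classes.

## Worked example

```python
from rfsubtype import CohortConfig, generate_cohort, discover_subtypes
from sklearn.metrics import adjusted_rand_score

cohort = generate_cohort(CohortConfig(seed=0))
result = discover_subtypes(cohort, n_trees=500, seed=42)

print(result.labels.value_counts().sort_index().to_dict())
print({g: round(s, 2) for g, s in result.cluster_mean_silhouettes.items()})
truth = cohort.subjects.loc[result.labels.index, "true_subtype"]
print(round(adjusted_rand_score(truth, result.labels), 2))
```

prints

```
{'S1': 26, 'S2': 48}
{'HC': 1.0, 'S1': 0.76, 'S2': 0.55}
1.0
```

that is: the two planted case subtypes are recovered exactly (26 mild, 48
severe; adjusted Rand index 1.0 against the generator's ground truth), the
HC group is maximally coherent under the forest distance, and the severe
subtype is the tighter of the two case clusters.

The same analysis from the shell:

```bash
rfsubtype simulate --seed 0 --out cohort
rfsubtype subtype --in cohort --trees 500 --seed 42 --out run1
rfsubtype run-all --seed 0 --out runs/full     # entire pipeline + manifest
rfsubtype report --run runs/full
```

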