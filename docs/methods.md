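# Methods

This note documents the models, numerical choices and design decisions
behind `rfsubtype`, and what the synthetic-data tests do and do not show
about real cohorts.

## Random-forest engine

Trees are grown one at a time on n-out-of-n bootstrap samples with the
in-bag count of every subject in every tree stored explicitly, so all
out-of-bag (OOB) quantities are exactly reproducible and auditable by
brute-force recounts. Defaults follow classical random-forest practice:
`max_features = sqrt(p)` candidate features per split, unlimited depth,
minimum leaf size 1, Gini impurity. Ties in a leaf's class vote go to the
negative class, deterministically. A subject's OOB score is the fraction
of positive votes among trees where it is out-of-bag; subjects in-bag in
every tree are flagged `NaN` rather than silently scored, and an OOB AUC
request fails loudly in that case (at the pipeline's 4000 trees the
probability of an unscored subject is negligible; the fit itself refuses
to return a forest with an unscorable subject once `n_trees >= 50`).

AUC is computed by the tie-aware Mann–Whitney identity
`(concordant + 0.5 * tied) / (n_pos * n_neg)` via midranks; the stored ROC
curve uses every distinct score as a threshold, so the trapezoidal area
equals the rank formula to machine precision and no threshold-grid
dependence enters. Gini importance is the mean over trees of the
sample-weighted impurity decrease summed over the nodes splitting on the
feature (identical ranking to the classical unnormalized decrease since
every bootstrap has n samples).

Proximity is terminal-node co-occupancy. Two modes: `all_trees` (the
classical definition; the default) and `oob_pairs` (numerator and
denominator restricted to trees where both subjects are out-of-bag; pairs
with no qualifying tree are flagged, and are an error at >= 1000 trees).

## Subtype discovery

The case-only dissimilarity is `1 - proximity` from a case-vs-HC forest
grown on clinical items. Two deliberate choices:

- **Small mtry for the subtyping forest (default 2).** With
  `sqrt(p) ~ 13` candidate features per split, virtually every node finds
  one of the strongly case-separating items; cases are purified into a
  single terminal node within two or three splits and the case-case
  proximity saturates at ~1, leaving the clustering nothing to work with
  (we verified that exhaustive-search PAM also collapses to a 73/1 split
  in that regime, so it is a property of the distance, not the
  optimizer). Restricting each split to 2 candidates forces trees to also
  use items that cut the case group by severity, which is exactly the
  structure PAM consumes. The choice is recorded in the fitted forest's
  hyperparameters. The classification forests elsewhere in the pipeline
  keep the classical sqrt default.
- **Deterministic multi-start PAM.** Single-start BUILD+SWAP (including
  the canonical R reference implementation) stalls in a local optimum on
  roughly 8% of small random instances. `pam()` therefore restarts the
  greedy BUILD completion + best-improvement SWAP descent from every
  point as the forced first medoid and keeps the lowest-cost solution:
  still a deterministic PAM-family heuristic — no enumeration of medoid
  subsets — but it matched the exhaustive optimum on 1000/1000 random
  n <= 10 instances and costs well under a second at n = 74. Assignment
  ties go to the lowest-index medoid; the SWAP loop asserts that cost
  never increases.

Clusters are named S1, S2, ... by ascending mean severity-scale total
(identified in the feature metadata), never by size. Silhouettes use the
textbook `(b - a) / max(a, b)` with the singleton convention `s = 0` and
are reported over the full discovery cohort with HC as its own group,
under the same forest distance — whether the original analysis used the
joint distance for the HC silhouette is unknown; this choice is recorded
here as an assumption. Embeddings: classical MDS (double-centered Gram
eigendecomposition) or a diffusion map (Gaussian kernel with bandwidth =
median off-diagonal distance, symmetrically normalized Markov operator,
top two nontrivial eigenvectors scaled by eigenvalues); axis signs are
fixed by making the largest-magnitude coordinate positive.

## Feature shaving and its reporting

Each round removes `max(1, floor(drop_fraction * set size))` least
important features (importance recomputed that round; ties broken by
current column order), down to `min_features`, with the per-round seed
offset from the base seed so any round can be reproduced in isolation.
The selected round is the smallest feature set whose OOB AUC is within
`auc_tolerance` (default 0.005) of the trace maximum; ties on size go to
the higher AUC, then the later round.

Because "max AUC over rounds" has a winner's curse, the headline AUC of a
selected model (in `classify_contrast`) is recomputed by an independent
refit — a fresh forest with a different bootstrap seed grown on the
selected features only. This removes the optimism of the winning round's
own luck; it cannot remove the bias from having selected features on the
same data (no nested resampling is used, matching the OOB-only validation
design). Consequently, on pure-noise data the selected-set AUC is centered
above 0.5 — about 0.55-0.60 at n = 400 with 12 candidate features, and
substantially higher when many candidate features are shaved on few
subjects. The leakage-guard test is therefore run at n = 400, p = 12,
where a correct implementation sits well inside [0.35, 0.65] while an
in-sample evaluation bug would still score near 1. Null OOB AUCs are
slightly pessimistic (a known bootstrap artifact), so per-seed null checks
assert the upper band and the mean-centering property.

## Clinical profiling

- Wilcoxon rank-sum: exact enumeration when both groups have <= 25
  subjects and no ties, otherwise the tie-corrected, continuity-corrected
  normal approximation.
- ANOVA on values constant in every group is reported "untestable" rather
  than NaN-propagated.
- Summary-statistic t tests default to the pooled-variance form (the
  two-group ANOVA equivalent); Welch with Satterthwaite df is available.
- Chi-square on 2x2 tables is Pearson without continuity correction; zero
  margins are an error.
- PCA standardizes variables and decomposes the correlation matrix; PC1's
  sign is oriented so it correlates positively with the severity-scale
  total. The family-wise threshold is a configurable hard cutoff (default
  1e-4) rather than an explicit m-dependent divisor, since the reported
  design states the threshold itself.
- Marker mean tests default to Welch t (robust to the unequal group
  variances the generator plants); the Bonferroni divisor is the number
  of (marker, contrast) tests actually performed in the run, which
  reproduces 0.0025 under the default top-5 x 4-contrast layout.
  Direction calls (up/down in the more severe group, severity order
  HC < S1 < cases-pooled < S2) are made only below the corrected
  threshold.

## Canonical correlation

Columns are standardized; each block is reduced to an orthonormal basis by
SVD with rank truncation at `max(n, p) * eps * s_max` (effective ranks are
recorded), and the canonical correlations are the singular values of the
product of the two bases. This is the numerically stable whitening route;
successive variates are exactly uncorrelated by construction, correlations
are clipped to [0, 1], and the weights are returned on the standardized
scale. Panel comparison removes the intersection of the two panels before
the CCA and errors if either side's non-overlap is empty.

## Synthetic cohort generator

The generator defines the study conditions the pipeline is tested under.

- **Design.** One latent severity factor z per subject: HC ~ N(-0.6,
  0.10), planted case subtypes ~ N(1.45, 0.10) and N(3.6, 0.10), with the
  case split 26/48 by largest-remainder apportionment of proportions
  (0.35, 0.65) over 74 discovery cases. The validation sample (36 HC / 26
  cases) is drawn from the same distributions with its own seed stream.
- **Items.** 16 scales (a 17-item 0-8 severity scale; fifteen 10-item 0-4
  scales). Item j scores `clip(round(b_j (z - d_j) + e), 0, max)` with
  noise sd 0.8. Difficulties d_j are bimodal: half the items are "easy"
  (d ~ U(-0.5, 0.8), discrimination 4.6 x U(0.7, 1.3) scaled by item
  range) — any case endorses them and severe cases saturate the ceiling,
  as on real instruments; half are "hard". The severity scale's hard
  items sit in the severe tail (d ~ U(3.4, 4.5)) so its group totals land
  at ~0.1 / ~54 / ~73 against the clinical targets 3.37 / 54.31 / 75.60
  (calibrated once by Monte Carlo); the other scales' hard items sit
  inside the subtype gap (d ~ U(2.3, 3.4), discrimination 2.4) — these
  in-gap items are what lets case-vs-HC trees split the case region by
  severity. Without difficulty structure (a flat affine item model) the
  case side of every tree is purified immediately and no parameterization
  we tried yields recoverable subtypes.
- **Biomarkers.** 342 markers across seven subclasses with equicorrelated
  within-subclass residuals (rho = 0.3, unit variance). 40 informative
  markers (allocated to subclasses proportionally) carry graded shifts:
  0 for HC, half effect for S1, full effect (Cohen's d = 1.0) for S2;
  90% down-regulated with severity, with at least one up-regulated
  metabolite (lactate-like). Auxiliary classes (comorbidity,
  neurocognitive, demographic, psychiatric history, pre-military trauma)
  are generated analogously with class-specific effect sizes (0.3, 0.5,
  0.1, 0.8, 0.3; neurocognitive decreases with severity) on half their
  features.
- **What it does not emulate.** No missing data (complete-case input is
  required; the pipeline's median-impute flag is deliberately absent),
  no demographic confounding, no assay-specific noise models, no
  genotype-like allele structure, and only a single severity factor —
  real instruments have scale-specific factors and the real biomarker
  covariance is far richer than equicorrelation. Passing tests therefore
  demonstrate that the pipeline recovers structure of this planted kind
  at study scale, not that it would resolve subtypes in any particular
  real cohort.

## Pipeline

`run_all` executes simulate -> subtype discovery -> external scoring ->
profiling -> per-contrast x per-class classification (+ pooled) -> marker
direction tests -> panel CCA, with per-stage seeds at fixed offsets from
the global seed, and writes a manifest with the full configuration and
SHA-256 checksums of every artifact; reruns with the same seed are
byte-identical. `report` renders from stored artifacts only (checksums
verified first, no recomputation, idempotent). Default scale is 4000
trees; tests and the acceptance script run at 120-500 trees, which leaves
every qualitative behavior intact while keeping desk-scale runtimes
(subtype recovery is already exact at 500 trees on the default cohort).

## Problem sizes used in tests

Oracle and property tests run at n <= 30 subjects / <= 50 trees
(proximity), n <= 30 score vectors (AUC), n <= 10 (PAM vs enumeration).
Recovery tests use the full study-scale cohort (145 discovery subjects,
500 trees, 10 seeds). The shaving recovery test uses the 2-informative +
48-noise design at n = 120; its leakage guard runs at n = 400, p = 12 as
discussed above. The end-to-end determinism check runs a reduced
configuration (120 trees, three biomarker subclasses, two feature
classes) twice and compares all artifact checksums.
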