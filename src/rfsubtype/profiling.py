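"""Clinical profiling of subtypes: PCA, ANOVA, rank-sum, chi-square tests.

Reproduces the machinery of the cohort-description and subtype-comparison
tables: per-scale group means with an omnibus one-way ANOVA across
HC/S1/S2 and pairwise Wilcoxon rank-sum tests, two-sample t tests from
printed summary statistics, Pearson chi-square tests on 2x2 count tables,
and a PCA of the clinical summary scales whose first component serves as a
one-number severity index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rfsubtype.synthetic import CLASS_CLINICAL_SUMMARY, AUX_CLASSES, CohortTable
from rfsubtype.subtypes import SubtypeResult

PAIRWISE_CONTRASTS = (("S1", "HC"), ("S2", "HC"), ("S2", "S1"))


@dataclass
class PcaResult:
    loadings: pd.DataFrame          # variables x components
    variance_fractions: np.ndarray  # non-increasing, sums to 1
    scores: pd.DataFrame            # subjects x components, PC1 severity-oriented


@dataclass
class GroupComparisonReport:
    table: pd.DataFrame
    threshold: float


def pca_summary(scores: pd.DataFrame, severity=None) -> PcaResult:
    """PCA of z-scored summary scales (eigendecomposition of the correlation
    matrix). PC1's sign is chosen so it correlates positively with
    ``severity`` (a Series/array, a column name, or by default the first
    column)."""
    if scores.shape[1] < 2:
        raise ValueError("PCA needs at least 2 variables")
    sd = scores.std(ddof=1)
    dead = sd.index[sd == 0]
    if len(dead):
        raise ValueError(f"zero-variance variable: {dead[0]!r}")
    Z = (scores - scores.mean()) / sd
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = np.maximum(w[order], 0.0), V[:, order]
    fractions = w / w.sum()
    comp_scores = Z.to_numpy() @ V

    if severity is None:
        sev = scores.iloc[:, 0].to_numpy()
    elif isinstance(severity, str):
        sev = scores[severity].to_numpy()
    else:
        sev = np.asarray(severity, dtype=float)
    if np.corrcoef(comp_scores[:, 0], sev)[0, 1] < 0:
        V[:, 0] = -V[:, 0]
        comp_scores[:, 0] = -comp_scores[:, 0]

    names = [f"PC{i + 1}" for i in range(V.shape[1])]
    return PcaResult(
        loadings=pd.DataFrame(V, index=scores.columns, columns=names),
        variance_fractions=fractions,
        scores=pd.DataFrame(comp_scores, index=scores.index, columns=names),
    )


def _wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Rank-sum test: exact when both groups are small and tie-free,
    otherwise the tie-corrected, continuity-corrected normal approximation."""
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    small = max(len(x), len(y)) <= 25
    method = "exact" if (small and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def omnibus_and_pairwise(values, groups, contrasts=PAIRWISE_CONTRASTS) -> dict:
    """One-way ANOVA across groups plus pairwise Wilcoxon rank-sum tests.

    Returns a flat record with per-group mean/sd, the omnibus F and p, and
    one (statistic, p) pair per contrast. Constant values in every group
    make the ANOVA undefined (NaN, flagged 'untestable')."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = sorted(set(groups.tolist()))
    samples = {g: values[groups == g] for g in names}
    if any(len(s) < 2 for s in samples.values()):
        raise ValueError("need at least 2 subjects per group")
    row: dict = {}
    for g in names:
        row[f"mean_{g}"] = float(samples[g].mean())
        row[f"sd_{g}"] = float(samples[g].std(ddof=1))
    if all(np.ptp(s) == 0 for s in samples.values()):
        row.update(F=np.nan, p_omnibus=np.nan, untestable=True)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            F, p = stats.f_oneway(*[samples[g] for g in names])
        # identical group means with within-group variance -> F = 0, p = 1
        row.update(F=float(F), p_omnibus=float(p), untestable=False)
    for a, b in contrasts:
        if a in samples and b in samples:
            u, p = _wilcoxon_rank_sum(samples[a], samples[b])
            row[f"W_{a}_vs_{b}"] = u
            row[f"p_{a}_vs_{b}"] = p
    return row


def t_test_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int, variant: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sample t test from summary statistics; returns (t, df, p)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]])
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), 1, float(p)


def profile_subtypes(
    cohort: CohortTable,
    subtype_result: SubtypeResult,
    alpha_family: float = 1e-4,
):
    """Full subtype profile: summary-scale comparisons, PCA, aux comparison.

    Returns (GroupComparisonReport over summary scales + PC1, PcaResult,
    S1-vs-S2 comparison of auxiliary features). The family-wise threshold is
    a configurable hard cutoff applied to every p in the summary report.
    """
    disc = cohort.subset(role="discovery")
    summary_ids = disc.feature_ids(CLASS_CLINICAL_SUMMARY)
    if not summary_ids:
        raise ValueError("cohort has no clinical summary scales")
    labels = subtype_result.labels
    group3 = np.array(
        [labels[s] if s in labels.index else "HC" for s in disc.subjects.index]
    )

    pca = pca_summary(disc.values[summary_ids], severity=disc.values[disc.severity_total_id])

    rows = {}
    pc1 = pca.scores["PC1"].to_numpy()
    rows["PC1"] = omnibus_and_pairwise(pc1, group3)
    for fid in summary_ids:
        rows[fid] = omnibus_and_pairwise(disc.values[fid].to_numpy(), group3)
    table = pd.DataFrame.from_dict(rows, orient="index")
    for col in [c for c in table.columns if c.startswith("p_")]:
        table[f"sig_{col[2:]}"] = table[col] < alpha_family
    report = GroupComparisonReport(table=table, threshold=alpha_family)

    # S1-vs-S2 comparison of auxiliary characteristics (two-group ANOVA,
    # equivalent to a pooled t test)
    aux_rows = {}
    s1 = disc.subjects.index[group3 == "S1"]
    s2 = disc.subjects.index[group3 == "S2"]
    for cls in AUX_CLASSES:
        for fid in disc.feature_ids(cls):
            x1 = disc.values.loc[s1, fid].to_numpy()
            x2 = disc.values.loc[s2, fid].to_numpy()
            t, df, p = t_test_from_summary(
                x1.mean(), x1.std(ddof=1), len(x1), x2.mean(), x2.std(ddof=1), len(x2)
            ) if x1.std(ddof=1) > 0 and x2.std(ddof=1) > 0 else (np.nan, np.nan, np.nan)
            aux_rows[fid] = {
                "class": cls,
                "mean_S1": x1.mean(),
                "sd_S1": x1.std(ddof=1),
                "mean_S2": x2.mean(),
                "sd_S2": x2.std(ddof=1),
                "t": t,
                "p": p,
            }
    aux_table = pd.DataFrame.from_dict(aux_rows, orient="index")

    pc1_means = {g: pc1[group3 == g].mean() for g in ("HC", "S1", "S2") if (group3 == g).any()}
    if "S1" in pc1_means and "S2" in pc1_means and pc1_means["S1"] != 0:
        report.table.attrs["pc1_mean_ratio_s2_s1"] = pc1_means["S2"] / pc1_means["S1"]
    report.table.attrs["pc1_variance_fraction"] = float(pca.variance_fractions[0])
    return report, pca, aux_table
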