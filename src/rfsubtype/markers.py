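"""Biomarker validation of subtypes: per-class classification, direction
tests, and canonical correlation of marker panels.

For each intergroup contrast (S1 vs HC, S2 vs HC, S2 vs S1, all cases vs
HC) and each feature class, a forest is grown and shaved, and the OOB AUC
of the selected model together with the retained, importance-ranked
markers is reported. The top markers per contrast are tested for mean
differences (Welch t) under a Bonferroni correction whose divisor is the
number of (marker, contrast) tests actually performed, and significant
markers are called up- or down-regulated in the more severe group. Two
marker panels are compared, after removing their overlap, by canonical
correlation analysis computed through whitening and an SVD of the
cross-covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from rfsubtype.forest import fit_forest, gini_importance, oob_auc
from rfsubtype.shaving import ShavingTrace, shave
from rfsubtype.synthetic import CLASS_BIOMARKER, AUX_CLASSES, CohortTable
from rfsubtype.subtypes import SubtypeResult

#: severity ordering used to identify "the more severe group" of a contrast
SEVERITY_RANK = {"HC": 0, "S1": 1, "case": 2, "S2": 3}

CONTRASTS = (("S1", "HC"), ("S2", "HC"), ("S2", "S1"), ("case", "HC"))


@dataclass
class ClassificationReport:
    contrast: tuple
    feature_class: str
    auc: float
    n_markers: int
    importance_ranks: list
    directions: dict = field(default_factory=dict)
    pooled: bool = False
    trace: ShavingTrace | None = None


@dataclass
class CcaResult:
    correlations: np.ndarray
    x_weights: np.ndarray
    y_weights: np.ndarray
    x_columns: list
    y_columns: list
    effective_rank: tuple


def group_vector(cohort: CohortTable, subtype_result: SubtypeResult, role: str = "discovery") -> pd.Series:
    """Subject -> group name among HC / S1 / S2 (cases keep 'case' when the
    subject has no subtype label, e.g. validation-role cases)."""
    sub = cohort.subset(role=role)
    labels = subtype_result.labels
    out = []
    for s, g in sub.subjects["group"].items():
        if g == "hc":
            out.append("HC")
        else:
            out.append(labels[s] if s in labels.index else "case")
    return pd.Series(out, index=sub.subjects.index, name="group")


def _resolve_members(groups: pd.Series, name: str) -> pd.Index:
    if name == "case":
        return groups.index[groups.isin(["S1", "S2", "case"])]
    return groups.index[groups == name]


def classify_contrast(
    cohort: CohortTable,
    groups: pd.Series,
    contrast: tuple,
    feature_class: str = CLASS_BIOMARKER,
    n_trees: int = 500,
    seed: int = 0,
    drop_fraction: float = 0.1,
    min_features: int = 5,
    auc_tolerance: float = 0.005,
) -> ClassificationReport:
    """Shaved forest classifying ``contrast`` on one feature class.

    ``feature_class='pooled'`` concatenates the biomarker panel with all
    auxiliary classes. The positive class is the first element of the
    contrast (the more severe group by convention).
    """
    a, b = contrast
    if feature_class == "pooled":
        fids = cohort.feature_ids(CLASS_BIOMARKER)
        for cls in AUX_CLASSES:
            fids += cohort.feature_ids(cls)
        pooled = True
    else:
        fids = cohort.feature_ids(feature_class)
        pooled = False
    if not fids:
        raise ValueError(f"unknown or empty feature class {feature_class!r}")
    ids_a, ids_b = _resolve_members(groups, a), _resolve_members(groups, b)
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValueError(f"empty group in contrast {a} vs {b}")
    ids = list(ids_b) + list(ids_a)
    y = np.array([0] * len(ids_b) + [1] * len(ids_a))
    X = cohort.values.loc[ids, fids]

    min_feats = min(min_features, max(1, len(fids) - 1))
    trace = shave(
        X, y, n_trees=n_trees, seed=seed,
        drop_fraction=drop_fraction, min_features=min_feats, auc_tolerance=auc_tolerance,
    )
    # the reported model is an independent refit on the selected set: the
    # trace's own per-round AUCs carry a winner's-curse from the max-AUC
    # selection rule, so the headline figure comes from a forest grown with
    # a fresh bootstrap seed on the selected features only
    selected = trace.selected_features
    refit = fit_forest(X[selected], y, n_trees=n_trees, seed=seed + 90001)
    ranked = list(gini_importance(refit).sort_values(ascending=False, kind="stable").index)
    return ClassificationReport(
        contrast=(a, b),
        feature_class=feature_class,
        auc=float(oob_auc(refit)),
        n_markers=len(ranked),
        importance_ranks=ranked,
        pooled=pooled,
        trace=trace,
    )


def marker_direction_tests(
    cohort: CohortTable,
    groups: pd.Series,
    markers_by_contrast: dict,
    alpha_fwer: float = 0.05,
) -> pd.DataFrame:
    """Welch t tests of marker mean equality with direction calls.

    The Bonferroni divisor m is the total number of (marker, contrast)
    tests performed (e.g. top 5 markers x 4 contrasts -> 0.05/20 = 0.0025).
    Direction (up/down in the more severe group) is assigned only to
    markers passing the corrected threshold; constant markers are reported
    untestable.
    """
    m = sum(len(v) for v in markers_by_contrast.values())
    if m == 0:
        raise ValueError("no (marker, contrast) tests requested")
    threshold = alpha_fwer / m
    rows = []
    for contrast, markers in markers_by_contrast.items():
        a, b = contrast
        severe = a if SEVERITY_RANK[a] >= SEVERITY_RANK[b] else b
        other = b if severe == a else a
        ids_sev, ids_oth = _resolve_members(groups, severe), _resolve_members(groups, other)
        for fid in markers:
            x = cohort.values.loc[ids_sev, fid].to_numpy()
            y = cohort.values.loc[ids_oth, fid].to_numpy()
            if np.ptp(x) == 0 and np.ptp(y) == 0:
                rows.append({"contrast": f"{a}_vs_{b}", "marker": fid, "p": np.nan,
                             "direction": "untestable", "mean_severe": x.mean(), "mean_other": y.mean()})
                continue
            t, p = stats.ttest_ind(x, y, equal_var=False)
            direction = "ns"
            if p < threshold:
                direction = "up" if x.mean() > y.mean() else "down"
            rows.append({"contrast": f"{a}_vs_{b}", "marker": fid, "p": float(p),
                         "direction": direction, "mean_severe": x.mean(), "mean_other": y.mean()})
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = threshold
    out.attrs["n_tests"] = m
    return out


def _standardize(M: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list]:
    if isinstance(M, pd.DataFrame):
        cols = list(M.columns)
        A = M.to_numpy(dtype=float)
    else:
        A = np.asarray(M, dtype=float)
        cols = [f"x{j}" for j in range(A.shape[1])]
    sd = A.std(axis=0, ddof=1)
    dead = np.where(sd == 0)[0]
    if len(dead):
        raise ValueError(f"zero-variance column: {cols[dead[0]]!r}")
    return (A - A.mean(axis=0)) / sd, cols


def cca(X, Y, n_components: int | None = None) -> CcaResult:
    """Canonical correlations via whitening + SVD of the cross-covariance.

    Columns are standardized internally; rank deficiency is handled by
    truncating the whitening basis at the numerical rank (recorded in
    ``effective_rank``). Correlations are clipped to [0, 1] and returned
    non-increasing.
    """
    Zx, cols_x = _standardize(X)
    Zy, cols_y = _standardize(Y)
    if Zx.shape[0] != Zy.shape[0]:
        raise ValueError("X and Y must have the same number of rows")

    def _whiten(Z):
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        tol = s.max() * max(Z.shape) * np.finfo(float).eps
        r = int((s > tol).sum())
        return U[:, :r], s[:r], Vt[:r], r

    Ux, sx, Vxt, rx = _whiten(Zx)
    Uy, sy, Vyt, ry = _whiten(Zy)
    U, s, Vt = np.linalg.svd(Ux.T @ Uy)
    k = min(rx, ry)
    if n_components is not None:
        k = min(k, n_components)
    corr = np.clip(s[:k], 0.0, 1.0)
    # weights mapping standardized columns to canonical variates
    x_weights = Vxt.T @ np.diag(1.0 / sx) @ U[:, :k]
    y_weights = Vyt.T @ np.diag(1.0 / sy) @ Vt.T[:, :k]
    return CcaResult(
        correlations=corr,
        x_weights=x_weights,
        y_weights=y_weights,
        x_columns=cols_x,
        y_columns=cols_y,
        effective_rank=(rx, ry),
    )


def compare_marker_panels(
    cohort_values: pd.DataFrame, panel_a: list, panel_b: list, n_components: int = 3
) -> CcaResult:
    """CCA of two marker panels restricted to their non-overlapping members."""
    shared = set(panel_a) & set(panel_b)
    a = [f for f in panel_a if f not in shared]
    b = [f for f in panel_b if f not in shared]
    if not a or not b:
        raise ValueError("empty non-overlap: panels are identical or nested")
    missing = [f for f in a + b if f not in cohort_values.columns]
    if missing:
        raise ValueError(f"panel features absent from cohort: {missing[:10]}")
    return cca(cohort_values[a], cohort_values[b], n_components=n_components)
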