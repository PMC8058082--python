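"""Bootstrap ensembles of classification trees with OOB machinery.

The ensemble is grown tree by tree so that the bootstrap membership of every
subject in every tree (the in-bag matrix) is stored explicitly. That makes
all out-of-bag (OOB) quantities — vote scores, AUC, proximities restricted
to OOB pairs — exactly reproducible and auditable against a brute-force
recount, which the classical high-level forest APIs do not expose.

Scores are class-vote fractions: each tree casts one vote per subject (the
majority class of the subject's terminal node, ties broken toward the
negative class), and a subject's score is the fraction of qualifying trees
voting for the positive class. The proximity between two subjects is the
fraction of trees in which they share a terminal node; 1 - proximity is the
dissimilarity used for clustering downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.tree import DecisionTreeClassifier

DEFAULT_N_TREES = 4000


def _as_matrix(table) -> tuple[np.ndarray, list[str], list]:
    """Accept a DataFrame (subjects x features) or ndarray."""
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), list(table.columns), list(table.index)
    X = np.asarray(table, dtype=float)
    return X, [f"f{j}" for j in range(X.shape[1])], list(range(X.shape[0]))


@dataclass
class RocResult:
    """ROC curve over the empirical score grid plus tie-aware AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class ProximityMatrix:
    subject_ids: list
    values: np.ndarray
    mode: str

    @property
    def distance(self) -> np.ndarray:
        return 1.0 - self.values

    def submatrix(self, subject_ids: list) -> "ProximityMatrix":
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        idx = np.array([pos[s] for s in subject_ids])
        return ProximityMatrix(list(subject_ids), self.values[np.ix_(idx, idx)], self.mode)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.subject_ids)


@dataclass
class ForestModel:
    """Fitted bootstrap ensemble with stored in-bag indicators.

    ``inbag[t, i]`` counts how often subject i entered tree t's bootstrap
    sample; OOB means a zero entry. ``class_labels`` is the ordered
    (negative, positive) pair; tree votes are encoded 0/1 accordingly.
    """

    trees: list
    inbag: np.ndarray
    feature_ids: list
    class_labels: tuple
    seed: int
    subject_ids: list
    X_train: np.ndarray
    y_train: np.ndarray
    hyperparams: dict = field(default_factory=dict)
    _leaf_train: np.ndarray | None = None
    _vote_train: np.ndarray | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Terminal-node index per tree (rows) and subject (columns)."""
        return np.vstack([t.apply(X) for t in self.trees])

    def votes(self, X: np.ndarray) -> np.ndarray:
        """0/1 class vote per tree (rows) and subject (columns)."""
        return np.vstack([t.predict(X).astype(np.int8) for t in self.trees])

    @property
    def leaf_train(self) -> np.ndarray:
        if self._leaf_train is None:
            self._leaf_train = self.apply(self.X_train)
        return self._leaf_train

    @property
    def vote_train(self) -> np.ndarray:
        if self._vote_train is None:
            self._vote_train = self.votes(self.X_train)
        return self._vote_train


def fit_forest(
    table,
    labels,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    classes: tuple | None = None,
    max_features="sqrt",
    max_depth: int | None = None,
    min_samples_leaf: int = 1,
) -> ForestModel:
    """Grow ``n_trees`` trees, each on an n-out-of-n bootstrap sample.

    ``classes`` fixes the (negative, positive) label order; by default the
    sorted order of the two observed labels is used. Deterministic given
    ``seed``.
    """
    X, feature_ids, subject_ids = _as_matrix(table)
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    labels = np.asarray(labels)
    observed = sorted(set(labels.tolist()))
    if len(observed) != 2:
        raise ValueError(f"need exactly 2 classes in labels, got {observed}")
    if classes is None:
        classes = tuple(observed)
    if sorted(classes) != observed:
        raise ValueError("classes must match the observed labels")
    y = (labels == classes[1]).astype(np.int8)
    n = len(y)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 subjects per class")

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    trees: list[DecisionTreeClassifier] = []
    inbag = np.zeros((n_trees, n), dtype=np.int16)
    for t in range(n_trees):
        idx = rng.integers(0, n, size=n)
        np.add.at(inbag[t], idx, 1)
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=max_features,
            max_depth=max_depth,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        # bootstrap may contain a single class; the tree then always votes it
        tree.fit(X[idx], y[idx])
        trees.append(tree)

    model = ForestModel(
        trees=trees,
        inbag=inbag,
        feature_ids=feature_ids,
        class_labels=tuple(classes),
        seed=seed,
        subject_ids=subject_ids,
        X_train=X,
        y_train=y,
        hyperparams={
            "max_features": max_features,
            "max_depth": max_depth,
            "min_samples_leaf": min_samples_leaf,
        },
    )
    if n_trees >= 50 and ((inbag > 0).all(axis=0)).any():
        bad = [subject_ids[i] for i in np.where((inbag > 0).all(axis=0))[0]]
        raise RuntimeError(f"subjects in-bag in every tree despite n_trees >= 50: {bad}")
    return model


def oob_scores(forest: ForestModel) -> np.ndarray:
    """Per-subject positive-vote fraction over trees where the subject is OOB.

    Subjects that are in-bag in every tree get NaN (flagged, never silently
    scored).
    """
    oob = forest.inbag == 0
    votes = forest.vote_train
    denom = oob.sum(axis=0).astype(float)
    num = (votes * oob).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denom > 0, num / np.maximum(denom, 1), np.nan)
    return scores


def oob_auc(forest: ForestModel) -> float:
    """OOB AUC of the forest on its training labels; errors on unscored subjects."""
    scores = oob_scores(forest)
    if np.isnan(scores).any():
        bad = [forest.subject_ids[i] for i in np.where(np.isnan(scores))[0]]
        raise RuntimeError(f"subjects OOB in zero trees cannot be scored: {bad}")
    return auc_roc(scores, forest.y_train).auc


def auc_roc(scores, labels) -> RocResult:
    """ROC and AUC by the tie-aware Mann-Whitney identity.

    AUC = (concordant + 0.5 * tied) / (n_pos * n_neg), computed through
    midranks; the stored curve uses every distinct score as a threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("both classes must be present")
    pos = labels == uniq.max() if labels.dtype.kind in "biuf" else labels == uniq[-1]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    s_sorted, p_sorted = scores[order], pos[order]
    thresholds, tp, fp = [], [], []
    tp_c = fp_c = 0
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and s_sorted[j] == s_sorted[i]:
            tp_c += int(p_sorted[j])
            fp_c += int(~p_sorted[j])
            j += 1
        thresholds.append(s_sorted[i])
        tp.append(tp_c)
        fp.append(fp_c)
        i = j
    tpr = np.concatenate([[0.0], np.array(tp) / n_pos])
    fpr = np.concatenate([[0.0], np.array(fp) / n_neg])
    thresholds = np.concatenate([[np.inf], np.array(thresholds)])
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=float(auc))


def gini_importance(forest: ForestModel) -> pd.Series:
    """Mean over trees of the summed, sample-weighted Gini decrease per feature."""
    total = np.zeros(len(forest.feature_ids))
    for tree in forest.trees:
        total += tree.tree_.compute_feature_importances(normalize=False)
    return pd.Series(total / forest.n_trees, index=forest.feature_ids)


def proximity(
    forest: ForestModel,
    subset: list | None = None,
    mode: str = "all_trees",
) -> ProximityMatrix:
    """Co-occupancy frequency of terminal nodes across trees.

    ``all_trees`` counts every tree; ``oob_pairs`` restricts numerator and
    denominator to trees in which both subjects are OOB. Pairs with no
    qualifying tree are NaN-flagged; with n_trees >= 1000 any flagged pair
    is an error.
    """
    if mode not in ("all_trees", "oob_pairs"):
        raise ValueError(f"unknown proximity mode {mode!r}")
    leaves = forest.leaf_train
    n = leaves.shape[1]
    if mode == "all_trees":
        counts = np.zeros((n, n))
        for t in range(forest.n_trees):
            counts += leaves[t, :, None] == leaves[t, None, :]
        values = counts / forest.n_trees
    else:
        oob = forest.inbag == 0
        num = np.zeros((n, n))
        den = np.zeros((n, n))
        for t in range(forest.n_trees):
            both = np.outer(oob[t], oob[t])
            num += both & (leaves[t, :, None] == leaves[t, None, :])
            den += both
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(den > 0, num / np.maximum(den, 1), np.nan)
        if forest.n_trees >= 1000 and np.isnan(values).any():
            raise RuntimeError("pairs with no joint-OOB tree at n_trees >= 1000")
    prox = ProximityMatrix(list(forest.subject_ids), values, mode)
    if subset is not None:
        prox = prox.submatrix(subset)
    return prox


def score_external(forest: ForestModel, new_table, labels=None):
    """Score unseen subjects by the all-tree positive-vote fraction.

    Returns a Series of scores; if binary ``labels`` are given, returns
    ``(scores, RocResult)``.
    """
    if isinstance(new_table, pd.DataFrame):
        missing = [f for f in forest.feature_ids if f not in new_table.columns]
        if missing:
            raise ValueError(f"new subjects lack training features: {missing[:10]}")
        X = new_table[forest.feature_ids].to_numpy(dtype=float)
        ids = list(new_table.index)
    else:
        X = np.asarray(new_table, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(forest.feature_ids):
            raise ValueError("feature count mismatch with training features")
        ids = list(range(X.shape[0]))
    if X.shape[0] == 0:
        raise ValueError("no subjects to score")
    votes = forest.votes(X)
    scores = pd.Series(votes.mean(axis=0), index=ids)
    if labels is None:
        return scores
    roc = auc_roc(scores.to_numpy(), np.asarray(labels))
    return scores, roc
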