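"""Case subtyping: PAM on the forest distance, silhouettes, 2-D embeddings.

The distance between cases is 1 minus the random-forest proximity from a
case-vs-control forest grown on clinical-scale items. Partitioning around
medoids (PAM, deterministic BUILD + best-improvement SWAP) splits the cases
into k subtypes, which are then named in order of their mean severity-scale
total (S1 = least severe). Cluster quality is reported as silhouettes
computed on the full-cohort distance with healthy controls kept as their
own group, and the geometry is visualized with classical MDS or a diffusion
map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rfsubtype.forest import ForestModel, fit_forest, proximity
from rfsubtype.synthetic import CLASS_CLINICAL_ITEM, CohortTable


def _check_distance(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if (D < -1e-12).any():
        raise ValueError("distance matrix must be non-negative")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    return D


def _build_from(D: np.ndarray, first: int, k: int) -> list[int]:
    """Greedy BUILD completion from a fixed first medoid (ties -> lowest index)."""
    n = D.shape[0]
    medoids = [first]
    nearest = D[first].copy()
    while len(medoids) < k:
        gains = np.array(
            [np.maximum(nearest - D[c], 0.0).sum() if c not in medoids else -np.inf for c in range(n)]
        )
        c = int(np.argmax(gains))
        medoids.append(c)
        nearest = np.minimum(nearest, D[c])
    return medoids


def _swap_descent(D: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    """Best-improvement SWAP until no single medoid exchange lowers cost."""
    n = D.shape[0]

    def cost_of(meds: list[int]) -> float:
        return float(D[:, meds].min(axis=1).sum())

    cost = cost_of(medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        for mi in range(len(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = h
                delta = cost_of(trial) - cost
                if delta < best[0] - 1e-15:
                    best = (delta, mi, h)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            new_cost = cost_of(medoids)
            assert new_cost <= cost + 1e-12, "SWAP must never increase total cost"
            cost = new_cost
            improved = True
    return medoids, cost


def pam(D, k: int, seed: int | None = None) -> tuple[np.ndarray, list[int], float]:
    """k-medoids by deterministic multi-start BUILD + best-improvement SWAP.

    Single-start BUILD+SWAP (the classical formulation, also what the R
    reference implementation runs) stalls in a local optimum on a few
    percent of small random instances. Here the BUILD/SWAP descent is
    restarted from every point as the forced first medoid and the
    lowest-cost solution kept, which is still a deterministic heuristic in
    the PAM family (no enumeration of medoid subsets) but in practice
    reaches the global optimum on small problems.

    Returns (labels, medoid indices, total cost). ``seed`` is accepted for
    interface symmetry but unused — the procedure is deterministic. Labels
    are 0..k-1 in ascending medoid index; assignment ties go to the
    lowest-index medoid.
    """
    D = _check_distance(D)
    n = D.shape[0]
    if k < 1 or k > n:
        raise ValueError("k must satisfy 1 <= k <= n")
    if k == n:
        return np.arange(n), list(range(n)), 0.0

    best_meds, best_cost = None, np.inf
    for first in range(n):
        meds, cost = _swap_descent(D, _build_from(D, first, k))
        if cost < best_cost - 1e-12 or (abs(cost - best_cost) <= 1e-12 and sorted(meds) < sorted(best_meds)):
            best_meds, best_cost = meds, cost

    medoids = sorted(best_meds)
    labels = np.argmin(D[:, medoids], axis=1)
    total = float(D[:, medoids].min(axis=1).sum())
    return labels, medoids, total


def silhouette(D, labels) -> tuple[np.ndarray, dict]:
    """Silhouette s(i) = (b - a) / max(a, b) on a precomputed distance.

    a(i): mean distance to own cluster (excluding self); b(i): smallest mean
    distance to another cluster. Members of singleton clusters get s = 0.
    Returns (per-subject values, per-cluster means).
    """
    D = _check_distance(D)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = D.shape[0]
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (own.sum() - 1)
        b = min(D[i, labels == c].mean() for c in clusters if c != labels[i])
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    cluster_means = {c: float(s[labels == c].mean()) for c in clusters}
    return s, cluster_means


def embed_2d(D, method: str = "diffusion_map", bandwidth: float | None = None) -> np.ndarray:
    """2-D coordinates from a distance matrix.

    ``classical_mds``: double-centered Gram eigendecomposition, top-2 axes,
    sign fixed so the largest-magnitude coordinate on each axis is positive.
    ``diffusion_map``: Gaussian kernel (default bandwidth = median off-diagonal
    distance), row-normalized Markov operator, top-2 nontrivial eigenvectors
    scaled by their eigenvalues.
    """
    D = _check_distance(D)
    n = D.shape[0]
    if np.allclose(D, 0.0):
        raise ValueError("degenerate all-zero distance matrix")

    if method == "classical_mds":
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D**2) @ J
        w, V = np.linalg.eigh(B)
        order = np.argsort(w)[::-1][:2]
        coords = V[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    elif method == "diffusion_map":
        off = D[~np.eye(n, dtype=bool)]
        eps = bandwidth if bandwidth is not None else float(np.median(off))
        if eps <= 0:
            raise ValueError("non-positive kernel bandwidth")
        K = np.exp(-(D**2) / (2.0 * eps**2))
        d = K.sum(axis=1)
        # symmetric conjugate of the Markov operator for a stable eigh
        S = K / np.sqrt(np.outer(d, d))
        w, U = np.linalg.eigh(S)
        order = np.argsort(w)[::-1]
        phi = U[:, order] / np.sqrt(d)[:, None]
        lam = w[order]
        coords = phi[:, 1:3] * lam[1:3]
    else:
        raise ValueError(f"unknown embedding method {method!r}")

    for j in range(coords.shape[1]):
        i_max = int(np.argmax(np.abs(coords[:, j])))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


@dataclass
class SubtypeResult:
    """PAM subtypes of cases plus validation diagnostics.

    ``labels`` maps case subject_id -> severity-ordered subtype name
    ('S1' = lowest mean severity total). Silhouettes cover the full cohort
    (controls as their own 'HC' group) under the same forest distance.
    """

    labels: pd.Series
    medoids: list
    k: int
    total_cost: float
    silhouettes: pd.Series
    cluster_mean_silhouettes: dict
    embedding: pd.DataFrame
    severity_order: dict
    forest: ForestModel
    case_distance: pd.DataFrame


def discover_subtypes(
    cohort: CohortTable,
    n_trees: int = 4000,
    seed: int = 0,
    k: int = 2,
    proximity_mode: str = "all_trees",
    embedding_method: str = "diffusion_map",
    max_features=2,
) -> SubtypeResult:
    """Forest on cases vs HC -> case-only proximity -> PAM -> severity naming.

    The subtyping forest deliberately uses a very small number of candidate
    features per split (default 2, recorded in the result's forest
    hyperparameters). With the classical sqrt(p) choice, almost every node
    finds one of the strongly case-vs-control-separating items, cases end
    up in a single pure terminal node, and the proximity matrix carries no
    within-case structure; a small mtry forces trees to also split on items
    that cut the case group by severity, which is what the clustering
    consumes.
    """
    disc = cohort.subset(role="discovery")
    items = disc.feature_ids(CLASS_CLINICAL_ITEM)
    if not items:
        raise ValueError("cohort has no clinical items")
    case_ids = list(disc.subjects.index[disc.subjects["group"] == "case"])
    if len(case_ids) < 2 * k:
        raise ValueError(f"need at least {2 * k} cases for k={k}")

    y = (disc.subjects["group"] == "case").astype(int).to_numpy()
    forest = fit_forest(
        disc.values[items], y, n_trees=n_trees, seed=seed, classes=(0, 1), max_features=max_features
    )
    prox = proximity(forest, mode=proximity_mode)
    D_full = prox.distance
    full_ids = prox.subject_ids
    pos = {s: i for i, s in enumerate(full_ids)}
    case_idx = np.array([pos[s] for s in case_ids])
    D_cases = D_full[np.ix_(case_idx, case_idx)]

    raw_labels, medoid_idx, total_cost = pam(D_cases, k=k)

    # severity naming: clusters ordered by mean severity-scale total
    sev = disc.values.loc[case_ids, disc.severity_total_id].to_numpy()
    means = [sev[raw_labels == c].mean() for c in range(k)]
    order = np.argsort(means, kind="stable")
    severity_order = {int(c): f"S{rank + 1}" for rank, c in enumerate(order)}
    named = pd.Series([severity_order[int(c)] for c in raw_labels], index=case_ids, name="subtype")

    group3 = np.array(
        [named[s] if s in named.index else "HC" for s in full_ids]
    )
    sil, cluster_sil = silhouette(D_full, group3)
    coords = embed_2d(D_full, method=embedding_method)

    return SubtypeResult(
        labels=named,
        medoids=[case_ids[i] for i in medoid_idx],
        k=k,
        total_cost=total_cost,
        silhouettes=pd.Series(sil, index=full_ids, name="silhouette"),
        cluster_mean_silhouettes={str(c): v for c, v in cluster_sil.items()},
        embedding=pd.DataFrame(coords, index=full_ids, columns=["dim1", "dim2"]),
        severity_order=severity_order,
        forest=forest,
        case_distance=pd.DataFrame(D_cases, index=case_ids, columns=case_ids),
    )
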