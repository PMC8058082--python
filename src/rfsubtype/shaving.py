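"""Recursive feature shaving with OOB-AUC tracking.

Shaving repeatedly refits the forest, eliminates the least Gini-important
features, and records the OOB AUC of every round. The selected model is the
smallest feature set whose AUC is within a small tolerance of the best AUC
seen along the trace — the "largest AUC with the smallest set of unshaved
variables" rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rfsubtype.forest import fit_forest, gini_importance, oob_auc


@dataclass
class ShavingRound:
    feature_ids: list
    oob_auc: float
    importance: pd.Series  # descending


@dataclass
class ShavingTrace:
    rounds: list
    selected_round: int
    selection_rule: dict

    @property
    def selected_features(self) -> list:
        return list(self.rounds[self.selected_round].feature_ids)

    @property
    def selected_auc(self) -> float:
        return self.rounds[self.selected_round].oob_auc

    def to_frame(self) -> pd.DataFrame:
        prev: set | None = None
        rows = []
        for i, r in enumerate(self.rounds):
            removed = sorted(prev - set(r.feature_ids)) if prev is not None else []
            rows.append(
                {
                    "round": i,
                    "n_features": len(r.feature_ids),
                    "oob_auc": r.oob_auc,
                    "selected": i == self.selected_round,
                    "removed_features": ";".join(removed),
                }
            )
            prev = set(r.feature_ids)
        return pd.DataFrame(rows)


def round_sizes(n_features: int, drop_fraction: float, min_features: int) -> list[int]:
    """Feature-set sizes visited: each round drops max(1, floor(f * size))."""
    sizes = [n_features]
    while sizes[-1] > min_features:
        drop = max(1, int(np.floor(drop_fraction * sizes[-1])))
        sizes.append(max(sizes[-1] - drop, min_features))
    return sizes


def shave(
    table,
    labels,
    n_trees: int = 500,
    seed: int = 0,
    drop_fraction: float = 0.1,
    min_features: int = 5,
    auc_tolerance: float = 0.005,
    **forest_kwargs,
) -> ShavingTrace:
    """Iteratively refit, rank by Gini importance, drop the tail.

    Importance is recomputed every round; ties at the removal boundary are
    broken by current column order so runs are deterministic. The base seed
    is offset by the round index so each round is individually reproducible.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(np.asarray(table, dtype=float))
        table.columns = [f"f{j}" for j in table.columns]
    if min_features >= table.shape[1]:
        raise ValueError("min_features must be smaller than the initial feature count")
    if min_features < 1:
        raise ValueError("min_features must be >= 1")

    current = list(table.columns)
    rounds: list[ShavingRound] = []
    r = 0
    while True:
        forest = fit_forest(table[current], labels, n_trees=n_trees, seed=seed + r, **forest_kwargs)
        imp = gini_importance(forest)
        rounds.append(
            ShavingRound(
                feature_ids=list(current),
                oob_auc=oob_auc(forest),
                importance=imp.sort_values(ascending=False, kind="stable"),
            )
        )
        if len(current) <= min_features:
            break
        drop = max(1, int(np.floor(drop_fraction * len(current))))
        drop = min(drop, len(current) - min_features)
        # stable ascending sort: ties resolved by current column order
        order = np.lexsort((np.arange(len(current)), imp.to_numpy()))
        dropped = {current[i] for i in order[:drop]}
        current = [f for f in current if f not in dropped]
        r += 1

    rule = {"drop_fraction": drop_fraction, "min_features": min_features, "auc_tolerance": auc_tolerance}
    trace = ShavingTrace(rounds=rounds, selected_round=0, selection_rule=rule)
    trace.selected_round = _select_index(trace, auc_tolerance)
    return trace


def _select_index(trace: ShavingTrace, auc_tolerance: float) -> int:
    aucs = np.array([r.oob_auc for r in trace.rounds])
    sizes = np.array([len(r.feature_ids) for r in trace.rounds])
    qualifying = np.where(aucs >= aucs.max() - auc_tolerance)[0]
    # smallest set; ties -> higher AUC, then later round
    best = min(qualifying, key=lambda i: (sizes[i], -aucs[i], -i))
    return int(best)


def select_optimal(trace: ShavingTrace, auc_tolerance: float | None = None) -> list:
    """Feature set of the smallest round within tolerance of the best AUC."""
    if not trace.rounds:
        raise ValueError("empty shaving trace")
    tol = trace.selection_rule["auc_tolerance"] if auc_tolerance is None else auc_tolerance
    return list(trace.rounds[_select_index(trace, tol)].feature_ids)
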