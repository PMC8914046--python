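"""Survival CART: binary recursive partitioning by exhaustive log-rank search.

Each split is chosen by scanning, for every candidate variable, every
midpoint between consecutive sorted unique values (or a user-supplied cutoff
grid) and maximizing the two-sample log-rank chi-square between the
``x < cutoff`` and ``x >= cutoff`` groups — "the highest outcome contrast".
Growth stops at a depth cap, a minimum leaf size, or when no admissible
split reaches the chi-square threshold. Leaves are labelled low /
intermediate / high risk by their relative event rates, supporting the
typical four-leaf tree (two high-risk leaves, one intermediate, one low)
obtained from a few hundred subjects.

Exposed both as plain functions (:func:`best_split`, :func:`grow_tree`,
:func:`classify`) and as the scikit-learn-style estimator
:class:`LogRankSurvivalTree`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import StatsError

__all__ = ["TreeNode", "best_split", "grow_tree", "classify", "LogRankSurvivalTree"]

RISK_LABELS = ("low", "intermediate", "high")


def _logrank_chi2(times: np.ndarray, events: np.ndarray, group: np.ndarray) -> float:
    """Two-sample log-rank chi-square (1 df); 0 when the statistic degenerates."""
    n = len(times)
    n1 = int(group.sum())
    if n1 == 0 or n1 == n:
        return 0.0
    uniq, inv = np.unique(times, return_inverse=True)
    d_tot = np.bincount(inv, weights=events, minlength=len(uniq))
    d1 = np.bincount(inv, weights=events * group, minlength=len(uniq))
    leave_tot = np.bincount(inv, minlength=len(uniq)).astype(float)
    leave1 = np.bincount(inv, weights=group, minlength=len(uniq))
    at_risk = n - np.concatenate(([0.0], np.cumsum(leave_tot)[:-1]))
    at_risk1 = n1 - np.concatenate(([0.0], np.cumsum(leave1)[:-1]))
    m = (d_tot > 0) & (at_risk > 1)
    if not m.any():
        return 0.0
    frac = at_risk1[m] / at_risk[m]
    o_minus_e = (d1[m] - d_tot[m] * frac).sum()
    var = (
        d_tot[m] * frac * (1.0 - frac) * (at_risk[m] - d_tot[m]) / (at_risk[m] - 1.0)
    ).sum()
    if var <= 0:
        return 0.0
    return float(o_minus_e * o_minus_e / var)


def best_split(
    times: np.ndarray,
    events: np.ndarray,
    X: pd.DataFrame,
    candidates: Sequence[str],
    min_leaf: int = 30,
    cutoff_grid: np.ndarray | None = None,
) -> tuple[str, float, float] | None:
    """Exhaustive log-rank split search over variables and cutoffs.

    Returns (variable, cutoff, chi2) of the best admissible split, or None
    when no cutoff leaves ``min_leaf`` subjects on each side. Ties are broken
    toward the smaller cutoff, then the earlier variable in ``candidates``.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, float)
    if len(times) < 2 * min_leaf or events.sum() < 1:
        return None
    best: tuple[str, float, float] | None = None
    for var in candidates:
        x = X[var].to_numpy(float)
        if cutoff_grid is not None:
            lo, hi = x.min(), x.max()
            cuts = cutoff_grid[(cutoff_grid > lo) & (cutoff_grid <= hi)]
        else:
            u = np.unique(x)
            if len(u) < 2:
                continue
            cuts = (u[:-1] + u[1:]) / 2.0
        for c in cuts:
            left = x < c
            nl = int(left.sum())
            if nl < min_leaf or len(x) - nl < min_leaf:
                continue
            chi2 = _logrank_chi2(times, events, left)
            if best is None or chi2 > best[2] + 1e-12:
                best = (var, float(c), chi2)
    return best


@dataclass
class TreeNode:
    """One node of the survival tree; leaves carry a risk label."""

    n: int
    n_events: int
    depth: int
    variable: str | None = None
    cutoff: float | None = None
    chi2: float | None = None
    left: "TreeNode | None" = None  # x < cutoff
    right: "TreeNode | None" = None  # x >= cutoff
    leaf_id: int | None = None
    risk_label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.variable is None

    @property
    def event_rate(self) -> float:
        return self.n_events / self.n if self.n else 0.0

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def to_dict(self) -> dict:
        base = {"n": self.n, "n_events": self.n_events, "event_rate": self.event_rate}
        if self.is_leaf:
            base.update({"leaf_id": self.leaf_id, "risk_label": self.risk_label})
        else:
            base.update(
                {
                    "variable": self.variable,
                    "cutoff": self.cutoff,
                    "logrank_chi2": self.chi2,
                    "left": self.left.to_dict(),
                    "right": self.right.to_dict(),
                }
            )
        return base


def _assign_risk_labels(root: TreeNode) -> None:
    leaves = root.leaves()
    for i, leaf in enumerate(leaves):
        leaf.leaf_id = i
    rates = np.array([leaf.event_rate for leaf in leaves])
    lo, hi = rates.min(), rates.max()
    if hi - lo < 1e-12:
        for leaf in leaves:
            leaf.risk_label = "intermediate"
        return
    rel = (rates - lo) / (hi - lo)
    for leaf, r in zip(leaves, rel):
        leaf.risk_label = "low" if r < 1 / 3 else ("high" if r > 2 / 3 else "intermediate")


def grow_tree(
    times: np.ndarray,
    events: np.ndarray,
    X: pd.DataFrame,
    candidates: Sequence[str] | None = None,
    max_depth: int = 3,
    min_leaf: int = 30,
    min_chi2: float = 3.84,
    cutoff_grid: np.ndarray | None = None,
) -> TreeNode:
    """Grow the survival tree by recursive best-split search.

    Defaults (depth 3, minimum leaf 30, chi-square threshold 3.84) yield the
    compact trees expected from cohorts of a few hundred subjects.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, float)
    if len(times) == 0:
        raise StatsError("cannot grow a tree on an empty cohort")
    candidates = list(candidates) if candidates is not None else list(X.columns)

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        node = TreeNode(n=len(idx), n_events=int(events[idx].sum()), depth=depth)
        if depth >= max_depth:
            return node
        split = best_split(
            times[idx], events[idx], X.iloc[idx], candidates, min_leaf, cutoff_grid
        )
        if split is None or split[2] < min_chi2:
            return node
        var, cut, chi2 = split
        node.variable, node.cutoff, node.chi2 = var, cut, chi2
        x = X[var].to_numpy(float)[idx]
        node.left = build(idx[x < cut], depth + 1)
        node.right = build(idx[x >= cut], depth + 1)
        return node

    root = build(np.arange(len(times)), 0)
    _assign_risk_labels(root)
    return root


def classify(subject: Mapping[str, float], root: TreeNode) -> tuple[int, str]:
    """Route one subject down the tree; returns (leaf_id, risk_label).

    Values equal to a cutoff go right (the '>=' child). Missing split
    variables are an error (no surrogate splits).
    """
    node = root
    while not node.is_leaf:
        if node.variable not in subject:
            raise StatsError(f"subject is missing split variable {node.variable!r}")
        node = node.left if subject[node.variable] < node.cutoff else node.right
    return node.leaf_id, node.risk_label


class LogRankSurvivalTree(BaseEstimator):
    """Scikit-learn-style survival tree with log-rank splitting.

    Parameters
    ----------
    max_depth : maximum number of splits on any root-to-leaf path.
    min_leaf : minimum subjects per leaf.
    min_chi2 : minimum log-rank chi-square for a split to be accepted
        (3.84 is the 0.05 critical value at 1 df).
    cutoff_grid : optional fixed grid of candidate cutoffs shared by all
        variables; default scans midpoints of consecutive unique values.

    After ``fit``, ``tree_`` holds the root :class:`TreeNode` and
    ``feature_names_in_`` the training columns. ``predict`` returns risk
    labels and ``apply`` returns leaf ids.
    """

    def __init__(
        self,
        max_depth: int = 3,
        min_leaf: int = 30,
        min_chi2: float = 3.84,
        cutoff_grid: np.ndarray | None = None,
    ):
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.min_chi2 = min_chi2
        self.cutoff_grid = cutoff_grid

    def fit(self, X: pd.DataFrame, y):
        """Fit on covariates ``X`` and survival outcome ``y`` = (time, event).

        ``y`` may be an (n, 2) array, a DataFrame with time/event columns, or
        a (times, events) tuple.
        """
        X = pd.DataFrame(X)
        if isinstance(y, tuple) and len(y) == 2:
            times, events = np.asarray(y[0], float), np.asarray(y[1], float)
        else:
            arr = np.asarray(y, float) if not isinstance(y, pd.DataFrame) else y.to_numpy(float)
            times, events = arr[:, 0], arr[:, 1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.tree_ = grow_tree(
            times,
            events,
            X,
            max_depth=self.max_depth,
            min_leaf=self.min_leaf,
            min_chi2=self.min_chi2,
            cutoff_grid=self.cutoff_grid,
        )
        self.leaves_ = self.tree_.leaves()
        return self

    def _check_fitted(self):
        if not hasattr(self, "tree_"):
            raise StatsError("estimator is not fitted; call fit first")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Risk label per subject ('low' / 'intermediate' / 'high')."""
        self._check_fitted()
        X = pd.DataFrame(X)
        return np.array([classify(row, self.tree_)[1] for _, row in X.iterrows()])

    def apply(self, X: pd.DataFrame) -> np.ndarray:
        """Leaf id per subject."""
        self._check_fitted()
        X = pd.DataFrame(X)
        return np.array([classify(row, self.tree_)[0] for _, row in X.iterrows()])

    def to_dict(self) -> dict:
        self._check_fitted()
        return self.tree_.to_dict()
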