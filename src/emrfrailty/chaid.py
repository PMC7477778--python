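"""Kass-style CHAID (Chi-square Automatic Interaction Detection) for binary outcomes.

The tree is grown by, at each node, testing every candidate predictor
against the binary outcome with a Pearson chi-square (no continuity
correction), Bonferroni-adjusting the best p-value for the number of
predictors examined (times the Kass partition coefficient when a
multi-category predictor was merged), and splitting on the winner only when
the adjusted p-value is at or below the significance level ``alpha``.
Growth also stops at the maximum height, at the minimum node size, or on a
pure node.  Multi-category predictors are first reduced by the classic
pairwise merge step: the most similar pair of categories (largest 2x2
p-value) is merged while that p-value exceeds the merge threshold.

Binary indicator matrices are the intended input; numeric columns (e.g. age)
are dichotomized at their training median.  Missing predictors at prediction
time read as 0, matching the missing-as-zero convention of the feature
matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import factorial
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ChaidParams",
    "ChaidNode",
    "ChaidClassifier",
    "chisq_2xk",
    "merge_categories",
    "kass_multiplier",
    "best_split",
    "SplitCandidate",
]


def chisq_2xk(contingency) -> tuple[float, float]:
    """Pearson chi-square for a 2 x k table, df = k - 1, right-tail p.

    No continuity correction.  Degenerate tables (k < 2 after removing
    all-zero columns, or an all-zero row) return (0.0, 1.0) by convention:
    the predictor is uninformative, not an error.
    """
    t = np.asarray(contingency, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("contingency must be a 2 x k table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    k = t.shape[1]
    if k < 2 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 0.0, 1.0
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    stat = float(((t - expected) ** 2 / expected).sum())
    p = float(_chi2_dist.sf(stat, k - 1))
    return stat, p


def _chisq_2x2_binary(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 2x2 Pearson chi-square of each binary column of x against y.

    Returns (stat, p) arrays; columns that do not vary (or with a single
    outcome class) get stat 0, p 1.
    """
    n = len(y)
    n1 = int(y.sum())
    n0 = n - n1
    a = x[y == 1].sum(axis=0).astype(float)   # x=1, y=1
    c = x.sum(axis=0).astype(float) - a       # x=1, y=0
    b = n1 - a                                # x=0, y=1
    d = n0 - c                                # x=0, y=0
    col1 = a + c
    col0 = b + d
    denom = (a + b) * (c + d) * col1 * col0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (a * d - b * c) ** 2 / denom
    stat = np.where(denom > 0, stat, 0.0)
    p = _chi2_dist.sf(stat, 1)
    p = np.where(denom > 0, p, 1.0)
    return stat, p


def merge_categories(values, labels, alpha_merge: float) -> list[tuple]:
    """CHAID category-merging for a nominal predictor against a binary label.

    Repeatedly merges the pair of category groups whose 2x2 sub-table has
    the largest p-value, while that p-value exceeds ``alpha_merge`` and more
    than two groups remain.  Binary predictors pass through unchanged.
    Returns the final partition as a sorted list of category tuples.
    """
    values = pd.Series(values).reset_index(drop=True)
    y = np.asarray(labels)
    cats = sorted(pd.unique(values), key=str)
    groups = [(c,) for c in cats]
    if len(groups) < 2:
        return groups

    def group_counts(group: tuple) -> np.ndarray:
        mask = values.isin(group).to_numpy()
        return np.array([np.sum(mask & (y == 0)), np.sum(mask & (y == 1))], float)

    while len(groups) > 2:
        best_p, best_pair = -1.0, None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                tab = np.column_stack([group_counts(groups[i]),
                                       group_counts(groups[j])])
                _, p = chisq_2xk(tab)
                if p > best_p:
                    best_p, best_pair = p, (i, j)
        if best_p <= alpha_merge:
            break
        i, j = best_pair
        merged = tuple(sorted(groups[i] + groups[j], key=str))
        groups = [g for idx, g in enumerate(groups) if idx not in (i, j)]
        groups.append(merged)
        groups.sort(key=lambda g: str(g[0]))
    return sorted(groups, key=lambda g: str(g[0]))


def kass_multiplier(n_categories: int, n_groups: int) -> int:
    """Number of ways to partition ``n_categories`` nominal categories into
    ``n_groups`` non-empty groups (the CHAID Bonferroni partition
    coefficient for free predictors)."""
    c, g = n_categories, n_groups
    if not 1 <= g <= c:
        raise ValueError("need 1 <= n_groups <= n_categories")
    return int(round(sum(
        (-1) ** i * (g - i) ** c / (factorial(i) * factorial(g - i))
        for i in range(g)
    )))


@dataclass(frozen=True)
class ChaidParams:
    """Hyper-parameters of the CHAID learner."""

    alpha: float = 0.12
    max_height: int = 4
    min_node_size: int = 10
    bonferroni: bool = True
    leaf_rule: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.max_height < 1:
            raise ValueError("max_height must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")


@dataclass(frozen=True)
class SplitCandidate:
    feature: str
    statistic: float
    p_value: float
    p_adjusted: float
    groups: tuple[tuple, ...]  # category partition; ((0,), (1,)) for binary


@dataclass
class ChaidNode:
    """One node of a fitted CHAID tree."""

    n_per_class: tuple[int, int]        # (not frail, frail)
    depth: int
    predicted: int
    proportion: float                   # frail proportion in the node
    feature: str | None = None
    statistic: float | None = None
    p_value: float | None = None
    p_adjusted: float | None = None
    children: dict = field(default_factory=dict)   # category value -> ChaidNode

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        d = {
            "n_per_class": list(self.n_per_class),
            "depth": self.depth,
            "predicted": self.predicted,
            "proportion": self.proportion,
        }
        if not self.is_leaf:
            d.update({
                "feature": self.feature,
                "statistic": self.statistic,
                "p_value": self.p_value,
                "p_adjusted": self.p_adjusted,
                "children": {str(k): v.to_dict() for k, v in self.children.items()},
            })
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChaidNode":
        node = cls(
            n_per_class=tuple(d["n_per_class"]),
            depth=d["depth"],
            predicted=d["predicted"],
            proportion=d["proportion"],
        )
        if "feature" in d:
            node.feature = d["feature"]
            node.statistic = d["statistic"]
            node.p_value = d["p_value"]
            node.p_adjusted = d["p_adjusted"]
            node.children = {
                int(k): cls.from_dict(v) for k, v in d["children"].items()
            }
        return node


def best_split(X: pd.DataFrame, y: np.ndarray,
               params: ChaidParams) -> SplitCandidate | None:
    """The most significant admissible split at a node, or None.

    Every column is tested (degenerate columns score p = 1 and still count
    in the Bonferroni multiplier); the smallest Bonferroni-adjusted p-value
    wins if it is at most ``params.alpha``.  Ties break toward the larger
    chi-square statistic, then the lexicographically first feature name.
    """
    if len(X) == 0:
        raise ValueError("empty node")
    y = np.asarray(y).astype(int)
    m = X.shape[1]
    if m == 0:
        return None

    names = list(X.columns)
    Xv = X.to_numpy()
    binary_mask = ((Xv == 0) | (Xv == 1)).all(axis=0)

    stats = np.zeros(m)
    raw_p = np.ones(m)
    kass = np.ones(m)
    groups: list[tuple[tuple, ...]] = [((0,), (1,))] * m

    bcols = np.flatnonzero(binary_mask)
    if len(bcols):
        s, p = _chisq_2x2_binary(Xv[:, bcols].astype(float), y)
        stats[bcols] = s
        raw_p[bcols] = p

    for j in np.flatnonzero(~binary_mask):
        vals = pd.Series(Xv[:, j])
        part = merge_categories(vals, y, alpha_merge=params.alpha)
        tab = np.zeros((2, len(part)))
        for gi, grp in enumerate(part):
            mask = vals.isin(grp).to_numpy()
            tab[0, gi] = np.sum(mask & (y == 0))
            tab[1, gi] = np.sum(mask & (y == 1))
        stats[j], raw_p[j] = chisq_2xk(tab)
        c = vals.nunique()
        if len(part) >= 1 and c >= len(part):
            kass[j] = kass_multiplier(c, len(part))
        groups[j] = tuple(part)

    mult = (m * kass) if params.bonferroni else kass * 0 + 1
    adj = np.minimum(raw_p * mult, 1.0)

    # admissible candidates
    ok = adj <= params.alpha
    if not ok.any():
        return None
    order = sorted(
        np.flatnonzero(ok),
        key=lambda j: (adj[j], -stats[j], names[j]),
    )
    j = order[0]
    return SplitCandidate(
        feature=names[j],
        statistic=float(stats[j]),
        p_value=float(raw_p[j]),
        p_adjusted=float(adj[j]),
        groups=groups[j],
    )


def _grow_node(X: pd.DataFrame, y: np.ndarray, params: ChaidParams,
               depth: int) -> ChaidNode:
    n1 = int(y.sum())
    n0 = len(y) - n1
    prop = n1 / len(y)
    node = ChaidNode(
        n_per_class=(n0, n1),
        depth=depth,
        predicted=int(prop > params.leaf_rule),
        proportion=prop,
    )
    if depth >= params.max_height or len(y) < params.min_node_size or n0 == 0 or n1 == 0:
        return node
    cand = best_split(X, y, params)
    if cand is None:
        return node
    node.feature = cand.feature
    node.statistic = cand.statistic
    node.p_value = cand.p_value
    node.p_adjusted = cand.p_adjusted
    col = X[cand.feature].to_numpy()
    for grp in cand.groups:
        mask = np.isin(col, grp)
        key = grp[0] if len(grp) == 1 else grp
        child = _grow_node(X.loc[mask], y[mask], params, depth + 1)
        node.children[int(key) if np.isscalar(key) else key] = child
    return node


class ChaidClassifier(ClassifierMixin, BaseEstimator):
    """CHAID decision-tree classifier for a binary outcome.

    Parameters
    ----------
    alpha : float, default 0.12
        Significance level a Bonferroni-adjusted split p-value must reach.
    max_height : int, default 4
        Maximum number of split levels.
    min_node_size : int, default 10
        Nodes smaller than this become leaves.
    bonferroni : bool, default True
        Apply the Bonferroni x Kass adjustment to split p-values.
    leaf_rule : float, default 0.5
        A leaf predicts the positive (frail) class when its positive
        proportion strictly exceeds this threshold.

    Attributes
    ----------
    tree_ : ChaidNode
        Root of the fitted tree.
    feature_names_in_ : ndarray of str
    thresholds_ : dict
        Median cut-points used to dichotomize numeric columns.
    depth_ : int
        Realized tree depth.
    """

    def __init__(self, alpha: float = 0.12, max_height: int = 4,
                 min_node_size: int = 10, bonferroni: bool = True,
                 leaf_rule: float = 0.5):
        self.alpha = alpha
        self.max_height = max_height
        self.min_node_size = min_node_size
        self.bonferroni = bonferroni
        self.leaf_rule = leaf_rule

    def _params(self) -> ChaidParams:
        return ChaidParams(self.alpha, self.max_height, self.min_node_size,
                           self.bonferroni, self.leaf_rule)

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X)
        return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])

    def _binarize(self, Xf: pd.DataFrame, fit: bool) -> pd.DataFrame:
        """Dichotomize numeric (non-0/1) columns at their training median."""
        V = Xf.to_numpy(dtype=float)
        cols = list(Xf.columns)
        if fit:
            binary = ((V == 0.0) | (V == 1.0)).all(axis=0)
            self.thresholds_ = {
                cols[j]: float(np.median(V[:, j]))
                for j in np.flatnonzero(~binary)
            }
        out = V.copy()
        for j, c in enumerate(cols):
            if c in self.thresholds_:
                out[:, j] = V[:, j] > self.thresholds_[c]
        return pd.DataFrame(out.astype(int), index=Xf.index, columns=cols)

    def fit(self, X, y) -> "ChaidClassifier":
        Xf = self._as_frame(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) > 2:
            raise ValueError("ChaidClassifier supports binary outcomes only")
        ybin = (y == self.classes_[-1]).astype(int) if len(self.classes_) == 2 \
            else np.zeros(len(y), dtype=int)
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        self.n_features_in_ = Xf.shape[1]
        params = self._params()
        Xb = self._binarize(Xf, fit=True)
        self.tree_ = _grow_node(Xb, ybin, params, depth=0)
        self.depth_ = _tree_depth(self.tree_)
        self.n_nodes_ = _tree_size(self.tree_)
        return self

    def _route(self, node: ChaidNode, row: np.ndarray,
               index: dict[str, int]) -> ChaidNode:
        while not node.is_leaf:
            j = index.get(node.feature)
            v = 0 if j is None else row[j]
            child = node.children.get(int(v) if np.isscalar(v) else v)
            if child is None:
                # value unseen at training: fall into the group containing it,
                # else the largest child
                child = max(node.children.values(), key=lambda c: sum(c.n_per_class))
            node = child
        return node

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "tree_")
        Xf = self._as_frame(X)
        for c in self.feature_names_in_:
            if c not in Xf.columns:
                Xf = Xf.copy()
                Xf[c] = 0.0   # missing feature reads as 0
        Xb = self._binarize(Xf[list(self.feature_names_in_)], fit=False)
        index = {c: j for j, c in enumerate(Xb.columns)}
        rows = Xb.to_numpy()
        p1 = np.array([
            self._route(self.tree_, rows[i], index).proportion
            for i in range(len(rows))
        ])
        if len(self.classes_) == 1:
            return np.ones((len(p1), 1))
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "tree_")
        Xf = self._as_frame(X)
        for c in self.feature_names_in_:
            if c not in Xf.columns:
                Xf = Xf.copy()
                Xf[c] = 0.0
        Xb = self._binarize(Xf[list(self.feature_names_in_)], fit=False)
        index = {c: j for j, c in enumerate(Xb.columns)}
        rows = Xb.to_numpy()
        pred = np.array([
            self._route(self.tree_, rows[i], index).predicted
            for i in range(len(rows))
        ])
        if len(self.classes_) == 1:
            return np.full(len(pred), self.classes_[0])
        return self.classes_[pred]

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        check_is_fitted(self, "tree_")
        payload = {
            "params": {
                "alpha": self.alpha,
                "max_height": self.max_height,
                "min_node_size": self.min_node_size,
                "bonferroni": self.bonferroni,
                "leaf_rule": self.leaf_rule,
            },
            "classes": [_jsonable(c) for c in self.classes_],
            "thresholds": self.thresholds_,
            "feature_names": list(self.feature_names_in_),
            "tree": self.tree_.to_dict(),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ChaidClassifier":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        est = cls(**payload["params"])
        est.classes_ = np.asarray(payload["classes"])
        est.thresholds_ = payload["thresholds"]
        est.feature_names_in_ = np.asarray(payload["feature_names"], dtype=object)
        est.n_features_in_ = len(est.feature_names_in_)
        est.tree_ = ChaidNode.from_dict(payload["tree"])
        est.depth_ = _tree_depth(est.tree_)
        est.n_nodes_ = _tree_size(est.tree_)
        return est


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def _tree_depth(node: ChaidNode) -> int:
    if node.is_leaf:
        return 0
    return 1 + max(_tree_depth(c) for c in node.children.values())


def _tree_size(node: ChaidNode) -> int:
    if node.is_leaf:
        return 1
    return 1 + sum(_tree_size(c) for c in node.children.values())
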