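"""Gini-based recursive partitioning (CART) and per-subgroup tool search.

CART serves two roles here: a transparent baseline classifier, and a
*pre-partitioner* that splits training patients into subgroups at a chosen
tree depth ("level") so that a separate screening tool can be trained per
subgroup.  Splits minimize Gini impurity over all (variable, observed
value) pairs, with the left branch taking values strictly below the split
value.  Groups at level L are the nodes at depth L, with members of nodes
that stopped splitting earlier carried down unchanged — every level is a
partition of the full cohort.

Validation patients are always routed through the *training* tree and
standardized/classified with training-derived per-group parameters and
tools; nothing is refit on validation data.  Child groups whose parent
group already achieved OMR = 0 inherit the parent's tool instead of
triggering a new search.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

from .io_data import CohortTable, StandardizationParams, fit_standardization, standardize
from .screening import (
    ScreeningTool,
    SearchConfig,
    ToolMetrics,
    classify,
    evaluate,
    search,
)

__all__ = [
    "CartNode",
    "CartTree",
    "LevelGroups",
    "GroupToolResult",
    "LevelResult",
    "gini",
    "fit_cart",
    "assign_groups",
    "per_group_search",
    "level_curves",
]


def gini(n1: int, n0: int) -> float:
    """Gini impurity 1 - p1^2 - p0^2 of a node with class counts (n1, n0)."""
    n = n1 + n0
    if n == 0:
        return 0.0
    p1 = n1 / n
    return 1.0 - p1 * p1 - (1.0 - p1) * (1.0 - p1)


@dataclass
class CartNode:
    node_id: int
    level: int
    index_in_level: int
    n1: int
    n0: int
    members: np.ndarray  # training row indices
    feature: str | None = None
    threshold: float | None = None
    left: int | None = None   # child node ids
    right: int | None = None
    parent: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def gini(self) -> float:
        return gini(self.n1, self.n0)

    @property
    def majority(self) -> int:
        return 1 if self.n1 > self.n0 else 0


@dataclass
class CartTree:
    nodes: list[CartNode]
    variables: list[str]
    max_depth: int

    @property
    def depth(self) -> int:
        return max(nd.level for nd in self.nodes)

    def node(self, node_id: int) -> CartNode:
        return self.nodes[node_id]

    def route(self, X: np.ndarray, level: int | None = None) -> np.ndarray:
        """Node id reached by each row, stopping at ``level`` if given."""
        ids = np.zeros(X.shape[0], dtype=np.int64)
        col = {v: j for j, v in enumerate(self.variables)}
        for i in range(X.shape[0]):
            nd = self.nodes[0]
            while not nd.is_leaf and (level is None or nd.level < level):
                j = col[nd.feature]
                nd = self.nodes[nd.left if X[i, j] < nd.threshold else nd.right]
            ids[i] = nd.node_id
        return ids

    def predict_proba(self, cohort: CohortTable) -> np.ndarray:
        if list(cohort.variables) != list(self.variables):
            raise ValueError("variables do not match the training cohort")
        ids = self.route(cohort.X)
        frac = np.array([nd.n1 / max(1, nd.n1 + nd.n0) for nd in self.nodes])
        return frac[ids]

    def to_dict(self) -> dict:
        return {
            "max_depth": self.max_depth,
            "nodes": [
                {
                    "id": nd.node_id, "level": nd.level,
                    "index_in_level": nd.index_in_level,
                    "n_ild": nd.n1, "n_no_ild": nd.n0,
                    "feature": nd.feature, "threshold": nd.threshold,
                    "left": nd.left, "right": nd.right, "parent": nd.parent,
                }
                for nd in self.nodes
            ],
        }


@dataclass
class LevelGroups:
    """The partition of a cohort into depth-L groups of a fitted tree."""

    level: int
    group_rows: dict[int, np.ndarray]  # node id -> cohort row indices
    counts: dict[int, tuple[int, int]]  # node id -> (n1, n0)

    @property
    def n_groups(self) -> int:
        return len(self.group_rows)


def _best_split(X: np.ndarray, y: np.ndarray, rows: np.ndarray,
                variables: list[str], min_leaf: int = 1):
    """Best (variable, observed value) split by Gini decrease.

    Returns (feature index, threshold, decrease) or None.  Ties are broken
    by (variable name, value).
    """
    n = rows.size
    yv = y[rows]
    n1 = int(yv.sum())
    parent_g = gini(n1, n - n1)
    best = None  # (decrease, name, value, feature_idx)
    tol = 1e-12  # impurity decreases this close count as tied
    for j in range(X.shape[1]):
        xv = X[rows, j]
        order = np.argsort(xv, kind="stable")
        xs = xv[order]
        ys = yv[order]
        c1 = np.cumsum(ys)
        # candidate split at observed value xs[k]: left = x < xs[k]
        ks = np.flatnonzero(xs[1:] > xs[:-1]) + 1  # first index of each new value
        for k in ks:
            if k < min_leaf or n - k < min_leaf:
                continue
            l1 = int(c1[k - 1])
            r1 = n1 - l1
            dec = parent_g - (k / n) * gini(l1, k - l1) \
                - ((n - k) / n) * gini(r1, (n - k) - r1)
            if best is None or dec > best[0] + tol:
                best = (dec, variables[j], float(xs[k]), j)
            elif dec > best[0] - tol and (variables[j], float(xs[k])) < best[1:3]:
                best = (max(dec, best[0]), variables[j], float(xs[k]), j)
    if best is None or best[0] <= 1e-15:
        return None
    return best[3], best[2], best[0]


def fit_cart(train: CohortTable, max_depth: int = 4,
             min_node: int = 2, min_leaf: int = 1) -> CartTree:
    """Grow a Gini tree breadth-first to at most ``max_depth`` levels.

    Nodes stop splitting when pure, smaller than ``min_node``, at
    ``max_depth``, or when no split decreases impurity.
    """
    if train.phenotype.min() == train.phenotype.max():
        raise ValueError("both phenotype classes must be present")
    X, y = train.X, train.phenotype
    root = CartNode(node_id=0, level=0, index_in_level=0,
                    n1=int(y.sum()), n0=int((1 - y).sum()),
                    members=np.arange(train.n_patients))
    nodes = [root]
    frontier = [root]
    for level in range(max_depth):
        next_frontier: list[CartNode] = []
        idx_counter = 0
        for nd in frontier:
            rows = nd.members
            if (rows.size < min_node or nd.n1 == 0 or nd.n0 == 0):
                continue
            found = _best_split(X, y, rows, train.variables, min_leaf)
            if found is None:
                continue
            j, thr, _ = found
            go_left = X[rows, j] < thr
            for side, sub in (("L", rows[go_left]), ("R", rows[~go_left])):
                child = CartNode(
                    node_id=len(nodes), level=level + 1,
                    index_in_level=idx_counter,
                    n1=int(y[sub].sum()), n0=int(sub.size - y[sub].sum()),
                    members=sub, parent=nd.node_id,
                )
                idx_counter += 1
                nodes.append(child)
                if side == "L":
                    nd.left = child.node_id
                else:
                    nd.right = child.node_id
                next_frontier.append(child)
            nd.feature = train.variables[j]
            nd.threshold = thr
        frontier = next_frontier
        if not frontier:
            break
    return CartTree(nodes=nodes, variables=list(train.variables),
                    max_depth=max_depth)


def assign_groups(tree: CartTree, cohort: CohortTable, level: int) -> LevelGroups:
    """Partition ``cohort`` into the tree's depth-``level`` groups.

    Members of nodes that stopped splitting above ``level`` stay in those
    nodes, so the groups always partition the cohort; level 0 is a single
    group at the root.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    if list(cohort.variables) != list(tree.variables):
        raise ValueError("variables do not match the training cohort")
    ids = tree.route(cohort.X, level=level)
    group_rows: dict[int, np.ndarray] = {}
    counts: dict[int, tuple[int, int]] = {}
    for nid in np.unique(ids):
        rows = np.flatnonzero(ids == nid)
        group_rows[int(nid)] = rows
        y = cohort.phenotype[rows]
        counts[int(nid)] = (int(y.sum()), int(rows.size - y.sum()))
    return LevelGroups(level=level, group_rows=group_rows, counts=counts)


@dataclass
class GroupToolResult:
    node_id: int
    tool: ScreeningTool
    params: StandardizationParams
    metrics: ToolMetrics
    inherited: bool


@dataclass
class LevelResult:
    level: int
    groups: list[GroupToolResult]
    pooled_omr: float


def _group_parent_result(tree: CartTree, node_id: int, level: int,
                         parent_results: dict[int, GroupToolResult] | None
                         ) -> GroupToolResult | None:
    """The previous level's result governing this group, if any."""
    if parent_results is None:
        return None
    nd = tree.node(node_id)
    # a node carried down from an earlier level is its own parent group
    prev_id = node_id if nd.level < level else nd.parent
    return parent_results.get(prev_id)


def _search_in_group(group: CohortTable, config: SearchConfig,
                     seed: int) -> tuple[ScreeningTool, StandardizationParams, ToolMetrics]:
    params = fit_standardization(group)
    # drop pool variables that are constant within this subgroup
    sd = group.X.std(axis=0, ddof=1)
    ok = {v for v, s in zip(group.variables, sd) if s > 0}
    pool = [v for v in config.pool if v in ok]
    if not pool:
        raise ValueError("no usable pool variables in subgroup")
    if len(pool) < len(config.pool):
        warnings.warn("dropped constant pool variable(s) within a subgroup")
    sizes = [s for s in config.sizes if s <= len(pool)] or [len(pool)]
    cfg = dataclasses.replace(config, pool=pool, sizes=sizes, seed=seed,
                              keep_leaderboard=False, checkpoint_path=None)
    z = standardize(group, params)
    res = search(z, params, cfg)
    return res.best_tools[0], params, res.best_metrics


def per_group_search(groups: LevelGroups, cohort: CohortTable,
                     config: SearchConfig, tree: CartTree,
                     parent_results: dict[int, GroupToolResult] | None = None
                     ) -> LevelResult:
    """Train a screening tool inside each depth-L group of ``cohort``.

    Groups whose governing parent group reached OMR = 0 inherit the
    parent's tool and standardization without a new search; empty or
    degenerate groups inherit likewise (with a warning).  The pooled level
    OMR is total misclassified over total patients.
    """
    results: list[GroupToolResult] = []
    total_mc = 0
    total = 0
    for nid, rows in sorted(groups.group_rows.items()):
        sub = cohort.subset(rows)
        parent = _group_parent_result(tree, nid, groups.level, parent_results)
        inherit = False
        if parent is not None and parent.metrics.omr == 0.0:
            inherit = True
        elif sub.n_patients < 2:
            warnings.warn(f"group {nid} too small to search; inheriting parent tool")
            inherit = True
        if inherit and parent is not None:
            tool, params = parent.tool, parent.params
            z = standardize(sub, params)
            m = evaluate(classify(tool, z), sub.phenotype)
        else:
            if groups.level == 0 and len(groups.group_rows) == 1:
                # a single root group is exactly the un-partitioned search
                seed = config.seed
            else:
                seed = int(np.random.SeedSequence(
                    config.seed, spawn_key=(groups.level, nid)
                ).generate_state(1)[0] % (2 ** 31))
            tool, params, _ = _search_in_group(sub, config, seed)
            z = standardize(sub, params)
            m = evaluate(classify(tool, z), sub.phenotype)
            # a deeper level must never do worse than the tool it could
            # inherit, so fall back to the parent tool if it beats the search
            if parent is not None:
                zp = standardize(sub, parent.params)
                mp = evaluate(classify(parent.tool, zp), sub.phenotype)
                if (mp.omr, -mp.tpr) < (m.omr, -m.tpr):
                    tool, params, m, inherit = parent.tool, parent.params, mp, True
        results.append(GroupToolResult(node_id=nid, tool=tool, params=params,
                                       metrics=m, inherited=inherit))
        total_mc += m.fp + m.fn
        total += m.total
    return LevelResult(level=groups.level, groups=results,
                       pooled_omr=total_mc / total)


def _apply_level(tree: CartTree, cohort: CohortTable, level: int,
                 trained: LevelResult) -> float:
    """Pooled OMR of a trained level's tools on another (validation) cohort."""
    groups = assign_groups(tree, cohort, level)
    by_id = {g.node_id: g for g in trained.groups}
    mc = 0
    for nid, rows in groups.group_rows.items():
        sub = cohort.subset(rows)
        g = by_id.get(nid)
        if g is None:
            # route deeper only through nodes the training level produced
            raise RuntimeError(f"validation group {nid} unseen in training")
        z = standardize(sub, g.params)
        m = evaluate(classify(g.tool, z), sub.phenotype)
        mc += m.fp + m.fn
    return mc / cohort.n_patients


@dataclass
class LevelCurves:
    levels: list[int]
    train_omr: list[float]
    valid_omr: list[float]
    best_level: int
    curves_cross: bool
    per_level: list[LevelResult]

    def to_dict(self) -> dict:
        return {
            "levels": self.levels,
            "train_omr": self.train_omr,
            "valid_omr": self.valid_omr,
            "best_level": self.best_level,
            "curves_cross": self.curves_cross,
        }


def level_curves(train: CohortTable, valid: CohortTable, tree: CartTree,
                 config: SearchConfig) -> LevelCurves:
    """Training and validation pooled OMR per pre-partitioning level.

    Tools are trained level by level (each level reusing the previous
    level's results for the parent-OMR-zero inheritance rule); validation
    patients are routed through the training tree and scored with the
    training tools.  ``best_level`` minimizes validation OMR (ties toward
    the shallower level); ``curves_cross`` flags the over-fitting
    signature of a validation curve rising while training keeps falling.
    """
    levels = list(range(tree.depth + 1))
    parent: dict[int, GroupToolResult] | None = None
    train_omr: list[float] = []
    valid_omr: list[float] = []
    per_level: list[LevelResult] = []
    for lv in levels:
        groups = assign_groups(tree, train, lv)
        res = per_group_search(groups, train, config, tree, parent)
        per_level.append(res)
        train_omr.append(res.pooled_omr)
        valid_omr.append(_apply_level(tree, valid, lv, res))
        parent = {g.node_id: g for g in res.groups}
    best_level = int(np.argmin(valid_omr))
    crossed = any(valid_omr[i + 1] > valid_omr[i]
                  and train_omr[i + 1] <= train_omr[i]
                  for i in range(len(levels) - 1))
    return LevelCurves(levels=levels, train_omr=train_omr, valid_omr=valid_omr,
                       best_level=best_level, curves_cross=crossed,
                       per_level=per_level)
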