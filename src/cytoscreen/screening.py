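"""Randomized design of any-out-of-bounds threshold screening tools.

A screening tool is deliberately simple: k variables, each with one
negative lower and one positive upper threshold in standardized (z-score)
units; a patient is declared a case iff *any* of their k standardized
expressions falls above its upper or below its lower threshold (strict
inequalities; values on a threshold count as in-bounds).

Tool design is a pure random search: for every candidate variable subset,
many threshold realizations are drawn uniformly over the standardized
training ranges — upper ~ U(0, zmax], lower ~ U[zmin, 0) per variable —
and tools are ranked by a two-level metric: minimize the overall
misclassification rate (OMR), break ties by maximal true positive rate
(TPR), then by a deterministic tool hash.  Best tools need not be unique;
all co-optimal tools are retained.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .io_data import CohortTable, StandardizationParams

__all__ = [
    "ScreeningTool",
    "ToolMetrics",
    "SearchConfig",
    "SearchResult",
    "classify",
    "evaluate",
    "random_tool",
    "enumerate_subsets",
    "search",
]


@dataclass
class ScreeningTool:
    """k variables with per-variable (lower < 0 < upper) z-thresholds."""

    variables: list[str]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        k = len(self.variables)
        if k < 1 or self.lower.shape != (k,) or self.upper.shape != (k,):
            raise ValueError("need k >= 1 variables with k lower and k upper thresholds")
        if not (np.all(self.lower < 0) and np.all(self.upper > 0)):
            raise ValueError("thresholds must satisfy lower < 0 < upper")

    @property
    def k(self) -> int:
        return len(self.variables)

    def hash(self) -> str:
        """Deterministic content hash used as the final tie-breaker."""
        h = hashlib.sha256()
        h.update(",".join(self.variables).encode())
        h.update(np.ascontiguousarray(self.lower).tobytes())
        h.update(np.ascontiguousarray(self.upper).tobytes())
        return h.hexdigest()

    def to_dict(self, params: StandardizationParams | None = None) -> dict:
        d = {
            "variables": list(self.variables),
            "lower_z": self.lower.tolist(),
            "upper_z": self.upper.tolist(),
        }
        if params is not None:
            idx = [params.variables.index(v) for v in self.variables]
            mean, sd = params.mean[idx], params.sd[idx]
            d["lower_raw"] = (self.lower * sd + mean).tolist()
            d["upper_raw"] = (self.upper * sd + mean).tolist()
        return d


@dataclass
class ToolMetrics:
    """Confusion counts and the four candidate selection metrics.

    ``metric1`` is predicted-positive count / (TP + FN); ``metric2`` is the
    TPR; ``metric3`` their product; ``score`` = 1 - OMR.  Model selection
    uses the two-level (OMR, TPR) policy, so the historically ambiguous
    metric1 never drives a decision.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def omr(self) -> float:
        return (self.fp + self.fn) / self.total

    @property
    def tpr(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else 0.0

    @property
    def metric1(self) -> float:
        pos = self.tp + self.fn
        return (self.tp + self.fp) / pos if pos else 0.0

    @property
    def metric2(self) -> float:
        return self.tpr

    @property
    def metric3(self) -> float:
        return self.metric1 * self.metric2

    @property
    def score(self) -> float:
        return 1.0 - self.omr

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "omr": self.omr, "tpr": self.tpr, "score": self.score}


@dataclass
class SearchConfig:
    """Random-search settings over subsets of a candidate pool."""

    pool: list[str]
    sizes: Sequence[int] = (3, 4, 5, 6)
    realizations: int = 1000
    seed: int = 0
    keep_leaderboard: bool = True
    checkpoint_path: str | Path | None = None
    checkpoint_every: int = 1000

    def __post_init__(self) -> None:
        if len(self.pool) == 0:
            raise ValueError("empty candidate pool")
        if len(set(self.pool)) != len(self.pool):
            raise ValueError("duplicate variables in pool")
        if any(s < 1 or s > len(self.pool) for s in self.sizes):
            raise ValueError("subset sizes must be within [1, pool size]")
        if self.realizations < 1:
            raise ValueError("realizations must be >= 1")


@dataclass
class SearchResult:
    best_tools: list[ScreeningTool]
    best_metrics: ToolMetrics
    n_subsets: int
    n_tools_evaluated: int
    leaderboard: list[dict] | None


def classify(tool: ScreeningTool, cohort: CohortTable) -> np.ndarray:
    """Per-patient 0/1 prediction on a *standardized* cohort.

    1 iff any member variable is strictly above its upper or strictly
    below its lower threshold.
    """
    missing = [v for v in tool.variables if v not in cohort.variables]
    if missing:
        raise ValueError(f"tool variable(s) missing from cohort: {missing}")
    cols = [cohort.variables.index(v) for v in tool.variables]
    Z = cohort.X[:, cols]
    out = (Z > tool.upper) | (Z < tool.lower)
    return out.any(axis=1).astype(np.int64)


def evaluate(predictions: np.ndarray, phenotype: np.ndarray) -> ToolMetrics:
    """Confusion counts of 0/1 predictions against 0/1 labels."""
    predictions = np.asarray(predictions)
    phenotype = np.asarray(phenotype)
    if predictions.shape != phenotype.shape:
        raise ValueError("predictions and phenotype lengths differ")
    if not set(np.unique(phenotype)) <= {0, 1}:
        raise ValueError("phenotype must be binary 0/1")
    tp = int(np.sum((predictions == 1) & (phenotype == 1)))
    fp = int(np.sum((predictions == 1) & (phenotype == 0)))
    tn = int(np.sum((predictions == 0) & (phenotype == 0)))
    fn = int(np.sum((predictions == 0) & (phenotype == 1)))
    return ToolMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def _threshold_ranges(variables: Sequence[str],
                      params: StandardizationParams) -> tuple[np.ndarray, np.ndarray]:
    idx = []
    for v in variables:
        if v not in params.variables:
            raise ValueError(f"no standardization parameters for {v!r}")
        idx.append(params.variables.index(v))
    zmin = params.zmin[idx].copy()
    zmax = params.zmax[idx].copy()
    onesided = (zmax <= 0) | (zmin >= 0)
    if onesided.any():
        eps = 1e-6
        warnings.warn("variable(s) entirely one-sided after standardization; "
                      "widening threshold range to +/- eps")
        zmax = np.where(zmax <= 0, eps, zmax)
        zmin = np.where(zmin >= 0, -eps, zmin)
    return zmin, zmax


def random_tool(variables: Sequence[str], params: StandardizationParams,
                rng: np.random.Generator) -> ScreeningTool:
    """One uniform threshold realization: upper ~ U(0, zmax], lower ~ U[zmin, 0)."""
    zmin, zmax = _threshold_ranges(variables, params)
    k = len(variables)
    upper = zmax * (1.0 - rng.random(k))
    lower = zmin * (1.0 - rng.random(k))
    return ScreeningTool(variables=list(variables), lower=lower, upper=upper)


def enumerate_subsets(pool_size: int, sizes: Iterable[int]
                      ) -> tuple[int, Iterator[tuple[int, ...]]]:
    """Exact count and deterministic lexicographic iterator of subsets.

    E.g. a pool of 27 with sizes 3..6 yields 2,925 + 17,550 + 80,730 +
    296,010 = 397,215 subsets; sizes 1..27 yield 2^27 - 1 = 134,217,727.
    """
    sizes = sorted(set(int(s) for s in sizes))
    if any(s < 0 or s > pool_size for s in sizes):
        raise ValueError(f"sizes must be within [0, {pool_size}]")
    count = sum(math.comb(pool_size, s) for s in sizes)

    def _iter() -> Iterator[tuple[int, ...]]:
        for s in sizes:
            yield from itertools.combinations(range(pool_size), s)

    return count, _iter()


def _batch_confusion(Z: np.ndarray, y: np.ndarray, lower: np.ndarray,
                     upper: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized confusion counts for a batch of tools on one subset.

    Z: (n, k) standardized values; lower/upper: (R, k) thresholds.
    """
    flagged = ((Z[None, :, :] > upper[:, None, :])
               | (Z[None, :, :] < lower[:, None, :])).any(axis=2)
    tp = flagged @ y
    predpos = flagged.sum(axis=1)
    fp = predpos - tp
    n1 = int(y.sum())
    n0 = y.size - n1
    fn = n1 - tp
    tn = n0 - fp
    return tp, fp, tn, fn


def search(train: CohortTable, params: StandardizationParams,
           config: SearchConfig) -> SearchResult:
    """Exhaustive subset enumeration x random threshold search.

    ``train`` must already be standardized with ``params``.  For each
    subset, ``config.realizations`` random tools are drawn from a
    per-subset generator deterministically derived from the master seed
    (so distributed execution over subset ranges reproduces the serial
    result); the global best under (OMR, then TPR, then tool hash) is
    kept, together with every co-optimal tool.
    """
    y = np.asarray(train.phenotype, dtype=np.int64)
    cols = [train.variables.index(v) for v in config.pool]
    Zpool = train.X[:, cols]
    zmin, zmax = _threshold_ranges(config.pool, params)

    n_subsets, subsets = enumerate_subsets(len(config.pool), config.sizes)
    best_key: tuple[float, float] | None = None  # (omr, -tpr)
    best: list[tuple[ScreeningTool, ToolMetrics]] = []
    leaderboard: list[dict] | None = [] if config.keep_leaderboard else None
    n_eval = 0
    R = config.realizations

    for s_idx, subset in enumerate(subsets):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(s_idx,)))
        k = len(subset)
        sub = list(subset)
        # one contiguous block of 2k uniforms per realization, so the first
        # R draws are identical for any larger R (nested-seed property)
        u = rng.random((R, 2, k))
        upper = zmax[sub] * (1.0 - u[:, 0, :])
        lower = zmin[sub] * (1.0 - u[:, 1, :])
        Z = Zpool[:, sub]
        tp, fp, tn, fn = _batch_confusion(Z, y, lower, upper)
        n_eval += R
        omr = (fp + fn) / y.size
        n1 = int(y.sum())
        tpr = tp / n1 if n1 else np.zeros_like(omr)
        # best within subset
        sub_best = np.lexsort((-tpr, omr))[0]
        sub_key = (float(omr[sub_best]), -float(tpr[sub_best]))
        if leaderboard is not None:
            leaderboard.append({
                "subset": [config.pool[j] for j in sub],
                "omr": float(omr[sub_best]),
                "tpr": float(tpr[sub_best]),
            })
        if best_key is None or sub_key <= best_key:
            # collect all co-optimal realizations of this subset
            ties = np.flatnonzero((omr == sub_key[0]) & (tpr == -sub_key[1]))
            new_tools = []
            for t in ties:
                tool = ScreeningTool(variables=[config.pool[j] for j in sub],
                                     lower=lower[t], upper=upper[t])
                m = ToolMetrics(tp=int(tp[t]), fp=int(fp[t]),
                                tn=int(tn[t]), fn=int(fn[t]))
                new_tools.append((tool, m))
            if best_key is None or sub_key < best_key:
                best_key = sub_key
                best = new_tools
            else:  # equal key: extend co-optimal set
                best.extend(new_tools)

        if (config.checkpoint_path is not None
                and (s_idx + 1) % config.checkpoint_every == 0):
            _write_checkpoint(config.checkpoint_path, s_idx + 1, n_subsets,
                              best, best_key)

    best.sort(key=lambda tm: tm[0].hash())
    return SearchResult(
        best_tools=[t for t, _ in best],
        best_metrics=best[0][1],
        n_subsets=n_subsets,
        n_tools_evaluated=n_eval,
        leaderboard=leaderboard,
    )


def _write_checkpoint(path: str | Path, done: int, total: int,
                      best: list[tuple[ScreeningTool, ToolMetrics]],
                      best_key) -> None:
    payload = {
        "subsets_done": done,
        "subsets_total": total,
        "best_omr": best_key[0],
        "best_tpr": -best_key[1],
        "best_tools": [t.to_dict() for t, _ in best],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
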