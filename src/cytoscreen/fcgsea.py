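"""Feature-set enrichment over flow-cytometry variables (GSEA-style).

Variables take the role of genes: an "FC set" of size G (typically the
top-G variables of a forest importance list) is scored against the list
of all N variables ranked by correlation with the binary phenotype, from
largest positive to largest negative.  Walking down the ranked list, the
running sum gains

    +sqrt((N - G) / G)   when the variable is a set member,
    -sqrt(G / (N - G))   otherwise,

so it returns to exactly 0 at the last step.  The enrichment score ES is
the supremum of the running sum; it is large when set members cluster
near the top of the ranked list, i.e. when the set moves in a coordinated
way with the phenotype.

Significance uses class-label randomization: the phenotype is permuted,
all correlations re-estimated and re-ranked, the walk re-run for the same
set, and the p-value is the fraction of permuted ES values exceeding the
observed one.  (Permuting variables instead would ignore inter-variable
correlation and be anticonservative.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .cif_forest import VariableImportanceList
from .io_data import CohortTable

__all__ = [
    "RankedCorrelationList",
    "FCSet",
    "RandomWalkResult",
    "EnrichmentResult",
    "rank_by_correlation",
    "form_fc_set",
    "form_fc_set_window",
    "form_fc_set_explicit",
    "random_walk",
    "scan_set_sizes",
    "permutation_pvalue",
]


@dataclass
class RankedCorrelationList:
    """Variables sorted by (signed or absolute) correlation with phenotype."""

    entries: list[tuple[str, float]]
    method: str  # "pearson" | "spearman"
    mode: str    # "signed" | "absolute"

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class FCSet:
    """A set of variables scored as one unit, with its provenance."""

    members: list[str]
    provenance: str = "explicit"

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError("FC set must be non-empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError("FC set members must be unique")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class RandomWalkResult:
    running_sum: np.ndarray
    es: float
    argmax_step: int  # 0-based index of the first step attaining the supremum


@dataclass
class EnrichmentResult:
    g_values: np.ndarray
    es: np.ndarray
    p_values: np.ndarray | None
    n_permutations: int
    best_g: int
    method: str
    mode: str

    def es_at(self, g: int) -> float:
        return float(self.es[int(np.flatnonzero(self.g_values == g)[0])])


# ---------------------------------------------------------------------------
# correlation ranking
# ---------------------------------------------------------------------------

def _prepared_columns(cohort: CohortTable, method: str) -> np.ndarray:
    """Columns (optionally rank-transformed), centered and L2-normalized.

    With a binary phenotype, Spearman correlation equals Pearson correlation
    of the rank-transformed columns (the rank transform of a 0/1 vector is
    affine in the vector), so both methods reduce to one matrix product.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    X = cohort.X
    if method == "spearman":
        X = np.apply_along_axis(rankdata, 0, X)
    Xc = X - X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        names = [cohort.variables[i] for i in bad]
        raise ValueError(f"constant variable(s), correlation undefined: {names}")
    return Xc / norms


def _corr_with(yc_unit: np.ndarray, Xn: np.ndarray) -> np.ndarray:
    return yc_unit @ Xn


def rank_by_correlation(cohort: CohortTable, method: str = "pearson",
                        mode: str = "signed") -> RankedCorrelationList:
    """Rank all variables by correlation with the 0/1 phenotype.

    Signed mode sorts from largest positive to largest negative; absolute
    mode sorts by |r| descending (only up-regulation is then possible in
    the walk).  Ties are broken lexicographically by variable name.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError(f"unknown mode {mode!r}")
    y = cohort.phenotype
    if y.min() == y.max():
        raise ValueError("phenotype has a single class; correlation undefined")
    Xn = _prepared_columns(cohort, method)
    yc = y - y.mean()
    yc = yc / np.linalg.norm(yc)
    r = _corr_with(yc, Xn)
    key = np.abs(r) if mode == "absolute" else r
    order = sorted(range(len(r)), key=lambda j: (-key[j], cohort.variables[j]))
    entries = [(cohort.variables[j], float(r[j])) for j in order]
    return RankedCorrelationList(entries=entries, method=method, mode=mode)


# ---------------------------------------------------------------------------
# FC set construction
# ---------------------------------------------------------------------------

def form_fc_set(vil: VariableImportanceList, g: int) -> FCSet:
    """Top-down set: the ``g`` highest-mean-importance variables."""
    if not 1 <= g < len(vil.entries):
        raise ValueError(f"G must be in [1, {len(vil.entries) - 1}], got {g}")
    return FCSet(members=vil.top(g), provenance=f"vil_top_down({g})")


def form_fc_set_window(vil: VariableImportanceList, a: int, b: int) -> FCSet:
    """Variables ranked ``a`` through ``b`` (1-based, inclusive) in the VIL."""
    if not 1 <= a <= b <= len(vil.entries):
        raise ValueError(f"window [{a}, {b}] out of range")
    members = [name for name, _ in vil.entries[a - 1:b]]
    return FCSet(members=members, provenance=f"vil_window({a},{b})")


def form_fc_set_explicit(names: list[str],
                         universe: list[str] | None = None) -> FCSet:
    """An explicitly specified set (e.g. a marker panel chosen a priori)."""
    if universe is not None:
        unknown = [n for n in names if n not in universe]
        if unknown:
            raise ValueError(f"unknown variable(s): {unknown}")
    return FCSet(members=list(names), provenance="explicit")


# ---------------------------------------------------------------------------
# random walk
# ---------------------------------------------------------------------------

def walk_increments(n: int, g: int) -> tuple[float, float]:
    """(hit, miss) step sizes: +sqrt((N-G)/G) and -sqrt(G/(N-G))."""
    if not 1 <= g < n:
        raise ValueError(f"need 1 <= G < N, got G={g}, N={n}")
    return math.sqrt((n - g) / g), -math.sqrt(g / (n - g))


def _walk_from_hits(hits: np.ndarray) -> RandomWalkResult:
    n = hits.size
    g = int(hits.sum())
    up, down = walk_increments(n, g)
    steps = np.where(hits, up, down)
    running = np.cumsum(steps)
    # signed supremum of the step values; >= 0 because the walk ends at 0
    argmax = int(np.argmax(running))
    es = float(running[argmax])
    if es < 0:
        es = 0.0
        argmax = n - 1
    return RandomWalkResult(running_sum=running, es=es, argmax_step=argmax)


def random_walk(ranked: RankedCorrelationList, fcset: FCSet,
                absolute_es: bool = False) -> RandomWalkResult:
    """Run the walk for ``fcset`` down the correlation-ranked list.

    ``absolute_es=True`` scores the maximal |running sum| instead of the
    signed supremum.
    """
    members = set(fcset.members)
    unknown = members - set(ranked.names)
    if unknown:
        raise ValueError(f"set members absent from ranked list: {sorted(unknown)}")
    hits = np.fromiter((name in members for name in ranked.names),
                       dtype=bool, count=len(ranked))
    result = _walk_from_hits(hits)
    if absolute_es:
        k = int(np.argmax(np.abs(result.running_sum)))
        result.es = float(abs(result.running_sum[k]))
        result.argmax_step = k
    return result


# ---------------------------------------------------------------------------
# permutation machinery (vectorized over permutations)
# ---------------------------------------------------------------------------

def _lex_prepared(cohort: CohortTable, method: str):
    """Columns sorted by name so a stable argsort breaks ties lexically."""
    lex = sorted(range(cohort.n_variables), key=lambda j: cohort.variables[j])
    Xn = _prepared_columns(cohort, method)[:, lex]
    names = [cohort.variables[j] for j in lex]
    return Xn, names


def _es_for_permutations(Xn: np.ndarray, member_mask: np.ndarray,
                         Y: np.ndarray, mode: str) -> np.ndarray:
    """ES of the walk for each permuted label row in ``Y``."""
    C = Y @ Xn  # proportional to Pearson r, same factor for every row/column
    key = np.abs(C) if mode == "absolute" else C
    order = np.argsort(-key, axis=1, kind="stable")
    hits = member_mask[order]
    n = Xn.shape[1]
    g = int(member_mask.sum())
    up, down = walk_increments(n, g)
    steps = np.where(hits, up, down)
    running = np.cumsum(steps, axis=1)
    return np.maximum(running.max(axis=1), 0.0)


def permutation_pvalue(fcset: FCSet, cohort: CohortTable, n_perm: int = 10_000,
                       method: str = "pearson", mode: str = "signed",
                       seed: int = 0, smoothed: bool = False) -> float:
    """Phenotype-permutation p-value for the observed ES of ``fcset``.

    Each permutation shuffles the labels, re-ranks *all* variables by their
    correlation with the shuffled labels, re-runs the walk for the fixed
    set and records its ES.  p = #{ES_perm > ES_obs} / n_perm (strict, per
    the counting definition); ``smoothed=True`` returns the add-one
    estimate (#+1)/(n_perm+1) instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = cohort.phenotype
    if y.min() == y.max():
        raise ValueError("phenotype has a single class")
    Xn, names = _lex_prepared(cohort, method)
    members = set(fcset.members)
    unknown = members - set(names)
    if unknown:
        raise ValueError(f"set members absent from cohort: {sorted(unknown)}")
    member_mask = np.fromiter((n in members for n in names), dtype=bool,
                              count=len(names))
    yc = (y - y.mean()).astype(float)
    es_obs = float(_es_for_permutations(Xn, member_mask, yc[None, :], mode)[0])

    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = 2048
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        Y = np.tile(yc, (k, 1))
        Y = rng.permuted(Y, axis=1)
        es_perm = _es_for_permutations(Xn, member_mask, Y, mode)
        exceed += int((es_perm > es_obs).sum())
        done += k
    if smoothed:
        return (exceed + 1) / (n_perm + 1)
    return exceed / n_perm


def scan_set_sizes(vil: VariableImportanceList, cohort: CohortTable,
                   g_range, method: str = "pearson", mode: str = "signed",
                   n_perm: int = 0, seed: int = 0) -> EnrichmentResult:
    """ES (and optional permutation p-values) for top-down sets over G.

    One fixed correlation-ranked list is used for every G.  ``best_g`` is
    the G with the largest ES, ties broken toward smaller G.  With
    ``n_perm > 0``, one shared pool of label permutations is re-ranked
    once and scored against every G's set.
    """
    g_values = np.asarray(sorted(set(int(g) for g in g_range)), dtype=int)
    if g_values.size == 0:
        raise ValueError("empty G range")
    if g_values.min() < 1 or g_values.max() >= cohort.n_variables:
        raise ValueError("G range must lie within [1, N-1]")
    ranked = rank_by_correlation(cohort, method=method, mode=mode)
    es = np.empty(g_values.size)
    sets = [form_fc_set(vil, int(g)) for g in g_values]
    for i, fcset in enumerate(sets):
        es[i] = random_walk(ranked, fcset).es

    p_values = None
    if n_perm > 0:
        Xn, names = _lex_prepared(cohort, method)
        masks = []
        for fcset in sets:
            members = set(fcset.members)
            masks.append(np.fromiter((n in members for n in names), dtype=bool,
                                     count=len(names)))
        y = cohort.phenotype
        yc = (y - y.mean()).astype(float)
        rng = np.random.default_rng(seed)
        exceed = np.zeros(g_values.size, dtype=int)
        chunk = 1024
        done = 0
        while done < n_perm:
            k = min(chunk, n_perm - done)
            Y = rng.permuted(np.tile(yc, (k, 1)), axis=1)
            C = Y @ Xn
            key = np.abs(C) if mode == "absolute" else C
            order = np.argsort(-key, axis=1, kind="stable")
            for i, mask in enumerate(masks):
                hits = mask[order]
                up, down = walk_increments(len(names), int(mask.sum()))
                running = np.cumsum(np.where(hits, up, down), axis=1)
                es_perm = np.maximum(running.max(axis=1), 0.0)
                exceed[i] += int((es_perm > es[i]).sum())
            done += k
        p_values = exceed / n_perm

    best_g = int(g_values[int(np.argmax(es))])  # argmax takes the first max
    return EnrichmentResult(g_values=g_values, es=es, p_values=p_values,
                            n_permutations=n_perm, best_g=best_g,
                            method=method, mode=mode)
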