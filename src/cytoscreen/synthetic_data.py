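"""Seeded synthetic cohorts with known ground truth.

Real cohorts of gated flow-cytometry expressions show two features the
downstream stages must cope with: (i) heavy correlation among variables
derived from the same staining panel / gating hierarchy, and (ii) a small
subset of variables with *coordinated* association with the phenotype —
some up-regulated and some down-regulated in cases.  The generator
emulates both with an equicorrelated-block Gaussian model:

    x_j = sqrt(rho) * f_b(j) + sqrt(1 - rho) * e_j        (unit variance)

where ``f_b`` is a per-block latent factor, so within-block correlation is
``rho`` and across-block correlation is 0.  Two phenotype mechanisms are
supported, exactly one active per spec:

* shift model — phenotype ~ Bernoulli(prevalence); each informative
  variable is shifted by ``effect * phenotype`` with the effect in SD
  units (signed, so mixed up/down regulation is expressible);
* planted threshold rule — phenotype is 1 iff any planted variable falls
  outside its planted bounds; this makes the screening-tool search
  recoverable by construction.

Defaults mirror the motivating study's scale: 119 patients, 112 variables,
case prevalence 0.48.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_data import CohortTable

__all__ = [
    "PlantedRule",
    "SyntheticSpec",
    "GroundTruth",
    "generate_cohort",
    "generate_null_cohort",
]


@dataclass
class PlantedRule:
    """A planted any-out-of-bounds rule: phenotype 1 iff any member variable
    is below its lower or above its upper bound (bounds in SD units)."""

    var_idx: list[int]
    lower: list[float]
    upper: list[float]

    def __post_init__(self) -> None:
        if not (len(self.var_idx) == len(self.lower) == len(self.upper)):
            raise ValueError("var_idx, lower and upper must have equal length")
        for lo, up in zip(self.lower, self.upper):
            if not lo < up:
                raise ValueError("each lower bound must be below its upper bound")

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Evaluate the rule on raw columns of ``X`` (strict inequalities)."""
        sub = X[:, self.var_idx]
        out = (sub > np.asarray(self.upper)) | (sub < np.asarray(self.lower))
        return out.any(axis=1).astype(np.int64)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic cohort; see the module docstring."""

    n_patients: int = 119
    n_vars: int = 112
    informative: list[tuple[int, float]] = field(default_factory=list)
    latent_blocks: list[list[int]] = field(default_factory=list)
    rho: float = 0.3
    prevalence: float = 0.48
    threshold_rule: PlantedRule | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_vars <= 0:
            raise ValueError("n_patients and n_vars must be positive")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        idx = [i for i, _ in self.informative]
        if any(not 0 <= i < self.n_vars for i in idx) or len(set(idx)) != len(idx):
            raise ValueError("informative indices invalid or duplicated")
        if any(not np.isfinite(e) for _, e in self.informative):
            raise ValueError("effect sizes must be finite")
        seen: set[int] = set()
        for block in self.latent_blocks:
            for i in block:
                if not 0 <= i < self.n_vars or i in seen:
                    raise ValueError("latent_blocks must be a partition of valid indices")
                seen.add(i)
        if self.threshold_rule is not None:
            if self.informative:
                raise ValueError("exactly one of shift model / threshold_rule may be active")
            if any(not 0 <= i < self.n_vars for i in self.threshold_rule.var_idx):
                raise ValueError("threshold_rule indices out of range")


@dataclass
class GroundTruth:
    """What was planted: informative (index, signed effect) pairs or a rule."""

    informative: list[tuple[int, float]]
    rule: PlantedRule | None
    blocks: list[list[int]]
    rho: float


def _variable_names(p: int) -> list[str]:
    return [f"fc{i + 1:03d}" for i in range(p)]


def generate_cohort(spec: SyntheticSpec) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort from ``spec``; reproducible for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_patients, spec.n_vars

    X = rng.standard_normal((n, p))
    if spec.rho > 0:
        for block in spec.latent_blocks:
            f = rng.standard_normal(n)
            X[:, block] = (
                np.sqrt(spec.rho) * f[:, None]
                + np.sqrt(1.0 - spec.rho) * X[:, block]
            )

    if spec.threshold_rule is not None:
        y = spec.threshold_rule.apply(X)
    else:
        y = (rng.random(n) < spec.prevalence).astype(np.int64)
        for j, effect in spec.informative:
            X[:, j] = X[:, j] + effect * y

    cohort = CohortTable(
        patient_ids=[f"p{i + 1:04d}" for i in range(n)],
        variables=_variable_names(p),
        X=X,
        phenotype=y,
    )
    truth = GroundTruth(
        informative=list(spec.informative),
        rule=spec.threshold_rule,
        blocks=[list(b) for b in spec.latent_blocks],
        rho=spec.rho,
    )
    return cohort, truth


def generate_null_cohort(n_patients: int, n_vars: int, seed: int) -> CohortTable:
    """Pure-noise cohort: no informative variables, prevalence 0.5."""
    spec = SyntheticSpec(
        n_patients=n_patients, n_vars=n_vars, informative=[],
        latent_blocks=[], rho=0.0, prevalence=0.5, seed=seed,
    )
    cohort, _ = generate_cohort(spec)
    return cohort
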