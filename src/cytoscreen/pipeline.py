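"""End-to-end orchestration: split -> mean VIL -> enrichment scan ->
screening-tool search (flat and CART pre-partitioned) -> validation.

Also houses the evaluation primitives shared by the stages: the mean-only
baseline (constant prediction at the training prevalence, whose in-sample
errors are exactly MSE = p(1-p) and MAE = 2p(1-p)), and ROC/AUC.

Every stochastic stage draws its seed from the master seed through named
spawn keys, so any stage can be replayed in isolation from the run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_curve

from . import cart_partition, cif_forest, fcgsea, screening
from .io_data import (
    CohortTable,
    fit_standardization,
    split_cohort,
    standardize,
)

__all__ = [
    "PipelineConfig",
    "EvaluationReport",
    "mean_only_baseline",
    "roc_auc",
    "run_pipeline",
]

logger = logging.getLogger("cytoscreen")


# ---------------------------------------------------------------------------
# evaluation primitives
# ---------------------------------------------------------------------------

def mean_only_baseline(train: CohortTable, eval_set: CohortTable
                       ) -> tuple[np.ndarray, float, float]:
    """Constant prediction at the training prevalence; (predictions, MAE, MSE)."""
    if train.n_patients == 0:
        raise ValueError("empty training set")
    p = train.prevalence
    y = eval_set.phenotype
    preds = np.full(eval_set.n_patients, p)
    mae = float(np.mean(np.abs(y - preds)))
    mse = float(np.mean((y - preds) ** 2))
    return preds, mae, mse


def roc_auc(scores: np.ndarray, labels: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points and trapezoidal AUC (equals the Mann-Whitney statistic).

    Returns (fpr, tpr, auc) with endpoints (0, 0) and (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def prob_errors(preds: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(MAE, MSE) of probability predictions against 0/1 labels."""
    d = np.asarray(labels, dtype=float) - np.asarray(preds, dtype=float)
    return float(np.mean(np.abs(d))), float(np.mean(d * d))


# ---------------------------------------------------------------------------
# configuration and report
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """One master seed plus the per-stage settings.

    Stage seeds are derived as SeedSequence(seed, spawn_key=(k,)) with a
    fixed key per stage, logged so stages can be replayed in isolation.
    """

    phenotype_column: str = "phenotype"
    n_train: int = 79
    seed: int = 0
    stratified_split: bool = False
    forest: cif_forest.ForestConfig = field(
        default_factory=lambda: cif_forest.ForestConfig())
    g_min: int = 3
    g_max: int = 50
    n_perm: int = 10_000
    corr_method: str = "pearson"
    corr_mode: str = "signed"
    sizes: tuple[int, ...] = (3, 4, 5, 6)
    realizations: int = 1000
    cart_max_depth: int = 4
    output_dir: str | Path | None = None

    def stage_seed(self, key: int) -> int:
        return int(np.random.SeedSequence(self.seed, spawn_key=(key,))
                   .generate_state(1)[0] % (2 ** 31))


_STAGE_KEYS = {"split": 1, "forest": 2, "gsea": 3, "screening": 4, "cart": 5}


@dataclass
class EvaluationReport:
    seeds: dict[str, int]
    baseline: dict
    forest_eval: dict
    vil: cif_forest.VariableImportanceList
    enrichment: fcgsea.EnrichmentResult
    fc_set: fcgsea.FCSet
    flat_search: screening.SearchResult
    flat_validation: screening.ToolMetrics
    level_curves: cart_partition.LevelCurves

    def to_dict(self) -> dict:
        enr = self.enrichment
        return {
            "seeds": self.seeds,
            "baseline": self.baseline,
            "forest_eval": self.forest_eval,
            "vil_top": self.vil.entries[:30],
            "enrichment": {
                "g": enr.g_values.tolist(),
                "es": enr.es.tolist(),
                "p": None if enr.p_values is None else enr.p_values.tolist(),
                "best_g": enr.best_g,
                "method": enr.method,
                "mode": enr.mode,
            },
            "fc_set": self.fc_set.members,
            "flat_search": {
                "best_omr": self.flat_search.best_metrics.omr,
                "best_tpr": self.flat_search.best_metrics.tpr,
                "n_subsets": self.flat_search.n_subsets,
                "n_co_optimal": len(self.flat_search.best_tools),
                "best_tool": self.flat_search.best_tools[0].to_dict(),
            },
            "flat_validation": self.flat_validation.to_dict(),
            "level_curves": self.level_curves.to_dict(),
        }


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cohort: CohortTable, config: PipelineConfig) -> EvaluationReport:
    """Run all four stages on ``cohort`` and return the evaluation report.

    Stages: (1) forest runs producing a mean variable importance list;
    (2) enrichment scan over set sizes with phenotype-permutation
    p-values, selecting the best set; (3) randomized screening-tool
    search over that set, flat and CART-pre-partitioned; (4) validation
    of the trained tools on the held-out split.
    """
    seeds = {name: config.stage_seed(k) for name, k in _STAGE_KEYS.items()}
    logger.info("stage seeds: %s", seeds)

    train, valid = split_cohort(cohort, config.n_train, seeds["split"],
                                stratify=config.stratified_split)
    logger.info("split: %d training / %d validation patients",
                train.n_patients, valid.n_patients)

    # baseline + forest evaluation (probability-scale errors, both
    # resubstitution and out-of-bag, plus training ROC/AUC)
    _, base_mae, base_mse = mean_only_baseline(train, train)
    forest_cfg = dataclasses.replace(config.forest, seed=seeds["forest"])
    model = cif_forest.fit_forest(train, forest_cfg)
    resub = cif_forest.predict(model, train)
    oob = cif_forest.predict_oob(model, train)
    resub_mae, resub_mse = prob_errors(resub, train.phenotype)
    oob_mae, oob_mse = prob_errors(oob, train.phenotype)
    _, _, auc_resub = roc_auc(resub, train.phenotype)
    _, _, auc_oob = roc_auc(oob, train.phenotype)

    vil = cif_forest.mean_vil(train, forest_cfg)
    logger.info("VIL head: %s", vil.entries[:5])

    g_hi = min(config.g_max, train.n_variables - 1)
    enrichment = fcgsea.scan_set_sizes(
        vil, train, range(config.g_min, g_hi + 1),
        method=config.corr_method, mode=config.corr_mode,
        n_perm=config.n_perm, seed=seeds["gsea"])
    fc_set = fcgsea.form_fc_set(vil, enrichment.best_g)
    logger.info("best G = %d (ES = %.3f)", enrichment.best_g,
                enrichment.es_at(enrichment.best_g))

    params = fit_standardization(train)
    ztrain = standardize(train, params)
    zvalid = standardize(valid, params)
    sizes = [s for s in config.sizes if s <= fc_set.size] or [fc_set.size]
    search_cfg = screening.SearchConfig(
        pool=fc_set.members, sizes=sizes,
        realizations=config.realizations, seed=seeds["screening"],
        keep_leaderboard=False)
    flat = screening.search(ztrain, params, search_cfg)
    flat_valid = screening.evaluate(
        screening.classify(flat.best_tools[0], zvalid), valid.phenotype)
    logger.info("flat search: training OMR %.4f, validation OMR %.4f",
                flat.best_metrics.omr, flat_valid.omr)

    tree = cart_partition.fit_cart(train, max_depth=config.cart_max_depth)
    cart_cfg = dataclasses.replace(search_cfg, seed=seeds["cart"])
    curves = cart_partition.level_curves(train, valid, tree, cart_cfg)
    logger.info("level curves: train %s valid %s", curves.train_omr,
                curves.valid_omr)

    report = EvaluationReport(
        seeds=seeds,
        baseline={"mae": base_mae, "mse": base_mse},
        forest_eval={
            "resub_mae": resub_mae, "resub_mse": resub_mse,
            "oob_mae": oob_mae, "oob_mse": oob_mse,
            "auc_resub": auc_resub, "auc_oob": auc_oob,
        },
        vil=vil,
        enrichment=enrichment,
        fc_set=fc_set,
        flat_search=flat,
        flat_validation=flat_valid,
        level_curves=curves,
    )
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True))
        vil_rows = "\n".join(f"{n},{v}" for n, v in vil.entries)
        (out / "vil.csv").write_text("variable,mean_vi\n" + vil_rows + "\n")
    return report
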