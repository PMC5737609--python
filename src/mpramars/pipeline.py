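"""End-to-end predictor: redundancy-sized tree clustering + per-cluster MARS.

``fit`` computes the sizing parameters from the design matrix, grows and
CV-prunes the regression tree, and trains one MARS response function per
terminal cluster.  ``evaluate_cv`` reports closed-test (training fit) and
open-test (k-fold cross-validated, default 100 folds) Pearson correlations.
The interpretation helpers reproduce the candidate-active-TFBS reports:
tree node summaries, selected-TFBS frequencies, condition-specific TFBS
sets, and the misfit fold-change screen over the prediction-error tails.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import mars, tree as tree_mod
from .design import DesignMatrix, SizingParams, pc1_proportion, sizing_params

logger = logging.getLogger(__name__)

# MARS needs a handful of rows to be worth fitting at all; the minbucket
# produced by the sizing formula is floored here (and the floor is what keeps
# CV refits legal when a fold nibbles at a small leaf).
MIN_LEAF_ROWS = 10


@dataclass
class PipelineConfig:
    cp: float = 0.01
    prune_folds: int = 10
    mars_max_terms: int = 61
    mars_max_degree: int = 2
    mars_penalty: float | None = None  # None -> 3 with interactions, else 2
    mars_rel_tol: float = 1e-4
    mars_max_knots: int = 500
    seed: int = 0

    def resolved_penalty(self) -> float:
        if self.mars_penalty is not None:
            return self.mars_penalty
        return 3.0 if self.mars_max_degree >= 2 else 2.0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(payload) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**payload)


@dataclass
class FittedPipeline:
    tree: tree_mod.RedundancyTree
    leaf_models: dict[int, mars.MarsModel]
    sizing: SizingParams
    config: PipelineConfig
    tfbs_columns: list[str]
    condition_columns: list[str]

    @property
    def n_clusters(self) -> int:
        return self.tree.n_leaves

    @property
    def max_predictors(self) -> int:
        return max(len(m.terms) for m in self.leaf_models.values())

    def predict_design(self, X: pd.DataFrame) -> np.ndarray:
        clusters = self.tree.assign(X)
        out = np.empty(len(X))
        for cid in np.unique(clusters):
            rows = clusters == cid
            out[rows] = self.leaf_models[int(cid)].predict(X.loc[rows])
        return out

    def to_dict(self) -> dict:
        return {
            "tree": self.tree.to_dict(),
            "leaf_models": {str(cid): m.to_dict() for cid, m in self.leaf_models.items()},
            "sizing": asdict(self.sizing),
            "config": asdict(self.config),
            "tfbs_columns": self.tfbs_columns,
            "condition_columns": self.condition_columns,
        }

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, payload: dict) -> "FittedPipeline":
        return cls(
            tree=tree_mod.RedundancyTree.from_dict(payload["tree"]),
            leaf_models={int(k): mars.MarsModel.from_dict(v)
                         for k, v in payload["leaf_models"].items()},
            sizing=SizingParams(**payload["sizing"]),
            config=PipelineConfig(**payload["config"]),
            tfbs_columns=list(payload["tfbs_columns"]),
            condition_columns=list(payload["condition_columns"]),
        )

    @classmethod
    def from_json(cls, path: str) -> "FittedPipeline":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class EvaluationResult:
    pearson_r_closed: float
    pearson_r_open: float
    n_folds: int
    predictions: pd.DataFrame  # row_id, fold, observed, predicted
    max_predictors: int
    pipeline: FittedPipeline


def fit(design: DesignMatrix, config: PipelineConfig | None = None) -> FittedPipeline:
    """Sizing -> grow -> CV prune -> per-leaf MARS; deterministic given the seed."""
    config = config or PipelineConfig()
    pc1 = pc1_proportion(design)
    sizing = sizing_params(pc1, design.n)
    minbucket = max(sizing.minbucket_int, MIN_LEAF_ROWS)
    if minbucket != sizing.minbucket_int:
        logger.info("minbucket floored to %d rows (sizing gave %.2f)",
                    minbucket, sizing.minbucket)
    if minbucket >= design.n:
        grown = tree_mod.grow(design, design.n, config.cp)  # bare root
    else:
        grown = tree_mod.grow(design, minbucket, config.cp)
        grown = tree_mod.cv_prune(grown, design, config.prune_folds, config.seed)
    clusters = grown.assign(design.X)
    leaf_models: dict[int, mars.MarsModel] = {}
    for leaf in grown.leaves():
        rows = clusters == leaf.cluster_id
        leaf_models[leaf.cluster_id] = mars.fit_mars(
            design.X.loc[rows], design.y.loc[rows].to_numpy(),
            max_terms=config.mars_max_terms,
            max_degree=config.mars_max_degree,
            rel_tol=config.mars_rel_tol,
            max_knots=config.mars_max_knots,
            penalty=config.resolved_penalty(),
        )
    return FittedPipeline(grown, leaf_models, sizing, config,
                          list(design.tfbs_columns), list(design.condition_columns))


def predict(
    pipeline: FittedPipeline,
    enrichments: pd.DataFrame,
    condition: str = "none",
) -> pd.Series:
    """Predict activities of new sequences under one condition.

    ``condition`` must be a training condition label or "none"; "none" sets
    every condition indicator to 0, the device used for cross-condition
    (e.g. cross-cell-type) prediction.
    """
    known = pipeline.condition_columns
    if condition != "none" and condition not in known:
        raise ValueError(f"unknown condition {condition!r}; known: {known or ['none']}")
    missing = set(pipeline.tfbs_columns) - set(enrichments.columns)
    if missing:
        raise ValueError(f"enrichment table is missing matrices: {sorted(missing)}")
    X = enrichments[pipeline.tfbs_columns].copy()
    for label in known:
        X[label] = 1 if label == condition else 0
    values = pipeline.predict_design(X)
    return pd.Series(values, index=enrichments.index, name="predicted_activity")


def evaluate_cv(
    design: DesignMatrix,
    config: PipelineConfig | None = None,
    n_folds: int = 100,
    seed: int = 0,
) -> EvaluationResult:
    """Closed-test and pooled open-test Pearson r under seeded k-fold CV.

    The whole pipeline (sizing, tree, pruning, leaf models) is refit on every
    training fold; held-out predictions are pooled before computing r.
    """
    config = config or PipelineConfig()
    n = design.n
    if not (2 <= n_folds <= n):
        raise ValueError("n_folds must lie in [2, n]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % n_folds

    full = fit(design, config)
    closed_pred = full.predict_design(design.X)
    y = design.y.to_numpy(dtype=float)

    open_pred = np.empty(n)
    for fold in range(n_folds):
        test = fold_of == fold
        fold_config = PipelineConfig(**{**asdict(config),
                                        "seed": (config.seed * 1009 + fold) % (2**31)})
        sub = design.subset(design.X.index[~test])
        fitted = fit(sub, fold_config)
        open_pred[test] = fitted.predict_design(design.X.loc[test])

    r_closed = float(stats.pearsonr(y, closed_pred)[0])
    r_open = float(stats.pearsonr(y, open_pred)[0])
    predictions = pd.DataFrame(
        {"row_id": design.X.index, "fold": fold_of, "observed": y, "predicted": open_pred}
    )
    return EvaluationResult(r_closed, r_open, n_folds, predictions,
                            full.max_predictors, full)


# ---------------------------------------------------------------------------
# Interpretation reports
# ---------------------------------------------------------------------------

def tfbs_tree_report(pipeline: FittedPipeline) -> pd.DataFrame:
    """Per-node summary: split rules, leaf mean activities, sample %, model size."""
    rows: list[dict] = []
    total = pipeline.tree.n

    def walk(node: tree_mod.TreeNode, depth: int) -> None:
        entry = {
            "depth": depth,
            "n": node.n,
            "proportion_pct": 100.0 * node.n / total,
            "mean_activity": node.mean,
        }
        if node.is_leaf:
            entry["kind"] = "leaf"
            entry["cluster_id"] = node.cluster_id
            entry["n_predictors"] = len(pipeline.leaf_models[node.cluster_id].terms)
        else:
            entry["kind"] = "split"
            entry["column"] = node.split.column
            entry["threshold"] = node.split.threshold
            walk(node.left, depth + 1)
            walk(node.right, depth + 1)
        rows.append(entry)

    walk(pipeline.tree.root, 0)
    return pd.DataFrame(rows)


def selected_tfbs_frequencies(pipeline: FittedPipeline) -> dict[str, int]:
    """How often each matrix appears in any hinge of any leaf response function."""
    counts: dict[str, int] = {}
    condition = set(pipeline.condition_columns)
    for model in pipeline.leaf_models.values():
        for term in model.terms:
            for hinge in term.hinges:
                if hinge.column in condition:
                    continue
                counts[hinge.column] = counts.get(hinge.column, 0) + 1
    return counts


def condition_specific_tfbs(
    pipeline_a: FittedPipeline, pipeline_b: FittedPipeline
) -> tuple[set[str], set[str], set[str]]:
    """(shared, only_a, only_b) selected-TFBS sets of two fitted pipelines."""
    a = set(selected_tfbs_frequencies(pipeline_a))
    b = set(selected_tfbs_frequencies(pipeline_b))
    return a & b, a - b, b - a


def misfit_enrichment(
    pipeline: FittedPipeline,
    design: DesignMatrix,
    tail_frac: float = 0.05,
    best_frac: float = 0.10,
    min_fold: float = 2.0,
    eps: float = 0.01,
) -> pd.DataFrame:
    """Motifs enriched or depleted among the worst-predicted constructs.

    Residuals (predicted - observed) rank rows; the top/bottom ``tail_frac``
    are the over-/under-estimated tails and the ``best_frac`` smallest
    absolute residuals are the reference set.  Per matrix the fold change is
    (mean tail enrichment + eps) / (mean reference enrichment + eps); rows
    with fold change >= min_fold or <= 1/min_fold are reported per tail.
    """
    if not (0.0 < tail_frac < 0.5 and 0.0 < best_frac < 0.5):
        raise ValueError("tail_frac and best_frac must lie in (0, 0.5)")
    residual = pipeline.predict_design(design.X) - design.y.to_numpy(dtype=float)
    n = design.n
    n_tail = max(1, int(math.ceil(tail_frac * n)))
    n_best = max(1, int(math.ceil(best_frac * n)))
    order = np.argsort(residual, kind="mergesort")
    under_rows = order[:n_tail]  # most under-estimated (most negative residual)
    over_rows = order[-n_tail:]  # most over-estimated
    best_rows = np.argsort(np.abs(residual), kind="mergesort")[:n_best]
    enr = design.X[design.tfbs_columns].to_numpy(dtype=float)
    ref_mean = enr[best_rows].mean(axis=0)
    out: list[dict] = []
    for tail, rows in (("over", over_rows), ("under", under_rows)):
        fold = (enr[rows].mean(axis=0) + eps) / (ref_mean + eps)
        for col, fc in zip(design.tfbs_columns, fold):
            if fc >= min_fold or fc <= 1.0 / min_fold:
                out.append({"matrix_id": col, "tail": tail, "fold_change": float(fc)})
    return pd.DataFrame(out, columns=["matrix_id", "tail", "fold_change"])
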