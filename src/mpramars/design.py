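"""Explanatory-variable matrix assembly and redundancy-dependent tree sizing.

Rows of the design matrix are (construct, condition) pairs; columns are TFBS
enrichment scores plus one 0/1 indicator per experimental condition.  The
redundancy of the enrichment columns - the proportion of variance carried by
their first principal component - sets the minimum terminal-cluster size of
the regression tree through

    variation_parameter = 2**(-pc1) * 1e7 / n**2
    minbucket           = variation_parameter * n

so highly redundant feature sets and small libraries yield large minimum
clusters (up to "no clustering at all"), while large, diverse libraries are
allowed to split finely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

CONDITION_PREFIX = "condition."
NO_CONDITION = "none"


@dataclass
class DesignMatrix:
    X: pd.DataFrame  # tfbs columns then condition columns, indexed by row id
    y: pd.Series  # activity, same index
    tfbs_columns: list[str]
    condition_columns: list[str]

    def __post_init__(self) -> None:
        if list(self.X.index) != list(self.y.index):
            raise ValueError("feature matrix and response must share the same row index")
        if self.X.isna().any().any() or self.y.isna().any():
            raise ValueError("design matrix must not contain missing values")
        for c in self.condition_columns:
            vals = set(self.X[c].unique())
            if not vals <= {0, 1}:
                raise ValueError(f"condition column {c!r} must be 0/1")

    @property
    def n(self) -> int:
        return len(self.y)

    def subset(self, row_ids) -> "DesignMatrix":
        return DesignMatrix(
            self.X.loc[row_ids], self.y.loc[row_ids],
            list(self.tfbs_columns), list(self.condition_columns),
        )

    def to_tsv(self, path: str) -> None:
        table = self.X.copy()
        table.columns = [
            CONDITION_PREFIX + c if c in self.condition_columns else c for c in table.columns
        ]
        table["activity"] = self.y
        table.to_csv(path, sep="\t", index_label="row_id")

    @classmethod
    def from_tsv(cls, path: str) -> "DesignMatrix":
        table = pd.read_csv(path, sep="\t", index_col="row_id")
        y = table.pop("activity")
        cond = [c for c in table.columns if c.startswith(CONDITION_PREFIX)]
        renames = {c: c[len(CONDITION_PREFIX):] for c in cond}
        table = table.rename(columns=renames)
        cond_cols = list(renames.values())
        tfbs_cols = [c for c in table.columns if c not in cond_cols]
        return cls(table, y, tfbs_cols, cond_cols)


@dataclass(frozen=True)
class SizingParams:
    pc1_proportion: float
    n_observations: int
    variation_parameter: float
    minbucket: float

    @property
    def minbucket_int(self) -> int:
        return int(np.ceil(self.minbucket))


def build_design_matrix(
    enrichments: pd.DataFrame,
    activities: pd.DataFrame,
    condition_labels: list[str] | None = None,
) -> DesignMatrix:
    """Pair enrichment vectors with activities into one matrix.

    ``activities`` needs columns construct_id, condition, activity.  With a
    single condition label no condition columns are appended; with several,
    each distinct label becomes a 0/1 column and each row is one-hot (a row
    labelled "none" is all-zero, meaning no/other condition).
    """
    for col in ("construct_id", "condition", "activity"):
        if col not in activities.columns:
            raise ValueError(f"activity table is missing column {col!r}")
    missing = sorted(set(activities["construct_id"]) - set(enrichments.index))
    if missing:
        raise ValueError(f"activities without a matching sequence/enrichment vector: {missing}")

    labels = sorted(set(activities["condition"]))
    if condition_labels is None:
        condition_labels = [c for c in labels if c != NO_CONDITION] if len(labels) > 1 else []
    unknown = set(labels) - set(condition_labels) - {NO_CONDITION}
    if condition_labels and unknown:
        raise ValueError(f"activity conditions not in condition_labels: {sorted(unknown)}")

    tfbs_cols = list(enrichments.columns)
    multi = bool(condition_labels)
    row_ids = [
        f"{cid}@{cond}" if multi else str(cid)
        for cid, cond in zip(activities["construct_id"], activities["condition"])
    ]
    X = enrichments.loc[activities["construct_id"]].copy()
    X.index = pd.Index(row_ids, name="row_id")
    for label in condition_labels:
        X[label] = (activities["condition"] == label).astype(int).to_numpy()
    y = pd.Series(activities["activity"].to_numpy(dtype=float), index=X.index, name="activity")
    return DesignMatrix(X, y, tfbs_cols, list(condition_labels))


def pc1_proportion(design: DesignMatrix) -> float:
    """Proportion of variance on the first principal component of the
    standardised TFBS enrichment columns (condition columns excluded)."""
    values = design.X[design.tfbs_columns].to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("pc1_proportion needs at least two non-constant TFBS columns")
    z = (values[:, keep] - values[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=1, svd_solver="covariance_eigh")
    pca.fit(z)
    return float(pca.explained_variance_ratio_[0])


def sizing_params(pc1: float, n_observations: int) -> SizingParams:
    """Apply the redundancy-dependent sizing formulas exactly as stated."""
    if not (0.0 <= pc1 <= 1.0):
        raise ValueError("pc1 must lie in [0, 1]")
    if n_observations < 1:
        raise ValueError("n_observations must be >= 1")
    variation_parameter = 2.0 ** (-pc1) * 1e7 / n_observations**2
    minbucket = variation_parameter * n_observations
    return SizingParams(pc1, int(n_observations), variation_parameter, minbucket)
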