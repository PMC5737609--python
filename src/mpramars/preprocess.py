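"""Barcode-count preprocessing: activities from MPRA count tables and QC filtering.

The activity of a construct is the log2 ratio of mRNA to DNA tag counts of
identical barcodes, summarised as the median over barcodes within a replicate
and the mean over replicates.  Constructs with unusually variable replicate
estimates are removed by a quantile rule on the replicate standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COUNT_COLUMNS = ["construct_id", "barcode", "replicate", "dna_count", "mrna_count"]
ACTIVITY_COLUMNS = ["construct_id", "condition", "activity", "replicate_sd"]


@dataclass
class PreprocessReport:
    n_constructs_in: int
    n_kept: int
    n_excluded_empty: int


def activity_from_counts(
    counts: pd.DataFrame, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Aggregate a barcode count table into per-construct activities.

    ``counts`` needs columns construct_id, barcode, replicate, dna_count,
    mrna_count, and optionally condition (defaulting to "none").  Per barcode
    the value is log2((mrna + pseudocount) / (dna + pseudocount)); per
    replicate the median over barcodes; the construct activity is the mean
    over replicates, with the replicate SD recorded for QC.
    """
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"count table is missing columns: {missing}")
    df = counts.copy()
    if "condition" not in df.columns:
        df["condition"] = "none"
    if (df[["dna_count", "mrna_count"]] < 0).any().any():
        raise ValueError("counts must be non-negative")
    has_zero = bool((df[["dna_count", "mrna_count"]] == 0).any().any())
    if has_zero and pseudocount <= 0:
        raise ValueError("pseudocount must be > 0 when zero counts are present")

    df["log_ratio"] = np.log2(
        (df["mrna_count"] + pseudocount) / (df["dna_count"] + pseudocount)
    )
    n_in = df.groupby(["construct_id", "condition"], sort=False).ngroups
    per_rep = (
        df.groupby(["construct_id", "condition", "replicate"], sort=False)["log_ratio"]
        .median()
        .reset_index()
    )
    agg = (
        per_rep.groupby(["construct_id", "condition"], sort=False)["log_ratio"]
        .agg(activity="mean", replicate_sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
        .reset_index()
    )
    report = PreprocessReport(n_constructs_in=n_in, n_kept=len(agg),
                              n_excluded_empty=n_in - len(agg))
    return agg[ACTIVITY_COLUMNS], report


def filter_irregular(
    activities: pd.DataFrame, sd_quantile: float = 0.95
) -> tuple[pd.DataFrame, list[str]]:
    """Drop constructs whose replicate SD exceeds the given quantile.

    The threshold is the ``sd_quantile`` quantile of all replicate SDs; rows
    strictly above it are removed (ties at the threshold are kept), and a
    construct irregular under any condition is removed under all of them.
    """
    if not (0.0 < sd_quantile < 1.0):
        raise ValueError("sd_quantile must lie in (0, 1)")
    if "replicate_sd" not in activities.columns or activities["replicate_sd"].isna().any():
        raise ValueError("replicate_sd must be present for irregularity filtering")
    sds = activities["replicate_sd"].to_numpy(dtype=float)
    threshold = float(np.quantile(sds, sd_quantile))
    bad = activities.loc[sds > threshold, "construct_id"].unique().tolist()
    kept = activities[~activities["construct_id"].isin(bad)].reset_index(drop=True)
    if kept.empty:
        raise RuntimeError("irregularity filter removed every construct; check sd_quantile")
    return kept, bad


def qc_table(activities: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """Histogram of replicate SDs for QC reporting (bin edges and counts)."""
    sds = activities["replicate_sd"].to_numpy(dtype=float)
    counts, edges = np.histogram(sds, bins=n_bins)
    return pd.DataFrame({"sd_bin_left": edges[:-1], "sd_bin_right": edges[1:], "n": counts})
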