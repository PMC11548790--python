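"""Prediction-quality metrics and method comparison for sparse testing.

For each cross-validation partition the test cells are scored with
Pearson's correlation (COR) and the normalized root mean square error
(NRMSE, normalized by the mean of the observed values by default), and the
lines with test cells are scored with the percentage of matching (PM_10,
PM_20): the overlap between the top 10%/20% of lines ranked by prediction
and by observed BLUEs.  Method comparisons use relative efficiency,

    RE = 100 * mean(GBLUP_TRN) / mean(other)     for COR / PM,
    RE = 100 * mean(other) / mean(GBLUP_TRN)     for NRMSE,

so RE > 100 always means GBLUP_TRN is the better method; gain = RE - 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PartitionMetrics",
    "MetricsReport",
    "pearson_cor",
    "nrmse",
    "percent_matching",
    "relative_efficiency",
    "evaluate_partition",
    "aggregate",
]


@dataclass
class PartitionMetrics:
    """All four metrics for one method on one partition's test set."""

    cor: float
    nrmse: float
    pm_10: float
    pm_20: float
    method_tag: str
    allocation_tag: str
    partition_index: int
    n_test_cells: int = 0

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.cor <= 1.0 + 1e-9:
            raise ValueError("correlation outside [-1, 1]")
        if self.nrmse < 0:
            raise ValueError("NRMSE must be non-negative")
        for v in (self.pm_10, self.pm_20):
            if not 0.0 <= v <= 100.0:
                raise ValueError("percentage of matching must be in [0, 100]")


@dataclass
class MetricsReport:
    """Per-partition records plus per-method summaries and RE tables."""

    per_partition: pd.DataFrame
    summary: pd.DataFrame  # mean/sd per (allocation, method, metric)
    relative_efficiencies: pd.DataFrame
    single_partition_flag: bool = False
    across_datasets: Optional[pd.DataFrame] = None


def pearson_cor(observed, predicted) -> float:
    """Product-moment correlation; refuses zero-variance inputs."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    if len(obs) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise ValueError("zero variance in observed or predicted values")
    return float(np.corrcoef(obs, pred)[0, 1])


def nrmse(observed, predicted, normalizer: str = "mean") -> float:
    """Root mean square error normalized by mean, sd or range of observed."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if normalizer == "mean":
        denom = float(np.mean(obs))
    elif normalizer == "sd":
        denom = float(np.std(obs, ddof=1))
    elif normalizer == "range":
        denom = float(obs.max() - obs.min())
    else:
        raise ValueError("normalizer must be 'mean', 'sd' or 'range'")
    if denom == 0:
        raise ValueError(
            f"{normalizer} of the observed values is zero; try normalizer='sd'"
            if normalizer == "mean"
            else f"{normalizer} of the observed values is zero"
        )
    return rmse / abs(denom)


def _top_set(scores: pd.Series, m: int) -> set:
    """Indices of the m largest scores; ties broken by identifier order."""
    df = pd.DataFrame({"score": scores})
    df = df.sort_index().sort_values("score", ascending=False, kind="mergesort")
    return set(df.index[:m])


def percent_matching(observed_scores, predicted_scores, top_frac: float) -> float:
    """Overlap (in %) between predicted and observed top-``top_frac`` lines.

    The top set holds ceil(top_frac * J) lines ranked by descending score
    (higher is better); ties are broken by line identifier.
    """
    if not 0.0 < top_frac < 1.0:
        raise ValueError("top_frac must be in (0, 1)")
    obs = pd.Series(observed_scores, dtype=float)
    pred = pd.Series(predicted_scores, dtype=float)
    if set(obs.index) != set(pred.index):
        raise ValueError("observed and predicted scores must cover the same lines")
    m = int(np.ceil(top_frac * len(obs)))
    overlap = _top_set(obs, m) & _top_set(pred, m)
    return 100.0 * len(overlap) / m


def relative_efficiency(
    trn_mean: float, other_mean: float, metric_kind: str
) -> tuple[float, float]:
    """(RE, gain) of GBLUP_TRN versus another method on averaged metrics.

    COR/PM use trn/other, NRMSE the inverted ratio, both scaled by 100, so
    RE > 100 always reads "GBLUP_TRN better".  gain = RE - 100.
    """
    if metric_kind not in ("cor", "pm", "nrmse"):
        raise ValueError("metric_kind must be 'cor', 'pm' or 'nrmse'")
    num, den = (
        (other_mean, trn_mean) if metric_kind == "nrmse" else (trn_mean, other_mean)
    )
    if den <= 0:
        raise ValueError("relative efficiency needs a positive denominator mean")
    re = 100.0 * num / den
    return re, re - 100.0


def evaluate_partition(
    test_obs: pd.DataFrame,
    predictions: Mapping[str, pd.Series],
    line_scores: Optional[Mapping[str, pd.Series]] = None,
    allocation_tag: str = "",
    partition_index: int = 0,
    nrmse_normalizer: str = "mean",
) -> list[PartitionMetrics]:
    """Score every method on one partition's test set.

    ``test_obs`` holds the observed test cells (columns line, env, value).
    ``predictions`` maps a method tag to cell-level predictions indexed by
    (line, env); ``line_scores`` maps a method tag to a per-line score used
    for every test cell of that line (the GBLUP_TRN route).  COR and NRMSE
    are computed over test cells; PM at the line level, where a line's
    observed score is the mean of its test-cell BLUEs and its predicted
    score the mean of its predicted test cells (or the line score itself).
    """
    cells = list(zip(test_obs["line"], test_obs["env"]))
    y = test_obs["value"].to_numpy(dtype=float)
    obs_by_line = test_obs.groupby("line")["value"].mean()

    out = []
    for tag, pred in predictions.items():
        missing = [c for c in cells if c not in pred.index]
        if missing:
            raise ValueError(f"method {tag}: missing predictions for cells {missing[:5]}")
        yhat = pred.loc[cells].to_numpy(dtype=float)
        pred_by_line = (
            pd.DataFrame({"line": test_obs["line"].to_numpy(), "pred": yhat})
            .groupby("line")["pred"]
            .mean()
        )
        out.append(
            PartitionMetrics(
                cor=pearson_cor(y, yhat),
                nrmse=nrmse(y, yhat, normalizer=nrmse_normalizer),
                pm_10=percent_matching(obs_by_line, pred_by_line, 0.10),
                pm_20=percent_matching(obs_by_line, pred_by_line, 0.20),
                method_tag=tag,
                allocation_tag=allocation_tag,
                partition_index=partition_index,
                n_test_cells=len(y),
            )
        )
    for tag, scores in (line_scores or {}).items():
        absent = set(test_obs["line"]) - set(scores.index)
        if absent:
            raise ValueError(f"method {tag}: missing line scores for {sorted(map(str, absent))[:5]}")
        yhat = scores.loc[test_obs["line"]].to_numpy(dtype=float)
        out.append(
            PartitionMetrics(
                cor=pearson_cor(y, yhat),
                nrmse=nrmse(y, yhat, normalizer=nrmse_normalizer),
                pm_10=percent_matching(obs_by_line, scores.loc[obs_by_line.index], 0.10),
                pm_20=percent_matching(obs_by_line, scores.loc[obs_by_line.index], 0.20),
                method_tag=tag,
                allocation_tag=allocation_tag,
                partition_index=partition_index,
                n_test_cells=len(y),
            )
        )
    return out


_METRIC_KINDS = {"cor": "cor", "nrmse": "nrmse", "pm_10": "pm", "pm_20": "pm"}


def _records_frame(records: Sequence[PartitionMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "allocation": r.allocation_tag,
                "method": r.method_tag,
                "partition": r.partition_index,
                "cor": r.cor,
                "nrmse": r.nrmse,
                "pm_10": r.pm_10,
                "pm_20": r.pm_20,
                "n_test_cells": r.n_test_cells,
            }
            for r in records
        ]
    )


def aggregate(
    records: Sequence[PartitionMetrics] | Mapping[str, Sequence[PartitionMetrics]],
    trn_tag: str = "GBLUP_TRN",
) -> MetricsReport:
    """Average partition metrics and build the relative-efficiency tables.

    Accepts either one dataset's records or a mapping dataset -> records;
    in the latter case an unweighted across-dataset average of the
    dataset-level means is included.  Relative efficiencies are computed
    from the per-method means (never per partition); with a single
    partition the standard deviation is reported as 0 and flagged.
    """
    if isinstance(records, Mapping):
        frames = []
        for name, recs in records.items():
            f = _records_frame(list(recs))
            f.insert(0, "dataset", name)
            frames.append(f)
        per_part = pd.concat(frames, ignore_index=True)
        group_cols = ["dataset", "allocation", "method"]
    else:
        per_part = _records_frame(list(records))
        group_cols = ["allocation", "method"]

    metric_cols = list(_METRIC_KINDS)
    grouped = per_part.groupby(group_cols)[metric_cols]
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    single = bool((grouped.size() == 1).any())
    sds = sds.fillna(0.0)
    summary = (
        means.add_suffix("_mean").join(sds.add_suffix("_sd")).reset_index()
    )

    lead = group_cols[:-1]
    mf = means.reset_index()
    re_rows = []
    for _, block in mf.groupby(lead, sort=True):
        sub = block.set_index("method")
        if trn_tag not in sub.index:
            continue
        for other in sub.index:
            if other == trn_tag:
                continue
            row = {c: sub.loc[other, c] for c in lead}
            row["method"] = other
            for metric in metric_cols:
                re, gain = relative_efficiency(
                    float(sub.loc[trn_tag, metric]),
                    float(sub.loc[other, metric]),
                    _METRIC_KINDS[metric],
                )
                row[f"re_{metric}"] = re
                row[f"gain_{metric}"] = gain
            re_rows.append(row)
    re_table = pd.DataFrame(re_rows)

    across = None
    if "dataset" in group_cols:
        across = (
            means.groupby(level=["allocation", "method"]).mean().reset_index()
        )
    return MetricsReport(
        per_partition=per_part,
        summary=summary,
        relative_efficiencies=re_table,
        single_partition_flag=single,
        across_datasets=across,
    )
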