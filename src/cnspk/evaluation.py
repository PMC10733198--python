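"""Prediction-performance metrics: fold errors, %AFE/%AAFE, VPC bands."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PredictionPair",
    "afe_percent",
    "aafe_percent",
    "fold_error_classification",
    "vpc_bands",
]


@dataclass
class PredictionPair:
    time_min: float
    predicted: float
    observed: float
    matrix: str = "plasma"


def _ratios(pairs):
    """log10(pred/obs) for each pair; raises listing non-positive offenders."""
    pred = np.array([p.predicted for p in pairs], dtype=float)
    obs = np.array([p.observed for p in pairs], dtype=float)
    if pred.size == 0:
        raise ValueError("need at least one prediction pair")
    bad = [
        f"(t={p.time_min}, pred={p.predicted}, obs={p.observed})"
        for p in pairs
        if p.predicted <= 0 or p.observed <= 0
    ]
    if bad:
        raise ValueError(
            "non-positive values in pairs (log-scale metrics require "
            f"positivity): {', '.join(bad)}"
        )
    return np.log10(pred / obs)


def afe_percent(pairs):
    """Percentage average fold error: 100 * 10^mean(log10(pred/obs)).

    100% means unbiased; >100% over-prediction on the geometric scale.
    """
    return 100.0 * 10.0 ** float(np.mean(_ratios(pairs)))


def aafe_percent(pairs):
    """Percentage absolute average fold error: 100 * 10^mean(|log10(pred/obs)|)."""
    return 100.0 * 10.0 ** float(np.mean(np.abs(_ratios(pairs))))


def fold_error_classification(pairs_by_drug, thresholds=(2.0, 5.0), rule="geometric"):
    """Classify each drug by the smallest fold-error limit it satisfies.

    With the default ``geometric`` rule a drug is "within-k" when its
    geometric absolute fold error 10^mean(|log10 ratio|) <= k; with the
    ``all_points`` rule every individual pair must satisfy the limit.
    Returns ``{drug: "within-2" | "within-5" | "beyond-5"}`` (labels follow
    the supplied thresholds).
    """
    if rule not in ("geometric", "all_points"):
        raise ValueError(f"unknown rule {rule!r}")
    thresholds = sorted(thresholds)
    out = {}
    for drug, pairs in pairs_by_drug.items():
        logr = _ratios(pairs)
        if rule == "geometric":
            fold = 10.0 ** float(np.mean(np.abs(logr)))
            worst = fold
        else:
            worst = 10.0 ** float(np.max(np.abs(logr)))
        label = f"beyond-{thresholds[-1]:g}"
        for k in thresholds:
            if worst <= k:
                label = f"within-{k:g}"
                break
        out[drug] = label
    return out


def vpc_bands(replicates, times=None, percentiles=(2.5, 50.0, 97.5)):
    """Pointwise empirical percentile bands across simulated replicates.

    ``replicates`` is an array-like of shape (n_replicates, n_times) on a
    common time grid (ragged input raises). Returns a DataFrame with one row
    per time point and one ``p<q>`` column per percentile.
    """
    try:
        arr = np.asarray(replicates, dtype=float)
    except ValueError as exc:
        raise ValueError("replicates must share a common time grid") from exc
    if arr.ndim != 2:
        raise ValueError("replicates must be a 2-D (replicate x time) array")
    if arr.shape[0] < 20:
        raise ValueError("need at least 20 replicates for VPC bands")
    if times is None:
        times = np.arange(arr.shape[1], dtype=float)
    times = np.asarray(times, dtype=float)
    if times.size != arr.shape[1]:
        raise ValueError("times length must match the replicate grid")
    data = {"time_min": times}
    for q in percentiles:
        data[f"p{q:g}"] = np.percentile(arr, q, axis=0)
    return pd.DataFrame(data)
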