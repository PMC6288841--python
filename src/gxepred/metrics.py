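"""Prediction-accuracy metrics: per-environment Pearson correlation,
heritability adjustment, and aggregation across cross-validation replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats


@dataclass
class AccuracyTable:
    """Rows of (model, env, apc, se, n_replicates [, apc_raw, se_raw]).

    apc is the mean heritability-adjusted Pearson correlation across outer
    replicates; se is the sample standard deviation over replicates divided
    by sqrt(n_replicates) (reported as 0 for a single replicate).
    """

    rows: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


def pearson(obs: np.ndarray, pred: np.ndarray) -> float:
    """Product-moment correlation between observed and predicted values."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("obs and pred must be 1-D vectors of equal length")
    if len(obs) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(scipy.stats.pearsonr(obs, pred)[0])


def adjust_by_heritability(r: float, h2: float) -> float:
    """Divide a correlation by sqrt(h2); may exceed 1 in magnitude when h2 < r^2."""
    if not (0.0 < h2 <= 1.0):
        raise ValueError(f"heritability must lie in (0, 1], got {h2}")
    return r / np.sqrt(h2)


def aggregate_accuracy(per_replicate: list[tuple[str, str, float]]) -> AccuracyTable:
    """Average per-replicate correlations into one row per (model, env).

    Input tuples are (model, env, r).  SE uses the n-1 sample standard
    deviation over replicates; with a single replicate SE is reported as 0.
    """
    if not per_replicate:
        raise ValueError("no replicate accuracies to aggregate")
    df = pd.DataFrame(per_replicate, columns=["model", "env", "r"])
    out = []
    for (model, env), grp in df.groupby(["model", "env"], sort=True):
        vals = grp["r"].to_numpy(dtype=float)
        n = len(vals)
        se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append({"model": model, "env": env, "apc": float(np.mean(vals)), "se": se, "n_replicates": n})
    return AccuracyTable(rows=pd.DataFrame(out))
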