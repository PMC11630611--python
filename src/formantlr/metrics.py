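"""System-validity metrics: log-LR cost (Cllr) and equal error rate (EER).

Cllr is the proper-scoring-rule summary of a likelihood-ratio system,

    Cllr = 1/2 ( mean over same-speaker trials of log2(1 + 1/LR_ss)
               + mean over different-speaker trials of log2(1 + LR_ds) ),

so a system that always answers LR = 1 costs exactly 1 bit regardless of
trial counts, a perfect system costs ~0, and a miscalibrated system can
cost more than 1.

EER is the operating point of the score threshold where the false-reject
rate (same-speaker scores below threshold) equals the false-accept rate
(different-speaker scores at/above threshold). Because the empirical rates
are step functions, the crossing is located by linear interpolation between
the adjacent empirical points. 0 is perfect; 0.5 is chance. A variant
reproducing the halved literal formula ``((FAR+FRR)/2)/2`` is exposed as
``variant="as-printed"``; its chance level is 0.25, which is why the
crossing-point convention is the default.

Because metrics are recomputed over many resampling iterations, the
aggregation step screens metric-level outliers with the same k*IQR rule
used for tokens before averaging.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["cllr", "eer", "aggregate"]


def cllr(lr_ss, lr_ds) -> float:
    """Log-likelihood-ratio cost of two sets of LRs (plain LRs, not logs)."""
    lr_ss = np.asarray(lr_ss, dtype=float)
    lr_ds = np.asarray(lr_ds, dtype=float)
    if lr_ss.size == 0 or lr_ds.size == 0:
        raise ValueError("both LR lists must be nonempty")
    if (lr_ss <= 0).any() or (lr_ds <= 0).any() or not (
        np.isfinite(lr_ss).all() and np.isfinite(lr_ds).all()
    ):
        raise ValueError("all LRs must be positive and finite")
    same_penalty = np.log2(1.0 + 1.0 / lr_ss).mean()
    diff_penalty = np.log2(1.0 + lr_ds).mean()
    return float(0.5 * (same_penalty + diff_penalty))


def _rates(ss: np.ndarray, ds: np.ndarray, ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # FRR(t) = P(ss < t); FAR(t) = P(ds >= t); ties count as false accepts
    frr = np.searchsorted(ss, ts, side="left") / len(ss)
    far = 1.0 - np.searchsorted(ds, ts, side="left") / len(ds)
    return far, frr


def eer(scores_ss, scores_ds, variant: str = "crossing") -> float:
    """Equal error rate of same/different-speaker score sets (any score scale).

    ``variant="crossing"`` (default) returns the common error rate where the
    interpolated FAR and FRR curves cross; ``variant="as-printed"`` returns
    half that value (the literal halved-average formula).
    """
    if variant not in ("crossing", "as-printed"):
        raise ValueError(f"unknown variant {variant!r}")
    ss = np.sort(np.asarray(scores_ss, dtype=float))
    ds = np.sort(np.asarray(scores_ds, dtype=float))
    if ss.size == 0 or ds.size == 0:
        raise ValueError("both score lists must be nonempty")

    pooled = np.unique(np.concatenate([ss, ds]))
    ts = np.concatenate([pooled, [pooled[-1] + 1.0]])  # final point: FAR = 0
    far, frr = _rates(ss, ds, ts)
    f = far - frr  # nonincreasing in t

    below = np.flatnonzero(f <= 0)
    i = below[0] if below.size else len(ts) - 1
    if f[i] == 0 or i == 0:
        value = 0.5 * (far[i] + frr[i])
    else:
        # crossing lies between ts[i-1] (f > 0) and ts[i] (f < 0)
        alpha = f[i - 1] / (f[i - 1] - f[i])
        far_x = far[i - 1] + alpha * (far[i] - far[i - 1])
        frr_x = frr[i - 1] + alpha * (frr[i] - frr[i - 1])
        value = 0.5 * (far_x + frr_x)
    if value > 0.5:  # worse than chance: scores ordered against the hypothesis
        warnings.warn(f"EER {value:.3f} exceeds the 0.5 chance level", RuntimeWarning, stacklevel=2)
    return float(value / 2.0) if variant == "as-printed" else float(value)


def aggregate(results: pd.DataFrame, k: float = 2.5) -> pd.DataFrame:
    """Summarise per-cell Cllr/EER over condition x subset with IQR screening.

    ``results`` needs columns ``condition``, ``subset``, ``cllr``, ``eer``
    (extra provenance columns are ignored). Within each condition x subset
    cell, values of each metric outside ``[Q1 - k*IQR, Q3 + k*IQR]`` are
    removed (independently per metric) before computing mean, median and
    quartiles. ``k = numpy.inf`` disables screening.
    """
    if not k > 0:
        raise ValueError("k must be positive")
    rows = []
    for (condition, subset), cell in results.groupby(["condition", "subset"], sort=True):
        if len(cell) == 0:
            continue
        row: dict = {"condition": condition, "subset": subset, "n_cells": len(cell)}
        for metric in ("cllr", "eer"):
            vals = cell[metric].to_numpy(dtype=float)
            if np.isfinite(k) and len(vals) >= 4:
                q1, q3 = np.percentile(vals, [25, 75])
                iqr = q3 - q1
                keep = (vals >= q1 - k * iqr) & (vals <= q3 + k * iqr)
            else:
                keep = np.ones(len(vals), dtype=bool)
            kept = vals[keep]
            q1k, medk, q3k = np.percentile(kept, [25, 50, 75])
            row.update(
                {
                    f"{metric}_mean": float(kept.mean()),
                    f"{metric}_median": float(medk),
                    f"{metric}_q1": float(q1k),
                    f"{metric}_q3": float(q3k),
                    f"{metric}_n_removed": int((~keep).sum()),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
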