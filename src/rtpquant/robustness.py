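"""Training-set-size cross-validation of RTP-based prediction.

For every training-set size k, random k-subsets of the samples define the
per-gene conversion factor (median RTP over training samples); every
held-out sample is predicted and its log-log Pearson across genes recorded.
The count target per size is interpreted as *prediction events* by default
(one held-out sample of one subset = one prediction); set
``count='subsets'`` to count training subsets instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rtpquant.rtp import _align, loglog_pearson, rtp_ratios

COUNT_MODES = ("predictions", "subsets")


@dataclass
class CVResult:
    """Per-size lists of held-out-sample Pearson values."""

    pearson_by_size: dict[int, np.ndarray]
    n_iterations: dict[int, int]
    seed: int
    count_mode: str
    n_samples: int = 0
    extra: dict = field(default_factory=dict)


def cv_curve(
    copies: pd.DataFrame,
    tpm: pd.DataFrame,
    sizes=None,
    n_predictions_per_size: int = 5000,
    seed: int = 0,
    count: str = "predictions",
) -> CVResult:
    """Random-subset cross-validation curve.

    Parameters
    ----------
    sizes : iterable of int, optional
        Training sizes; defaults to ``1 .. n_samples - 1``. Each must lie in
        that range.
    n_predictions_per_size : int
        Stop once this many prediction events (or subsets, per ``count``)
        have accumulated for a size.
    seed : int
        Seeds one generator for the whole run; results are a pure function
        of (data, sizes, n, seed, count).
    """
    if count not in COUNT_MODES:
        raise ValueError(f"count must be one of {COUNT_MODES}, got {count!r}")
    c, t = _align(copies, tpm)
    n_samples = c.shape[1]
    if n_samples < 2:
        raise ValueError("cross-validation requires at least two samples")
    sizes = list(range(1, n_samples)) if sizes is None else sorted(int(k) for k in sizes)
    for k in sizes:
        if not 1 <= k <= n_samples - 1:
            raise ValueError(f"training size {k} outside [1, {n_samples - 1}]")

    ratios, _ = rtp_ratios(c, t)
    rmat = ratios.to_numpy(dtype=float)
    tmat = t.to_numpy(dtype=float)
    cmat = c.to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    pearson_by_size: dict[int, np.ndarray] = {}
    n_iterations: dict[int, int] = {}
    for k in sizes:
        values: list[float] = []
        iters = 0
        while True:
            if count == "predictions" and len(values) >= n_predictions_per_size:
                break
            if count == "subsets" and iters >= n_predictions_per_size:
                break
            train = rng.choice(n_samples, size=k, replace=False)
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> NaN
                factor = np.nanmedian(rmat[:, train], axis=1)
            held_out = np.setdiff1d(np.arange(n_samples), train)
            for j in held_out:
                pred = tmat[:, j] * factor
                values.append(loglog_pearson(pred, cmat[:, j]))
            iters += 1
        if count == "predictions":
            values = values[:n_predictions_per_size]
        pearson_by_size[k] = np.asarray(values, dtype=float)
        n_iterations[k] = iters
    return CVResult(
        pearson_by_size=pearson_by_size,
        n_iterations=n_iterations,
        seed=seed,
        count_mode=count,
        n_samples=n_samples,
    )


def summarize_cv(result: CVResult) -> pd.DataFrame:
    """Box-plot summary per training size.

    Median, first/third quartile (linear interpolation), whisker bounds at
    1.5 x IQR clipped to the data range, and the number of outliers beyond
    the whiskers.
    """
    if not result.pearson_by_size:
        raise ValueError("empty cross-validation result")
    rows = []
    for k in sorted(result.pearson_by_size):
        vals = result.pearson_by_size[k]
        vals = vals[np.isfinite(vals)]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        rows.append(
            {
                "k": k,
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": inside.min() if len(inside) else np.nan,
                "whisker_high": inside.max() if len(inside) else np.nan,
                "n_outliers": int(((vals < lo_fence) | (vals > hi_fence)).sum()),
                "n_predictions": len(vals),
                "n_iterations": result.n_iterations[k],
            }
        )
    return pd.DataFrame(rows).set_index("k")
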