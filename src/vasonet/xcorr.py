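"""Lagged, segmented, demeaned-normalized cross-correlation between cells.

Signal pairs are compared over an extended window (10 s of pre-activation
baseline plus the activity period, truncated to the shortest compared
duration and aligned on activity onsets). Each pair's trace is split into
two equal segments; per segment the demeaned, normalized cross-correlation
is maximized over integer-frame lags within +/- max_lag (3x the median FDHM
across datasets), floored at 0; the pair coefficient is the median of the
two segment values (= their mean for two values), so it lies in [0, 1].
Per-node connectivity to a comparison set is summarized by the 75th
percentile of its pairwise coefficients.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events import TraceSet

__all__ = [
    "align_and_window",
    "xcorr_pair",
    "correlation_matrix",
    "connectivity_summary",
]


def align_and_window(
    tracesets: list[TraceSet],
    onsets: list[float] | None = None,
    baseline_span: float = 10.0,
    events: list[pd.DataFrame] | None = None,
) -> list[np.ndarray]:
    """Cut comparable (baseline + activity) segments from several recordings.

    The onset of each dataset is its configured stimulus time; if absent, the
    time of its first detected event (``events`` required then). All segments
    start ``baseline_span`` seconds before onset and are truncated to the
    shortest combined duration across datasets.
    """
    if onsets is None:
        onsets = []
        for i, ts in enumerate(tracesets):
            if ts.stimulus_onset is not None:
                onsets.append(float(ts.stimulus_onset))
            elif events is not None and len(events[i]):
                onsets.append(float(events[i].peak_time.min()))
            else:
                raise ValueError(f"dataset {i}: no stimulus onset and no events to infer it")
    spans = []
    for ts, onset in zip(tracesets, onsets):
        start = onset - baseline_span
        if start < 0:
            raise ValueError("need >= baseline_span seconds of pre-onset recording")
        spans.append(ts.time[-1] + 1.0 / ts.frame_rate - start)
    length = min(spans)
    out = []
    for ts, onset in zip(tracesets, onsets):
        i0 = int(round((onset - baseline_span) * ts.frame_rate))
        i1 = i0 + int(round(length * ts.frame_rate))
        out.append(ts.values[i0:i1])
    n = min(seg.shape[0] for seg in out)
    return [seg[:n] for seg in out]


def _best_lag_corr(x: np.ndarray, y: np.ndarray, max_lag: int) -> float:
    """Max over lags of the demeaned, normalized correlation on the overlap.

    Each lag's coefficient is the Pearson correlation of the overlapping
    samples (demeaned over the overlap), so an exactly shifted copy scores 1
    at its true lag.
    """
    best = -np.inf
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            xs, ys = x[lag:], y[: y.size - lag]
        else:
            xs, ys = x[: x.size + lag], y[-lag:]
        if xs.size < 2:
            continue
        xd = xs - xs.mean()
        yd = ys - ys.mean()
        nx = np.linalg.norm(xd)
        ny = np.linalg.norm(yd)
        if nx == 0 or ny == 0:
            continue
        best = max(best, float(np.dot(xd, yd) / (nx * ny)))
    return best if np.isfinite(best) else 0.0


def xcorr_pair(sig1: np.ndarray, sig2: np.ndarray, max_lag: int) -> float:
    """Cross-correlation coefficient in [0, 1] for one signal pair.

    ``max_lag`` is in frames. Each of the two equal time segments contributes
    its lag-maximized coefficient floored at 0; the pair value is their
    median (mean of two).
    """
    sig1 = np.asarray(sig1, dtype=float)
    sig2 = np.asarray(sig2, dtype=float)
    if sig1.size != sig2.size:
        raise ValueError("signals must have equal length")
    if sig1.size < 2 * max_lag:
        raise ValueError("segments must be at least twice the maximum lag")
    half = sig1.size // 2
    vals = []
    for sl in (slice(0, half), slice(half, sig1.size)):
        a, b = sig1[sl], sig2[sl]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            vals.append(0.0)  # zero-variance segment carries no similarity
            continue
        vals.append(max(0.0, _best_lag_corr(a, b, max_lag)))
    return float(np.mean(vals))


def correlation_matrix(
    seg_a: np.ndarray,
    seg_b: np.ndarray | None,
    max_lag: int,
    cols_a: list[int],
    cols_b: list[int] | None = None,
) -> pd.DataFrame:
    """Pairwise coefficients between columns of two segments.

    With ``seg_b=None`` the within-set symmetric matrix of ``seg_a`` columns
    is computed (unit diagonal skipped as self-pairs).
    """
    if seg_b is None:
        n = len(cols_a)
        m = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                c = xcorr_pair(seg_a[:, i], seg_a[:, j], max_lag)
                m[i, j] = m[j, i] = c
        return pd.DataFrame(m, index=cols_a, columns=cols_a)
    cols_b = cols_b if cols_b is not None else list(range(seg_b.shape[1]))
    m = np.zeros((len(cols_a), len(cols_b)))
    for i in range(len(cols_a)):
        for j in range(len(cols_b)):
            m[i, j] = xcorr_pair(seg_a[:, i], seg_b[:, j], max_lag)
    return pd.DataFrame(m, index=cols_a, columns=cols_b)


def connectivity_summary(
    coefficients: pd.DataFrame, within: bool, q: float = 75.0
) -> pd.Series:
    """Per-node percentile summary of its coefficients to the comparison set.

    ``within=True`` marks a symmetric within-set matrix whose diagonal
    (self-pairs) is excluded. The 75th percentile uses linear interpolation
    between order statistics.
    """
    vals = {}
    for node in coefficients.index:
        row = coefficients.loc[node].to_numpy(dtype=float)
        if within:
            row = np.delete(row, list(coefficients.index).index(node))
        if row.size == 0:
            continue
        vals[node] = float(np.percentile(row, q))
    s = pd.Series(vals, name=f"p{q:g}")
    s.index.name = "cell_id"
    return s
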