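"""Quietest-period Z-scoring of ΔF/F traces.

Each trace is standardized against its own "quietest period": the contiguous
10 s window with the lowest sample standard deviation of ΔF/F. The modified
Z-score is

    Z(t) = (F(t) - mean(quietest period)) / SD(quietest period)

which maps baseline noise to ~N(0, 1) regardless of a cell's indicator
expression level, so a single event threshold (Z > 3) is meaningful across
cells. The transform is affine and strictly increasing, hence rank- and
correlation-preserving.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import TraceMatrix, ZScoreTraces
from .errors import DegenerateTraceError, InputError, ParameterError

#: quietest-window SDs at or below this are treated as a dead/constant ROI
SD_EPS = 1e-9


def window_length(frame_rate: float, window_s: float = 10.0) -> int:
    """Window length in frames: ``round(window_s * frame_rate)``, minimum 2."""
    if frame_rate <= 0 or window_s <= 0:
        raise ParameterError("frame_rate and window_s must be positive")
    n = int(round(window_s * frame_rate))
    return max(n, 2)


def find_quietest_window(trace: np.ndarray, frame_rate: float,
                         window_s: float = 10.0) -> tuple[int, int]:
    """Locate the contiguous window minimizing the sample SD (ddof=1).

    The window slides by one frame; ties break to the earliest start.

    Returns
    -------
    (start_frame, length) : tuple of int
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise InputError("trace must be 1-D")
    wlen = window_length(frame_rate, window_s)
    if trace.size < wlen:
        raise InputError(
            f"trace ({trace.size} frames) shorter than window ({wlen} frames)")
    windows = sliding_window_view(trace, wlen)
    sds = windows.std(axis=1, ddof=1)
    start = int(np.argmin(sds))  # argmin returns the first minimum: earliest tie
    return start, wlen


def zscore_trace(trace: np.ndarray, frame_rate: float, window_s: float = 10.0,
                 eps: float = SD_EPS, cell_id=None):
    """Modified Z-score of a single trace.

    Returns
    -------
    z : ndarray
    meta : dict with quiet_window_start, quiet_window_len, quiet_mean, quiet_sd

    Raises
    ------
    DegenerateTraceError
        If the quietest-window SD is at or below ``eps`` (constant ROI).
    """
    trace = np.asarray(trace, dtype=float)
    start, wlen = find_quietest_window(trace, frame_rate, window_s)
    quiet = trace[start:start + wlen]
    quiet_mean = float(quiet.mean())
    quiet_sd = float(quiet.std(ddof=1))
    if quiet_sd <= eps:
        raise DegenerateTraceError(
            f"quietest-window SD {quiet_sd:.3g} <= {eps:.3g}"
            + (f" for cell {cell_id}" if cell_id is not None else ""),
            cell_id=cell_id)
    z = (trace - quiet_mean) / quiet_sd
    meta = {"quiet_window_start": start, "quiet_window_len": wlen,
            "quiet_mean": quiet_mean, "quiet_sd": quiet_sd}
    return z, meta


class QuietestWindowZScorer(TransformerMixin, BaseEstimator):
    """Transformer computing modified Z-scores row-wise on (cells x frames).

    Parameters
    ----------
    frame_rate : float
        Imaging rate, Hz.
    window_s : float
        Quietest-window length, seconds (default 10).
    on_degenerate : {"raise", "nan"}
        Whether a constant row aborts the transform or yields a NaN row
        flagged in ``degenerate_``.

    Attributes (after ``fit``)
    --------------------------
    quiet_window_start_ : ndarray of int, per cell
    quiet_window_len_ : int
    quiet_mean_, quiet_sd_ : ndarray, per cell (ΔF/F units)
    degenerate_ : ndarray of bool, per cell
    """

    def __init__(self, frame_rate: float = 7.8, window_s: float = 10.0,
                 on_degenerate: str = "raise"):
        self.frame_rate = frame_rate
        self.window_s = window_s
        self.on_degenerate = on_degenerate

    def fit(self, X, y=None):
        X = self._check_X(X)
        wlen = window_length(self.frame_rate, self.window_s)
        n = X.shape[0]
        starts = np.zeros(n, dtype=int)
        means = np.zeros(n)
        sds = np.zeros(n)
        degenerate = np.zeros(n, dtype=bool)
        for i in range(n):
            start, _ = find_quietest_window(X[i], self.frame_rate, self.window_s)
            quiet = X[i, start:start + wlen]
            starts[i] = start
            means[i] = quiet.mean()
            sds[i] = quiet.std(ddof=1)
            if sds[i] <= SD_EPS:
                if self.on_degenerate == "raise":
                    raise DegenerateTraceError(
                        f"cell {i}: quietest-window SD {sds[i]:.3g} below tolerance",
                        cell_id=i)
                degenerate[i] = True
        self.quiet_window_start_ = starts
        self.quiet_window_len_ = wlen
        self.quiet_mean_ = means
        self.quiet_sd_ = sds
        self.degenerate_ = degenerate
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "quiet_sd_")
        X = self._check_X(X)
        if X.shape[0] != self.quiet_mean_.shape[0]:
            raise InputError("transform called with a different number of cells than fit")
        sd = np.where(self.degenerate_, np.nan, self.quiet_sd_)
        z = (X - self.quiet_mean_[:, None]) / sd[:, None]
        return z

    def _check_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise InputError("X must be 2-D (cells x frames)")
        if not np.all(np.isfinite(X)):
            raise InputError("X contains non-finite values")
        return X


def zscore_matrix(traces: TraceMatrix, window_s: float = 10.0,
                  on_degenerate: str = "nan") -> ZScoreTraces:
    """Z-score every cell of a :class:`TraceMatrix` (thin estimator wrapper)."""
    est = QuietestWindowZScorer(frame_rate=traces.frame_rate, window_s=window_s,
                                on_degenerate=on_degenerate)
    z = est.fit(traces.dff).transform(traces.dff)
    return ZScoreTraces(z=z, frame_rate=traces.frame_rate,
                        quiet_window_start=est.quiet_window_start_,
                        quiet_window_len=est.quiet_window_len_,
                        quiet_mean=est.quiet_mean_, quiet_sd=est.quiet_sd_,
                        t0=traces.t0, cell_ids=traces.cell_ids,
                        degenerate=est.degenerate_)
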