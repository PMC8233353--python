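"""Spontaneous-activity metrics on the ~100 s pre-stimulus Z-score block."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import events as _events
from .errors import InputError
from .evoked import auc as _auc

MIN_BLOCK_S = 10.0


@dataclass
class SpontaneousMetrics:
    """Per-cell spontaneous summary."""

    event_rate: float        # events/min by default
    mean_event_amp: float    # Z units; NaN if no events
    total_auc: float         # Z*s over the whole block
    block_duration: float    # s
    n_events: int


def spontaneous_summary(z_block: np.ndarray, frame_rate: float,
                        min_height: float = _events.DEFAULT_MIN_HEIGHT,
                        selectivity="auto",
                        per_minute: bool = True) -> SpontaneousMetrics:
    """Transient rate, mean amplitude, and total AUC of a spontaneous block.

    The block must span at least 10 s. Rate is events/min unless
    ``per_minute=False`` (then events/s).
    """
    z_block = np.asarray(z_block, dtype=float)
    duration = z_block.size / frame_rate
    if duration < MIN_BLOCK_S:
        raise InputError(f"spontaneous block of {duration:.1f} s is shorter than "
                         f"{MIN_BLOCK_S:.0f} s")
    peaks = _events.find_peaks(z_block, min_height=min_height, selectivity=selectivity)
    rate = len(peaks) / duration
    if per_minute:
        rate *= 60.0
    amp = float(np.mean([p.amplitude for p in peaks])) if peaks else np.nan
    return SpontaneousMetrics(event_rate=rate, mean_event_amp=amp,
                              total_auc=_auc(z_block, frame_rate),
                              block_duration=duration, n_events=len(peaks))


class SpontaneousSummarizer(TransformerMixin, BaseEstimator):
    """Transformer mapping (cells x frames) spontaneous Z-blocks to metric rows."""

    def __init__(self, frame_rate: float = 7.8,
                 min_height: float = _events.DEFAULT_MIN_HEIGHT,
                 selectivity="auto", per_minute: bool = True):
        self.frame_rate = frame_rate
        self.min_height = min_height
        self.selectivity = selectivity
        self.per_minute = per_minute

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        X = np.asarray(X, dtype=float)
        rows = []
        for i in range(X.shape[0]):
            m = spontaneous_summary(X[i], self.frame_rate, self.min_height,
                                    self.selectivity, self.per_minute)
            rows.append({"cell_id": i, "event_rate": m.event_rate,
                         "mean_event_amp": m.mean_event_amp,
                         "total_auc": m.total_auc,
                         "block_duration": m.block_duration,
                         "n_events": m.n_events})
        return pd.DataFrame(rows)
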