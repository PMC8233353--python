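"""Whisker stimulation protocols and their rasterization to frame vectors.

A protocol is an ordered list of stimulus epochs (onset, shared duration).
The default matches the study design used throughout this package: 20 epochs
of 1 s separated by a 3 s interstimulus interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ProtocolError


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered stimulus epochs.

    Attributes
    ----------
    onsets_s : ndarray
        Strictly increasing epoch onset times, seconds.
    duration_s : float
        Epoch duration, seconds (all epochs share it).
    """

    onsets_s: np.ndarray
    duration_s: float = 1.0

    def __post_init__(self):
        onsets = np.atleast_1d(np.asarray(self.onsets_s, dtype=float))
        object.__setattr__(self, "onsets_s", onsets)
        if onsets.size < 1:
            raise ParameterError("protocol needs at least one epoch")
        if not self.duration_s > 0:
            raise ParameterError("duration_s must be positive")
        if onsets.size > 1:
            gaps = np.diff(onsets)
            if np.any(gaps <= 0):
                raise ProtocolError("epoch onsets must be strictly increasing")
            if np.any(gaps < self.duration_s):
                raise ProtocolError("stimulus epochs overlap")

    @property
    def n_epochs(self) -> int:
        return int(self.onsets_s.size)

    @property
    def end_s(self) -> float:
        """Time at which the last epoch ends."""
        return float(self.onsets_s[-1] + self.duration_s)

    def onset_frames(self, frame_rate: float, t0: float = 0.0) -> np.ndarray:
        """Index of the first frame acquired at or after each onset."""
        rel = (self.onsets_s - t0) * frame_rate
        return np.ceil(rel - 1e-9).astype(int)

    def rasterize(self, n_frames: int, frame_rate: float, t0: float = 0.0) -> np.ndarray:
        """Binary per-frame stimulus vector.

        Frame ``k`` (time ``t0 + k/frame_rate``) is 1 exactly when its
        acquisition time falls inside some epoch ``[onset, onset + duration)``.
        """
        if n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        t = t0 + np.arange(n_frames) / frame_rate
        v = np.zeros(n_frames, dtype=np.uint8)
        for onset in self.onsets_s:
            v |= ((t >= onset - 1e-12) & (t < onset + self.duration_s - 1e-12)).astype(np.uint8)
        return v

    def to_dict(self) -> dict:
        return {"onsets_s": self.onsets_s.tolist(), "duration_s": float(self.duration_s)}

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(onsets_s=np.asarray(d["onsets_s"], dtype=float),
                   duration_s=float(d.get("duration_s", 1.0)))


def build_protocol(n_epochs: int = 20, duration_s: float = 1.0, isi_s: float = 3.0,
                   t_start: float = 0.0) -> StimulusProtocol:
    """Regular stimulus train: onsets at ``t_start + k*(duration + isi)``.

    Defaults encode the 20 x (1 s on / 3 s off) whisker-deflection train.
    """
    if n_epochs < 1:
        raise ParameterError("n_epochs must be >= 1")
    if duration_s <= 0 or isi_s < 0:
        raise ParameterError("duration_s must be > 0 and isi_s >= 0")
    onsets = t_start + np.arange(n_epochs) * (duration_s + isi_s)
    return StimulusProtocol(onsets_s=onsets, duration_s=duration_s)
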