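"""Calcium-activity epoch and transient-peak detection on Z-score traces.

An *activity epoch* is a maximal run of at least ``min_run`` consecutive
frames with Z strictly above ``threshold`` (defaults 4 frames, Z > 3). Epochs
are what the scramble null preserves intact, and what separates signal from
background in the classifier.

Peaks are local maxima filtered by amplitude (``min_height``) and by
topographic prominence (``selectivity``): a local maximum must stand above
the surrounding minima by at least the selectivity to count as a transient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .errors import ParameterError

DEFAULT_THRESHOLD = 3.0
DEFAULT_MIN_RUN = 4
DEFAULT_MIN_HEIGHT = 3.0


@dataclass(frozen=True)
class PeakCall:
    """One detected transient peak."""

    peak_frame: int
    amplitude: float  # Z at the peak frame
    prominence: float


def detect_epochs(z: np.ndarray, threshold: float = DEFAULT_THRESHOLD,
                  min_run: int = DEFAULT_MIN_RUN) -> list[tuple[int, int]]:
    """Maximal runs of frames with ``z > threshold`` kept iff length >= min_run.

    Returns half-open ``[start, end)`` intervals in 0-based frames, sorted and
    disjoint.
    """
    if min_run < 1:
        raise ParameterError("min_run must be >= 1")
    z = np.asarray(z, dtype=float)
    above = z > threshold
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_run]


def _resolve_selectivity(segment: np.ndarray, selectivity) -> float:
    if isinstance(selectivity, str):
        if selectivity != "auto":
            raise ParameterError(f"unknown selectivity {selectivity!r}")
        rng = float(segment.max() - segment.min())
        return rng / 4.0
    sel = float(selectivity)
    if sel < 0:
        raise ParameterError("selectivity must be >= 0")
    return sel


def find_peaks(segment: np.ndarray, min_height: float = DEFAULT_MIN_HEIGHT,
               selectivity="auto") -> list[PeakCall]:
    """Local maxima with amplitude >= min_height and prominence >= selectivity.

    ``selectivity="auto"`` uses (max - min)/4 of the segment. Segments shorter
    than 3 frames have no interior local maximum and return an empty list.
    Plateau maxima report their left edge.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1:
        raise ParameterError("segment must be 1-D")
    if segment.size < 3:
        return []
    sel = _resolve_selectivity(segment, selectivity)
    idx, props = _signal.find_peaks(segment, height=min_height,
                                    prominence=max(sel, 1e-300))
    return [PeakCall(peak_frame=int(i), amplitude=float(segment[i]),
                     prominence=float(p))
            for i, p in zip(idx, props["prominences"])]


def largest_peak(peaks: list[PeakCall]) -> PeakCall | None:
    """The largest-amplitude call (ties to the earliest frame), or None."""
    if not peaks:
        return None
    return max(peaks, key=lambda p: (p.amplitude, -p.peak_frame))


def epochs_to_table(epochs_per_cell: dict[int, list[tuple[int, int]]]):
    """Flatten per-cell epoch lists into a tidy records list (cell_id, start, end)."""
    return [{"cell_id": cid, "start": s, "end": e}
            for cid, eps in epochs_per_cell.items() for s, e in eps]
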