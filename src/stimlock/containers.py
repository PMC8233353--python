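"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError


@dataclass
class TraceMatrix:
    """Neuropil-corrected ΔF/F traces for one field of view.

    Parameters
    ----------
    dff : ndarray, shape (n_cells, n_frames)
        Fractional fluorescence change per cell per frame (dimensionless).
    frame_rate : float
        Imaging rate in Hz.
    t0 : float
        Acquisition time of frame 0 in seconds.
    cell_ids : ndarray of int, optional
        Stable identifiers; defaults to ``0..n_cells-1``.
    """

    dff: np.ndarray
    frame_rate: float
    t0: float = 0.0
    cell_ids: np.ndarray | None = None

    def __post_init__(self):
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim != 2:
            raise InputError("dff must be a 2-D (cells x frames) array")
        if self.dff.shape[0] < 1 or self.dff.shape[1] < 2:
            raise InputError("need at least 1 cell and 2 frames")
        if not np.all(np.isfinite(self.dff)):
            bad = np.unique(np.nonzero(~np.isfinite(self.dff))[0])
            raise InputError(f"non-finite dF/F values in cells {bad.tolist()}")
        if not self.frame_rate > 0:
            raise InputError("frame_rate must be positive")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.dff.shape[0])
        else:
            self.cell_ids = np.asarray(self.cell_ids)
            if self.cell_ids.shape[0] != self.dff.shape[0]:
                raise InputError("cell_ids length must match number of cells")

    @property
    def n_cells(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame, in seconds."""
        return self.t0 + np.arange(self.n_frames) / self.frame_rate


@dataclass
class ZScoreTraces:
    """Modified Z-scores plus the quietest-window statistics used per cell.

    Within each cell's quietest window, ``z`` has mean ~0 and SD ~1 by
    construction.
    """

    z: np.ndarray
    frame_rate: float
    quiet_window_start: np.ndarray
    quiet_window_len: int
    quiet_mean: np.ndarray
    quiet_sd: np.ndarray
    t0: float = 0.0
    cell_ids: np.ndarray | None = None
    degenerate: np.ndarray | None = None  # True where z-scoring was impossible

    def __post_init__(self):
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.z.shape[0])
        if self.degenerate is None:
            self.degenerate = np.zeros(self.z.shape[0], dtype=bool)

    @property
    def n_cells(self) -> int:
        return self.z.shape[0]

    @property
    def n_frames(self) -> int:
        return self.z.shape[1]
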