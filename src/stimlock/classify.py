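"""Scramble-bootstrap classification of stimulus-locked neurons.

For each cell the observed Pearson correlation between its Z-score trace and
the binary stimulus vector is compared against a null distribution obtained
by scrambling the trace while preserving every calcium-activity epoch
(Z > 3 for >= 4 consecutive frames) as an intact block. A cell is
stimulus-locked when its observed correlation strictly exceeds the empirical
top-``alpha`` quantile (default: top 1%) of the scrambled correlations.

Two scramble mechanisms are available:

* ``"block"`` (default): the trace is cut at epoch boundaries into alternating
  background and epoch blocks whose order is uniformly permuted. Length and
  the multiset of sample values are preserved exactly.
* ``"replace"``: background samples are shuffled individually and each epoch
  is re-inserted contiguously at a random offset.

Both keep each epoch's sample sequence contiguous and unaltered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import events as _events
from .containers import ZScoreTraces
from .errors import DegenerateTraceError, InputError, ParameterError, ProtocolError
from .protocol import StimulusProtocol

DEFAULT_N_SCRAMBLES = 10_000
DEFAULT_ALPHA = 0.01


@dataclass
class StimLockResult:
    """Per-cell outcome of the scramble bootstrap."""

    observed_r: float
    null_r: np.ndarray
    null_cutoff: float
    is_locked: bool
    n_scrambles: int
    cell_id: int | None = None


def split_blocks(z: np.ndarray, epochs: list[tuple[int, int]]) -> tuple[list[np.ndarray], list[bool]]:
    """Cut ``z`` into alternating background / epoch blocks.

    Returns the block list (in original order) and a parallel list marking
    which blocks are activity epochs. Empty background stretches between
    adjacent epochs are dropped.
    """
    blocks: list[np.ndarray] = []
    is_epoch: list[bool] = []
    pos = 0
    for s, e in epochs:
        if s > pos:
            blocks.append(z[pos:s])
            is_epoch.append(False)
        blocks.append(z[s:e])
        is_epoch.append(True)
        pos = e
    if pos < z.size:
        blocks.append(z[pos:])
        is_epoch.append(False)
    return blocks, is_epoch


def scramble_z(z: np.ndarray, epochs: list[tuple[int, int]],
               rng: np.random.Generator, mode: str = "block") -> np.ndarray:
    """One scramble of the Z vector preserving activity epochs intact.

    ``mode="block"`` permutes the order of epoch and background blocks;
    ``mode="replace"`` shuffles background samples and drops each epoch back
    in contiguously at a random position.
    """
    z = np.asarray(z, dtype=float)
    if mode == "block":
        blocks, _ = split_blocks(z, epochs)
        if len(blocks) <= 1:
            return z.copy()
        order = rng.permutation(len(blocks))
        return np.concatenate([blocks[i] for i in order])
    if mode == "replace":
        blocks, is_epoch = split_blocks(z, epochs)
        epoch_blocks = [b for b, ep in zip(blocks, is_epoch) if ep]
        bg_blocks = [b for b, ep in zip(blocks, is_epoch) if not ep]
        background = rng.permutation(np.concatenate(bg_blocks)) if bg_blocks \
            else np.empty(0)
        if not epoch_blocks:
            return background
        # choose all insertion points in the background up front so epochs
        # cannot split each other; coincident points make epochs adjacent
        cuts = np.sort(rng.integers(0, background.size + 1, len(epoch_blocks)))
        order = rng.permutation(len(epoch_blocks))
        pieces, prev = [], 0
        for cut, j in zip(cuts, order):
            pieces.append(background[prev:cut])
            pieces.append(epoch_blocks[j])
            prev = cut
        pieces.append(background[prev:])
        return np.concatenate(pieces)
    raise ParameterError(f"unknown scramble mode {mode!r}")


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise DegenerateTraceError("correlation undefined for a constant vector")
    return float(xc @ yc) / denom


def null_cutoff_index(n_scrambles: int, alpha: float) -> int:
    """0-based index of the top-``alpha`` order statistic: ceil((1-alpha)*n) 1-based."""
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    k = int(math.ceil((1.0 - alpha) * n_scrambles - 1e-12))
    return min(max(k, 1), n_scrambles) - 1


def classify_cell(z: np.ndarray, stim_vector: np.ndarray,
                  n_scrambles: int = DEFAULT_N_SCRAMBLES,
                  alpha: float = DEFAULT_ALPHA,
                  seed=None, rng: np.random.Generator | None = None,
                  epoch_threshold: float = _events.DEFAULT_THRESHOLD,
                  min_run: int = _events.DEFAULT_MIN_RUN,
                  scramble_mode: str = "block",
                  cell_id=None) -> StimLockResult:
    """Scramble-bootstrap verdict for a single cell.

    The observed Pearson correlation between ``z`` and the binary stimulus
    vector is compared with ``n_scrambles`` epoch-preserving scrambles; the
    cell is stimulus-locked iff the observed value strictly exceeds the
    empirical top-``alpha`` quantile of the null sample.
    """
    z = np.asarray(z, dtype=float)
    stim = np.asarray(stim_vector, dtype=float)
    if z.shape != stim.shape:
        raise InputError("z and stim_vector must have equal length")
    if n_scrambles < 100:
        raise ParameterError("n_scrambles must be >= 100 for a stable quantile")
    if stim.min() == stim.max():
        raise ProtocolError("stimulus vector is constant")
    if z.min() == z.max():
        raise DegenerateTraceError("constant Z trace", cell_id=cell_id)
    if rng is None:
        rng = np.random.default_rng(seed)

    # Pearson r against a fixed stim vector reduces to an affine map of the dot
    # product, and mean/SD of z are scramble-invariant; precompute accordingly.
    sc = stim - stim.mean()
    z_mean = z.mean()
    z_norm = math.sqrt(float(((z - z_mean) ** 2).sum()))
    s_norm = math.sqrt(float(sc @ sc))
    denom = z_norm * s_norm

    def corr(vec: np.ndarray) -> float:
        return float((vec - z_mean) @ sc) / denom

    observed_r = corr(z)
    epochs = _events.detect_epochs(z, threshold=epoch_threshold, min_run=min_run)
    null_r = np.empty(n_scrambles)
    for i in range(n_scrambles):
        null_r[i] = corr(scramble_z(z, epochs, rng, mode=scramble_mode))
    cutoff = float(np.sort(null_r)[null_cutoff_index(n_scrambles, alpha)])
    return StimLockResult(observed_r=observed_r, null_r=null_r,
                          null_cutoff=cutoff,
                          is_locked=bool(observed_r > cutoff),
                          n_scrambles=n_scrambles, cell_id=cell_id)


def classify_fov(z_traces, stim_vector=None, protocol: StimulusProtocol | None = None,
                 n_scrambles: int = DEFAULT_N_SCRAMBLES, alpha: float = DEFAULT_ALPHA,
                 seed=None,
                 epoch_threshold: float = _events.DEFAULT_THRESHOLD,
                 min_run: int = _events.DEFAULT_MIN_RUN,
                 scramble_mode: str = "block") -> pd.DataFrame:
    """Classify every cell of a FOV; per-cell failures become flagged rows.

    ``z_traces`` is a :class:`ZScoreTraces` or a (cells x frames) Z array.
    Cells use independent substreams spawned from one master seed, so verdicts
    are reproducible and independent of cell order.
    """
    if isinstance(z_traces, ZScoreTraces):
        z = z_traces.z
        cell_ids = z_traces.cell_ids
        frame_rate = z_traces.frame_rate
        t0 = z_traces.t0
        pre_degenerate = z_traces.degenerate
    else:
        z = np.asarray(z_traces, dtype=float)
        cell_ids = np.arange(z.shape[0])
        frame_rate = None
        t0 = 0.0
        pre_degenerate = np.zeros(z.shape[0], dtype=bool)
    if stim_vector is None:
        if protocol is None:
            raise InputError("provide stim_vector or protocol")
        if frame_rate is None:
            raise InputError("a bare array needs an explicit stim_vector")
        stim_vector = protocol.rasterize(z.shape[1], frame_rate, t0)
    stim_vector = np.asarray(stim_vector)

    streams = np.random.SeedSequence(seed).spawn(z.shape[0])
    rows = []
    for i in range(z.shape[0]):
        row = {"cell_id": cell_ids[i], "observed_r": np.nan, "null_cutoff": np.nan,
               "is_locked": False, "n_scrambles": n_scrambles, "flag": ""}
        if pre_degenerate[i]:
            row["flag"] = "degenerate"
            rows.append(row)
            continue
        try:
            res = classify_cell(z[i], stim_vector, n_scrambles=n_scrambles,
                                alpha=alpha, rng=np.random.default_rng(streams[i]),
                                epoch_threshold=epoch_threshold, min_run=min_run,
                                scramble_mode=scramble_mode, cell_id=cell_ids[i])
            row.update(observed_r=res.observed_r, null_cutoff=res.null_cutoff,
                       is_locked=res.is_locked)
        except DegenerateTraceError:
            row["flag"] = "degenerate"
        rows.append(row)
    return pd.DataFrame(rows)


class ScrambleBootstrapClassifier(ClassifierMixin, BaseEstimator):
    """Per-cell stimulus-locking test as an sklearn-style classifier.

    Each sample (row of X) is one cell's Z-score trace; the "features" are
    frames. ``fit`` runs the scramble bootstrap on every row and stores the
    verdicts; ``predict`` applies the same test to new rows. There is no
    training in the supervised sense — the estimator encapsulates the test's
    configuration and fitted per-cell statistics.

    Parameters
    ----------
    stim_vector : array-like of 0/1, required
        Binary stimulus boxcar at the imaging frame rate (same length as rows).
    n_scrambles : int, default 10_000
    alpha : float, default 0.01
        Top quantile of the null defining the verdict.
    epoch_threshold, min_run : epoch-detection settings preserved by scrambles.
    scramble_mode : {"block", "replace"}
    random_state : int or None

    Attributes (after ``fit``)
    --------------------------
    observed_r_ : ndarray — Pearson r of each cell against the stimulus.
    null_cutoff_ : ndarray — per-cell empirical top-alpha null quantile.
    labels_ : ndarray of bool — stimulus-locked verdicts.
    flags_ : ndarray of str — "degenerate" for constant cells, else "".
    results_ : DataFrame — tidy per-cell table.
    """

    def __init__(self, stim_vector=None, n_scrambles: int = DEFAULT_N_SCRAMBLES,
                 alpha: float = DEFAULT_ALPHA,
                 epoch_threshold: float = _events.DEFAULT_THRESHOLD,
                 min_run: int = _events.DEFAULT_MIN_RUN,
                 scramble_mode: str = "block", random_state=None):
        self.stim_vector = stim_vector
        self.n_scrambles = n_scrambles
        self.alpha = alpha
        self.epoch_threshold = epoch_threshold
        self.min_run = min_run
        self.scramble_mode = scramble_mode
        self.random_state = random_state

    def _run(self, X) -> pd.DataFrame:
        if self.stim_vector is None:
            raise InputError("stim_vector is required")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise InputError("X must be 2-D (cells x frames)")
        return classify_fov(X, stim_vector=self.stim_vector,
                            n_scrambles=self.n_scrambles, alpha=self.alpha,
                            seed=self.random_state,
                            epoch_threshold=self.epoch_threshold,
                            min_run=self.min_run,
                            scramble_mode=self.scramble_mode)

    def fit(self, X, y=None):
        res = self._run(X)
        self.results_ = res
        self.observed_r_ = res["observed_r"].to_numpy()
        self.null_cutoff_ = res["null_cutoff"].to_numpy()
        self.labels_ = res["is_locked"].to_numpy(dtype=bool)
        self.flags_ = res["flag"].to_numpy()
        self.classes_ = np.array([False, True])
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def predict(self, X):
        return self._run(X)["is_locked"].to_numpy(dtype=bool)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
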