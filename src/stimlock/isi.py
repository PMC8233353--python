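"""Intrinsic-signal-imaging (ISI) map computation and quantification.

Evoked cortical activity darkens tissue under 630 nm illumination, so the
whisker map appears as a *negative* ΔR/R region. Per trial and pixel

    ΔR/R = (mean post-stimulus reflectance - mean pre-stimulus reflectance)
           / mean pre-stimulus reflectance

averaged over trials, then standardized to Z over all valid pixels. The map
is the set of pixels with Z < -3; its area is pixel count x pixel_size^2 and
its intensity is the mean over the map normalized to the mean over the
background outside the map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .errors import DegenerateTraceError, InputError, ParameterError

DEFAULT_THRESHOLD = -3.0


@dataclass
class IsiTrialStack:
    """Reflectance frames for one ISI session.

    frames: (n_trials, pre_frames + post_frames, H, W); acquisition at
    ``frame_rate`` Hz with ``pre_frames`` before stimulus onset per trial.
    """

    frames: np.ndarray
    pre_frames: int
    post_frames: int
    frame_rate: float = 30.0
    pixel_size_mm: float = 1.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4:
            raise InputError("frames must be 4-D (trials, frames, H, W)")
        if self.pre_frames < 1 or self.post_frames < 1:
            raise InputError("pre_frames and post_frames must be >= 1")
        if self.frames.shape[1] != self.pre_frames + self.post_frames:
            raise InputError("pre_frames + post_frames must equal frames per trial")

    @property
    def n_trials(self) -> int:
        return self.frames.shape[0]


def compute_drr(stack: IsiTrialStack) -> np.ndarray:
    """Trial-averaged ΔR/R image (H x W).

    Pixels whose pre-stimulus baseline is <= 0 in any trial are flagged NaN and
    excluded from downstream statistics.
    """
    pre = stack.frames[:, :stack.pre_frames].mean(axis=1)    # (trials, H, W)
    post = stack.frames[:, stack.pre_frames:].mean(axis=1)
    bad = pre <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        drr_trials = (post - pre) / pre
    drr_trials[bad] = np.nan
    if not bad.any():
        return drr_trials.mean(axis=0)
    import warnings
    with warnings.catch_warnings():
        # pixels invalid in every trial stay NaN by design
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(drr_trials, axis=0)


def zscore_image(drr: np.ndarray) -> np.ndarray:
    """Standardize an image to zero mean / unit SD over all valid pixels."""
    drr = np.asarray(drr, dtype=float)
    valid = np.isfinite(drr)
    if not valid.any():
        raise InputError("no valid pixels")
    mu = drr[valid].mean()
    sd = drr[valid].std(ddof=1)
    if sd == 0:
        raise DegenerateTraceError("constant ΔR/R image")
    z = np.full(drr.shape, np.nan)
    z[valid] = (drr[valid] - mu) / sd
    return z


def threshold_map(z_img: np.ndarray, threshold: float = DEFAULT_THRESHOLD,
                  pixel_size_mm: float = 1.0) -> tuple[np.ndarray, float]:
    """Evoked-map mask (Z < threshold; NaN pixels excluded) and area in mm^2."""
    z_img = np.asarray(z_img, dtype=float)
    with np.errstate(invalid="ignore"):
        mask = z_img < threshold
    area = float(mask.sum()) * pixel_size_mm ** 2
    return mask, area


def map_intensity(img: np.ndarray, mask: np.ndarray,
                  fallback_roi: np.ndarray | None = None) -> float:
    """Mean intensity over the map (or fallback ROI when the map is empty)
    divided by the mean over the background outside both regions."""
    img = np.asarray(img, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    region = mask
    if not region.any():
        if fallback_roi is None or not np.asarray(fallback_roi, dtype=bool).any():
            raise InputError("empty map and no fallback ROI")
        region = np.asarray(fallback_roi, dtype=bool)
    background = ~region & np.isfinite(img)
    if fallback_roi is not None:
        background &= ~np.asarray(fallback_roi, dtype=bool)
    if not background.any():
        raise InputError("empty background")
    region = region & np.isfinite(img)
    bg_mean = img[background].mean()
    if bg_mean == 0:
        raise InputError("background mean is zero; intensity ratio undefined")
    return float(img[region].mean() / bg_mean)


class IsiMapper(BaseEstimator):
    """Estimator turning an ISI trial stack into a quantified whisker map.

    Attributes (after ``fit``)
    --------------------------
    drr_ : trial-averaged ΔR/R image
    z_img_ : standardized image
    mask_ : boolean evoked-map mask (Z < threshold)
    area_mm2_ : thresholded area
    signal_ratio_ : map mean / background mean on the ΔR/R image
        (NaN when the map and fallback are both empty)
    """

    def __init__(self, threshold: float = DEFAULT_THRESHOLD,
                 pixel_size_mm: float = 1.0, fallback_roi=None):
        self.threshold = threshold
        self.pixel_size_mm = pixel_size_mm
        self.fallback_roi = fallback_roi

    def fit(self, stack: IsiTrialStack, y=None):
        if self.threshold >= 0:
            raise ParameterError("threshold must be negative (evoked darkening)")
        self.drr_ = compute_drr(stack)
        self.z_img_ = zscore_image(self.drr_)
        px = self.pixel_size_mm if self.pixel_size_mm is not None else stack.pixel_size_mm
        self.mask_, self.area_mm2_ = threshold_map(self.z_img_, self.threshold, px)
        try:
            self.signal_ratio_ = map_intensity(self.drr_, self.mask_, self.fallback_roi)
        except InputError:
            self.signal_ratio_ = float("nan")
        return self
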