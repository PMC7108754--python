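"""Prestimulus baseline statistics and the adaptive significant-pixel detector.

A pixel-frame is a positive significant signal pixel when its intensity
exceeds the prestimulus mean by more than ``k_sigma`` prestimulus standard
deviations in ``run_length`` consecutive frames (strict inequality,
run-start indexed); negative significance is the mirrored criterion below
the baseline.  The detector adapts to each pixel's own baseline mean and
variability, which suppresses spontaneous speckle/intensity fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import minimum_filter1d, maximum_filter1d

from .dataio import BScanSeries

__all__ = ["BaselineStats", "compute_baseline", "detect_significant",
           "runs_to_coverage", "estimate_noise", "intensity_mask"]


@dataclass
class BaselineStats:
    """Per-pixel prestimulus mean and sample STD maps."""

    Ib: np.ndarray
    sigma_b: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("baseline needs >= 2 prestimulus frames")
        if self.Ib.shape != self.sigma_b.shape:
            raise ValueError("Ib and sigma_b shape mismatch")
        if not np.all(np.isfinite(self.Ib)):
            raise ValueError("non-finite baseline mean")
        if np.any(self.sigma_b < 0):
            raise ValueError("negative baseline STD")


def compute_baseline(series: BScanSeries) -> BaselineStats:
    """Average intensity over the prestimulus window, per pixel.

    The mean is the arithmetic mean over the prestimulus frames; the STD is
    the sample standard deviation (N-1 denominator) over the same frames.
    """
    n_pre = series.protocol.n_prestim_frames(series.fps)
    if n_pre < 2:
        raise ValueError(f"only {n_pre} prestimulus frames; need >= 2")
    pre = series.data[:, :, :n_pre].astype(np.float64)
    return BaselineStats(Ib=pre.mean(axis=2),
                         sigma_b=pre.std(axis=2, ddof=1),
                         n_frames=n_pre)


def detect_significant(series: BScanSeries | np.ndarray,
                       baseline: BaselineStats,
                       k_sigma: float = 3.0,
                       run_length: int = 5) -> np.ndarray:
    """Label significant pixel-frames: +1 / -1 / 0 (run-start indexed).

    labels[z, x, t] = +1 iff I(z, x, t .. t+run_length-1) all exceed
    Ib + k_sigma * sigma_b (strict), -1 for the mirrored criterion below
    Ib - k_sigma * sigma_b, else 0.  Frames within run_length - 1 of the end
    of the series cannot start a run and are 0.  Intensity exactly on the
    threshold is not significant.
    """
    if run_length < 1:
        raise ValueError("run_length must be >= 1")
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    data = series.data if isinstance(series, BScanSeries) else np.asarray(series)
    if data.shape[:2] != baseline.Ib.shape:
        raise ValueError(f"series frame shape {data.shape[:2]} != "
                         f"baseline shape {baseline.Ib.shape}")
    hi = baseline.Ib + k_sigma * baseline.sigma_b
    lo = baseline.Ib - k_sigma * baseline.sigma_b
    above = data > hi[:, :, None]
    below = data < lo[:, :, None]
    labels = np.zeros(data.shape, dtype=np.int8)
    for cond, value in ((above, 1), (below, -1)):
        # all-true over [t, t + run_length - 1]
        run = minimum_filter1d(cond.astype(np.uint8), size=run_length,
                               axis=2, mode="constant", cval=0,
                               origin=-(run_length // 2))
        if run_length > 1:
            run[:, :, -(run_length - 1):] = 0
        labels[run.astype(bool)] = value
    return labels


def runs_to_coverage(labels: np.ndarray, run_length: int = 5) -> np.ndarray:
    """Dilate run-start labels to every frame covered by a run.

    A pixel-frame is covered with sign s if any s-labeled run starting in
    the preceding ``run_length`` frames (inclusive) spans it.  Positive and
    negative runs cannot overlap by construction (a frame cannot be both
    above and below the baseline band).
    """
    if run_length < 1:
        raise ValueError("run_length must be >= 1")
    cov = np.zeros(labels.shape, dtype=np.int8)
    for value in (1, -1):
        started = (labels == value).astype(np.uint8)
        # any start in [t - run_length + 1, t]
        covered = maximum_filter1d(started, size=run_length, axis=2,
                                   mode="constant", cval=0,
                                   origin=run_length // 2)
        cov[covered.astype(bool)] = value
    return cov


def estimate_noise(series: BScanSeries, deep_fraction: float = 0.1):
    """Noise level from the deepest rows of a series (blank condition).

    Returns ``(noise_mean, noise_sigma)``.  ``noise_mean`` is the mean
    intensity of the deepest ``deep_fraction`` of z rows, where backscatter
    has attenuated towards the detector floor.  ``noise_sigma`` is the
    temporal (frame-to-frame) STD averaged over those pixels: with static
    speckle the temporal fluctuation isolates the detector noise, whereas
    the spatial spread of the region would be dominated by speckle contrast.
    """
    if not 0 < deep_fraction <= 1:
        raise ValueError("deep_fraction must be in (0, 1]")
    n_z = series.data.shape[0]
    n_rows = max(1, int(round(deep_fraction * n_z)))
    region = series.data[n_z - n_rows:, :, :].astype(np.float64)
    return float(region.mean()), float(region.std(axis=2, ddof=1).mean())


def intensity_mask(baseline: BaselineStats,
                   noise_mean: float,
                   noise_sigma: float,
                   factor: float = 6.0) -> np.ndarray:
    """Sufficient-intensity mask: Ib above the noise level by factor x STD.

    Pixels whose baseline mean does not exceed ``noise_mean + factor *
    noise_sigma`` carry no reliable scattering signal and are excluded from
    fractional-change pooling.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    return baseline.Ib > noise_mean + factor * noise_sigma
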