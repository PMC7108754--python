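"""Onset/peak latency estimation, dose-response regression, coregistration.

The onset delay of a stimulus-locked course is the first post-onset time at
which the signal power exceeds the prestimulus baseline mean by more than
``k`` baseline standard deviations; the peak delay is the time of maximal
signal power after onset.  Signal power defaults to |value| so a darkening
(negative) course and a scattering increase are handled uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .response import TimeCourse

__all__ = ["LatencyResult", "DoseResponse", "onset_delay", "peak_delay",
           "dose_response_fit", "coregister", "projection_view"]


@dataclass
class LatencyResult:
    """Detected onset/peak delays in seconds after stimulus onset.

    ``onset_s`` is None when the course never crossed the threshold
    ("not detected").
    """

    onset_s: Optional[float] = None
    peak_s: Optional[float] = None
    baseline_mean: float = np.nan
    baseline_sigma: float = np.nan
    threshold: float = np.nan

    @property
    def detected(self) -> bool:
        return self.onset_s is not None


@dataclass
class DoseResponse:
    """Ordinary least-squares line of peak response versus radiant exposure."""

    exposures: np.ndarray
    peak_values: np.ndarray
    slope: float
    intercept: float
    r: float


def _power(tc: TimeCourse, power: str) -> np.ndarray:
    if power == "abs":
        return np.abs(tc.value)
    if power == "square":
        return tc.value ** 2
    raise ValueError(f"unknown power mode {power!r}")


def onset_delay(tc: TimeCourse, k: float = 3.0, power: str = "abs",
                min_run: int = 5) -> LatencyResult:
    """Threshold-crossing onset estimator.

    Baseline mean and STD are computed from the prestimulus samples of the
    power signal; the onset is the first time >= 0 at which the power
    exceeds mean + k*STD and stays above it for ``min_run`` consecutive
    samples.  The persistence requirement mirrors the run criterion of the
    significance detector and keeps a single noise excursion among the
    hundreds of post-onset samples from faking an early onset.  The onset is
    reported at the sample time of the first crossing (no sub-sample
    interpolation).  Returns ``onset_s=None`` when never crossed.
    """
    p = _power(tc, power)
    pre = p[tc.time_s < 0]
    pre = pre[np.isfinite(pre)]
    if pre.size < 2:
        raise ValueError("course has no usable prestimulus window")
    mu, sd = float(pre.mean()), float(pre.std(ddof=1))
    thr = mu + k * sd
    post = tc.time_s >= 0
    t_post = tc.time_s[post]
    above = np.isfinite(p[post]) & (p[post] > thr)
    if sd == 0 and not above.any():
        return LatencyResult(onset_s=None, baseline_mean=mu, baseline_sigma=sd,
                             threshold=thr)
    if min_run <= 1:
        hits = np.nonzero(above)[0]
    elif above.size < min_run:
        hits = np.empty(0, dtype=int)
    else:
        window = np.lib.stride_tricks.sliding_window_view(above, min_run)
        hits = np.nonzero(window.all(axis=1))[0]
    idx = int(hits[0]) if hits.size else None
    if idx is None:
        return LatencyResult(onset_s=None, baseline_mean=mu, baseline_sigma=sd,
                             threshold=thr)
    return LatencyResult(onset_s=float(t_post[idx]), baseline_mean=mu,
                         baseline_sigma=sd, threshold=thr)


def peak_delay(tc: TimeCourse, power: str = "abs") -> float:
    """Time of maximal signal power at t >= 0; ties break to the earliest."""
    p = _power(tc, power)
    post = tc.time_s >= 0
    if not post.any():
        raise ValueError("course has no post-onset samples")
    vals = p[post]
    if not np.isfinite(vals).any():
        raise ValueError("course has no finite post-onset samples")
    vals = np.where(np.isfinite(vals), vals, -np.inf)
    return float(tc.time_s[post][int(np.argmax(vals))])


def dose_response_fit(exposures, peak_values) -> DoseResponse:
    """OLS line of peak response versus radiant exposure (J/cm^2)."""
    exposures = np.asarray(exposures, dtype=float)
    peak_values = np.asarray(peak_values, dtype=float)
    if np.unique(exposures).size < 2:
        raise ValueError("need >= 2 distinct exposures for a fit")
    fit = stats.linregress(exposures, peak_values)
    return DoseResponse(exposures=exposures, peak_values=peak_values,
                        slope=float(fit.slope), intercept=float(fit.intercept),
                        r=float(fit.rvalue))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    den = np.sqrt((a * a).sum() * (b * b).sum())
    if den == 0:
        raise ValueError("degenerate (constant) image: correlation undefined")
    return float((a * b).sum() / den)


def coregister(image_a: np.ndarray, image_b: np.ndarray,
               max_shift: int = 10):
    """Translation-only coregistration maximizing Pearson's correlation.

    Exhaustive integer-shift search within +/- ``max_shift`` along both
    axes, maximizing the correlation over the overlap.  The returned
    ``(dy, dx)`` satisfies ``image_b[i, j] ~ image_a[i + dy, j + dx]``.
    Shifts whose overlap is smaller than half of the smaller image are
    skipped.  Ties resolve to the smallest |shift|, then lexicographically.
    Returns ``(dy, dx, r)``.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    min_overlap = 0.5 * min(a.size, b.size)
    best = None
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            ay0, ay1 = max(0, dy), min(a.shape[0], b.shape[0] + dy)
            ax0, ax1 = max(0, dx), min(a.shape[1], b.shape[1] + dx)
            if ay1 - ay0 <= 1 or ax1 - ax0 <= 1:
                continue
            if (ay1 - ay0) * (ax1 - ax0) < min_overlap:
                continue
            sub_a = a[ay0:ay1, ax0:ax1]
            sub_b = b[ay0 - dy:ay1 - dy, ax0 - dx:ax1 - dx]
            r = _pearson(sub_a, sub_b)
            key = (-r, abs(dy) + abs(dx), dy, dx)
            if best is None or key < best[0]:
                best = (key, dy, dx, r)
    if best is None:
        raise ValueError("no shift satisfies the overlap requirement")
    return best[1], best[2], best[3]


def projection_view(volume: np.ndarray) -> np.ndarray:
    """Depth-mean projection of a volumetric scan.

    Input is (n_z, n_x, n_y); output is the (n_y, n_x) mean over depth, in
    the same orientation as the camera image so the two can be coregistered
    directly.  The mean (rather than max) preserves vessel shadows, which
    are the landmarks shared with the camera view.
    """
    volume = np.asarray(volume)
    if volume.size == 0:
        raise ValueError("empty volume")
    return volume.mean(axis=0).T
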