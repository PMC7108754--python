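"""Inter-B-scan decorrelation angiography, vascular masking and velocity index.

Moving red blood cells refresh the speckle between repeated B-scans, so the
windowed zero-lag normalized cross-correlation of adjacent frames drops
inside vessels.  The decorrelation D = 1 - rho (clipped to [0, 1]) maps the
vasculature, its magnitude indexes flow velocity, and thresholding plus an
intersection over frames yields the binary avascular mask that keeps
hemodynamics out of the fractional-scattering pooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.filters import threshold_otsu

from .dataio import BScanSeries

__all__ = ["DecorrelationMap", "VascularMask", "interframe_decorrelation",
           "angiogram_series", "build_vascular_mask", "velocity_index",
           "decorrelation_velocity_curve"]


@dataclass
class DecorrelationMap:
    """Per-pixel decorrelation of one adjacent-frame pair, in [0, 1]."""

    values: np.ndarray
    window: tuple = (3, 3)

    def __post_init__(self) -> None:
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("decorrelation values must lie in [0, 1]")


@dataclass
class VascularMask:
    """Binary map: 1 = avascular tissue, 0 = vessel or tail artifact."""

    avascular: np.ndarray
    threshold: float

    @property
    def vessel(self) -> np.ndarray:
        return ~self.avascular


def _windowed_mean(a: np.ndarray, window: tuple) -> np.ndarray:
    size = tuple(window) + (1,) * (a.ndim - len(window))
    return uniform_filter(a, size=size, mode="nearest")


def _decorrelation_stack(data: np.ndarray, window: tuple) -> np.ndarray:
    """D for every adjacent frame pair of (n_z, n_x, n_frames) data.

    rho is the windowed sum of A*B over sqrt(windowed sums of A^2 and B^2);
    a window with zero energy in both frames is defined as D = 0.
    """
    a = data[:, :, :-1].astype(np.float64)
    b = data[:, :, 1:].astype(np.float64)
    num = _windowed_mean(a * b, window)
    den = np.sqrt(_windowed_mean(a * a, window) * _windowed_mean(b * b, window))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / np.maximum(den, 1e-300), 1.0)
    return np.clip(1.0 - rho, 0.0, 1.0)


def interframe_decorrelation(frame_a: np.ndarray, frame_b: np.ndarray,
                             window: tuple = (3, 3)) -> DecorrelationMap:
    """Decorrelation map of one frame pair.

    D = 1 - rho with rho the windowed zero-lag normalized cross-correlation,
    computed over a (wz, wx) window centred at each pixel.  D is invariant
    to a global intensity gain applied to either frame.
    """
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must have the same shape")
    if min(window) < 1:
        raise ValueError("window must be >= 1x1")
    stack = np.stack([frame_a, frame_b], axis=2)
    return DecorrelationMap(values=_decorrelation_stack(stack, window)[:, :, 0],
                            window=tuple(window))


def angiogram_series(series: BScanSeries | np.ndarray,
                     window: tuple = (3, 3)):
    """Decorrelation maps for all adjacent frame pairs of a series.

    Returns ``(maps, mean_map)`` where maps has shape (n_z, n_x, n_frames-1)
    and mean_map is the temporal mean used for display and thresholding.
    """
    data = series.data if isinstance(series, BScanSeries) else np.asarray(series)
    if data.shape[2] < 2:
        raise ValueError("need at least 2 frames for an angiogram")
    maps = _decorrelation_stack(data, window)
    return maps, maps.mean(axis=2)


def build_vascular_mask(maps: np.ndarray,
                        threshold: float | str = "otsu",
                        tail_extend: bool = True) -> VascularMask:
    """Binarize per-frame decorrelation maps and intersect over frames.

    Each pair map is binarized at a single threshold (Otsu's method on the
    temporal-mean map by default); with ``tail_extend`` the vessel label of a
    frame propagates down each A-line to the bottom (shadow artifact).  The
    final avascular mask is the logical AND of all single-frame avascular
    masks, i.e. a pixel flagged as vessel in any frame stays excluded.
    """
    maps = np.asarray(maps)
    if maps.ndim == 2:
        maps = maps[:, :, None]
    if threshold == "otsu":
        mean_map = maps.mean(axis=2)
        if np.ptp(mean_map) == 0:
            thr = float(mean_map.flat[0]) + 1.0     # no vessels anywhere
        else:
            thr = float(threshold_otsu(mean_map))
    else:
        thr = float(threshold)
    vessel_any = (maps > thr).any(axis=2)
    if tail_extend:
        # union over frames commutes with the per-frame downward propagation
        vessel_any = np.maximum.accumulate(vessel_any, axis=0)
    return VascularMask(avascular=~vessel_any, threshold=thr)


def velocity_index(trials: Sequence[BScanSeries],
                   roi: np.ndarray,
                   window: tuple = (3, 3)):
    """ROI-mean decorrelation per adjacent frame pair, trial-averaged.

    The decorrelation magnitude serves as a relative blood-flow-velocity
    index.  Returns a TimeCourse on the pair-midpoint time grid.
    """
    from .response import TimeCourse
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    trials = list(trials)
    if not trials:
        raise ValueError("no trials")
    per_trial = []
    for s in trials:
        maps = _decorrelation_stack(s.data, window)
        per_trial.append(maps[roi, :].mean(axis=0))
    t = trials[0].time_s
    t_pairs = 0.5 * (t[:-1] + t[1:])
    value = np.mean(per_trial, axis=0)
    return TimeCourse(time_s=t_pairs, value=value,
                      n_pixels=np.full(t_pairs.size, int(roi.sum())),
                      labels={"kind": "velocity_index",
                              "n_trials": len(trials)},
                      prestim_s=trials[0].protocol.prestim_s)


def decorrelation_velocity_curve(phantom_series: dict,
                                 window: tuple = (3, 3),
                                 margin: int = 2):
    """Mean decorrelation versus programmed phantom velocity.

    ``phantom_series`` maps velocity (mm/s) -> BScanSeries.  The mean is
    taken over all frame pairs and over the frame interior (a ``margin``
    keeps window edge effects out).  Returns a DataFrame with columns
    velocity_mm_s and decorrelation, sorted by velocity.
    """
    import pandas as pd
    if len(phantom_series) < 2:
        raise ValueError("need at least 2 phantom velocities")
    rows = []
    for v in sorted(phantom_series):
        maps = _decorrelation_stack(phantom_series[v].data, window)
        core = maps[margin:maps.shape[0] - margin,
                    margin:maps.shape[1] - margin, :]
        rows.append({"velocity_mm_s": v, "decorrelation": float(core.mean())})
    return pd.DataFrame(rows)
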