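"""Fractional scattering change dR/R, mask-filtered pooling and time courses.

dR/R(z, x, t) = (I(z, x, t) - Ib(z, x)) / Ib(z, x) relative to the per-pixel
prestimulus baseline.  Pooling keeps only pixels that are significant,
avascular and of sufficient intensity; negative-labeled responses are
inverted so darkening and brightening pixels average constructively; the
pooled value is then averaged over the repeated trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dataio import BScanSeries
from .significance import BaselineStats, runs_to_coverage

__all__ = ["FractionalChangeStack", "TimeCourse", "fractional_change",
           "significant_pixel_sets", "aggregate_foct", "depth_resolved",
           "oisi_signal", "activation_map", "center_roi"]


@dataclass
class FractionalChangeStack:
    """Per-trial dR/R stack plus the per-pixel validity map (Ib > 0)."""

    drr: np.ndarray          # (n_z, n_x, n_frames)
    valid: np.ndarray        # (n_z, n_x) boolean
    time_s: np.ndarray
    trial_index: int = 0
    exposure: float = 1.0


@dataclass
class TimeCourse:
    """A stimulus-locked scalar signal versus time.

    time_s is relative to the stimulus onset (prestimulus times negative);
    value may contain NaN where no eligible pixel was available (flagged,
    never silently zero); n_pixels records how many pixels were pooled per
    frame.
    """

    time_s: np.ndarray
    value: np.ndarray
    n_pixels: Optional[np.ndarray] = None
    labels: dict = field(default_factory=dict)
    prestim_s: Optional[float] = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_s.shape != self.value.shape:
            raise ValueError("time and value shape mismatch")

    @property
    def prestim(self) -> np.ndarray:
        """Values at prestimulus times (t < 0)."""
        return self.value[self.time_s < 0]

    def at(self, t: float) -> float:
        """Value at the frame nearest to time t."""
        return float(self.value[np.argmin(np.abs(self.time_s - t))])


def fractional_change(series: BScanSeries,
                      baseline: BaselineStats) -> FractionalChangeStack:
    """Elementwise (I - Ib) / Ib.

    Pixels with Ib <= 0 cannot carry a fractional change; they are marked
    invalid and their dR/R set to 0 so downstream masking excludes them
    instead of propagating NaN.
    """
    if series.data.shape[:2] != baseline.Ib.shape:
        raise ValueError("baseline shape mismatch")
    valid = baseline.Ib > 0
    ib = np.where(valid, baseline.Ib, 1.0)
    drr = (series.data.astype(np.float64) - ib[:, :, None]) / ib[:, :, None]
    drr[~valid, :] = 0.0
    return FractionalChangeStack(drr=drr, valid=valid, time_s=series.time_s,
                                 trial_index=series.trial_index,
                                 exposure=series.exposure)


def significant_pixel_sets(labels: np.ndarray,
                           time_s: np.ndarray,
                           response_window_s: tuple = (0.0, 2.0)):
    """Spatial sets of positively / negatively responding pixels.

    A pixel belongs to the positive (negative) set when at least one +1 (-1)
    run starts inside the response window.  The rare pixel with runs of both
    signs is assigned the sign with more run starts; an exact tie drops it.
    """
    w = (time_s >= response_window_s[0]) & (time_s <= response_window_s[1])
    n_pos = (labels[:, :, w] == 1).sum(axis=2)
    n_neg = (labels[:, :, w] == -1).sum(axis=2)
    pos = (n_pos > 0) & (n_pos >= n_neg) & ~((n_pos == n_neg) & (n_neg > 0))
    neg = (n_neg > 0) & (n_neg > n_pos)
    return pos, neg


def _pool_trial(drr: np.ndarray, pos: np.ndarray, neg: np.ndarray):
    """Signed pooled mean per frame over the given pixel sets."""
    n = int(pos.sum() + neg.sum())
    if n == 0:
        return None, 0
    total = drr[pos, :].sum(axis=0) - drr[neg, :].sum(axis=0)
    return total / n, n


def aggregate_foct(drr_stacks: Sequence[FractionalChangeStack],
                   sig_labels: Sequence[np.ndarray],
                   vascular_mask: Optional[np.ndarray] = None,
                   intensity_mask: Optional[np.ndarray] = None,
                   run_length: int = 5,
                   pooling: str = "pixel_set",
                   response_window_s: tuple = (0.0, 2.0),
                   restrict: Optional[np.ndarray] = None,
                   prestim_s: Optional[float] = None) -> TimeCourse:
    """Mask-filtered, sign-normalized, trial-averaged fOCT time course.

    Eligible pixels are avascular, of sufficient intensity and have a valid
    baseline; ``restrict`` optionally confines pooling to a section of
    interest or depth slab.  Negative-labeled pixels contribute -dR/R so
    both response polarities average constructively.

    pooling="pixel_set" (default): each trial pools, at every frame, the
    fixed spatial set of pixels that had a significant run inside the
    response window — the pooled course is defined on the full time grid,
    including the prestimulus baseline the latency estimators need.
    pooling="per_frame": a pixel contributes only at frames covered by a
    significant run; frames with no covered pixel are NaN (flagged).
    """
    if len(drr_stacks) != len(sig_labels) or not drr_stacks:
        raise ValueError("need one significance label stack per trial")
    shape = drr_stacks[0].drr.shape[:2]
    eligible = np.ones(shape, dtype=bool)
    for mask in (vascular_mask, intensity_mask, restrict):
        if mask is not None:
            if mask.shape != shape:
                raise ValueError("mask shape mismatch")
            eligible &= mask
    time_s = drr_stacks[0].time_s
    courses, counts = [], []
    for stack, labels in zip(drr_stacks, sig_labels):
        elig = eligible & stack.valid
        if pooling == "pixel_set":
            pos, neg = significant_pixel_sets(labels, time_s, response_window_s)
            course, n = _pool_trial(stack.drr, pos & elig, neg & elig)
            courses.append(np.full(time_s.size, np.nan) if course is None else course)
            counts.append(np.full(time_s.size, n))
        elif pooling == "per_frame":
            cov = runs_to_coverage(labels, run_length)
            contrib = np.where(cov == 1, stack.drr,
                               np.where(cov == -1, -stack.drr, 0.0))
            use = (cov != 0) & elig[:, :, None]
            n_t = use.sum(axis=(0, 1))
            with np.errstate(invalid="ignore", divide="ignore"):
                course = np.where(n_t > 0,
                                  (contrib * use).sum(axis=(0, 1)) /
                                  np.maximum(n_t, 1), np.nan)
            courses.append(course)
            counts.append(n_t)
        else:
            raise ValueError(f"unknown pooling mode {pooling!r}")
    courses = np.asarray(courses)
    counts = np.asarray(counts)
    n_finite = np.isfinite(courses).sum(axis=0)
    value = np.where(n_finite > 0,
                     np.nansum(courses, axis=0) / np.maximum(n_finite, 1),
                     np.nan)
    return TimeCourse(time_s=time_s, value=value,
                      n_pixels=counts.sum(axis=0),
                      labels={"kind": "foct", "pooling": pooling,
                              "n_trials": len(drr_stacks),
                              "exposure": drr_stacks[0].exposure},
                      prestim_s=prestim_s)


def depth_resolved(drr_stacks: Sequence[FractionalChangeStack],
                   sig_labels: Sequence[np.ndarray],
                   z_pitch_um: float,
                   vascular_mask: Optional[np.ndarray] = None,
                   intensity_mask: Optional[np.ndarray] = None,
                   bin_um: float = 100.0,
                   n_bins: int = 6,
                   **kwargs) -> list:
    """fOCT time courses per depth slab of ``bin_um`` micrometres.

    Bins are half-open [k*bin, (k+1)*bin) in depth from the cortical
    surface; a slab with no eligible pixel yields an all-NaN course
    (flagged via n_pixels = 0).
    """
    n_z = drr_stacks[0].drr.shape[0]
    if n_bins * bin_um > n_z * z_pitch_um + 1e-9:
        raise ValueError("depth bins exceed the imaged depth")
    z_um = np.arange(n_z) * z_pitch_um
    out = []
    for k in range(n_bins):
        slab = (z_um >= k * bin_um) & (z_um < (k + 1) * bin_um)
        restrict = np.zeros(drr_stacks[0].drr.shape[:2], dtype=bool)
        restrict[slab, :] = True
        tc = aggregate_foct(drr_stacks, sig_labels, vascular_mask,
                            intensity_mask, restrict=restrict, **kwargs)
        tc.labels["depth_bin"] = k + 1
        tc.labels["depth_um"] = (k * bin_um, (k + 1) * bin_um)
        out.append(tc)
    return out


def center_roi(shape: tuple, center: tuple, size: int = 20) -> np.ndarray:
    """Square ROI mask of ``size`` x ``size`` pixels centred at (row, col)."""
    r0 = max(0, int(center[0]) - size // 2)
    c0 = max(0, int(center[1]) - size // 2)
    roi = np.zeros(shape, dtype=bool)
    roi[r0:r0 + size, c0:c0 + size] = True
    return roi


def oisi_signal(trials: Sequence[BScanSeries], roi: np.ndarray) -> TimeCourse:
    """Unmasked ROI-mean fractional intrinsic signal, trial-averaged.

    For each trial the per-pixel baseline is the prestimulus mean of the
    camera frames (same window convention as OCT, -1 to 0 s), and the course
    is the ROI mean of (I - Ib)/Ib.  No significance, vascular or intensity
    masks are applied.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    trials = list(trials)
    if not trials:
        raise ValueError("no trials")
    per_trial = []
    for s in trials:
        n_pre = s.protocol.n_prestim_frames(s.fps)
        pre = s.data[:, :, :n_pre].astype(np.float64)
        ib = pre.mean(axis=2)
        ok = roi & (ib > 0)
        if not ok.any():
            raise ValueError("ROI has no valid-baseline pixels")
        drr = (s.data[ok, :].astype(np.float64) - ib[ok][:, None]) / ib[ok][:, None]
        per_trial.append(drr.mean(axis=0))
    t = trials[0].time_s
    return TimeCourse(time_s=t, value=np.mean(per_trial, axis=0),
                      n_pixels=np.full(t.size, int(roi.sum())),
                      labels={"kind": "oisi", "n_trials": len(trials),
                              "exposure": trials[0].exposure},
                      prestim_s=trials[0].protocol.prestim_s)


def activation_map(drr_stacks: Sequence[FractionalChangeStack],
                   sig_labels: Sequence[np.ndarray],
                   time_window_s: tuple = (0.0, 1.0),
                   vascular_mask: Optional[np.ndarray] = None,
                   intensity_mask: Optional[np.ndarray] = None):
    """Mean dR/R map over a time window for significant pixels, plus count.

    A pixel enters the map if it has a significant run starting inside the
    window in any trial and passes the masks; non-significant pixels are
    NaN.  Returns ``(map, n_significant)``.
    """
    shape = drr_stacks[0].drr.shape[:2]
    time_s = drr_stacks[0].time_s
    w = (time_s >= time_window_s[0]) & (time_s <= time_window_s[1])
    eligible = np.ones(shape, dtype=bool)
    for mask in (vascular_mask, intensity_mask):
        if mask is not None:
            eligible &= mask
    sig_any = np.zeros(shape, dtype=bool)
    acc = np.zeros(shape)
    for stack, labels in zip(drr_stacks, sig_labels):
        sig_any |= (labels[:, :, w] != 0).any(axis=2)
        acc += stack.drr[:, :, w].mean(axis=2)
    sig_any &= eligible
    out = np.where(sig_any, acc / len(drr_stacks), np.nan)
    return out, int(sig_any.sum())
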