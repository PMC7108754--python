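"""Spike detection, PSTH construction and stimulus-response statistics.

Extracellular spikes are detected as negative-going threshold crossings
(default -41 mV at 30 kHz) with a 1-ms refractory window against double
counting.  No spike sorting: single- and multi-unit activity are treated
alike as threshold crossings.  Responses are summarized as peristimulus
time histograms (PSTHs) and validated with a paired two-tailed t-test of
per-trial spike counts in the stimulation window against the pre- and
post-stimulation windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["SpikeData", "PSTH", "detect_spikes", "build_psth",
           "ins_response_test", "spike_onset_latency"]


@dataclass
class SpikeData:
    """Per-trial spike timestamps, stimulus-onset-locked seconds."""

    trials: list
    sampling_rate_hz: float = 30000.0
    threshold_mv: float = -41.0

    def __post_init__(self) -> None:
        self.trials = [np.sort(np.asarray(t, dtype=float)) for t in self.trials]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def counts_in_window(self, window: tuple) -> np.ndarray:
        """Per-trial spike counts in [window[0], window[1])."""
        a, b = window
        return np.array([int(np.sum((t >= a) & (t < b))) for t in self.trials])


@dataclass
class PSTH:
    """Counts per stimulus-locked bin, summed over trials."""

    bin_edges_s: np.ndarray
    counts: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        if self.counts.size != self.bin_edges_s.size - 1:
            raise ValueError("counts / bin_edges size mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def bin_width_s(self) -> float:
        return float(self.bin_edges_s[1] - self.bin_edges_s[0])

    @property
    def bin_left_s(self) -> np.ndarray:
        return self.bin_edges_s[:-1]

    @property
    def rate_hz(self) -> np.ndarray:
        """Trial-averaged firing rate per bin."""
        return self.counts / (self.n_trials * self.bin_width_s)


def detect_spikes(voltage_mv: np.ndarray,
                  sampling_rate_hz: float = 30000.0,
                  threshold_mv: float = -41.0,
                  refractory_ms: float = 1.0,
                  t0_s: float = 0.0) -> np.ndarray:
    """Negative-going threshold-crossing spike times for one trial.

    A spike is stamped at each sample where the trace crosses the threshold
    downwards (previous sample above or at threshold, current strictly
    below); subsequent crossings inside the refractory window are
    suppressed.  ``t0_s`` is the stimulus-locked time of sample 0.
    """
    v = np.asarray(voltage_mv, dtype=float)
    if v.ndim != 1:
        raise ValueError("voltage trace must be 1-D")
    crossing = np.nonzero((v[1:] < threshold_mv) & (v[:-1] >= threshold_mv))[0] + 1
    if crossing.size == 0:
        return np.empty(0)
    refractory = refractory_ms / 1000.0 * sampling_rate_hz
    kept = [crossing[0]]
    for c in crossing[1:]:
        if c - kept[-1] >= refractory:
            kept.append(c)
    return np.asarray(kept) / sampling_rate_hz + t0_s


def build_psth(spikes: SpikeData, bin_ms: float = 10.0,
               window_s: tuple = (-1.0, 19.0)) -> PSTH:
    """Histogram spike times over stimulus-locked, half-open bins."""
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    width = bin_ms / 1000.0
    n_bins = int(round((window_s[1] - window_s[0]) / width))
    edges = window_s[0] + width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins, dtype=int)
    for t in spikes.trials:
        counts += np.histogram(t, bins=edges)[0]
    return PSTH(bin_edges_s=edges, counts=counts, n_trials=spikes.n_trials)


def ins_response_test(spikes: SpikeData,
                      stim_window: tuple = (0.0, 0.5),
                      pre_window: tuple = (-0.5, 0.0),
                      post_window: tuple = (0.5, 1.0)) -> dict:
    """Paired two-tailed t-tests of stimulation-window spike counts.

    Per-trial counts in the stimulation window are compared against the
    pre-stimulation and post-stimulation windows.  Returns t statistics and
    p values for both comparisons; a comparison whose paired differences
    have zero variance is flagged (p undefined).
    """
    if spikes.n_trials < 2:
        raise ValueError("need >= 2 trials for a paired test")
    stim = spikes.counts_in_window(stim_window)
    out = {}
    for name, window in (("pre", pre_window), ("post", post_window)):
        ref = spikes.counts_in_window(window)
        diff = stim - ref
        if np.all(diff == 0):
            # no difference in any trial: no evidence against the null
            out[name] = {"t": 0.0, "p": 1.0, "flag": None}
        elif np.all(diff == diff[0]):
            out[name] = {"t": np.inf if diff[0] > 0 else -np.inf, "p": None,
                         "flag": "zero-variance differences"}
        else:
            t, p = stats.ttest_rel(stim, ref)
            out[name] = {"t": float(t), "p": float(p), "flag": None}
    return out


def spike_onset_latency(psth: PSTH, k: float = 3.0,
                        min_run: int = 2) -> Optional[float]:
    """First post-onset bin whose rate exceeds prestim mean + k*STD.

    The prestimulus bins provide the baseline statistics (sample STD).  With
    millisecond bins the counts are sparse, so the crossing must persist for
    ``min_run`` consecutive bins; the latency is the left edge of the first
    bin of that run.  Returns None when the rate never crosses.
    """
    rate = psth.rate_hz
    left = psth.bin_left_s
    pre = rate[left < 0]
    if pre.size < 2:
        raise ValueError("PSTH has no prestimulus bins")
    thr = pre.mean() + k * pre.std(ddof=1)
    post = left >= 0
    above = rate[post] > thr
    if min_run <= 1:
        hits = np.nonzero(above)[0]
    elif above.size < min_run:
        hits = np.empty(0, dtype=int)
    else:
        window = np.lib.stride_tricks.sliding_window_view(above, min_run)
        hits = np.nonzero(window.all(axis=1))[0]
    if hits.size == 0:
        return None
    return float(left[post][int(hits[0])])
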