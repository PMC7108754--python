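"""Acquisition protocol and stimulus-locked response templates.

The protocol captures the trial structure used throughout: a 1-s prestimulus
baseline, a 0.5-s infrared pulse train (250-us pulses at 200 Hz), and an
18.5-s poststimulus recovery window, repeated over 15 trials.  OCT B-frames
are acquired at 100 fps for spatial/dose analysis and 240 fps for temporal
analysis; the intrinsic-signal camera runs at 20 or 60 fps respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = ["AcquisitionProtocol", "ResponseTemplate",
           "FOCT_TEMPLATE", "OISI_TEMPLATE", "VELOCITY_TEMPLATE"]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Trial timing, frame rates, stimulus parameters and scan geometry.

    Durations are seconds, pitches are micrometres per pixel, radiant
    exposures are J/cm^2 per pulse.
    """

    prestim_s: float = 1.0
    stim_s: float = 0.5
    poststim_s: float = 18.5
    n_trials: int = 15
    oct_fps: float = 100.0
    oisi_fps: float = 20.0
    pulse_width_us: float = 250.0
    pulse_rate_hz: float = 200.0
    radiant_exposures: tuple = (0.3, 0.5, 0.7, 1.0)
    z_pitch_um: float = 10.0
    x_pitch_um: float = 10.0
    n_z: int = 60
    n_x: int = 64

    def __post_init__(self) -> None:
        for name in ("prestim_s", "stim_s", "poststim_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for name in ("oct_fps", "oisi_fps", "pulse_rate_hz", "z_pitch_um",
                     "x_pitch_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        n_pulses = self.pulse_rate_hz * self.stim_s
        if abs(n_pulses - round(n_pulses)) > 1e-9:
            raise ValueError(
                f"pulse_rate_hz * stim_s = {n_pulses} is not an integer pulse count")
        if self.n_z < 1 or self.n_x < 1:
            raise ValueError("frame dimensions must be positive")

    @property
    def trial_s(self) -> float:
        return self.prestim_s + self.stim_s + self.poststim_s

    @property
    def n_pulses(self) -> int:
        """Number of stimulation pulses per trial (rate x duration)."""
        return round(self.pulse_rate_hz * self.stim_s)

    def n_frames(self, fps: float) -> int:
        return round(self.trial_s * fps)

    def n_prestim_frames(self, fps: float) -> int:
        return round(self.prestim_s * fps)

    def time_axis(self, fps: float) -> np.ndarray:
        """Frame times in seconds, stimulus onset at t = 0 (prestim negative)."""
        return np.arange(self.n_frames(fps)) / fps - self.prestim_s

    def to_dict(self) -> dict:
        d = asdict(self)
        d["radiant_exposures"] = list(self.radiant_exposures)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        d = dict(d)
        d["radiant_exposures"] = tuple(d.get("radiant_exposures", (0.3, 0.5, 0.7, 1.0)))
        return cls(**d)


@dataclass(frozen=True)
class ResponseTemplate:
    """Stimulus-locked fractional-change template.

    The template is exactly zero before ``onset_delay_s`` (measured from
    stimulus onset), rises as a quarter sine wave to its peak at
    ``peak_delay_s`` and recovers exponentially with time constant
    ``decay_tau_s``.  The quarter-sine rise has a non-zero slope at onset,
    which is what makes a threshold-crossing onset estimator able to resolve
    the programmed latency at the frame rate used here; a rise with zero
    initial slope would bias any such estimator late by tens of
    milliseconds regardless of noise level.

    Amplitude scales linearly with radiant exposure:
    ``amplitude(E) = amplitude_vs_exposure_slope * E`` so that
    ``peak_amplitude`` is reached at the reference exposure of 1 J/cm^2.
    ``sign`` is +1 for a scattering increase and -1 for a darkening response.
    """

    onset_delay_s: float
    peak_delay_s: float
    peak_amplitude: float
    decay_tau_s: float = 2.0
    sign: int = 1
    amplitude_vs_exposure_slope: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.onset_delay_s < self.peak_delay_s):
            raise ValueError("require 0 <= onset_delay_s < peak_delay_s")
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be >= 0")
        if self.decay_tau_s <= 0:
            raise ValueError("decay_tau_s must be positive")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if self.amplitude_vs_exposure_slope is None:
            object.__setattr__(self, "amplitude_vs_exposure_slope",
                               self.peak_amplitude)

    def amplitude_at(self, exposure: float) -> float:
        """Peak amplitude at a given radiant exposure (J/cm^2), linear scaling."""
        return self.amplitude_vs_exposure_slope * exposure

    def shape(self, t: np.ndarray | float) -> np.ndarray:
        """Unit-amplitude template value at stimulus-locked time t (seconds)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        rise = (t >= self.onset_delay_s) & (t <= self.peak_delay_s)
        t_rise = self.peak_delay_s - self.onset_delay_s
        out[rise] = np.sin(0.5 * np.pi * (t[rise] - self.onset_delay_s) / t_rise)
        fall = t > self.peak_delay_s
        out[fall] = np.exp(-(t[fall] - self.peak_delay_s) / self.decay_tau_s)
        return out

    def __call__(self, t: np.ndarray | float, exposure: float = 1.0) -> np.ndarray:
        """Signed fractional change at time t for the given exposure."""
        return self.sign * self.amplitude_at(exposure) * self.shape(t)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseTemplate":
        return cls(**d)


# Default templates for the three stimulus-locked responses the generator
# programs.  fOCT: scattering increase, onset ~30 ms, peak ~528 ms, 2.5% at
# 1 J/cm^2.  OISI: darkening, onset ~40 ms, peak ~533 ms, 0.12% at 1 J/cm^2
# (the OISI latencies are the fOCT ones plus the ~10/~5 ms modality lags).
# Velocity: fractional blood-flow-velocity increase with ~1 s hemodynamic
# onset and a rapid rise to peak ~1.5 s after stimulus onset.
FOCT_TEMPLATE = ResponseTemplate(onset_delay_s=0.030, peak_delay_s=0.528,
                                 peak_amplitude=0.025, decay_tau_s=2.0, sign=+1)
OISI_TEMPLATE = ResponseTemplate(onset_delay_s=0.040, peak_delay_s=0.533,
                                 peak_amplitude=0.0012, decay_tau_s=2.0, sign=-1)
VELOCITY_TEMPLATE = ResponseTemplate(onset_delay_s=1.0, peak_delay_s=1.5,
                                     peak_amplitude=1.25, decay_tau_s=3.0, sign=+1)
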