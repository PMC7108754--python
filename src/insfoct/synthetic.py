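"""Synthetic-data generators with known ground truth.

The generators emit everything the analysis consumes: B-M-mode OCT intensity
series with multiplicative speckle, vessels and a programmed activation
region; intrinsic-signal (OISI) camera frames sharing the vessel geometry;
flow-phantom series at controlled velocities; a volumetric structural scan;
and stimulus-locked Poisson spike trains.

Speckle model: per-pixel intensity = reflectivity x an exponential(1)
speckle factor that is drawn once per trial for static tissue and, for
moving scatterers, partially refreshed every frame with mixing fraction
``min(1, v * dt / beam_width)`` — the simplest model that reproduces the
velocity dependence of inter-frame speckle decorrelation up to the
full-refresh saturation velocity.  Detector noise is additive zero-mean
Gaussian.  Pixels beneath a vessel receive the shadow ("tail") artifact:
attenuated intensity and a fraction of the vessel's speckle mixing.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .protocol import AcquisitionProtocol, ResponseTemplate
from .scene import SceneSpec, GroundTruth, default_scene
from .dataio import BScanSeries

__all__ = ["simulate_bm_series", "simulate_oisi_series",
           "simulate_flow_phantom", "simulate_spike_trains",
           "simulate_volume_scan", "oisi_vessel_image", "trial_rng"]


def trial_rng(seed: int, *keys: int) -> np.random.Generator:
    """Independent generator for (seed, key...) so trials are reproducible."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


def _mixing_fraction(velocity_mm_s, dt_s: float, beam_width_um: float):
    """Per-frame speckle refresh fraction for a scatterer velocity."""
    return np.minimum(1.0, np.asarray(velocity_mm_s) * 1000.0 * dt_s / beam_width_um)


def _speckle_trajectory(s0: np.ndarray, mixing: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """AR speckle refresh: S_t = (1-m_t) S_{t-1} + m_t E_t, E_t ~ Exp(1).

    s0: (n_px,) initial factors; mixing: (n_px, n_frames); returns
    (n_px, n_frames) with column 0 equal to s0.
    """
    n_px, n_f = mixing.shape
    out = np.empty((n_px, n_f))
    out[:, 0] = s0
    fresh = rng.exponential(1.0, size=(n_px, n_f))
    cur = s0.copy()
    for t in range(1, n_f):
        m = mixing[:, t]
        cur = (1.0 - m) * cur + m * fresh[:, t]
        out[:, t] = cur
    return out


def simulate_bm_series(protocol: AcquisitionProtocol,
                       scene: SceneSpec,
                       exposure: float = 1.0,
                       seed: int = 0,
                       fps: Optional[float] = None,
                       n_trials: Optional[int] = None):
    """Generate the B-M-mode OCT series for one condition.

    Returns ``(trials, ground_truth)`` where *trials* is a list of
    ``n_trials`` :class:`BScanSeries` of shape (n_z, n_x, n_frames).
    ``exposure`` is the radiant exposure in J/cm^2 (0 = blank condition:
    no activation and no hemodynamic response, vessels keep their baseline
    flow).  Static tissue keeps its speckle realization for the whole trial;
    vessel pixels are refreshed at a rate set by the scatterer velocity.
    """
    if fps is None:
        fps = protocol.oct_fps
    if n_trials is None:
        n_trials = protocol.n_trials
    if exposure < 0:
        raise ValueError("exposure must be >= 0")
    n_z, n_x = scene.shape
    n_f = protocol.n_frames(fps)
    t = protocol.time_axis(fps)
    dt = 1.0 / fps

    shape_t = scene.response_template.shape(t)
    amp = scene.response_template.sign * scene.response_template.amplitude_at(exposure)

    vessel_mask = scene.vessel_mask()
    tail_mask = scene.tail_mask()
    act_mask = scene.activation_region & ~vessel_mask & ~tail_mask

    # reflectivity with the tail-shadow attenuation baked in
    refl = scene.reflectivity_map.copy()
    refl[tail_mask] *= scene.tail_intensity_factor

    # per-pixel mixing source: each dynamic pixel follows one vessel
    dyn_rows, dyn_cols, dyn_scale, dyn_vel, dyn_resp = [], [], [], [], []
    claimed = np.zeros((n_z, n_x), dtype=bool)
    for v in scene.vessels:
        vm = v.mask(n_z, n_x) & ~claimed
        below = np.zeros_like(vm)
        below[1:] = np.maximum.accumulate(vm, axis=0)[:-1]
        tm = below & tail_mask & ~claimed & ~vm
        for mask, scale in ((vm, 1.0), (tm, scene.tail_mixing_factor)):
            zz, xx = np.nonzero(mask)
            dyn_rows.append(zz)
            dyn_cols.append(xx)
            dyn_scale.append(np.full(zz.size, scale))
            dyn_vel.append(np.full(zz.size, v.velocity_mm_s))
            dyn_resp.append(np.full(zz.size, v.responds, dtype=bool))
            claimed |= mask
    if dyn_rows:
        dyn_rows = np.concatenate(dyn_rows)
        dyn_cols = np.concatenate(dyn_cols)
        dyn_scale = np.concatenate(dyn_scale)
        dyn_vel = np.concatenate(dyn_vel)
        dyn_resp = np.concatenate(dyn_resp)
    else:
        dyn_rows = np.empty(0, dtype=int)

    hemo_shape = (scene.hemodynamic_template.shape(t)
                  if scene.hemodynamic_template is not None else np.zeros_like(t))
    hemo_amp = (scene.hemodynamic_template.amplitude_at(exposure)
                if scene.hemodynamic_template is not None else 0.0)

    az, ax = np.nonzero(act_mask)
    trials = []
    for tr in range(n_trials):
        rng = trial_rng(seed, tr)
        jitter = max(0.0, 1.0 + scene.amplitude_cv * rng.standard_normal())
        speckle = rng.exponential(1.0, size=(n_z, n_x))
        base = refl * speckle

        data = np.empty((n_z, n_x, n_f), dtype=np.float32)
        data[:] = base[:, :, None]
        if az.size and exposure > 0:
            data[az, ax, :] = (base[az, ax][:, None] *
                               (1.0 + amp * jitter * shape_t[None, :])
                               ).astype(np.float32)
        if dyn_rows.size:
            vel_t = dyn_vel[:, None] * (
                1.0 + (hemo_amp * jitter if exposure > 0 else 0.0) *
                dyn_resp[:, None] * hemo_shape[None, :])
            mixing = _mixing_fraction(vel_t, dt, scene.beam_width_um) * dyn_scale[:, None]
            traj = _speckle_trajectory(speckle[dyn_rows, dyn_cols], mixing, rng)
            data[dyn_rows, dyn_cols, :] = (refl[dyn_rows, dyn_cols][:, None] *
                                           traj).astype(np.float32)
        if scene.noise_floor > 0:
            data += rng.standard_normal(data.shape, dtype=np.float32) * \
                np.float32(scene.noise_floor)
            np.clip(data, 0, None, out=data)
        trials.append(BScanSeries(data=data, protocol=protocol, fps=fps,
                                  trial_index=tr, exposure=exposure,
                                  modality="oct"))
    gt = GroundTruth(activation_region=act_mask, vessels=list(scene.vessels),
                     response_template=scene.response_template,
                     oisi_template=scene.oisi_template,
                     hemodynamic_template=scene.hemodynamic_template,
                     exposure=exposure, seed=seed)
    return trials, gt


def oisi_vessel_image(scene: SceneSpec, n_y: int, n_x: int,
                      darkening: float = 0.45) -> np.ndarray:
    """Static (y, x) reflectance pattern with the scene's vessels dark.

    Vessel axes run along y with the per-vessel lateral drift, so the same
    geometry appears in the OCT volumetric scan and the camera image.
    """
    img = np.ones((n_y, n_x))
    yy = np.arange(n_y)
    xx = np.arange(n_x)
    for v in scene.vessels:
        xc = v.center_x + v.slope_px_per_y * (yy - n_y / 2.0)
        dark = np.abs(xx[None, :] - xc[:, None]) <= v.radius_px
        img[dark] *= 1.0 - darkening
    return img


def _activation_disc(scene: SceneSpec, n_y: int, n_x: int) -> np.ndarray:
    """Lateral activation footprint as a disc in the camera (y, x) plane."""
    cols = np.nonzero(scene.activation_region.any(axis=0))[0]
    if cols.size == 0:
        return np.zeros((n_y, n_x), dtype=bool)
    cx = 0.5 * (cols[0] + cols[-1])
    radius = 0.5 * (cols[-1] - cols[0])
    yy, xx = np.ogrid[:n_y, :n_x]
    return (yy - n_y / 2.0) ** 2 + (xx - cx) ** 2 <= radius ** 2


def simulate_oisi_series(protocol: AcquisitionProtocol,
                         scene: SceneSpec,
                         exposure: float = 1.0,
                         seed: int = 0,
                         fps: Optional[float] = None,
                         n_trials: Optional[int] = None,
                         n_y: Optional[int] = None,
                         base_reflectance: float = 100.0):
    """Generate the camera (OISI) frame series for one condition.

    2-D (y, x) frames at the camera frame rate; the activation disc darkens
    following the OISI template (sign -1) and the vessel pattern is shared
    with the OCT scene so coregistration is testable.
    """
    if fps is None:
        fps = protocol.oisi_fps
    if n_trials is None:
        n_trials = protocol.n_trials
    if n_y is None:
        n_y = scene.shape[1]
    if exposure < 0:
        raise ValueError("exposure must be >= 0")
    n_x = scene.shape[1]
    n_f = protocol.n_frames(fps)
    t = protocol.time_axis(fps)
    img = base_reflectance * oisi_vessel_image(scene, n_y, n_x)
    disc = _activation_disc(scene, n_y, n_x)
    dy, dx = np.nonzero(disc)
    shape_t = scene.oisi_template.shape(t)
    amp = scene.oisi_template.sign * scene.oisi_template.amplitude_at(exposure)
    sigma = scene.oisi_noise_fraction * float(img.mean())

    trials = []
    for tr in range(n_trials):
        rng = trial_rng(seed, 1000 + tr)
        jitter = max(0.0, 1.0 + scene.amplitude_cv * rng.standard_normal())
        data = np.empty((n_y, n_x, n_f), dtype=np.float32)
        data[:] = img[:, :, None]
        if dy.size and exposure > 0:
            data[dy, dx, :] = (img[dy, dx][:, None] *
                               (1.0 + amp * jitter * shape_t[None, :])
                               ).astype(np.float32)
        if sigma > 0:
            data += rng.standard_normal(data.shape, dtype=np.float32) * np.float32(sigma)
            np.clip(data, 0, None, out=data)
        trials.append(BScanSeries(data=data, protocol=protocol, fps=fps,
                                  trial_index=tr, exposure=exposure,
                                  modality="oisi"))
    gt = GroundTruth(activation_region=disc, vessels=list(scene.vessels),
                     response_template=scene.response_template,
                     oisi_template=scene.oisi_template,
                     hemodynamic_template=scene.hemodynamic_template,
                     exposure=exposure, seed=seed)
    return trials, gt


def simulate_flow_phantom(velocities: Sequence[float],
                          seed: int = 0,
                          fps: float = 240.0,
                          n_frames: int = 480,
                          frame_shape: tuple = (40, 40),
                          reflectivity: float = 100.0,
                          noise_floor: float = 1.0,
                          beam_width_um: float = 10.0) -> dict:
    """Homogeneous scattering phantom series, one per pump velocity (mm/s).

    Every pixel moves at the set velocity; v = 0 gives a static series whose
    inter-frame decorrelation is at the noise floor.  Returns a dict mapping
    velocity -> BScanSeries.
    """
    velocities = [float(v) for v in velocities]
    if any(v < 0 for v in velocities):
        raise ValueError("phantom velocities must be >= 0")
    # the phantom is never stimulated; the protocol only records timing
    trial_s = n_frames / fps
    protocol = AcquisitionProtocol(prestim_s=trial_s / 4, stim_s=trial_s / 2,
                                   poststim_s=trial_s / 4, n_trials=1,
                                   oct_fps=fps, pulse_rate_hz=2.0 / trial_s,
                                   n_z=frame_shape[0], n_x=frame_shape[1])
    n_z, n_x = frame_shape
    out = {}
    for k, v in enumerate(velocities):
        rng = trial_rng(seed, 2000 + k)
        s0 = rng.exponential(1.0, size=n_z * n_x)
        m = np.full((n_z * n_x, n_frames),
                    _mixing_fraction(v, 1.0 / fps, beam_width_um))
        traj = _speckle_trajectory(s0, m, rng)
        data = (reflectivity * traj).reshape(n_z, n_x, n_frames).astype(np.float32)
        if noise_floor > 0:
            data += rng.standard_normal(data.shape, dtype=np.float32) * \
                np.float32(noise_floor)
            np.clip(data, 0, None, out=data)
        out[v] = BScanSeries(data=data, protocol=protocol, fps=fps,
                             trial_index=k, exposure=0.0, modality="oct")
    return out


def simulate_volume_scan(protocol: AcquisitionProtocol,
                         scene: SceneSpec,
                         seed: int = 0,
                         n_y: int = 64) -> np.ndarray:
    """Static volumetric raster scan (n_z, n_x, n_y) with slanted vessel tubes.

    Vessels attenuate everything beneath them, so the depth-mean projection
    shows the same dark streaks as the camera vessel image.
    """
    rng = trial_rng(seed, 3000)
    n_z, n_x = scene.shape
    vol = np.empty((n_z, n_x, n_y))
    yy = np.arange(n_y)
    for j in range(n_y):
        refl = scene.reflectivity_map.copy()
        vm = np.zeros((n_z, n_x), dtype=bool)
        for v in scene.vessels:
            xc = v.center_x + v.slope_px_per_y * (j - n_y / 2.0)
            zz, xx = np.ogrid[:n_z, :n_x]
            vm |= (zz - v.center_z) ** 2 + (xx - xc) ** 2 <= v.radius_px ** 2
        below = np.zeros_like(vm)
        below[1:] = np.maximum.accumulate(vm, axis=0)[:-1]
        refl[below & ~vm] *= scene.tail_intensity_factor
        vol[:, :, j] = refl * rng.exponential(1.0, size=(n_z, n_x))
    if scene.noise_floor > 0:
        vol += rng.normal(0.0, scene.noise_floor, size=vol.shape)
        np.clip(vol, 0, None, out=vol)
    return vol


def simulate_spike_trains(baseline_rate_hz: float = 5.0,
                          stim_rate_hz: float = 300.0,
                          onset_latency_s: float = 0.004,
                          n_trials: int = 30,
                          protocol: Optional[AcquisitionProtocol] = None,
                          seed: int = 0) -> list:
    """Stimulus-locked inhomogeneous-Poisson spike trains.

    The rate steps from baseline to ``stim_rate_hz`` at (stimulus onset +
    ``onset_latency_s``), back to baseline at stimulus offset.  Returns a
    list of ``n_trials`` sorted timestamp arrays in stimulus-locked seconds.
    """
    if baseline_rate_hz < 0 or stim_rate_hz < 0:
        raise ValueError("rates must be >= 0")
    if protocol is None:
        protocol = AcquisitionProtocol()
    t0 = -protocol.prestim_s
    t_end = protocol.stim_s + protocol.poststim_s
    step_on = onset_latency_s
    step_off = protocol.stim_s
    segments = [(t0, step_on, baseline_rate_hz),
                (step_on, step_off, stim_rate_hz),
                (step_off, t_end, baseline_rate_hz)]
    trials = []
    for tr in range(n_trials):
        rng = trial_rng(seed, 4000 + tr)
        ts = []
        for a, b, rate in segments:
            if b <= a or rate == 0:
                continue
            n = rng.poisson(rate * (b - a))
            ts.append(rng.uniform(a, b, size=n))
        trials.append(np.sort(np.concatenate(ts)) if ts else np.empty(0))
    return trials
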