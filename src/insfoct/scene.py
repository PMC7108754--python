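"""Scene description for the synthetic cortex: reflectivity, activation, vessels.

The scene is the cross-sectional (depth z x lateral x) picture of the imaged
cortex that the generator renders: a mean-reflectivity map with depth
attenuation, a spatially confined activation region around the stimulation
locus, and a handful of vessels whose moving scatterers decorrelate the
speckle.  Vessels cast shadow ("tail") artifacts on the A-line segments
beneath them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .protocol import (AcquisitionProtocol, ResponseTemplate,
                       FOCT_TEMPLATE, OISI_TEMPLATE, VELOCITY_TEMPLATE)

__all__ = ["Vessel", "SceneSpec", "GroundTruth", "default_scene"]


@dataclass(frozen=True)
class Vessel:
    """A circular vessel cross-section at (row, column) with a flow velocity.

    ``responds`` marks the vessel as hemodynamically responsive: its
    scatterer velocity follows the scene's hemodynamic template after the
    stimulus.  ``slope_px_per_y`` tilts the vessel axis in the slow (y)
    direction and only matters for volumetric rendering.
    """

    center_z: int
    center_x: int
    radius_px: int
    velocity_mm_s: float
    responds: bool = False
    slope_px_per_y: float = 0.0

    def __post_init__(self) -> None:
        if self.velocity_mm_s < 0:
            raise ValueError("vessel velocity must be >= 0")
        if self.radius_px < 1:
            raise ValueError("vessel radius must be >= 1 px")

    def mask(self, n_z: int, n_x: int) -> np.ndarray:
        zz, xx = np.ogrid[:n_z, :n_x]
        return ((zz - self.center_z) ** 2 + (xx - self.center_x) ** 2
                <= self.radius_px ** 2)

    def to_dict(self) -> dict:
        return {"center_z": self.center_z, "center_x": self.center_x,
                "radius_px": self.radius_px, "velocity_mm_s": self.velocity_mm_s,
                "responds": self.responds, "slope_px_per_y": self.slope_px_per_y}


@dataclass
class SceneSpec:
    """Static description of the imaged sample.

    reflectivity_map : (n_z, n_x) mean backscatter intensity, arbitrary units.
    activation_region : (n_z, n_x) boolean map of pixels whose reflectivity is
        modulated by the stimulus-locked response template.
    vessels : vessels with per-vessel scatterer velocity (mm/s).
    noise_floor : additive detector-noise STD in intensity units.
    response_template / oisi_template / hemodynamic_template : stimulus-locked
        fractional-change templates for scattering, camera reflectance and
        vessel velocity respectively.
    beam_width_um : lateral resolution; sets the speckle decorrelation scale
        (a scatterer moving one beam width between frames fully refreshes the
        speckle).
    amplitude_cv : trial-to-trial multiplicative amplitude jitter (coefficient
        of variation) shared by all responses within a trial.
    """

    reflectivity_map: np.ndarray
    activation_region: np.ndarray
    vessels: list = field(default_factory=list)
    noise_floor: float = 0.0
    response_template: ResponseTemplate = FOCT_TEMPLATE
    oisi_template: ResponseTemplate = OISI_TEMPLATE
    hemodynamic_template: Optional[ResponseTemplate] = VELOCITY_TEMPLATE
    beam_width_um: float = 10.0
    amplitude_cv: float = 0.20
    tail_intensity_factor: float = 0.6
    tail_mixing_factor: float = 0.5
    oisi_noise_fraction: float = 5e-4

    def __post_init__(self) -> None:
        self.reflectivity_map = np.asarray(self.reflectivity_map, dtype=float)
        self.activation_region = np.asarray(self.activation_region, dtype=bool)
        if self.reflectivity_map.ndim != 2:
            raise ValueError("reflectivity_map must be 2-D (n_z, n_x)")
        if self.reflectivity_map.size == 0:
            raise ValueError("scene is empty")
        if np.any(self.reflectivity_map < 0):
            raise ValueError("reflectivity must be >= 0")
        if self.activation_region.shape != self.reflectivity_map.shape:
            raise ValueError("activation_region shape mismatch")
        n_z, n_x = self.reflectivity_map.shape
        for v in self.vessels:
            if not (0 <= v.center_z < n_z and 0 <= v.center_x < n_x):
                raise ValueError("vessel centre outside the frame")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")

    @property
    def shape(self) -> tuple:
        return self.reflectivity_map.shape

    def vessel_mask(self) -> np.ndarray:
        n_z, n_x = self.shape
        m = np.zeros((n_z, n_x), dtype=bool)
        for v in self.vessels:
            m |= v.mask(n_z, n_x)
        return m

    def tail_mask(self) -> np.ndarray:
        """Pixels strictly below any vessel pixel, down to the bottom of the A-line."""
        vm = self.vessel_mask()
        below = np.zeros_like(vm)
        below[1:] = np.maximum.accumulate(vm, axis=0)[:-1]
        return below & ~vm


@dataclass
class GroundTruth:
    """Programmed truth serialized alongside every generated dataset."""

    activation_region: np.ndarray
    vessels: list
    response_template: ResponseTemplate
    oisi_template: ResponseTemplate
    hemodynamic_template: Optional[ResponseTemplate]
    exposure: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "activation_pixels": [[int(z), int(x)] for z, x in
                                  zip(*np.nonzero(self.activation_region))],
            "activation_shape": list(self.activation_region.shape),
            "vessels": [v.to_dict() for v in self.vessels],
            "response_template": self.response_template.to_dict(),
            "oisi_template": self.oisi_template.to_dict(),
            "hemodynamic_template": (self.hemodynamic_template.to_dict()
                                     if self.hemodynamic_template else None),
            "exposure": self.exposure,
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        act = np.zeros(tuple(d["activation_shape"]), dtype=bool)
        for z, x in d["activation_pixels"]:
            act[z, x] = True
        hemo = d.get("hemodynamic_template")
        return cls(
            activation_region=act,
            vessels=[Vessel(**v) for v in d["vessels"]],
            response_template=ResponseTemplate.from_dict(d["response_template"]),
            oisi_template=ResponseTemplate.from_dict(d["oisi_template"]),
            hemodynamic_template=ResponseTemplate.from_dict(hemo) if hemo else None,
            exposure=d["exposure"],
            seed=d["seed"],
        )


def default_scene(protocol: AcquisitionProtocol | None = None,
                  surface_reflectivity: float = 100.0,
                  attenuation_um: float = 300.0,
                  noise_fraction: float = 0.005,
                  activation_diameter_um: float = 400.0,
                  activation_depth_um: float = 500.0) -> SceneSpec:
    """Default scene matching the emulated study conditions.

    Reflectivity decays exponentially with depth (single-scattering
    attenuation).  The activation region is the stimulation locus: a
    ~0.4-mm-wide column centred laterally and extending from the surface to
    500 um depth.  Two vessels sit outside the activation region: a
    superficial pial vessel and a deeper hemodynamically responsive vessel.
    Additive detector noise defaults to 0.5% of the mean tissue intensity,
    which keeps the 3-sigma/5-frame detector essentially free of false
    positives while letting the trial-averaged course resolve the programmed
    onset latency to within one frame at 240 fps.
    """
    if protocol is None:
        protocol = AcquisitionProtocol()
    n_z, n_x = protocol.n_z, protocol.n_x
    z_um = np.arange(n_z) * protocol.z_pitch_um
    refl = surface_reflectivity * np.exp(-z_um / attenuation_um)[:, None]
    refl = np.broadcast_to(refl, (n_z, n_x)).copy()

    cx = n_x // 2
    half_w = activation_diameter_um / 2.0 / protocol.x_pitch_um
    xx = np.arange(n_x)
    act = (np.abs(xx - cx)[None, :] <= half_w) & \
          (z_um[:, None] < activation_depth_um)

    vessels = [
        Vessel(center_z=3, center_x=6, radius_px=2, velocity_mm_s=0.8,
               responds=False, slope_px_per_y=0.3),
        Vessel(center_z=10, center_x=n_x - 7, radius_px=5, velocity_mm_s=0.5,
               responds=True, slope_px_per_y=-0.2),
    ]
    noise = noise_fraction * float(refl.mean())
    return SceneSpec(reflectivity_map=refl, activation_region=act,
                     vessels=vessels, noise_floor=noise)
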