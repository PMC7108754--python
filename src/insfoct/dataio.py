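"""Containers and on-disk formats: multi-page TIFF stacks + JSON sidecar + CSV.

A dataset directory holds one multi-page TIFF per trial per modality (pages
are frames), a single ``dataset.json`` sidecar describing the acquisition
protocol, every series file, the ground truth (for synthetic data) and the
seed, and optionally a ``spikes.csv`` with per-trial spike timestamps.
Intensities are stored linearly; log compression is a display concern only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .protocol import AcquisitionProtocol
from .scene import GroundTruth

__all__ = ["BScanSeries", "Dataset", "SidecarError", "ShapeMismatchError",
           "DataError", "save_dataset", "load_dataset", "write_results"]

SIDECAR_NAME = "dataset.json"


class SidecarError(ValueError):
    """Missing or malformed dataset sidecar."""


class ShapeMismatchError(ValueError):
    """Array shape disagrees with the sidecar metadata."""


class DataError(ValueError):
    """Invalid pixel data (NaN, negative, non-finite)."""


@dataclass
class BScanSeries:
    """One trial of a B-M-mode intensity series.

    data : (n_z, n_x, n_frames) non-negative intensity stack.  The z index 0
        is the cortical surface.  For the camera modality the first axis is
        the slow image axis (y) instead of depth.
    fps : frame rate of this series (OCT and OISI rates differ).
    exposure : radiant exposure in J/cm^2; 0 marks the blank (no stimulation)
        condition.
    modality : "oct" or "oisi".
    """

    data: np.ndarray
    protocol: AcquisitionProtocol
    fps: float
    trial_index: int = 0
    exposure: float = 1.0
    modality: str = "oct"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeMismatchError("series data must be 3-D (n_z, n_x, n_frames)")
        if self.modality not in ("oct", "oisi"):
            raise ValueError(f"unknown modality {self.modality!r}")
        n_expected = self.protocol.n_frames(self.fps)
        if self.data.shape[2] != n_expected:
            raise ShapeMismatchError(
                f"frame count {self.data.shape[2]} != round(trial_s * fps) = {n_expected}")
        if not np.all(np.isfinite(self.data)):
            raise DataError("series contains non-finite values")
        if self.data.min() < 0:
            raise DataError("series contains negative intensities")

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def time_s(self) -> np.ndarray:
        """Frame times with the stimulus onset at t = 0."""
        return self.protocol.time_axis(self.fps)

    @property
    def prestim_slice(self) -> slice:
        return slice(0, self.protocol.n_prestim_frames(self.fps))


@dataclass
class Dataset:
    """All series of one experiment plus optional spikes and ground truth."""

    protocol: AcquisitionProtocol
    series: list = field(default_factory=list)
    spike_trials: Optional[list] = None     # list of 1-D timestamp arrays
    ground_truth: Optional[GroundTruth] = None
    seed: Optional[int] = None

    def trials(self, modality: str = "oct",
               exposure: Optional[float] = None) -> list:
        out = [s for s in self.series if s.modality == modality]
        if exposure is not None:
            out = [s for s in out if np.isclose(s.exposure, exposure)]
        return sorted(out, key=lambda s: s.trial_index)

    @property
    def exposures(self) -> list:
        return sorted({float(s.exposure) for s in self.series if s.exposure > 0})


def save_dataset(dataset: Dataset, path: str | Path) -> Path:
    """Write TIFF stacks, JSON sidecar and spike CSV under *path*."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    records = []
    for s in dataset.series:
        fname = f"{s.modality}_e{s.exposure:g}_trial{s.trial_index:03d}.tif"
        # pages are frames: (n_frames, n_z, n_x)
        tifffile.imwrite(path / fname,
                         np.ascontiguousarray(np.moveaxis(s.data, 2, 0)))
        records.append({"file": fname, "modality": s.modality,
                        "trial_index": s.trial_index, "exposure": s.exposure,
                        "fps": s.fps, "shape_zxt": list(s.data.shape),
                        "dtype": str(s.data.dtype)})
    sidecar = {
        "protocol": dataset.protocol.to_dict(),
        "series": records,
        "seed": dataset.seed,
        "ground_truth": dataset.ground_truth.to_dict() if dataset.ground_truth else None,
    }
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))
    if dataset.spike_trials is not None:
        rows = [(i, float(t)) for i, ts in enumerate(dataset.spike_trials)
                for t in ts]
        pd.DataFrame(rows, columns=["trial", "timestamp_s"]).to_csv(
            path / "spikes.csv", index=False)
    return path


def load_dataset(path: str | Path) -> Dataset:
    """Load a dataset directory, validating arrays against the sidecar."""
    path = Path(path)
    sc_path = path / SIDECAR_NAME
    if not sc_path.exists():
        raise SidecarError(f"missing sidecar {sc_path}")
    try:
        sidecar = json.loads(sc_path.read_text())
    except json.JSONDecodeError as e:
        raise SidecarError(f"malformed sidecar: {e}") from e
    protocol = AcquisitionProtocol.from_dict(sidecar["protocol"])
    series = []
    for rec in sidecar["series"]:
        fpath = path / rec["file"]
        if not fpath.exists():
            raise SidecarError(f"sidecar references missing file {rec['file']}")
        data = np.moveaxis(tifffile.imread(fpath), 0, 2)
        if list(data.shape) != rec["shape_zxt"]:
            raise ShapeMismatchError(
                f"{rec['file']}: stack shape {list(data.shape)} != "
                f"sidecar {rec['shape_zxt']}")
        if np.isnan(data).any():
            raise DataError(f"{rec['file']}: NaN pixels")
        series.append(BScanSeries(data=data, protocol=protocol, fps=rec["fps"],
                                  trial_index=rec["trial_index"],
                                  exposure=rec["exposure"],
                                  modality=rec["modality"]))
    spikes = None
    if (path / "spikes.csv").exists():
        df = pd.read_csv(path / "spikes.csv")
        n = int(df["trial"].max()) + 1 if len(df) else 0
        spikes = [np.sort(df.loc[df["trial"] == i, "timestamp_s"].to_numpy())
                  for i in range(n)]
    gt = sidecar.get("ground_truth")
    return Dataset(protocol=protocol, series=series, spike_trials=spikes,
                   ground_truth=GroundTruth.from_dict(gt) if gt else None,
                   seed=sidecar.get("seed"))


def write_results(path: str | Path,
                  tables: dict | None = None,
                  maps: dict | None = None,
                  report: dict | None = None) -> Path:
    """Write result tables as CSV, maps as TIFF and the run report as JSON.

    Tables are pandas DataFrames (an empty table yields a header-only CSV);
    maps are 2-D arrays; the report records every threshold used in the run.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, df in (tables or {}).items():
        df.to_csv(path / f"{name}.csv", index=False)
    for name, arr in (maps or {}).items():
        tifffile.imwrite(path / f"{name}.tif",
                         np.asarray(arr, dtype=np.float32))
    if report is not None:
        (path / "report.json").write_text(json.dumps(report, indent=1,
                                                     default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
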