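"""End-to-end orchestration: detect -> mask -> aggregate -> latency -> dose.

`process_foct_condition` runs the full fOCT chain for one radiant-exposure
condition (baseline statistics, adaptive significance, vascular and
intensity masks, dR/R pooling); `run_pipeline` composes all conditions and
modalities of a dataset into time courses, latency and dose-response tables
and a run report that records every threshold used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import angiography, response, significance, timing, ephys as ephys_mod
from .dataio import BScanSeries, Dataset, write_results
from .significance import BaselineStats

__all__ = ["RunConfig", "FoctConditionResult", "process_foct_condition",
           "run_pipeline", "PipelineResult"]


@dataclass
class RunConfig:
    """Every analysis parameter of a run; serialized into the run report."""

    k_sigma: float = 3.0
    run_length: int = 5
    intensity_factor: float = 6.0
    noise_deep_fraction: float = 0.1
    decorr_window: tuple = (3, 3)
    vessel_threshold: float | str = "otsu"
    tail_extend: bool = True
    pooling: str = "pixel_set"
    response_window_s: tuple = (0.0, 2.0)
    depth_bin_um: float = 100.0
    n_depth_bins: int = 6
    onset_k: float = 3.0
    onset_min_run: int = 5
    power: str = "abs"
    oisi_roi_size: int = 20
    activation_window_s: tuple = (0.0, 1.0)
    psth_bin_ms: float = 1.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["decorr_window"] = list(self.decorr_window)
        d["response_window_s"] = list(self.response_window_s)
        d["activation_window_s"] = list(self.activation_window_s)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw = raw.get("run", raw)
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        for key in ("decorr_window", "response_window_s", "activation_window_s"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class FoctConditionResult:
    """All intermediates of one fOCT condition."""

    course: response.TimeCourse
    drr_stacks: list
    sig_labels: list
    baselines: list
    avascular: np.ndarray
    intensity: np.ndarray
    noise_mean: float
    noise_sigma: float
    exposure: float


def _combined_baseline(baselines: Sequence[BaselineStats]) -> BaselineStats:
    return BaselineStats(Ib=np.mean([b.Ib for b in baselines], axis=0),
                         sigma_b=np.mean([b.sigma_b for b in baselines], axis=0),
                         n_frames=baselines[0].n_frames)


def process_foct_condition(trials: Sequence[BScanSeries],
                           config: RunConfig,
                           noise_stats: Optional[tuple] = None,
                           blank_trials: Optional[Sequence[BScanSeries]] = None,
                           restrict: Optional[np.ndarray] = None
                           ) -> FoctConditionResult:
    """Full fOCT chain for the trials of one condition.

    The noise level for the intensity mask comes from ``noise_stats``
    (mean, sigma) when given, else from the deepest rows of the blank
    condition, else from the deepest rows of the condition itself.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials")
    if noise_stats is None:
        src = list(blank_trials)[0] if blank_trials else trials[0]
        noise_stats = significance.estimate_noise(src, config.noise_deep_fraction)
    noise_mean, noise_sigma = noise_stats

    baselines, sig_labels, drr_stacks = [], [], []
    avascular = None
    for s in trials:
        b = significance.compute_baseline(s)
        baselines.append(b)
        sig_labels.append(significance.detect_significant(
            s, b, config.k_sigma, config.run_length))
        stack = response.fractional_change(s, b)
        stack.drr = stack.drr.astype(np.float32)
        drr_stacks.append(stack)
        maps, _ = angiography.angiogram_series(s, config.decorr_window)
        vm = angiography.build_vascular_mask(maps, config.vessel_threshold,
                                             config.tail_extend)
        avascular = vm.avascular if avascular is None else (avascular & vm.avascular)

    imask = significance.intensity_mask(_combined_baseline(baselines),
                                        noise_mean, noise_sigma,
                                        config.intensity_factor)
    course = response.aggregate_foct(drr_stacks, sig_labels, avascular, imask,
                                     run_length=config.run_length,
                                     pooling=config.pooling,
                                     response_window_s=config.response_window_s,
                                     restrict=restrict,
                                     prestim_s=trials[0].protocol.prestim_s)
    return FoctConditionResult(course=course, drr_stacks=drr_stacks,
                               sig_labels=sig_labels, baselines=baselines,
                               avascular=avascular, intensity=imask,
                               noise_mean=noise_mean, noise_sigma=noise_sigma,
                               exposure=trials[0].exposure)


@dataclass
class PipelineResult:
    courses: dict
    latency_table: pd.DataFrame
    dose_table: pd.DataFrame
    ephys_table: pd.DataFrame
    activation_maps: dict
    report: dict


def _latency_row(tc, config, modality, exposure) -> dict:
    try:
        lat = timing.onset_delay(tc, k=config.onset_k, power=config.power,
                                 min_run=config.onset_min_run)
    except ValueError:
        # e.g. blank condition with no significant pixel at all
        lat = timing.LatencyResult(onset_s=None)
    row = {"modality": modality, "exposure": exposure,
           "onset_s": lat.onset_s if lat.detected else None,
           "detected": lat.detected,
           "threshold": lat.threshold}
    finite = np.isfinite(tc.value[tc.time_s >= 0])
    row["peak_s"] = timing.peak_delay(tc, power=config.power) if finite.any() else None
    row["peak_value"] = tc.at(row["peak_s"]) if row["peak_s"] is not None else None
    return row


def run_pipeline(dataset: Dataset, config: RunConfig,
                 out_dir: Optional[str] = None) -> PipelineResult:
    """Run every analysis stage the dataset supports and collect the tables.

    Stages: per-exposure fOCT processing (masks + pooled course), a
    depth-resolved decomposition at the highest exposure, unmasked OISI ROI
    courses, the vessel velocity-index course, latency estimation for every
    course, the dose-response fit over exposures, and the spike statistics
    when spike data are present.  Deterministic given the dataset.
    """
    courses: dict = {}
    maps: dict = {}
    latency_rows, dose_rows, ephys_rows = [], [], []
    report: dict = {"config": config.to_dict(),
                    "protocol": dataset.protocol.to_dict(),
                    "seed": dataset.seed, "stages": []}

    blank = dataset.trials("oct", 0.0)
    noise_stats = (significance.estimate_noise(blank[0], config.noise_deep_fraction)
                   if blank else None)
    exposures = dataset.exposures
    oct_results = {}
    try:
        for e in exposures:
            trials = dataset.trials("oct", e)
            if not trials:
                continue
            res = process_foct_condition(trials, config, noise_stats=noise_stats)
            oct_results[e] = res
            courses[f"foct_e{e:g}"] = res.course
            latency_rows.append(_latency_row(res.course, config, "foct", e))
            amap, count = response.activation_map(
                res.drr_stacks, res.sig_labels, config.activation_window_s,
                res.avascular, res.intensity)
            maps[f"activation_e{e:g}"] = amap
            report["stages"].append({"stage": "foct", "exposure": e,
                                     "n_significant": count,
                                     "noise_mean": res.noise_mean,
                                     "noise_sigma": res.noise_sigma})
        if blank:
            res = process_foct_condition(blank, config, noise_stats=noise_stats)
            courses["foct_blank"] = res.course
            latency_rows.append(_latency_row(res.course, config, "foct", 0.0))

        if exposures and exposures[-1] in oct_results:
            top = oct_results[exposures[-1]]
            z_pitch = dataset.protocol.z_pitch_um
            n_z = top.avascular.shape[0]
            n_bins = min(config.n_depth_bins,
                         int(n_z * z_pitch // config.depth_bin_um))
            depth = response.depth_resolved(
                top.drr_stacks, top.sig_labels, z_pitch,
                top.avascular, top.intensity,
                bin_um=config.depth_bin_um, n_bins=n_bins,
                pooling=config.pooling,
                response_window_s=config.response_window_s,
                prestim_s=dataset.protocol.prestim_s)
            for tc in depth:
                courses[f"foct_depth{tc.labels['depth_bin']}"] = tc

            # velocity index on the hemodynamically responsive vessel
            roi = None
            if dataset.ground_truth is not None:
                resp = [v for v in dataset.ground_truth.vessels if v.responds]
                if resp:
                    n_z, n_x = top.avascular.shape
                    roi = np.zeros((n_z, n_x), dtype=bool)
                    for v in resp:
                        roi |= v.mask(n_z, n_x)
            if roi is None and not top.avascular.all():
                roi = ~top.avascular
            if roi is not None and roi.any():
                vtc = angiography.velocity_index(
                    dataset.trials("oct", exposures[-1]), roi,
                    config.decorr_window)
                courses["velocity"] = vtc
                latency_rows.append(_latency_row(vtc, config, "velocity",
                                                 exposures[-1]))

        # OISI: unmasked ROI course at the activation centre
        for e in exposures:
            otr = dataset.trials("oisi", e)
            if not otr:
                continue
            shape = otr[0].data.shape[:2]
            if dataset.ground_truth is not None and \
                    dataset.ground_truth.activation_region.shape == shape:
                zz, xx = np.nonzero(dataset.ground_truth.activation_region)
                center = (int(zz.mean()), int(xx.mean())) if zz.size else \
                    (shape[0] // 2, shape[1] // 2)
            else:
                center = (shape[0] // 2, shape[1] // 2)
            roi = response.center_roi(shape, center, config.oisi_roi_size)
            tc = response.oisi_signal(otr, roi)
            courses[f"oisi_e{e:g}"] = tc
            latency_rows.append(_latency_row(tc, config, "oisi", e))

        # dose-response over fOCT peak values
        peaks = [(r["exposure"], abs(r["peak_value"])) for r in latency_rows
                 if r["modality"] == "foct" and r["exposure"] > 0
                 and r["peak_value"] is not None]
        if len({e for e, _ in peaks}) >= 2:
            fit = timing.dose_response_fit([e for e, _ in peaks],
                                           [p for _, p in peaks])
            dose_rows = [{"exposure": e, "peak_value": p} for e, p in peaks]
            report["dose_fit"] = {"slope": fit.slope, "intercept": fit.intercept,
                                  "r": fit.r}

        if dataset.spike_trials:
            sd = ephys_mod.SpikeData(trials=dataset.spike_trials)
            psth = ephys_mod.build_psth(sd, bin_ms=config.psth_bin_ms)
            tests = ephys_mod.ins_response_test(sd)
            onset = ephys_mod.spike_onset_latency(psth, k=config.onset_k)
            ephys_rows.append({
                "n_trials": sd.n_trials, "bin_ms": config.psth_bin_ms,
                "onset_s": onset,
                "t_vs_pre": tests["pre"]["t"], "p_vs_pre": tests["pre"]["p"],
                "t_vs_post": tests["post"]["t"], "p_vs_post": tests["post"]["p"]})
    except Exception as exc:                           # noqa: BLE001
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    result = PipelineResult(
        courses=courses,
        latency_table=pd.DataFrame(latency_rows),
        dose_table=pd.DataFrame(dose_rows),
        ephys_table=pd.DataFrame(ephys_rows),
        activation_maps=maps,
        report=report)

    if out_dir is not None:
        tables = {"latency": result.latency_table,
                  "dose_response": result.dose_table,
                  "ephys": result.ephys_table}
        for name, tc in courses.items():
            tables[f"course_{name}"] = pd.DataFrame(
                {"time_s": tc.time_s, "value": tc.value,
                 "n_pixels": tc.n_pixels if tc.n_pixels is not None else 0})
        write_results(out_dir, tables=tables, maps=maps, report=report)
    return result
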