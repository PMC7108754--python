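# Methods

## Signal model and analysis chain

The recorded quantity is the B-M-mode OCT intensity `I(z, x, t)`: repeated
cross-sectional B-scans at a fixed slow-axis position, depth `z` ×
lateral `x`, at 100 frames/s (spatial and dose analyses) or 240 frames/s
(temporal analysis). Trials follow a fixed stimulus-locked structure —
1 s prestimulus, 0.5 s infrared pulse train (250 µs pulses at 200 Hz,
0.3–1.0 J/cm² per pulse), 18.5 s recovery — repeated 15 times per
condition, with time `t = 0` at stimulus onset and prestimulus times
negative everywhere in the package.

Per pixel, the prestimulus frames give the baseline mean `Ib` and sample
STD `σb` (N−1 denominator). The analysis chain is:

1. **Significance.** A pixel-frame starts a positive run when
   `I > Ib + k·σb` (default `k = 3`, strict inequality) holds for
   `run_length = 5` consecutive frames; negative runs mirror this below
   `Ib − k·σb`. Labels are run-start indexed; `runs_to_coverage` dilates
   them to every frame a run spans. Exact threshold ties are not
   significant. The detector is invariant under a joint affine intensity
   rescaling and, on Gaussian baseline noise, has a per-start false-positive
   probability of order `(1.35e-3)^5` — effectively zero — which is what
   licenses interpreting any run as stimulus-driven.
2. **Angiography / avascular mask.** For each adjacent frame pair,
   `D = 1 − ρ` with `ρ = Σ(AB)/√(ΣA²·ΣB²)` summed over a 3×3 (z, x) window
   (zero-energy windows define `D = 0`; `D` is clipped to [0, 1] and is
   gain-invariant). Each pair map is binarized at a single threshold —
   Otsu's method on the temporal-mean map by default, overridable with a
   fixed value — the vessel label is propagated down each A-line (shadow
   "tail" artifact), and the final avascular mask is the AND of all
   per-frame avascular masks, so a pixel flagged in any frame stays
   excluded. The mean `D` over a vessel ROI per frame pair, trial-averaged,
   is the blood-flow velocity index; its monotone dependence on velocity is
   checked on simulated flow phantoms over 0–1.2 mm/s.
3. **Pooling.** `dR/R = (I − Ib)/Ib` (pixels with `Ib ≤ 0` are marked
   invalid and excluded rather than propagated as NaN). The pooled course
   averages `dR/R` over pixels that are significant ∧ avascular ∧
   intensity-sufficient, with negative-labeled pixels contributing
   `−dR/R` (the label's sign, not the sample's), then averages the 15
   per-trial courses. Two pooling readings are implemented:
   * `pixel_set` (default): each trial pools the fixed spatial set of
     pixels with at least one run start inside the response window
     (default 0–2 s). This yields a course defined on the full time grid —
     including the prestimulus baseline that the latency estimators
     require — and matches the reading "averaged over all the significant
     pixels and 15 repeated trials". A pixel with runs of both signs takes
     the majority sign; an exact tie drops it.
   * `per_frame`: a pixel contributes only at frames covered by a run;
     frames with no eligible pixel are NaN (flagged, never silently zero).
     This stricter reading is kept selectable because it is the literal
     per-frame form of the run criterion.
4. **Intensity mask.** `Ib > noise_mean + 6·noise_sigma`. The noise level
   is estimated from the deepest 10% of z rows (of the blank condition when
   available): `noise_mean` is the region's mean intensity and
   `noise_sigma` the frame-to-frame (temporal) STD averaged over its
   pixels. The temporal estimator is deliberate: with static speckle the
   spatial spread of any region is dominated by speckle contrast (≈ the
   local mean itself), which would inflate the 6σ threshold by orders of
   magnitude; the temporal fluctuation isolates the detector noise.
5. **Latencies.** Onset = first time ≥ 0 at which the signal power
   (|value| by default, squared selectable) exceeds prestimulus
   mean + k·STD **and stays above for 5 consecutive samples**; reported at
   the sample time of the first crossing, no sub-sample interpolation.
   The persistence requirement mirrors the 5-frame significance rule; a
   bare first-crossing rule scanned over hundreds of post-onset samples
   (240 frame pairs precede the 1-s hemodynamic onset at 240 fps) would
   falsely trigger on a single ~1%-probability noise excursion in most
   runs. Peak = earliest argmax of power at t ≥ 0. Onset ≤ peak whenever
   both are defined, and onset is non-decreasing in k.
6. **Dose–response.** OLS line (slope, intercept, Pearson r) of peak |dR/R|
   versus radiant exposure; ≥ 2 distinct exposures required.
7. **Coregistration.** Exhaustive integer-translation search (±max_shift)
   maximizing Pearson's r between the camera vessel image and the
   depth-mean OCT projection over their overlap (≥ 50% of the smaller
   image); ties resolve to the smallest |shift|. Translation-only by
   design; the mean (not max) projection preserves the vessel shadows used
   as landmarks.
8. **Electrophysiology.** Spikes are negative-going crossings of −41 mV
   (30 kHz sampling) with a 1-ms refractory window; no sorting. PSTHs use
   half-open stimulus-locked bins; the response test is a paired two-tailed
   t-test of per-trial spike counts in the 0–0.5 s window against the
   −0.5–0 s and 0.5–1.0 s windows (all-zero differences return t = 0,
   p = 1; constant non-zero differences are flagged as zero-variance).
   Spike-rate onset uses the 3×STD rule on 1-ms bins with a 2-bin
   persistence requirement (millisecond bins are sparse-count).

## Synthetic data generator

The generator emulates what the analysis consumes, not the optics: no
spectral-domain forward model, wavelength-dependent absorption or
photothermal physics.

* **Speckle.** Pixel intensity = reflectivity × exponential(1) speckle
  factor, drawn once per trial for static tissue. Moving scatterers
  partially refresh each frame: `S_t = (1−m)S_{t−1} + m·E_t` with mixing
  `m = min(1, v·Δt / beam_width)` (beam width 10 µm, the lateral
  resolution). This is the simplest model that makes inter-frame
  decorrelation increase monotonically with velocity and saturate when the
  speckle fully refreshes between frames (≈ 2.4 mm/s at 240 fps).
* **Scene.** Reflectivity decays with depth (attenuation length 300 µm over
  a 600-µm, 60×64-pixel frame at 10 µm/pixel). The activation region is a
  0.4-mm-wide column from the surface to 500 µm depth at the stimulation
  locus. Two vessels sit outside it: a superficial pial vessel (0.8 mm/s)
  and a deeper 5-px-radius vessel (0.5 mm/s) that carries the hemodynamic
  response. Pixels beneath a vessel get 0.6× intensity and 50% of the
  vessel's speckle mixing (tail artifact).
* **Response templates.** Fractional-change templates are exactly zero
  before onset, rise as a quarter sine to the peak, and recover
  exponentially (τ = 2 s; 3 s for the velocity response). Defaults: fOCT
  onset 30 ms, peak 528 ms, 2.5% at 1 J/cm²; OISI onset 40 ms, peak 533 ms,
  0.12%, sign −1 (the OISI latencies are the fOCT ones plus the ~10/~5 ms
  modality lags); velocity onset 1.0 s, peak 1.5 s. Amplitudes scale
  linearly with radiant exposure. The quarter-sine rise (non-zero slope at
  onset) is a deliberate choice: a rise with zero initial slope — e.g. a
  half-cosine — delays any threshold-crossing onset estimate by tens of
  milliseconds regardless of noise level, so the programmed onsets would be
  unrecoverable at the stated frame rates. Only onset, peak time and
  amplitude are anchored to the emulated study; the curve shape is not.
* **Noise and variability.** Additive zero-mean Gaussian detector noise,
  default 0.5% of the mean tissue reflectivity (clipped at zero intensity);
  camera noise 0.05% of mean reflectance. These defaults were fixed once,
  by requiring that the trial-averaged courses resolve the programmed
  onsets to within one frame under the default trial counts while the
  adaptive detector stays false-positive-free (its threshold scales with
  the noise, so the false-positive rate is noise-level-independent).
  Trial-to-trial variability is a multiplicative Gaussian amplitude jitter,
  CV = 20%, shared by all responses within a trial — consistent with the
  emulated trial spreads (0.52% on 2.5%). The hemodynamic velocity step
  (+125% at 1 J/cm²) was likewise chosen so the decorrelation course rises
  steeply enough for its 1-s onset to be resolved against the ROI-averaged
  decorrelation noise; it is on the high side of functional-hyperemia
  velocity changes.
* **Spike trains.** Inhomogeneous Poisson, rate stepping from 5 Hz to
  300 Hz at stimulus onset + 4 ms and back at stimulus offset, 30 trials.
* **Determinism.** Every stream derives from `SeedSequence([seed, key])`
  with fixed per-trial/per-modality keys; outputs are bit-reproducible for
  a fixed seed.

What passing recovery tests does **not** show about real data: the
generator has no motion artifacts, no bulk intensity drift, no spatially
correlated physiological noise, no multiple scattering, and its trial
variability is a single scalar per trial — so the recovery tolerances here
are optimistic relative to in-vivo recordings.

## Problem sizes and numerical choices

* Default frames are 60×64 pixels (600 µm × 640 µm at 10 µm pitch): large
  enough for a 0.4-mm activation region, two vessels with tails and six
  100-µm depth bins, small enough that the full 240-fps, 15-trial temporal
  study (72 000 frames) runs in about a minute on one CPU. The
  dose–response analysis uses shortened trials (2.5 s poststimulus,
  40×48 px) since only the response peak enters the fit, and pools peaks
  over five seeds before fitting.
* Decorrelation windows use `scipy.ndimage.uniform_filter` with edge
  replication; the window mean cancels in the correlation ratio.
* Baseline and noise STDs use the N−1 sample convention throughout.
* Degenerate inputs are errors, not silent zeros: empty ROIs, single-frame
  angiograms, single-exposure dose fits, constant images in coregistration,
  courses without a prestimulus window; frames or depth slabs with no
  eligible pixel yield NaN with a zero pixel count.
* Coverage dilation, vessel-tail propagation and per-frame mask
  intersection are implemented with separable min/max filters and
  cumulative maxima, so the pipeline is O(pixels × frames).

## Known limitations

* The avascular mask over-excludes dim deep tissue (noise-dominated
  decorrelation); those pixels are also removed by the intensity mask, so
  pooling is unaffected, but vessel-area estimates from the mask would be
  biased high.
* Onset estimates carry a small positive bias (the course must climb above
  the 3×STD threshold), bounded by about one frame for the fOCT/OISI
  defaults and ~40 ms for the velocity index, where the decorrelation noise
  is largest.
* The peak-delay estimator is an argmax over a locally flat template, so
  its Monte-Carlo spread (~±20 ms at 240 fps) is much larger than its bias.
* Coregistration is integer-pixel and translation-only.
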