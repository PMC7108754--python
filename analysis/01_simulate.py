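#!/usr/bin/env python
"""Generate a demonstration synthetic dataset and write it to disk.

Produces a scaled-down recording session (100-fps OCT, 20-fps OISI, two
radiant exposures plus a blank condition, 5 trials each, stimulus-locked
spike trains) with its ground truth, in the TIFF + JSON sidecar layout the
rest of the analysis consumes.  Stacks are binary scratch output; every
downstream script regenerates what it needs, so this dataset exists to
demonstrate and exercise the I/O layer.
"""
import sys
from pathlib import Path

from insfoct import AcquisitionProtocol, Dataset, default_scene, save_dataset
from insfoct.synthetic import (simulate_bm_series, simulate_oisi_series,
                               simulate_spike_trains)

OUT = Path(__file__).resolve().parents[1] / "scratch" / "demo_dataset"
SEED = 0


def main() -> None:
    protocol = AcquisitionProtocol(n_trials=5)
    scene = default_scene(protocol)
    series, gt = [], None
    for exposure in (0.5, 1.0):
        trials, gt = simulate_bm_series(protocol, scene, exposure=exposure,
                                        seed=SEED)
        series.extend(trials)
    oisi, _ = simulate_oisi_series(protocol, scene, exposure=1.0, seed=SEED)
    series.extend(oisi)
    blank, _ = simulate_bm_series(protocol, scene, exposure=0.0, seed=SEED)
    series.extend(blank)
    spikes = simulate_spike_trains(protocol=protocol, seed=SEED)
    ds = Dataset(protocol=protocol, series=series, spike_trials=spikes,
                 ground_truth=gt, seed=SEED)
    save_dataset(ds, OUT)
    print(f"wrote {len(series)} series ({len(spikes)} spike trials) to {OUT}")
    print(f"programmed activation: {int(gt.activation_region.sum())} pixels, "
          f"{len(gt.vessels)} vessels "
          f"({sum(v.responds for v in gt.vessels)} hemodynamically responsive)")


if __name__ == "__main__":
    sys.exit(main())
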