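#!/usr/bin/env python
"""Spatiotemporal organisation and the session summary.

Computes pairwise Pearson correlations of smoothed peri-movement
activity, pairwise ROI distances, and the bootstrapped median differences
between high-decoding-accuracy neurons and the population; then writes
the end-to-end session summary (class proportions, decoding numbers, d').
A cross-animal clustering mixed model needs multiple sessions — see
08_clustering_model.py.
"""

import importlib
import json
import warnings

sim = importlib.import_module("01_simulate")

if __name__ == "__main__":
    warnings.filterwarnings("ignore")
    out = sim.main(stages=["simulate", "preprocess", "onsets", "classify",
                           "decode", "pca", "spatial", "report"])
    spatial = json.loads((out / "spatial_summary.json").read_text())
    print(f"HDA-vs-population median pairwise r difference: "
          f"{spatial['hda_median_r_difference']:+.3f} "
          f"CI {tuple(round(x, 3) for x in spatial['hda_median_r_ci'])}")
    print(f"HDA-vs-population median pairwise distance difference: "
          f"{spatial['hda_median_distance_difference']:+.1f} um "
          f"CI {tuple(round(x, 1) for x in spatial['hda_median_distance_ci'])}")
    summary = json.loads((out / "summary.json").read_text())
    print("session summary written to", out / "summary.json")
    print(json.dumps(summary, indent=2))
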