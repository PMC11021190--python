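"""Batch-process a multiwell run with a single config.

Each sample is either a trace file or a simulation recipe; the pipeline
simulates/loads, detects peaks in every channel, matches them into particle
events and fits the diffusion model, writing per-sample tables plus a
manifest that makes the run reproducible (config snapshot, seeds, hashes,
row counts).
"""

import json
import tempfile
from pathlib import Path

from spp.pipeline import run_pipeline

config = {
    "samples": [
        {"id": f"well_{i:02d}",
         "simulate": {
             "populations": [
                 {"concentration": 0.2, "D": 4.9,
                  "brightness": {"ref": 100.0, "cargo": 100.0},
                  "label": "colabeled"}],
             "seed": 100 + i,
             "box": [1.5, 1.5, 4.5],
             "bin_time": 1e-5,
             "duration": 2.0,
             "background": {"ref": 2.0, "cargo": 2.0}}}
        for i in range(3)
    ],
    "detect": {"k": 4.0, "merge_gap_bins": 100, "min_width_bins": 10},
    "profile": {"channels": ["ref", "cargo"], "reference": "ref",
                "cargo": "cargo"},
    "fcs": {"enabled": True, "omega": 0.25, "ar": 5.0, "channel": "ref"},
}

out = run_pipeline(config, Path(tempfile.mkdtemp()) / "run")
manifest = json.loads((out / "manifest.json").read_text())
print(f"pipeline wrote {out}")
for s in manifest["samples"]:
    fit = json.loads((out / s["outputs"]["fit"]).read_text())
    print(f"  {s['id']}: {s['status']}, "
          f"{s['row_counts']['events']} events, "
          f"co-occurrence {s['cooccurrence_fraction']:.2f}, "
          f"D = {fit['D']:.1f} µm²/s")
print("identical config + seeds reproduce these numbers exactly")
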