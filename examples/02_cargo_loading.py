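"""Per-particle cargo loading of carrier nanoparticles (LNP-style assay).

A carrier dye defines the particles (reference channel); a second channel
reports the cargo.  Per particle we ask (1) does a cargo peak co-occur with
the carrier peak, and (2) how much cargo relative to carrier — the
ratiometric index (I_cargo - I_ref)/(I_cargo + I_ref), where -1 means an
empty carrier.  The bulk dye-exclusion efficiency only gives the overall
loaded percentage; the per-particle readout shows the full/empty split.
"""

import numpy as np

import spp

DET = dict(k=4.0, merge_gap_bins=100, min_width_bins=10)

# ground truth: 60% of carriers hold cargo, 40% are empty; dilute enough
# that chance coincidences of two particles in the focus are rare
cfg = spp.SimConfig(
    populations=[
        spp.Population(concentration=0.06, D=4.9,
                       brightness={"ref": 100.0, "cargo": 80.0},
                       label="loaded"),
        spp.Population(concentration=0.04, D=4.9,
                       brightness={"ref": 100.0}, label="empty"),
    ],
    seed=2, box=(1.5, 1.5, 4.5), bin_time=1e-5, duration=15.0,
    background={"ref": 2.0, "cargo": 2.0})
trace, _ = spp.simulate_trace(cfg, record_transits=False)

events = spp.match_peaks(spp.detect_peaks(trace, "ref", **DET),
                         spp.detect_peaks(trace, "cargo", **DET))
spp.annotate_events(events, cargo="cargo", ref="ref")
_, sigma = spp.estimate_baseline(trace, "ref")
ref_events = [e for e in events if e.intensities.get("ref", 0) >= 10 * sigma]

frac = sum(e.cooccurs for e in ref_events) / len(ref_events)
print(f"{len(ref_events)} carrier particles detected")
print(f"fraction with cargo signal: {frac:.2f} (ground truth 0.60)")

idx = np.array([e.ratio_index for e in ref_events if e.ratio_index is not None])
print(f"ratiometric index: {np.sum(idx == -1.0)} empty carriers at -1, "
      f"loaded mode at {np.median(idx[idx > -1]):.2f}")

# bulk comparator: free cargo before lysis vs total after lysis
print(f"bulk efficiency for c_before=25, c_after=100: "
      f"{spp.encapsulation_efficiency(25.0, 100.0):.0f}% "
      "(no information on the full/empty split)")
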