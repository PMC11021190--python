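"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from spp import Population, SimConfig, Trace

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

# Detection settings for single-particle transit analysis at 10 µs bins with
# ~100 nm particles (tau_D ~ 2 ms): the merge gap bridges shot-noise dropouts
# within one transit (~tau_D/2) and the width filter requires a sustained
# excursion, not isolated spikes.
TRANSIT_DETECT = dict(k=4.0, merge_gap_bins=100, min_width_bins=10)


def make_poisson_trace(lam: float, n_bins: int, seed: int,
                       channels=("a",), bin_time: float = 1e-5) -> Trace:
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam, size=(len(channels), n_bins))
    return Trace(list(channels), bin_time, counts, {"sample": f"poisson{seed}"})


def inject_gaussian_bursts(counts: np.ndarray, centers, amplitude: float,
                           width_bins: float) -> np.ndarray:
    """Add deterministic Gaussian-shaped bursts to a counts array."""
    out = counts.astype(np.int64).copy()
    idx = np.arange(len(out))
    for c in centers:
        out += np.round(
            amplitude * np.exp(-0.5 * ((idx - c) / width_bins) ** 2)
        ).astype(np.int64)
    return out


def brute_force_multitau(a, b, bin_time, max_lag):
    """Naive-loop reference implementation of the multi-tau estimator:
    symmetric normalization over the valid overlap, both lag directions
    averaged, counts rebinned by pairwise summation at each octave with 16
    lags in the first octave and 8 per further octave."""
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    lags, g = [], []
    level, binsize = 0, 1
    while True:
        lag_range = range(1, 17) if level == 0 else range(9, 17)
        for t in lag_range:
            lag_s = t * binsize * bin_time
            if lag_s > max_lag or len(a) - t < 32:
                return np.asarray(lags), np.asarray(g)
            m = len(a) - t
            s_al = sum(a[:m]) / m
            s_br = sum(b[t:]) / m
            s_bl = sum(b[:m]) / m
            s_ar = sum(a[t:]) / m
            fw = sum(a[i] * b[i + t] for i in range(m)) / m
            bw = sum(b[i] * a[i + t] for i in range(m)) / m
            g_fw = fw / (s_al * s_br) - 1.0
            g_bw = bw / (s_bl * s_ar) - 1.0
            lags.append(lag_s)
            g.append(0.5 * (g_fw + g_bw))
        n2 = (len(a) // 2) * 2
        a = [a[i] + a[i + 1] for i in range(0, n2, 2)]
        b = [b[i] + b[i + 1] for i in range(0, n2, 2)]
        binsize *= 2
        level += 1
        if len(a) < 64:
            return np.asarray(lags), np.asarray(g)


def colabeled_config(frac_colabeled: float, seed: int, *, duration: float = 15.0,
                     concentration: float = 0.15, brightness: float = 100.0,
                     D: float = 4.9) -> SimConfig:
    """Dilute two-channel sample: a fraction of particles carries both
    labels, the rest only the reference label."""
    pops = []
    if frac_colabeled > 0:
        pops.append(Population(concentration=concentration * frac_colabeled,
                               D=D, brightness={"ref": brightness,
                                                "cargo": brightness},
                               label="colabeled"))
    if frac_colabeled < 1:
        pops.append(Population(
            concentration=concentration * (1 - frac_colabeled), D=D,
            brightness={"ref": brightness}, label="ref_only"))
    return SimConfig(populations=pops, seed=seed, box=(1.5, 1.5, 4.5),
                     bin_time=1e-5, duration=duration,
                     background={"ref": 2.0, "cargo": 2.0})


def gp_config(pop_specs, seed: int, *, duration: float = 15.0,
              brightness: float = 200.0, D: float = 4.9) -> SimConfig:
    """Sample of membrane-dye-labelled particles; ``pop_specs`` is a list of
    (concentration, gp_true) pairs."""
    pops = [Population.from_gp(concentration=c, D=D,
                               total_brightness=brightness, gp_true=g,
                               short="s", long="l", label=f"pop{i}")
            for i, (c, g) in enumerate(pop_specs)]
    return SimConfig(populations=pops, seed=seed, box=(1.5, 1.5, 4.5),
                     bin_time=1e-5, duration=duration,
                     background={"s": 2.0, "l": 2.0})


@pytest.fixture(scope="session")
def dilute_colabeled_trace():
    """One fully colabeled 15-s trace plus its ground truth (session-scoped:
    several tests read it, none mutates it)."""
    import spp

    cfg = colabeled_config(1.0, seed=20260923)
    return spp.simulate_trace(cfg)
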