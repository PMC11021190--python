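"""Brownian-dynamics simulation of confocal fluctuation traces.

Freely diffusing point particles in a periodic box cross a 3D Gaussian
observation volume; each time bin the expected photon count per channel is
background plus the sum of per-particle brightnesses weighted by the PSF, and
the recorded count is a Poisson draw.  The simulator shares one PSF
convention with the correlation fitter: the lateral size is the full-width at
half-maximum (FWHM) ``omega`` and the axial elongation is the aspect ratio
``AR``; the 1/e^2 <-> FWHM conversion lives in a single function so the two
modules cannot drift apart by a factor of 2.

Time discretization is one Brownian step per bin (no sub-stepping), valid
when the RMS step sqrt(2 D dt) is much smaller than omega; defaults respect
this condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from spp.io import Trace

BOLTZMANN_J_PER_K = 1.380649e-23

#: defaults for the Stokes-Einstein conversion: water at 25 C
DEFAULT_TEMPERATURE_K = 298.15
DEFAULT_VISCOSITY_PA_S = 8.9e-4

FOUR_LN2 = 4.0 * math.log(2.0)

#: a ground-truth transit spans the bins where the PSF weight exceeds this
#: fraction of its maximum
TRANSIT_WEIGHT_THRESHOLD = 0.01


def fwhm_to_e2(omega: float) -> float:
    """Convert a FWHM beam size to the 1/e^2 Gaussian radius.

    ``exp(-4 ln2 x^2/omega^2) == exp(-2 x^2/w^2)`` gives w = omega/sqrt(2 ln2).
    """
    return omega / math.sqrt(2.0 * math.log(2.0))


def effective_volume(omega: float, aspect_ratio: float) -> float:
    """Effective confocal observation volume in µm^3.

    V_eff = pi^(3/2) * w_xy^2 * w_z with w the 1/e^2 radii; the fitted FCS
    amplitude 1/N corresponds to N = concentration * V_eff.
    """
    w_xy = fwhm_to_e2(omega)
    w_z = aspect_ratio * w_xy
    return math.pi ** 1.5 * w_xy**2 * w_z


def diffusion_from_radius(radius_nm: float,
                          temperature_K: float = DEFAULT_TEMPERATURE_K,
                          viscosity_Pa_s: float = DEFAULT_VISCOSITY_PA_S) -> float:
    """Stokes-Einstein: D = kB*T / (6 pi eta r), returned in µm^2/s."""
    if radius_nm <= 0 or temperature_K <= 0 or viscosity_Pa_s <= 0:
        raise ValueError("radius, temperature and viscosity must be positive")
    r_m = radius_nm * 1e-9
    d_m2_s = BOLTZMANN_J_PER_K * temperature_K / (6.0 * math.pi * viscosity_Pa_s * r_m)
    return d_m2_s * 1e12  # m^2/s -> µm^2/s


def radius_from_diffusion(D_um2_s: float,
                          temperature_K: float = DEFAULT_TEMPERATURE_K,
                          viscosity_Pa_s: float = DEFAULT_VISCOSITY_PA_S) -> float:
    """Inverse Stokes-Einstein: hydrodynamic radius in nm from D in µm^2/s."""
    if D_um2_s <= 0 or temperature_K <= 0 or viscosity_Pa_s <= 0:
        raise ValueError("diffusion, temperature and viscosity must be positive")
    d_m2_s = D_um2_s * 1e-12
    r_m = BOLTZMANN_J_PER_K * temperature_K / (6.0 * math.pi * viscosity_Pa_s * d_m2_s)
    return r_m * 1e9


@dataclass
class Population:
    """One ground-truth particle species.

    Parameters
    ----------
    concentration : float
        Particles per µm^3.
    D : float, optional
        Diffusion coefficient in µm^2/s; alternatively give ``radius_nm`` and
        it is derived via Stokes-Einstein.
    brightness : dict
        Expected counts per bin at the focus center, per channel.
    gp_true : float, optional
        Ground-truth generalized polarization of the species; when present it
        must be consistent with a two-channel brightness split
        (B_short - B_long)/(B_short + B_long) where the dict order is
        (short, long).
    """

    concentration: float
    brightness: dict[str, float]
    D: float | None = None
    radius_nm: float | None = None
    gp_true: float | None = None
    label: str = "pop"

    def __post_init__(self) -> None:
        if self.D is None:
            if self.radius_nm is None:
                raise ValueError("give either D or radius_nm")
            self.D = diffusion_from_radius(self.radius_nm)
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not any(b > 0 for b in self.brightness.values()):
            raise ValueError("at least one channel brightness must be > 0")
        if any(b < 0 for b in self.brightness.values()):
            raise ValueError("brightness must be >= 0")
        if self.gp_true is not None:
            if not -1.0 <= self.gp_true <= 1.0:
                raise ValueError("gp_true must lie in [-1, 1]")
            vals = list(self.brightness.values())
            if len(vals) != 2:
                raise ValueError("gp_true requires exactly two channels")
            implied = (vals[0] - vals[1]) / (vals[0] + vals[1])
            if abs(implied - self.gp_true) > 1e-9:
                raise ValueError(
                    f"gp_true {self.gp_true} inconsistent with brightness "
                    f"split (implied {implied:.6f})"
                )

    @classmethod
    def from_gp(cls, concentration: float, D: float, total_brightness: float,
                gp_true: float, short: str, long: str,
                label: str = "pop") -> "Population":
        """Build a two-channel population whose brightness split encodes a
        ground-truth GP value."""
        b_short = total_brightness * (1.0 + gp_true) / 2.0
        b_long = total_brightness * (1.0 - gp_true) / 2.0
        return cls(concentration=concentration, D=D,
                   brightness={short: b_short, long: b_long},
                   gp_true=gp_true, label=label)


@dataclass
class SimConfig:
    """Ground-truth description of a synthetic sample.

    ``box`` holds the half-widths (µm) of the periodic simulation volume; each
    must be at least 3x the corresponding PSF half-width (omega/2 laterally,
    AR*omega/2 axially) so edge effects are negligible.  ``seed`` is required:
    identical configs with identical seeds produce bit-identical traces.
    """

    populations: list[Population]
    seed: int
    psf_fwhm: float = 0.25          # omega, µm (default; not a calibrated value)
    aspect_ratio: float = 5.0       # AR, axial/lateral
    box: tuple[float, float, float] | None = None
    bin_time: float = 1e-5          # s
    duration: float = 15.0          # s, matches 40x15 s acquisition practice
    background: dict[str, float] = field(default_factory=dict)
    label: str = "sample"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required")
        if self.box is None:
            half = 3.0
            self.box = (half, half, half * self.aspect_ratio)
        min_lat = 3.0 * self.psf_fwhm / 2.0
        min_ax = 3.0 * self.aspect_ratio * self.psf_fwhm / 2.0
        bx, by, bz = self.box
        if bx < min_lat or by < min_lat or bz < min_ax:
            raise ValueError(
                f"box half-widths {self.box} smaller than 3x PSF half-widths "
                f"({min_lat:.3f}, {min_lat:.3f}, {min_ax:.3f})"
            )
        if self.bin_time <= 0 or self.duration <= 0:
            raise ValueError("bin_time and duration must be positive")
        if any(v < 0 for v in self.background.values()):
            raise ValueError("background must be >= 0")

    @property
    def channel_ids(self) -> list[str]:
        seen: list[str] = []
        for src in [self.background, *[p.brightness for p in self.populations]]:
            for c in src:
                if c not in seen:
                    seen.append(c)
        return seen

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.bin_time))

    @property
    def box_volume(self) -> float:
        bx, by, bz = self.box
        return 8.0 * bx * by * bz


@dataclass
class GroundTruth:
    """Everything the simulator knows that an experiment would not.

    ``transits`` has one row per particle passage through the region where the
    PSF weight exceeds :data:`TRANSIT_WEIGHT_THRESHOLD` of its maximum:
    particle id, population label, entry/exit bins (inclusive) and the maximum
    PSF weight reached, from which the expected peak height of the transit in
    channel c is ``brightness_c * max_weight``.
    """

    config: SimConfig
    n_particles: dict[str, int]
    transits: pd.DataFrame

    def expected_peak_height(self, channel: str) -> np.ndarray:
        """Expected baseline-subtracted peak height per transit in a channel."""
        bright = {p.label: p.brightness.get(channel, 0.0)
                  for p in self.config.populations}
        return (self.transits["population"].map(bright).to_numpy()
                * self.transits["max_weight"].to_numpy())


def _extract_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive [start, end] index pairs of True runs in a 1D boolean array."""
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2] - 1
    return list(zip(starts.tolist(), ends.tolist()))


def simulate_trace(config: SimConfig, chunk_bins: int = 16384,
                   record_transits: bool = True) -> tuple[Trace, GroundTruth]:
    """Simulate one multi-channel fluctuation trace.

    Particle numbers per population are Poisson draws around
    concentration x box volume (grand-canonical occupancy, so focal-volume
    number fluctuations have the correct statistics).  Positions start uniform
    in the box and advance each bin by Gaussian steps with per-axis variance
    2 D dt, wrapped periodically.  Counts are Poisson per bin per channel.
    """
    rng = np.random.default_rng(config.seed)
    channels = config.channel_ids
    n_bins = config.n_bins
    box = np.asarray(config.box)
    omega = config.psf_fwhm
    ar = config.aspect_ratio

    # per-population state
    n_per_pop = [int(rng.poisson(p.concentration * config.box_volume))
                 for p in config.populations]
    positions = [rng.uniform(-box, box, size=(n, 3)) for n in n_per_pop]
    step_sigma = [math.sqrt(2.0 * p.D * config.bin_time)
                  for p in config.populations]

    expected = np.empty((len(channels), n_bins))
    for ci, ch in enumerate(channels):
        expected[ci].fill(config.background.get(ch, 0.0))

    # open transit runs carried across chunk boundaries: per population a dict
    # particle index -> [start_bin, max_weight]
    open_runs: list[dict[int, list]] = [{} for _ in config.populations]
    transit_rows: list[tuple] = []
    inv_lat = FOUR_LN2 / omega**2
    inv_ax = FOUR_LN2 / (ar * omega) ** 2

    for lo in range(0, n_bins, chunk_bins):
        hi = min(lo + chunk_bins, n_bins)
        m = hi - lo
        for pi, pop in enumerate(config.populations):
            n = n_per_pop[pi]
            if n == 0:
                continue
            steps = rng.normal(0.0, step_sigma[pi], size=(m, n, 3))
            pos = positions[pi][np.newaxis] + np.cumsum(steps, axis=0)
            # periodic wrap into [-L, L)
            pos = (pos + box) % (2.0 * box) - box
            positions[pi] = pos[-1]
            w = np.exp(-(inv_lat * (pos[..., 0] ** 2 + pos[..., 1] ** 2)
                         + inv_ax * pos[..., 2] ** 2))  # (m, n)
            total_w = w.sum(axis=1)
            for ci, ch in enumerate(channels):
                b = pop.brightness.get(ch, 0.0)
                if b > 0:
                    expected[ci, lo:hi] += b * total_w
            if record_transits:
                above = w > TRANSIT_WEIGHT_THRESHOLD
                runs = open_runs[pi]
                # a run still open from the previous chunk that is not above
                # threshold in this chunk's first bin ended at the boundary
                for j in list(runs):
                    if not above[0, j]:
                        s0, wmax0 = runs.pop(j)
                        transit_rows.append((pi, int(j), s0, lo - 1, wmax0))
                for j in np.flatnonzero(above.any(axis=0)):
                    col = above[:, j]
                    for s, e in _extract_runs(col):
                        wmax = float(w[s:e + 1, j].max())
                        if s == 0 and j in runs:
                            runs[j][1] = max(runs[j][1], wmax)
                            if e == m - 1:
                                continue
                            s0, wmax0 = runs.pop(j)
                            transit_rows.append((pi, int(j), s0, lo + e, wmax0))
                        elif e == m - 1:
                            runs[j] = [lo + s, wmax]
                        else:
                            transit_rows.append(
                                (pi, int(j), lo + s, lo + e, wmax))
    # close runs still open at trace end
    if record_transits:
        for pi, runs in enumerate(open_runs):
            for j, (s, wmax) in runs.items():
                transit_rows.append((pi, int(j), s, n_bins - 1, wmax))

    counts = rng.poisson(expected).astype(np.int64)
    trace = Trace(channel_ids=list(channels), bin_time=config.bin_time,
                  counts=counts,
                  metadata={"sample": config.label, "seed": config.seed})

    labels = [p.label for p in config.populations]
    df = pd.DataFrame(transit_rows,
                      columns=["pop_index", "particle", "start_bin",
                               "end_bin", "max_weight"])
    df["population"] = df["pop_index"].map(dict(enumerate(labels)))
    df = df.drop(columns="pop_index").sort_values(
        ["start_bin", "population", "particle"]).reset_index(drop=True)
    truth = GroundTruth(config=config,
                        n_particles=dict(zip(labels, n_per_pop)),
                        transits=df)
    return trace, truth


def expected_mean_intensity(config: SimConfig, channel: str,
                            n_particles: dict[str, int] | None = None) -> float:
    """Closed-form long-run mean counts per bin in one channel.

    background + sum over populations of n_pop * brightness * <PSF>_box,
    where <PSF>_box = integral(PSF over box)/V_box is the mean PSF weight of
    a uniformly distributed particle (evaluated exactly with erf) and n_pop
    defaults to concentration x V_box.  Pass the realized ``n_particles``
    (from :class:`GroundTruth`) to get the expectation conditional on the
    drawn particle numbers.
    """
    from scipy.special import erf

    omega, ar = config.psf_fwhm, config.aspect_ratio
    bx, by, bz = config.box

    def axis_integral(half_width: float, fwhm: float) -> float:
        a = math.sqrt(FOUR_LN2) / fwhm
        return math.sqrt(math.pi) / a * erf(a * half_width)

    psf_int = (axis_integral(bx, omega) * axis_integral(by, omega)
               * axis_integral(bz, ar * omega))
    mean = config.background.get(channel, 0.0)
    for p in config.populations:
        n = (n_particles[p.label] if n_particles is not None
             else p.concentration * config.box_volume)
        mean += n * p.brightness.get(channel, 0.0) * psf_int / config.box_volume
    return mean
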