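"""Per-particle profiling: cross-channel matching, content and biophysics.

Peaks detected independently in two channels are matched into particle
events by bin-extent overlap: two peaks co-occur iff their inclusive
[start_bin, end_bin] extents share at least one bin.  Matching is greedy by
decreasing overlap and each peak is used at most once; unmatched peaks become
single-channel events.

Two normalized difference indices are computed per event:

* ratiometric content index (I_cargo - I_ref)/(I_cargo + I_ref) — bounded in
  [-1, 1], equal to -1 for a particle with no cargo signal (an empty carrier);
* generalized polarization GP = (I_short - I_long)/(I_short + I_long) —
  bounded in [-1, 1], inversely related to membrane fluidity; the
  short-wavelength emission window is the ordered-phase channel.

Channel roles are always passed by named parameters; there is no positional
guessing of which channel is "short".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from spp.peaks import Peak

logger = logging.getLogger("spp")


@dataclass
class ParticleEvent:
    """Peaks matched across channels, one diffusing particle."""

    event_id: int
    intensities: dict[str, float]   # counts; 0 for channels with no peak
    widths: dict[str, float]        # s; 0 for channels with no peak
    cooccurs: bool
    ratio_index: float | None = None
    gp: float | None = None
    trace_id: str = ""
    start_bin: int = -1
    end_bin: int = -1

    def __post_init__(self) -> None:
        if not any(v > 0 for v in self.intensities.values()):
            raise ValueError("event must have positive intensity in >= 1 channel")
        for v in (self.ratio_index, self.gp):
            if v is not None and not -1.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"index {v} outside [-1, 1]")


@dataclass
class GPStats:
    """Gaussian summary of a per-particle GP (or ratiometric) histogram."""

    mu: float
    sigma: float
    n_events: int
    components: list[tuple[float, float, float]] = field(default_factory=list)
    n_components_selected: int = 0


def _overlap(a: Peak, b: Peak) -> int:
    return min(a.end_bin, b.end_bin) - max(a.start_bin, b.start_bin) + 1


def match_peaks(peaks_a: list[Peak], peaks_b: list[Peak]) -> list[ParticleEvent]:
    """Match two channels' peak lists into particle events.

    Candidate pairs are every (a, b) whose extents overlap by >= 1 bin;
    pairs are accepted greedily by decreasing overlap with each peak used at
    most once.  Leftover peaks become single-channel events.  Both lists must
    come from the same trace (same bin grid).
    """
    ids_a = {p.trace_id for p in peaks_a}
    ids_b = {p.trace_id for p in peaks_b}
    if ids_a and ids_b and ids_a != ids_b:
        raise ValueError(f"peak lists from different traces: {ids_a} vs {ids_b}")

    pairs = [(_overlap(a, b), i, j)
             for i, a in enumerate(peaks_a)
             for j, b in enumerate(peaks_b)
             if _overlap(a, b) >= 1]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    used_a: set[int] = set()
    used_b: set[int] = set()
    events: list[ParticleEvent] = []
    eid = 0

    def _event(pa: Peak | None, pb: Peak | None) -> ParticleEvent:
        nonlocal eid
        chans = {}
        widths = {}
        for p in (pa, pb):
            if p is not None:
                chans[p.channel] = p.brightness
                widths[p.channel] = p.width
        present = [p for p in (pa, pb) if p is not None]
        start = min(p.start_bin for p in present)
        end = max(p.end_bin for p in present)
        ev = ParticleEvent(event_id=eid, intensities=chans, widths=widths,
                           cooccurs=(pa is not None and pb is not None),
                           trace_id=present[0].trace_id,
                           start_bin=start, end_bin=end)
        eid += 1
        return ev

    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        events.append(_event(peaks_a[i], peaks_b[j]))
    for i, p in enumerate(peaks_a):
        if i not in used_a:
            events.append(_event(p, None))
    for j, p in enumerate(peaks_b):
        if j not in used_b:
            events.append(_event(None, p))
    events.sort(key=lambda e: e.start_bin)
    for new_id, ev in enumerate(events):
        ev.event_id = new_id
    return events


def cooccurrence_fraction(events: list[ParticleEvent],
                          reference_channel: str) -> float:
    """Fraction of reference-channel particles whose peak co-occurs with a
    peak in the other channel.

    The reference channel defines the particle (e.g. the lipid dye of a
    nanoparticle carrier); events with no reference-channel peak are not
    counted.
    """
    ref = [e for e in events if e.intensities.get(reference_channel, 0.0) > 0]
    if not ref:
        raise ValueError(
            f"no events with a peak in reference channel {reference_channel!r}"
        )
    return sum(e.cooccurs for e in ref) / len(ref)


def ratiometric_index(I_cargo: float, I_ref: float) -> float:
    """Normalized cargo-vs-carrier content index in [-1, 1].

    (I_cargo - I_ref)/(I_cargo + I_ref): -1 means no cargo signal (an empty
    carrier particle), higher values mean more cargo per particle.
    """
    if I_ref <= 0:
        raise ValueError("reference intensity must be positive")
    if I_cargo < 0:
        raise ValueError("cargo intensity must be non-negative")
    return (I_cargo - I_ref) / (I_cargo + I_ref)


def gp(I_short: float, I_long: float) -> float:
    """Generalized polarization (I_short - I_long)/(I_short + I_long).

    ``I_short`` is the short-wavelength (ordered-phase) emission window,
    ``I_long`` the long-wavelength (disordered-phase) window.  Bounded in
    [-1, +1]; +1 when the long-wavelength intensity vanishes; higher GP means
    lower membrane fluidity.
    """
    if I_short < 0 or I_long < 0:
        raise ValueError("intensities must be non-negative")
    total = I_short + I_long
    if total == 0:
        raise ValueError("GP undefined for zero total intensity")
    return (I_short - I_long) / total


def annotate_events(events: list[ParticleEvent], *, cargo: str | None = None,
                    ref: str | None = None, short: str | None = None,
                    long: str | None = None) -> list[ParticleEvent]:
    """Fill ``ratio_index`` and/or ``gp`` on events in place.

    The ratiometric index is computed for events with a reference-channel
    peak (cargo intensity 0 when unmatched); events with a cargo peak but no
    reference peak are excluded from cargo analysis — the reference channel
    defines the particle — and logged.  GP is computed for events with signal
    in at least one of the two emission windows.
    """
    n_orphan = 0
    for ev in events:
        if cargo is not None and ref is not None:
            i_ref = ev.intensities.get(ref, 0.0)
            i_cargo = ev.intensities.get(cargo, 0.0)
            if i_ref > 0:
                ev.ratio_index = ratiometric_index(i_cargo, i_ref)
            elif i_cargo > 0:
                n_orphan += 1
        if short is not None and long is not None:
            i_s = ev.intensities.get(short, 0.0)
            i_l = ev.intensities.get(long, 0.0)
            if i_s + i_l > 0:
                ev.gp = gp(i_s, i_l)
    if n_orphan:
        logger.info("annotate_events: %d cargo-only events excluded from "
                    "cargo analysis (no reference-channel peak)", n_orphan)
    return events


def gp_from_trace(trace, events: list[ParticleEvent], *, short: str,
                  long: str, min_snr: float | None = None,
                  cooccurring_only: bool = True) -> list[ParticleEvent]:
    """Fill per-event GP from photons integrated over the transit.

    For each event the baseline-subtracted counts of the short- and
    long-wavelength channels are summed over the union bin extent of the
    matched peaks and GP is computed from those integrated intensities.
    Integrating over the shared extent uses every detected photon of the
    transit, so the estimate is far less noisy than a ratio of single-bin
    peak maxima and free of the extreme-value bias a per-channel maximum
    carries.

    ``min_snr`` keeps only events whose brighter channel peak exceeds that
    multiple of its channel's robust baseline sigma; ``cooccurring_only``
    drops single-channel events (whose GP would saturate at +/-1).
    """
    from spp.peaks import estimate_baseline

    c_short = trace.channel(short).astype(float)
    c_long = trace.channel(long).astype(float)
    b_short, s_short = estimate_baseline(trace, short)
    b_long, s_long = estimate_baseline(trace, long)
    for ev in events:
        if cooccurring_only and not ev.cooccurs:
            continue
        if min_snr is not None:
            snr = max(
                ev.intensities.get(short, 0.0) / s_short if s_short > 0 else 0.0,
                ev.intensities.get(long, 0.0) / s_long if s_long > 0 else 0.0)
            if snr < min_snr:
                continue
        n = ev.end_bin - ev.start_bin + 1
        a_short = c_short[ev.start_bin:ev.end_bin + 1].sum() - b_short * n
        a_long = c_long[ev.start_bin:ev.end_bin + 1].sum() - b_long * n
        if a_short + a_long <= 0:
            continue
        ev.gp = float(np.clip((a_short - a_long) / (a_short + a_long), -1.0, 1.0))
    return events


def fit_gp_histogram(gp_values, n_bins_rule: str = "freedman-diaconis") -> GPStats:
    """Single-Gaussian fit to the per-particle GP histogram.

    Values are histogrammed with Freedman-Diaconis bins clipped to [-1, 1]
    and the bin counts are fitted with a Gaussian by least squares; sigma of
    the fitted Gaussian is the sample-heterogeneity measure.  Requires >= 100
    events; a degenerate sample (all values identical) short-circuits to
    (mu=value, sigma=0).
    """
    from scipy.optimize import curve_fit

    values = np.asarray(gp_values, dtype=float)
    if values.size < 100:
        raise ValueError(f"need >= 100 events, got {values.size}")
    if np.ptp(values) == 0:
        return GPStats(mu=float(values[0]), sigma=0.0, n_events=values.size)
    if n_bins_rule != "freedman-diaconis":
        raise ValueError(f"unknown binning rule {n_bins_rule!r}")

    lo, hi = max(values.min(), -1.0), min(values.max(), 1.0)
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    width = 2.0 * iqr / values.size ** (1 / 3)
    n_bins = max(10, int(np.ceil((hi - lo) / width))) if width > 0 else 10
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, amp, mu, sigma):
        return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    p0 = [counts.max(), float(np.mean(values)), float(np.std(values))]
    mu = sigma = None
    try:
        popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=10000,
                            bounds=([0.0, -1.0, 1e-6],
                                    [np.inf, 1.0, 2.0]))
        resid = counts - gauss(centers, *popt)
        r2 = 1.0 - resid @ resid / max(np.var(counts) * counts.size, 1e-30)
        if r2 >= 0.5:
            mu, sigma = float(popt[1]), abs(float(popt[2]))
    except RuntimeError:
        pass
    if mu is None:
        # e.g. strongly bimodal histograms, where a single Gaussian is
        # ill-posed: report sample moments instead
        logger.warning("single-Gaussian histogram fit failed or fits poorly; "
                       "falling back to sample moments")
        mu, sigma = float(np.mean(values)), float(np.std(values))
    return GPStats(mu=mu, sigma=sigma, n_events=int(values.size))


def fit_gp_mixture(gp_values, max_components: int = 3,
                   random_state: int = 0) -> GPStats:
    """Gaussian mixture deconvolution of a GP histogram.

    Mixtures with 1..max_components Gaussians are fitted to the raw event
    values (not bin counts) and the component count with the lowest BIC is
    selected; components are returned sorted by mean.  Requires >= 500
    events.
    """
    from sklearn.mixture import GaussianMixture

    values = np.asarray(gp_values, dtype=float).reshape(-1, 1)
    if values.size < 500:
        raise ValueError(f"need >= 500 events, got {values.size}")

    best = None
    best_bic = np.inf
    for k in range(1, max_components + 1):
        try:
            gm = GaussianMixture(n_components=k, n_init=3,
                                 random_state=random_state).fit(values)
        except Exception as exc:  # pragma: no cover - sklearn convergence
            logger.warning("mixture with %d components failed: %s", k, exc)
            continue
        bic = gm.bic(values)
        if bic < best_bic:
            best, best_bic = gm, bic
    if best is None:
        raise RuntimeError("no mixture converged")

    order = np.argsort(best.means_.ravel())
    comps = [(float(best.weights_[i]), float(best.means_.ravel()[i]),
              float(np.sqrt(best.covariances_.ravel()[i])))
             for i in order]
    mu = sum(w * m for w, m, _ in comps)
    var = sum(w * (s**2 + (m - mu) ** 2) for w, m, s in comps)
    return GPStats(mu=float(mu), sigma=float(np.sqrt(var)),
                   n_events=int(values.size), components=comps,
                   n_components_selected=best.n_components)


def encapsulation_efficiency(c_before: float, c_after: float) -> float:
    """Bulk cargo-loading efficiency in percent.

    (c_after - c_before)/c_after x 100, where c_before and c_after are the
    free-cargo concentrations measured before and after particle lysis (the
    dye-exclusion bulk assay SPP's per-particle readout is compared against).
    """
    if c_after <= 0:
        raise ValueError("c_after must be positive")
    if c_before < 0 or c_before > c_after:
        raise ValueError("need 0 <= c_before <= c_after")
    return (c_after - c_before) / c_after * 100.0


def density_map(events: list[ParticleEvent], channel_x: str, channel_y: str,
                n_bins: int = 64):
    """2D histogram of per-event intensities, as an (x, y, count) table for
    external plotting."""
    import pandas as pd

    x = np.array([e.intensities.get(channel_x, 0.0) for e in events])
    y = np.array([e.intensities.get(channel_y, 0.0) for e in events])
    counts, xe, ye = np.histogram2d(x, y, bins=n_bins)
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    xv, yv = np.meshgrid(xc, yc, indexing="ij")
    return pd.DataFrame({"x": xv.ravel(), "y": yv.ravel(),
                         "count": counts.ravel().astype(int)})
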