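"""Fluctuation correlation analysis and 3D diffusion fitting.

The correlator follows the multi-tau scheme standard in fluorescence
correlation spectroscopy: 16 linear lags in the first octave, the counts
rebinned by 2 at each further octave with 8 new lags per octave, giving a
logarithmic lag grid at O(n log n) cost.  Normalization is symmetric — the
means entering G(tau) are computed over the valid overlap at each lag — and
cross-correlations are averaged over both lag directions so that
G_AB == G_BA holds exactly.

Correlation decays are fitted with the single-species 3D diffusion model

    G(tau) = (1/N) * (1 + tau/tau_D)^-1 * (1 + tau/(AR^2 tau_D))^-1/2

where N is the mean number of fluorescent species in the focal volume,
tau_D the diffusion time and AR the axial/lateral aspect ratio of the
observation volume.  The diffusion coefficient follows from the lateral
PSF full-width at half-maximum omega as D = omega^2 / (8 ln2 tau_D); omega
is a required calibration input, so D is only as accurate as omega^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from spp.io import Trace

logger = logging.getLogger("spp")

LAGS_FIRST_OCTAVE = 16
LAGS_PER_OCTAVE = 8
MIN_CORRELATION_BINS = 10_000
EIGHT_LN2 = 8.0 * math.log(2.0)


@dataclass
class CorrelationCurve:
    """A correlation decay G(tau)."""

    lags: np.ndarray          # s, strictly increasing
    g: np.ndarray             # dimensionless amplitude
    kind: str                 # "auto" | "cross"
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("non-finite correlation values")


@dataclass
class DiffusionFit:
    """Fitted 3D diffusion model parameters and derived quantities."""

    N: float                  # mean occupancy of the focal volume
    tau_D: float              # s
    AR: float                 # aspect ratio (fixed or fitted)
    omega: float              # µm, lateral PSF FWHM (calibration input)
    residual_rms: float
    converged: bool
    ar_fitted: bool = False

    @property
    def D(self) -> float:
        """Diffusion coefficient in µm^2/s, derived as omega^2/(8 ln2 tau_D)."""
        return diffusion_coefficient(self.tau_D, self.omega)


def diffusion_model(tau, N, tau_D, AR):
    """G(tau) = (1/N)(1 + tau/tau_D)^-1 (1 + tau/(AR^2 tau_D))^-1/2."""
    tau = np.asarray(tau, dtype=float)
    return (1.0 / N) / (1.0 + tau / tau_D) / np.sqrt(1.0 + tau / (AR**2 * tau_D))


def diffusion_coefficient(tau_D: float, omega: float) -> float:
    """D = omega^2 / (8 ln2 tau_D) in µm^2/s (omega in µm, tau_D in s)."""
    if tau_D <= 0 or omega <= 0:
        raise ValueError("tau_D and omega must be positive")
    return omega**2 / (EIGHT_LN2 * tau_D)


def _symmetric_g(a: np.ndarray, b: np.ndarray, lag: int) -> float:
    """Symmetric-normalized, direction-averaged correlation at one lag (in
    current bin units)."""
    a_l, b_r = a[:-lag], b[lag:]
    b_l, a_r = b[:-lag], a[lag:]
    m_al, m_br = a_l.mean(), b_r.mean()
    m_bl, m_ar = b_l.mean(), a_r.mean()
    if m_al == 0 or m_br == 0 or m_bl == 0 or m_ar == 0:
        raise ValueError("correlation undefined for a zero-mean segment")
    g_fw = (a_l @ b_r) / (len(a_l) * m_al * m_br) - 1.0
    g_bw = (b_l @ a_r) / (len(b_l) * m_bl * m_ar) - 1.0
    return 0.5 * (g_fw + g_bw)


def _rebin2(x: np.ndarray) -> np.ndarray:
    n = (len(x) // 2) * 2
    return x[:n].reshape(-1, 2).sum(axis=1)


def _multitau(a: np.ndarray, b: np.ndarray, bin_time: float,
              max_lag: float | None) -> tuple[np.ndarray, np.ndarray]:
    if a.mean() == 0 or b.mean() == 0:
        raise ValueError("correlation undefined for a zero-mean trace")
    lags_s: list[float] = []
    g: list[float] = []
    level = 0
    binsize = 1
    while True:
        lag_range = (range(1, LAGS_FIRST_OCTAVE + 1) if level == 0
                     else range(LAGS_PER_OCTAVE + 1, 2 * LAGS_PER_OCTAVE + 1))
        for t in lag_range:
            lag_s = t * binsize * bin_time
            if max_lag is not None and lag_s > max_lag:
                return np.asarray(lags_s), np.asarray(g)
            if len(a) - t < 2 * LAGS_FIRST_OCTAVE:
                return np.asarray(lags_s), np.asarray(g)
            lags_s.append(lag_s)
            g.append(_symmetric_g(a, b, t))
        a, b = _rebin2(a), _rebin2(b)
        binsize *= 2
        level += 1
        if len(a) < 4 * LAGS_FIRST_OCTAVE:
            return np.asarray(lags_s), np.asarray(g)


def autocorrelate(trace: Trace, channel: str, scheme: str = "multi-tau",
                  max_lag: float | None = None) -> CorrelationCurve:
    """Multi-tau autocorrelation of one channel.

    Requires >= 10^4 bins.  ``max_lag`` (s) defaults to one quarter of the
    trace duration; the schedule also stops once the rebinned series gets too
    short for a stable estimate.
    """
    if scheme != "multi-tau":
        raise ValueError(f"unknown correlator scheme {scheme!r}")
    counts = trace.channel(channel).astype(float)
    if counts.size < MIN_CORRELATION_BINS:
        raise ValueError(f"need >= {MIN_CORRELATION_BINS} bins, got {counts.size}")
    if max_lag is None:
        max_lag = trace.duration / 4.0
    lags, g = _multitau(counts, counts, trace.bin_time, max_lag)
    return CorrelationCurve(lags=lags, g=g, kind="auto", channels=(channel,))


def crosscorrelate(trace: Trace, channel_a: str, channel_b: str,
                   max_lag: float | None = None) -> CorrelationCurve:
    """Multi-tau cross-correlation of two channels (direction-averaged, so
    the result is symmetric under channel swap)."""
    a = trace.channel(channel_a).astype(float)
    b = trace.channel(channel_b).astype(float)
    if a.size < MIN_CORRELATION_BINS:
        raise ValueError(f"need >= {MIN_CORRELATION_BINS} bins, got {a.size}")
    if max_lag is None:
        max_lag = trace.duration / 4.0
    lags, g = _multitau(a, b, trace.bin_time, max_lag)
    return CorrelationCurve(lags=lags, g=g, kind="cross",
                            channels=(channel_a, channel_b))


def fit_diffusion(curve: CorrelationCurve, omega: float,
                  ar: float = 5.0, ar_mode: str = "fixed",
                  lag_window: tuple[float, float] | None = None,
                  weighting: str = "inverse-spacing") -> DiffusionFit:
    """Fit the 3D diffusion model to a correlation curve.

    Parameters
    ----------
    omega : float
        Lateral PSF FWHM in µm (calibration input; required for D).
    ar : float
        Aspect ratio; fixed by default, fitted when ``ar_mode="free"``.
        Fixing AR is standard when axial calibration is absent and the model
        is weakly sensitive to it.
    lag_window : (float, float), optional
        Lags (s) included in the fit; defaults to [2nd curve lag, max lag],
        excluding the shot-noise-dominated first lag.
    weighting : {"inverse-spacing", "uniform"}
        Residual weights; inverse lag spacing rebalances the log-spaced
        multi-tau grid so the decay region is not swamped by the dense short
        lags.
    """
    import lmfit

    lags, g = curve.lags, curve.g
    if lag_window is None:
        lag_window = (lags[1] if len(lags) > 1 else lags[0], lags[-1])
    mask = (lags >= lag_window[0]) & (lags <= lag_window[1])
    lags_f, g_f = lags[mask], g[mask]
    if len(lags_f) < 4:
        raise ValueError("too few lags in fitting window")
    if g_f[0] <= 0:
        raise ValueError("non-positive correlation amplitude at first fitted lag")

    n0 = 1.0 / g_f[0]
    below = np.nonzero(g_f <= g_f[0] / 2.0)[0]
    tau0 = lags_f[below[0]] if len(below) else lags_f[len(lags_f) // 2]

    if weighting == "inverse-spacing":
        weights = 1.0 / np.gradient(lags_f)
        weights /= weights.max()
    elif weighting == "uniform":
        weights = np.ones_like(lags_f)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    model = lmfit.Model(diffusion_model)
    params = model.make_params(N=n0, tau_D=tau0, AR=ar)
    params["N"].set(min=1e-12)
    params["tau_D"].set(min=1e-12)
    params["AR"].set(vary=(ar_mode == "free"), min=1.0)
    result = model.fit(g_f, params, tau=lags_f, weights=weights)
    converged = bool(result.success)
    if not converged:
        logger.warning("diffusion fit did not converge: %s", result.message)
    resid = result.best_fit - g_f
    return DiffusionFit(N=float(result.params["N"].value),
                        tau_D=float(result.params["tau_D"].value),
                        AR=float(result.params["AR"].value), omega=omega,
                        residual_rms=float(np.sqrt(np.mean(resid**2))),
                        converged=converged, ar_fitted=(ar_mode == "free"))


def multiparameter_table(gp_stats: dict, fits: dict):
    """Join per-sample GP statistics and diffusion fits into the (D, GP)
    feature table used for multiparametric particle-class separation.

    One row per sample: fitted D, mean GP, GP sigma, event count.  Sample
    identifiers of the two inputs must match exactly.
    """
    import pandas as pd

    missing_fit = sorted(set(gp_stats) - set(fits))
    missing_gp = sorted(set(fits) - set(gp_stats))
    if missing_fit or missing_gp:
        raise ValueError(
            f"unmatched sample identifiers: no fit for {missing_fit}, "
            f"no GP stats for {missing_gp}"
        )
    rows = [{"sample": s, "D": fits[s].D, "tau_D": fits[s].tau_D,
             "N": fits[s].N, "gp_mean": gp_stats[s].mu,
             "gp_sigma": gp_stats[s].sigma, "n_events": gp_stats[s].n_events}
            for s in sorted(gp_stats)]
    return pd.DataFrame(rows)
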