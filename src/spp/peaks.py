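"""Single-particle peak calling on fluctuation traces.

A peak is a maximal run of bins whose counts exceed a robust threshold
``baseline + k * sigma`` where the baseline is the median of the trace and
sigma is 1.4826x the median absolute deviation — both insensitive to the
peaks themselves as long as particles are dilute.  Runs separated by a small
gap are merged (a particle briefly dipping below threshold mid-transit is one
particle) and runs narrower than a minimum width are discarded as shot-noise
spikes.

Peak brightness is the maximum baseline-subtracted count within the run;
the integrated baseline-subtracted area is recorded as a secondary field.
Peak width is the FWHM of the baseline-subtracted profile with linear
sub-bin interpolation; peak centers stay on the bin grid because downstream
co-occurrence matching operates on bin extents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from spp.io import Trace

logger = logging.getLogger("spp")

MIN_BASELINE_BINS = 100


@dataclass
class Peak:
    """A detected single-particle transit event in one channel."""

    channel: str
    start_bin: int
    end_bin: int          # inclusive
    center_time: float    # s, time of the maximum count
    brightness: float     # counts, max baseline-subtracted count in the run
    area: float           # counts, integrated baseline-subtracted counts
    width: float          # s, FWHM of the baseline-subtracted profile
    baseline: float       # counts per bin
    baseline_sigma: float # counts per bin
    center_bin: int = -1
    trace_id: str = ""

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1


def estimate_baseline(trace: Trace, channel: str) -> tuple[float, float]:
    """Robust baseline level and noise of one channel.

    Returns ``(median, 1.4826 * MAD)``; requires at least 100 bins so both
    statistics are meaningful.
    """
    counts = trace.channel(channel)
    if counts.size < MIN_BASELINE_BINS:
        raise ValueError(
            f"need >= {MIN_BASELINE_BINS} bins to estimate a baseline, "
            f"got {counts.size}"
        )
    baseline = float(np.median(counts))
    sigma = 1.4826 * float(np.median(np.abs(counts - baseline)))
    return baseline, sigma


def _fwhm_bins(profile: np.ndarray) -> float:
    """FWHM of a baseline-subtracted peak profile in bins, linear sub-bin
    interpolation on both flanks; falls back to the run length when the
    profile never dips below half maximum inside the run."""
    peak_idx = int(np.argmax(profile))
    half = profile[peak_idx] / 2.0
    # left crossing
    left = 0.0
    for i in range(peak_idx, -1, -1):
        if profile[i] < half:
            frac = (half - profile[i]) / (profile[i + 1] - profile[i])
            left = i + frac
            break
    else:
        left = 0.0
    right = float(len(profile) - 1)
    for i in range(peak_idx, len(profile)):
        if profile[i] < half:
            frac = (profile[i - 1] - half) / (profile[i - 1] - profile[i])
            right = i - 1 + frac
            break
    return right - left


def detect_peaks(trace: Trace, channel: str, k: float = 4.0,
                 min_width_bins: int = 2, merge_gap_bins: int = 1) -> list[Peak]:
    """Detect single-particle peaks in one channel.

    Bins with counts above ``baseline + k * sigma`` form candidate runs; runs
    separated by at most ``merge_gap_bins`` are merged and runs shorter than
    ``min_width_bins`` are dropped.  When the robust sigma is zero (e.g. a
    mostly-empty photon trace) an absolute threshold of ``baseline + 1`` is
    used instead.  An all-zero trace yields an empty list.
    """
    counts = trace.channel(channel).astype(float)
    if not counts.any():
        return []
    baseline, sigma = estimate_baseline(trace, channel)
    threshold = baseline + (k * sigma if sigma > 0 else 1.0)

    above = counts > threshold
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2] - 1  # inclusive

    # merge runs separated by <= merge_gap_bins
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] - 1 <= merge_gap_bins:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])

    trace_id = str(trace.metadata.get("sample", trace.metadata.get("source", "")))
    peaks: list[Peak] = []
    for s, e in merged:
        # width filter counts above-threshold bins so that a few isolated
        # shot-noise spikes bridged by a wide merge gap cannot pass by extent
        if int(above[s:e + 1].sum()) < min_width_bins:
            continue
        profile = counts[s:e + 1] - baseline
        brightness = float(profile.max())
        # ties (e.g. a flat-topped pulse) resolve to the plateau middle
        top = np.flatnonzero(profile == profile.max())
        center = s + int(top[len(top) // 2])
        if brightness <= 0:
            continue
        peaks.append(Peak(
            channel=channel, start_bin=s, end_bin=e,
            center_bin=center, center_time=center * trace.bin_time,
            brightness=brightness, area=float(profile.sum()),
            width=_fwhm_bins(profile) * trace.bin_time,
            baseline=baseline, baseline_sigma=sigma, trace_id=trace_id,
        ))
    return peaks


def flag_outlier_peaks(peaks: list[Peak], brightness_mult: float = 10.0,
                       width_mult: float = 5.0) -> tuple[list[Peak], list[tuple[Peak, str]]]:
    """Partition peaks into (regular, outliers-with-reason).

    A peak is an outlier — a candidate aggregate or large impurity — when its
    brightness exceeds ``brightness_mult`` x the median brightness or its
    width exceeds ``width_mult`` x the median width.  With fewer than 10
    peaks the medians are unreliable, so everything is returned regular and a
    warning is logged.
    """
    if not peaks:
        return [], []
    if len(peaks) < 10:
        logger.warning("flag_outlier_peaks: only %d peaks, medians unreliable; "
                       "no outliers flagged", len(peaks))
        return list(peaks), []
    med_b = float(np.median([p.brightness for p in peaks]))
    med_w = float(np.median([p.width for p in peaks]))
    regular: list[Peak] = []
    outliers: list[tuple[Peak, str]] = []
    for p in peaks:
        reasons = []
        if p.brightness > brightness_mult * med_b:
            reasons.append(f"brightness > {brightness_mult:g}x median")
        if p.width > width_mult * med_w:
            reasons.append(f"width > {width_mult:g}x median")
        if reasons:
            outliers.append((p, "; ".join(reasons)))
        else:
            regular.append(p)
    return regular, outliers


def peaks_to_frame(peaks: list[Peak]):
    """Peaks as a DataFrame with a fixed, documented column order."""
    import pandas as pd

    cols = ["trace_id", "channel", "start_bin", "end_bin", "center_bin",
            "center_time", "brightness", "area", "width", "baseline",
            "baseline_sigma"]
    return pd.DataFrame([{c: getattr(p, c) for c in cols} for p in peaks],
                        columns=cols)


def peaks_from_frame(df) -> list[Peak]:
    """Inverse of :func:`peaks_to_frame`."""
    return [Peak(channel=row.channel, start_bin=int(row.start_bin),
                 end_bin=int(row.end_bin), center_bin=int(row.center_bin),
                 center_time=float(row.center_time),
                 brightness=float(row.brightness), area=float(row.area),
                 width=float(row.width), baseline=float(row.baseline),
                 baseline_sigma=float(row.baseline_sigma),
                 trace_id=str(row.trace_id))
            for row in df.itertuples(index=False)]
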