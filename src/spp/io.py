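"""Trace and result table I/O.

All traces move through one plain-text dialect: comma-separated, header row
``time,<ch1>,<ch2>,...``, time in seconds, counts as non-negative integers per
bin.  Units are fixed package-wide: seconds, counts per bin, micrometres,
µm²/s.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("spp")

#: relative jitter tolerated in the time column before bin-time inference fails
TIME_JITTER_TOL = 0.01


class TraceFormatError(ValueError):
    """Raised when a trace file cannot be parsed in the documented dialect."""


class TraceValidationError(ValueError):
    """Raised when a parsed trace violates a Trace invariant."""


@dataclass
class Trace:
    """Time-binned photon counts for one or more detection channels.

    Parameters
    ----------
    channel_ids : list of str
        Short channel labels, e.g. ``["green", "red"]``.
    bin_time : float
        Bin duration in seconds, > 0.
    counts : ndarray, shape (n_channels, n_bins)
        Non-negative integer photon counts per bin.
    metadata : dict
        Free-form sample annotations (sample id, well id, ...).
    """

    channel_ids: list[str]
    bin_time: float
    counts: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim == 1:
            self.counts = self.counts[np.newaxis, :]
        if self.counts.shape[0] != len(self.channel_ids):
            raise TraceValidationError(
                f"{self.counts.shape[0]} count rows for "
                f"{len(self.channel_ids)} channels"
            )
        if self.bin_time <= 0:
            raise TraceValidationError("bin_time must be positive")
        if np.any(self.counts < 0):
            raise TraceValidationError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def n_channels(self) -> int:
        return self.counts.shape[0]

    @property
    def duration(self) -> float:
        """Total trace length in seconds (n_bins x bin_time)."""
        return self.n_bins * self.bin_time

    @property
    def times(self) -> np.ndarray:
        """Left edge of every bin in seconds."""
        return np.arange(self.n_bins) * self.bin_time

    def channel(self, channel_id: str) -> np.ndarray:
        """Counts of one channel by label."""
        try:
            idx = self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(
                f"channel {channel_id!r} not in {self.channel_ids}"
            ) from None
        return self.counts[idx]


def read_trace(path: str | Path, dialect: str = "csv-wide",
               bin_time: float | None = None) -> Trace:
    """Read a multi-channel trace from a CSV file.

    First column is time in seconds (or a bare bin index when ``bin_time`` is
    given); remaining columns are per-channel counts.  Bin time is inferred
    from the median spacing of the time column unless supplied; spacing jitter
    beyond 1% is an error rather than silently resampled, because resampling
    would corrupt downstream correlation analysis.
    """
    if dialect != "csv-wide":
        raise ValueError(f"unknown trace dialect {dialect!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise TraceFormatError(f"{path}: need a time column plus >= 1 channel")
    if df.isna().any().any():
        raise TraceFormatError(f"{path}: ragged rows / missing values")
    times = df.iloc[:, 0].to_numpy(dtype=float)
    counts = df.iloc[:, 1:].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise TraceFormatError(f"{path}: non-numeric count values")
    if np.any(counts < 0):
        raise TraceValidationError(f"{path}: negative counts")
    if bin_time is None:
        if len(times) < 2:
            raise TraceValidationError(f"{path}: cannot infer bin time from one row")
        diffs = np.diff(times)
        bin_time = float(np.median(diffs))
        if bin_time <= 0:
            raise TraceValidationError(f"{path}: non-increasing time column")
        if np.any(np.abs(diffs - bin_time) > TIME_JITTER_TOL * bin_time):
            raise TraceValidationError(
                f"{path}: time spacing jitter exceeds {TIME_JITTER_TOL:.0%}"
            )
    return Trace(
        channel_ids=[str(c) for c in df.columns[1:]],
        bin_time=float(bin_time),
        counts=counts.T.astype(np.int64, copy=False),
        metadata={"source": str(path)},
    )


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace in the same CSV dialect ``read_trace`` accepts."""
    path = Path(path)
    df = pd.DataFrame({"time": trace.times})
    for cid, row in zip(trace.channel_ids, trace.counts):
        df[cid] = row
    df.to_csv(path, index=False)


#: fixed column order of the per-event results table
_RESULT_SCALARS = ["event_id", "trace_id", "cooccurs", "ratio_index", "gp"]


def write_results(events: Sequence, path: str | Path) -> None:
    """Write one row per particle event: intensities and widths per channel,
    co-occurrence flag, ratiometric index and GP (blank when not applicable).

    Accepts an empty list (header-only table).  Column order is stable:
    event_id, trace_id, <intensity_ch...>, <width_ch...>, cooccurs,
    ratio_index, gp.
    """
    path = Path(path)
    channels: list[str] = []
    for ev in events:
        for c in ev.intensities:
            if c not in channels:
                channels.append(c)
    cols = (["event_id", "trace_id"]
            + [f"intensity_{c}" for c in channels]
            + [f"width_{c}" for c in channels]
            + ["cooccurs", "ratio_index", "gp"])
    rows = []
    for ev in events:
        row: dict = {"event_id": ev.event_id, "trace_id": ev.trace_id,
                     "cooccurs": ev.cooccurs,
                     "ratio_index": ev.ratio_index, "gp": ev.gp}
        for c in channels:
            row[f"intensity_{c}"] = ev.intensities.get(c, 0.0)
            row[f"width_{c}"] = ev.widths.get(c, 0.0)
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results table written by :func:`write_results`."""
    return pd.read_csv(path)


def iter_batch(directory: str | Path, pattern: str = "*.csv") -> Iterator[Path]:
    """Enumerate trace files of a multiwell batch in deterministic
    (lexicographic) order."""
    yield from sorted(Path(directory).glob(pattern))


def write_run_summary(path: str | Path, parameters: Mapping,
                      seed: int | None = None) -> None:
    """JSON run summary: package version, parameters, seed."""
    from spp import __version__

    payload = {"spp_version": __version__, "seed": seed,
               "parameters": dict(parameters)}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
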