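"""Trace-to-event processing.

A droplet transiting the detection laser produces a plateau in the
fluorescence time trace, separated from its neighbours by near-zero
carrier-oil gaps. Events are found with a single fixed threshold on the
detection channel — a maximal run of consecutive samples strictly above
the threshold, at least ``min_width`` samples long — and summarised by
their duration (a proxy for droplet size) and per-channel mean
fluorescence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TraceRecord", "detect_events", "summarize_trace"]


@dataclass
class TraceRecord:
    """A sampled multi-channel fluorescence time series.

    ``samples`` is time-ordered, rows = time points, columns = channels in
    ``channel_names`` order. ``detection_channel`` names the channel used
    to find droplets.
    """

    sampling_rate: float
    channel_names: list[str]
    samples: np.ndarray
    detection_channel: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.shape[1] != len(self.channel_names):
            raise ValueError("samples column count must match channel_names")
        if not self.channel_names:
            raise ValueError("at least one channel is required")
        if not (self.sampling_rate > 0) or not math.isfinite(self.sampling_rate):
            raise ValueError("sampling_rate must be positive and finite")
        if self.detection_channel not in self.channel_names:
            raise ValueError(f"detection channel {self.detection_channel!r} not in channels")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        return self.samples[:, self.channel_names.index(name)]


def detect_events(
    trace: TraceRecord,
    threshold: float,
    min_width: int = 3,
    spike_metric: bool = False,
) -> pd.DataFrame:
    """Segment a trace into droplet events with a fixed threshold.

    An event is a maximal run of consecutive detection-channel samples
    strictly greater than ``threshold``, of length >= ``min_width``.
    Runs are half-open ``[start, end)``, 0-based, returned sorted by start.

    Parameters
    ----------
    trace
        The multi-channel time trace.
    threshold
        Fixed fluorescence cutoff separating droplets from carrier oil;
        must sit above the oil baseline.
    min_width
        Minimum run length in samples (debounce against single-sample
        noise crossings). Default 3.
    spike_metric
        When True, add a ``max_over_mean_<detection>`` column (per-event
        peak / mean on the detection channel) usable downstream to flag
        nucleus-like spike artifacts. Default off.

    Returns
    -------
    DataFrame with columns ``droplet_id``, ``start``, ``end``,
    ``duration_samples`` and one ``mean_<channel>`` per channel.
    """
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if min_width < 1:
        raise ValueError("min_width must be >= 1")

    above = trace.channel(trace.detection_channel) > threshold
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    keep = (ends - starts) >= min_width
    starts, ends = starts[keep], ends[keep]

    cols = {
        "droplet_id": np.arange(starts.size),
        "start": starts,
        "end": ends,
        "duration_samples": ends - starts,
    }
    # per-run channel means via cumulative sums (O(n) over the whole trace)
    csum = np.vstack([np.zeros(trace.samples.shape[1]), np.cumsum(trace.samples, axis=0)])
    for j, ch in enumerate(trace.channel_names):
        sums = csum[ends, j] - csum[starts, j]
        cols[f"mean_{ch}"] = sums / np.maximum(ends - starts, 1)
    events = pd.DataFrame(cols)
    if spike_metric:
        det = trace.channel(trace.detection_channel)
        maxima = np.array([det[s:e].max() for s, e in zip(starts, ends)], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            events[f"max_over_mean_{trace.detection_channel}"] = (
                maxima / events[f"mean_{trace.detection_channel}"]
            )
    return events


def summarize_trace(
    trace: TraceRecord, threshold: float, min_width: int = 3
) -> dict[str, float]:
    """Event count, event rate (Hz) and duration quantiles for one trace."""
    events = detect_events(trace, threshold, min_width)
    span_s = trace.duration_s
    durations = events["duration_samples"].to_numpy()
    q = (
        np.quantile(durations, [0.25, 0.5, 0.75])
        if durations.size
        else np.array([np.nan] * 3)
    )
    return {
        "n_events": int(len(events)),
        "event_rate_hz": len(events) / span_s,
        "duration_q25_samples": float(q[0]),
        "duration_median_samples": float(q[1]),
        "duration_q75_samples": float(q[2]),
        "duration_median_s": float(q[1]) / trace.sampling_rate if durations.size else float("nan"),
    }
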