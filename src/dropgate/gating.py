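"""Gating cascade for droplet event tables.

Mirrors the standard processing order for droplet cytometry data:
spectral compensation, a size gate on droplet duration, a stain gate
separating cell-containing droplets from empties, down-sampling for
cross-sample comparability, an amplification threshold anchored at the
empty-droplet median, and per-marker positive/negative classification.

Conventions (all deterministic):

* size gate removes ``floor(trim * n)`` events from each duration tail,
  ties broken by droplet id;
* a droplet is a cell iff its stain-channel mean is strictly greater than
  ``stain_fold`` x the median stain fluorescence of all events;
* the amplification threshold is ``amp_fold`` x the median of the empty
  population (default fold 2.8);
* medians of even-sized sets are the mean of the two central values;
* negative compensated values are kept (clipping would bias medians).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import mean_col

__all__ = [
    "CompensationMatrix",
    "GateConfig",
    "compensate",
    "estimate_compensation",
    "size_gate",
    "cell_gate",
    "downsample",
    "amplification_threshold",
    "classify_positive",
    "percent_positive",
    "quadrant_counts",
    "run_gating",
]


@dataclass
class CompensationMatrix:
    """Spillover matrix S with observed = S @ true; unit diagonal, invertible."""

    matrix: np.ndarray
    channels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.channels)
        if self.matrix.shape != (k, k):
            raise ValueError("matrix must be square with one row per channel")
        if not np.allclose(np.diag(self.matrix), 1.0):
            raise ValueError("spillover matrix must have a unit diagonal")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("spillover matrix is singular")

    @classmethod
    def identity(cls, channels: list[str]) -> "CompensationMatrix":
        return cls(np.eye(len(channels)), list(channels))


@dataclass
class GateConfig:
    """Tunable parameters of the gating cascade.

    Defaults follow the droplet-cytometry conventions the pipeline was
    built around: trim 8% of events from each duration tail, call a
    droplet a cell at 2.8-fold over the median stain fluorescence,
    down-sample to 10,000 cells, and call amplification positive at
    2.8-fold over the empty-droplet median.
    """

    size_trim_fraction: float = 0.08
    stain_channel: str = "HEX"
    stain_fold: float = 2.8
    downsample_n: int = 10_000
    amp_fold: float = 2.8
    marker_channels: list[str] = field(default_factory=lambda: ["FAM"])
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.size_trim_fraction < 0.5):
            raise ValueError("size_trim_fraction must be in [0, 0.5)")
        if self.stain_fold <= 1 or self.amp_fold <= 1:
            raise ValueError("fold thresholds must be > 1")
        if self.downsample_n < 1:
            raise ValueError("downsample_n must be >= 1")


def _channel_cols(events: pd.DataFrame) -> list[str]:
    return [c for c in events.columns if c.startswith("mean_")]


def compensate(events: pd.DataFrame, matrix: CompensationMatrix) -> pd.DataFrame:
    """Undo spectral crosstalk: replace each event's fluorescence vector
    by ``S^-1 @ observed``. Durations and ids are untouched."""
    cols = [mean_col(ch) for ch in matrix.channels]
    missing = [c for c in cols if c not in events.columns]
    if missing:
        raise ValueError(f"event table lacks channel column {missing[0]!r}")
    out = events.copy()
    observed = events[cols].to_numpy(dtype=float)
    out[cols] = np.linalg.solve(matrix.matrix, observed.T).T
    return out


def estimate_compensation(
    controls: dict[str, pd.DataFrame], channels: list[str]
) -> CompensationMatrix:
    """Estimate spillover from single-positive control populations.

    ``controls[ch]`` is an event table positive only in channel ``ch``.
    Entry (i, j) of the matrix is the median ratio of channel-i to
    channel-j signal among the j-only positives; the diagonal is 1.
    """
    k = len(channels)
    S = np.eye(k)
    for j, ch_j in enumerate(channels):
        if ch_j not in controls:
            raise ValueError(f"no single-positive control for channel {ch_j!r}")
        tbl = controls[ch_j]
        if len(tbl) == 0:
            raise ValueError(f"control for channel {ch_j!r} has no events")
        primary = tbl[mean_col(ch_j)].to_numpy(dtype=float)
        for i, ch_i in enumerate(channels):
            if i == j:
                continue
            S[i, j] = float(np.median(tbl[mean_col(ch_i)].to_numpy(dtype=float) / primary))
    return CompensationMatrix(S, list(channels))


def size_gate(events: pd.DataFrame, trim: float = 0.08) -> pd.DataFrame:
    """Drop the ``floor(trim * n)`` largest and smallest droplets by duration.

    Ties in duration are broken by droplet id so the gate is deterministic;
    surviving events keep their original order.
    """
    if len(events) == 0:
        raise ValueError("size gate requires a non-empty event table")
    if trim >= 0.5:
        raise ValueError("trim must be < 0.5")
    if trim == 0:
        return events.copy()
    n_cut = int(math.floor(trim * len(events)))
    if n_cut == 0:
        return events.copy()
    order = np.lexsort(
        (events["droplet_id"].to_numpy(), events["duration_samples"].to_numpy())
    )
    drop = np.concatenate([order[:n_cut], order[-n_cut:]])
    keep = np.setdiff1d(np.arange(len(events)), drop)
    return events.iloc[keep].copy()


def cell_gate(
    events: pd.DataFrame, config: GateConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition events into (cells, empties) by the stain channel.

    A droplet is a cell iff its stain mean is strictly above
    ``stain_fold`` x the median stain fluorescence of all events.
    """
    col = mean_col(config.stain_channel)
    if col not in events.columns:
        raise ValueError(f"stain channel column {col!r} missing")
    cutoff = config.stain_fold * float(events[col].median())
    is_cell = events[col] > cutoff
    return events[is_cell].copy(), events[~is_cell].copy()


def downsample(events: pd.DataFrame, n: int, seed: int = 0) -> pd.DataFrame:
    """Uniform sample of ``n`` events without replacement (identity if
    ``n`` >= table size); reproducible from ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n >= len(events):
        return events.copy()
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(events), size=n, replace=False))
    return events.iloc[idx].copy()


def amplification_threshold(
    empties: pd.DataFrame, channel: str, fold: float = 2.8
) -> float:
    """Positive/negative cutoff: ``fold`` x the empty-population median."""
    if len(empties) == 0:
        raise ValueError("empty-droplet population is empty")
    return fold * float(empties[mean_col(channel)].median())


def classify_positive(
    cells: pd.DataFrame, thresholds: dict[str, float]
) -> pd.DataFrame:
    """Add one boolean ``call_<marker>`` column per thresholded channel."""
    out = cells.copy()
    for ch, thr in thresholds.items():
        col = mean_col(ch)
        if col not in out.columns:
            raise ValueError(f"no fluorescence column for channel {ch!r}")
        out[f"call_{ch}"] = out[col] > thr
    return out


def percent_positive(calls: pd.DataFrame, marker: str) -> float:
    """Fraction of events called positive for ``marker`` (in [0, 1])."""
    col = f"call_{marker}"
    if col not in calls.columns:
        raise ValueError(f"no call column for marker {marker!r}")
    if len(calls) == 0:
        raise ValueError("empty event table")
    return float(calls[col].mean())


def quadrant_counts(
    calls: pd.DataFrame, marker_x: str, marker_y: str
) -> dict[str, int]:
    """Two-marker quadrant counts keyed '--', '+-', '-+', '++' (x then y)."""
    for m in (marker_x, marker_y):
        if f"call_{m}" not in calls.columns:
            raise ValueError(f"no call column for marker {m!r}")
    x = calls[f"call_{marker_x}"].to_numpy(dtype=bool)
    y = calls[f"call_{marker_y}"].to_numpy(dtype=bool)
    return {
        "--": int(np.sum(~x & ~y)),
        "+-": int(np.sum(x & ~y)),
        "-+": int(np.sum(~x & y)),
        "++": int(np.sum(x & y)),
    }


def run_gating(
    events: pd.DataFrame,
    config: GateConfig,
    compensation: CompensationMatrix | None = None,
) -> dict:
    """Run the full cascade and return a structured report.

    Order: compensate -> size gate -> cell gate -> down-sample cells ->
    amplification thresholds from the (size-gated, stain-negative) empty
    population -> classify. Thresholds are computed before down-sampling
    so they do not depend on the random subset.
    """
    report: dict = {"n_input": int(len(events))}
    if compensation is not None:
        events = compensate(events, compensation)
    sized = size_gate(events, config.size_trim_fraction)
    report["n_removed_size_gate"] = report["n_input"] - len(sized)
    cells, empties = cell_gate(sized, config)
    report["n_cells"] = int(len(cells))
    report["n_empties"] = int(len(empties))
    thresholds = {
        ch: amplification_threshold(empties, ch, config.amp_fold)
        for ch in config.marker_channels
    }
    report["thresholds"] = thresholds
    sampled = downsample(cells, config.downsample_n, config.seed)
    report["n_removed_downsample"] = int(len(cells) - len(sampled))
    calls = classify_positive(sampled, thresholds)
    report["n_analyzed"] = int(len(calls))
    report["percent_positive"] = {
        ch: percent_positive(calls, ch) for ch in config.marker_channels
    }
    if len(config.marker_channels) >= 2:
        mx, my = config.marker_channels[:2]
        report["quadrants"] = quadrant_counts(calls, mx, my)
    report["calls"] = calls
    return report
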