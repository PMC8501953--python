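"""Synthetic droplet-assay data with known ground truth.

Emulates the statistical structure of a droplet RT-LAMP cytometry run:
cells are Poisson-loaded into ~500 pL droplets (about one occupied droplet
in ten at the default loading rate), each cell's markers amplify with a
per-class probability (the assay's true positive rate), empty droplets
fire spuriously at the assay's false positive rate, and the detector reads
multi-channel fluorescence with spectral crosstalk and additive noise.

Two levels of output are provided: per-droplet event tables (what the
downstream gating consumes) and raw photodetector time traces (what the
event detector consumes), both paired with a ground-truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace import TraceRecord

__all__ = [
    "CellClass",
    "AssayModel",
    "simulate_event_table",
    "simulate_traces",
    "mean_col",
]

#: Default Poisson loading rate: P(>=1 cell) = 1 - exp(-0.105) ~ 0.0997,
#: i.e. about one in every ten droplets contains a cell.
DEFAULT_LOADING_RATE = 0.105

#: Default per-marker false positive rate for empty droplets (0.02%).
DEFAULT_FPR = 2e-4


def mean_col(channel: str) -> str:
    """Column name holding the per-droplet mean fluorescence of *channel*."""
    return f"mean_{channel}"


@dataclass(frozen=True)
class CellClass:
    """A cell population with per-marker amplification probabilities.

    ``expression`` maps marker (channel) names to the probability that the
    marker amplifies in a cell of this class — the assay TPR for a marker
    the class truly expresses, or a residual rate for one it does not.
    ``stain_level`` is the mean stain-channel fluorescence of a stained
    (live) cell, in the same arbitrary units as the channel baselines.
    """

    name: str
    expression: dict[str, float]
    stain_level: float = 1000.0

    def __post_init__(self) -> None:
        for marker, p in self.expression.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(
                    f"expression probability for {marker!r} must be in [0, 1], got {p}"
                )
        if not math.isfinite(self.stain_level) or self.stain_level <= 0:
            raise ValueError("stain_level must be positive and finite")


@dataclass
class AssayModel:
    """Generative parameters for a synthetic droplet assay.

    Parameters
    ----------
    classes, proportions
        Cell populations present and their mixture weights (must sum to 1).
    loading_rate
        Mean cells per droplet (Poisson lambda). The default 0.105 puts a
        cell in roughly one droplet out of ten.
    fpr_per_marker
        Probability that an *empty* droplet registers marker-positive
        (spurious amplification from free nucleic acids or unstained
        debris). Default 2e-4.
    stain_channel, marker_channels
        Channel layout; the stain channel reports cell presence, marker
        channels report amplification. The detection channel used by the
        trace simulator defaults to the stain channel.
    droplet_rate
        Droplets per second passing the detector (default 300 Hz).
    sampling_rate
        Detector sampling rate in Hz for trace synthesis.
    duration_mean, duration_cv
        Lognormal in-laser duration (samples): mean and coefficient of
        variation. Lognormal keeps durations positive and right-skewed.
    empty_baseline
        Mean per-channel fluorescence of an empty droplet (a.u.); also the
        plateau height that separates droplets from carrier oil (oil reads
        ~0 plus noise).
    amp_signal
        Added marker-channel fluorescence when the marker amplified.
        Default 10x the baseline so a 2.8-fold-over-median threshold
        cleanly splits the populations.
    crosstalk
        Square spillover matrix S (channels x channels, unit diagonal):
        observed = S @ true. None means no crosstalk.
    noise_sd
        Additive Gaussian noise per channel (a.u.).
    spike_rate, spike_amplitude_factor
        Probability of a nucleus-like spike artifact per droplet and its
        amplitude as a multiple of ``amp_signal``; spikes are short
        transients on the marker channels, off by default.
    seed
        RNG seed; every output is reproducible from it.
    """

    classes: list[CellClass]
    proportions: list[float]
    loading_rate: float = DEFAULT_LOADING_RATE
    fpr_per_marker: float = DEFAULT_FPR
    stain_channel: str = "HEX"
    marker_channels: list[str] = field(default_factory=lambda: ["FAM"])
    droplet_rate: float = 300.0
    sampling_rate: float = 100_000.0
    duration_mean: float = 100.0
    duration_cv: float = 0.10
    empty_baseline: float = 100.0
    amp_signal: float = 1000.0
    crosstalk: np.ndarray | None = None
    noise_sd: float = 5.0
    spike_rate: float = 0.0
    spike_amplitude_factor: float = 5.0
    seed: int = 0

    @property
    def channels(self) -> list[str]:
        return [self.stain_channel, *self.marker_channels]

    def validate(self) -> None:
        if not self.classes:
            raise ValueError("at least one cell class is required")
        if len(self.proportions) != len(self.classes):
            raise ValueError("proportions and classes must have equal length")
        props = np.asarray(self.proportions, dtype=float)
        if np.any(props < 0) or not math.isclose(props.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("proportions must be non-negative and sum to 1")
        if not (self.loading_rate > 0) or not math.isfinite(self.loading_rate):
            raise ValueError("loading_rate must be positive and finite")
        if not (0.0 <= self.fpr_per_marker <= 1.0):
            raise ValueError("fpr_per_marker must be in [0, 1]")
        if not (0.0 <= self.spike_rate <= 1.0):
            raise ValueError("spike_rate must be in [0, 1]")
        for name, v in [
            ("droplet_rate", self.droplet_rate),
            ("sampling_rate", self.sampling_rate),
            ("duration_mean", self.duration_mean),
            ("empty_baseline", self.empty_baseline),
            ("amp_signal", self.amp_signal),
        ]:
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite")
        if self.crosstalk is not None:
            S = np.asarray(self.crosstalk, dtype=float)
            k = len(self.channels)
            if S.shape != (k, k):
                raise ValueError(f"crosstalk must be {k}x{k} for channels {self.channels}")
            if not np.allclose(np.diag(S), 1.0):
                raise ValueError("crosstalk matrix must have a unit diagonal")
            if np.any(S < 0):
                raise ValueError("crosstalk entries must be non-negative")


def _draw_ground_truth(model: AssayModel, n_droplets: int, rng: np.random.Generator):
    """Sample per-droplet occupancy, class composition and marker states."""
    cell_counts = rng.poisson(model.loading_rate, size=n_droplets)
    class_idx = np.full(n_droplets, -1, dtype=int)
    markers = model.marker_channels
    states = {m: np.zeros(n_droplets, dtype=bool) for m in markers}
    stain = np.zeros(n_droplets, dtype=float)

    empty = np.flatnonzero(cell_counts == 0)
    singlet = np.flatnonzero(cell_counts == 1)
    multi = np.flatnonzero(cell_counts >= 2)

    # Empty droplets fire spuriously at the assay FPR, independently per marker.
    for m in markers:
        states[m][empty] = rng.random(empty.size) < model.fpr_per_marker

    props = np.asarray(model.proportions, dtype=float)
    expr = {
        m: np.array([c.expression.get(m, 0.0) for c in model.classes])
        for m in markers
    }
    stain_levels = np.array([c.stain_level for c in model.classes])

    # Singlets (the bulk of occupied droplets) are drawn vectorized.
    cls_s = rng.choice(len(model.classes), size=singlet.size, p=props)
    class_idx[singlet] = cls_s
    for m in markers:
        states[m][singlet] = rng.random(singlet.size) < expr[m][cls_s]
    stain[singlet] = stain_levels[cls_s]

    # Doublets and beyond: each cell draws a class; the droplet's marker
    # state is the OR of its cells' states, its stain the sum of stains.
    for i in multi:
        k = cell_counts[i]
        cls = rng.choice(len(model.classes), size=k, p=props)
        class_idx[i] = cls[0]  # recorded class = first cell's class
        for m in markers:
            states[m][i] = bool(np.any(rng.random(k) < expr[m][cls]))
        stain[i] = float(stain_levels[cls].sum())

    spikes = rng.random(n_droplets) < model.spike_rate

    gt = pd.DataFrame(
        {
            "droplet_id": np.arange(n_droplets),
            "cell_count": cell_counts,
            "cell_class": [
                model.classes[c].name if c >= 0 else "" for c in class_idx
            ],
            "spike": spikes,
            **{f"true_{m}": states[m] for m in markers},
        }
    )
    return gt, stain


def _true_fluorescence(model: AssayModel, gt: pd.DataFrame, stain: np.ndarray) -> np.ndarray:
    """Noise-free per-droplet channel vector before crosstalk, rows = droplets."""
    n = len(gt)
    channels = model.channels
    F = np.full((n, len(channels)), model.empty_baseline, dtype=float)
    F[:, 0] += stain
    for j, m in enumerate(model.marker_channels, start=1):
        F[:, j] += model.amp_signal * gt[f"true_{m}"].to_numpy()
    return F


def simulate_event_table(
    model: AssayModel, n_droplets: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a per-droplet event table plus its ground truth.

    Returns ``(events, ground_truth)``. The event table carries
    ``droplet_id``, ``duration_samples`` and one ``mean_<channel>`` column
    per channel; observed fluorescence is baseline + amplification signal,
    mixed through the spillover matrix, plus Gaussian noise. A spike
    artifact (when enabled) adds a transient whose contribution to the
    droplet mean is ``spike_amplitude_factor * amp_signal / 10`` (the
    transient occupies ~10% of the droplet).
    """
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    model.validate()
    rng = np.random.default_rng(model.seed)

    gt, stain = _draw_ground_truth(model, n_droplets, rng)
    F = _true_fluorescence(model, gt, stain)

    if model.spike_rate > 0:
        spike_mean = model.spike_amplitude_factor * model.amp_signal * 0.1
        F[gt["spike"].to_numpy(), 1:] += spike_mean

    if model.crosstalk is not None:
        F = F @ np.asarray(model.crosstalk, dtype=float).T
    if model.noise_sd > 0:
        F = F + rng.normal(0.0, model.noise_sd, size=F.shape)

    mu = math.log(model.duration_mean / math.sqrt(1.0 + model.duration_cv**2))
    sigma = math.sqrt(math.log(1.0 + model.duration_cv**2))
    durations = np.maximum(3, np.round(rng.lognormal(mu, sigma, n_droplets))).astype(int)

    events = pd.DataFrame({"droplet_id": np.arange(n_droplets), "duration_samples": durations})
    for j, ch in enumerate(model.channels):
        events[mean_col(ch)] = F[:, j]
    return events, gt


def simulate_traces(
    model: AssayModel, n_droplets: int
) -> tuple[TraceRecord, pd.DataFrame]:
    """Synthesize a raw multi-channel detector trace plus ground truth.

    Droplet plateaus (per-channel heights equal to the event-table values
    before noise) are separated by near-zero oil gaps; per-sample Gaussian
    noise is added everywhere. Spike artifacts appear as short
    high-amplitude transients inside their droplet. Ground truth gains
    ``start``/``end`` sample columns marking each plateau.
    """
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    model.validate()
    samples_per_period = model.sampling_rate / model.droplet_rate
    if model.duration_mean < 3 or model.duration_mean > samples_per_period:
        raise ValueError(
            "duration/rate combination leaves < 3 samples per droplet or no oil gap"
        )
    rng = np.random.default_rng(model.seed)

    gt, stain = _draw_ground_truth(model, n_droplets, rng)
    F = _true_fluorescence(model, gt, stain)
    if model.crosstalk is not None:
        F = F @ np.asarray(model.crosstalk, dtype=float).T

    mu = math.log(model.duration_mean / math.sqrt(1.0 + model.duration_cv**2))
    sigma = math.sqrt(math.log(1.0 + model.duration_cv**2))
    durations = np.maximum(3, np.round(rng.lognormal(mu, sigma, n_droplets))).astype(int)
    gap_mean = max(3.0, samples_per_period - model.duration_mean)
    gaps = np.maximum(3, np.round(rng.lognormal(
        math.log(gap_mean / math.sqrt(1.01)), math.sqrt(math.log(1.01)), n_droplets + 1
    ))).astype(int)

    total = int(gaps.sum() + durations.sum())
    k = len(model.channels)
    X = np.zeros((total, k), dtype=float)
    starts = np.zeros(n_droplets, dtype=int)
    ends = np.zeros(n_droplets, dtype=int)
    pos = int(gaps[0])
    spike_flags = gt["spike"].to_numpy()
    for i in range(n_droplets):
        d = int(durations[i])
        starts[i], ends[i] = pos, pos + d
        X[pos : pos + d, :] = F[i]
        if spike_flags[i]:
            w = max(1, d // 10)
            s0 = pos + (d - w) // 2
            X[s0 : s0 + w, 1:] += model.spike_amplitude_factor * model.amp_signal
        pos += d + int(gaps[i + 1])

    if model.noise_sd > 0:
        X = X + rng.normal(0.0, model.noise_sd, size=X.shape)

    gt = gt.copy()
    gt["start"] = starts
    gt["end"] = ends
    trace = TraceRecord(
        sampling_rate=model.sampling_rate,
        channel_names=model.channels,
        samples=X,
        detection_channel=model.stain_channel,
    )
    return trace, gt
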