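"""Spike-level processing: detection, trial firing rates, F1/F0 class.

Converts voltage traces or per-trial spike-time tables into the quantities
the tuning analysis consumes: raw and spontaneous-subtracted firing rates
per trial, and the modulation ratio (first Fourier harmonic over mean) that
separates simple from complex cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StimulusProtocol:
    """Drifting-grating protocol: 24 motion directions, 4-6 repeats each.

    ``prestim_duration_s`` is the mean-luminance epoch preceding every
    stimulus, from which spontaneous activity is measured.
    """

    directions_deg: tuple[float, ...] = tuple(float(d) for d in range(0, 360, 15))
    n_reps: int = 5
    stim_duration_s: float = 3.0
    prestim_duration_s: float = 1.0
    temporal_freq_hz: float = 2.0

    def __post_init__(self) -> None:
        dirs = self.directions_deg
        if len(set(dirs)) != len(dirs):
            raise ValueError("stimulus directions must be unique")
        if any(d < 0 or d >= 360 for d in dirs):
            raise ValueError("directions must lie in [0, 360)")
        if tuple(sorted(dirs)) != dirs:
            raise ValueError("directions must be sorted")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.stim_duration_s <= 0 or self.prestim_duration_s <= 0:
            raise ValueError("durations must be positive")
        if self.temporal_freq_hz <= 0:
            raise ValueError("temporal frequency must be positive")


@dataclass(frozen=True)
class VoltageTrace:
    """A single-channel extracellular voltage trace."""

    samples: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times within one epoch of one trial."""

    times_s: np.ndarray
    epoch: str  # "prestim" | "stim"
    duration_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] >= self.duration_s):
            raise ValueError("spike times must be strictly increasing in [0, duration)")

    @property
    def rate(self) -> float:
        return len(self.times_s) / self.duration_s


@dataclass
class Trial:
    """One direction x repetition: stimulus and pre-stimulus spike trains."""

    direction_deg: float
    rep: int
    stim: SpikeTrain
    prestim: SpikeTrain


@dataclass
class TrialSet:
    """All trials recorded from one neuron under one protocol."""

    neuron_id: str
    protocol: StimulusProtocol
    trials: list[Trial] = field(default_factory=list)

    def by_direction(self, direction_deg: float) -> list[Trial]:
        return [t for t in self.trials if t.direction_deg == direction_deg]


@dataclass(frozen=True)
class TrialResponse:
    direction_deg: float
    rep: int
    raw_rate: float
    prestim_rate: float

    @property
    def evoked_rate(self) -> float:
        """Spontaneous-subtracted rate; may be negative and is kept so."""
        return self.raw_rate - self.prestim_rate


@dataclass
class ModulationResult:
    f1: float
    f0: float
    ratio: float  # nan when f0 <= 0
    cell_class: str | None  # "simple" | "complex" | None when undefined


def detect_spikes(
    trace: VoltageTrace, threshold_k: float = 4.0, refractory_ms: float = 1.0
) -> SpikeTrain:
    """Threshold-crossing spike detection on a voltage trace.

    An event is an upward crossing of mean + ``threshold_k`` * SD; its time
    is the crossing sample.  Events closer than ``refractory_ms`` to the
    previously kept event are collapsed onto it.
    """
    if threshold_k <= 0:
        raise ValueError("threshold_k must be positive")
    x = np.asarray(trace.samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty voltage trace")
    sd = float(np.std(x))
    if sd == 0.0:
        logger.warning("flat voltage trace (SD=0): no spikes detected")
        return SpikeTrain(np.empty(0), "stim", trace.duration_s)
    thr = float(np.mean(x)) + threshold_k * sd
    above = x >= thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    times = crossings / trace.rate_hz
    refractory_s = refractory_ms / 1000.0
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= refractory_s:
            kept.append(float(t))
    return SpikeTrain(np.asarray(kept), "stim", trace.duration_s)


def trial_rates(trial_set: TrialSet) -> list[TrialResponse]:
    """Per-trial raw, pre-stimulus and evoked (subtracted) firing rates."""
    out = []
    for tr in trial_set.trials:
        if tr.stim is None or tr.prestim is None:
            raise ValueError(
                f"trial (dir={tr.direction_deg}, rep={tr.rep}) lacks a paired epoch"
            )
        out.append(
            TrialResponse(
                direction_deg=tr.direction_deg,
                rep=tr.rep,
                raw_rate=tr.stim.rate,
                prestim_rate=tr.prestim.rate,
            )
        )
    return out


def modulation_ratio(
    stim_trains: list[SpikeTrain],
    temporal_freq_hz: float,
    prestim_rate: float,
    n_bins: int = 32,
    subtract_spontaneous: bool = True,
) -> ModulationResult:
    """F1/F0 modulation ratio from a cycle histogram at the drift frequency.

    Spikes from all repeats at the preferred direction are folded at the
    stimulus temporal period into ``n_bins`` bins; the final partial cycle
    of each repeat is discarded.  F0 is the mean rate of the histogram with
    spontaneous activity subtracted (toggle via ``subtract_spontaneous``);
    F1 is the amplitude of the first Fourier harmonic.  Cells with ratio
    strictly greater than 1 are simple; a ratio of exactly 1 is complex.
    Undefined when F0 <= 0 (flagged with ``cell_class=None``).
    """
    if temporal_freq_hz <= 0:
        raise ValueError("temporal frequency must be positive")
    if not stim_trains:
        raise ValueError("no stimulus spike trains supplied")
    period = 1.0 / temporal_freq_hz
    counts = np.zeros(n_bins)
    total_time = 0.0
    for train in stim_trains:
        n_cycles = math.floor(train.duration_s / period)
        if n_cycles < 1:
            raise ValueError("stimulus shorter than one temporal cycle")
        t = np.asarray(train.times_s, dtype=float)
        t = t[t < n_cycles * period]
        phase = np.mod(t, period) / period  # in [0, 1)
        idx = np.minimum((phase * n_bins).astype(int), n_bins - 1)
        np.add.at(counts, idx, 1)
        total_time += n_cycles * period
    bin_rates = counts / (total_time / n_bins)
    f0 = float(np.mean(bin_rates))
    if subtract_spontaneous:
        f0 -= prestim_rate
    k = np.arange(n_bins)
    harmonic = np.sum(bin_rates * np.exp(-2j * np.pi * (k + 0.5) / n_bins))
    f1 = float(2.0 * np.abs(harmonic) / n_bins)
    if f0 <= 0:
        return ModulationResult(f1=f1, f0=f0, ratio=float("nan"), cell_class=None)
    ratio = f1 / f0
    return ModulationResult(
        f1=f1, f0=f0, ratio=ratio, cell_class="simple" if ratio > 1.0 else "complex"
    )
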