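"""Phase-locking, rate, and ITD-coding statistics.

Vector strength (VS) is the resultant length of per-spike phase angles
relative to the stimulus waveform,

    VS = sqrt((sum cos th)^2 + (sum sin th)^2) / n,

and the *relative* VS divides by the spike count N of a matched control
condition instead of n, so it jointly penalizes desynchronization and spike
loss (relative_vs = vs * n / N, an exact identity).

Phases are measured against the waveform at a reference ear: th = 2 pi
(t - t1)/(t2 - t1) with t1, t2 the waveform peaks bracketing the spike.
ITD coding is summarized by the left-minus-right MSO rate curve over the
ITD grid (delta R), its peak-to-trough amplitude, and the best ITD
(argmax, ties broken toward 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .periphery import SpikeTrainSet
from .stimulus import SoundStimulus


class UndefinedMetricError(ValueError):
    """Raised when a statistic is undefined (e.g. VS of zero spikes)."""


def spike_phases(
    spikes_ms, stim: SoundStimulus, ear_offset_ms: float = 0.0
) -> np.ndarray:
    """Per-spike phase angles in [0, 2 pi) relative to the waveform peaks.

    The waveform at the reference ear is sin(2 pi f (t - offset)); its peaks
    sit at phase pi/2, so th = (2 pi f (t - offset)/1000 - pi/2) mod 2 pi.
    Spikes outside [0, duration] are excluded with a warning.
    """
    t = np.asarray(spikes_ms, dtype=float)
    inside = (t >= 0.0) & (t <= stim.duration_ms)
    if not np.all(inside):
        warnings.warn(
            f"{int((~inside).sum())} spike(s) outside the stimulus window excluded",
            stacklevel=2,
        )
        t = t[inside]
    phase = 2.0 * np.pi * stim.frequency_hz * (t - ear_offset_ms) / 1000.0 - np.pi / 2.0
    return np.mod(phase, 2.0 * np.pi)


def vector_strength(phases: np.ndarray) -> float:
    """Resultant length of the phase sample; undefined for n = 0."""
    phases = np.asarray(phases, dtype=float)
    n = len(phases)
    if n == 0:
        raise UndefinedMetricError("vector strength undefined for zero spikes")
    return float(np.hypot(np.cos(phases).sum(), np.sin(phases).sum()) / n)


def relative_vector_strength(phases: np.ndarray, n_control: int) -> float:
    """Resultant length divided by the control spike count N."""
    if n_control < 1:
        raise UndefinedMetricError("control spike count must be >= 1")
    phases = np.asarray(phases, dtype=float)
    if len(phases) == 0:
        return 0.0
    return float(np.hypot(np.cos(phases).sum(), np.sin(phases).sum()) / n_control)


def mean_phase_angle(phases: np.ndarray) -> float:
    """Circular mean atan2(sum sin, sum cos) mapped to [0, 2 pi)."""
    phases = np.asarray(phases, dtype=float)
    if len(phases) == 0:
        raise UndefinedMetricError("mean phase undefined for zero spikes")
    s, c = np.sin(phases).sum(), np.cos(phases).sum()
    if np.hypot(c, s) < 1e-12 * max(len(phases), 1):
        raise UndefinedMetricError("mean phase undefined: zero resultant")
    return float(np.mod(np.arctan2(s, c), 2.0 * np.pi))


def population_rate(spikes: SpikeTrainSet, window_ms: tuple) -> float:
    """Mean per-cell firing rate (spikes/s) within a time window."""
    t0, t1 = window_ms
    if not t1 > t0:
        raise ValueError("empty rate window")
    if spikes.n_cells == 0:
        return 0.0
    total = sum(int(np.count_nonzero((np.asarray(t) >= t0) & (np.asarray(t) < t1)))
                for t in spikes.trains)
    return total / (spikes.n_cells * (t1 - t0) / 1000.0)


def spike_probability(n_spikes: int, n_inputs: int) -> float:
    """Output spikes per synaptic input event (resonance-probe statistic)."""
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    p = n_spikes / n_inputs
    if p > 1.0:
        warnings.warn(f"spike probability {p:.3f} exceeds 1", stacklevel=2)
    return p


@dataclass
class DeltaRCurve:
    """Left/right MSO rates over the ITD grid and their difference."""

    itd_grid_ms: np.ndarray
    left_rate: np.ndarray
    right_rate: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.itd_grid_ms)
        if not (len(self.left_rate) == len(self.right_rate) == n):
            raise ValueError("ITD grid and rate curves have mismatched lengths")

    @property
    def delta_r(self) -> np.ndarray:
        return np.asarray(self.left_rate) - np.asarray(self.right_rate)

    @property
    def amplitude(self) -> float:
        d = self.delta_r
        return float(d.max() - d.min())

    @property
    def best_itd_ms(self) -> float:
        """ITD maximizing delta R; ties broken toward the smallest |ITD|."""
        d = self.delta_r
        best = d.max()
        candidates = np.asarray(self.itd_grid_ms)[d >= best - 1e-12]
        return float(candidates[np.argmin(np.abs(candidates))])


def delta_r(left_rates, right_rates, itd_grid_ms) -> DeltaRCurve:
    left = np.asarray(left_rates, dtype=float)
    right = np.asarray(right_rates, dtype=float)
    grid = np.asarray(itd_grid_ms, dtype=float)
    if len(left) != len(grid) or len(right) != len(grid):
        raise ValueError("rate curves do not align with the ITD grid")
    return DeltaRCurve(itd_grid_ms=grid, left_rate=left, right_rate=right)
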