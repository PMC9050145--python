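"""Scripted experiment protocols over the SOC circuit.

Each protocol mirrors one of the study designs this simulator supports:
neuropathy sweeps of rate / phase-locking per population, the SGN-jitter
control, ITD tuning curves and their left-right difference, the single-cell
resonance map, frequency x level sweeps of ITD sensitivity, and the paired
with/without-inhibition comparison.  All protocols are deterministic given
their seed; "relative" measures are always taken against the same
experiment's 0% condition with matched seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import (
    DeltaRCurve,
    delta_r,
    population_rate,
    relative_vector_strength,
    spike_phases,
    spike_probability,
    vector_strength,
)
from .network import (
    SIDES,
    POPULATIONS,
    CircuitConfig,
    CircuitResult,
    disable_inhibition_variant,
    run_circuit,
)
from .neurons import MSO_PARAMS, MSOCellParams, run_mso_population
from .periphery import NeuropathyConfig, jitter_spike_trains
from .stimulus import SoundStimulus, ear_arrival_offsets

DEFAULT_ITD_GRID_MS = np.round(np.arange(-1.0, 1.0001, 0.1), 10)
SWEEP_FREQUENCIES_HZ = (200, 400, 600, 800, 1000, 1200)
SWEEP_LEVELS_DB = (50.0, 65.0, 80.0)


@dataclass(frozen=True)
class SweepSpec:
    """Axes of a neuropathy sweep experiment."""

    kind: str  # myelinopathy | HT | random
    levels_pct: tuple = (0.0, 50.0, 100.0)
    stimulus: SoundStimulus = field(
        default_factory=lambda: SoundStimulus(200.0, 50.0, 100.0, 0.0)
    )
    config: CircuitConfig = field(default_factory=CircuitConfig)
    seed: int = 0

    def neuropathy(self, level: float) -> NeuropathyConfig:
        if self.kind == "myelinopathy":
            return NeuropathyConfig(myelinopathy_pct=level)
        return NeuropathyConfig(synaptopathy_kind=self.kind, synaptopathy_pct=level)


def _phase_reference_offset(population: str, side: str, stim: SoundStimulus) -> float:
    """Reference-ear offset for phase measurement.

    Monaural populations are scored against their own ear's waveform; MSO
    cells against the contralateral ear (their dominant excitatory drive).
    """
    off_l, off_r = ear_arrival_offsets(stim.itd_ms)
    ear = side
    if population == "MSO":
        ear = "right" if side == "left" else "left"
    return off_l if ear == "left" else off_r


def condition_summary(result: CircuitResult, control: CircuitResult | None = None) -> pd.DataFrame:
    """Per-population rate / VS summary pooled over sides and trials.

    Relative measures use the matched `control` result (itself when None).
    """
    if control is None:
        control = result
    window = result.config.rate_window_ms
    rows = []
    for pop in POPULATIONS:
        rates = []
        resultant = np.zeros(2)
        n_spikes = 0
        n_control = 0
        for side in SIDES:
            off = _phase_reference_offset(pop, side, result.stimulus)
            for sts in result.trains(pop, side):
                rates.append(population_rate(sts, window))
                t = sts.pooled()
                t = t[(t >= window[0]) & (t < window[1])]
                ph = spike_phases(t, result.stimulus, off)
                resultant += (np.cos(ph).sum(), np.sin(ph).sum())
                n_spikes += len(ph)
            for sts in control.trains(pop, side):
                t = sts.pooled()
                n_control += int(np.count_nonzero((t >= window[0]) & (t < window[1])))
        vs = float(np.hypot(*resultant) / n_spikes) if n_spikes else np.nan
        rel_vs = float(np.hypot(*resultant) / n_control) if n_control else np.nan
        ctrl_rate = np.mean([
            population_rate(sts, window) for side in SIDES for sts in control.trains(pop, side)
        ])
        rate = float(np.mean(rates))
        rows.append({
            "population": pop,
            "rate_hz": rate,
            "relative_rate": rate / ctrl_rate if ctrl_rate > 0 else np.nan,
            "vs": vs,
            "relative_vs": rel_vs,
            "n_spikes": n_spikes,
            "n_control": n_control,
        })
    return pd.DataFrame(rows)


def neuropathy_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Relative rate and relative VS per population per neuropathy level.

    The 0% level must be included: it defines the denominators of both
    relative measures.
    """
    if 0.0 not in spec.levels_pct:
        raise ValueError("the 0% control level must be part of the sweep")
    results = {
        level: run_circuit(spec.stimulus, spec.neuropathy(level), spec.config, spec.seed)
        for level in spec.levels_pct
    }
    control = results[0.0]
    frames = []
    for level, res in results.items():
        df = condition_summary(res, control)
        df.insert(0, "level_pct", level)
        df.insert(0, "kind", spec.kind)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def jitter_experiment(
    jitter_levels_ms=(0.0, 1.25, 2.5),
    myelinopathy_levels_pct=(0.0, 50.0, 100.0),
    stim: SoundStimulus | None = None,
    config: CircuitConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Rates and relative VS after artificially jittering SGN spike times.

    SGN trains are generated once per myelinopathy level and re-used across
    jitter levels (so SGN rates are identical by construction); downstream
    populations are re-simulated from the jittered input.  Relative VS is
    against the unjittered 0%-myelinopathy control.
    """
    stim = stim or SoundStimulus(200.0, 50.0, 100.0, 0.0)
    config = config or CircuitConfig()
    base = {
        v: run_circuit(stim, NeuropathyConfig(myelinopathy_pct=v), config, seed)
        for v in myelinopathy_levels_pct
    }
    control = base[min(myelinopathy_levels_pct)]
    frames = []
    for v, res in base.items():
        for delta in jitter_levels_ms:
            if delta == 0.0:
                jres = res
            else:
                override = {}
                for ti in range(config.n_trials):
                    for si, side in enumerate(SIDES):
                        sgn = res.get("SGN", side, ti)
                        jit = jitter_spike_trains(
                            sgn, delta,
                            np.random.SeedSequence([seed, 4, ti, si, int(delta * 1000)]),
                        )
                        override[(side, ti)] = jit.trains
                jres = run_circuit(stim, NeuropathyConfig(myelinopathy_pct=v), config,
                                   seed, sgn_override=override)
            df = condition_summary(jres, control)
            df.insert(0, "jitter_ms", delta)
            df.insert(0, "myelinopathy_pct", v)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def itd_sweep(
    stim: SoundStimulus,
    neuropathy: NeuropathyConfig,
    itd_grid_ms=DEFAULT_ITD_GRID_MS,
    config: CircuitConfig | None = None,
    seed: int = 0,
) -> tuple:
    """Left/right MSO rate curves over the ITD grid and their difference.

    Returns (DeltaRCurve, tidy DataFrame of per-ITD per-side MSO rates).
    """
    config = config or CircuitConfig()
    window = config.rate_window_ms
    left, right, rows = [], [], []
    for itd in itd_grid_ms:
        res = run_circuit(stim.with_itd(float(itd)), neuropathy, config, seed)
        rates = {
            side: float(np.mean([population_rate(s, window) for s in res.trains("MSO", side)]))
            for side in SIDES
        }
        left.append(rates["left"])
        right.append(rates["right"])
        for side in SIDES:
            rows.append({"itd_ms": float(itd), "side": side, "mso_rate_hz": rates[side]})
    curve = delta_r(left, right, itd_grid_ms)
    return curve, pd.DataFrame(rows)


@dataclass
class ResonanceMap:
    """Spike probability of a single MSO cell over (frequency, conductance)."""

    frequency_hz: np.ndarray
    conductance_ns: np.ndarray
    probability: np.ndarray  # (n_freq, n_conductance)
    p_criterion: float = 0.5

    @property
    def threshold_ns(self) -> np.ndarray:
        """Smallest conductance reaching the criterion, per frequency (nan if never)."""
        out = np.full(len(self.frequency_hz), np.nan)
        for i in range(len(self.frequency_hz)):
            ok = np.flatnonzero(self.probability[i] >= self.p_criterion)
            if len(ok):
                out[i] = self.conductance_ns[ok[0]]
        return out

    @property
    def resonant_frequency_hz(self) -> float:
        """Frequency with the lowest threshold conductance.

        Ties (same minimal threshold at several frequencies) are resolved by
        the largest spike probability at that threshold conductance.
        """
        thr = self.threshold_ns
        if np.all(np.isnan(thr)):
            raise ValueError("criterion never reached at any frequency")
        best = np.nanmin(thr)
        cand = np.flatnonzero(thr == best)
        if len(cand) > 1:
            col = [self.probability[i, np.searchsorted(self.conductance_ns, thr[i])]
                   for i in cand]
            cand = cand[np.argmax(col):][:1]
        return float(self.frequency_hz[cand[0]])


def resonance_probe(
    frequency_grid_hz=None,
    conductance_grid_ns=None,
    duration_ms: float = 200.0,
    dt_ms: float = 0.005,
    params: MSOCellParams = MSO_PARAMS,
    p_criterion: float = 0.5,
) -> ResonanceMap:
    """Map single-MSO-cell spike probability under periodic alpha drive.

    Inhibition is zero; excitation restarts an alpha conductance at every
    multiple of 1/f (presynaptic times t - mod(t, 1/f)).  Spike probability
    is output spikes divided by the number of synaptic inputs.  Fully
    deterministic.
    """
    f_grid = np.asarray(
        frequency_grid_hz if frequency_grid_hz is not None else np.arange(50, 1001, 25),
        dtype=float,
    )
    a_grid = np.asarray(
        conductance_grid_ns if conductance_grid_ns is not None
        else np.geomspace(1.0, 100.0, 40),
        dtype=float,
    )
    prob = np.zeros((len(f_grid), len(a_grid)))
    for i, f in enumerate(f_grid):
        n_inputs = int(np.floor(duration_ms * f / 1000.0)) + 1
        for j, a in enumerate(a_grid):
            trains, _ = run_mso_population(
                [np.empty(0)], [np.empty(0)], params, dt_ms, duration_ms,
                periodic_drive=(f, a),
            )
            prob[i, j] = spike_probability(len(trains[0]), n_inputs)
    return ResonanceMap(f_grid, a_grid, prob, p_criterion)


def freq_level_sweep(
    frequencies_hz=SWEEP_FREQUENCIES_HZ,
    levels_db=SWEEP_LEVELS_DB,
    neuropathies=(("none", 0.0),),
    itd_grid_ms=DEFAULT_ITD_GRID_MS,
    config: CircuitConfig | None = None,
    seed: int = 0,
    duration_ms: float = 100.0,
) -> pd.DataFrame:
    """Delta-R amplitude and mean MSO rate per (frequency, level, neuropathy).

    `neuropathies` is a sequence of (kind, level_pct) with kind in
    {none, myelinopathy, HT, random}.
    """
    config = config or CircuitConfig()
    rows = []
    for kind, level in neuropathies:
        if kind == "myelinopathy":
            npth = NeuropathyConfig(myelinopathy_pct=level)
        elif kind == "none":
            npth = NeuropathyConfig()
        else:
            npth = NeuropathyConfig(synaptopathy_kind=kind, synaptopathy_pct=level)
        for level_db in levels_db:
            for f in frequencies_hz:
                stim = SoundStimulus(float(f), float(level_db), duration_ms, 0.0)
                curve, df = itd_sweep(stim, npth, itd_grid_ms, config, seed)
                rows.append({
                    "frequency_hz": float(f),
                    "level_db": float(level_db),
                    "neuropathy_kind": kind,
                    "neuropathy_pct": float(level),
                    "amplitude_hz": curve.amplitude,
                    "best_itd_ms": curve.best_itd_ms,
                    "mean_mso_rate_hz": float(np.mean([curve.left_rate, curve.right_rate])),
                })
    return pd.DataFrame(rows)


def inhibition_comparison(
    frequencies_hz=(200, 300, 400, 600),
    level_db: float = 50.0,
    neuropathy: NeuropathyConfig | None = None,
    itd_grid_ms=DEFAULT_ITD_GRID_MS,
    config: CircuitConfig | None = None,
    seed: int = 0,
    duration_ms: float = 100.0,
) -> pd.DataFrame:
    """Paired best-ITD and amplitude differences with vs without inhibition.

    Both variants run with matched seeds so the excitatory pathway is
    spike-for-spike identical; the difference isolates the GBC-mediated
    inhibitory contribution.
    """
    config = config or CircuitConfig()
    neuropathy = neuropathy or NeuropathyConfig()
    no_inh = disable_inhibition_variant(config)
    rows = []
    for f in frequencies_hz:
        stim = SoundStimulus(float(f), float(level_db), duration_ms, 0.0)
        with_c, _ = itd_sweep(stim, neuropathy, itd_grid_ms, config, seed)
        without_c, _ = itd_sweep(stim, neuropathy, itd_grid_ms, no_inh, seed)
        rows.append({
            "frequency_hz": float(f),
            "best_itd_with_ms": with_c.best_itd_ms,
            "best_itd_without_ms": without_c.best_itd_ms,
            "best_itd_diff_ms": without_c.best_itd_ms - with_c.best_itd_ms,
            "amplitude_with_hz": with_c.amplitude,
            "amplitude_without_hz": without_c.amplitude,
            "amplitude_diff_hz": without_c.amplitude - with_c.amplitude,
        })
    return pd.DataFrame(rows)
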