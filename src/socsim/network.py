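"""Bilateral SOC circuit assembly: SGN -> SBC/GBC -> MSO of both sides.

Wiring (per side): each SBC pools 4 ipsilateral SGN fibers, each GBC 40;
each MSO cell receives 6 excitatory SBC inputs from each side (axonal delays
1.5 ms ipsi / 1.6 ms contra) and 3 inhibitory GBC inputs from each side
(1.5 ms ipsi / 1.0 ms contra).  MNTB/LNTB relays are absorbed into the
inhibitory delays.  The same index wiring is used on both sides, which makes
the circuit exactly mirror-symmetric up to the stochastic periphery.

Seeding: a run seed fans out through numpy SeedSequence children tagged by
(purpose, trial, side); connectivity and the SGN population draws are fixed
across the trials of one run, only the stimulus-driven periphery resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .periphery import (
    NeuropathyConfig,
    PeripheryParams,
    SGNPopulationSpec,
    SpikeTrainSet,
    build_sgn_population,
    generate_release_trains,
    transduce_to_sgn_spikes,
)
from .neurons import (
    BushyCellParams,
    GBC_PARAMS,
    MSO_PARAMS,
    MSOCellParams,
    SBC_PARAMS,
    run_bushy_population,
    run_mso_population,
)
from .stimulus import SoundStimulus

SIDES = ("left", "right")
POPULATIONS = ("SGN", "SBC", "GBC", "MSO")


@dataclass(frozen=True)
class CircuitConfig:
    """Population sizes, integration settings and trial protocol."""

    n_sgn_per_class: int = 100
    n_sbc: int = 300
    n_gbc: int = 300
    n_mso: int = 300
    dt_ms: float = 0.005
    duration_ms: float = 100.0
    n_trials: int = 5
    inhibition_enabled: bool = True
    settle_ms: float = 5.0
    sbc_indegree: int = 4
    gbc_indegree: int = 40
    mso_exc_indegree_per_side: int = 6
    mso_inh_indegree_per_side: int = 3
    periphery: PeripheryParams = field(default_factory=PeripheryParams)
    sbc_params: BushyCellParams = field(default_factory=lambda: SBC_PARAMS)
    gbc_params: BushyCellParams = field(default_factory=lambda: GBC_PARAMS)
    mso_params: MSOCellParams = field(default_factory=lambda: MSO_PARAMS)

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        n_sgn = 3 * self.n_sgn_per_class
        if self.n_sbc < self.mso_exc_indegree_per_side:
            raise ValueError("n_sbc smaller than MSO excitatory in-degree")
        if self.n_gbc < self.mso_inh_indegree_per_side:
            raise ValueError("n_gbc smaller than MSO inhibitory in-degree")
        if n_sgn < max(self.sbc_indegree, self.gbc_indegree):
            raise ValueError("SGN population smaller than bushy in-degree")

    @property
    def n_sgn(self) -> int:
        return 3 * self.n_sgn_per_class

    @property
    def rate_window_ms(self) -> tuple:
        return (self.settle_ms, self.duration_ms)


def disable_inhibition_variant(config: CircuitConfig) -> CircuitConfig:
    """Copy of the config with GBC->MSO inhibition identically zero."""
    return replace(config, inhibition_enabled=False)


@dataclass
class Connectivity:
    """Fixed in-degree source index lists (same wiring used on both sides)."""

    sbc_sources: np.ndarray  # (n_sbc, 4) into SGN
    gbc_sources: np.ndarray  # (n_gbc, 40) into SGN
    mso_exc_ipsi: np.ndarray  # (n_mso, 6) into SBC
    mso_exc_contra: np.ndarray  # (n_mso, 6) into SBC
    mso_inh_ipsi: np.ndarray  # (n_mso, 3) into GBC
    mso_inh_contra: np.ndarray  # (n_mso, 3) into GBC


def build_connectivity(config: CircuitConfig, seed) -> Connectivity:
    """Draw sources without replacement per postsynaptic cell."""
    rng = np.random.default_rng(seed)

    def draw(n_post, n_pre, k):
        return np.vstack([rng.choice(n_pre, size=k, replace=False) for _ in range(n_post)])

    return Connectivity(
        sbc_sources=draw(config.n_sbc, config.n_sgn, config.sbc_indegree),
        gbc_sources=draw(config.n_gbc, config.n_sgn, config.gbc_indegree),
        mso_exc_ipsi=draw(config.n_mso, config.n_sbc, config.mso_exc_indegree_per_side),
        mso_exc_contra=draw(config.n_mso, config.n_sbc, config.mso_exc_indegree_per_side),
        mso_inh_ipsi=draw(config.n_mso, config.n_gbc, config.mso_inh_indegree_per_side),
        mso_inh_contra=draw(config.n_mso, config.n_gbc, config.mso_inh_indegree_per_side),
    )


@dataclass
class CircuitResult:
    """Spike trains per (population, side, trial) plus full provenance."""

    stimulus: SoundStimulus
    neuropathy: NeuropathyConfig
    config: CircuitConfig
    seed: int
    spikes: dict  # (population, side, trial) -> SpikeTrainSet
    populations_spec: dict  # side -> SGNPopulationSpec

    def get(self, population: str, side: str, trial: int) -> SpikeTrainSet:
        return self.spikes[(population, side, trial)]

    def trains(self, population: str, side: str):
        """Iterate SpikeTrainSets of one population/side across trials."""
        for t in range(self.config.n_trials):
            yield self.spikes[(population, side, t)]


def _merge_sources(trains, sources, delay_ms: float = 0.0):
    out = []
    for row in sources:
        parts = [np.asarray(trains[i], dtype=float) + delay_ms for i in row]
        out.append(np.sort(np.concatenate(parts)) if parts else np.empty(0))
    return out


def _seed_for(seed: int, *tags: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), *map(int, tags)])


def run_circuit(
    stim: SoundStimulus,
    neuropathy: NeuropathyConfig,
    config: CircuitConfig,
    seed: int,
    sgn_override: dict | None = None,
) -> CircuitResult:
    """Simulate the full bilateral circuit for `config.n_trials` stimuli.

    `sgn_override`, if given, maps (side, trial) -> list of per-fiber spike
    arrays and replaces periphery generation (used by the jitter protocol);
    entries missing from the mapping fall back to generated spikes.
    """
    conn = build_connectivity(config, _seed_for(seed, 0))
    pops = {
        side: build_sgn_population(
            config.n_sgn_per_class, neuropathy, _seed_for(seed, 1, si)
        )
        for si, side in enumerate(SIDES)
    }
    spikes: dict = {}
    for trial in range(config.n_trials):
        sgn_trains = {}
        for si, side in enumerate(SIDES):
            key = (side, trial)
            if sgn_override is not None and key in sgn_override:
                trains = [np.asarray(t, dtype=float) for t in sgn_override[key]]
                sgn = SpikeTrainSet("SGN", side, trial, trains)
            else:
                rel = generate_release_trains(
                    pops[side], stim, config.periphery,
                    _seed_for(seed, 2, trial, si), side=side,
                )
                sgn = transduce_to_sgn_spikes(
                    pops[side], rel, config.periphery,
                    _seed_for(seed, 3, trial, si), trial=trial,
                )
            spikes[("SGN", side, trial)] = sgn
            sgn_trains[side] = sgn.trains
        bushy_trains = {}
        for side in SIDES:
            sbc_ev = _merge_sources(sgn_trains[side], conn.sbc_sources)
            sbc, _ = run_bushy_population(
                sbc_ev, config.sbc_params, config.dt_ms, config.duration_ms
            )
            gbc_ev = _merge_sources(sgn_trains[side], conn.gbc_sources)
            gbc, _ = run_bushy_population(
                gbc_ev, config.gbc_params, config.dt_ms, config.duration_ms
            )
            bushy_trains[side] = (sbc, gbc)
            spikes[("SBC", side, trial)] = SpikeTrainSet("SBC", side, trial, sbc)
            spikes[("GBC", side, trial)] = SpikeTrainSet("GBC", side, trial, gbc)
        mp = config.mso_params
        for side in SIDES:
            contra = "right" if side == "left" else "left"
            sbc_i, gbc_i = bushy_trains[side]
            sbc_c, gbc_c = bushy_trains[contra]
            exc = [
                np.sort(np.concatenate([a, b]))
                for a, b in zip(
                    _merge_sources(sbc_i, conn.mso_exc_ipsi, mp.delay_exc_ipsi_ms),
                    _merge_sources(sbc_c, conn.mso_exc_contra, mp.delay_exc_contra_ms),
                )
            ]
            if config.inhibition_enabled:
                inh = [
                    np.sort(np.concatenate([a, b]))
                    for a, b in zip(
                        _merge_sources(gbc_i, conn.mso_inh_ipsi, mp.delay_inh_ipsi_ms),
                        _merge_sources(gbc_c, conn.mso_inh_contra, mp.delay_inh_contra_ms),
                    )
                ]
            else:
                inh = [np.empty(0)] * config.n_mso
            mso, _ = run_mso_population(
                exc, inh, mp, config.dt_ms, config.duration_ms
            )
            spikes[("MSO", side, trial)] = SpikeTrainSet("MSO", side, trial, mso)
    return CircuitResult(
        stimulus=stim,
        neuropathy=neuropathy,
        config=config,
        seed=int(seed),
        spikes=spikes,
        populations_spec=pops,
    )
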