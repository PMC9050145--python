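"""Single-compartment conductance-based bushy (SBC/GBC) and MSO cell models.

The bushy current balance is

    C dV/dt = -( g_l(V-E_rest) + g_Na m^3 h (V-E_Na)
                 + g_KHT(0.85 n^2 + 0.15 p)(V-E_K) + g_KLT w^4 z (V-E_K)
                 + g_h r (V-E_h) + I_syn ) + I_ext

with excitatory synapses as instantaneous-rise exponentials of decay 0.2 ms.
The MSO balance replaces KHT with nothing (no n, p gates) and receives
alpha-function excitation (tau 0.17 ms, delays 1.5/1.6 ms ipsi/contra) and
double-exponential inhibition (0.14/1.6 ms, delays 1.5/1.0 ms ipsi/contra,
reversal -70 mV).  Inhibition is implemented as a non-negative conductance
times (V - E_in): with E_in well below rest the current is hyperpolarizing.

Integration is fixed-step RK4 (default dt 0.005 ms) through numba kernels;
see :mod:`socsim._kernels` for the numerical details.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import gating
from ._kernels import TAU_FLOOR_MS, _run_bushy_pop, _run_mso_pop

DT_MAX_MS = 0.01
SPIKE_THRESHOLD_MV = -20.0
DETECT_REFRACTORY_MS = 1.0

_TAB_V_MIN = -150.0
_TAB_V_MAX = 100.0
_TAB_DV = 0.025


@dataclass(frozen=True)
class BushyCellParams:
    """Electrophysiological parameters for SBC/GBC cells.

    Defaults are the SBC/GBC column of the model's parameter table; the two
    cell types differ only in synaptic strength (13 nS SBC, 4.76 nS GBC)
    and in-degree.
    """

    c_m_pf: float = 12.0
    e_rest_mv: float = -65.0
    g_l_ns: float = 37.0
    g_na_ns: float = 4592.8
    g_kht_ns: float = 35.1
    g_klt_ns: float = 367.4
    g_h_ns: float = 36.7
    e_na_mv: float = 50.0
    e_k_mv: float = -77.0
    e_h_mv: float = -43.0
    a_syn_ns: float = 13.0  # 13 for SBC, 4.76 for GBC
    syn_decay_ms: float = 0.2
    e_ex_mv: float = 0.0

    def __post_init__(self) -> None:
        for name in ("g_l_ns", "g_na_ns", "g_kht_ns", "g_klt_ns", "g_h_ns", "a_syn_ns"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.c_m_pf, self.e_rest_mv, self.g_l_ns, self.g_na_ns, self.g_kht_ns,
             self.g_klt_ns, self.g_h_ns, self.e_na_mv, self.e_k_mv, self.e_h_mv,
             self.e_ex_mv]
        )


SBC_PARAMS = BushyCellParams(a_syn_ns=13.0)
GBC_PARAMS = BushyCellParams(a_syn_ns=4.76)


@dataclass(frozen=True)
class MSOCellParams:
    """Electrophysiological and synaptic parameters for MSO cells."""

    c_m_pf: float = 70.0
    e_rest_mv: float = -55.8
    g_l_ns: float = 13.0
    g_na_ns: float = 3900.0
    g_klt_ns: float = 650.0
    g_h_ns: float = 520.0
    e_na_mv: float = 56.2
    e_k_mv: float = -90.0
    e_h_mv: float = -35.0
    a_exc_ns: float = 54.37
    a_inh_ns: float = 5.5
    e_ex_mv: float = 0.0
    e_in_mv: float = -70.0
    tau_exc_ms: float = 0.17
    tau_inh_rise_ms: float = 0.14
    tau_inh_decay_ms: float = 1.6
    delay_exc_ipsi_ms: float = 1.5
    delay_exc_contra_ms: float = 1.6
    delay_inh_ipsi_ms: float = 1.5
    delay_inh_contra_ms: float = 1.0

    def __post_init__(self) -> None:
        for name in ("g_l_ns", "g_na_ns", "g_klt_ns", "g_h_ns", "a_exc_ns", "a_inh_ns"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.c_m_pf, self.e_rest_mv, self.g_l_ns, self.g_na_ns, self.g_klt_ns,
             self.g_h_ns, self.e_na_mv, self.e_k_mv, self.e_h_mv, self.e_ex_mv,
             self.e_in_mv]
        )


MSO_PARAMS = MSOCellParams()


@dataclass
class MembraneTrace:
    """Uniformly sampled membrane-potential trajectory of one cell."""

    dt_ms: float
    v_mv: np.ndarray
    gates: np.ndarray | None = None  # (n_samples, n_gates), optional
    gate_names: tuple = ()

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(len(self.v_mv)) * self.dt_ms


class IntegrationError(RuntimeError):
    pass


# ------------------------------------------------- synaptic closed forms ----

def bushy_syn_conductance(t_ms, presyn_spikes_ms, a_ns: float, tau_ms: float = 0.2):
    """Summed exponential-decay conductance g(t) = sum A e^{-(t-ts)/tau}."""
    t = np.atleast_1d(np.asarray(t_ms, dtype=float))
    g = np.zeros_like(t)
    for ts in presyn_spikes_ms:
        x = t - ts
        m = x >= 0
        g[m] += a_ns * np.exp(-x[m] / tau_ms)
    return g if np.ndim(t_ms) else float(g[0])


def mso_exc_conductance(t_ms, presyn_spikes_ms, side: str, params: MSOCellParams = MSO_PARAMS):
    """Alpha-function conductance sum A (x/tau) e^{-x/tau}, x = t - ts - delay.

    `side` selects the axonal delay: 'ipsi' 1.5 ms, 'contra' 1.6 ms.
    """
    delay = params.delay_exc_ipsi_ms if side == "ipsi" else params.delay_exc_contra_ms
    tau = params.tau_exc_ms
    t = np.atleast_1d(np.asarray(t_ms, dtype=float))
    g = np.zeros_like(t)
    for ts in presyn_spikes_ms:
        x = t - ts - delay
        m = x >= 0
        g[m] += params.a_exc_ns * (x[m] / tau) * np.exp(-x[m] / tau)
    return g if np.ndim(t_ms) else float(g[0])


def mso_inh_conductance(t_ms, presyn_spikes_ms, side: str, params: MSOCellParams = MSO_PARAMS):
    """Double-exponential inhibitory conductance (non-negative).

    g(t) = sum A (e^{-x/tau_decay} - e^{-x/tau_rise}), x = t - ts - delay,
    with tau_rise = 0.14 ms, tau_decay = 1.6 ms; `side` selects the delay
    ('ipsi' 1.5 ms, 'contra' 1.0 ms).  Used with reversal E_in = -70 mV the
    resulting current hyperpolarizes for V > E_in.
    """
    delay = params.delay_inh_ipsi_ms if side == "ipsi" else params.delay_inh_contra_ms
    t = np.atleast_1d(np.asarray(t_ms, dtype=float))
    g = np.zeros_like(t)
    for ts in presyn_spikes_ms:
        x = t - ts - delay
        m = x >= 0
        g[m] += params.a_inh_ns * (
            np.exp(-x[m] / params.tau_inh_decay_ms) - np.exp(-x[m] / params.tau_inh_rise_ms)
        )
    return g if np.ndim(t_ms) else float(g[0])


# ----------------------------------------------------- gate table caches ----

_table_cache: dict = {}


def _bushy_table() -> np.ndarray:
    if "bushy" not in _table_cache:
        v = np.arange(_TAB_V_MIN, _TAB_V_MAX + _TAB_DV / 2, _TAB_DV)
        fns = gating.bushy_gate_functions(v)
        rows = []
        for g in gating.BUSHY_GATES:
            rows.append(fns[f"{g}_inf"])
            rows.append(np.maximum(fns[f"tau_{g}"], TAU_FLOOR_MS))
        _table_cache["bushy"] = np.ascontiguousarray(np.vstack(rows))
    return _table_cache["bushy"]


def _mso_table() -> np.ndarray:
    if "mso" not in _table_cache:
        v = np.arange(_TAB_V_MIN, _TAB_V_MAX + _TAB_DV / 2, _TAB_DV)
        fns = gating.mso_gate_functions(v)
        rows = []
        for g in gating.MSO_GATES:
            rows.append(fns[f"{g}_inf"])
            rows.append(np.maximum(fns[f"tau_{g}"], TAU_FLOOR_MS))
        _table_cache["mso"] = np.ascontiguousarray(np.vstack(rows))
    return _table_cache["mso"]


def bushy_initial_gates(v_mv: float) -> np.ndarray:
    fns = gating.bushy_gate_functions(v_mv)
    return np.array([float(fns[f"{g}_inf"]) for g in gating.BUSHY_GATES])


def mso_initial_gates(v_mv: float) -> np.ndarray:
    fns = gating.mso_gate_functions(v_mv)
    return np.array([float(fns[f"{g}_inf"]) for g in gating.MSO_GATES])


def _events_to_csr(event_lists, dt_ms: float, n_steps: int):
    """Snap per-cell arrival times to grid indices; return (idx, ptr)."""
    ptr = np.zeros(len(event_lists) + 1, dtype=np.int64)
    chunks = []
    for i, ev in enumerate(event_lists):
        ev = np.asarray(ev, dtype=float)
        idx = np.rint(ev / dt_ms).astype(np.int64)
        idx = np.sort(idx[(idx >= 0) & (idx < n_steps)])
        chunks.append(idx)
        ptr[i + 1] = ptr[i] + len(idx)
    idx_flat = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
    return idx_flat.astype(np.int64), ptr


def _alloc_spikes(n_cells: int, duration_ms: float, det_refrac: float):
    max_spikes = int(duration_ms / det_refrac) + 2
    return np.full(n_cells * max_spikes, np.nan), np.zeros(n_cells, dtype=np.int64), max_spikes


def run_bushy_population(
    exc_event_lists,
    params: BushyCellParams,
    dt_ms: float,
    duration_ms: float,
    i_ext_pa: float = 0.0,
    i_ext_window_ms: tuple = (0.0, 0.0),
    record_trace: bool = False,
):
    """Integrate a population of bushy cells given per-cell presynaptic times.

    Returns (list of per-cell spike-time arrays, MembraneTrace of cell 0 or
    None).
    """
    if dt_ms > DT_MAX_MS:
        raise ValueError(f"dt must be <= {DT_MAX_MS} ms")
    n_steps = int(round(duration_ms / dt_ms))
    idx, ptr = _events_to_csr(exc_event_lists, dt_ms, n_steps)
    spike_times, spike_counts, max_spikes = _alloc_spikes(len(exc_event_lists), duration_ms, DETECT_REFRACTORY_MS)
    tab = _bushy_table()
    v_rec = np.zeros(n_steps + 1 if record_trace else 1)
    g_rec = np.zeros((n_steps + 1 if record_trace else 1, 7))
    status = _run_bushy_pop(
        dt_ms, n_steps, params.as_vector(), tab, _TAB_V_MIN, 1.0 / _TAB_DV,
        idx, ptr, params.a_syn_ns, params.syn_decay_ms,
        i_ext_pa, i_ext_window_ms[0], i_ext_window_ms[1],
        params.e_rest_mv, bushy_initial_gates(params.e_rest_mv),
        SPIKE_THRESHOLD_MV, DETECT_REFRACTORY_MS,
        spike_times, spike_counts, max_spikes,
        record_trace, v_rec, g_rec,
    )
    if status < 0:
        raise IntegrationError(f"bushy integration blew up at t = {-status * dt_ms:.3f} ms")
    trains = [spike_times[c * max_spikes: c * max_spikes + spike_counts[c]].copy()
              for c in range(len(exc_event_lists))]
    trace = MembraneTrace(dt_ms, v_rec, g_rec, gating.BUSHY_GATES) if record_trace else None
    return trains, trace


def run_mso_population(
    exc_event_lists,
    inh_event_lists,
    params: MSOCellParams,
    dt_ms: float,
    duration_ms: float,
    periodic_drive: tuple | None = None,  # (frequency_hz, strength_ns)
    i_ext_pa: float = 0.0,
    i_ext_window_ms: tuple = (0.0, 0.0),
    record_trace: bool = False,
):
    """Integrate a population of MSO cells.

    `exc_event_lists` / `inh_event_lists` hold per-cell *arrival* times (the
    caller applies axonal delays).  `periodic_drive` adds the resonance-probe
    conductance: an alpha function restarted every 1/f, closed form
    A (mod(t,1/f)/tau) e^{-mod(t,1/f)/tau}.
    """
    if dt_ms > DT_MAX_MS:
        raise ValueError(f"dt must be <= {DT_MAX_MS} ms")
    n_cells = max(len(exc_event_lists), 1)
    if not exc_event_lists:
        exc_event_lists = [np.empty(0)] * n_cells
    if not inh_event_lists:
        inh_event_lists = [np.empty(0)] * n_cells
    n_steps = int(round(duration_ms / dt_ms))
    eidx, eptr = _events_to_csr(exc_event_lists, dt_ms, n_steps)
    iidx, iptr = _events_to_csr(inh_event_lists, dt_ms, n_steps)
    spike_times, spike_counts, max_spikes = _alloc_spikes(n_cells, duration_ms, DETECT_REFRACTORY_MS)
    tab = _mso_table()
    f_hz, a_ns = periodic_drive if periodic_drive is not None else (0.0, 0.0)
    v_rec = np.zeros(n_steps + 1 if record_trace else 1)
    g_rec = np.zeros((n_steps + 1 if record_trace else 1, 5))
    status = _run_mso_pop(
        dt_ms, n_steps, params.as_vector(), tab, _TAB_V_MIN, 1.0 / _TAB_DV,
        eidx, eptr, params.a_exc_ns, params.tau_exc_ms,
        iidx, iptr, params.a_inh_ns, params.tau_inh_rise_ms, params.tau_inh_decay_ms,
        float(f_hz), float(a_ns),
        i_ext_pa, i_ext_window_ms[0], i_ext_window_ms[1],
        params.e_rest_mv, mso_initial_gates(params.e_rest_mv),
        SPIKE_THRESHOLD_MV, DETECT_REFRACTORY_MS,
        spike_times, spike_counts, max_spikes,
        record_trace, v_rec, g_rec,
    )
    if status < 0:
        raise IntegrationError(f"MSO integration blew up at t = {-status * dt_ms:.3f} ms")
    trains = [spike_times[c * max_spikes: c * max_spikes + spike_counts[c]].copy()
              for c in range(n_cells)]
    trace = MembraneTrace(dt_ms, v_rec, g_rec, gating.MSO_GATES) if record_trace else None
    return trains, trace


def integrate_cell(
    params,
    syn_event_streams=None,
    dt_ms: float = 0.005,
    duration_ms: float = 100.0,
    external_current=None,  # (amplitude_pA, t_on_ms, t_off_ms)
    periodic_drive=None,
) -> MembraneTrace:
    """Integrate a single cell and return its membrane trace.

    `syn_event_streams` is a dict with keys 'exc' and (MSO only) 'inh'
    holding presynaptic *arrival* times in ms.  `external_current` injects a
    step of given amplitude (pA) over [t_on, t_off).
    """
    streams = syn_event_streams or {}
    i_amp, (t0, t1) = 0.0, (0.0, 0.0)
    if external_current is not None:
        i_amp, t0, t1 = external_current
    if isinstance(params, MSOCellParams):
        trains, trace = run_mso_population(
            [np.asarray(streams.get("exc", ()), dtype=float)],
            [np.asarray(streams.get("inh", ()), dtype=float)],
            params, dt_ms, duration_ms, periodic_drive=periodic_drive,
            i_ext_pa=i_amp, i_ext_window_ms=(t0, t1), record_trace=True,
        )
    elif isinstance(params, BushyCellParams):
        trains, trace = run_bushy_population(
            [np.asarray(streams.get("exc", ()), dtype=float)],
            params, dt_ms, duration_ms,
            i_ext_pa=i_amp, i_ext_window_ms=(t0, t1), record_trace=True,
        )
    else:
        raise TypeError(f"unsupported parameter type {type(params)!r}")
    trace.spikes_ms = trains[0]  # convenience attribute
    return trace


def detect_spikes(trace: MembraneTrace, threshold_mv: float = SPIKE_THRESHOLD_MV,
                  refractory_ms: float = DETECT_REFRACTORY_MS) -> np.ndarray:
    """Upward threshold crossings of a trace, linearly interpolated in time.

    Crossings within `refractory_ms` of the previously detected spike are
    ignored.
    """
    v = trace.v_mv
    dt = trace.dt_ms
    out = []
    last = -np.inf
    below = v[:-1] < threshold_mv
    above = v[1:] >= threshold_mv
    for i in np.flatnonzero(below & above):
        t_cross = i * dt + dt * (threshold_mv - v[i]) / (v[i + 1] - v[i])
        if t_cross - last >= refractory_ms:
            out.append(t_cross)
            last = t_cross
    return np.asarray(out)


def resting_equilibrium(params) -> float:
    """Zero of the total steady-state current (independent of integration).

    Solves I_total(V) = 0 with every gate at its steady state; used both to
    report the true resting point and as an oracle for quiescent traces.
    """
    if isinstance(params, MSOCellParams):
        def f(v):
            g = gating.mso_gate_functions(v)
            return (
                params.g_l_ns * (v - params.e_rest_mv)
                + params.g_na_ns * g["m_inf"] ** 3 * g["h_inf"] * (v - params.e_na_mv)
                + params.g_klt_ns * g["w_inf"] ** 4 * g["z_inf"] * (v - params.e_k_mv)
                + params.g_h_ns * g["r_inf"] * (v - params.e_h_mv)
            )
    else:
        def f(v):
            g = gating.bushy_gate_functions(v)
            return (
                params.g_l_ns * (v - params.e_rest_mv)
                + params.g_na_ns * g["m_inf"] ** 3 * g["h_inf"] * (v - params.e_na_mv)
                + params.g_kht_ns * (0.85 * g["n_inf"] ** 2 + 0.15 * g["p_inf"]) * (v - params.e_k_mv)
                + params.g_klt_ns * g["w_inf"] ** 4 * g["z_inf"] * (v - params.e_k_mv)
                + params.g_h_ns * g["r_inf"] * (v - params.e_h_mv)
            )
    return float(brentq(f, -90.0, -30.0, xtol=1e-10))
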