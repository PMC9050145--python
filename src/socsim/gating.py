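"""Voltage-dependent gating kinetics for bushy (SBC/GBC) and MSO cells.

Bushy cells follow Rothman-Manis-style type-II kinetics: Na activation and
inactivation (m, h) are given as rate constants alpha/beta; the high- and
low-threshold K+ gates (n, p, w, z) and the H-current gate (r) as steady
states and time constants.  The MSO cell uses steady-state/time-constant
form for all five gates (m, h, w, z, r).

Voltages are mV, times ms, rates 1/ms.  The two removable singularities in
alpha_m (V = -49) and beta_m (V = -58) are evaluated by their limits.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "bushy_gate_functions",
    "mso_gate_functions",
    "BUSHY_GATES",
    "MSO_GATES",
]


def _expm1_ratio(x):
    """x / (1 - exp(-x)) with the x -> 0 limit handled (value 1)."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x) < 1e-9, 1.0 + x / 2.0, x / -np.expm1(np.where(np.abs(x) < 1e-9, 1.0, -x)))
    return out


# ---------------------------------------------------------------- bushy ----

def alpha_m_bushy(v):
    # 1.872 (V+49) / (1 - e^{-(V+49)/3}); limit 5.616 at V = -49
    x = (np.asarray(v, dtype=float) + 49.0) / 3.0
    return 1.872 * 3.0 * _expm1_ratio(x)


def beta_m_bushy(v):
    # -2.08 (V+58) / (1 - e^{(V+58)/20}); limit 41.6 at V = -58
    x = (np.asarray(v, dtype=float) + 58.0) / 20.0
    return 2.08 * 20.0 * _expm1_ratio(-x)


def alpha_h_bushy(v):
    v = np.asarray(v, dtype=float)
    return 12.48 / (1.0 + np.exp((v + 68.0) / 3.0)) + 25.344 / (1.0 + np.exp(v + 61.3))


def beta_h_bushy(v):
    v = np.asarray(v, dtype=float)
    return 18.72 / (1.0 + np.exp(-(v + 21.0) / 10.0))


def w_inf_bushy(v):
    v = np.asarray(v, dtype=float)
    return (1.0 + np.exp(-(v + 48.0) / 6.0)) ** -0.25


def tau_w_bushy(v):
    v = np.asarray(v, dtype=float)
    return 1.5 + 100.0 / (6.0 * np.exp((v + 60.0) / 6.0) + 16.0 * np.exp(-(v + 60.0) / 45.0))


def z_inf_bushy(v):
    v = np.asarray(v, dtype=float)
    return 0.5 + 1.0 / (2.0 * (1.0 + np.exp((v + 71.0) / 10.0)))


def tau_z_bushy(v):
    v = np.asarray(v, dtype=float)
    return 50.0 + 1000.0 / (np.exp((v + 60.0) / 20.0) + np.exp(-(v + 60.0) / 8.0))


def r_inf_bushy(v):
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp((v + 76.0) / 7.0))


def tau_r_bushy(v):
    v = np.asarray(v, dtype=float)
    return 25.0 + 1.0e5 / (237.0 * np.exp((v + 60.0) / 12.0) + 17.0 * np.exp(-(v + 60.0) / 14.0))


def n_inf_bushy(v):
    v = np.asarray(v, dtype=float)
    return (1.0 + np.exp(-(v + 15.0) / 5.0)) ** -0.5


def tau_n_bushy(v):
    v = np.asarray(v, dtype=float)
    return 0.7 + 100.0 / (11.0 * np.exp((v + 60.0) / 24.0) + 21.0 * np.exp(-(v + 60.0) / 23.0))


def p_inf_bushy(v):
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp(-(v + 23.0) / 6.0))


def tau_p_bushy(v):
    v = np.asarray(v, dtype=float)
    return 5.0 + 100.0 / (4.0 * np.exp((v + 60.0) / 32.0) + 5.0 * np.exp(-(v + 60.0) / 22.0))


def m_inf_bushy(v):
    a, b = alpha_m_bushy(v), beta_m_bushy(v)
    return a / (a + b)


def tau_m_bushy(v):
    return 1.0 / (alpha_m_bushy(v) + beta_m_bushy(v))


def h_inf_bushy(v):
    a, b = alpha_h_bushy(v), beta_h_bushy(v)
    return a / (a + b)


def tau_h_bushy(v):
    return 1.0 / (alpha_h_bushy(v) + beta_h_bushy(v))


def bushy_gate_functions(v):
    """All bushy steady states and time constants at voltage(s) v.

    Returns a dict with keys '<gate>_inf' and 'tau_<gate>' for gates
    m, h, n, p, w, z, r, plus raw 'alpha_m', 'beta_m', 'alpha_h', 'beta_h'.
    """
    return {
        "alpha_m": alpha_m_bushy(v),
        "beta_m": beta_m_bushy(v),
        "alpha_h": alpha_h_bushy(v),
        "beta_h": beta_h_bushy(v),
        "m_inf": m_inf_bushy(v),
        "tau_m": tau_m_bushy(v),
        "h_inf": h_inf_bushy(v),
        "tau_h": tau_h_bushy(v),
        "n_inf": n_inf_bushy(v),
        "tau_n": tau_n_bushy(v),
        "p_inf": p_inf_bushy(v),
        "tau_p": tau_p_bushy(v),
        "w_inf": w_inf_bushy(v),
        "tau_w": tau_w_bushy(v),
        "z_inf": z_inf_bushy(v),
        "tau_z": tau_z_bushy(v),
        "r_inf": r_inf_bushy(v),
        "tau_r": tau_r_bushy(v),
    }


# ------------------------------------------------------------------ MSO ----

def m_inf_mso(v):
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp(-(v + 38.0) / 7.0))


def tau_m_mso(v):
    v = np.asarray(v, dtype=float)
    return 0.48 / (5.0 * np.exp((v + 60.0) / 18.0) + 36.0 * np.exp(-(v + 60.0) / 25.0))


def h_inf_mso(v):
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp((v + 65.0) / 6.0))


def tau_h_mso(v):
    v = np.asarray(v, dtype=float)
    return 19.23 / (7.0 * np.exp((v + 60.0) / 11.0) + 10.0 * np.exp(-(v + 60.0) / 25.0)) + 0.12


def w_inf_mso(v):
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp(-(v + 57.3) / 11.7))


def tau_w_mso(v):
    v = np.asarray(v, dtype=float)
    return 46.0 / (6.0 * np.exp((v + 75.0) / 12.15) + 24.0 * np.exp(-(v + 75.0) / 25.0)) + 0.55


def z_inf_mso(v):
    v = np.asarray(v, dtype=float)
    return 0.4 + 0.6 / (1.0 + np.exp((v + 57.0) / 5.44))


def tau_z_mso(v):
    v = np.asarray(v, dtype=float)
    return 12.0 + 240.0 / (np.exp((v + 60.0) / 20.0) + np.exp(-(v + 60.0) / 8.0))


def r_inf_mso(v):
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp((v + 80.4) / 10.0))


def tau_r_mso(v):
    v = np.asarray(v, dtype=float)
    return 79.0 + np.exp(-(v + 61.5) / 2800.0)


def mso_gate_functions(v):
    """All MSO steady states and time constants at voltage(s) v."""
    return {
        "m_inf": m_inf_mso(v),
        "tau_m": tau_m_mso(v),
        "h_inf": h_inf_mso(v),
        "tau_h": tau_h_mso(v),
        "w_inf": w_inf_mso(v),
        "tau_w": tau_w_mso(v),
        "z_inf": z_inf_mso(v),
        "tau_z": tau_z_mso(v),
        "r_inf": r_inf_mso(v),
        "tau_r": tau_r_mso(v),
    }


BUSHY_GATES = ("m", "h", "n", "p", "w", "z", "r")
MSO_GATES = ("m", "h", "w", "z", "r")
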