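"""Single-cell dynamics: synaptic conductance closed forms, resting
equilibrium, phasic vs tonic firing, spike detection, dt-convergence."""

import numpy as np
import pytest

from socsim import neurons as N
from socsim.neurons import (
    GBC_PARAMS,
    MSO_PARAMS,
    SBC_PARAMS,
    MembraneTrace,
    bushy_syn_conductance,
    detect_spikes,
    integrate_cell,
    mso_exc_conductance,
    mso_inh_conductance,
    resting_equilibrium,
)


class TestSynapticConductances:
    def test_bushy_epsg_closed_form(self):
        assert bushy_syn_conductance(5.0, [5.0], 13.0) == pytest.approx(13.0)
        assert bushy_syn_conductance(5.2, [5.0], 13.0) == pytest.approx(13.0 / np.e)
        # superposition of two spikes
        g = bushy_syn_conductance(5.2, [5.0, 5.2], 13.0)
        assert g == pytest.approx(13.0 / np.e + 13.0)
        assert SBC_PARAMS.a_syn_ns == 13.0 and GBC_PARAMS.a_syn_ns == 4.76

    def test_mso_alpha_function(self):
        p = MSO_PARAMS
        # zero at onset, peak A/e at x = tau after the side-specific delay
        assert mso_exc_conductance(1.5, [0.0], "ipsi", p) == pytest.approx(0.0)
        peak_t = 1.5 + 0.17
        assert mso_exc_conductance(peak_t, [0.0], "ipsi", p) == pytest.approx(
            54.37 / np.e, rel=1e-12
        )
        assert 54.37 / np.e == pytest.approx(20.0, abs=0.1)
        # ipsi vs contra onsets differ by 0.1 ms
        x = np.linspace(0, 5, 5001)
        gi = mso_exc_conductance(x, [0.0], "ipsi", p)
        gc = mso_exc_conductance(x, [0.0], "contra", p)
        assert x[np.argmax(gi > 0)] - 1.5 < 2e-3
        assert x[np.argmax(gc > 0)] - 1.6 < 2e-3

    def test_mso_inhibition_double_exponential(self):
        p = MSO_PARAMS
        assert mso_inh_conductance(1.5, [0.0], "ipsi", p) == pytest.approx(0.0)
        x = np.linspace(1.5, 12.0, 200001)
        g = mso_inh_conductance(x, [0.0], "ipsi", p)
        assert np.all(g >= 0.0)
        x_peak = x[np.argmax(g)] - 1.5
        t1, t2 = 0.14, 1.6
        x_star = t1 * t2 / (t2 - t1) * np.log(t2 / t1)
        assert x_peak == pytest.approx(x_star, abs=1e-3)
        assert x_star == pytest.approx(0.374, abs=1e-3)
        # contralateral inhibition arrives 0.5 ms before ipsilateral
        assert p.delay_inh_ipsi_ms - p.delay_inh_contra_ms == pytest.approx(0.5)


class TestQuiescentEquilibrium:
    @pytest.mark.parametrize("params", [MSO_PARAMS, SBC_PARAMS], ids=["mso", "bushy"])
    def test_trace_settles_at_root_solved_equilibrium(self, params):
        """The integrated quiescent cell stays within 1 mV of the zero of the
        steady-state current balance found by an independent root finder."""
        veq = resting_equilibrium(params)
        tr = integrate_cell(params, dt_ms=0.005, duration_ms=100.0)
        assert len(tr.spikes_ms) == 0
        assert abs(tr.v_mv[-1] - veq) < 1.0
        assert np.all(np.abs(tr.v_mv - tr.v_mv[0]) < 5.0)


class TestFiringModes:
    def test_mso_is_phasic_over_step_amplitude_grid(self):
        """A sustained suprathreshold step evokes exactly one MSO spike,
        across a 10-point amplitude grid."""
        for amp in np.linspace(2200.0, 8000.0, 10):
            tr = integrate_cell(MSO_PARAMS, dt_ms=0.005, duration_ms=80.0,
                                external_current=(float(amp), 5.0, 75.0))
            assert len(tr.spikes_ms) == 1, f"amplitude {amp}"

    def test_mso_subthreshold_step_is_silent(self):
        tr = integrate_cell(MSO_PARAMS, dt_ms=0.005, duration_ms=60.0,
                            external_current=(500.0, 5.0, 55.0))
        assert len(tr.spikes_ms) == 0

    def test_bushy_fires_tonically_to_sustained_volley_drive(self):
        """Phase-locked suprathreshold volleys drive repeated bushy firing,
        unlike the single-spike MSO step response."""
        cycles = np.arange(5.0, 95.0, 5.0)
        ev = np.sort(np.concatenate([cycles + 0.05 * j for j in range(4)]))
        tr = integrate_cell(SBC_PARAMS, {"exc": ev}, dt_ms=0.005, duration_ms=100.0)
        assert len(tr.spikes_ms) >= 3

    def test_gates_stay_in_unit_interval_on_driven_trace(self):
        cycles = np.arange(5.0, 95.0, 5.0)
        ev = np.sort(np.concatenate([cycles + 0.05 * j for j in range(4)]))
        for params, stream in ((SBC_PARAMS, {"exc": ev}), (MSO_PARAMS, {"exc": ev})):
            tr = integrate_cell(params, stream, dt_ms=0.005, duration_ms=100.0)
            assert tr.gates is not None
            assert tr.gates.min() >= 0.0 and tr.gates.max() <= 1.0


class TestSpikeDetection:
    def test_flat_trace_has_no_spikes(self):
        tr = MembraneTrace(0.01, np.full(1000, -65.0))
        assert len(detect_spikes(tr)) == 0

    def test_single_crossing_interpolated(self):
        v = np.array([-60.0, -40.0, 0.0, -40.0, -60.0])
        tr = MembraneTrace(0.1, v)
        s = detect_spikes(tr, threshold_mv=-20.0)
        # crossing between samples 1 and 2: t = 0.1 + 0.1*(20/40)
        assert s == pytest.approx([0.15])

    def test_refractory_merges_close_crossings(self):
        v = np.full(200, -60.0)
        v[50:52] = 0.0   # crossing at ~0.5 ms
        v[80:82] = 0.0   # second crossing 0.3 ms later
        tr = MembraneTrace(0.01, v)
        assert len(detect_spikes(tr, refractory_ms=1.0)) == 1
        assert len(detect_spikes(tr, refractory_ms=0.1)) == 2

    def test_kernel_detection_matches_offline_detection(self):
        cycles = np.arange(5.0, 95.0, 5.0)
        ev = np.sort(np.concatenate([cycles + 0.05 * j for j in range(4)]))
        tr = integrate_cell(SBC_PARAMS, {"exc": ev}, dt_ms=0.005, duration_ms=100.0)
        offline = detect_spikes(tr)
        np.testing.assert_allclose(tr.spikes_ms, offline, atol=1e-9)


class TestConvergence:
    @pytest.mark.parametrize("params", [MSO_PARAMS, SBC_PARAMS], ids=["mso", "bushy"])
    def test_spike_times_stable_under_dt_halving(self, params):
        """Halving dt from 0.005 to 0.0025 ms leaves the spike count
        unchanged and every spike time within 0.02 ms (event times chosen on
        both grids)."""
        ev = sorted(list(np.arange(5.0, 95.0, 5.0)) * 4)
        a = integrate_cell(params, {"exc": ev}, dt_ms=0.005, duration_ms=100.0)
        b = integrate_cell(params, {"exc": ev}, dt_ms=0.0025, duration_ms=100.0)
        assert len(a.spikes_ms) == len(b.spikes_ms) > 0
        np.testing.assert_allclose(a.spikes_ms, b.spikes_ms, atol=0.02)

    def test_dt_above_limit_rejected(self):
        with pytest.raises(ValueError):
            integrate_cell(MSO_PARAMS, dt_ms=0.02, duration_ms=10.0)
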