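"""Synthetic-periphery behavior: population construction, release statistics,
transduction, and spike-time jitter."""

import numpy as np
import pytest

from socsim import (
    NeuropathyConfig,
    PeripheryParams,
    SoundStimulus,
    build_sgn_population,
    ear_arrival_offsets,
    generate_release_trains,
    jitter_spike_trains,
    transduce_to_sgn_spikes,
)
from socsim.metrics import vector_strength
from socsim.periphery import FiberClass, SpikeTrainSet, release_intensity


class TestPopulationConstruction:
    def test_control_population_is_homogeneous_and_intact(self):
        pop = build_sgn_population(100, NeuropathyConfig(), seed=0)
        assert pop.n_fibers == 300
        assert np.all(pop.l_u_um == 10.0)
        assert pop.intact.all()
        assert {c: int((pop.fiber_class == c).sum()) for c in ("LT", "MT", "HT")} == {
            "LT": 100, "MT": 100, "HT": 100,
        }

    def test_full_myelinopathy_draws_uniform_10_20(self):
        pop = build_sgn_population(500, NeuropathyConfig(myelinopathy_pct=100.0), seed=1)
        assert pop.l_u_um.min() >= 10.0 and pop.l_u_um.max() <= 20.0
        # uniform[10,20]: mean 15 +- 3*SE, variance ~ 100/12
        se = np.sqrt(100.0 / 12.0 / 1500)
        assert abs(pop.l_u_um.mean() - 15.0) < 3 * se

    @pytest.mark.parametrize("pct,expected_removed", [(50.0, 50), (100.0, 100)])
    def test_ht_synaptopathy_removes_only_ht(self, pct, expected_removed):
        pop = build_sgn_population(
            100, NeuropathyConfig(synaptopathy_kind="HT", synaptopathy_pct=pct), seed=2
        )
        removed = ~pop.intact
        assert removed.sum() == expected_removed
        assert set(pop.fiber_class[removed]) == {"HT"}

    def test_random_synaptopathy_removes_same_count_across_classes(self):
        pop = build_sgn_population(
            100, NeuropathyConfig(synaptopathy_kind="random", synaptopathy_pct=100.0), seed=3
        )
        assert (~pop.intact).sum() == 100

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            build_sgn_population(0, NeuropathyConfig(), seed=0)
        with pytest.raises(ValueError):
            NeuropathyConfig(myelinopathy_pct=120.0)
        with pytest.raises(ValueError):
            NeuropathyConfig(synaptopathy_kind="LT")


class TestEarOffsets:
    @pytest.mark.parametrize(
        "itd,expected",
        [(0.0, (0.0, 0.0)), (0.5, (0.0, 0.5)), (-0.5, (0.5, 0.0))],
    )
    def test_sign_convention(self, itd, expected):
        assert ear_arrival_offsets(itd) == expected

    def test_out_of_range_itd_rejected(self):
        with pytest.raises(ValueError):
            ear_arrival_offsets(2.5)


class TestReleaseTrains:
    def test_non_intact_synapses_are_silent(self, control_stim):
        pop = build_sgn_population(
            10, NeuropathyConfig(synaptopathy_kind="random", synaptopathy_pct=100.0), seed=0
        )
        rel = generate_release_trains(pop, control_stim, PeripheryParams(), seed=1)
        for i in np.flatnonzero(~pop.intact):
            assert len(rel.trains[i]) == 0

    def test_poisson_count_statistics_match_closed_form(self):
        """Event counts over many seeds match the analytic mean of the
        intensity integral, with variance ~ mean (Poisson law)."""
        params = PeripheryParams()
        stim = SoundStimulus(200.0, 50.0, 100.0, 0.0)
        pop = build_sgn_population(1, NeuropathyConfig(), seed=0)
        # LT fiber is index 0; analytic mean rate = driven + spontaneous
        mean_rate = params.driven_rate(FiberClass.LT, 50.0) + params.spontaneous_rate_hz
        expected = mean_rate * 0.1
        counts = [
            len(generate_release_trains(pop, stim, params, seed=s).trains[0])
            for s in range(400)
        ]
        counts = np.asarray(counts, dtype=float)
        se = np.sqrt(expected / len(counts))
        assert abs(counts.mean() - expected) < 3 * se
        # variance within 20% of the mean
        assert 0.8 < counts.var() / counts.mean() < 1.2

    def test_far_subthreshold_level_leaves_spontaneous_rate(self):
        params = PeripheryParams()
        stim = SoundStimulus(200.0, -60.0, 200.0, 0.0)
        pop = build_sgn_population(50, NeuropathyConfig(), seed=4)
        rel = generate_release_trains(pop, stim, params, seed=5)
        rate = rel.total_events() / 150 / 0.2
        expected = params.spontaneous_rate_hz
        assert abs(rate - expected) < 4 * np.sqrt(expected / (150 * 0.2))

    def test_intensity_time_average_equals_driven_plus_spont(self, control_stim):
        params = PeripheryParams()
        t = np.linspace(0.0, 100.0, 200001)
        lam = release_intensity(t, control_stim, FiberClass.MT, params, 0.0)
        avg = np.trapezoid(lam, t) / 100.0
        want = params.driven_rate(FiberClass.MT, 50.0) + params.spontaneous_rate_hz
        assert avg == pytest.approx(want, rel=1e-3)

    def test_release_vs_increases_with_phase_locking_exponent(self, control_stim):
        pop = build_sgn_population(30, NeuropathyConfig(), seed=6)
        vs = []
        for e in (1.0, 4.0, 8.0):
            params = PeripheryParams(phase_locking_exponent=e, spontaneous_rate_hz=0.0,
                                     max_driven_rate_hz=300.0)
            rel = generate_release_trains(pop, control_stim, params, seed=7)
            phases = 2 * np.pi * np.mod(np.concatenate(rel.trains), 5.0) / 5.0
            vs.append(vector_strength(phases))
        assert vs[0] < vs[1] < vs[2]


class TestTransduction:
    def test_identity_transduction(self, control_stim):
        """p = 1 and zero jitter: spikes are releases shifted by the latency."""
        params = PeripheryParams(firing_prob_intercept=1.0, firing_prob_slope_per_um=0.0,
                                 jitter_intercept_ms=0.0, jitter_slope_ms_per_um=0.0,
                                 max_driven_rate_hz=40.0, spontaneous_rate_hz=0.0)
        pop = build_sgn_population(5, NeuropathyConfig(), seed=0)
        rel = generate_release_trains(pop, control_stim, params, seed=1)
        sgn = transduce_to_sgn_spikes(pop, rel, params, seed=2)
        for i in range(pop.n_fibers):
            r = rel.trains[i]
            keep = [r[0]] if len(r) else []
            for x in r[1:]:
                if x - keep[-1] >= params.refractory_ms:
                    keep.append(x)
            np.testing.assert_allclose(sgn.trains[i], np.asarray(keep) + 0.5, atol=1e-12)

    def test_refractory_drops_close_spikes(self):
        params = PeripheryParams(firing_prob_intercept=1.0, firing_prob_slope_per_um=0.0,
                                 jitter_intercept_ms=0.0, jitter_slope_ms_per_um=0.0)
        pop = build_sgn_population(1, NeuropathyConfig(), seed=0)
        from socsim.periphery import ReleaseTrainSet

        rel = ReleaseTrainSet(side="left", trains=[np.array([10.0, 10.1])] + [np.empty(0)] * 2)
        sgn = transduce_to_sgn_spikes(pop, rel, params, seed=1)
        assert len(sgn.trains[0]) == 1

    def test_myelinopathy_lowers_rate_and_synchrony(self, control_stim):
        """Monte-Carlo: the 100% myelinopathy population fires fewer, less
        phase-locked spikes than the homogeneous control (p and sigma are
        monotone in L_u).  Probed below release saturation: at the default
        burst-regime rates the refractory period masks the rate effect (the
        spike-probability loss is absorbed by surplus releases), so the
        transduction monotonicity is only visible at moderate drive."""
        params = PeripheryParams(max_driven_rate_hz=300.0)
        rates = {0.0: [], 100.0: []}
        vs = {0.0: [], 100.0: []}
        for s in range(100):
            for level in (0.0, 100.0):
                pop = build_sgn_population(6, NeuropathyConfig(myelinopathy_pct=level), seed=s)
                rel = generate_release_trains(pop, control_stim, params, seed=1000 + s)
                sgn = transduce_to_sgn_spikes(pop, rel, params, seed=2000 + s)
                t = sgn.pooled()
                rates[level].append(len(t))
                vs[level].append(vector_strength(2 * np.pi * np.mod(t, 5.0) / 5.0))
        assert np.mean(rates[100.0]) < np.mean(rates[0.0])
        assert np.mean(vs[100.0]) < np.mean(vs[0.0])

    def test_negative_jitter_rejected(self):
        with pytest.raises(ValueError):
            PeripheryParams(jitter_intercept_ms=-0.1)


class TestSynaptopathyRateShares:
    def test_random_removal_is_rate_proportional(self, control_stim):
        """Expected SGN population rate under 100% random synaptopathy is
        ~2/3 of control (proportional to surviving synapse count)."""
        params = PeripheryParams()
        ratios = []
        for s in range(6):
            tot = {}
            for kind, pct in (("none", 0.0), ("random", 100.0)):
                pop = build_sgn_population(
                    100, NeuropathyConfig(synaptopathy_kind=kind, synaptopathy_pct=pct), seed=s
                )
                rel = generate_release_trains(pop, control_stim, params, seed=100 + s)
                sgn = transduce_to_sgn_spikes(pop, rel, params, seed=200 + s)
                tot[kind] = sgn.total_spikes()
            ratios.append(tot["random"] / tot["none"])
        assert np.mean(ratios) == pytest.approx(2.0 / 3.0, abs=0.02)

    def test_ht_removal_cheaper_than_random_at_50db(self, control_stim):
        """At 50 dB the HT class is configured weakest, so full HT loss costs
        a smaller rate fraction than random loss of the same synapse count."""
        params = PeripheryParams()
        tot = {}
        for kind in ("none", "HT", "random"):
            pct = 0.0 if kind == "none" else 100.0
            pop = build_sgn_population(
                100, NeuropathyConfig(synaptopathy_kind=kind, synaptopathy_pct=pct), seed=9
            )
            rel = generate_release_trains(pop, control_stim, params, seed=10)
            sgn = transduce_to_sgn_spikes(pop, rel, params, seed=11)
            tot[kind] = sgn.total_spikes()
        assert tot["none"] > tot["HT"] > tot["random"]


class TestJitter:
    def _spikes(self):
        rng = np.random.default_rng(0)
        return SpikeTrainSet("SGN", "left", 0,
                             [np.sort(rng.uniform(0, 100, rng.integers(5, 40)))
                              for _ in range(20)])

    def test_zero_jitter_is_identity(self):
        s = self._spikes()
        j = jitter_spike_trains(s, 0.0, seed=1)
        for a, b in zip(s.trains, j.trains):
            np.testing.assert_array_equal(a, b)

    def test_counts_preserved_sorted_nonnegative(self):
        s = self._spikes()
        j = jitter_spike_trains(s, 2.5, seed=2)
        assert j.total_spikes() == s.total_spikes()
        for b in j.trains:
            assert np.all(np.diff(b) >= 0)
            assert np.all(b >= 0.0)

    def test_shift_magnitudes_bounded(self):
        # sorting is 1-Lipschitz in the sup norm, so sorted displacements are
        # bounded by delta_max whenever no spike is clipped at zero
        s = SpikeTrainSet("SGN", "left", 0, [np.linspace(10.0, 90.0, 50)])
        j = jitter_spike_trains(s, 2.5, seed=3)
        assert np.max(np.abs(j.trains[0] - s.trains[0])) <= 2.5 + 1e-12
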