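"""Circuit model: EIF dynamics, network construction, schedules, engine."""

import numpy as np
import pytest

from spinalsynergy.circuit import (
    ConnectionSpec,
    InputSchedule,
    NetworkSpec,
    NeuronParameters,
    PopulationSpec,
    RateSeries,
    build_default_network,
    density_snapshot,
    eif_drift,
    make_afferent_condition,
    make_cortical_drive,
    simulate,
)


class TestEifDrift:
    def test_at_rest_is_tiny_positive(self):
        # Closed form: delta_T * exp((v_rest - v_thres)/delta_T) / tau
        assert eif_drift(-70.0, NeuronParameters()) == pytest.approx(3.4959e-5, rel=1e-3)

    def test_at_soft_threshold(self):
        # (-14 + 1.48) / 3.3
        assert eif_drift(-56.0, NeuronParameters()) == pytest.approx(-3.7939, rel=1e-3)

    def test_small_delta_T_approaches_leaky_integrator(self):
        p = NeuronParameters(delta_T=1e-9)
        v = -63.0
        assert eif_drift(v, p) == pytest.approx(-(v - p.v_rest) / p.tau, rel=1e-6)

    def test_vectorized_and_finite_above_cutoff(self):
        p = NeuronParameters()
        out = eif_drift(np.array([-80.0, -70.0, -51.0, 0.0]), p)
        assert out.shape == (4,)
        assert np.all(np.isfinite(out))


class TestParameterInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"v_rest": -50.0},          # v_rest >= v_thres
            {"v_spike": -60.0},         # v_spike <= v_thres
            {"tau": 0.0},
            {"delta_T": -1.0},
            {"t_refractory": -1.0},
        ],
    )
    def test_invalid_neuron_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NeuronParameters(**kwargs)

    def test_invalid_connections_rejected(self):
        with pytest.raises(ValueError):
            ConnectionSpec("A", "B", 0.0, 10)
        with pytest.raises(ValueError):
            ConnectionSpec("A", "B", 0.1, 0)
        with pytest.raises(ValueError):
            ConnectionSpec("A", "B", 0.1, 10, delay=-1.0)

    def test_schedule_invariants(self):
        with pytest.raises(ValueError):
            InputSchedule("x", ((0.0, 1.0), (0.0, 2.0)))  # non-increasing times
        with pytest.raises(ValueError):
            InputSchedule("x", ((0.0, -1.0),))            # negative rate

    def test_unresolved_endpoint_rejected(self):
        pops = [PopulationSpec("A", NeuronParameters(), 10)]
        conns = [ConnectionSpec("A", "Ghost", 0.1, 10)]
        with pytest.raises(ValueError, match="Ghost"):
            NetworkSpec(pops, conns, inputs=[])


class TestDefaultNetwork:
    def test_eight_populations(self):
        net = build_default_network()
        assert len(net.populations) == 8

    def test_published_connection_rows(self):
        net = build_default_network()

        def row(target, source):
            matches = [c for c in net.connections
                       if c.target == target and c.source == source]
            assert len(matches) == 1
            return matches[0]

        c = row("MN-RF", "InhibRF")
        assert (c.efficacy, c.n_connections, c.delay) == (-0.052, 70, 2.0)
        c = row("MN-RF", "ExtensorInterneurons")
        assert (c.efficacy, c.n_connections) == (-0.052, 20)
        c = row("MN-ST", "ExtensorInterneurons")
        assert (c.efficacy, c.n_connections) == (0.052, 70)
        c = row("ExtensorInterneurons", "FlexorInterneurons")
        assert (c.efficacy, c.n_connections) == (-0.052, 70)
        c = row("FlexorInterneurons", "ExtensorInterneurons")
        assert (c.efficacy, c.n_connections) == (-0.052, 70)
        assert row("MN-VL", "Background").rate_hz == 320.0
        assert row("InhibRF", "Background").rate_hz == 300.0
        assert row("FlexorInterneurons", "senFlInt").efficacy == 0.1

    def test_motor_pools_have_no_direct_afferent_input(self):
        net = build_default_network()
        for c in net.connections:
            if c.target.startswith("MN-"):
                assert c.source not in ("senFlInt", "senExtInt", "senInhRF")


class TestCorticalDrive:
    def test_mid_hold_at_peak(self):
        s = make_cortical_drive()
        assert s.rate(500 + 1000 + 2500) == pytest.approx(20.0)

    def test_zero_peak_identically_zero(self):
        s = make_cortical_drive(peak=0.0)
        t = np.linspace(0, 8000, 100)
        assert np.all(np.asarray(s.rate(t)) == 0.0)

    def test_linear_ramp_midpoint(self):
        s = make_cortical_drive(t_start=500.0, peak=20.0, ramp=1000.0)
        assert s.rate(1000.0) == pytest.approx(10.0)

    def test_negative_durations_rejected(self):
        with pytest.raises(ValueError):
            make_cortical_drive(ramp=0.0)
        with pytest.raises(ValueError):
            make_cortical_drive(hold=-1.0)


class TestAfferentConditions:
    @pytest.mark.parametrize(
        "position,angle,plateau",
        [(1, 0, 150.0), (1, 20, 75.0), (1, 60, 38.0), (1, 90, 0.0),
         (2, 20, 38.0)],
    )
    def test_senflint_plateaus(self, position, angle, plateau):
        sched = make_afferent_condition(position, angle)
        assert sched["senFlInt"].rate(3000.0) == pytest.approx(plateau)

    def test_full_extension_identical_between_positions(self):
        s1 = make_afferent_condition(1, 0)
        s2 = make_afferent_condition(2, 0)
        for name in ("senFlInt", "senExtInt", "senInhRF"):
            assert s1[name].breakpoints == s2[name].breakpoints

    def test_seninhrf_only_in_position_two(self):
        assert make_afferent_condition(2, 20)["senInhRF"].rate(3000.0) == 50.0
        assert make_afferent_condition(1, 20)["senInhRF"].rate(3000.0) == 0.0

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            make_afferent_condition(3, 0)
        with pytest.raises(ValueError):
            make_afferent_condition(1, 45)


class TestEngine:
    def test_zero_input_zero_noise_is_silent(self):
        p = NeuronParameters(sigma_noise=0.0)
        net = NetworkSpec(
            populations=[PopulationSpec("A", p, 40), PopulationSpec("B", p, 40)],
            connections=[ConnectionSpec("B", "A", 0.1, 50, 1.0)],
            inputs=[InputSchedule("off", ((0.0, 0.0), (500.0, 0.0)))],
            seed=1,
        )
        res = simulate(net, 400.0)
        assert np.all(res["A"].rates == 0.0)
        assert np.all(res["B"].rates == 0.0)

    def test_determinism_bit_identical(self, small_net):
        r1 = simulate(small_net, 600.0)
        r2 = simulate(small_net, 600.0)
        for name in r1.rates:
            np.testing.assert_array_equal(r1[name].rates, r2[name].rates)

    def test_seed_changes_output(self, small_net):
        r1 = simulate(small_net, 600.0)
        small_net.seed = 124
        r2 = simulate(small_net, 600.0)
        assert any(
            not np.array_equal(r1[n].rates, r2[n].rates) for n in r1.rates
        )

    def test_sampling_grid(self, small_net):
        res = simulate(small_net, 600.0)
        t = res["MN-RF"].times
        assert t[0] == pytest.approx(small_net.rate_sample_interval)
        assert np.allclose(np.diff(t), small_net.rate_sample_interval)

    def test_rate_series_validation(self):
        with pytest.raises(ValueError):
            RateSeries("x", np.arange(3.0), np.array([1.0, -2.0, 0.0]))
        with pytest.raises(ValueError):
            RateSeries("x", np.arange(3.0), np.zeros(2))


class TestDensity:
    def test_mass_normalized_and_rest_concentrated(self):
        p = NeuronParameters(sigma_noise=0.0)
        net = NetworkSpec(
            populations=[PopulationSpec("A", p, 200)],
            connections=[ConnectionSpec("A", "Drive", 0.1, 10, rate_hz=0.0)],
            inputs=[],
            seed=2,
        )
        res = simulate(net, 100.0, membrane_times=[50.0])
        h = density_snapshot(res, "A", 50.0)
        assert h.mass.sum() == pytest.approx(1.0, abs=1e-9)
        centers = (h.bin_edges[:-1] + h.bin_edges[1:]) / 2
        assert abs(centers[np.argmax(h.mass)] - p.v_rest) < 1.0

    def test_drive_shifts_mass_toward_spike_cutoff(self):
        net = build_default_network(ensemble_size=150, seed=5)
        res = simulate(net, 3000.0, membrane_times=[250.0, 2500.0],
                       membrane_populations=["MN-RF"])
        before = density_snapshot(res, "MN-RF", 250.0)
        during = density_snapshot(res, "MN-RF", 2500.0)
        centers = (before.bin_edges[:-1] + before.bin_edges[1:]) / 2
        hi = centers > -56.0  # mass above the soft threshold
        assert during.mass[hi].sum() > before.mass[hi].sum()

    def test_unknown_population_rejected(self, small_net):
        res = simulate(small_net, 100.0, membrane_times=[50.0])
        with pytest.raises(KeyError):
            density_snapshot(res, "Nope", 50.0)
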