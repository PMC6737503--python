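"""Unit tests for the LIF network primitives."""

import numpy as np
import pytest

from ftsts.network import (
    ConfigurationError,
    NetworkParams,
    build_connectivity,
    detect_and_reset,
    lif_period,
    membrane_step,
    synapse_step,
    synaptic_drive,
)
from ftsts.simulate import SimulationConfig, run_simulation


class TestNetworkParams:
    def test_defaults_follow_published_table(self):
        p = NetworkParams()
        assert (p.n_e, p.n_i) == (1600, 400)
        assert p.mu_e == 20.8 and p.mu_i == 18.0
        assert p.v_threshold == 20.0 and p.v_reset == 0.0
        assert p.J["EI"] == 100.0
        assert p.C["IE"] == pytest.approx(600.0)  # 0.3 * N_tot
        assert p.delay_steps == 50

    @pytest.mark.parametrize(
        "kw",
        [
            dict(dt=0.0),
            dict(n_e=0),
            dict(v_threshold=0.0),  # equals v_reset
            dict(t_delay=5.05),  # not a multiple of dt
            dict(epsilon={"IE": 1.5, "EI": 0.1}),
            dict(tau_m=-1.0),
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            NetworkParams(**kw)

    def test_per_neuron_tau_m_vector(self):
        tau = np.linspace(8, 12, 30)
        p = NetworkParams(n_e=20, n_i=10, tau_m=tau)
        assert np.array_equal(p.tau_m_vector(), tau)
        with pytest.raises(ConfigurationError):
            NetworkParams(n_e=20, n_i=10, tau_m=tau[:-1])


class TestConnectivity:
    def test_full_connectivity_two_neuron(self, rng):
        p = NetworkParams(n_e=1, n_i=1, epsilon={"IE": 1.0, "EI": 1.0},
                          C={"IE": 10.0, "EI": 10.0})
        projs = build_connectivity(p, {"IE": {}, "EI": {}}, rng)
        assert projs["IE"].adjacency.all() and projs["EI"].adjacency.all()

    def test_zero_probability_gives_empty_adjacency(self, rng):
        p = NetworkParams(n_e=10, n_i=5, epsilon={"IE": 0.0, "EI": 0.0})
        projs = build_connectivity(p, {"IE": {}}, rng)
        assert not projs["IE"].adjacency.any()
        assert projs["IE"].n_synapses == 0

    def test_synapse_count_matches_binomial_expectation(self, rng):
        p = NetworkParams()  # 1600 x 400, epsilon 0.1
        projs = build_connectivity(p, {"IE": {}}, rng)
        n = projs["IE"].n_synapses
        mean, sd = 64000.0, np.sqrt(640000 * 0.1 * 0.9)
        assert abs(n - mean) < 3 * sd

    def test_recurrent_projections_exclude_self_connections(self, rng):
        p = NetworkParams(n_e=50, n_i=20,
                          epsilon={"IE": 1.0, "EI": 1.0, "EE": 1.0, "II": 1.0})
        projs = build_connectivity(p, {"EE": {}, "II": {}}, rng)
        assert not np.diag(projs["EE"].adjacency).any()
        assert not np.diag(projs["II"].adjacency).any()

    def test_unknown_projection_label_rejected(self, rng):
        p = NetworkParams()
        with pytest.raises(ConfigurationError):
            build_connectivity(p, {"XY": {}}, rng)


class TestSynapticDrive:
    def _proj(self, rng, source="E"):
        p = NetworkParams(n_e=4, n_i=2, epsilon={"IE": 1.0, "EI": 1.0},
                          C={"IE": 600.0, "EI": 600.0})
        label = "IE" if source == "E" else "EI"
        return build_connectivity(p, {label: {}}, rng)[label]

    def test_zero_state_gives_zero_drive(self, rng):
        proj = self._proj(rng)
        Z = synaptic_drive(proj, np.zeros(2))
        assert np.all(Z == 0.0)

    def test_drive_arithmetic(self, rng):
        # J = 100 mV, C = 600, summed S = 6 -> 1 mV per target neuron
        proj = self._proj(rng)
        proj.J, proj.C = 100.0, 600.0
        Z = synaptic_drive(proj, np.array([6.0, 6.0]))
        assert Z == pytest.approx([1.0, 1.0])

    def test_inhibitory_source_drives_negative(self, rng):
        proj = self._proj(rng, source="I")
        Z = synaptic_drive(proj, np.array([1.0] * 4))
        assert np.all(Z < 0)


class TestSynapseCascade:
    def test_quiescence(self):
        X, S = np.zeros(3), np.zeros(3)
        for _ in range(100):
            X, S = synapse_step(X, S, np.zeros(3), 1.0, 1.0, 0.1)
        assert np.all(X == 0.0) and np.all(S == 0.0)

    def test_single_arrival_matches_analytic_solution(self):
        # tau_r = tau_d = 1 ms: S(t) = W * t * exp(-t), peak W/e at t = 1 ms
        dt = 0.01
        X, S = np.zeros(1), np.zeros(1)
        X, S = synapse_step(X, S, np.array([1.0]), 1.0, 1.0, dt)
        trace = [S[0]]
        for _ in range(int(3.0 / dt)):
            X, S = synapse_step(X, S, np.zeros(1), 1.0, 1.0, dt)
            trace.append(S[0])
        trace = np.asarray(trace)
        t_peak = np.argmax(trace) * dt
        assert trace.max() == pytest.approx(np.exp(-1.0), abs=0.01)
        assert t_peak == pytest.approx(1.0, abs=0.05)

    def test_linearity_of_superposed_arrivals(self):
        dt = 0.1
        # response to two arrivals = sum of single-arrival responses
        def response(arrival_steps, n_steps=80):
            X, S = np.zeros(1), np.zeros(1)
            out = []
            for k in range(n_steps):
                wa = np.array([2.5]) if k in arrival_steps else np.zeros(1)
                X, S = synapse_step(X, S, wa, 1.0, 1.0, dt)
                out.append(S[0])
            return np.asarray(out)

        combined = response({3, 17})
        assert combined == pytest.approx(response({3}) + response({17}), rel=1e-12)


class TestMembraneAndReset:
    def test_fixed_point_at_zero_input(self):
        v = np.zeros(4)
        out = membrane_step(v, np.zeros(4), np.zeros(4), np.zeros(4),
                            np.full(4, 10.0), np.zeros(4), 0.1, np.zeros(4))
        assert np.all(out == 0.0)

    def test_single_euler_step_arithmetic(self):
        # v=0, mu=20.8, dt=0.1, tau_m=10 -> one step gives 0.208 mV
        out = membrane_step(np.zeros(1), np.zeros(1), np.zeros(1),
                            np.array([20.8]), np.array([10.0]), np.zeros(1),
                            0.1, np.zeros(1))
        assert out[0] == pytest.approx(0.208)

    def test_non_finite_drive_raises(self):
        with pytest.raises(FloatingPointError):
            membrane_step(np.zeros(1), np.array([np.nan]), np.zeros(1),
                          np.zeros(1), np.array([10.0]), np.zeros(1),
                          0.1, np.zeros(1))

    def test_threshold_uses_greater_equal_and_resets(self):
        v = np.array([19.9, 20.0, 25.0])
        spikes = detect_and_reset(v, 20.0, 0.0)
        assert spikes.tolist() == [1, 2]
        assert v.tolist() == [19.9, 0.0, 0.0]

    def test_all_neurons_may_spike_in_one_step(self):
        v = np.full(100, 21.0)
        spikes = detect_and_reset(v, 20.0, 0.0)
        assert spikes.size == 100 and np.all(v == 0.0)


class TestDeterministicLifPeriod:
    def test_closed_form_value(self):
        assert lif_period(20.8, 20.0, 0.0, 10.0) == pytest.approx(
            10.0 * np.log(26.0), rel=1e-12
        )

    def test_simulated_period_matches_closed_form_within_dt(self):
        p = NetworkParams(n_e=1, n_i=1, sigma_e=0.0, sigma_i=0.0,
                          epsilon={"IE": 0.0, "EI": 0.0})
        cfg = SimulationConfig(params=p, plasticity={}, initial_weight={},
                               burn_in=400.0, seed=0)
        res = run_simulation(cfg)
        et, _ = res.spikes.population("E")
        periods = np.diff(et)
        assert periods.size >= 10
        assert np.allclose(periods, periods[0])  # perfectly regular
        assert abs(periods[0] - 10.0 * np.log(26.0)) <= p.dt

    def test_halving_dt_changes_period_by_less_than_one_percent(self):
        periods = {}
        for dt in (0.1, 0.05):
            p = NetworkParams(n_e=1, n_i=1, sigma_e=0.0, sigma_i=0.0,
                              epsilon={"IE": 0.0, "EI": 0.0}, dt=dt)
            cfg = SimulationConfig(params=p, plasticity={}, initial_weight={},
                                   burn_in=400.0, seed=0)
            res = run_simulation(cfg)
            et, _ = res.spikes.population("E")
            periods[dt] = np.diff(et).mean()
        assert abs(periods[0.1] - periods[0.05]) / periods[0.05] < 0.01


class TestDelayContract:
    def test_spike_influences_drive_no_earlier_than_delay(self):
        # single E neuron driven to spike once; its effect on the I neuron's
        # synaptic state must appear exactly t_delay after the spike
        p = NetworkParams(n_e=1, n_i=1, sigma_e=0.0, sigma_i=0.0, mu_i=0.0,
                          epsilon={"IE": 1.0, "EI": 0.0},
                          C={"IE": 1.0, "EI": 1.0})
        cfg = SimulationConfig(params=p, projections=("IE",), plasticity={},
                               initial_weight={"IE": 300.0}, burn_in=80.0, seed=0)
        res = run_simulation(cfg, engine="python")
        et, _ = res.spikes.population("E")
        it, _ = res.spikes.population("I")
        assert et.size >= 1 and it.size >= 1
        # I is silent (mu_i = 0) unless kicked by the delayed E spike: the
        # earliest possible I spike follows the first E spike by >= t_delay
        assert it[0] >= et[0] + p.t_delay
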