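"""Unit and property tests for the plasticity rules.

The central check is oracle equivalence: the trace-based pair-rule
accumulation over arbitrary spike trains must equal the explicit
sum of the pair kernel over all (pre, post) spike pairs.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect

from ftsts.network import NetworkParams, build_connectivity
from ftsts.plasticity import (
    HebbianStdpParams,
    PlasticityState,
    SymmetricStdpParams,
    apply_pair_stdp,
    apply_symmetric_stdp,
    decay_traces,
    increment_traces,
    make_rule,
    record_spike_times,
    stdp_kernel,
    step_traces,
    symmetric_kernel,
)

TABLE = HebbianStdpParams()  # published values
DT = 0.1


class TestKernel:
    def test_pre_before_post_value(self):
        # eta*a_LTP*A0*exp(-10/20) = 0.25*1*0.005*e^-0.5
        assert stdp_kernel(10.0, TABLE) == pytest.approx(
            0.25 * 1.0 * 0.005 * np.exp(-0.5), rel=1e-12
        )

    def test_post_before_pre_value(self):
        assert stdp_kernel(-10.0, TABLE) == pytest.approx(
            0.25 * (-1.1) * 0.005 * np.exp(-10.0 / 22.0), rel=1e-12
        )

    def test_zero_learning_rate_gives_zero(self):
        p = HebbianStdpParams(eta_e=0.0)
        lags = np.array([-30.0, -1.0, 1.0, 30.0])
        assert np.all(stdp_kernel(lags, p) == 0.0)

    def test_simultaneous_pair_contributes_nothing(self):
        assert stdp_kernel(0.0, TABLE) == 0.0

    def test_sign_structure_hebbian(self):
        lags = np.linspace(0.1, 80.0, 50)
        assert np.all(np.asarray(stdp_kernel(lags, TABLE)) > 0)
        assert np.all(np.asarray(stdp_kernel(-lags, TABLE)) < 0)

    def test_anti_hebbian_flips_signs(self):
        anti = make_rule("anti_hebbian")
        lags = np.linspace(0.1, 80.0, 50)
        assert np.all(np.asarray(stdp_kernel(lags, anti)) < 0)
        assert np.all(np.asarray(stdp_kernel(-lags, anti)) > 0)

    def test_kernel_decays_monotonically_to_zero(self):
        lags = np.linspace(0.5, 200.0, 400)
        branch = np.asarray(stdp_kernel(lags, TABLE))
        assert np.all(np.diff(branch) < 0)
        assert branch[-1] < 1e-7


class TestPresets:
    def test_hebbian_preset_is_published_table(self):
        p = make_rule("hebbian")
        assert (p.a_ltp, p.a_ltd) == (1.0, -1.1)
        assert (p.tau_ltp, p.tau_ltd) == (20.0, 22.0)
        assert (p.eta_e, p.a0) == (0.25, 0.005)

    def test_anti_hebbian_preset(self):
        p = make_rule("anti_hebbian")
        assert (p.a_ltp, p.a_ltd) == (-1.1, 1.0)

    def test_ltp_dominant_preset(self):
        p = make_rule("ltp_dominant")
        assert (p.a_ltp, p.a_ltd) == (1.01, -1.0)
        assert (p.tau_ltp, p.tau_ltd) == (20.0, 20.0)

    def test_symmetric_preset(self):
        p = make_rule("symmetric")
        assert (p.c_p, p.c_d, p.tau_p, p.tau_d) == (0.038, 0.02, 10.0, 25.0)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            make_rule("oja")


class TestTraces:
    def test_decay_over_one_time_constant(self):
        st_ = PlasticityState.zeros(1, 1)
        st_.pre_trace[0] = 0.005
        for _ in range(200):  # 20 ms at dt=0.1, tau_ltp = 20 ms
            decay_traces(st_, DT, TABLE)
        assert st_.pre_trace[0] == pytest.approx(0.005 * np.exp(-1.0), rel=1e-9)

    def test_spike_increments_by_a0(self):
        st_ = PlasticityState.zeros(2, 2)
        step_traces(st_, np.array([1]), np.array([0]), DT, TABLE)
        assert st_.pre_trace[1] == pytest.approx(0.005)
        assert st_.post_trace[0] == pytest.approx(0.005)

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=200))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_traces_never_negative(self, spike_pattern):
        st_ = PlasticityState.zeros(1, 1)
        for s in spike_pattern:
            spikes = np.array([0]) if s else np.array([], dtype=int)
            step_traces(st_, spikes, spikes, DT, TABLE)
            assert st_.pre_trace[0] >= 0 and st_.post_trace[0] >= 0


def _single_synapse_projection(plastic=True, w0=1.0):
    rng = np.random.default_rng(0)
    p = NetworkParams(n_e=1, n_i=1, epsilon={"IE": 1.0, "EI": 1.0},
                      C={"IE": 10.0, "EI": 10.0})
    proj = build_connectivity(
        p, {"IE": {"plastic": plastic, "init_w": w0, "w_min": -1e9, "w_max": 1e9}},
        rng)["IE"]
    return proj


def _run_pair_rule(pre_steps, post_steps, params, n_steps, w0=1.0):
    """Drive the trace-based rule with prescribed spike trains (steps)."""
    proj = _single_synapse_projection(w0=w0)
    state = PlasticityState.zeros(1, 1)
    for k in range(n_steps):
        pre = np.array([0]) if k in pre_steps else np.array([], dtype=int)
        post = np.array([0]) if k in post_steps else np.array([], dtype=int)
        decay_traces(state, DT, params)
        apply_pair_stdp(proj, state, pre, post, params)
        increment_traces(state, pre, post, params)
    return proj.W[0, 0] - w0


def _all_pairs_oracle(pre_steps, post_steps, params):
    total = 0.0
    for a in pre_steps:
        for b in post_steps:
            total += stdp_kernel((b - a) * DT, params)
    return total


class TestPairRule:
    def test_single_pair_reduces_to_kernel(self):
        # pre at 0 ms, post at 10 ms
        dw = _run_pair_rule({0}, {100}, TABLE, 150)
        assert dw == pytest.approx(stdp_kernel(10.0, TABLE), rel=1e-12)

    @given(
        st.sets(st.integers(0, 300), min_size=1, max_size=10),
        st.sets(st.integers(0, 300), min_size=1, max_size=10),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_trace_accumulation_equals_all_pairs_sum(self, pre, post):
        dw = _run_pair_rule(pre, post, TABLE, 320)
        oracle = _all_pairs_oracle(pre, post, TABLE)
        assert dw == pytest.approx(oracle, rel=1e-9, abs=1e-15)

    def test_anti_hebbian_negates_with_swapped_windows(self):
        pre, post = {0, 40, 111}, {25, 60, 200}
        anti = make_rule("anti_hebbian")
        dw = _run_pair_rule(pre, post, anti, 260)
        assert dw == pytest.approx(_all_pairs_oracle(pre, post, anti), rel=1e-9)
        # every isolated pair has the opposite sign of the Hebbian rule
        for lag in (-15.0, -1.0, 1.0, 15.0):
            assert np.sign(stdp_kernel(lag, anti)) == -np.sign(stdp_kernel(lag, TABLE))

    def test_repeated_post_before_pre_drives_weight_to_lower_bound(self):
        rng = np.random.default_rng(0)
        p = NetworkParams(n_e=1, n_i=1, epsilon={"IE": 1.0, "EI": 1.0},
                          C={"IE": 10.0, "EI": 10.0})
        proj = build_connectivity(
            p, {"IE": {"plastic": True, "init_w": 0.3, "w_min": 0.1, "w_max": 2.9}},
            rng)["IE"]
        state = PlasticityState.zeros(1, 1)
        w_hist = [proj.W[0, 0]]
        for cycle in range(400):
            for k in range(120):  # post at step 0, pre at step 10 (1 ms later)
                post = np.array([0]) if k == 0 else np.array([], dtype=int)
                pre = np.array([0]) if k == 10 else np.array([], dtype=int)
                decay_traces(state, DT, TABLE)
                apply_pair_stdp(proj, state, pre, post, TABLE)
                increment_traces(state, pre, post, TABLE)
            w_hist.append(proj.W[0, 0])
        w_hist = np.asarray(w_hist)
        assert np.all(np.diff(w_hist) <= 1e-15)
        assert w_hist[-1] == pytest.approx(0.1)  # hard saturation at the bound

    def test_weight_bounds_always_respected(self):
        proj = _single_synapse_projection()
        proj.w_min, proj.w_max = 0.1, 2.9
        state = PlasticityState.zeros(1, 1)
        rng = np.random.default_rng(5)
        for _ in range(2000):
            pre = np.array([0]) if rng.random() < 0.2 else np.array([], dtype=int)
            post = np.array([0]) if rng.random() < 0.2 else np.array([], dtype=int)
            decay_traces(state, DT, TABLE)
            apply_pair_stdp(proj, state, pre, post, TABLE)
            increment_traces(state, pre, post, TABLE)
            assert 0.1 <= proj.W[0, 0] <= 2.9


class TestSymmetricRule:
    SYM = SymmetricStdpParams()

    def test_kernel_at_zero_isi(self):
        assert symmetric_kernel(0.0, self.SYM) == pytest.approx(0.018)

    def test_zero_crossing_matches_bisection_oracle(self):
        root = bisect(lambda x: symmetric_kernel(x, self.SYM), 1.0, 30.0,
                      xtol=1e-10)
        analytic = np.log(0.038 / 0.02) / (1.0 / 10.0 - 1.0 / 25.0)
        assert analytic == pytest.approx(root, abs=1e-6)
        assert analytic == pytest.approx(10.6976, abs=1e-3)
        assert self.SYM.zero_crossing == pytest.approx(root, abs=1e-6)

    def test_long_isi_depresses(self):
        expect = 0.038 * np.exp(-3.0) - 0.02 * np.exp(-1.2)
        assert symmetric_kernel(30.0, self.SYM) == pytest.approx(expect, rel=1e-12)
        assert expect < 0

    def test_no_update_without_opposite_side_spike(self):
        proj = _single_synapse_projection()
        state = PlasticityState.zeros(1, 1)
        apply_symmetric_stdp(proj, state, np.array([0]), np.array([], dtype=int),
                             5.0, self.SYM)
        assert proj.W[0, 0] == 1.0

    def test_event_pairs_with_last_opposite_spike(self):
        proj = _single_synapse_projection()
        state = PlasticityState.zeros(1, 1)
        # post fires at t=0; pre fires at t=4 -> one event with ISI 4
        record_spike_times(state, np.array([], dtype=int), np.array([0]), 0.0)
        apply_symmetric_stdp(proj, state, np.array([0]), np.array([], dtype=int),
                             4.0, self.SYM)
        assert proj.W[0, 0] - 1.0 == pytest.approx(symmetric_kernel(4.0, self.SYM))
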