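"""Euler integration loop: configuration, execution, recording.

:func:`run_simulation` advances the network in fixed order per step —
synaptic drive, membrane update, threshold detection, plasticity, trace
bookkeeping, delayed spike delivery, recording — with the stimulation
protocol applied between burn-in and a weight-triggered stop rule.  Two
engines exist: the compiled default (:mod:`ftsts._kernel`) and a slow pure
NumPy reference (``engine="python"``) that performs identical arithmetic and
is used to cross-validate the compiled loop on small networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import metrics as _metrics
from ._kernel import run_chunk
from .network import (
    ConfigurationError,
    NetworkParams,
    build_connectivity,
    detect_and_reset,
    membrane_step,
    synapse_step,
    synaptic_drive,
)
from .plasticity import (
    HebbianStdpParams,
    PlasticityState,
    SymmetricStdpParams,
    apply_pair_stdp,
    apply_symmetric_stdp,
    decay_traces,
    increment_traces,
)
from .stimulation import BoundStimulus, StimulusProtocol, bind_protocol

__all__ = ["SimulationConfig", "SpikeRecord", "SimulationResult", "run_simulation"]


def _default_plasticity() -> dict:
    return {"IE": HebbianStdpParams()}


def _default_initial_weight() -> dict:
    return {"IE": 290.0}


def _default_bounds() -> dict:
    return {"IE": (10.0, 290.0)}


@dataclass
class SimulationConfig:
    """Everything needed to run (and re-run bit-identically) one simulation.

    Durations are in ms.  The run consists of three phases: ``burn_in``
    without stimulation, up to ``stim_max`` with the protocol active (cut
    short by its stop rule), and ``post`` unstimulated.  ``initial_weight``
    gives the initial mean synaptic weight J*W in mV per projection
    (static projections default to coupling 1, i.e. J*W = J).
    ``plateau = (window_ms, tol_mV)`` optionally ends an unstimulated run
    early once the sampled E-to-I weight changes by less than ``tol_mV``
    over ``window_ms`` (used for attractor-convergence runs).
    """

    params: NetworkParams = field(default_factory=NetworkParams)
    projections: tuple = ("IE", "EI")
    plasticity: dict = field(default_factory=_default_plasticity)
    initial_weight: dict = field(default_factory=_default_initial_weight)
    w_bounds: dict = field(default_factory=_default_bounds)
    protocol: Optional[StimulusProtocol] = None
    burn_in: float = 0.0
    stim_max: float = 0.0
    post: float = 0.0
    plateau: Optional[tuple] = None
    min_duration: float = 0.0
    record_spikes: bool = True
    sample_every_ms: float = 10.0
    chunk_ms: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.stim_max < 0 or self.post < 0:
            raise ConfigurationError("phase durations must be non-negative")
        if self.stim_max > 0 and self.protocol is None:
            raise ConfigurationError("stim_max > 0 requires a protocol")
        se = self.sample_every_ms / self.params.dt
        if abs(se - round(se)) > 1e-9 or round(se) < 1:
            raise ConfigurationError("sample_every_ms must be a multiple of dt")
        for label in self.plasticity:
            if label not in self.projections:
                raise ConfigurationError(f"plastic projection {label} not built")
        for label, rule in self.plasticity.items():
            if label == "EI" and not isinstance(rule, HebbianStdpParams):
                raise ConfigurationError("I-to-E plasticity supports the pair rule only")
            if label in ("EE", "II"):
                raise ConfigurationError("recurrent projections are static")

    @property
    def duration(self) -> float:
        return self.burn_in + self.stim_max + self.post

    def manifest(self) -> dict:
        """JSON-serializable echo of the fully resolved configuration."""
        import dataclasses

        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    "__type__": type(obj).__name__,
                    **{k: enc(v) for k, v in dataclasses.asdict(obj).items()},
                }
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return enc(self)


@dataclass
class SpikeRecord:
    """Time-stamped spikes: parallel arrays of times (ms) and neuron ids.

    Neuron ids ``0 .. n_e-1`` are excitatory, ``n_e .. n_e+n_i-1`` inhibitory.
    """

    times: np.ndarray
    ids: np.ndarray
    n_e: int
    n_i: int

    def population(self, pop: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.ids < self.n_e if pop == "E" else self.ids >= self.n_e
        return self.times[mask], self.ids[mask]

    def __len__(self) -> int:
        return self.times.size


@dataclass
class SimulationResult:
    spikes: SpikeRecord
    weight_times: np.ndarray
    weights: dict  # label -> mean J*W series (mV)
    stop_time: Optional[float]  # stop-rule crossing time (None if never fired)
    stim_on_time: Optional[float]  # protocol activation time
    stim_off_time: Optional[float]  # deactivation (stop rule or window end)
    stim_log: Optional[tuple]  # (times, mean|V| over E, mean|V| over I)
    period_T: Optional[float]
    t_end: float
    final_weight: dict  # label -> final mean J*W (mV)
    config: SimulationConfig

    @property
    def stim_duration(self) -> Optional[float]:
        """Protocol-on duration in ms (the desynchronization/resynchronization time)."""
        if self.stim_on_time is None or self.stim_off_time is None:
            return None
        return self.stim_off_time - self.stim_on_time

    def sync_series(self, t_start: float, t_stop: float, dt_eval: float = 1.0):
        """R(t) of the excitatory population on a regular grid."""
        return _metrics.sync_series(
            self.spikes.times, self.spikes.ids, self.spikes.n_e, t_start, t_stop, dt_eval
        )

    def windowed_R(self, t0: float, t1: float) -> float:
        times, R = self.sync_series(t0, t1)
        return _metrics.windowed_R(times, R, t0, t1)


_DUMMY_W = np.zeros((1, 1))
_DUMMY_M = np.zeros((1, 1), dtype=bool)
_DUMMY_V = np.zeros(1)


class _State:
    """Prepared arrays for the integration loop (shared by both engines)."""

    def __init__(self, config: SimulationConfig):
        p = config.params
        self.config = config
        self.p = p
        ss = np.random.SeedSequence(config.seed)
        rng_conn, rng_init, rng_noise, rng_stim = (
            np.random.default_rng(s) for s in ss.spawn(4)
        )
        self.rng_noise = rng_noise
        self.rng_stim = rng_stim

        proj_opts: dict[str, dict] = {}
        for label in config.projections:
            plastic = label in config.plasticity
            opts: dict = {"plastic": plastic}
            if label in config.initial_weight:
                opts["init_w"] = config.initial_weight[label] / p.J[label]
            if plastic:
                lo, hi = config.w_bounds.get(label, (10.0, 290.0))
                opts["w_min"] = lo / p.J[label]
                opts["w_max"] = hi / p.J[label]
            proj_opts[label] = opts
        self.projs = build_connectivity(p, proj_opts, rng_conn)

        N = p.n_tot
        self.v = rng_init.uniform(p.v_reset, p.v_threshold, N)
        tau = p.tau_m_vector()
        self.tau_m = tau
        self.a_leak = p.dt / tau
        self.mu = np.concatenate([np.full(p.n_e, p.mu_e), np.full(p.n_i, p.mu_i)])
        self.sigma = np.concatenate(
            [np.full(p.n_e, p.sigma_e), np.full(p.n_i, p.sigma_i)]
        )
        # fixed-step Euler integration of the sigma*sqrt(tau_m)*chi(t) term:
        # per-step noise std sigma * dt / sqrt(tau_m)
        self.sigma_amp = self.sigma * (p.dt / np.sqrt(tau))
        self.ring = np.zeros((p.delay_steps, N), dtype=np.uint8)
        self.X = {lbl: np.zeros(pr.adjacency.shape[0]) for lbl, pr in self.projs.items()}
        self.S = {lbl: np.zeros(pr.adjacency.shape[0]) for lbl, pr in self.projs.items()}
        self.last_spike_t = np.full(N, -np.inf)

        self.pstate: dict[str, PlasticityState] = {}
        for label, rule in config.plasticity.items():
            pr = self.projs[label]
            n_post, n_pre = pr.adjacency.shape
            if isinstance(rule, (HebbianStdpParams, SymmetricStdpParams)):
                self.pstate[label] = PlasticityState.zeros(n_pre, n_post)
            else:
                raise ConfigurationError(f"unknown plasticity rule for {label}")

        self.sample_every = int(round(config.sample_every_ms / p.dt))

    def proj_or_dummy(self, label: str):
        if label in self.projs:
            pr = self.projs[label]
            g = pr.sign * (pr.J / pr.C)
            return True, pr.W, pr.adjacency, g, self.X[label], self.S[label]
        return False, _DUMMY_W, _DUMMY_M, 0.0, _DUMMY_V.copy(), _DUMMY_V.copy()

    def rule_code(self, label: str) -> int:
        rule = self.config.plasticity.get(label)
        if rule is None:
            return 0
        return 2 if isinstance(rule, SymmetricStdpParams) else 1


def _kernel_args(st: _State):
    """Constant (per-run) kernel arguments describing projections and rules."""
    cfg, p = st.config, st.p
    has_ie, W_ie, M_ie, g_ie, X_ie, S_ie = st.proj_or_dummy("IE")
    has_ei, W_ei, M_ei, g_ei, X_ei, S_ei = st.proj_or_dummy("EI")
    has_ee, W_ee, M_ee, g_ee, X_ee, S_ee = st.proj_or_dummy("EE")
    has_ii, W_ii, M_ii, g_ii, X_ii, S_ii = st.proj_or_dummy("II")

    rule_ie = st.rule_code("IE")
    rule_ei = st.rule_code("EI")
    hp = cfg.plasticity.get("IE")
    if rule_ie == 1:
        coeff_ltp_ie = hp.eta_e * hp.a_ltp
        coeff_ltd_ie = hp.eta_e * hp.a_ltd
        a0_ie = hp.a0
        dec_pre_ie = np.exp(-p.dt / hp.tau_ltp)
        dec_post_ie = np.exp(-p.dt / hp.tau_ltd)
        pre_tr_ie = st.pstate["IE"].pre_trace
        post_tr_ie = st.pstate["IE"].post_trace
        sym = (0.0, 0.0, 1.0, 1.0)
    elif rule_ie == 2:
        coeff_ltp_ie = coeff_ltd_ie = a0_ie = 0.0
        dec_pre_ie = dec_post_ie = 1.0
        pre_tr_ie, post_tr_ie = _DUMMY_V.copy(), _DUMMY_V.copy()
        sym = (hp.c_p, hp.c_d, hp.tau_p, hp.tau_d)
    else:
        coeff_ltp_ie = coeff_ltd_ie = a0_ie = 0.0
        dec_pre_ie = dec_post_ie = 1.0
        pre_tr_ie, post_tr_ie = _DUMMY_V.copy(), _DUMMY_V.copy()
        sym = (0.0, 0.0, 1.0, 1.0)
    if rule_ie:
        pr = st.projs["IE"]
        wlo_ie, whi_ie = pr.w_min, pr.w_max
    else:
        wlo_ie, whi_ie = 0.0, 0.0

    ep = cfg.plasticity.get("EI")
    if rule_ei == 1:
        coeff_ltp_ei = ep.eta_e * ep.a_ltp
        coeff_ltd_ei = ep.eta_e * ep.a_ltd
        a0_ei = ep.a0
        dec_pre_ei = np.exp(-p.dt / ep.tau_ltp)
        dec_post_ei = np.exp(-p.dt / ep.tau_ltd)
        pre_tr_ei = st.pstate["EI"].pre_trace
        post_tr_ei = st.pstate["EI"].post_trace
        pr = st.projs["EI"]
        wlo_ei, whi_ei = pr.w_min, pr.w_max
    else:
        coeff_ltp_ei = coeff_ltd_ei = a0_ei = 0.0
        dec_pre_ei = dec_post_ei = 1.0
        pre_tr_ei, post_tr_ei = _DUMMY_V.copy(), _DUMMY_V.copy()
        wlo_ei, whi_ei = 0.0, 0.0

    jw_scale_ie = (
        st.projs["IE"].J / st.projs["IE"].n_synapses
        if "IE" in st.projs and st.projs["IE"].n_synapses
        else 0.0
    )
    jw_scale_ei = (
        st.projs["EI"].J / st.projs["EI"].n_synapses
        if "EI" in st.projs and st.projs["EI"].n_synapses
        else 0.0
    )
    return dict(
        proj=(
            has_ie, W_ie, M_ie, g_ie, X_ie, S_ie,
            has_ei, W_ei, M_ei, g_ei, X_ei, S_ei,
            has_ee, W_ee, M_ee, g_ee, X_ee, S_ee,
            has_ii, W_ii, M_ii, g_ii, X_ii, S_ii,
        ),
        rules=(
            rule_ie, coeff_ltp_ie, coeff_ltd_ie, a0_ie, dec_pre_ie, dec_post_ie,
            pre_tr_ie, post_tr_ie, wlo_ie, whi_ie, *sym,
            rule_ei, coeff_ltp_ei, coeff_ltd_ei, a0_ei, dec_pre_ei, dec_post_ei,
            pre_tr_ei, post_tr_ei, wlo_ei, whi_ei,
        ),
        scales=(jw_scale_ie, jw_scale_ei),
    )


def _exec_chunk_numba(st, ka, step0, n_steps, noise, stim, stop_mode, stop_thr):
    p = st.p
    cap = n_steps * p.n_tot
    spike_steps = np.empty(cap, dtype=np.int64)
    spike_ids = np.empty(cap, dtype=np.int64)
    n_samp_cap = n_steps // st.sample_every + 2
    w_ie = np.empty(n_samp_cap)
    w_ei = np.empty(n_samp_cap)
    smp_steps = np.empty(n_samp_cap, dtype=np.int64)
    n_spk, n_smp, stop_step = run_chunk(
        np.int64(step0), np.int64(n_steps), p.dt, p.n_e, p.n_i,
        st.v, st.a_leak, st.mu, st.sigma_amp, noise, stim,
        p.v_threshold, p.v_reset, st.ring,
        1.0 / p.tau_r, p.dt / p.tau_r, p.dt / p.tau_d,
        *ka["proj"], *ka["rules"], st.last_spike_t,
        spike_steps, spike_ids, np.int64(st.sample_every),
        *ka["scales"], w_ie, w_ei, smp_steps,
        np.int64(stop_mode), stop_thr,
    )
    return (
        spike_steps[:n_spk].copy(), spike_ids[:n_spk].copy(),
        w_ie[:n_smp].copy(), w_ei[:n_smp].copy(), smp_steps[:n_smp].copy(),
        int(stop_step),
    )


def _exec_chunk_python(st, ka, step0, n_steps, noise, stim, stop_mode, stop_thr):
    """Reference loop built from the module-level step operations.

    Operation order and arithmetic mirror the compiled kernel so that the
    two engines agree bit-for-bit on pair-STDP networks.
    """
    p = st.p
    cfg = st.config
    N = p.n_tot
    D = p.delay_steps
    order = [lbl for lbl in ("IE", "EI", "EE", "II") if lbl in st.projs]
    spk_steps, spk_ids = [], []
    w_ie_s, w_ei_s, smp_steps = [], [], []
    stop_step = -1
    for s in range(n_steps):
        g = step0 + s
        Z = np.zeros(N)
        for lbl in order:
            pr = st.projs[lbl]
            tgt = slice(0, p.n_e) if pr.target == "E" else slice(p.n_e, N)
            Z[tgt] += synaptic_drive(pr, st.S[lbl])
        st.v[:] = membrane_step(
            st.v, Z, stim[s], st.mu, st.tau_m, st.sigma, p.dt, noise[s]
        )
        spikes = detect_and_reset(st.v, p.v_threshold, p.v_reset)
        e_spikes = spikes[spikes < p.n_e]
        i_spikes = spikes[spikes >= p.n_e] - p.n_e
        spk_steps.extend([g] * spikes.size)
        spk_ids.extend(spikes.tolist())

        t_now = g * p.dt
        for lbl in ("IE", "EI"):
            rule = cfg.plasticity.get(lbl)
            if isinstance(rule, HebbianStdpParams):
                decay_traces(st.pstate[lbl], p.dt, rule)
        if spikes.size:
            for lbl in ("IE", "EI"):
                rule = cfg.plasticity.get(lbl)
                if rule is None:
                    continue
                pre_sp = e_spikes if lbl == "IE" else i_spikes
                post_sp = i_spikes if lbl == "IE" else e_spikes
                pst = st.pstate[lbl]
                if isinstance(rule, HebbianStdpParams):
                    apply_pair_stdp(st.projs[lbl], pst, pre_sp, post_sp, rule)
                    increment_traces(pst, pre_sp, post_sp, rule)
                else:
                    # last-spike arrays live in the global last_spike_t view
                    pst.last_pre = st.last_spike_t[: p.n_e]
                    pst.last_post = st.last_spike_t[p.n_e :]
                    apply_symmetric_stdp(
                        st.projs[lbl], pst, pre_sp, post_sp, t_now, rule
                    )
            st.last_spike_t[spikes] = t_now

        idx = g % D
        arriving = np.flatnonzero(st.ring[idx])
        for lbl in order:
            pr = st.projs[lbl]
            src = arriving[arriving < p.n_e] if pr.source == "E" else (
                arriving[arriving >= p.n_e] - p.n_e
            )
            wa = np.zeros(pr.adjacency.shape[0])
            for j in src:
                wa += pr.W[:, j] * pr.adjacency[:, j]
            st.X[lbl], st.S[lbl] = synapse_step(
                st.X[lbl], st.S[lbl], wa, p.tau_r, p.tau_d, p.dt
            )
        st.ring[idx] = 0
        st.ring[idx, spikes] = 1

        if (g + 1) % st.sample_every == 0:
            jw_ie = (
                _metrics.average_weight(st.projs["IE"]) if "IE" in st.projs else 0.0
            )
            jw_ei = (
                _metrics.average_weight(st.projs["EI"]) if "EI" in st.projs else 0.0
            )
            w_ie_s.append(jw_ie)
            w_ei_s.append(jw_ei)
            smp_steps.append(g)
            if stop_mode == 1 and jw_ie <= stop_thr:
                stop_step = g
                break
            if stop_mode == 2 and jw_ie >= stop_thr:
                stop_step = g
                break
    return (
        np.asarray(spk_steps, dtype=np.int64), np.asarray(spk_ids, dtype=np.int64),
        np.asarray(w_ie_s), np.asarray(w_ei_s),
        np.asarray(smp_steps, dtype=np.int64), stop_step,
    )


def run_simulation(config: SimulationConfig, engine: str = "numba") -> SimulationResult:
    """Run one simulation and return its recorded result.

    The run is bit-reproducible for a fixed ``config.seed``: connectivity,
    initial conditions, membrane noise and all protocol randomness derive
    from independent streams spawned from it.
    """
    if engine not in ("numba", "python"):
        raise ConfigurationError(f"unknown engine {engine!r}")
    st = _State(config)
    ka = _kernel_args(st)
    execute = _exec_chunk_numba if engine == "numba" else _exec_chunk_python
    p = config.params
    chunk_steps = max(1, int(round(config.chunk_ms / p.dt)))

    all_steps: list[np.ndarray] = []
    all_ids: list[np.ndarray] = []
    w_times = [0.0]
    w_ie = [config.initial_weight.get("IE", p.J["IE"]) if "IE" in st.projs else 0.0]
    w_ei = [config.initial_weight.get("EI", p.J["EI"]) if "EI" in st.projs else 0.0]
    stim_log_t: list[float] = []
    stim_log_e: list[float] = []
    stim_log_i: list[float] = []
    stop_time: Optional[float] = None
    period_T: Optional[float] = None

    bound: Optional[BoundStimulus] = None
    protocol = config.protocol
    g0 = 0

    def run_phase(duration, active, stop_mode, stop_thr, plateau):
        nonlocal g0, stop_time
        n_total = int(round(duration / p.dt))
        done = 0
        stopped = False
        while done < n_total:
            nc = min(chunk_steps, n_total - done)
            noise = st.rng_noise.standard_normal((nc, p.n_tot))
            if active and bound is not None:
                stim = bound.chunk(g0, nc)
            else:
                stim = np.zeros((nc, p.n_tot))
            sst, sid, wie, wei, smp, stop_step = execute(
                st, ka, g0, nc, noise, stim, stop_mode if active else 0, stop_thr
            )
            if config.record_spikes:
                all_steps.append(sst)
                all_ids.append(sid)
            ts = (smp + 1) * p.dt
            w_times.extend(ts.tolist())
            w_ie.extend(wie.tolist())
            w_ei.extend(wei.tolist())
            rel = smp - g0
            stim_log_t.extend(ts.tolist())
            stim_log_e.extend(np.abs(stim[rel, : p.n_e]).mean(axis=1).tolist())
            stim_log_i.extend(np.abs(stim[rel, p.n_e :]).mean(axis=1).tolist())
            if stop_step >= 0:
                g0 = stop_step + 1
                stop_time = stop_step * p.dt
                stopped = True
                break
            g0 += nc
            done += nc
            if plateau is not None and w_times[-1] >= config.min_duration:
                win, tol = plateau
                t_arr = np.asarray(w_times)
                sel = t_arr >= t_arr[-1] - win
                if sel.sum() >= 2 and t_arr[-1] - t_arr[sel][0] >= win * 0.99:
                    vals = np.asarray(w_ie)[sel]
                    if vals.max() - vals.min() < tol:
                        break
        return stopped

    # phase 1: burn-in
    run_phase(config.burn_in, False, 0, 0.0,
              config.plateau if protocol is None else None)

    # phase 2: stimulation
    if protocol is not None and protocol.kind != "none" and config.stim_max > 0:
        if protocol.kind in ("cr", "ftsts_cr") and protocol.cr.T is None:
            ts_arr = np.concatenate(all_steps) * p.dt if all_steps else np.empty(0)
            ids_arr = np.concatenate(all_ids) if all_ids else np.empty(0, dtype=int)
            e_times = ts_arr[ids_arr < p.n_e]
            t1 = g0 * p.dt
            period_T = _metrics.estimate_period(e_times, max(0.0, t1 - 2000.0), t1)
        bound = bind_protocol(
            protocol, p.n_e, p.n_i, p.dt, g0 * p.dt, config.stim_max,
            st.rng_stim, period_T,
        )
        stop_mode, stop_thr = 0, 0.0
        if protocol.stop_rule is not None:
            stop_mode = 1 if protocol.stop_rule.direction == "falling" else 2
            stop_thr = protocol.stop_rule.threshold
        stim_on_time = g0 * p.dt
        run_phase(config.stim_max, True, stop_mode, stop_thr, None)
        stim_off_time = stop_time if stop_time is not None else g0 * p.dt
        bound = None
    else:
        stim_on_time = stim_off_time = None

    # phase 3: post-stimulation
    run_phase(config.post, False, 0, 0.0, None)

    if all_steps:
        steps = np.concatenate(all_steps)
        ids = np.concatenate(all_ids)
    else:
        steps = np.empty(0, dtype=np.int64)
        ids = np.empty(0, dtype=np.int64)
    spikes = SpikeRecord(times=steps * p.dt, ids=ids, n_e=p.n_e, n_i=p.n_i)
    weights = {}
    if "IE" in st.projs:
        weights["IE"] = np.asarray(w_ie)
    if "EI" in st.projs:
        weights["EI"] = np.asarray(w_ei)
    final = {lbl: _metrics.average_weight(pr) for lbl, pr in st.projs.items()
             if pr.n_synapses}
    return SimulationResult(
        spikes=spikes,
        weight_times=np.asarray(w_times),
        weights=weights,
        stop_time=stop_time,
        stim_on_time=stim_on_time,
        stim_off_time=stim_off_time,
        stim_log=(
            np.asarray(stim_log_t), np.asarray(stim_log_e), np.asarray(stim_log_i)
        ),
        period_T=period_T,
        t_end=g0 * p.dt,
        final_weight=final,
        config=config,
    )
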