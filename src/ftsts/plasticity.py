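"""Synaptic weight update rules.

Two families are implemented, both operating on the dimensionless coupling
``W`` of a plastic :class:`~ftsts.network.Projection` (weights are reported as
``J*W`` in mV):

* a trace-based pair rule (Hebbian STDP and its anti-Hebbian and
  LTP-dominant variants).  Every presynaptic spike leaves an exponential
  trace with time constant ``tau_ltp``, every postsynaptic spike one with
  ``tau_ltd``; at a postsynaptic spike each incoming synapse is potentiated
  by ``eta_e * a_ltp * pre_trace`` and at a presynaptic spike each outgoing
  synapse changes by ``eta_e * a_ltd * post_trace`` (``a_ltd < 0`` for the
  Hebbian preset, i.e. depression).  Traces accumulate without reset, so the
  rule is exactly equivalent to summing the pair kernel
  :func:`stdp_kernel` over all spike pairs.

* a symmetric inter-spike-interval rule: at each spike of either side of a
  synapse the weight changes by ``c_p*exp(-|ISI|/tau_p) - c_d*exp(-|ISI|/tau_d)``
  where ISI is the lag to the last spike of the opposite side
  (nearest-spike pairing).  The sign depends only on |ISI|: short intervals
  potentiate, long intervals depress, with a zero crossing at
  ``ln(c_p/c_d) / (1/tau_p - 1/tau_d)``.

Weights are clipped to the projection bounds after every update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Projection

__all__ = [
    "HebbianStdpParams",
    "SymmetricStdpParams",
    "PlasticityState",
    "make_rule",
    "stdp_kernel",
    "symmetric_kernel",
    "decay_traces",
    "increment_traces",
    "step_traces",
    "apply_pair_stdp",
    "apply_symmetric_stdp",
    "record_spike_times",
]


@dataclass
class HebbianStdpParams:
    """Parameters of the trace-based pair STDP rule.

    ``a_ltd`` carries its own sign: negative for the Hebbian preset
    (post-before-pre depresses), positive for the anti-Hebbian one.
    """

    eta_e: float = 0.25
    a_ltp: float = 1.0
    a_ltd: float = -1.1
    tau_ltp: float = 20.0
    tau_ltd: float = 22.0
    a0: float = 0.005

    def __post_init__(self) -> None:
        if self.tau_ltp <= 0 or self.tau_ltd <= 0:
            raise ValueError("STDP time constants must be positive")
        if self.a0 <= 0:
            raise ValueError("A_0 must be positive")


@dataclass
class SymmetricStdpParams:
    """Parameters of the symmetric ISI rule."""

    c_p: float = 0.038
    c_d: float = 0.02
    tau_p: float = 10.0
    tau_d: float = 25.0

    def __post_init__(self) -> None:
        if min(self.c_p, self.c_d, self.tau_p, self.tau_d) <= 0:
            raise ValueError("symmetric-rule parameters must be positive")

    @property
    def zero_crossing(self) -> float:
        """|ISI| at which potentiation and depression balance exactly."""
        return np.log(self.c_p / self.c_d) / (1.0 / self.tau_p - 1.0 / self.tau_d)


#: published parameter presets, by name
_PRESETS = {
    "hebbian": dict(a_ltp=1.0, a_ltd=-1.1, tau_ltp=20.0, tau_ltd=22.0),
    "anti_hebbian": dict(a_ltp=-1.1, a_ltd=1.0, tau_ltp=20.0, tau_ltd=22.0),
    "ltp_dominant": dict(a_ltp=1.01, a_ltd=-1.0, tau_ltp=20.0, tau_ltd=20.0),
}


def make_rule(preset: str) -> HebbianStdpParams | SymmetricStdpParams:
    """Return the published parameter bundle for a named rule preset.

    Presets: ``hebbian`` (LTD-dominant pair rule), ``anti_hebbian`` (sign
    convention inverted, used on plastic I-to-E synapses), ``ltp_dominant``
    (pair rule with LTP slightly dominating, no bistability), ``symmetric``
    (the ISI rule).
    """
    if preset == "symmetric":
        return SymmetricStdpParams()
    try:
        return HebbianStdpParams(**_PRESETS[preset])
    except KeyError:
        raise ValueError(f"unknown plasticity preset: {preset!r}") from None


def stdp_kernel(delta_t, params: HebbianStdpParams):
    """Weight change for one isolated spike pair with lag ``delta_t = t_post - t_pre``.

    Pre-before-post (``delta_t > 0``) samples the LTP branch, post-before-pre
    the LTD branch; exactly simultaneous pairs contribute nothing.
    """
    dt = np.asarray(delta_t, dtype=float)
    ltp = params.eta_e * params.a_ltp * params.a0 * np.exp(-np.abs(dt) / params.tau_ltp)
    ltd = params.eta_e * params.a_ltd * params.a0 * np.exp(-np.abs(dt) / params.tau_ltd)
    out = np.where(dt > 0, ltp, np.where(dt < 0, ltd, 0.0))
    return out if out.ndim else float(out)


def symmetric_kernel(isi, params: SymmetricStdpParams):
    """Weight change of the symmetric rule for an inter-spike interval |ISI|."""
    isi = np.abs(np.asarray(isi, dtype=float))
    out = params.c_p * np.exp(-isi / params.tau_p) - params.c_d * np.exp(-isi / params.tau_d)
    return out if out.ndim else float(out)


@dataclass
class PlasticityState:
    """Per-neuron traces and bookkeeping for one plastic projection."""

    pre_trace: np.ndarray  # one per presynaptic neuron, time constant tau_ltp
    post_trace: np.ndarray  # one per postsynaptic neuron, time constant tau_ltd
    last_pre: np.ndarray  # last spike time per presynaptic neuron (ms, -inf if none)
    last_post: np.ndarray

    @classmethod
    def zeros(cls, n_pre: int, n_post: int) -> "PlasticityState":
        return cls(
            pre_trace=np.zeros(n_pre),
            post_trace=np.zeros(n_post),
            last_pre=np.full(n_pre, -np.inf),
            last_post=np.full(n_post, -np.inf),
        )


def decay_traces(state: PlasticityState, dt: float, params: HebbianStdpParams) -> None:
    """Exponentially decay both traces over one step (exact decay factor)."""
    state.pre_trace *= np.exp(-dt / params.tau_ltp)
    state.post_trace *= np.exp(-dt / params.tau_ltd)


def increment_traces(
    state: PlasticityState,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    params: HebbianStdpParams,
) -> None:
    """Add A_0 to the trace of every neuron that spiked this step."""
    state.pre_trace[pre_spikes] += params.a0
    state.post_trace[post_spikes] += params.a0


def step_traces(
    state: PlasticityState,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    dt: float,
    params: HebbianStdpParams,
) -> PlasticityState:
    """Decay traces over ``dt`` then add A_0 for this step's spikes."""
    decay_traces(state, dt, params)
    increment_traces(state, pre_spikes, post_spikes, params)
    return state


def _clip(projection: Projection) -> None:
    np.clip(projection.W, projection.w_min, projection.w_max, out=projection.W)
    projection.W *= projection.adjacency


def apply_pair_stdp(
    projection: Projection,
    state: PlasticityState,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    params: HebbianStdpParams,
) -> None:
    """Apply one step of the trace-based pair rule for this step's spikes.

    Must be called with traces decayed to the current step but *before*
    this step's increments, so that simultaneous pre/post pairs contribute
    no update.
    """
    if not projection.plastic:
        raise ValueError(f"projection {projection.label} is not plastic")
    W, M = projection.W, projection.adjacency
    touched = False
    if len(post_spikes):
        W[post_spikes] += (params.eta_e * params.a_ltp) * (
            state.pre_trace[None, :] * M[post_spikes]
        )
        touched = True
    if len(pre_spikes):
        W[:, pre_spikes] += (params.eta_e * params.a_ltd) * (
            state.post_trace[:, None] * M[:, pre_spikes]
        )
        touched = True
    if touched:
        _clip(projection)


def apply_symmetric_stdp(
    projection: Projection,
    state: PlasticityState,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    t_now: float,
    params: SymmetricStdpParams,
) -> None:
    """Apply the symmetric ISI rule for this step's spikes.

    Each spiking neuron updates its synapses against the *last* spike of the
    opposite side recorded before this step (no update while the opposite
    side has never fired).  Presynaptic events are processed before
    postsynaptic ones; call :func:`record_spike_times` afterwards.
    """
    if not projection.plastic:
        raise ValueError(f"projection {projection.label} is not plastic")
    W, M = projection.W, projection.adjacency
    touched = False
    for j in np.sort(pre_spikes):
        valid = np.isfinite(state.last_post)
        if not valid.any():
            continue
        dw = np.where(valid, symmetric_kernel(t_now - state.last_post, params), 0.0)
        W[:, j] += dw * M[:, j]
        touched = True
    for i in np.sort(post_spikes):
        valid = np.isfinite(state.last_pre)
        if not valid.any():
            continue
        dw = np.where(valid, symmetric_kernel(t_now - state.last_pre, params), 0.0)
        W[i, :] += dw * M[i, :]
        touched = True
    if touched:
        _clip(projection)


def record_spike_times(
    state: PlasticityState,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    t_now: float,
) -> None:
    state.last_pre[pre_spikes] = t_now
    state.last_post[post_spikes] = t_now
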