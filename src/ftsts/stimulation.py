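"""Stimulation waveform generators.

FTSTS delivers mirrored charge-balanced biphasic voltage pulses to the two
populations so that one population is forced to fire a fixed lag before the
other, steering spike-timing-dependent plasticity in a chosen direction.
Each cycle of period ``2*T_stim + T_neutral`` consists of a +U phase and a -U
phase (each ``T_stim`` wide) followed by a quiescent gap.  With the
``desynchronize`` polarity the inhibitory (postsynaptic) population receives
+U first and the excitatory population the exact negation, forcing
post-before-pre firing and hence depression of the E-to-I weights; the
``synchronize`` polarity swaps the two waveforms.  ``T_offset`` delays the
inhibitory train only (used with the symmetric ISI rule to select the forced
inter-spike interval).

Coordinated-reset (CR) style schedules split each population into ``n_sub``
subpopulations and stimulate one subpopulation per slot, ``n_sub`` slots per
period T, with a fresh uniform random slot ordering each period.  In ``cr``
mode each slot is a single rectangular pulse; in ``ftsts_cr`` mode each slot
delivers the full mirrored FTSTS pulse pair to the selected E/I subpopulation
pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .network import ConfigurationError

__all__ = [
    "FtstsParams",
    "CrParams",
    "StopRule",
    "StimulusProtocol",
    "ftsts_waveform_pair",
    "jittered_amplitudes",
    "cr_schedule",
    "apply_mixing",
    "BoundStimulus",
    "bind_protocol",
]


@dataclass
class FtstsParams:
    """FTSTS pulse-train parameters (amplitudes mV, durations ms)."""

    u_stim: float = 100.0
    t_stim: float = 1.0
    t_neutral: float = 10.0
    t_offset: float = 0.0
    polarity: Literal["desynchronize", "synchronize"] = "desynchronize"
    jitter: bool = False

    def __post_init__(self) -> None:
        if self.u_stim < 0:
            raise ConfigurationError("u_stim must be >= 0")
        if self.t_stim <= 0 or self.t_neutral < 0:
            raise ConfigurationError("t_stim must be > 0 and t_neutral >= 0")
        if self.polarity not in ("desynchronize", "synchronize"):
            raise ConfigurationError(f"unknown polarity {self.polarity!r}")

    @property
    def cycle_period(self) -> float:
        return 2.0 * self.t_stim + self.t_neutral


@dataclass
class CrParams:
    """Coordinated-reset schedule parameters.

    ``T`` is the stimulation period, equal to the intrinsic period of the
    synchronous network; leave ``None`` to have the simulator estimate it
    from pre-stimulation activity.  Slot spacing is ``T / n_sub``.
    """

    pulse: FtstsParams = field(default_factory=FtstsParams)
    n_sub: int = 4
    T: float | None = None
    mode: Literal["cr", "ftsts_cr"] = "ftsts_cr"

    def __post_init__(self) -> None:
        if self.n_sub < 1:
            raise ConfigurationError("n_sub must be >= 1")
        if self.T is not None and self.T <= 0:
            raise ConfigurationError("period T must be positive")


@dataclass
class StopRule:
    """Turn the protocol off permanently when the monitored mean J*W crosses
    ``threshold`` in the given direction ("falling" or "rising")."""

    threshold: float
    direction: Literal["falling", "rising"] = "falling"

    def __post_init__(self) -> None:
        if self.direction not in ("falling", "rising"):
            raise ConfigurationError(f"unknown stop direction {self.direction!r}")


@dataclass
class StimulusProtocol:
    """A stimulation protocol: waveform kind, parameters, stop rule, mixing."""

    kind: Literal["none", "ftsts", "cr", "ftsts_cr"] = "none"
    ftsts: FtstsParams | None = None
    cr: CrParams | None = None
    stop_rule: StopRule | None = None
    inseparable_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "ftsts", "cr", "ftsts_cr"):
            raise ConfigurationError(f"unknown protocol kind {self.kind!r}")
        if not 0.0 <= self.inseparable_fraction <= 1.0:
            raise ConfigurationError("inseparable_fraction must lie in [0, 1]")
        if self.kind == "ftsts" and self.ftsts is None:
            self.ftsts = FtstsParams()
        if self.kind in ("cr", "ftsts_cr") and self.cr is None:
            self.cr = CrParams(mode=self.kind)


def _unit_biphasic(tau: np.ndarray, t_stim: float, period: float) -> np.ndarray:
    """+1 on [0, T_stim), -1 on [T_stim, 2 T_stim), 0 otherwise, periodic.

    Negative times (before the train starts) give 0.
    """
    out = np.zeros_like(tau, dtype=float)
    started = tau >= 0.0
    ph = np.mod(tau, period)
    out[started & (ph < t_stim)] = 1.0
    out[started & (ph >= t_stim) & (ph < 2.0 * t_stim)] = -1.0
    return out


def ftsts_waveform_pair(
    params: FtstsParams,
    t,
    amplitudes: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Population waveform values (V_E, V_I) at time(s) ``t`` (ms from protocol onset).

    Both populations receive the same charge-balanced biphasic pulse (+U for
    ``T_stim`` then -U for ``T_stim``); the follower population's pulse is
    the leader's delayed by ``T_stim``, so the leader fires during its +U
    phase and the follower one pulse-width later — the forced spike-time
    lag is ``T_stim``.  (An exactly sign-mirrored pair cannot force follower
    spikes at the published amplitudes: the leading -U phase leaves the
    follower too hyperpolarized to reach threshold within ``T_stim``.)
    With ``desynchronize`` polarity the inhibitory population leads,
    forcing post-before-pre; ``synchronize`` swaps leader and follower.
    A non-zero ``T_offset`` (the symmetric-rule protocol variant) instead
    anchors the excitatory pulse at the cycle start and places the
    inhibitory pulse ``T_offset`` later, so the forced inter-spike interval
    equals ``T_offset``.  ``amplitudes`` optionally gives a per-cycle
    amplitude (jitter); otherwise every cycle uses ``u_stim``.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    P = params.cycle_period

    def wave(tau: np.ndarray) -> np.ndarray:
        base = _unit_biphasic(tau, params.t_stim, P)
        if amplitudes is None:
            return base * params.u_stim
        cyc = np.clip(np.floor(tau / P).astype(int), 0, len(amplitudes) - 1)
        return base * np.asarray(amplitudes, dtype=float)[cyc]

    if params.t_offset != 0.0:
        # offset variant (symmetric-rule protocols): the excitatory pulse
        # anchors the cycle and the inhibitory pulse is placed T_offset
        # later, so the forced inter-spike interval equals T_offset exactly
        v_e = wave(t)
        v_i = wave(t - params.t_offset)
    elif params.polarity == "desynchronize":
        v_i = wave(t)
        v_e = wave(t - params.t_stim)
    else:
        v_e = wave(t)
        v_i = wave(t - params.t_stim)
    if scalar:
        return float(v_e[0]), float(v_i[0])
    return v_e, v_i


def jittered_amplitudes(
    params: FtstsParams, n_pulses: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-cycle pulse amplitudes ~ Normal(U_stim, variance U_stim/10), truncated at 0."""
    if params.u_stim <= 0:
        raise ConfigurationError("jitter requires u_stim > 0")
    draws = rng.normal(params.u_stim, np.sqrt(params.u_stim / 10.0), n_pulses)
    return np.clip(draws, 0.0, None)


def cr_schedule(
    params: CrParams, n_periods: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Slot-to-subpopulation assignments for ``n_periods`` periods.

    Returns (perm_e, perm_i), each (n_periods x n_sub): ``perm_e[p, s]`` is
    the excitatory subpopulation stimulated in slot ``s`` of period ``p``.
    Every subpopulation is stimulated exactly once per period; orderings are
    fresh uniform permutations each period, independent for E and I.
    """
    perm_e = np.empty((n_periods, params.n_sub), dtype=np.int64)
    perm_i = np.empty((n_periods, params.n_sub), dtype=np.int64)
    for p in range(n_periods):
        perm_e[p] = rng.permutation(params.n_sub)
        perm_i[p] = rng.permutation(params.n_sub)
    return perm_e, perm_i


def apply_mixing(
    v_e: np.ndarray,
    v_i: np.ndarray,
    n_e: int,
    n_i: int,
    insep_e: np.ndarray,
    insep_i: np.ndarray,
) -> np.ndarray:
    """Per-neuron stimulus from population waveforms with partial inseparability.

    ``v_e``/``v_i`` are (n_steps,) population waveforms.  Separable neurons
    receive their own population's waveform; neurons flagged inseparable
    receive the sum of both (for exactly mirrored waveforms the sum is zero).
    Returns an (n_steps x n_e+n_i) array.
    """
    n_steps = v_e.shape[0]
    stim = np.empty((n_steps, n_e + n_i))
    stim[:, :n_e] = v_e[:, None]
    stim[:, n_e:] = v_i[:, None]
    if insep_e.size:
        stim[:, insep_e] += v_i[:, None]
    if insep_i.size:
        stim[:, n_e + insep_i] += v_e[:, None]
    return stim


class BoundStimulus:
    """A protocol bound to a concrete network: per-neuron waveform sampler.

    Randomness (jitter amplitudes, CR subpopulation split and per-period slot
    orderings, inseparable-neuron selection) is drawn once at bind time from
    the supplied generator, so a fixed seed reproduces the stimulus exactly.
    ``chunk(step0, n_steps)`` returns the (n_steps x N) stimulus for global
    steps ``step0 .. step0+n_steps-1``; times are measured from protocol
    onset ``t_on``.
    """

    def __init__(
        self,
        protocol: StimulusProtocol,
        n_e: int,
        n_i: int,
        dt: float,
        t_on: float,
        max_duration: float,
        rng: np.random.Generator,
        period_T: float | None = None,
    ) -> None:
        self.protocol = protocol
        self.n_e, self.n_i, self.dt, self.t_on = n_e, n_i, dt, t_on
        self.rng = rng
        k_e = int(round(protocol.inseparable_fraction * n_e))
        k_i = int(round(protocol.inseparable_fraction * n_i))
        self.insep_e = np.sort(rng.choice(n_e, size=k_e, replace=False))
        self.insep_i = np.sort(rng.choice(n_i, size=k_i, replace=False))
        self.amplitudes: np.ndarray | None = None
        if protocol.kind == "ftsts":
            p = protocol.ftsts
            if p.jitter:
                n_cycles = int(np.ceil(max_duration / p.cycle_period)) + 2
                self.amplitudes = jittered_amplitudes(p, n_cycles, rng)
        elif protocol.kind in ("cr", "ftsts_cr"):
            cr = protocol.cr
            self.T = cr.T if cr.T is not None else period_T
            if self.T is None:
                raise ConfigurationError(
                    "CR protocols need a period T (given or estimated)"
                )
            n_periods = int(np.ceil(max_duration / self.T)) + 2
            self.perm_e, self.perm_i = cr_schedule(cr, n_periods, rng)
            # random equal split of each population into n_sub subpopulations
            self.sub_of_e = rng.permutation(n_e) % cr.n_sub
            self.sub_of_i = rng.permutation(n_i) % cr.n_sub

    def chunk(self, step0: int, n_steps: int) -> np.ndarray:
        """Per-neuron stimulus for ``n_steps`` global steps starting at ``step0``."""
        N = self.n_e + self.n_i
        t = (step0 + np.arange(n_steps)) * self.dt - self.t_on
        kind = self.protocol.kind
        if kind == "none":
            return np.zeros((n_steps, N))
        if kind == "ftsts":
            v_e, v_i = ftsts_waveform_pair(self.protocol.ftsts, t, self.amplitudes)
            return apply_mixing(v_e, v_i, self.n_e, self.n_i, self.insep_e, self.insep_i)
        return self._cr_chunk(t)

    def _cr_chunk(self, t: np.ndarray) -> np.ndarray:
        cr = self.protocol.cr
        p = cr.pulse
        N = self.n_e + self.n_i
        stim = np.zeros((t.size, N))
        active = t >= 0.0
        spacing = self.T / cr.n_sub
        period_idx = np.floor_divide(t, self.T).astype(int)
        in_period = np.mod(t, self.T)
        slot = np.minimum(np.floor_divide(in_period, spacing).astype(int), cr.n_sub - 1)
        tau = in_period - slot * spacing  # time within the slot
        if cr.mode == "cr":
            val = np.where(active & (tau < p.t_stim), p.u_stim, 0.0)
            lead_i, follow_e = val, val
        else:
            # ftsts_cr: biphasic pair per slot, I subpopulation leads and the
            # E subpopulation receives the same pulse delayed by T_stim
            # (post-before-pre forcing, as in the plain FTSTS waveform)
            def bip(tt):
                out = np.zeros_like(tt)
                out[(tt >= 0) & (tt < p.t_stim)] = 1.0
                out[(tt >= p.t_stim) & (tt < 2.0 * p.t_stim)] = -1.0
                return out

            lead_i = p.u_stim * bip(tau)
            follow_e = p.u_stim * bip(tau - p.t_stim)
            lead_i[~active] = 0.0
            follow_e[~active] = 0.0
        e_sub = self.perm_e[np.clip(period_idx, 0, len(self.perm_e) - 1), slot]
        i_sub = self.perm_i[np.clip(period_idx, 0, len(self.perm_i) - 1), slot]
        for k in range(cr.n_sub):
            members_e = np.flatnonzero(self.sub_of_e == k)
            rows = np.flatnonzero(active & (e_sub == k))
            if rows.size and members_e.size:
                stim[np.ix_(rows, members_e)] = follow_e[rows, None]
            members_i = np.flatnonzero(self.sub_of_i == k)
            rows = np.flatnonzero(active & (i_sub == k))
            if rows.size and members_i.size:
                stim[np.ix_(rows, self.n_e + members_i)] = lead_i[rows, None]
        return stim

    def stimulus_at(self, t_abs: float) -> np.ndarray:
        """Per-neuron stimulus vector at one absolute time (ms)."""
        step = int(round(t_abs / self.dt))
        return self.chunk(step, 1)[0]


def bind_protocol(
    protocol: StimulusProtocol,
    n_e: int,
    n_i: int,
    dt: float,
    t_on: float,
    max_duration: float,
    rng: np.random.Generator,
    period_T: float | None = None,
) -> BoundStimulus:
    return BoundStimulus(protocol, n_e, n_i, dt, t_on, max_duration, rng, period_T)
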