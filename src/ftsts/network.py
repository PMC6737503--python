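"""Leaky integrate-and-fire E-I network: parameters, connectivity, single-step dynamics.

The network consists of an excitatory (E) and an inhibitory (I) population of
LIF neurons.  Projections between populations are labelled ``"<target><source>"``
following the usual matrix-index convention: ``"IE"`` is the E-to-I projection
(target I, source E), ``"EI"`` is I-to-E, plus optional recurrent ``"EE"`` and
``"II"``.

Membrane dynamics (Euler-Maruyama, step ``dt``)::

    v <- v + (dt/tau_m) * (-v + Z + mu + V_stim) + sigma*sqrt(dt/tau_m)*xi

with ``xi`` i.i.d. standard normal per neuron per step.  The synaptic input to
a target population is ``Z = sum_proj sign(source) * (J/C) * S`` where ``S`` is
the per-target-neuron output of a two-stage linear filter driven by delayed,
weight-scaled presynaptic spikes; inhibitory-source projections enter with a
negative sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "PROJECTION_LABELS",
    "NetworkParams",
    "Projection",
    "build_connectivity",
    "synaptic_drive",
    "synapse_step",
    "membrane_step",
    "detect_and_reset",
    "lif_period",
]

#: recognised projection labels, in canonical build order
PROJECTION_LABELS = ("IE", "EI", "EE", "II")


class ConfigurationError(ValueError):
    """Raised for invalid network or protocol configuration."""


def _default_J() -> dict:
    return {"IE": 100.0, "EI": 100.0, "EE": 50.0, "II": 50.0}


def _default_epsilon() -> dict:
    return {"IE": 0.1, "EI": 0.1, "EE": 0.1, "II": 0.1}


@dataclass
class NetworkParams:
    """All neuron, synapse and connectivity constants of the E-I network.

    Times are in ms, potentials in mV.  ``tau_m`` may be a scalar or a
    per-neuron vector of length ``n_e + n_i`` (excitatory neurons first) to
    model heterogeneous membrane time constants.  ``C`` defaults to
    ``0.3 * N_tot`` for the between-population projections and ``N_tot`` for
    the recurrent ones; it acts as a normalizing divisor of the summed
    synaptic output.
    """

    n_e: int = 1600
    n_i: int = 400
    tau_m: float | np.ndarray = 10.0
    mu_e: float = 20.8
    mu_i: float = 18.0
    sigma_e: float = 1.0
    sigma_i: float = 3.0
    v_reset: float = 0.0
    v_threshold: float = 20.0
    tau_d: float = 1.0
    tau_r: float = 1.0
    t_delay: float = 5.0
    dt: float = 0.1
    J: dict = field(default_factory=_default_J)
    C: dict | None = None
    epsilon: dict = field(default_factory=_default_epsilon)

    def __post_init__(self) -> None:
        if self.n_e < 1 or self.n_i < 1:
            raise ConfigurationError("n_e and n_i must be >= 1")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        for name in ("tau_d", "tau_r"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        tau_m = np.asarray(self.tau_m, dtype=float)
        if np.any(tau_m <= 0):
            raise ConfigurationError("tau_m must be positive")
        if tau_m.ndim == 1 and tau_m.size != self.n_tot:
            raise ConfigurationError("per-neuron tau_m must have length n_e + n_i")
        if self.v_threshold <= self.v_reset:
            raise ConfigurationError("v_threshold must exceed v_reset")
        steps = self.t_delay / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ConfigurationError("t_delay must be an integer multiple of dt")
        if self.C is None:
            self.C = {
                "IE": 0.3 * self.n_tot,
                "EI": 0.3 * self.n_tot,
                "EE": float(self.n_tot),
                "II": float(self.n_tot),
            }
        for lbl, eps in self.epsilon.items():
            if not 0.0 <= eps <= 1.0:
                raise ConfigurationError(f"epsilon[{lbl}] must lie in [0, 1]")

    @property
    def n_tot(self) -> int:
        return self.n_e + self.n_i

    @property
    def delay_steps(self) -> int:
        return int(round(self.t_delay / self.dt))

    def tau_m_vector(self) -> np.ndarray:
        """Membrane time constants as a per-neuron vector (E first, then I)."""
        tau = np.asarray(self.tau_m, dtype=float)
        if tau.ndim == 0:
            return np.full(self.n_tot, float(tau))
        return tau.copy()

    def pop_size(self, pop: str) -> int:
        return self.n_e if pop == "E" else self.n_i


@dataclass
class Projection:
    """One directed projection between populations.

    ``adjacency`` and ``W`` are (target x source) matrices; ``W`` is the
    dimensionless coupling, kept exactly zero wherever ``adjacency`` is
    False.  The synaptic weight reported everywhere is the product ``J * W``
    in mV; ``w_min``/``w_max`` bound the coupling of plastic projections so
    that ``J*W`` stays inside the configured range.
    """

    target: str
    source: str
    adjacency: np.ndarray
    W: np.ndarray
    J: float
    C: float
    plastic: bool = False
    w_min: float = 0.0
    w_max: float = np.inf

    @property
    def label(self) -> str:
        return self.target + self.source

    @property
    def sign(self) -> float:
        """Drive sign: excitatory sources depolarize, inhibitory hyperpolarize."""
        return -1.0 if self.source == "I" else 1.0

    @property
    def n_synapses(self) -> int:
        return int(self.adjacency.sum())

    def validate(self) -> None:
        if self.W.shape != self.adjacency.shape:
            raise ConfigurationError("W and adjacency shapes differ")
        if np.any(self.W[~self.adjacency] != 0.0):
            raise ConfigurationError("W must be zero off-adjacency")
        if self.plastic and self.n_synapses:
            w = self.W[self.adjacency]
            if w.min() < self.w_min - 1e-12 or w.max() > self.w_max + 1e-12:
                raise ConfigurationError("plastic couplings outside bounds")


def build_connectivity(
    params: NetworkParams,
    projections: Mapping[str, dict],
    rng: np.random.Generator,
) -> dict[str, Projection]:
    """Draw random connectivity for the requested projections.

    ``projections`` maps a label from :data:`PROJECTION_LABELS` to an options
    dict with optional keys ``plastic`` (bool), ``init_w`` (uniform initial
    coupling; defaults to 1.0, the static I-to-E value W_EI,0), ``w_min`` and
    ``w_max``.  Each ordered (target, source) pair is connected independently
    with probability ``epsilon[label]``; self-connections are excluded in the
    recurrent projections.
    """
    out: dict[str, Projection] = {}
    for label in PROJECTION_LABELS:
        if label not in projections:
            continue
        opts = dict(projections[label])
        tgt, src = label[0], label[1]
        if label not in params.epsilon:
            raise ConfigurationError(f"epsilon undefined for projection {label}")
        n_t, n_s = params.pop_size(tgt), params.pop_size(src)
        adj = rng.random((n_t, n_s)) < params.epsilon[label]
        if tgt == src:
            np.fill_diagonal(adj, False)
        init_w = float(opts.pop("init_w", 1.0))
        W = np.where(adj, init_w, 0.0)
        proj = Projection(
            target=tgt,
            source=src,
            adjacency=adj,
            W=W,
            J=params.J[label],
            C=params.C[label],
            plastic=bool(opts.pop("plastic", False)),
            w_min=float(opts.pop("w_min", 0.0)),
            w_max=float(opts.pop("w_max", np.inf)),
        )
        if opts:
            raise ConfigurationError(f"unknown projection options: {sorted(opts)}")
        proj.validate()
        out[label] = proj
    unknown = set(projections) - set(PROJECTION_LABELS)
    if unknown:
        raise ConfigurationError(f"unknown projection labels: {sorted(unknown)}")
    return out


def synaptic_drive(projection: Projection, S: np.ndarray) -> np.ndarray:
    """Per-target-neuron drive Z = sign * (J/C) * S in mV.

    ``S`` is the projection's synaptic state per target neuron (the filter
    output already summed over sources).  Drives are additive across
    projections onto the same target population.
    """
    return projection.sign * (projection.J / projection.C) * S


def synapse_step(
    X: np.ndarray,
    S: np.ndarray,
    weighted_arrivals: np.ndarray,
    tau_r: float,
    tau_d: float,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One Euler step of the two-stage synaptic cascade.

    ``weighted_arrivals[i]`` is the sum of couplings ``W[i, j]`` over source
    neurons ``j`` whose spikes (emitted ``t_delay`` earlier) arrive at target
    ``i`` this step.  The rise-stage state ``X`` decays with ``tau_r`` and
    receives ``W/tau_r`` per arrival; ``S`` low-passes ``X`` with ``tau_d``.
    """
    X = X + (dt / tau_r) * (-X)
    X = X + weighted_arrivals * (1.0 / tau_r)
    S = S + (dt / tau_d) * (-S + X)
    return X, S


def membrane_step(
    v: np.ndarray,
    Z: np.ndarray,
    V_stim: np.ndarray,
    mu: np.ndarray,
    tau_m: np.ndarray,
    sigma: np.ndarray,
    dt: float,
    noise: np.ndarray,
) -> np.ndarray:
    """One fixed-step Euler step of the LIF membrane equation.

    ``noise`` must contain one standard-normal draw per neuron.  The
    stochastic baseline term ``sigma*sqrt(tau_m)*chi(t)`` is integrated like
    the deterministic terms (multiplied by ``dt/tau_m``), giving a per-step
    noise standard deviation of ``sigma * dt / sqrt(tau_m)`` — the fixed-step
    solver convention under which the network exhibits its documented
    bistable synchronous/asynchronous regimes.
    """
    if not (np.all(np.isfinite(Z)) and np.all(np.isfinite(V_stim))):
        raise FloatingPointError("non-finite synaptic drive or stimulus")
    a = dt / tau_m
    return v + a * (((-v + Z) + mu) + V_stim) + (sigma * (dt / np.sqrt(tau_m))) * noise


def detect_and_reset(v: np.ndarray, v_threshold: float, v_reset: float) -> np.ndarray:
    """Return indices of neurons at or above threshold and reset them in place."""
    spikes = np.flatnonzero(v >= v_threshold)
    v[spikes] = v_reset
    return spikes


def lif_period(mu: float, v_threshold: float, v_reset: float, tau_m: float) -> float:
    """Closed-form inter-spike period of a noiseless, input-free LIF neuron.

    Valid for suprathreshold drive ``mu > v_threshold``; with ``v_reset = 0``
    this is ``tau_m * ln(mu / (mu - v_threshold))``.
    """
    if mu <= v_threshold:
        return np.inf
    return tau_m * np.log((mu - v_reset) / (mu - v_threshold))
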