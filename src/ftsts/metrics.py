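"""Synchrony and weight metrics.

The synchrony measure is the Kuramoto order parameter of the excitatory
population, computed from spike times: within each inter-spike interval a
neuron's phase falls linearly from 2*pi at one spike to 0 at the next,

    phi_k(t) = 2*pi * (t_{k,i+1} - t) / (t_{k,i+1} - t_{k,i}),

and R(t) e^{i psi(t)} is the mean unit phasor over neurons with a defined
phase at t (phase is undefined before a neuron's first and after its last
spike; such neurons are excluded and the mean renormalized by the valid
count).  R = 1 means perfect synchrony, R ~ 0 asynchrony (with a finite-size
floor of order 1/sqrt(N) for N independent phases).
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = [
    "spike_phases",
    "kuramoto",
    "sync_series",
    "windowed_R",
    "average_weight",
    "classify_regime",
    "estimate_period",
    "PeriodEstimationError",
]


class PeriodEstimationError(RuntimeError):
    """Raised when no periodicity can be detected in the population rate."""


def spike_phases(
    spike_times: np.ndarray,
    spike_ids: np.ndarray,
    n_neurons: int,
    times: np.ndarray,
) -> np.ndarray:
    """Phase matrix (n_neurons x len(times)), NaN where the phase is undefined.

    ``spike_times`` must be sorted; neurons with fewer than two spikes have an
    undefined phase everywhere.
    """
    times = np.asarray(times, dtype=float)
    phases = np.full((n_neurons, times.size), np.nan)
    order = np.argsort(spike_ids, kind="stable")
    ids_sorted = np.asarray(spike_ids)[order]
    ts_sorted = np.asarray(spike_times, dtype=float)[order]
    bounds = np.searchsorted(ids_sorted, np.arange(n_neurons + 1))
    for k in range(n_neurons):
        st = ts_sorted[bounds[k] : bounds[k + 1]]
        if st.size < 2:
            continue
        # interval index such that st[i] <= t < st[i+1]
        idx = np.searchsorted(st, times, side="right") - 1
        valid = (idx >= 0) & (idx < st.size - 1)
        i = idx[valid]
        t = times[valid]
        phases[k, valid] = 2.0 * np.pi * (st[i + 1] - t) / (st[i + 1] - st[i])
        # at exactly the spike time the phase is 2*pi (covered by formula)
    return phases


def kuramoto(phases: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Order parameter R, mean phase psi, and valid count from a phase matrix.

    ``phases`` is (n_neurons x n_times) with NaN marking undefined phases.
    Times with zero valid phases yield NaN R and psi.
    """
    phases = np.atleast_2d(phases)
    valid = np.isfinite(phases)
    count = valid.sum(axis=0)
    z = np.where(valid, np.exp(1j * np.where(valid, phases, 0.0)), 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_z = np.where(count > 0, z / np.maximum(count, 1), np.nan + 0j)
    R = np.abs(mean_z)
    psi = np.angle(mean_z)
    R[count == 0] = np.nan
    return R, psi, count


def sync_series(
    spike_times: np.ndarray,
    spike_ids: np.ndarray,
    n_e: int,
    t_start: float,
    t_stop: float,
    dt_eval: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """R(t) of the excitatory population on a regular grid (times, R)."""
    times = np.arange(t_start, t_stop, dt_eval)
    mask = spike_ids < n_e
    phases = spike_phases(spike_times[mask], spike_ids[mask], n_e, times)
    R, _, _ = kuramoto(phases)
    return times, R


def windowed_R(times: np.ndarray, R: np.ndarray, t0: float, t1: float) -> float:
    """Time-average of the defined R(t) samples in [t0, t1)."""
    sel = (times >= t0) & (times < t1)
    if not sel.any():
        raise ValueError("empty window")
    vals = R[sel]
    if not np.isfinite(vals).any():
        return np.nan
    return float(np.nanmean(vals))


def average_weight(projection) -> float:
    """Mean synaptic weight J*W in mV over existing synapses."""
    n = projection.n_synapses
    if n == 0:
        raise ValueError(f"projection {projection.label} has no synapses")
    return float(projection.J * projection.W[projection.adjacency].mean())


def classify_regime(avg_weight_mv: float, boundary: float = 100.0) -> str:
    """Basin of attraction of the bistable weight dynamics.

    Above the boundary the weight flows to the high (synchronous) attractor,
    below it to the low (asynchronous) one.
    """
    if avg_weight_mv > boundary:
        return "synchronous-basin"
    if avg_weight_mv < boundary:
        return "asynchronous-basin"
    return "boundary"


def estimate_period(
    spike_times: np.ndarray,
    t_start: float,
    t_stop: float,
    bin_ms: float = 1.0,
    min_coeff: float = 0.2,
) -> float:
    """Dominant oscillation period T (ms) of the population firing rate.

    Bins the pooled spike train, autocorrelates the mean-subtracted rate over
    the window and returns the lag of the first local maximum beyond zero lag.
    Raises :class:`PeriodEstimationError` when no peak reaches ``min_coeff``
    of the zero-lag autocorrelation (no detectable periodicity).
    """
    sel = (spike_times >= t_start) & (spike_times < t_stop)
    edges = np.arange(t_start, t_stop + bin_ms, bin_ms)
    rate, _ = np.histogram(spike_times[sel], bins=edges)
    x = rate.astype(float) - rate.mean()
    if np.allclose(x, 0.0):
        raise PeriodEstimationError("population rate is flat in the window")
    ac = signal.correlate(x, x, mode="full")[x.size - 1 :]
    ac = ac / ac[0]
    peaks, props = signal.find_peaks(ac[1:], height=min_coeff)
    if peaks.size == 0:
        raise PeriodEstimationError(
            "no off-zero autocorrelation peak; supply the period explicitly"
        )
    return float((peaks[0] + 1) * bin_ms)
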