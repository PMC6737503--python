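"""Scenario registry: each published experiment as a reproducible configuration.

Every scenario is a factory producing a :class:`~ftsts.simulate.SimulationConfig`
with the published network and pulse parameters.  Full scale is a
2,000-neuron network (1,600 E / 400 I; the large-network scenario uses
10,000).  ``scale`` shrinks the populations while keeping the per-neuron
in-degree (connection probability is raised in proportion) and the drive
normalizers C of the full-scale network, which preserves the mean synaptic
drive and its fluctuation statistics; weight and synchrony dynamics are then
comparable to full scale at a fraction of the cost.  ``DESK_SCALE`` (0.2,
i.e. 400 neurons; 0.1 for the 10,000-neuron scenario) is the default used by
the test-suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .metrics import classify_regime
from .network import ConfigurationError, NetworkParams
from .plasticity import make_rule
from .simulate import SimulationConfig, SimulationResult, run_simulation
from .stimulation import CrParams, FtstsParams, StimulusProtocol, StopRule

__all__ = [
    "Scenario",
    "list_scenarios",
    "get_scenario",
    "run_scenario",
    "make_fixture",
    "DESK_SCALE",
]

#: default shrink factor for quick (test/acceptance) runs
DESK_SCALE = 0.2

#: attractors and basin boundary of the bistable weight dynamics (mV)
HIGH_ATTRACTOR = 290.0
LOW_ATTRACTOR = 10.0
BASIN_BOUNDARY = 100.0


def scaled_network(
    n_e: int = 1600,
    n_i: int = 400,
    scale: float = 1.0,
    epsilon: Optional[dict] = None,
    **kwargs,
) -> NetworkParams:
    """Table-parameter network shrunk by ``scale`` with preserved in-degree.

    Population sizes are multiplied by ``scale``; every connection
    probability by ``1/scale`` (capped at 1); the C normalizers stay those
    of the full-scale network unless given explicitly.
    """
    if not 0 < scale <= 1:
        raise ConfigurationError("scale must lie in (0, 1]")
    eps = dict(epsilon or {"IE": 0.1, "EI": 0.1})
    n_tot_full = n_e + n_i
    if "C" not in kwargs or kwargs["C"] is None:
        kwargs["C"] = {
            "IE": 0.3 * n_tot_full,
            "EI": 0.3 * n_tot_full,
            "EE": float(n_tot_full),
            "II": float(n_tot_full),
        }
    if scale < 1.0:
        eps = {k: min(1.0, v / scale) for k, v in eps.items()}
        n_e = int(round(n_e * scale))
        n_i = int(round(n_i * scale))
    return NetworkParams(n_e=n_e, n_i=n_i, epsilon=eps, **kwargs)


def _desync_ftsts(u_stim=100.0, t_neutral=10.0, stop=75.0, **kw) -> StimulusProtocol:
    return StimulusProtocol(
        kind="ftsts",
        ftsts=FtstsParams(u_stim=u_stim, t_stim=1.0, t_neutral=t_neutral, **kw),
        stop_rule=StopRule(stop, "falling") if stop is not None else None,
    )


@dataclass
class Scenario:
    """A named, parameter-complete experiment."""

    name: str
    description: str
    factory: Callable[..., SimulationConfig]
    #: published parameter values this scenario encodes, for auditing
    published: dict = field(default_factory=dict)

    def config(self, seed: int = 0, scale: float = DESK_SCALE, **overrides):
        cfg = self.factory(seed=seed, scale=scale, **overrides)
        return cfg


def _bistability(seed, scale, initial_weight=250.0):
    cfg = SimulationConfig(
        params=scaled_network(scale=scale),
        projections=("IE", "EI"),
        plasticity={"IE": make_rule("hebbian")},
        initial_weight={"IE": initial_weight},
        burn_in=150_000.0,
        plateau=(5_000.0, 1.0),
        min_duration=20_000.0,
        seed=seed,
    )
    return cfg


def _two_neuron(seed, scale, polarity="desynchronize"):
    params = NetworkParams(
        n_e=1,
        n_i=1,
        epsilon={"IE": 1.0, "EI": 1.0},
        C={"IE": 10.0, "EI": 10.0, "EE": 10.0, "II": 10.0},  # C = 10 * N_target
    )
    return SimulationConfig(
        params=params,
        plasticity={"IE": make_rule("hebbian")},
        initial_weight={"IE": 150.0},
        protocol=StimulusProtocol(
            kind="ftsts",
            ftsts=FtstsParams(u_stim=300.0, t_stim=1.0, t_neutral=10.0,
                              polarity=polarity),
        ),
        burn_in=500.0,
        stim_max=10_000.0,
        post=500.0,
        seed=seed,
    )


def _desync_2000(seed, scale, jitter=False, inseparable=0.0, tau_m=10.0,
                 dual=False):
    proto = _desync_ftsts(u_stim=100.0, stop=75.0, jitter=jitter)
    proto.inseparable_fraction = inseparable
    params = scaled_network(scale=scale, tau_m=tau_m)
    plasticity = {"IE": make_rule("hebbian")}
    if dual:
        plasticity["EI"] = make_rule("anti_hebbian")
    return SimulationConfig(
        params=params,
        plasticity=plasticity,
        initial_weight={"IE": HIGH_ATTRACTOR},
        w_bounds={"IE": (10.0, 290.0), "EI": (10.0, 290.0)},
        protocol=proto,
        burn_in=2_000.0,
        stim_max=120_000.0,
        post=10_000.0,
        seed=seed,
    )


def _resync_2000(seed, scale):
    return SimulationConfig(
        params=scaled_network(scale=scale),
        plasticity={"IE": make_rule("hebbian")},
        initial_weight={"IE": LOW_ATTRACTOR},
        protocol=StimulusProtocol(
            kind="ftsts",
            ftsts=FtstsParams(u_stim=200.0, t_stim=1.0, t_neutral=10.0,
                              polarity="synchronize"),
            stop_rule=StopRule(125.0, "rising"),
        ),
        burn_in=2_000.0,
        stim_max=120_000.0,
        post=10_000.0,
        seed=seed,
    )


def _desync_10000(seed, scale):
    params = scaled_network(
        n_e=8000, n_i=2000, scale=scale, epsilon={"IE": 0.01, "EI": 0.01}
    )
    return SimulationConfig(
        params=params,
        plasticity={"IE": make_rule("hebbian")},
        initial_weight={"IE": HIGH_ATTRACTOR},
        protocol=_desync_ftsts(u_stim=100.0, stop=25.0),
        burn_in=2_000.0,
        stim_max=120_000.0,
        post=10_000.0,
        seed=seed,
    )


def _taum_uniform(seed, scale):
    # per-neuron tau_m ~ U(8, 12) ms, drawn from the scenario seed
    cfg = _desync_2000(seed, scale)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A0]))
    tau = rng.uniform(8.0, 12.0, cfg.params.n_tot)
    cfg.params = scaled_network(scale=scale, tau_m=tau)
    # report the time to reach the asynchronous regime (weight < 100 mV)
    cfg.protocol.stop_rule = StopRule(BASIN_BOUNDARY, "falling")
    return cfg


def _ee_ii(seed, scale, protocol=None):
    params = scaled_network(
        scale=scale,
        J={"IE": 100.0, "EI": 90.0, "EE": 50.0, "II": 50.0},
        epsilon={"IE": 0.1, "EI": 0.1, "EE": 0.1, "II": 0.1},
    )
    return SimulationConfig(
        params=params,
        projections=("IE", "EI", "EE", "II"),
        plasticity={"IE": make_rule("hebbian")},
        initial_weight={"IE": HIGH_ATTRACTOR},
        protocol=protocol or _desync_ftsts(u_stim=100.0, stop=75.0),
        burn_in=2_000.0,
        stim_max=150_000.0,
        post=10_000.0,
        seed=seed,
    )


def _cr(seed, scale, variant="ftsts_cr"):
    if variant not in ("cr", "ftsts_cr"):
        raise ConfigurationError(f"unknown CR variant {variant!r}")
    proto = StimulusProtocol(
        kind=variant,
        cr=CrParams(
            pulse=FtstsParams(u_stim=100.0, t_stim=1.0, t_neutral=7.0),
            n_sub=4,
            T=None,  # estimated from pre-stimulation activity
            mode=variant,
        ),
        stop_rule=StopRule(75.0, "falling"),
    )
    cfg = _ee_ii(seed, scale, protocol=proto)
    cfg.stim_max = 250_000.0
    cfg.post = 8_000.0
    return cfg


def _symmetric(seed, scale, variant="resynchronize"):
    if variant == "resynchronize":
        pulse = FtstsParams(u_stim=100.0, t_stim=1.0, t_neutral=10.0, t_offset=5.0)
        stop = StopRule(125.0, "rising")
        initial = LOW_ATTRACTOR
    elif variant == "desynchronize":
        pulse = FtstsParams(u_stim=200.0, t_stim=1.0, t_neutral=22.0, t_offset=11.0)
        stop = StopRule(75.0, "falling")
        initial = HIGH_ATTRACTOR
    else:
        raise ConfigurationError(f"unknown symmetric variant {variant!r}")
    return SimulationConfig(
        params=scaled_network(scale=scale),
        plasticity={"IE": make_rule("symmetric")},
        initial_weight={"IE": initial},
        protocol=StimulusProtocol(kind="ftsts", ftsts=pulse, stop_rule=stop),
        burn_in=2_000.0,
        stim_max=120_000.0,
        post=10_000.0,
        seed=seed,
    )


def _ltp_dominant(seed, scale, variant="ftsts_cr", stim_max=30_000.0):
    proto = StimulusProtocol(
        kind=variant,
        cr=CrParams(
            pulse=FtstsParams(u_stim=200.0, t_stim=0.5, t_neutral=3.0),
            n_sub=4,
            mode=variant,
        ),
    )
    cfg = SimulationConfig(
        params=scaled_network(scale=scale),
        plasticity={"IE": make_rule("ltp_dominant")},
        initial_weight={"IE": HIGH_ATTRACTOR},
        protocol=proto,
        burn_in=2_000.0,
        stim_max=stim_max,
        post=8_000.0,
        seed=seed,
    )
    return cfg


_REGISTRY: dict[str, Scenario] = {}


def _register(name, description, factory, published):
    _REGISTRY[name] = Scenario(name, description, factory, published)


_register(
    "bistability",
    "Unstimulated weight convergence to the high/low attractor",
    _bistability,
    {"high_attractor_mV": 290.0, "low_attractor_mV": 10.0, "boundary_mV": 100.0},
)
_register(
    "two_neuron",
    "Two-neuron E-I pair under FTSTS (mechanism demonstration)",
    _two_neuron,
    {"U_stim_mV": 300.0, "T_stim_ms": 1.0, "T_neutral_ms": 10.0, "epsilon": 1.0},
)
_register(
    "desync_2000",
    "Desynchronize the 2,000-neuron network (stop at 75 mV)",
    lambda seed, scale: _desync_2000(seed, scale),
    {"U_stim_mV": 100.0, "T_stim_ms": 1.0, "T_neutral_ms": 10.0, "stop_mV": 75.0},
)
_register(
    "resync_2000",
    "Resynchronize from the asynchronous basin (swapped polarity, stop 125 mV)",
    _resync_2000,
    {"U_stim_mV": 200.0, "stop_mV": 125.0},
)
_register(
    "desync_10000",
    "Desynchronize the 10,000-neuron network (epsilon 0.01, stop 25 mV)",
    _desync_10000,
    {"epsilon": 0.01, "U_stim_mV": 100.0, "stop_mV": 25.0},
)
_register(
    "jitter",
    "Desynchronization with Gaussian per-pulse amplitude jitter",
    lambda seed, scale: _desync_2000(seed, scale, jitter=True),
    {"U_stim_mV": 100.0, "amplitude_variance": "U_stim/10"},
)
_register(
    "taum_uniform",
    "Desynchronization with per-neuron tau_m ~ U(8,12) ms",
    _taum_uniform,
    {"tau_m_distribution": "U(8,12) ms", "U_stim_mV": 100.0},
)
_register(
    "ee_ii",
    "Desynchronization with added E-E and I-I synapses",
    lambda seed, scale: _ee_ii(seed, scale),
    {"J_EI_mV": 90.0, "J_EE_mV": 50.0, "J_II_mV": 50.0,
     "epsilon_EE": 0.1, "epsilon_II": 0.1, "C_EE": "N_tot", "C_II": "N_tot"},
)
_register(
    "inseparable_25",
    "25% of each population receives both populations' waveforms",
    lambda seed, scale: _desync_2000(seed, scale, inseparable=0.25),
    {"inseparable_fraction": 0.25, "U_stim_mV": 100.0},
)
_register(
    "cr_vs_ftstscr",
    "Hybrid FTSTS-CR (default) or plain CR on the E-E/I-I network",
    lambda seed, scale, variant="ftsts_cr": _cr(seed, scale, variant),
    {"n_sub": 4, "U_stim_mV": 100.0, "T_stim_ms": 1.0, "T_neutral_ms": 7.0,
     "stop_mV": 75.0},
)
_register(
    "dual_plasticity",
    "Hebbian E-to-I plus anti-Hebbian I-to-E plasticity",
    lambda seed, scale: _desync_2000(seed, scale, dual=True),
    {"anti_hebbian_a_LTD": 1.0, "anti_hebbian_a_LTP": -1.1},
)
_register(
    "symmetric",
    "Symmetric ISI rule with offset FTSTS (desync and resync variants)",
    lambda seed, scale, variant="resynchronize": _symmetric(seed, scale, variant),
    {"c_P": 0.038, "c_D": 0.02, "tau_P_ms": 10.0, "tau_D_ms": 25.0,
     "resync": {"U_stim_mV": 100.0, "T_neutral_ms": 10.0, "T_offset_ms": 5.0},
     "desync": {"U_stim_mV": 200.0, "T_neutral_ms": 22.0, "T_offset_ms": 11.0}},
)
_register(
    "ltp_dominant",
    "LTP-dominant pair rule under FTSTS-CR vs CR (no bistability)",
    lambda seed, scale, variant="ftsts_cr": _ltp_dominant(seed, scale, variant),
    {"a_LTD": -1.0, "a_LTP": 1.01, "tau_LTD_ms": 20.0, "tau_LTP_ms": 20.0,
     "U_stim_mV": 200.0, "T_stim_ms": 0.5, "T_neutral_ms": 3.0},
)


def list_scenarios() -> dict[str, Scenario]:
    """The scenario registry, name -> :class:`Scenario`."""
    return dict(_REGISTRY)


def get_scenario(name: str) -> Scenario:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ConfigurationError(f"unknown scenario {name!r}") from None


def run_scenario(
    name: str,
    seed: int = 0,
    scale: float = DESK_SCALE,
    engine: str = "numba",
    **overrides,
) -> tuple[SimulationResult, dict]:
    """Run a scenario and return (result, summary row).

    The summary reports the pre-stimulation windowed R (last second of
    burn-in), the post-stimulation windowed R (a 1-s window starting 5 s
    after protocol offset, when the run extends that far), the final mean
    E-to-I weight and its basin, and the protocol-on duration.
    """
    scn = get_scenario(name)
    cfg = scn.config(seed=seed, scale=scale, **overrides)
    res = run_simulation(cfg, engine=engine)
    summary: dict = {
        "scenario": name,
        "seed": seed,
        "scale": scale,
        "final_weight_mV": res.final_weight.get("IE"),
        "regime": classify_regime(res.final_weight["IE"]) if "IE" in res.final_weight
        else None,
        "stop_time_ms": res.stop_time,
        "stim_duration_ms": res.stim_duration,
        "period_T_ms": res.period_T,
    }
    if cfg.burn_in >= 1_000.0 and len(res.spikes):
        summary["pre_R"] = res.windowed_R(cfg.burn_in - 1_000.0, cfg.burn_in)
    if res.stim_off_time is not None and res.t_end >= res.stim_off_time + 6_000.0:
        t0 = res.stim_off_time + 5_000.0
        summary["post_R"] = res.windowed_R(t0, t0 + 1_000.0)
    return res, summary


def make_fixture(kind: str, **kw):
    """Deterministic tiny inputs for unit tests.

    Kinds: ``two_neuron`` (a two-neuron E-I configuration),
    ``prescribed_pair_trains`` (short pre/post spike trains with exact
    times), ``periodic_raster`` (perfectly synchronous spike record),
    ``antiphase_raster`` (two neurons half a period out of phase).
    """
    if kind == "two_neuron":
        return _two_neuron(seed=kw.get("seed", 0), scale=1.0)
    if kind == "prescribed_pair_trains":
        return {
            "pre": np.array([0.0, 7.3, 15.0, 31.4, 52.0]),
            "post": np.array([2.0, 9.9, 13.0, 36.0, 49.5]),
        }
    if kind == "periodic_raster":
        n, period, n_spikes = kw.get("n", 10), kw.get("period", 25.0), kw.get("k", 8)
        times = np.tile(np.arange(n_spikes) * period, n)
        ids = np.repeat(np.arange(n), n_spikes)
        order = np.argsort(times, kind="stable")
        return times[order], ids[order], n
    if kind == "antiphase_raster":
        period = kw.get("period", 20.0)
        t0 = np.arange(8) * period
        t1 = t0 + period / 2.0
        times = np.concatenate([t0, t1])
        ids = np.concatenate([np.zeros(8, int), np.ones(8, int)])
        order = np.argsort(times, kind="stable")
        return times[order], ids[order], 2
    raise ConfigurationError(f"unknown fixture kind {kind!r}")
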