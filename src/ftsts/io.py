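"""Configuration files and result writers.

Configs are YAML or TOML mappings; omitted fields fall back to the published
table defaults.  Results are written as plain CSV time series plus a JSON
manifest sufficient to re-run the simulation bit-identically.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import ConfigurationError, NetworkParams
from .plasticity import HebbianStdpParams, SymmetricStdpParams
from .simulate import SimulationConfig, SimulationResult
from .stimulation import CrParams, FtstsParams, StimulusProtocol, StopRule

__all__ = ["load_config", "write_results"]

_NETWORK_KEYS = {
    "n_e", "n_i", "tau_m", "mu_e", "mu_i", "sigma_e", "sigma_i",
    "v_reset", "v_threshold", "tau_d", "tau_r", "t_delay", "dt",
    "J", "C", "epsilon",
}
_TOP_KEYS = {
    "network", "projections", "plasticity", "initial_weight", "w_bounds",
    "protocol", "burn_in", "stim_max", "post", "plateau", "min_duration",
    "record_spikes", "sample_every_ms", "chunk_ms", "seed",
}


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _parse_plasticity(section: dict) -> dict:
    out = {}
    for label, rule in section.items():
        rule = dict(rule)
        kind = rule.pop("rule", "pair")
        if kind == "pair":
            out[label] = HebbianStdpParams(**rule)
        elif kind == "symmetric":
            out[label] = SymmetricStdpParams(**rule)
        else:
            raise ConfigurationError(f"unknown plasticity rule {kind!r}")
    return out


def _parse_protocol(section: dict) -> StimulusProtocol:
    section = dict(section)
    kind = section.pop("kind", "none")
    stop = section.pop("stop_rule", None)
    stop_rule = StopRule(**stop) if stop else None
    insep = section.pop("inseparable_fraction", 0.0)
    if kind == "ftsts":
        return StimulusProtocol(
            kind="ftsts", ftsts=FtstsParams(**section), stop_rule=stop_rule,
            inseparable_fraction=insep,
        )
    if kind in ("cr", "ftsts_cr"):
        pulse = FtstsParams(**section.pop("pulse", {}))
        return StimulusProtocol(
            kind=kind,
            cr=CrParams(pulse=pulse, mode=kind, **section),
            stop_rule=stop_rule,
            inseparable_fraction=insep,
        )
    if kind == "none":
        return StimulusProtocol(kind="none")
    raise ConfigurationError(f"unknown protocol kind {kind!r}")


def load_config(path: str | Path) -> SimulationConfig:
    """Parse a YAML/TOML config file into a validated SimulationConfig.

    An empty file yields the pure table defaults (Hebbian plasticity on
    E-to-I, eta_e 0.25, A_0 0.005, J_EI 100 mV, ...).  Unknown keys raise a
    :class:`ConfigurationError` naming the key.
    """
    path = Path(path)
    if path.suffix in (".toml", ".tml"):
        raw = tomllib.loads(path.read_text())
    else:
        raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    kwargs: dict = {}
    net = raw.pop("network", {})
    _check_keys(net, _NETWORK_KEYS, "network")
    kwargs["params"] = NetworkParams(**net)
    if "projections" in raw:
        kwargs["projections"] = tuple(raw.pop("projections"))
    if "plasticity" in raw:
        kwargs["plasticity"] = _parse_plasticity(raw.pop("plasticity"))
    if "protocol" in raw:
        kwargs["protocol"] = _parse_protocol(raw.pop("protocol"))
    for key in ("initial_weight", "w_bounds", "burn_in", "stim_max", "post",
                "plateau", "min_duration", "record_spikes", "sample_every_ms",
                "chunk_ms", "seed"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if kwargs.get("plateau") is not None and "plateau" in kwargs:
        kwargs["plateau"] = tuple(kwargs["plateau"])
    if "w_bounds" in kwargs:
        kwargs["w_bounds"] = {k: tuple(v) for k, v in kwargs["w_bounds"].items()}
    return SimulationConfig(**kwargs)


def write_results(result: SimulationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write spikes.csv, weights.csv, sync.csv, stimulus.csv and manifest.json.

    ``sync.csv`` contains R(t), psi(t) and the valid-phase count on a 1-ms
    grid over the whole run.  Returns the mapping of artifact name to path.
    """
    from . import metrics as m

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    spikes = result.spikes
    pop = np.where(spikes.ids < spikes.n_e, "E", "I")
    df = pd.DataFrame(
        {"time_ms": spikes.times, "neuron_id": spikes.ids, "population": pop}
    )
    paths["spikes"] = out / "spikes.csv"
    df.to_csv(paths["spikes"], index=False)

    wdf = pd.DataFrame({"time_ms": result.weight_times})
    for label, series in result.weights.items():
        wdf[f"mean_JW_mV_{label}"] = series
    paths["weights"] = out / "weights.csv"
    wdf.to_csv(paths["weights"], index=False)

    if len(spikes) and result.t_end > 0:
        times = np.arange(0.0, result.t_end, 1.0)
        e_t, e_i = spikes.population("E")
        phases = m.spike_phases(e_t, e_i, spikes.n_e, times)
        R, psi, count = m.kuramoto(phases)
    else:
        times = np.empty(0)
        R = psi = np.empty(0)
        count = np.empty(0, dtype=int)
    sdf = pd.DataFrame({"time_ms": times, "R": R, "psi": psi, "valid_count": count})
    paths["sync"] = out / "sync.csv"
    sdf.to_csv(paths["sync"], index=False)

    if result.stim_log is not None:
        t, se, si = result.stim_log
        stim_df = pd.DataFrame(
            {"time_ms": t, "mean_abs_V_E_mV": se, "mean_abs_V_I_mV": si}
        )
        paths["stimulus"] = out / "stimulus.csv"
        stim_df.to_csv(paths["stimulus"], index=False)

    manifest = {
        "config": result.config.manifest(),
        "seed": result.config.seed,
        "stop_time_ms": result.stop_time,
        "stim_on_ms": result.stim_on_time,
        "stim_off_ms": result.stim_off_time,
        "period_T_ms": result.period_T,
        "t_end_ms": result.t_end,
        "final_weight_mV": result.final_weight,
        "n_spikes": int(len(spikes)),
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
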