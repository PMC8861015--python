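"""Declarative run configuration and end-to-end experiment orchestration.

A RunConfig is a nested mapping (typically loaded from YAML) whose
sections mirror the library's dataclasses:

    seed: 1
    outdir: runs/demo
    network:   {n_modules: 8, module_size: 100, ...}
    simulate:  {duration_ms: 5000, drive: gaussian, sigma_exc: 5.0, ...}
    complexity: {window_ms: 50, slide_ms: 20}
    training:  {enabled: false, alpha: 2200.0, epochs: 1, ...}
    target:    {kind: synth_eeg, duration_s: 3.0, fs: 128, ...}
    synapse:   {kind: double, tau_r: 2.0, tau_d: 20.0}

:func:`run_experiment` executes build -> simulate -> complexity
(-> train -> replay when enabled), writes every artifact under
``outdir`` and a ``manifest.json`` with seeds, stage outputs and content
hashes, so a run is reproducible from the config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import complexity as _complexity
from . import neuron as _neuron
from . import signal_io as _signal_io
from . import training as _training
from .synapse import SynapseConfig
from .topology import ModularNetworkConfig, build_modular_swn, save_network

__all__ = ["RunConfig", "load_config", "run_experiment"]


_DEFAULTS: dict = {
    "seed": 0,
    "outdir": "run",
    "network": {},
    "simulate": {"duration_ms": 5000, "drive": "gaussian", "sigma_exc": 5.0, "sigma_inh": 2.0},
    "complexity": {"window_ms": 50, "slide_ms": 20},
    "training": {"enabled": False},
    "target": {"kind": "synth_eeg", "duration_s": 3.0, "fs": 128.0, "interp_factor": 4},
    "synapse": {},
}


class RunConfig(dict):
    """Validated nested run configuration (a dict with defaults filled)."""

    @classmethod
    def from_mapping(cls, mapping: dict | None) -> "RunConfig":
        cfg = cls()
        mapping = mapping or {}
        unknown = set(mapping) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        for key, default in _DEFAULTS.items():
            if isinstance(default, dict):
                merged = dict(default)
                merged.update(mapping.get(key) or {})
                cfg[key] = merged
            else:
                cfg[key] = mapping.get(key, default)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        """Instantiate every sub-config so bad values fail before compute."""
        self.network_config()
        self.synapse_config()
        if self["training"].get("enabled"):
            self.training_config()
        if self["simulate"]["duration_ms"] < 1:
            raise ValueError("simulate.duration_ms must be positive")

    def network_config(self) -> ModularNetworkConfig:
        kwargs = dict(self["network"])
        kwargs.setdefault("seed", self["seed"])
        return ModularNetworkConfig(**kwargs)

    def synapse_config(self) -> SynapseConfig:
        return SynapseConfig(**self["synapse"])

    def training_config(self) -> _training.TrainingConfig:
        kwargs = {k: v for k, v in self["training"].items() if k != "enabled"}
        kwargs.setdefault("stimulus_seed", self["seed"] + 1)
        return _training.TrainingConfig(**kwargs)


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_mapping(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_experiment(config: RunConfig | dict) -> dict:
    """Execute the configured pipeline and write all artifacts.

    Returns the manifest dictionary (also written to
    ``outdir/manifest.json``): per-stage outputs, file hashes and the
    seeds used.  Any stage error propagates annotated with the stage
    name.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_mapping(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config["seed"], "stages": {}, "files": {}}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    # build ----------------------------------------------------------------
    net_cfg = config.network_config()
    network = _stage("build", lambda: build_modular_swn(net_cfg))
    save_network(network, str(outdir / "network.npz"))
    manifest["stages"]["build"] = {
        "n_neurons": network.n_neurons,
        "n_edges": int((network.weights != 0).sum()),
        "directed": network.directed,
    }

    # simulate -------------------------------------------------------------
    sim = config["simulate"]
    params = _neuron.sample_params(network.neuron_type, seed=config["seed"] + 10)
    duration = int(sim["duration_ms"])
    if sim["drive"] == "gaussian":
        stim = _neuron.noise_drive(
            network.neuron_type,
            duration,
            seed=config["seed"] + 20,
            sigma_exc=sim["sigma_exc"],
            sigma_inh=sim["sigma_inh"],
        )
    elif sim["drive"] == "pink":
        stim = _training.pink_noise(
            duration, network.n_neurons, sim.get("amplitude", 5.0), seed=config["seed"] + 20
        )
    else:
        raise RuntimeError(f"stage 'simulate' failed: unknown drive {sim['drive']!r}")
    result = _stage("simulate", lambda: _neuron.simulate(network, params, stim, duration))
    _neuron.write_raster(result.raster, str(outdir / "raster.txt"))
    manifest["stages"]["simulate"] = {
        "duration_ms": duration,
        "n_spikes": len(result.raster),
        "mean_rate_hz": 1000.0 * len(result.raster) / (network.n_neurons * duration),
    }

    # complexity -----------------------------------------------------------
    cx = config["complexity"]
    report = _stage(
        "complexity",
        lambda: _complexity.complexity_from_raster(
            result.raster, network.module_id, cx["window_ms"], cx["slide_ms"]
        ),
    )
    report_dict = {
        "H_S": report.H_S,
        "H_i": report.H_i.tolist(),
        "I_S": report.I_S,
        "MI_i": report.MI_i.tolist(),
        "C_S": report.C_S,
        "ridge_applied": report.ridge_applied,
    }
    (outdir / "complexity.json").write_text(json.dumps(report_dict, indent=2))
    manifest["stages"]["complexity"] = {"C_S": report.C_S, "I_S": report.I_S}

    # training + replay (optional) ------------------------------------------
    if config["training"].get("enabled"):
        tgt_cfg = config["target"]
        if tgt_cfg["kind"] == "synth_eeg":
            target = _signal_io.synth_eeg(
                duration_s=tgt_cfg["duration_s"],
                fs=tgt_cfg["fs"],
                seed=config["seed"] + 30,
            )
        elif tgt_cfg["kind"] == "file":
            target = _signal_io.read_timeseries(tgt_cfg["path"], fs=tgt_cfg["fs"])[
                int(tgt_cfg.get("channel", 0))
            ]
        else:
            raise RuntimeError(f"stage 'train' failed: unknown target kind")
        factor = int(tgt_cfg.get("interp_factor", 1))
        if factor >= 2:
            target = _signal_io.lowpass_interpolate(target, factor)
        train_cfg = config.training_config()
        fit = _stage(
            "train",
            lambda: _training.train(
                network, params, target.samples, train_cfg, config.synapse_config()
            ),
        )
        _signal_io.write_timeseries(
            _signal_io.TargetSignal(fit.z, target.fs, "modelled"),
            str(outdir / "fit_z.csv"),
        )
        manifest["stages"]["train"] = {
            "rmse": fit.rmse,
            "rmse_per_epoch": fit.rmse_per_epoch,
            "n_updates": len(fit.weight_history),
        }
        rep = _stage(
            "replay",
            lambda: _training.replay(
                network, params, fit, target=target.samples,
                syn_config=config.synapse_config(),
            ),
        )
        _signal_io.write_timeseries(
            _signal_io.TargetSignal(rep.z, target.fs, "replay"),
            str(outdir / "replay_z.csv"),
        )
        manifest["stages"]["replay"] = {"rmse": rep.rmse}

    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
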