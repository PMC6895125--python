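"""Configuration-driven runs: validation, dispatch, manifests.

A run is declared in a YAML/JSON mapping with a ``task`` key naming a
protocol, generator, fit or measurement, a ``cell`` block describing the
model (synthetic morphology + preset), task parameters under ``params``, and
a ``seed``.  :func:`run_from_config` validates the config, executes the task,
writes results tables (tab-separated text with unit-annotated headers) plus a
JSON :class:`RunManifest` into the output directory, and returns the
manifest.  Reruns with identical config and seed produce identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .morphology import (GeometryParams, discretize, generate_synthetic_morphology,
                         read_swc, write_swc)
from .model import CellModel, preset_cell_model
from .engine import measure_rin, nernst_potential, resting_potential
from .protocols import (protocol_conductance_mapping, protocol_discharge,
                        protocol_ie_mapping, protocol_ie_surface,
                        protocol_ipsp_propagation)
from .inference import calibrate_local_ggaba, fit_ggaba_gradient
from .synthetic import gen_attenuation_target, gen_iv_dataset, gen_sweep_set
from .estimators import fit_egaba

__all__ = ["RunManifest", "run_from_config", "load_config", "config_hash",
            "ConfigError", "build_cell_from_config", "TASKS"]

log = logging.getLogger("dendrinh")


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending keys."""


@dataclass
class RunManifest:
    task: str
    config_hash: str
    seed: int
    version: str
    input_digests: dict
    outputs: list
    started_unix: float
    finished_unix: float = 0.0

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def apply_overrides(cfg: dict, overrides: dict) -> dict:
    """Apply {'a.b.c': value} dotted-path overrides to a copied config."""
    out = json.loads(json.dumps(cfg))
    for dotted, value in overrides.items():
        node = out
        *parents, last = dotted.split(".")
        for key in parents:
            node = node.setdefault(key, {})
        node[last] = value
    return out


_CELL_KEYS = {"cell_type", "morphology_swc", "seed", "preset", "spiking",
              "passive_only", "drop_ih", "ggaba", "egaba_uniform_mv",
              "geometry"}


def build_cell_from_config(cell_cfg: dict, seed: int) -> CellModel:
    unknown = set(cell_cfg) - _CELL_KEYS
    if unknown:
        raise ConfigError(f"unknown cell config keys: {sorted(unknown)}")
    cell_type = cell_cfg.get("cell_type", "PVI")
    if "morphology_swc" in cell_cfg:
        path = cell_cfg["morphology_swc"]
        if not Path(path).exists():
            raise FileNotFoundError(f"morphology file not found: {path}")
        morph = read_swc(path)
    else:
        geom = None
        if "geometry" in cell_cfg:
            geom = GeometryParams.for_cell_type(cell_type)
            for k, v in cell_cfg["geometry"].items():
                if not hasattr(geom, k):
                    raise ConfigError(f"unknown geometry key: {k}")
                setattr(geom, k, v)
        morph = generate_synthetic_morphology(
            cell_type, geom, seed=cell_cfg.get("seed", seed))
    kwargs = {k: cell_cfg[k] for k in
              ("spiking", "passive_only", "drop_ih", "ggaba", "egaba_uniform_mv")
              if k in cell_cfg}
    return preset_cell_model(discretize(morph), cell_type, **kwargs)


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# -- task runners: each returns {filename: DataFrame-or-dict} ---------------

def _task_gmap(cell, params, seed):
    prof = protocol_conductance_mapping(cell.passive_variant(), **params)
    return {"conductance_mapping.tsv": pd.DataFrame({
        "distance_um": prof.distances_um, "g_est_ns": prof.g_est_ns,
        "g_norm": prof.g_norm})}


def _task_ie_map(cell, params, seed):
    prof = protocol_ie_mapping(cell, **params)
    return {"ie_mapping.tsv": pd.DataFrame({
        "relative_location_um": prof.relative_location_um, "ie": prof.ie,
        "epsp_amp_mv": prof.epsp_amp_mv})}


def _task_ie_surface(cell, params, seed):
    out = protocol_ie_surface(cell, **params)
    rows = []
    for i, eg in enumerate(out["egaba_mv"]):
        for j, gg in enumerate(out["ggaba_ns"]):
            rows.append({"egaba_mv": eg, "ggaba_ns": gg,
                         "ie": out["ie"][i, j]})
    return {"ie_surface.tsv": pd.DataFrame(rows)}


def _task_discharge(cell, params, seed):
    params = dict(params)
    grid = params.pop("g_exc_grid_ns", (4.0, 8.0, 12.0, 16.0, 20.0))
    curve = protocol_discharge(cell, grid, seed=seed, **params)
    return {"discharge.tsv": pd.DataFrame({
        "g_exc_ns": curve.g_exc_ns,
        "spikes_per_trial": curve.spikes_per_trial,
        "p_any_spike": curve.p_any_spike}),
        "sigmoid.json": curve.sigmoid}


def _task_ipsp_prop(cell, params, seed):
    out = protocol_ipsp_propagation(cell, **params)
    return {"ipsp_propagation.tsv": pd.DataFrame({
        "distance_from_site_um": out["distance_from_site_um"],
        "path_distance_um": out["path_distance_um"],
        "amplitude_mv": out["amplitude_mv"],
        "normalized": out["normalized"]})}


def _task_fit_ggaba_gradient(cell, params, seed):
    params = dict(params)
    target_path = params.pop("target_table", None)
    if target_path:
        df = pd.read_csv(target_path, sep="\t")
        from .protocols import AttenuationProfile
        target = AttenuationProfile(df["distance_um"].values,
                                    df["g_norm"].values, df["g_norm"].values)
    else:
        target = gen_attenuation_target(params.pop("target_style", "PVI_like"))
    fit = fit_ggaba_gradient(cell.passive_variant(), target, **params)
    return {"gradient_fit.json": {
        "distal_value_ns": fit.distal_value_ns, "objective": fit.objective,
        "search_trace": fit.search_trace},
        "gradient_fit_profile.tsv": pd.DataFrame({
            "distance_um": fit.profile_model.distances_um,
            "g_norm_model": fit.profile_model.g_norm})}


def _task_fit_ggaba_local(cell, params, seed):
    g = calibrate_local_ggaba(cell.passive_variant(), **params)
    return {"local_ggaba.json": {"local_ggaba_ns": g}}


def _task_fit_egaba(cell, params, seed):
    df = pd.read_csv(params["table"], sep="\t")
    from .estimators import IVDataset
    data = IVDataset(df.iloc[:, 0].values, df.iloc[:, 1].values,
                     params.get("amplitude_kind", "pa"))
    return {"egaba_fit.json": {"e_gaba_mv": fit_egaba(data)}}


def _task_synth_iv(cell, params, seed):
    out = gen_iv_dataset(seed=seed, **params)
    return {"iv_dataset.tsv": pd.DataFrame({
        "v_h_mv": out.dataset.v_h_mv,
        f"amplitude_{out.dataset.amplitude_kind}": out.dataset.amplitude}),
        "iv_truth.json": out.truth}


def _task_synth_sweeps(cell, params, seed):
    ss = gen_sweep_set(seed=seed, **params)
    frames = {}
    for i, sw in enumerate(ss.sweeps):
        frames[f"sweep_{i:03d}.tsv"] = pd.DataFrame({
            "time_ms": sw["epsp"].times_ms,
            "epsp_mv": sw["epsp"].values,
            "ipsp_mv": sw["ipsp"].values,
            "psp_mv": sw["psp"].values})
    frames["sweep_truth.json"] = ss.truth
    return frames


def _task_synth_morphology(cell, params, seed):
    return {"__morphology__": params}       # handled specially in run_from_config


def _task_synth_attenuation(cell, params, seed):
    prof = gen_attenuation_target(**params)
    return {"attenuation_target.tsv": pd.DataFrame({
        "distance_um": prof.distances_um, "g_norm": prof.g_norm})}


def _task_measure_rin(cell, params, seed):
    return {"rin.json": {"rin_mohm": measure_rin(cell, **params),
                         "resting_mv": resting_potential(cell)}}


def _task_measure_nernst(cell, params, seed):
    return {"nernst.json": {"e_mv": nernst_potential(**params)}}


TASKS = {
    "protocol.gmap": (_task_gmap, True),
    "protocol.ie-map": (_task_ie_map, True),
    "protocol.ie-surface": (_task_ie_surface, True),
    "protocol.discharge": (_task_discharge, True),
    "protocol.ipsp-prop": (_task_ipsp_prop, True),
    "fit.ggaba-gradient": (_task_fit_ggaba_gradient, True),
    "fit.ggaba-local": (_task_fit_ggaba_local, True),
    "fit.egaba": (_task_fit_egaba, False),
    "synth.iv": (_task_synth_iv, False),
    "synth.sweeps": (_task_synth_sweeps, False),
    "synth.morphology": (_task_synth_morphology, False),
    "synth.attenuation": (_task_synth_attenuation, False),
    "measure.rin": (_task_measure_rin, True),
    "measure.nernst": (_task_measure_nernst, False),
}

_TOP_KEYS = {"task", "cell", "params", "seed", "out_dir"}


def run_from_config(config: dict | str | Path, overrides: dict | None = None,
                    out_dir: str | Path | None = None) -> RunManifest:
    """Validate, dispatch and record one configured run."""
    input_digests = {}
    if not isinstance(config, dict):
        path = Path(config)
        input_digests[str(path)] = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
        config = load_config(path)
    if overrides:
        config = apply_overrides(config, overrides)

    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    task = config.get("task")
    if task not in TASKS:
        raise ConfigError(
            f"unknown task {task!r}; expected one of {sorted(TASKS)}")
    seed = int(config.get("seed", 0))
    params = dict(config.get("params", {}))
    out = Path(out_dir or config.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)

    runner, needs_cell = TASKS[task]
    cell = None
    if needs_cell:
        cell = build_cell_from_config(config.get("cell", {}), seed)

    chash = config_hash(config)
    log.info("[%s seed=%d] running %s", chash, seed, task)
    manifest = RunManifest(task=task, config_hash=chash, seed=seed,
                           version=__version__, input_digests=input_digests,
                           outputs=[], started_unix=time.time())

    if task == "synth.morphology":
        morph = generate_synthetic_morphology(
            params.get("cell_type", "PVI"), seed=seed,
            calibrate=params.get("calibrate", True))
        dest = out / f"morphology_{params.get('cell_type', 'PVI')}_{seed}.swc"
        write_swc(morph, dest)
        manifest.outputs.append(dest.name)
    else:
        results = runner(cell, params, seed)
        for name, payload in results.items():
            dest = out / name
            if isinstance(payload, pd.DataFrame):
                _write_table(payload, dest)
            else:
                dest.write_text(json.dumps(payload, indent=2, sort_keys=True,
                                           default=lambda o: np.asarray(o).tolist()))
            manifest.outputs.append(name)

    manifest.finished_unix = time.time()
    manifest.write(out / "manifest.json")
    log.info("[%s seed=%d] wrote %d outputs to %s", chash, seed,
             len(manifest.outputs), out)
    return manifest
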