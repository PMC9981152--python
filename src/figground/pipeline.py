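"""End-to-end pipeline: simulate -> figure maps -> modulation -> decode.

A pipeline run is driven by a config mapping (usually loaded from YAML),
writes every stage output plus a manifest into a run directory, and is
bit-for-bit reproducible: every stochastic stage derives its seed from the
global seed and the stage name by stable hashing.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .decoding import DecodingConfig, decoding_curve
from .figure_maps import build_figure_map
from .geometry import CanvasGeometry
from .io import export_trial_table, read_session, write_session
from .modulation import ZoneSpec, label_trials_by_zone, modulation_for_cell
from .population import (NoiseModel, SurroundParams, sample_population,
                         simulate_session)
from .session import PositionGrid, build_figure_map_session

__all__ = ["stage_seed", "config_hash", "run_pipeline", "DEFAULT_CONFIG",
           "read_session", "write_session"]

KNOWN_STAGES = ("simulate", "figure_maps", "modulation", "decode")

#: Preset reproducing the model decoding-curve experiment: LN population,
#: noise variance twice the condition population mean, ridge decoding per
#: texture condition over a neuron-count sweep.
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "stages": ["simulate", "figure_maps", "modulation", "decode"],
    "simulate": {
        "n_neurons": 200,
        "model": "ln",            # "ln" or "surround"
        "noise_factor": 2.0,
        "grid": {},               # PositionGrid overrides
    },
    "modulation": {"convention": "results", "n_shuffles": 500,
                   "max_cells": 50},
    "decode": {"conditions": ["Cross", "Iso", "Nat"],
               "neuron_counts": [5, 20, 100, 200],
               "n_iterations": 100},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | None = None,
                 out_dir: str | Path = "figground_run") -> dict:
    """Execute the configured stages and write outputs plus a manifest.

    Returns the manifest dict.  Unknown stage names fail validation before
    any compute; re-running with the same config reproduces all outputs.
    """
    config = _merge(DEFAULT_CONFIG, config or {})
    unknown = [s for s in config["stages"] if s not in KNOWN_STAGES]
    if unknown:
        raise ValueError(f"unknown pipeline stages: {unknown}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    chash = config_hash(config)
    manifest: dict[str, Any] = {
        "config": config, "config_hash": chash, "seed": seed,
        "version": __version__, "stages": {},
    }

    responses = None
    session = None
    for stage in config["stages"]:
        t0 = time.perf_counter()
        s_seed = stage_seed(seed, stage)
        if stage == "simulate":
            sim = config["simulate"]
            grid = PositionGrid(**sim.get("grid", {}))
            session = build_figure_map_session(
                grid, seed=stage_seed(seed, "session"),
                canvas=CanvasGeometry())
            population = sample_population(int(sim["n_neurons"]),
                                           seed=s_seed,
                                           canvas=session.canvas)
            surround = (SurroundParams() if sim.get("model") == "surround"
                        else None)
            noise = NoiseModel(float(sim.get("noise_factor", 0.0)))
            responses = simulate_session(population, session, surround,
                                         noise, seed=s_seed)
            write_session(out_dir / "session.h5", responses,
                          {"config_hash": chash, "seed": s_seed,
                           "stage": stage})
            export_trial_table(responses.trials, out_dir / "trials.csv")
        elif stage == "figure_maps":
            if responses is None:
                raise RuntimeError("figure_maps requires the simulate stage "
                                   "output (or a session on disk)")
            rows = []
            grid = session.grid
            for cond in sorted(set(responses.trials["condition"])):
                for var in sorted(set(responses.trials["variant"])):
                    for n in range(responses.n_neurons):
                        fmap = build_figure_map(responses.responses[n],
                                                responses.trials, grid,
                                                cond, var, neuron=n)
                        el, az = np.indices(fmap.shape)
                        rows.append(pd.DataFrame({
                            "neuron": n, "condition": cond, "variant": var,
                            "az": az.ravel() + 1, "el": el.ravel() + 1,
                            "mean": fmap.values.ravel(),
                            "n": fmap.n_trials.ravel().astype(int)}))
            maps = pd.concat(rows, ignore_index=True)
            maps["config_hash"] = chash
            maps["seed"] = s_seed
            maps.to_csv(out_dir / "figure_maps.csv", index=False)
        elif stage == "modulation":
            if responses is None:
                raise RuntimeError("modulation requires simulated responses")
            mod_cfg = config["modulation"]
            zone = ZoneSpec(convention=mod_cfg.get("convention", "results"))
            labels = label_trials_by_zone(responses.trials, session.grid, zone)
            rows = []
            n_cells = min(responses.n_neurons,
                          int(mod_cfg.get("max_cells", responses.n_neurons)))
            for n in range(n_cells):
                for cond in sorted(set(responses.trials["condition"])):
                    for index_type in ("FGM", "BOM"):
                        try:
                            res = modulation_for_cell(
                                responses.responses[n], labels,
                                responses.trials, index_type, cond,
                                n_shuffles=int(mod_cfg.get("n_shuffles", 500)),
                                seed=s_seed + n)
                        except ValueError:
                            continue
                        rows.append({"cell": n, "condition": cond,
                                     "index_type": index_type,
                                     "value": res.index_value,
                                     "r_a": res.r_a, "r_b": res.r_b,
                                     "n_a": res.n_a, "n_b": res.n_b,
                                     "p": res.p_value})
            mod = pd.DataFrame(rows)
            mod["config_hash"] = chash
            mod["seed"] = s_seed
            mod.to_csv(out_dir / "modulation.csv", index=False)
        elif stage == "decode":
            if responses is None:
                raise RuntimeError("decode requires simulated responses")
            dec = config["decode"]
            cfg = DecodingConfig(n_iterations=int(dec["n_iterations"]),
                                 seed=s_seed)
            curve = decoding_curve(responses, list(dec["conditions"]),
                                   [int(n) for n in dec["neuron_counts"]],
                                   cfg)
            flat = curve.drop(columns=["r2_iterations"]).copy()
            flat["config_hash"] = chash
            flat["seed"] = s_seed
            flat.to_csv(out_dir / "decoding_curve.csv", index=False)
        manifest["stages"][stage] = {
            "seed": s_seed, "wall_s": round(time.perf_counter() - t0, 3)}

    manifest["checksums"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        for p in sorted(out_dir.glob("*.csv"))}
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return manifest
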