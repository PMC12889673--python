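"""End-to-end pipeline: synth → fit → stability → perturb.

A single YAML configuration drives all stages; every stage writes into the
output directory and a manifest records the materialized configuration,
package version, seeds and wall-clock times, so outputs are
self-describing and reruns with the same config and seed reproduce all
deterministic stage outputs bit-exactly.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

import spatialssn
from spatialssn.fitting import FitConfig, fit_multistart
from spatialssn.grid import RetinotopicGrid
from spatialssn.io import read_rate_table, write_model_yaml, write_rate_table
from spatialssn.network import RECURRENT_TYPES
from spatialssn.perturbation import PerturbationSpec, parity_check, simulate_perturbation
from spatialssn.stability import classify_stabilization
from spatialssn.synth import (
    DEFAULT_SIZES,
    NoiseSpec,
    generate_dataset,
    make_ground_truth_model,
    make_input_fields,
)

logger = logging.getLogger("spatialssn")


class StageError(RuntimeError):
    """A pipeline stage failed; carries a machine-readable record."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.record = {"stage": stage, "error": message}


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "grid": {"n_x": 12, "n_y": 12, "spacing": 6.0},
    "synth": {"enabled": True, "regime": "isn", "noise_sd": 0.0},
    "data": None,   # path to observed rates CSV (if synth disabled)
    "drive": None,  # path to drive CSV (if synth disabled)
    "fit": {"n_restarts": 10, "top_k": 5, "variant": "full", "maxiter": 120},
    "stability": {"sizes": None},  # default: all stimulus sizes
    "perturb": {"size": 55.0, "targets": ["all_inhibitory", "PV", "SST", "VIP"],
                "pattern": "uniform", "gamma": 0.001},
    "log_level": "WARNING",
}


def _merged(base: Mapping, override: Mapping | None) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _merged(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path) -> Path:
    """Run the full pipeline and return the output directory.

    ``config`` is a nested mapping (or path to a YAML file) following
    :data:`DEFAULT_CONFIG`; unspecified keys take their defaults and the
    fully materialized configuration is echoed into the manifest.
    """
    if isinstance(config, (str, Path)):
        with open(config) as f:
            config = yaml.safe_load(f) or {}
    cfg = _merged(DEFAULT_CONFIG, config)
    logging.basicConfig(level=cfg["log_level"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": cfg,
        "version": spatialssn.__version__,
        "stages": {},
    }
    seed = int(cfg["seed"])
    rng_seed = seed

    # --- synth / load -----------------------------------------------------
    t0 = time.time()
    try:
        if cfg["synth"]["enabled"]:
            grid = RetinotopicGrid(**cfg["grid"])
            drive = make_input_fields(grid, DEFAULT_SIZES)
            truth = make_ground_truth_model(
                rng_seed, grid, regime=cfg["synth"]["regime"], drive=drive
            )
            ds = generate_dataset(
                truth, drive, NoiseSpec(sd=cfg["synth"]["noise_sd"], seed=rng_seed + 1)
            )
            data, template = ds.observed, truth
            write_rate_table(out / "observed.csv", data)
            write_rate_table(out / "drive.csv", drive)
            write_model_yaml(out / "truth.yaml", truth)
        else:
            for key in ("data", "drive"):
                p = cfg[key]
                if p is None or not Path(p).exists():
                    raise StageError("load", f"missing {key} path: {p}")
            data = read_rate_table(cfg["data"])
            drive = read_rate_table(cfg["drive"], drive=True)
            template = make_ground_truth_model(
                rng_seed, data.grid, regime="weak"
            )
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("synth", str(e)) from e
    manifest["stages"]["synth"] = {"seconds": round(time.time() - t0, 2)}

    # --- fit --------------------------------------------------------------
    t0 = time.time()
    try:
        fit_cfg = FitConfig(seed=seed, **cfg["fit"])
        ranked = fit_multistart(template, data, drive, fit_cfg)
        rows = []
        for rank, r in enumerate(ranked):
            write_model_yaml(out / f"model_rank{rank:02d}.yaml", r.model)
            rows.append(
                {"rank": rank, "restart": r.restart, "loss": r.loss,
                 "converged": r.converged}
            )
        pd.DataFrame(rows).to_csv(out / "ranking.csv", index=False)
        best = ranked[0].model
    except Exception as e:  # noqa: BLE001
        raise StageError("fit", str(e)) from e
    manifest["stages"]["fit"] = {"seconds": round(time.time() - t0, 2)}

    # --- stability --------------------------------------------------------
    t0 = time.time()
    try:
        sizes = cfg["stability"]["sizes"] or list(drive.sizes)
        rep = classify_stabilization(best, drive, sizes=sizes)
        ent = rep.entries.copy()
        flag_rows = [
            {"size": s, **{k: bool(v) for k, v in fl.items()}}
            for s, fl in rep.flags.items()
        ]
        ent.to_csv(out / "stability.csv", index=False)
        pd.DataFrame(flag_rows).to_csv(out / "stability_flags.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("stability", str(e)) from e
    manifest["stages"]["stability"] = {"seconds": round(time.time() - t0, 2)}

    # --- perturb ----------------------------------------------------------
    t0 = time.time()
    try:
        pcfg = cfg["perturb"]
        summary = {}
        for target in pcfg["targets"]:
            spec = PerturbationSpec(
                target=target,
                pattern=0 if pcfg["pattern"] == "eig1" else pcfg["pattern"],
                gamma=float(pcfg["gamma"]),
            )
            res = simulate_perturbation(best, drive, float(pcfg["size"]), spec)
            label = target if isinstance(target, str) else "+".join(target)
            pd.DataFrame(
                {"time_s": res.times, "delta_mean": res.readout_mean,
                 "delta_dot": res.readout_dot}
            ).to_csv(out / f"perturb_{label}.csv", index=False)
            summary[label] = {
                "analytic_mean": res.analytic_mean,
                "analytic_dot": res.analytic_dot,
                "simulated_mean": float(res.readout_mean[-1]),
                "simulated_dot": float(res.readout_dot[-1]),
                "paradoxical": res.paradoxical,
            }
            if isinstance(target, str) and target in RECURRENT_TYPES and target != "E":
                pc = parity_check(best, drive, float(pcfg["size"]), target)
                summary[label]["parity"] = {
                    "n_unstable": pc.n_unstable,
                    "n_paradoxical": pc.n_paradoxical,
                    "holds": pc.holds,
                }
        with open(out / "perturbation.json", "w") as f:
            json.dump(summary, f, indent=2)
    except Exception as e:  # noqa: BLE001
        raise StageError("perturb", str(e)) from e
    manifest["stages"]["perturb"] = {"seconds": round(time.time() - t0, 2)}

    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    return out
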