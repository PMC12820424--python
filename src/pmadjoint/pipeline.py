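"""Orchestration: synth → forward → forcing → adjoint (deaths, USD) →
attribution → validation, with file outputs and a reproducibility manifest.

Each stage reads the previous stage's files from the output directory (or
reuses in-memory results when driven from Python), logs a JSON summary line
to stderr, and records its outputs in the run manifest.  Re-running with an
unchanged configuration skips stages whose outputs already exist.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from pathlib import Path

import numpy as np

from . import io as pio
from .adjoint import SensitivityField, run_adjoint
from .attribution import (negative_sensitivity_census, reduction_burden,
                          seasonal_summary, sector_contribution)
from .gemm import GemmCost
from .grid import Trajectory
from .synth import World, WorldConfig, make_scenario, make_world
from .valuation import vsl_map
from .validation import adjoint_vs_fdm_report

__all__ = ["hourly_forcing", "run_pipeline", "load_config", "STAGES"]

STAGES = ("synth", "forward", "forcing", "adjoint", "adjoint_usd",
          "attribute", "validate")


def hourly_forcing(traj: Trajectory, cost, vsl: np.ndarray | None = None) -> np.ndarray:
    """Adjoint forcing per stored hour, (n_hours, ny, nx).

    The cost's exposure gradient is spread uniformly over the non-spin-up
    hours; spin-up hours get zero.  With a VSL map the forcing is monetized
    at the receptor before the backward run.
    """
    g = traj.grid
    grad = cost.gradient(traj.exposure_mean())
    if vsl is not None:
        grad = grad * vsl
    per_hour = grad / traj.effective_hours
    forcing = np.zeros((g.n_hours, g.ny, g.nx))
    forcing[traj.spin_up_hours:] = per_hour
    return forcing


def load_config(path) -> WorldConfig:
    """Read a run configuration from YAML (schema = WorldConfig fields)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "scenario" in raw:
        name = raw.pop("scenario")
        cfg = make_scenario(name, seed=raw.pop("seed", 0))
        return dataclasses.replace(cfg, **_coerce(raw))
    fields = {f.name for f in dataclasses.fields(WorldConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return WorldConfig(**_coerce(raw))


def _coerce(raw: dict) -> dict:
    out = dict(raw)
    for key in ("bmr_range", "o3bg_range", "gdp_ratio_range",
                "cpi_change_range", "income_growth_range"):
        if key in out and isinstance(out[key], list):
            out[key] = tuple(out[key])
    return out


def _config_hash(cfg: WorldConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _log(stage: str, **info) -> None:
    print(json.dumps({"stage": stage, **info}), file=sys.stderr)


def run_pipeline(cfg: WorldConfig, outdir, stages=STAGES, f: float = 0.10,
                 n_probes: int = 20, force: bool = False) -> dict:
    """Execute the requested stages in dependency order.

    Returns the run manifest (also written to ``manifest.json``): config
    hash, seed, per-stage timings and output paths.  Outputs that already
    exist under the same config hash are reused unless ``force``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    manifest_path = outdir / "manifest.json"
    manifest: dict = {"config_hash": chash, "seed": cfg.seed,
                      "stages": {}, "files": {}}
    if manifest_path.exists() and not force:
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == chash:
            manifest = old
            manifest.setdefault("stages", {})
            manifest.setdefault("files", {})

    world = make_world(cfg)
    cost = GemmCost(world.panel, world.gemm)
    state: dict = {}

    def fresh(stage: str, *files: str) -> bool:
        if force:
            return False
        done = stage in manifest["stages"]
        return done and all((outdir / f).exists() for f in files)

    def record(stage: str, t0: float, *files: str) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        for f in files:
            manifest["files"][f] = str(outdir / f)
        manifest_path.write_text(json.dumps(manifest, indent=2))

    def ensure_forward():
        """Forward run + checkpoint records (recomputed when needed; the
        chemistry linearization records are never serialized)."""
        if "traj" not in state:
            model = world.model()
            traj, records = model.run(world.emissions(), cfg.spin_up_hours,
                                      keep_records=True)
            state.update(model=model, traj=traj, records=records,
                         forcing=hourly_forcing(traj, cost))
        return state["model"], state["traj"], state["records"], state["forcing"]

    def ensure_sens(monetized: bool) -> SensitivityField:
        key = "usd_sens" if monetized else "sens"
        fname = "sensitivity_usd.nc" if monetized else "sensitivity_deaths.nc"
        stage = "adjoint_usd" if monetized else "adjoint"
        if key in state:
            return state[key]
        if fresh(stage, fname):
            state[key] = pio.load_sensitivity(outdir / fname, world.species)
            return state[key]
        t0 = time.time()
        model, traj, records, forcing = ensure_forward()
        if monetized:
            vsl = vsl_map(world.mask.ids, world.econ)
            forcing = hourly_forcing(traj, cost, vsl=vsl)
        units = "usd/ton" if monetized else "deaths/ton"
        s = run_adjoint(model, traj, records, forcing, units=units)
        pio.save_sensitivity(s, outdir / fname)
        record(stage, t0, fname)
        _log(stage, max_per_ton=float(s.values.max()))
        state[key] = s
        return s

    if "synth" in stages:
        files = ("met.nc", "emissions.nc", "population.csv", "regions.csv",
                 "economics.csv")
        if fresh("synth", *files):
            _log("synth", skipped=True)
        else:
            t0 = time.time()
            pio.save_met(world.met, outdir / "met.nc")
            pio.save_inventory(world.inventory, outdir / "emissions.nc")
            pio.save_exposure_panel(world.panel, outdir / "population.csv")
            pio.save_region_mask(world.mask, outdir / "regions.csv")
            pio.save_econ_panel(world.econ, outdir / "economics.csv")
            record("synth", t0, *files)
            _log("synth", total_population=float(world.panel.population.sum()),
                 total_emissions_tons=float(world.emissions().sum()))

    if "forward" in stages:
        if fresh("forward", "trajectory.nc"):
            _log("forward", skipped=True)
        else:
            t0 = time.time()
            _, traj, _, _ = ensure_forward()
            pio.save_trajectory(traj, outdir / "trajectory.nc")
            record("forward", t0, "trajectory.nc")
            _log("forward", mean_pm25=float(traj.exposure_mean().mean()),
                 max_pm25=float(traj.exposure_mean().max()))

    if "forcing" in stages:
        _, traj, _, forcing = ensure_forward()
        _log("forcing", total_mortality=cost.value(traj.exposure_mean()),
             forced_cells=int((forcing[-1] > 0).sum()))

    if "adjoint" in stages:
        ensure_sens(monetized=False)
    if "adjoint_usd" in stages:
        ensure_sens(monetized=True)

    if "attribute" in stages:
        t0 = time.time()
        sens = ensure_sens(monetized=False)
        usd_sens = ensure_sens(monetized=True)
        burden = reduction_burden(sens, world.inventory, world.mask, f=f,
                                  usd_sens=usd_sens)
        burden.to_csv(outdir / "burden.csv", index=False)
        sector_contribution(burden).to_csv(outdir / "sector_shares.csv",
                                           index=False)
        seasonal_summary(sens).to_csv(outdir / "seasonal.csv", index=False)
        census = negative_sensitivity_census(sens)
        census.to_csv(outdir / "negative_census.csv", index=False)
        record("attribute", t0, "burden.csv", "sector_shares.csv",
               "seasonal.csv", "negative_census.csv")
        _log("attribute", f=f,
             total_deaths=float(burden["deaths"].sum()),
             total_usd=float(burden["usd"].sum()),
             negative_cells=int(census["n_negative_cells"].sum()))

    if "validate" in stages:
        t0 = time.time()
        sens = ensure_sens(monetized=False)
        report = adjoint_vs_fdm_report(
            world, n_probes=n_probes, seed=cfg.seed,
            adaptive=cfg.chemistry_mode == "titration", sens=sens)
        table = report.pop("table")
        table.to_csv(outdir / "fdm_probes.csv", index=False)
        (outdir / "fdm_summary.json").write_text(json.dumps(report, indent=2))
        record("validate", t0, "fdm_probes.csv", "fdm_summary.json")
        _log("validate", **report)

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
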