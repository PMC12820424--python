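"""File formats: NetCDF for gridded fields, CSV for tables, YAML for config.

Every gridded artifact uses dimensions (hour, y, x) — species either as a
dimension (trajectories, sensitivities, inventories) or as separate
variables (winds).  A units attribute is mandatory on read and write: unit
bugs are the main failure mode of this kind of pipeline, so a file without
units is rejected outright.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .adjoint import SensitivityField
from .attribution import EmissionInventory, RegionMask
from .gemm import ExposurePanel
from .grid import GridSpec, MetFields, SpeciesSet, Trajectory
from .valuation import EconPanel

__all__ = [
    "save_trajectory", "load_trajectory",
    "save_sensitivity", "load_sensitivity",
    "save_met", "load_met",
    "save_inventory", "load_inventory",
    "save_exposure_panel", "load_exposure_panel",
    "save_region_mask", "load_region_mask",
    "save_econ_panel", "load_econ_panel",
]

_ENGINE = "scipy"  # NetCDF3 classic; no compiled NetCDF4 dependency


def _require_units(da: xr.DataArray, path) -> str:
    units = da.attrs.get("units")
    if not units:
        raise ValueError(f"{path}: variable {da.name!r} lacks a units attribute")
    return units


def _require_hour_dim(ds: xr.Dataset, path) -> None:
    if "hour" not in ds.dims:
        raise ValueError(f"{path}: gridded file lacks an 'hour' dimension")


# -- trajectories -----------------------------------------------------------

def save_trajectory(traj: Trajectory, path) -> None:
    ds = xr.Dataset(
        {"conc": (("hour", "species", "y", "x"), traj.concentrations)},
        coords={"hour": np.arange(traj.concentrations.shape[0]),
                "species": list(traj.species.names)},
        attrs={"spin_up_hours": traj.spin_up_hours,
               "dx_km": traj.grid.dx_km, "dt_s": traj.grid.dt_s,
               "boundary": traj.grid.boundary,
               "mixing_height_m": traj.grid.mixing_height_m},
    )
    ds["conc"].attrs["units"] = "ug/m3"
    ds.to_netcdf(path, engine=_ENGINE)


def load_trajectory(path, species: SpeciesSet | None = None) -> Trajectory:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds = ds.load()
    _require_hour_dim(ds, path)
    _require_units(ds["conc"], path)
    species = species or SpeciesSet()
    names = tuple(str(s) for s in ds["species"].values)
    if names != species.names:
        raise ValueError(f"{path}: species {names} do not match the run's species set")
    conc = np.asarray(ds["conc"].values)
    n_hours = conc.shape[0] - 1
    grid = GridSpec(
        nx=conc.shape[3], ny=conc.shape[2],
        dx_km=float(ds.attrs["dx_km"]), dt_s=float(ds.attrs["dt_s"]),
        n_hours=n_hours, boundary=str(ds.attrs["boundary"]),
        mixing_height_m=float(ds.attrs["mixing_height_m"]),
    )
    return Trajectory(conc, species, grid, int(ds.attrs["spin_up_hours"]))


# -- sensitivities ----------------------------------------------------------

def save_sensitivity(sens: SensitivityField, path) -> None:
    ds = xr.Dataset(
        {"sens": (("species", "hour", "y", "x"), sens.values),
         "spin_up": (("hour",), sens.spin_up_mask.astype(np.int8))},
        coords={"hour": np.arange(sens.grid.n_hours),
                "species": list(sens.species.names)},
        attrs={"dx_km": sens.grid.dx_km, "dt_s": sens.grid.dt_s,
               "boundary": sens.grid.boundary,
               "mixing_height_m": sens.grid.mixing_height_m},
    )
    ds["sens"].attrs["units"] = sens.units
    ds.to_netcdf(path, engine=_ENGINE)


def load_sensitivity(path, species: SpeciesSet | None = None) -> SensitivityField:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds = ds.load()
    _require_hour_dim(ds, path)
    units = _require_units(ds["sens"], path)
    species = species or SpeciesSet()
    vals = np.asarray(ds["sens"].values)
    grid = GridSpec(
        nx=vals.shape[3], ny=vals.shape[2],
        dx_km=float(ds.attrs["dx_km"]), dt_s=float(ds.attrs["dt_s"]),
        n_hours=vals.shape[1], boundary=str(ds.attrs["boundary"]),
        mixing_height_m=float(ds.attrs["mixing_height_m"]),
    )
    mask = np.asarray(ds["spin_up"].values).astype(bool)
    return SensitivityField(vals, species, grid, units=units, spin_up_mask=mask)


# -- meteorology ------------------------------------------------------------

def save_met(met: MetFields, path) -> None:
    data = {
        "u": (("hour", "y", "x"), met.u),
        "v": (("hour", "y", "x"), met.v),
    }
    t = met.temperature_index
    if t.ndim == 1:
        data["temperature_index"] = (("hour",), t)
    else:
        data["temperature_index"] = (("hour", "channel"), t)
    if met.o3bg is not None:
        data["o3bg"] = (("hour", "y", "x"), met.o3bg)
    ds = xr.Dataset(data, coords={"hour": np.arange(met.u.shape[0])})
    ds["u"].attrs["units"] = "m/s"
    ds["v"].attrs["units"] = "m/s"
    ds["temperature_index"].attrs["units"] = "1"
    if met.o3bg is not None:
        ds["o3bg"].attrs["units"] = "ug/m3"
    ds.to_netcdf(path, engine=_ENGINE)


def load_met(path) -> MetFields:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds = ds.load()
    _require_hour_dim(ds, path)
    for var in ("u", "v", "temperature_index"):
        _require_units(ds[var], path)
    o3 = np.asarray(ds["o3bg"].values) if "o3bg" in ds else None
    return MetFields(np.asarray(ds["u"].values), np.asarray(ds["v"].values),
                     np.asarray(ds["temperature_index"].values), o3)


# -- emissions --------------------------------------------------------------

def save_inventory(inv: EmissionInventory, path) -> None:
    sectors = list(inv.sectors)
    stack = np.stack([inv.rates[s] for s in sectors])
    ds = xr.Dataset(
        {"emissions": (("sector", "species", "hour", "y", "x"), stack)},
        coords={"sector": sectors, "species": list(inv.species_names),
                "hour": np.arange(stack.shape[2])},
        attrs={"levels": " ".join(f"{s}:{inv.level[s]}" for s in sectors)},
    )
    ds["emissions"].attrs["units"] = "tons/hr"
    ds.to_netcdf(path, engine=_ENGINE)


def load_inventory(path) -> EmissionInventory:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds = ds.load()
    _require_hour_dim(ds, path)
    _require_units(ds["emissions"], path)
    sectors = [str(s) for s in ds["sector"].values]
    names = tuple(str(s) for s in ds["species"].values)
    levels = dict(item.split(":") for item in ds.attrs["levels"].split())
    arr = np.asarray(ds["emissions"].values)
    rates = {s: arr[i] for i, s in enumerate(sectors)}
    return EmissionInventory(rates, names, levels)


# -- tables -----------------------------------------------------------------

def save_exposure_panel(panel: ExposurePanel, path) -> None:
    ny, nx = panel.population.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    pd.DataFrame({
        "y": yy.ravel(), "x": xx.ravel(),
        "population": panel.population.ravel(),
        "bmr": panel.bmr.ravel(),
    }).to_csv(path, index=False)


def load_exposure_panel(path) -> ExposurePanel:
    df = pd.read_csv(path)
    required = {"y", "x", "population", "bmr"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}")
    ny, nx = int(df["y"].max()) + 1, int(df["x"].max()) + 1
    pop = np.zeros((ny, nx))
    bmr = np.zeros((ny, nx))
    pop[df["y"], df["x"]] = df["population"]
    bmr[df["y"], df["x"]] = df["bmr"]
    return ExposurePanel(pop, bmr)


def save_region_mask(mask: RegionMask, path) -> None:
    ny, nx = mask.ids.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    pd.DataFrame({
        "y": yy.ravel(), "x": xx.ravel(),
        "region": mask.ids.ravel(),
        "name": [mask.names[int(r)] for r in mask.ids.ravel()],
    }).to_csv(path, index=False)


def load_region_mask(path) -> RegionMask:
    df = pd.read_csv(path)
    ny, nx = int(df["y"].max()) + 1, int(df["x"].max()) + 1
    ids = np.zeros((ny, nx), dtype=int)
    ids[df["y"], df["x"]] = df["region"]
    names = {int(r): str(n) for r, n in
             df[["region", "name"]].drop_duplicates().itertuples(index=False)}
    return RegionMask(ids, names)


def save_econ_panel(econ: EconPanel, path) -> None:
    econ.table.to_csv(path, index=False)


def load_econ_panel(path) -> EconPanel:
    return EconPanel(pd.read_csv(path))
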