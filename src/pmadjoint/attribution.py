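"""Reporting layer: regional f-fraction burdens, sector shares, seasons.

Sensitivities are marginal (per ton at the current state), so the first-order
burden of reducing a set of emissions by a fraction f is f·Σ sens·E over the
selected sources, additive across sectors.  Burdens are attributed to the
*source* cell's region (where the reduction happens); deaths and USD
variants come from the respective sensitivity fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adjoint import SensitivityField

__all__ = [
    "EmissionInventory",
    "RegionMask",
    "reduction_burden",
    "sector_contribution",
    "seasonal_summary",
    "negative_sensitivity_census",
    "season_of_hour",
    "SEASONS",
]

SEASONS = ("DJF", "MAM", "JJA", "SON")


@dataclass
class EmissionInventory:
    """Per-sector hourly emissions with a surface/elevated attribution tag.

    ``rates[sector][s, h, j, i]`` in tons/hr, species axis aligned with the
    run's SpeciesSet.  In a single-layer model the level tag cannot alter
    dispersion; it is carried purely as a reporting label.
    """

    rates: dict[str, np.ndarray]
    species_names: tuple[str, ...]
    level: dict[str, str] = field(default_factory=dict)  # sector -> surface|elevated

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.rates.values()}
        if len(shapes) > 1:
            raise ValueError(f"sector arrays disagree in shape: {shapes}")
        for name, arr in self.rates.items():
            if (arr < 0).any():
                raise ValueError(f"negative emissions in sector {name!r}")
            if arr.shape[0] != len(self.species_names):
                raise ValueError(f"sector {name!r} species axis mismatch")
        for sec in self.rates:
            self.level.setdefault(sec, "surface")

    @property
    def sectors(self) -> tuple[str, ...]:
        return tuple(self.rates)

    def total(self) -> np.ndarray:
        """Sum over sectors, (n_species, n_hours, ny, nx) — what the forward
        model burns."""
        return np.sum(list(self.rates.values()), axis=0)

    def by_level(self, level: str) -> np.ndarray:
        sel = [v for k, v in self.rates.items() if self.level[k] == level]
        if not sel:
            first = next(iter(self.rates.values()))
            return np.zeros_like(first)
        return np.sum(sel, axis=0)


@dataclass
class RegionMask:
    """Total partition of the grid into named regions."""

    ids: np.ndarray  # (ny, nx), int region id per cell
    names: dict[int, str]

    def __post_init__(self) -> None:
        present = set(np.unique(self.ids).tolist())
        if not present <= set(self.names):
            raise ValueError(f"regions without names: {present - set(self.names)}")

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.names)


def _burden_slice(sens_values: np.ndarray, emis: np.ndarray, f: float,
                  mask: RegionMask, species_names, per_species_cellhour=None):
    """f·Σ sens·E rolled up by source region × species."""
    contrib = sens_values * emis  # (ns, nh, ny, nx), cost per (1/f) fraction
    rows = []
    for r in mask.region_ids:
        cells = mask.ids == r
        for si, sname in enumerate(species_names):
            rows.append((mask.names[r], sname,
                         f * float(contrib[si][:, cells].sum())))
    return rows


def reduction_burden(sens: SensitivityField, inventory: EmissionInventory,
                     mask: RegionMask, f: float = 0.10,
                     usd_sens: SensitivityField | None = None,
                     include_spin_up: bool = False) -> pd.DataFrame:
    """First-order burden of an f-fraction reduction of all emissions.

    Returns tidy rows (region, sector, species, level, deaths[, usd]) where
    ``deaths`` is the avoided mortality attributed to reducing that sector's
    emissions of that species in that source region by the fraction f.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    g = sens.grid
    keep = np.ones(g.n_hours, dtype=bool) if include_spin_up else ~sens.spin_up_mask
    sv = sens.values[:, keep]
    uv = usd_sens.values[:, keep] if usd_sens is not None else None
    rows = []
    for sector, arr in inventory.rates.items():
        e = arr[:, keep]
        for r in mask.region_ids:
            cells = mask.ids == r
            for si, sname in enumerate(sens.species.names):
                deaths = f * float((sv[si] * e[si])[:, cells].sum())
                row = {
                    "region": mask.names[r],
                    "sector": sector,
                    "species": sname,
                    "level": inventory.level[sector],
                    "deaths": deaths,
                }
                if uv is not None:
                    row["usd"] = f * float((uv[si] * e[si])[:, cells].sum())
                rows.append(row)
    return pd.DataFrame(rows)


def sector_contribution(burden: pd.DataFrame) -> pd.DataFrame:
    """Per-sector totals and fractional shares of the whole-inventory burden.

    Shares are taken over the full inventory (the configured anthropogenic
    sectors plus any natural/residual sector), so they sum to 1.
    """
    if burden.empty:
        raise ValueError("empty burden table")
    cols = ["deaths"] + (["usd"] if "usd" in burden.columns else [])
    by_sector = burden.groupby("sector")[cols].sum()
    totals = by_sector.sum()
    for c in cols:
        by_sector[f"{c}_share"] = (
            by_sector[c] / totals[c] if totals[c] != 0 else np.nan
        )
    return by_sector.reset_index()


def season_of_hour(n_hours: int, seasons: tuple[str, ...] = SEASONS) -> np.ndarray:
    """Map hour index -> season label, proportionally for short calendars.

    A full year maps to the four meteorological quarters; a toy calendar of
    n hours is split into len(seasons) equal consecutive blocks.
    """
    edges = np.linspace(0, n_hours, len(seasons) + 1)
    labels = np.empty(n_hours, dtype=object)
    for k, name in enumerate(seasons):
        labels[(np.arange(n_hours) >= edges[k]) & (np.arange(n_hours) < edges[k + 1])] = name
    return labels


def seasonal_summary(sens: SensitivityField,
                     calendar: np.ndarray | None = None) -> pd.DataFrame:
    """Per-season, per-species max and mean sensitivity (deaths/kton units).

    ``calendar`` maps each hour to a season label; omitted, the run's hours
    are split proportionally into DJF/MAM/JJA/SON.
    """
    g = sens.grid
    if calendar is None:
        calendar = season_of_hour(g.n_hours)
    calendar = np.asarray(calendar)
    if calendar.shape != (g.n_hours,) or (calendar == None).any():  # noqa: E711
        raise ValueError("calendar must label every hour")
    per_kton = sens.per_kton()
    rows = []
    for season in pd.unique(calendar):
        hours = calendar == season
        for si, name in enumerate(sens.species.names):
            block = per_kton[si, hours]
            rows.append({
                "season": season,
                "species": name,
                "n_hours": int(hours.sum()),
                "max_per_kton": float(block.max()),
                "mean_per_kton": float(block.mean()),
            })
    return pd.DataFrame(rows)


def negative_sensitivity_census(sens: SensitivityField,
                                include_spin_up: bool = False) -> pd.DataFrame:
    """Cells whose annual aggregate sensitivity is negative, per species.

    Empty in linear-chemistry mode (non-negativity invariant); expected
    nonempty for NOx under titration chemistry in oxidant-limited,
    populated areas.
    """
    annual = sens.annual(include_spin_up=include_spin_up)
    rows = []
    for si, name in enumerate(sens.species.names):
        neg = annual[si] < 0
        rows.append({
            "species": name,
            "n_negative_cells": int(neg.sum()),
            "min_annual_per_ton": float(annual[si].min()),
        })
    return pd.DataFrame(rows)
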