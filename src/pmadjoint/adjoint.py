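"""Exact discrete adjoint of the forward transport model.

The backward sweep applies the transposes of the forward sub-operators in
exactly reversed order (diffuse, advect, deposit, chemistry), injecting the
cost-function forcing at each stored hour, and reads off the sensitivity of
the cost to emissions at every (species, cell, hour) — one backward run per
cost function, instead of one forward run per source.

Because the adjoint is the transpose of the *coded* forward update (discrete
adjoint), duality ⟨Ax, y⟩ = ⟨x, Aᵀy⟩ holds to machine precision, which the
validation module exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec, SpeciesSet, Trajectory
from .transport import ForwardModel

__all__ = ["SensitivityField", "run_adjoint", "emission_weighted_primary_pm"]


@dataclass
class SensitivityField:
    """∂J/∂E per (species, hour, y, x), internally in cost units per ton.

    ``values[s, h, j, i]`` is the change in the cost J per ton of species s
    emitted in cell (j, i) during hour h (i.e. at a rate of 1 ton/hr
    sustained for that hour).  ``units`` is ``"deaths/ton"`` or
    ``"usd/ton"``.  ``spin_up_mask`` flags emission hours inside the forward
    spin-up window, whose sensitivities are excluded from annual aggregates
    by default.
    """

    values: np.ndarray
    species: SpeciesSet
    grid: GridSpec
    units: str = "deaths/ton"
    spin_up_mask: np.ndarray | None = None  # (n_hours,), True = spin-up hour

    def __post_init__(self) -> None:
        g = self.grid
        expected = (self.species.n_species, g.n_hours, g.ny, g.nx)
        if self.values.shape != expected:
            raise ValueError(f"sensitivity shape {self.values.shape} != {expected}")
        if self.spin_up_mask is None:
            self.spin_up_mask = np.zeros(g.n_hours, dtype=bool)

    def per_kton(self) -> np.ndarray:
        """Reporting view: deaths (or USD) per kiloton."""
        return self.values * 1000.0

    def annual(self, include_spin_up: bool = False) -> np.ndarray:
        """Aggregate over emission hours: (species, ny, nx), per ton."""
        if include_spin_up:
            return self.values.sum(axis=1)
        keep = ~self.spin_up_mask
        return self.values[:, keep].sum(axis=1)

    def select(self, name: str) -> np.ndarray:
        return self.values[self.species.index(name)]


def run_adjoint(model: ForwardModel, trajectory: Trajectory,
                records: list, forcing: np.ndarray,
                units: str = "deaths/ton") -> SensitivityField:
    """Backward sweep driven by hourly forcing fields.

    Parameters
    ----------
    model
        The forward model the trajectory came from (supplies the transposes).
    trajectory, records
        Output of ``model.run(..., keep_records=True)``; the records hold the
        chemistry linearization at every stored sub-step (checkpointing).
    forcing
        ∂J/∂(concentration at the state stored for hour h), shape
        (n_hours, ny, nx), applied equally to every PM2.5-component species.
        Hour h of this array forces the state at the *end* of hour h
        (``trajectory.concentrations[h+1]`` ... index h forces state h+1).

    Returns
    -------
    SensitivityField in ``units`` per ton emitted.
    """
    g = model.grid
    sp = model.species
    if trajectory.n_hours != g.n_hours:
        raise ValueError("trajectory does not cover the model's hours")
    if forcing.shape != (g.n_hours, g.ny, g.nx):
        raise ValueError(
            f"forcing shape {forcing.shape} != {(g.n_hours, g.ny, g.nx)}"
        )
    if len(records) != g.n_hours:
        raise ValueError(
            f"checkpoint records cover {len(records)} hours, need {g.n_hours}"
        )
    pm_idx = sp.indices(sp.pm_species)
    lam = np.zeros((sp.n_species, g.ny, g.nx))
    sens = np.zeros((sp.n_species, g.n_hours, g.ny, g.nx))
    conv = model.emission_conversion
    for h in range(g.n_hours - 1, -1, -1):
        # forcing for the state at the end of hour h
        lam[pm_idx] += forcing[h]
        hour_recs = records[h]
        if len(hour_recs) != g.steps_per_hour:
            raise ValueError(f"missing checkpoint records at hour {h}")
        for rec in reversed(hour_recs):
            lam = model.substep_transpose(lam, rec, h)
            # λ here is ∂J/∂(state immediately before this sub-step's
            # injection); emissions held constant over the hour accumulate
            # one conv-weighted contribution per sub-step.
            sens[:, h] += lam * conv
    mask = np.arange(g.n_hours) < trajectory.spin_up_hours
    return SensitivityField(sens, sp, g, units=units, spin_up_mask=mask)


def emission_weighted_primary_pm(sens: SensitivityField,
                                 emissions: np.ndarray) -> np.ndarray:
    """Aggregate primary-species sensitivities into one primary-PM channel.

    Per cell-hour, the aggregate is the emission-mass-weighted mean of the
    primary species' sensitivities; where no primary PM is emitted the
    unweighted mean is used (the species are then indistinguishable).

    Parameters
    ----------
    sens
        Full sensitivity field.
    emissions
        (n_species, n_hours, ny, nx) tons/hr, aligned with ``sens``.

    Returns
    -------
    (n_hours, ny, nx) array in the same per-ton units as ``sens``.
    """
    sp = sens.species
    idx = sp.indices(sp.primary)
    s = sens.values[idx]
    e = np.asarray(emissions)[idx]
    total = e.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        weighted = np.where(total > 0, (s * e).sum(axis=0) / total, s.mean(axis=0))
    return weighted
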