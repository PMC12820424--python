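"""Brute-force finite-difference verification of the adjoint.

The traditional way to get a source sensitivity is to perturb one emission
and rerun the forward model.  Here that brute-force estimate — a central
difference over two full forward runs with the true (non-linearized) cost —
serves as the independent oracle for the adjoint: probes are sampled over
(species, cell, hour), paired adjoint/FDM values are regressed, and the
report carries the OLS slope, R² and error summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import scipy.stats

from .adjoint import SensitivityField, run_adjoint
from .gemm import GemmCost
from .synth import World

__all__ = ["FdmProbe", "fdm_sensitivity", "adjoint_vs_fdm_report",
           "deaths_sensitivity_field"]


@dataclass(frozen=True)
class FdmProbe:
    """One brute-force perturbation: which emission, and by how much."""

    species: int
    y: int
    x: int
    hour: int
    delta_tons_per_h: float

    def __post_init__(self) -> None:
        if self.delta_tons_per_h <= 0:
            raise ValueError("perturbation must be > 0")


def _cost_of(world: World, emissions: np.ndarray, cost=None) -> float:
    model = world.model()
    traj = model.run(emissions, world.config.spin_up_hours)
    cost = cost or GemmCost(world.panel, world.gemm)
    return cost.value(traj.exposure_mean())


def fdm_sensitivity(world: World, probe: FdmProbe, cost=None,
                    emissions: np.ndarray | None = None) -> float:
    """Central-difference sensitivity, cost units per ton.

    Two forward runs at E ± δ·e, where e emits during one hour in one cell;
    δ tons/hr for one hour is δ tons, so the difference quotient is per ton.
    """
    E = world.emissions() if emissions is None else emissions
    g = world.grid
    if not (0 <= probe.hour < g.n_hours and 0 <= probe.y < g.ny
            and 0 <= probe.x < g.nx):
        raise ValueError("probe outside the grid/time bounds")
    d = probe.delta_tons_per_h
    up = E.copy()
    up[probe.species, probe.hour, probe.y, probe.x] += d
    dn = E.copy()
    dn[probe.species, probe.hour, probe.y, probe.x] -= d
    if dn[probe.species, probe.hour, probe.y, probe.x] < 0:
        # keep the two-sided stencil but never feed negative emissions forward
        dn[probe.species, probe.hour, probe.y, probe.x] = 0.0
        d_eff = (up[probe.species, probe.hour, probe.y, probe.x]
                 - 0.0) / 2.0
        jp = _cost_of(world, up, cost)
        jm = _cost_of(world, dn, cost)
        return (jp - jm) / (2.0 * d_eff)
    jp = _cost_of(world, up, cost)
    jm = _cost_of(world, dn, cost)
    return (jp - jm) / (2.0 * d)


def deaths_sensitivity_field(world: World, cost=None) -> SensitivityField:
    """One forward + one backward run: the adjoint sensitivity field."""
    from .pipeline import hourly_forcing  # local import avoids a cycle

    model = world.model()
    traj, records = model.run(world.emissions(), world.config.spin_up_hours,
                              keep_records=True)
    cost = cost or GemmCost(world.panel, world.gemm)
    forcing = hourly_forcing(traj, cost)
    return run_adjoint(model, traj, records, forcing)


def adjoint_vs_fdm_report(world: World, n_probes: int = 50, seed: int = 0,
                          delta: float | None = None,
                          adaptive: bool = False,
                          cost=None,
                          sens: SensitivityField | None = None) -> dict:
    """Paired adjoint/FDM comparison over sampled probes.

    Probes are sampled with weights proportional to |adjoint sensitivity|
    (plus a floor), so the regression is not dominated by cells the receptors
    cannot see.  ``adaptive`` tries δ ∈ {1e-1, 1e-2, 1e-3}·max(local E, 1)
    per probe and keeps the value where successive estimates agree best —
    the right default for the nonlinear titration mechanism.

    Returns a dict with slope, intercept, r2, max_rel_err, median_rel_err
    and the probe table.
    """
    if n_probes < 2:
        raise ValueError("need at least two probes")
    rng = np.random.default_rng(seed)
    if sens is None:
        sens = deaths_sensitivity_field(world, cost)
    mag = np.abs(sens.values)
    if mag.max() == 0:
        raise ValueError("degenerate comparison: all adjoint sensitivities are zero "
                         "(is the forcing empty?)")
    w = (mag + 1e-3 * mag.max()).ravel()
    w /= w.sum()
    flat_idx = rng.choice(mag.size, size=n_probes, replace=False, p=w)
    E = world.emissions()
    rows = []
    for fi in flat_idx:
        si, h, yj, xi = np.unravel_index(fi, mag.shape)
        local = E[si, h, yj, xi]
        base = max(local, 1.0)
        adj_val = float(sens.values[si, h, yj, xi])
        if adaptive:
            cands = []
            for scale in (1e-1, 1e-2, 1e-3):
                p = FdmProbe(int(si), int(yj), int(xi), int(h), scale * base)
                cands.append(fdm_sensitivity(world, p, cost))
            # keep the finer-δ member of the most mutually consistent pair
            diffs = [abs(cands[i + 1] - cands[i]) for i in range(len(cands) - 1)]
            fdm_val = cands[int(np.argmin(diffs)) + 1]
            d_used = (1e-1, 1e-2, 1e-3)[int(np.argmin(diffs)) + 1] * base
        else:
            d_used = (delta if delta is not None else 1e-2) * base
            probe = FdmProbe(int(si), int(yj), int(xi), int(h), d_used)
            fdm_val = fdm_sensitivity(world, probe, cost)
        rows.append({"species": world.species.names[si], "hour": int(h),
                     "y": int(yj), "x": int(xi), "delta": d_used,
                     "adjoint": adj_val, "fdm": fdm_val})
    table = pd.DataFrame(rows)
    fit = scipy.stats.linregress(table["adjoint"], table["fdm"])
    denom = np.maximum(np.abs(table["fdm"]), 1e-300)
    rel = np.abs(table["adjoint"] - table["fdm"]) / denom
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue**2),
        "max_rel_err": float(rel.max()),
        "median_rel_err": float(rel.median()),
        "n_probes": int(n_probes),
        "table": table,
    }
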