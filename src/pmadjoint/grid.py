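"""Domain containers for the reduced single-layer Eulerian transport model.

The model lives on a rectangular grid of square cells with winds defined at
cell centers, a single well-mixed vertical layer of fixed depth, and an
hourly clock.  Everything downstream (the adjoint, the health cost, the
attribution reports) indexes fields as (hour, y, x) row-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "Conversion",
    "SpeciesSet",
    "MetFields",
    "Trajectory",
    "TONS_TO_UG",
]

#: micrograms per (metric) ton — the unit bridge between emission inventories
#: (tons/hr) and concentrations (μg/m³).
TONS_TO_UG = 1.0e12


class ConfigurationError(ValueError):
    """Raised when a run configuration is internally inconsistent."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry and clock of a run.

    Parameters
    ----------
    nx, ny
        Cell counts along x (east) and y (north).
    dx_km
        Cell edge length in kilometres (cells are square).
    dt_s
        Transport timestep in seconds; must divide one hour evenly.
    n_hours
        Simulation length in hours.
    boundary
        ``"zero_inflow"`` (limited-area domain, default) or ``"periodic"``
        (used chiefly for conservation tests).
    mixing_height_m
        Effective depth of the single well-mixed layer, metres.
    """

    nx: int
    ny: int
    dx_km: float = 100.0
    dt_s: float = 3600.0
    n_hours: int = 240
    boundary: str = "zero_inflow"
    mixing_height_m: float = 800.0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ConfigurationError("nx and ny must be >= 1")
        if self.dx_km <= 0 or self.dt_s <= 0 or self.mixing_height_m <= 0:
            raise ConfigurationError("dx_km, dt_s, mixing_height_m must be > 0")
        if self.boundary not in ("zero_inflow", "periodic"):
            raise ConfigurationError(f"unknown boundary {self.boundary!r}")
        if abs(3600.0 / self.dt_s - round(3600.0 / self.dt_s)) > 1e-9:
            raise ConfigurationError("dt_s must divide 3600 s evenly")
        if self.n_hours < 1:
            raise ConfigurationError("n_hours must be >= 1")

    @property
    def steps_per_hour(self) -> int:
        return int(round(3600.0 / self.dt_s))

    @property
    def dx_m(self) -> float:
        return self.dx_km * 1000.0

    @property
    def cell_area_m2(self) -> float:
        return self.dx_m * self.dx_m

    @property
    def cell_volume_m3(self) -> float:
        return self.cell_area_m2 * self.mixing_height_m

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def check_cfl(self, u: np.ndarray, v: np.ndarray) -> None:
        """Refuse winds whose combined Courant number exceeds 1.

        Donor-cell positivity in two dimensions needs
        ``|u| dt/dx + |v| dt/dx <= 1``, a slightly stronger condition than
        each direction alone.
        """
        cu = float(np.max(np.abs(u))) * self.dt_s / self.dx_m
        cv = float(np.max(np.abs(v))) * self.dt_s / self.dx_m
        if cu + cv > 1.0 + 1e-12:
            raise ConfigurationError(
                "CFL violation: max|u|*dt/dx + max|v|*dt/dx = "
                f"{cu:.4f} + {cv:.4f} > 1 "
                f"(max|u|={np.max(np.abs(u)):.3f} m/s, "
                f"max|v|={np.max(np.abs(v)):.3f} m/s, dt={self.dt_s} s, "
                f"dx={self.dx_m} m)"
            )

    def check_diffusion(self, k_m2s: float) -> None:
        if k_m2s < 0:
            raise ConfigurationError("diffusivity must be >= 0")
        nu = k_m2s * self.dt_s / self.dx_m**2
        if nu > 0.25 + 1e-12:
            raise ConfigurationError(
                f"explicit diffusion unstable: K*dt/dx^2 = {nu:.4f} > 1/4 "
                f"(K={k_m2s} m2/s, dt={self.dt_s} s, dx={self.dx_m} m)"
            )


@dataclass(frozen=True)
class Conversion:
    """One stylized gas → particle channel (first-order in the gas)."""

    gas: str
    particle: str
    rate_per_h: float  # base rate, modulated hourly by the temperature index
    yield_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.rate_per_h < 0:
            raise ConfigurationError("conversion rate must be >= 0")
        if not 0.0 <= self.yield_fraction <= 1.0:
            raise ConfigurationError("yield must lie in [0, 1]")


@dataclass(frozen=True)
class SpeciesSet:
    """Species list with roles, deposition rates, and conversion channels.

    Roles partition the list: ``primary`` are directly emitted PM2.5
    components, ``gases`` are precursors, ``secondary`` are the particulate
    products of the conversion channels.  PM2.5 mass is the sum of primary
    and secondary species.
    """

    primary: tuple[str, ...] = ("EC", "OC", "CRUST")
    gases: tuple[str, ...] = ("SO2", "NOX", "NH3")
    secondary: tuple[str, ...] = ("PSO4", "PNO3", "PNH4")
    deposition_per_h: dict = field(
        default_factory=lambda: {
            "EC": 0.03, "OC": 0.03, "CRUST": 0.05,
            "SO2": 0.05, "NOX": 0.08, "NH3": 0.10,
            "PSO4": 0.03, "PNO3": 0.04, "PNH4": 0.03,
        }
    )
    conversions: tuple[Conversion, ...] = (
        Conversion("SO2", "PSO4", 0.03),
        Conversion("NOX", "PNO3", 0.04),
        Conversion("NH3", "PNH4", 0.05),
    )

    def __post_init__(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            raise ConfigurationError("species names must be unique (roles partition)")
        for s in names:
            if self.deposition_per_h.get(s, 0.0) < 0:
                raise ConfigurationError(f"deposition rate for {s} must be >= 0")
        for c in self.conversions:
            if c.gas not in self.gases or c.particle not in self.secondary:
                raise ConfigurationError(
                    f"conversion {c.gas}->{c.particle} must map a gas to a secondary species"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return self.primary + self.gases + self.secondary

    @property
    def n_species(self) -> int:
        return len(self.names)

    @property
    def pm_species(self) -> tuple[str, ...]:
        """Species whose mass counts toward PM2.5."""
        return self.primary + self.secondary

    def index(self, name: str) -> int:
        return self.names.index(name)

    def indices(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)

    def deposition_vector(self) -> np.ndarray:
        return np.array([self.deposition_per_h.get(s, 0.0) for s in self.names])


@dataclass
class MetFields:
    """Hourly meteorology: winds, a seasonal temperature index, oxidant field.

    ``u`` and ``v`` are cell-center winds, shape (n_hours, ny, nx), m/s.
    ``temperature_index`` multiplies the base conversion rates each hour
    (a unitless stand-in for the temperature dependence of secondary
    formation and partitioning).  ``o3bg`` is the background oxidant proxy
    used only by the titration chemistry option.
    """

    u: np.ndarray
    v: np.ndarray
    temperature_index: np.ndarray  # (n_hours,) or (n_hours, n_conversions)
    o3bg: np.ndarray | None = None  # (n_hours, ny, nx), μg/m³ proxy

    def validate(self, grid: GridSpec) -> None:
        shape = (grid.n_hours, grid.ny, grid.nx)
        if self.u.shape != shape or self.v.shape != shape:
            raise ConfigurationError(
                f"wind shapes {self.u.shape}/{self.v.shape} != {shape}"
            )
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise ConfigurationError("winds must be finite")
        if self.temperature_index.shape[0] != grid.n_hours:
            raise ConfigurationError("temperature_index must cover every hour")
        if not np.isfinite(self.temperature_index).all():
            raise ConfigurationError("temperature_index must be finite")
        if self.o3bg is not None:
            if self.o3bg.shape != shape:
                raise ConfigurationError(f"o3bg shape {self.o3bg.shape} != {shape}")
            if not np.isfinite(self.o3bg).all():
                raise ConfigurationError("o3bg must be finite")

    def rate_scale(self, hour: int, conv_index: int) -> float:
        """Hourly multiplier for conversion channel ``conv_index``."""
        t = self.temperature_index
        if t.ndim == 1:
            return float(t[hour])
        return float(t[hour, conv_index])


@dataclass
class Trajectory:
    """Hourly concentration states, (n_hours+1, n_species, ny, nx), μg/m³.

    Index 0 is the initial condition; index h the state at the end of hour h.
    ``spin_up_hours`` marks the leading hours excluded from the chronic
    exposure average.
    """

    concentrations: np.ndarray
    species: SpeciesSet
    grid: GridSpec
    spin_up_hours: int = 0

    @property
    def n_hours(self) -> int:
        return self.concentrations.shape[0] - 1

    @property
    def effective_hours(self) -> int:
        """Hours entering the chronic exposure mean."""
        return self.n_hours - self.spin_up_hours

    def pm25(self) -> np.ndarray:
        """Total PM2.5 mass per stored state, (n_hours+1, ny, nx)."""
        idx = self.species.indices(self.species.pm_species)
        return self.concentrations[:, idx].sum(axis=1)

    def exposure_mean(self) -> np.ndarray:
        """Period-mean PM2.5 over non-spin-up hours, (ny, nx).

        States at the end of hours spin_up+1 .. n_hours contribute.
        """
        if self.effective_hours <= 0:
            raise ConfigurationError("spin_up_hours must leave at least one hour")
        pm = self.pm25()
        return pm[self.spin_up_hours + 1:].mean(axis=0)
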