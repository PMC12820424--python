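"""Reduced forward chemical-transport model.

Operator-split, single layer, fixed sub-step sequence
``inject -> chemistry -> deposit -> advect -> diffuse``.  Advection is
flux-form donor-cell (first-order upwind) and diffusion an explicit 5-point
stencil; both are assembled as sparse matrices so the adjoint can apply
their exact transposes.  Deposition is exact exponential decay.  Chemistry
is a stylized first-order gas-to-particle mechanism with an optional
oxidant-limited ("titration") NOx channel whose linearization is recorded
for the adjoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .grid import (
    TONS_TO_UG,
    ConfigurationError,
    GridSpec,
    MetFields,
    SpeciesSet,
    Trajectory,
)

__all__ = [
    "advection_matrix",
    "diffusion_matrix",
    "advect",
    "diffuse",
    "deposit",
    "inject_emissions",
    "chemistry_step",
    "ChemistryParams",
    "ForwardModel",
    "run_forward",
]


# ---------------------------------------------------------------------------
# transport operators as sparse matrices (cells flattened row-major y*nx+x)

def advection_matrix(u: np.ndarray, v: np.ndarray, grid: GridSpec,
                     dt_s: float | None = None) -> sp.csr_matrix:
    """Donor-cell upwind advection as a sparse linear operator.

    Face velocities are the mean of adjacent cell-center winds; the flux
    through a face is carried by the upwind cell.  Flux form conserves mass
    exactly under the periodic boundary; under zero_inflow, outflow faces
    use the interior donor and inflow faces carry zero flux, so mass is
    non-increasing.
    """
    dt = grid.dt_s if dt_s is None else dt_s
    grid.check_cfl(u, v)
    nx, ny = grid.nx, grid.ny
    n = grid.n_cells
    s = dt / grid.dx_m
    periodic = grid.boundary == "periodic"

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add(r: np.ndarray, c: np.ndarray, w: np.ndarray) -> None:
        rows.append(r.ravel())
        cols.append(c.ravel())
        vals.append(w.ravel())

    idx = np.arange(n).reshape(ny, nx)

    # interior + wrap x-faces: left cell (y,x), right cell (y,(x+1)%nx)
    if nx > 1 or periodic:
        xl = np.arange(nx if periodic else nx - 1)
        xr = (xl + 1) % nx
        L = idx[:, xl]
        R = idx[:, xr]
        uf = 0.5 * (u[:, xl] + u[:, xr])
        donor = np.where(uf >= 0, L, R)
        w = s * uf
        add(L, donor, -w)
        add(R, donor, w)
    if not periodic and nx > 0:
        # open boundary faces in x: outflow only
        Lw = idx[:, 0]
        uw = u[:, 0]
        out = np.minimum(uw, 0.0)  # westward outflow through west face
        add(Lw, Lw, s * out)
        Re = idx[:, -1]
        ue = u[:, -1]
        out = np.maximum(ue, 0.0)  # eastward outflow through east face
        add(Re, Re, -s * out)

    # y-faces: south cell (y,x), north cell ((y+1)%ny,x)
    if ny > 1 or periodic:
        ys = np.arange(ny if periodic else ny - 1)
        yn = (ys + 1) % ny
        S = idx[ys, :]
        N = idx[yn, :]
        vf = 0.5 * (v[ys, :] + v[yn, :])
        donor = np.where(vf >= 0, S, N)
        w = s * vf
        add(S, donor, -w)
        add(N, donor, w)
    if not periodic and ny > 0:
        Ss = idx[0, :]
        vs = v[0, :]
        out = np.minimum(vs, 0.0)
        add(Ss, Ss, s * out)
        Nn = idx[-1, :]
        vn = v[-1, :]
        out = np.maximum(vn, 0.0)
        add(Nn, Nn, -s * out)

    flux = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return (sp.identity(n, format="csr") + flux.tocsr()).tocsr()


def diffusion_matrix(k_m2s: float, grid: GridSpec,
                     dt_s: float | None = None) -> sp.csr_matrix:
    """Explicit 5-point diffusion operator.

    Periodic boundary wraps; zero_inflow uses no-flux (Neumann) walls so
    diffusion alone never destroys mass.
    """
    dt = grid.dt_s if dt_s is None else dt_s
    grid.check_diffusion(k_m2s)
    nx, ny, n = grid.nx, grid.ny, grid.n_cells
    nu = k_m2s * dt / grid.dx_m**2
    if nu == 0.0:
        return sp.identity(n, format="csr")
    periodic = grid.boundary == "periodic"
    idx = np.arange(n).reshape(ny, nx)
    rows, cols, vals = [], [], []

    def pair(a: np.ndarray, b: np.ndarray) -> None:
        # symmetric exchange nu across the face between cells a and b
        rows.extend([a.ravel(), a.ravel(), b.ravel(), b.ravel()])
        cols.extend([a.ravel(), b.ravel(), b.ravel(), a.ravel()])
        o = np.full(a.size, nu)
        vals.extend([-o, o, -o, o])

    if nx > 1:
        xl = np.arange(nx - 1)
        pair(idx[:, xl], idx[:, xl + 1])
    if periodic and nx > 1:
        pair(idx[:, -1], idx[:, 0])
    if ny > 1:
        ys = np.arange(ny - 1)
        pair(idx[ys, :], idx[ys + 1, :])
    if periodic and ny > 1:
        pair(idx[-1, :], idx[0, :])
    if not rows:
        return sp.identity(n, format="csr")
    lap = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return (sp.identity(n, format="csr") + lap.tocsr()).tocsr()


def advect(field: np.ndarray, u: np.ndarray, v: np.ndarray,
           grid: GridSpec) -> np.ndarray:
    """One upwind advection step of a (ny, nx) field."""
    if not np.isfinite(field).all():
        raise ValueError("field must be finite")
    A = advection_matrix(u, v, grid)
    return (A @ field.ravel()).reshape(grid.ny, grid.nx)


def diffuse(field: np.ndarray, k_m2s: float, grid: GridSpec) -> np.ndarray:
    """One explicit diffusion step of a (ny, nx) field."""
    D = diffusion_matrix(k_m2s, grid)
    return (D @ field.ravel()).reshape(grid.ny, grid.nx)


def deposit(conc: np.ndarray, rates_per_h: np.ndarray, dt_h: float) -> np.ndarray:
    """Exact exponential first-order removal, per species.

    ``conc`` has species on the first axis; ``rates_per_h`` is one rate per
    species (1/h).  The exponential form is unconditionally stable and its
    adjoint is multiplication by the same factor.
    """
    rates = np.asarray(rates_per_h, dtype=float)
    if (rates < 0).any():
        raise ValueError("deposition rates must be >= 0")
    fac = np.exp(-rates * dt_h).reshape((-1,) + (1,) * (conc.ndim - 1))
    return conc * fac


def inject_emissions(conc: np.ndarray, emis_tons_per_h: np.ndarray,
                     grid: GridSpec, dt_h: float) -> np.ndarray:
    """Add emissions to the mixed layer.

    1 ton emitted into a cell of area A (m²) and mixing height H (m) over
    dt hours raises the concentration by 1e12/(A·H) μg/m³.
    """
    if emis_tons_per_h.shape != conc.shape:
        raise ValueError(
            f"emission shape {emis_tons_per_h.shape} != concentration shape {conc.shape}"
        )
    if (np.asarray(emis_tons_per_h) < 0).any():
        raise ValueError("emissions must be >= 0")
    conv = TONS_TO_UG * dt_h / grid.cell_volume_m3
    return conc + emis_tons_per_h * conv


@dataclass(frozen=True)
class ChemistryParams:
    """Mechanism configuration beyond the per-channel base rates."""

    mode: str = "linear"  # or "titration"
    titration_k: float = 0.002   # 1/h per (μg/m³ oxidant surplus)
    titration_gamma: float = 1.0  # oxidant consumed per unit NOx (proxy)

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "titration"):
            raise ConfigurationError(f"unknown chemistry mode {self.mode!r}")
        if self.titration_k < 0 or self.titration_gamma < 0:
            raise ConfigurationError("titration parameters must be >= 0")


def chemistry_step(conc: np.ndarray, species: SpeciesSet, met: MetFields,
                   hour: int, dt_h: float,
                   params: ChemistryParams | None = None):
    """Advance the stylized mechanism one sub-step.

    Linear mode: each gas loses a fraction k·Δt (forward Euler) to its
    particulate product, scaled by the hour's temperature index.  Titration
    mode replaces the NOx channel's rate coefficient with
    ``k_t · max(0, O3bg − γ·[NOx])``: production vanishes (and locally
    decreases with added NOx) where NOx overwhelms the available oxidant.

    Returns the updated concentrations and a jacobian record — for every
    channel the per-cell loss fraction and its derivative with respect to
    the gas, which is all the adjoint needs to linearize about this state.
    """
    if (conc < 0).any():
        raise ValueError("negative concentrations entering chemistry")
    params = params or ChemistryParams()
    out = conc.copy()
    record = []
    for ci, conv in enumerate(species.conversions):
        gi = species.index(conv.gas)
        pi = species.index(conv.particle)
        gas = conc[gi]
        scale = met.rate_scale(hour, ci)
        if params.mode == "titration" and conv.gas == "NOX":
            if met.o3bg is None:
                raise ConfigurationError("titration mode requires an o3bg field")
            o3 = met.o3bg[hour]
            surplus = o3 - params.titration_gamma * gas
            keff = params.titration_k * np.maximum(0.0, surplus) * scale
            frac = keff * dt_h
            clipped = frac > 1.0
            frac = np.minimum(frac, 1.0)
            # d(frac)/d(gas): active only strictly inside the (0, 1) branch
            active = (surplus > 0) & ~clipped
            dfrac = np.where(
                active, -params.titration_k * params.titration_gamma * scale * dt_h, 0.0
            )
            # reacted R = frac(gas)·gas  =>  dR/dgas = frac + gas·dfrac
            dR = frac + gas * dfrac
        else:
            k = conv.rate_per_h * scale
            frac = k * dt_h
            if np.any(frac > 1.0):
                raise ConfigurationError(
                    f"forward-Euler chemistry unstable for {conv.gas}: k*dt = "
                    f"{np.max(frac):.3f} > 1"
                )
            frac = np.broadcast_to(np.asarray(frac, dtype=float), gas.shape)
            dR = frac
        reacted = frac * gas
        out[gi] = out[gi] - reacted
        out[pi] = out[pi] + conv.yield_fraction * reacted
        record.append((gi, pi, conv.yield_fraction, np.asarray(dR, dtype=float)))
    return out, record


def chemistry_transpose(lam: np.ndarray, record) -> np.ndarray:
    """Apply the transpose of a recorded (linearized) chemistry sub-step."""
    out = lam.copy()
    for gi, pi, y, dR in record:
        out[gi] = (1.0 - dR) * lam[gi] + y * dR * lam[pi]
    return out


class ForwardModel:
    """The operator-split forward model with cached hourly transport matrices.

    The same object later serves the adjoint: it exposes the linear part of
    each sub-step (and the chemistry records from a stored run) so the
    backward sweep can apply exact transposes.
    """

    def __init__(self, grid: GridSpec, species: SpeciesSet, met: MetFields,
                 diffusivity_m2s: float = 0.0,
                 chemistry: ChemistryParams | None = None):
        met.validate(grid)
        grid.check_diffusion(diffusivity_m2s)
        self.grid = grid
        self.species = species
        self.met = met
        self.diffusivity = diffusivity_m2s
        self.chemistry = chemistry or ChemistryParams()
        self._adv_cache: dict[int, sp.csr_matrix] = {}
        self._adv_cache_T: dict[int, sp.csr_matrix] = {}
        self._dep = np.exp(-species.deposition_vector() * (grid.dt_s / 3600.0))
        self._diff = diffusion_matrix(diffusivity_m2s, grid)
        self._diff_T = self._diff.T.tocsr()

    # -- per-hour operators -------------------------------------------------
    def _adv(self, hour: int) -> sp.csr_matrix:
        if hour not in self._adv_cache:
            A = advection_matrix(self.met.u[hour], self.met.v[hour], self.grid)
            self._adv_cache[hour] = A
            self._adv_cache_T[hour] = A.T.tocsr()
        return self._adv_cache[hour]

    @property
    def dt_h(self) -> float:
        return self.grid.dt_s / 3600.0

    @property
    def emission_conversion(self) -> float:
        """μg/m³ gained per (ton/hr) emitted for one sub-step."""
        return TONS_TO_UG * self.dt_h / self.grid.cell_volume_m3

    # -- one sub-step -------------------------------------------------------
    def substep(self, conc: np.ndarray, emis_hour: np.ndarray, hour: int):
        """inject -> chemistry -> deposit -> advect -> diffuse; returns record."""
        c = inject_emissions(conc, emis_hour, self.grid, self.dt_h)
        c, rec = chemistry_step(c, self.species, self.met, hour, self.dt_h,
                                self.chemistry)
        c = c * self._dep.reshape(-1, 1, 1)
        self._adv(hour)
        flat = c.reshape(self.species.n_species, -1)
        # y = A @ x per species, batched over rows: Y = X @ A.T
        flat = flat @ self._adv_cache_T[hour]
        flat = flat @ self._diff_T
        return flat.reshape(conc.shape), rec

    def substep_linear(self, conc: np.ndarray, record, hour: int) -> np.ndarray:
        """Linear part of a sub-step about a stored state (no injection)."""
        c = conc.copy()
        for gi, pi, y, dR in record:
            reacted = dR * conc[gi]
            c[gi] = c[gi] - reacted
            c[pi] = c[pi] + y * reacted
        c = c * self._dep.reshape(-1, 1, 1)
        self._adv(hour)
        flat = c.reshape(self.species.n_species, -1)
        flat = flat @ self._adv_cache_T[hour]
        flat = flat @ self._diff_T
        return flat.reshape(conc.shape)

    def substep_transpose(self, lam: np.ndarray, record, hour: int) -> np.ndarray:
        """Exact transpose of :meth:`substep_linear`."""
        flat = lam.reshape(self.species.n_species, -1)
        # λ' = Dᵀ λ per species, batched: Λ @ (Dᵀ)ᵀ = Λ @ D
        flat = flat @ self._diff
        flat = flat @ self._adv(hour)
        lam2 = flat.reshape(lam.shape) * self._dep.reshape(-1, 1, 1)
        return chemistry_transpose(lam2, record)

    # -- full run -----------------------------------------------------------
    def run(self, emissions: np.ndarray, spin_up_hours: int = 0,
            initial: np.ndarray | None = None,
            keep_records: bool = False):
        """Integrate the model over all hours.

        ``emissions`` is (n_species, n_hours, ny, nx) in tons/hr, held
        constant within each hour.  Returns a :class:`Trajectory` (and the
        chemistry records when ``keep_records``).
        """
        g = self.grid
        ns = self.species.n_species
        if emissions.shape != (ns, g.n_hours, g.ny, g.nx):
            raise ValueError(
                f"emissions shape {emissions.shape} != "
                f"{(ns, g.n_hours, g.ny, g.nx)}"
            )
        if spin_up_hours >= g.n_hours:
            raise ConfigurationError("spin_up_hours must be < n_hours")
        conc = np.zeros((ns, g.ny, g.nx)) if initial is None else initial.copy()
        traj = np.empty((g.n_hours + 1, ns, g.ny, g.nx))
        traj[0] = conc
        records: list[list] = []
        spr = g.steps_per_hour
        for h in range(g.n_hours):
            hour_recs = []
            for _ in range(spr):
                conc, rec = self.substep(conc, emissions[:, h], h)
                if keep_records:
                    hour_recs.append(rec)
            if not np.isfinite(conc).all():
                raise FloatingPointError(f"NaN/Inf in forward state at hour {h + 1}")
            traj[h + 1] = conc
            if keep_records:
                records.append(hour_recs)
        trajectory = Trajectory(traj, self.species, g, spin_up_hours)
        if keep_records:
            return trajectory, records
        return trajectory


def run_forward(grid: GridSpec, species: SpeciesSet, met: MetFields,
                emissions: np.ndarray, diffusivity_m2s: float = 0.0,
                chemistry: ChemistryParams | None = None,
                spin_up_hours: int = 0) -> Trajectory:
    """Convenience wrapper: build a :class:`ForwardModel` and integrate."""
    model = ForwardModel(grid, species, met, diffusivity_m2s, chemistry)
    return model.run(emissions, spin_up_hours)
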