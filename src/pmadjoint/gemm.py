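"""GEMM concentration–response: hazard transform, mortality cost, forcing.

The Global Exposure Mortality Model (GEMM) maps chronic PM2.5 exposure to
the hazard of death from non-communicable disease and lower respiratory
infection.  Writing z = max(0, PM2.5 − Cf) for the exposure increment above
the counterfactual Cf,

    T(z) = log(1 + z/α) · ω(z),        ω(z) = 1 / (1 + exp(−(z − μ)/ν)),

the hazard ratio is exp(θ·T(z)) and the attributable mortality in cell i is

    J = Σ_i M0_i · P_i · (1 − exp(−θ·T(z_i))),

with P_i the adult (25+) population and M0_i the baseline mortality rate.
The adjoint forcing is the exact analytic derivative ∂J/∂C, spread uniformly
over the hours entering the chronic-exposure mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GemmParams",
    "ExposurePanel",
    "omega",
    "hazard_T",
    "hazard_T_prime",
    "mortality_J",
    "forcing_dJdC",
    "GemmCost",
    "LinearCost",
]


@dataclass(frozen=True)
class GemmParams:
    """GEMM NCD+LRI coefficients for adults 25+ (the all-cohort fit)."""

    theta: float = 0.1231   # log-hazard slope
    alpha: float = 1.5      # curvature, μg/m³
    mu: float = 10.4        # logistic center, μg/m³
    nu: float = 25.9        # logistic width, μg/m³
    cf: float = 2.4         # counterfactual concentration, μg/m³

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.nu <= 0:
            raise ValueError("alpha and nu must be > 0")
        if self.cf < 0:
            raise ValueError("cf must be >= 0")


@dataclass
class ExposurePanel:
    """Per-cell adult population and baseline mortality rate.

    ``population`` in persons, ``bmr`` in deaths per person per year, both
    shaped (ny, nx).
    """

    population: np.ndarray
    bmr: np.ndarray

    def __post_init__(self) -> None:
        self.population = np.asarray(self.population, dtype=float)
        self.bmr = np.asarray(self.bmr, dtype=float)
        if self.population.shape != self.bmr.shape:
            raise ValueError("population and bmr shapes differ")
        if (self.population < 0).any():
            raise ValueError("population must be >= 0")
        if (self.bmr < 0).any() or (self.bmr > 1).any():
            raise ValueError("bmr must lie in [0, 1]")


def _z(pm: np.ndarray, params: GemmParams) -> np.ndarray:
    return np.maximum(0.0, np.asarray(pm, dtype=float) - params.cf)


def omega(z, params: GemmParams = GemmParams()):
    """Logistic weight ω(z) with center μ and width ν."""
    z = np.asarray(z, dtype=float)
    return 1.0 / (1.0 + np.exp(-(z - params.mu) / params.nu))


def hazard_T(z, params: GemmParams = GemmParams()):
    """GEMM hazard transform T(z) = log(1 + z/α)·ω(z); T(0) = 0 since the
    log term vanishes (ω(0) > 0 does not matter there)."""
    z = np.asarray(z, dtype=float)
    return np.log1p(z / params.alpha) * omega(z, params)


def hazard_T_prime(z, params: GemmParams = GemmParams()):
    """Analytic T′(z) = ω/(α+z) + log(1+z/α)·ω(1−ω)/ν."""
    z = np.asarray(z, dtype=float)
    w = omega(z, params)
    return w / (params.alpha + z) + np.log1p(z / params.alpha) * w * (1.0 - w) / params.nu


def mortality_J(exposure_pm: np.ndarray, panel: ExposurePanel,
                params: GemmParams = GemmParams()):
    """Attributable deaths for a period-mean PM2.5 field.

    Returns ``(J, per_cell)`` with J the domain total (deaths/year at the
    panel's BMR timescale) and ``per_cell`` the cellwise contributions,
    needed later for receptor-side roll-ups and monetization.
    """
    pm = np.asarray(exposure_pm, dtype=float)
    if pm.shape != panel.population.shape:
        raise ValueError("exposure and panel shapes differ")
    z = _z(pm, params)
    per_cell = panel.bmr * panel.population * (-np.expm1(-params.theta * hazard_T(z, params)))
    return float(per_cell.sum()), per_cell


def forcing_dJdC(exposure_pm: np.ndarray, panel: ExposurePanel,
                 params: GemmParams = GemmParams(),
                 n_effective_hours: int = 1) -> np.ndarray:
    """Adjoint forcing: ∂J/∂(hourly PM2.5 concentration), (ny, nx).

    The chronic cost is defined on the period-mean exposure, so each of the
    ``n_effective_hours`` non-spin-up hours receives 1/n of the exposure
    gradient

        ∂J/∂PM̄_i = M0_i·P_i·θ·exp(−θT(z_i))·T′(z_i)   (0 where PM ≤ Cf).

    The same forcing applies to every particulate species counted in PM2.5
    mass.  Units: deaths per (μg/m³).
    """
    if n_effective_hours <= 0:
        raise ValueError("n_effective_hours must be > 0")
    pm = np.asarray(exposure_pm, dtype=float)
    z = _z(pm, params)
    grad = (panel.bmr * panel.population * params.theta
            * np.exp(-params.theta * hazard_T(z, params))
            * hazard_T_prime(z, params))
    grad = np.where(pm > params.cf, grad, 0.0)
    return grad / n_effective_hours


class GemmCost:
    """The nonlinear chronic-mortality cost bound to a population panel."""

    def __init__(self, panel: ExposurePanel, params: GemmParams = GemmParams()):
        self.panel = panel
        self.params = params

    def value(self, exposure_pm: np.ndarray) -> float:
        return mortality_J(exposure_pm, self.panel, self.params)[0]

    def per_cell(self, exposure_pm: np.ndarray) -> np.ndarray:
        return mortality_J(exposure_pm, self.panel, self.params)[1]

    def gradient(self, exposure_pm: np.ndarray) -> np.ndarray:
        """∂J/∂PM̄ per cell (deaths per μg/m³)."""
        return forcing_dJdC(exposure_pm, self.panel, self.params, 1)


class LinearCost:
    """A cost linear in the period-mean exposure, J = Σ w_i · PM̄_i.

    Used where exactness matters more than realism: with linear chemistry a
    linear cost makes the adjoint gradient, finite differences, and the
    f-fraction burden identity all exact to round-off.
    """

    def __init__(self, weights: np.ndarray):
        self.weights = np.asarray(weights, dtype=float)

    def value(self, exposure_pm: np.ndarray) -> float:
        return float((self.weights * exposure_pm).sum())

    def per_cell(self, exposure_pm: np.ndarray) -> np.ndarray:
        return self.weights * exposure_pm

    def gradient(self, exposure_pm: np.ndarray) -> np.ndarray:
        return np.broadcast_to(self.weights, np.asarray(exposure_pm).shape).copy()
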