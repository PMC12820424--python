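"""VSL unit-value transfer and monetization of mortality quantities.

A region's value of statistical life is transferred from a base (OECD 2005)
value through GDP ratios, cumulative CPI change and income growth, with an
income elasticity b:

    VSL_c = VSL_base · (Y_c / Y_ref)^b · (1 + %ΔP + %ΔY)^b .

Monetization multiplies death-valued quantities by the VSL of the cell where
the deaths occur (receptor side).  For sensitivity fields this weighting
must enter the adjoint *forcing*: a monetized sensitivity run is a second
backward sweep driven by USD-valued forcing, not a rescaling of the deaths
field (sources affect many receptors with different VSLs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EconPanel",
    "vsl_transfer",
    "vsl_map",
    "monetize_per_cell",
    "deaths_per_kton",
]

DEFAULT_INCOME_ELASTICITY = 0.8  # OECD-recommended


@dataclass
class EconPanel:
    """Per-region economics for the VSL transfer.

    ``table`` columns: region (id), gdp_per_capita, gdp_per_capita_ref,
    cpi_change (fraction), income_growth (fraction), elasticity,
    vsl_base_usd.  The base VSL has no universal default and must be
    supplied.
    """

    table: pd.DataFrame

    REQUIRED = (
        "region", "gdp_per_capita", "gdp_per_capita_ref",
        "cpi_change", "income_growth", "elasticity", "vsl_base_usd",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"EconPanel missing columns: {missing}")
        unknown = [c for c in self.table.columns if c not in self.REQUIRED]
        if unknown:
            raise ValueError(f"EconPanel has unknown columns: {unknown}")
        if (self.table["gdp_per_capita"] <= 0).any() or \
           (self.table["gdp_per_capita_ref"] <= 0).any():
            raise ValueError("GDP per capita must be > 0")
        b = self.table["elasticity"]
        if ((b <= 0) | (b > 2)).any():
            raise ValueError("income elasticity must lie in (0, 2]")

    def vsl_by_region(self) -> dict[int, float]:
        return {
            int(row.region): vsl_transfer(
                row.gdp_per_capita, row.gdp_per_capita_ref,
                row.cpi_change, row.income_growth,
                row.elasticity, row.vsl_base_usd,
            )
            for row in self.table.itertuples()
        }

    def uniform(self, value: float | None = None) -> "EconPanel":
        """The uniform-global-VSL ethical variant: every region equal.

        Defaults to the population-unweighted mean of the transferred VSLs.
        """
        t = self.table.copy()
        if value is None:
            value = float(np.mean(list(self.vsl_by_region().values())))
        t["gdp_per_capita"] = t["gdp_per_capita_ref"]
        t["cpi_change"] = 0.0
        t["income_growth"] = 0.0
        t["vsl_base_usd"] = value
        return EconPanel(t)


def vsl_transfer(gdp_per_capita: float, gdp_per_capita_ref: float,
                 cpi_change: float, income_growth: float,
                 elasticity: float = DEFAULT_INCOME_ELASTICITY,
                 vsl_base_usd: float = 1.0) -> float:
    """Transfer the base VSL to one region (USD).

    The growth bracket is additive, (1 + %ΔP + %ΔY), raised to the same
    elasticity as the GDP ratio.  Strictly increasing in the region's GDP.
    """
    if gdp_per_capita <= 0 or gdp_per_capita_ref <= 0:
        raise ValueError("GDP per capita must be > 0")
    bracket = 1.0 + cpi_change + income_growth
    if bracket <= 0:
        raise ValueError("1 + cpi_change + income_growth must be > 0")
    return float(
        vsl_base_usd
        * (gdp_per_capita / gdp_per_capita_ref) ** elasticity
        * bracket ** elasticity
    )


def vsl_map(region_mask: np.ndarray, econ: EconPanel) -> np.ndarray:
    """Per-cell VSL (USD), looked up from the cell's region."""
    by_region = econ.vsl_by_region()
    out = np.empty(region_mask.shape, dtype=float)
    regions = np.unique(region_mask)
    for r in regions:
        if int(r) not in by_region:
            raise ValueError(f"no VSL for region {int(r)} in the economics table")
        out[region_mask == r] = by_region[int(r)]
    return out


def monetize_per_cell(deaths_per_cell: np.ndarray, vsl: np.ndarray) -> np.ndarray:
    """USD value of a per-cell deaths field at receptor-side VSLs."""
    if deaths_per_cell.shape != vsl.shape:
        raise ValueError("deaths field and VSL map shapes differ")
    return deaths_per_cell * vsl


def deaths_per_kton(deaths_per_ton: np.ndarray) -> np.ndarray:
    """Reporting conversion; USD/ton stays per ton."""
    return np.asarray(deaths_per_ton) * 1000.0
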