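"""Compartmental mass balance of potential geosmin contributions.

Per-cell yields measured in culture are extrapolated to the producer
populations of each compartment (water, intestinal mucous, digesta,
fin surface) and compared against measured geosmin in flesh and water.
Uncertainties propagate by the first-order delta method assuming
independent inputs.

Reporting units are compartment-native: ng/L for water, ng per intestine
for mucous, pg/g for digesta and ng/cm^2 for fins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

NG_PER_G = 1e9
PG_PER_G = 1e12
ML_PER_L = 1e3

COMPARTMENTS = ("water", "mucous", "digesta", "fin")


@dataclass(frozen=True)
class Uncertain:
    """A value with a standard error, combining by the delta method.

    Products and quotients add relative variances; sums and differences
    add absolute variances. Inputs are treated as independent.
    """

    value: float
    se: float = 0.0

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be non-negative")

    def _coerce(self, other) -> "Uncertain":
        if isinstance(other, Uncertain):
            return other
        return Uncertain(float(other), 0.0)

    def __add__(self, other) -> "Uncertain":
        o = self._coerce(other)
        return Uncertain(self.value + o.value, math.hypot(self.se, o.se))

    __radd__ = __add__

    def __sub__(self, other) -> "Uncertain":
        o = self._coerce(other)
        return Uncertain(self.value - o.value, math.hypot(self.se, o.se))

    def __rsub__(self, other) -> "Uncertain":
        return self._coerce(other).__sub__(self)

    def _rel(self) -> float:
        if self.value == 0.0:
            if self.se == 0.0:
                return 0.0
            raise ZeroDivisionError("relative SE undefined for zero value with nonzero SE")
        return self.se / abs(self.value)

    def __mul__(self, other) -> "Uncertain":
        o = self._coerce(other)
        v = self.value * o.value
        if v == 0.0:
            # exact zero factor annihilates first-order uncertainty
            se = abs(o.value) * self.se if o.se == 0 else abs(self.value) * o.se
            if self.value == 0 and o.value == 0:
                se = 0.0
            return Uncertain(v, se)
        return Uncertain(v, abs(v) * math.hypot(self._rel(), o._rel()))

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Uncertain":
        o = self._coerce(other)
        if o.value == 0.0:
            raise ZeroDivisionError("division by zero-valued Uncertain")
        v = self.value / o.value
        if v == 0.0:
            return Uncertain(0.0, self.se / abs(o.value))
        return Uncertain(v, abs(v) * math.hypot(self._rel(), o._rel()))

    def __rtruediv__(self, other) -> "Uncertain":
        return self._coerce(other).__truediv__(self)


@dataclass(frozen=True)
class CellYield:
    """Per-cell geosmin masses from the culture experiment (g/cell)."""

    free_g_per_cell: float
    bound_g_per_cell: float
    total_g_per_cell: float = field(init=False)

    def __post_init__(self) -> None:
        if self.free_g_per_cell < 0 or self.bound_g_per_cell < 0:
            raise ValueError("per-cell yields must be non-negative")
        object.__setattr__(
            self, "total_g_per_cell", self.free_g_per_cell + self.bound_g_per_cell
        )


def per_cell_yield(
    supernatant_geosmin_g: float,
    pellet_geosmin_g: float,
    cell_count: float,
    culture_volume_l: float | None = None,
) -> CellYield:
    """Per-cell free and bound yields from total culture masses.

    free = supernatant mass / cells; bound = pellet mass / cells.
    ``culture_volume_l`` is recorded for provenance only; the masses and
    cell count already refer to the same culture aliquot.
    """
    if cell_count <= 0:
        raise ZeroDivisionError("cell count must be positive")
    if supernatant_geosmin_g < 0 or pellet_geosmin_g < 0:
        raise ValueError("geosmin masses must be non-negative")
    if culture_volume_l is not None and culture_volume_l <= 0:
        raise ValueError("culture volume must be positive")
    return CellYield(
        free_g_per_cell=supernatant_geosmin_g / cell_count,
        bound_g_per_cell=pellet_geosmin_g / cell_count,
    )


def compartment_production(
    cell_density: Uncertain | float,
    compartment: str,
    cell_yield: CellYield,
    *,
    mucous_area_cm2: float | None = None,
    copies_per_cell: float = 1.0,
) -> Uncertain:
    """Potential geosmin production of one compartment's producer population.

    ``cell_density`` is in gene copies per native unit (per mL for water,
    per cm^2 for mucous and fin, per g for digesta); ``copies_per_cell``
    converts copies to cells. Output units:

    - water:   ng/L        (density/mL * 1000 mL/L * yield)
    - mucous:  ng/intestine (density/cm^2 * mucous area * yield)
    - digesta: pg/g        (density/g * yield)
    - fin:     ng/cm^2     (density/cm^2 * yield)
    """
    if compartment not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}; expected one of {COMPARTMENTS}")
    if copies_per_cell <= 0:
        raise ValueError("copies_per_cell must be positive")
    d = cell_density if isinstance(cell_density, Uncertain) else Uncertain(float(cell_density))
    if d.value < 0:
        raise ValueError("cell density must be non-negative")
    cells = d / copies_per_cell
    y = cell_yield.total_g_per_cell
    if compartment == "water":
        return cells * (ML_PER_L * y * NG_PER_G)
    if compartment == "mucous":
        if mucous_area_cm2 is None or mucous_area_cm2 <= 0:
            raise ValueError("mucous production needs a positive mucous_area_cm2")
        return cells * (mucous_area_cm2 * y * NG_PER_G)
    if compartment == "digesta":
        return cells * (y * PG_PER_G)
    return cells * (y * NG_PER_G)  # fin


def contribution_to_flesh(
    mucous_production_ng: float,
    flesh_conc_ng_per_kg: float,
    fish_mass_kg: float = 1.0,
) -> float:
    """Percent of the measured flesh geosmin that intestinal producers could supply.

    percent = 100 * production / (flesh concentration * fish mass).
    Undefined (NaN) when the flesh concentration is not positive.
    """
    if fish_mass_kg <= 0:
        raise ValueError("fish mass must be positive")
    if mucous_production_ng < 0:
        raise ValueError("production must be non-negative")
    if flesh_conc_ng_per_kg <= 0:
        return float("nan")
    return 100.0 * mucous_production_ng / (flesh_conc_ng_per_kg * fish_mass_kg)


def contribution_to_water(calc_ng_per_l: float, measured_ng_per_l: float) -> float:
    """Percent of measured water geosmin attributable to water-column producers.

    Zero calculated production gives 0% regardless of the denominator;
    a zero measurement with positive production is undefined (NaN).
    """
    if calc_ng_per_l < 0 or measured_ng_per_l < 0:
        raise ValueError("concentrations must be non-negative")
    if calc_ng_per_l == 0.0:
        return 0.0
    if measured_ng_per_l == 0.0:
        return float("nan")
    return 100.0 * calc_ng_per_l / measured_ng_per_l


@dataclass
class ContributionRow:
    """One farm's line of the contribution table."""

    farm_id: str
    mucous_production: Uncertain | None
    flesh_geosmin: Uncertain | None
    contribution_pct: float
    digesta_production: Uncertain | None
    fin_production: Uncertain | None
    water_calc: Uncertain | None
    water_measured: Uncertain | None
    gaps: tuple[str, ...] = ()


def build_contribution_table(
    densities: Mapping[str, Mapping[str, Uncertain]],
    measurements: Mapping[str, Mapping[str, Uncertain]],
    cell_yield: CellYield,
    *,
    mucous_area_cm2: float,
    fish_mass_kg: float = 1.0,
    copies_per_cell: float = 1.0,
) -> list[ContributionRow]:
    """Assemble per-farm contribution rows.

    ``densities[farm][compartment]`` are producer gene-copy densities in
    native units; ``measurements[farm]`` holds ``flesh`` (ng/kg) and
    ``water`` (ng/L) geosmin. Farms missing a compartment or measurement
    get an explicit gap flag rather than a silent drop. Values are kept
    at full precision; rounding belongs to serialization.
    """
    rows: list[ContributionRow] = []
    for farm in sorted(densities):
        dens = densities[farm]
        meas = measurements.get(farm, {})
        gaps: list[str] = []

        def prod(comp: str) -> Uncertain | None:
            if comp not in dens:
                gaps.append(f"missing_density:{comp}")
                return None
            return compartment_production(
                dens[comp],
                comp,
                cell_yield,
                mucous_area_cm2=mucous_area_cm2,
                copies_per_cell=copies_per_cell,
            )

        mucous = prod("mucous")
        digesta = prod("digesta")
        fin = prod("fin")
        water_calc = prod("water")

        flesh = meas.get("flesh")
        if flesh is None:
            gaps.append("missing_measurement:flesh")
        water_meas = meas.get("water")
        if water_meas is None:
            gaps.append("missing_measurement:water")

        if mucous is not None and flesh is not None:
            pct = contribution_to_flesh(mucous.value, flesh.value, fish_mass_kg)
        else:
            pct = float("nan")

        rows.append(
            ContributionRow(
                farm_id=farm,
                mucous_production=mucous,
                flesh_geosmin=flesh,
                contribution_pct=pct,
                digesta_production=digesta,
                fin_production=fin,
                water_calc=water_calc,
                water_measured=water_meas,
                gaps=tuple(gaps),
            )
        )
    return rows


def contribution_table_frame(rows: list[ContributionRow]) -> pd.DataFrame:
    """Serialize contribution rows, percent rounded to one decimal."""

    def v(u: Uncertain | None) -> float:
        return float("nan") if u is None else u.value

    def s(u: Uncertain | None) -> float:
        return float("nan") if u is None else u.se

    return pd.DataFrame(
        {
            "farm": [r.farm_id for r in rows],
            "mucous_ng_per_intestine": [v(r.mucous_production) for r in rows],
            "mucous_se": [s(r.mucous_production) for r in rows],
            "flesh_ng_per_kg": [v(r.flesh_geosmin) for r in rows],
            "flesh_se": [s(r.flesh_geosmin) for r in rows],
            "contribution_pct": [
                round(r.contribution_pct, 1) if math.isfinite(r.contribution_pct) else float("nan")
                for r in rows
            ],
            "digesta_pg_per_g": [v(r.digesta_production) for r in rows],
            "digesta_se": [s(r.digesta_production) for r in rows],
            "fin_ng_per_cm2": [v(r.fin_production) for r in rows],
            "fin_se": [s(r.fin_production) for r in rows],
            "water_calc_ng_per_l": [v(r.water_calc) for r in rows],
            "water_calc_sd": [s(r.water_calc) for r in rows],
            "water_measured_ng_per_l": [v(r.water_measured) for r in rows],
            "water_measured_sd": [s(r.water_measured) for r in rows],
            "gaps": [";".join(r.gaps) for r in rows],
        }
    )
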