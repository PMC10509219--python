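"""Emission inventory: sources, plume rise, release-height layers, scaling.

A source carries annual masses (metric tons/yr) of the five PM2.5-relevant
pollutants plus CO2, a sector and economic-region label, and — for point
sources — physical stack parameters from which the effective stack height
(ESH: physical height plus plume rise) is computed with the Holland formula
and discretized into three release layers (ground 0–57 m, low 57–379 m,
high > 379 m).  Area sources release at ground level and are distributed to
grid cells with non-negative surrogate weights.  Policy scenarios scale the
inventory with a region × category factor table, with optional
balancing-area overrides for power-sector CO2/SO2/NOx and optional
region × broad-sector CO2 adjustment targets.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    AllocationError,
    ConfigurationError,
    DomainError,
    ImputationError,
    ScalingError,
)

#: Pollutants tracked per source (metric tons/yr), besides CO2.
POLLUTANTS = ("pm25", "so2", "nox", "nh3", "voc")

#: Sector vocabulary used throughout the package.
SECTORS = (
    "electricity-coal",
    "electricity-other",
    "transportation",
    "industry",
    "residential",
    "food-agriculture",
    "other",
)

#: Collapse detailed sectors into the broad sectors used for CO2
#: adjustments and sector-level optimization constraints.
BROAD_SECTOR = {
    "electricity-coal": "electricity",
    "electricity-other": "electricity",
    "transportation": "transportation",
    "industry": "industry",
    "residential": "residential",
    "food-agriculture": "food-agriculture",
    "other": "other",
}

#: Pollutants whose power-sector emissions are rescaled per balancing area.
BALANCING_POLLUTANTS = ("co2", "so2", "nox")


class ESHLayer(enum.Enum):
    """Effective-stack-height release layer."""

    GROUND = "ground"  # [0, 57) m
    LOW = "low"        # [57, 379] m
    HIGH = "high"      # (379, inf) m


#: Layer boundaries in metres. Ground is half-open at the top; the low
#: layer is closed at both ends so the three layers partition [0, inf).
ESH_GROUND_TOP_M = 57.0
ESH_LOW_TOP_M = 379.0


@dataclass(frozen=True)
class StackParams:
    """Physical stack parameters of a point source."""

    height_m: float
    diameter_m: float
    exit_velocity_mps: float
    exit_temperature_k: float

    def __post_init__(self) -> None:
        for name in ("height_m", "diameter_m", "exit_velocity_mps", "exit_temperature_k"):
            if getattr(self, name) <= 0:
                raise DomainError(f"stack {name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class MetParams:
    """Ambient meteorology at the release point."""

    ambient_temperature_k: float
    wind_speed_mps: float
    ambient_pressure_mb: float = 1013.25

    def __post_init__(self) -> None:
        if self.wind_speed_mps <= 0:
            raise DomainError(f"wind_speed must be > 0, got {self.wind_speed_mps}")
        if self.ambient_temperature_k <= 0:
            raise DomainError(f"ambient_temperature must be > 0, got {self.ambient_temperature_k}")


@dataclass
class EmissionSource:
    """One point or area emission source."""

    id: str
    kind: str  # "point" | "area"
    cell: int
    x_km: float
    y_km: float
    region: str
    sector: str
    tier2: str
    pollutants: dict[str, float] = field(default_factory=dict)
    co2: float = 0.0
    balancing_area: str | None = None
    stack: StackParams | None = None
    esh_layer: ESHLayer | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("point", "area"):
            raise ConfigurationError(f"source {self.id}: kind must be point|area, got {self.kind!r}")
        for p, m in self.pollutants.items():
            if m < 0:
                raise ConfigurationError(f"source {self.id}: negative {p} mass {m}")
        if self.co2 < 0:
            raise ConfigurationError(f"source {self.id}: negative CO2 {self.co2}")
        if self.kind == "area":
            # Area sources release at ground level by construction.
            self.esh_layer = ESHLayer.GROUND

    def mass(self, pollutant: str) -> float:
        return float(self.pollutants.get(pollutant, 0.0))


def holland_plume_rise(stack: StackParams, met: MetParams) -> float:
    """Plume rise (m) from the Holland formula.

    Δh = (v_s · d / u) · (1.5 + 2.68e-3 · p · d · (T_s − T_a) / T_s)

    with exit velocity v_s (m/s), stack diameter d (m), wind speed u (m/s),
    ambient pressure p (millibar) and stack/ambient temperatures in kelvin.
    Momentum rise alone (T_s = T_a) gives 1.5·v_s·d/u; buoyancy adds the
    pressure-weighted temperature-excess term.
    """
    if met.wind_speed_mps <= 0:
        raise DomainError("wind speed must be positive")
    if stack.exit_temperature_k <= 0:
        raise DomainError("stack exit temperature must be positive")
    ts, ta = stack.exit_temperature_k, met.ambient_temperature_k
    momentum = stack.exit_velocity_mps * stack.diameter_m / met.wind_speed_mps
    buoyancy = 2.68e-3 * met.ambient_pressure_mb * stack.diameter_m * (ts - ta) / ts
    return momentum * (1.5 + buoyancy)


def barometric_pressure(sea_level_temperature_k: float, height_m: float,
                        p0_mb: float = 1013.25) -> float:
    """Ambient pressure (mb) at a stack top from the isothermal barometric law.

    p(h) = p0 · exp(−g·M·h / (R·T)).  Decouples meteorology sourcing from the
    plume-rise calculation for callers that only know sea-level conditions.
    """
    if sea_level_temperature_k <= 0:
        raise DomainError("sea level temperature must be > 0")
    if height_m < 0:
        raise DomainError("height must be >= 0")
    g, molar_mass, gas_const = 9.80665, 0.0289644, 8.31446
    return p0_mb * math.exp(-g * molar_mass * height_m / (gas_const * sea_level_temperature_k))


def effective_stack_height(stack: StackParams, met: MetParams) -> float:
    """Physical stack height plus Holland plume rise (m), floored at 0."""
    return stack.height_m + max(holland_plume_rise(stack, met), 0.0)


def assign_esh_layer(esh_m: float) -> ESHLayer:
    """Discretize an effective stack height into its release layer."""
    if esh_m < 0:
        raise DomainError(f"effective stack height must be >= 0, got {esh_m}")
    if esh_m < ESH_GROUND_TOP_M:
        return ESHLayer.GROUND
    if esh_m <= ESH_LOW_TOP_M:
        return ESHLayer.LOW
    return ESHLayer.HIGH


def impute_stack(source: EmissionSource, inventory: list[EmissionSource]) -> ESHLayer:
    """Layer of the geographically nearest same-tier2 source with a layer.

    Used for point sources lacking stack data. Ties in distance are broken
    by the lowest candidate id.
    """
    candidates = [
        s for s in inventory
        if s.id != source.id and s.tier2 == source.tier2 and s.esh_layer is not None
    ]
    if not candidates:
        raise ImputationError(
            f"source {source.id}: no tier2={source.tier2!r} source with a resolved layer"
        )
    best = min(
        candidates,
        key=lambda s: (math.hypot(s.x_km - source.x_km, s.y_km - source.y_km), s.id),
    )
    return best.esh_layer


def resolve_layers(inventory: list[EmissionSource], met: MetParams) -> list[EmissionSource]:
    """Assign every source its ESH layer.

    Point sources with stack data get the Holland-formula layer; area sources
    are ground; point sources without stack data inherit the layer of the
    nearest same-tier2 resolved source.
    """
    resolved: list[EmissionSource] = []
    pending: list[EmissionSource] = []
    for s in inventory:
        if s.kind == "area":
            resolved.append(replace(s, esh_layer=ESHLayer.GROUND))
        elif s.stack is not None:
            resolved.append(replace(s, esh_layer=assign_esh_layer(effective_stack_height(s.stack, met))))
        elif s.esh_layer is not None:  # pre-assigned layer stands
            resolved.append(s)
        else:
            pending.append(s)
    out = resolved + [replace(s, esh_layer=impute_stack(s, resolved)) for s in pending]
    order = {s.id: i for i, s in enumerate(inventory)}  # keep input ordering
    out.sort(key=lambda s: order[s.id])
    return out


def allocate_area_source(source: EmissionSource,
                         weights: dict[int, float]) -> list[tuple[int, float]]:
    """Surrogate allocation fractions for an area source.

    Fractions are proportional to the non-negative weights and sum to one;
    multiply by any pollutant mass to distribute it while conserving total
    mass exactly.
    """
    cells = sorted(weights)
    w = np.array([weights[c] for c in cells], dtype=float)
    if (w < 0).any():
        raise AllocationError(f"source {source.id}: negative surrogate weight")
    total = w.sum()
    if total <= 0:
        raise AllocationError(f"source {source.id}: all surrogate weights are zero")
    return [(c, float(f)) for c, f in zip(cells, w / total)]


def split_area_source(source: EmissionSource,
                      weights: dict[int, float]) -> list[EmissionSource]:
    """Realize an area source as per-cell ground-level sources."""
    parts = []
    for i, (cell, frac) in enumerate(allocate_area_source(source, weights)):
        parts.append(replace(
            source,
            id=f"{source.id}#{i}",
            cell=cell,
            pollutants={p: m * frac for p, m in source.pollutants.items()},
            co2=source.co2 * frac,
        ))
    return parts


@dataclass
class ScalingTable:
    """Region × category scaling factors for projecting an inventory.

    ``factors`` rows: region, category (sector label), pollutant_class,
    factor.  ``pollutant_class`` is a concrete pollutant name ("so2", "co2",
    ...), the class "co2" / "copollutant", or "all"; resolution prefers the
    concrete name, then the class, then "all".

    ``balancing_area_factors`` rows (optional): balancing_area, pollutant,
    factor — override the region factor for electricity-sector CO2/SO2/NOx of
    sources carrying that balancing-area label.

    ``co2_adjustments`` rows (optional): region, broad_sector, target_co2 —
    after factor application, CO2 of matching sources is rescaled so the
    group total hits the target.
    """

    factors: pd.DataFrame
    balancing_area_factors: pd.DataFrame | None = None
    co2_adjustments: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"region", "category", "pollutant_class", "factor"}
        missing = required - set(self.factors.columns)
        if missing:
            raise ConfigurationError(f"scaling table missing columns {sorted(missing)}")
        if (self.factors["factor"] < 0).any():
            raise ConfigurationError("scaling factors must be >= 0")
        self._lookup = {
            (r.region, r.category, r.pollutant_class): float(r.factor)
            for r in self.factors.itertuples()
        }
        self._ba_lookup = {}
        if self.balancing_area_factors is not None:
            self._ba_lookup = {
                (r.balancing_area, r.pollutant): float(r.factor)
                for r in self.balancing_area_factors.itertuples()
            }

    def factor_for(self, region: str, category: str, pollutant: str) -> float:
        pclass = "co2" if pollutant == "co2" else "copollutant"
        for key in ((region, category, pollutant),
                    (region, category, pclass),
                    (region, category, "all")):
            if key in self._lookup:
                return self._lookup[key]
        raise ScalingError(f"no scaling factor for (region={region!r}, category={category!r})")

    def balancing_factor(self, balancing_area: str | None, pollutant: str) -> float | None:
        if balancing_area is None:
            return None
        return self._ba_lookup.get((balancing_area, pollutant))


def scale_inventory(inventory: list[EmissionSource], scaling: ScalingTable) -> list[EmissionSource]:
    """Project an inventory to a scenario with a scaling table.

    The (region, sector) factor applies uniformly per pollutant class; for
    electricity sources with a balancing-area label, CO2/SO2/NOx use the
    balancing-area factor when one is present; finally, per (region,
    broad-sector) CO2 totals are rescaled to any adjustment targets.  Source
    identity, locations and layers are unchanged; masses stay non-negative.
    """
    scaled: list[EmissionSource] = []
    for s in inventory:
        new_poll = {}
        for p in POLLUTANTS:
            f = None
            if p in BALANCING_POLLUTANTS and BROAD_SECTOR.get(s.sector) == "electricity":
                f = scaling.balancing_factor(s.balancing_area, p)
            if f is None:
                f = scaling.factor_for(s.region, s.sector, p)
            new_poll[p] = s.mass(p) * f
        f_co2 = None
        if BROAD_SECTOR.get(s.sector) == "electricity":
            f_co2 = scaling.balancing_factor(s.balancing_area, "co2")
        if f_co2 is None:
            f_co2 = scaling.factor_for(s.region, s.sector, "co2")
        scaled.append(replace(s, pollutants=new_poll, co2=s.co2 * f_co2))

    if scaling.co2_adjustments is not None:
        for row in scaling.co2_adjustments.itertuples():
            idx = [i for i, s in enumerate(scaled)
                   if s.region == row.region and BROAD_SECTOR.get(s.sector) == row.broad_sector]
            current = sum(scaled[i].co2 for i in idx)
            if current > 0:
                mult = float(row.target_co2) / current
                for i in idx:
                    scaled[i] = replace(scaled[i], co2=scaled[i].co2 * mult)
    return scaled


def total_mass(inventory: list[EmissionSource], pollutant: str) -> float:
    """Inventory-wide annual mass of one pollutant (or "co2")."""
    if pollutant == "co2":
        return sum(s.co2 for s in inventory)
    return sum(s.mass(pollutant) for s in inventory)
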