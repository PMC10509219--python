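"""Population-weighted exposure and relative disparity metrics.

A group's exposure is its population-weighted mean concentration,
E_g = Σ_cells pop_g·C / Σ_cells pop_g.  Relative disparity is the
percentage difference from the total population,
D_g = 100·(E_g − E_total)/E_total; the total population's disparity is
identically zero, and white + minority partition the total, so
P_white·E_white + P_minority·E_minority = P_total·E_total exactly.
Scenario effects are reported as ΔE_g (µg/m³) and ΔD_g (percentage
points, policy minus baseline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .airquality import ConcentrationField
from .errors import LabelError, ShapeError, UndefinedMetricError, ValidationError

#: Component racial/ethnic groups; minority = total − white (everyone except
#: the non-Hispanic white population), so asian+black+hispanic ≤ minority
#: (other races are included in minority but not broken out).
COMPONENT_GROUPS = ("asian", "black", "hispanic", "white")
GROUPS = COMPONENT_GROUPS + ("minority", "total")

#: Relative tolerance for the minority + white = total partition check.
PARTITION_RTOL = 1e-6


@dataclass
class PopulationGrid:
    """Per-cell population counts by racial/ethnic group.

    ``data`` is indexed by cell id with the group columns plus optional
    ``state`` and ``urban_area`` label columns.  The partition invariant
    minority + white = total is validated on construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"white", "minority", "total"} - set(self.data.columns)
        if missing:
            raise ValidationError(f"population grid missing columns {sorted(missing)}")
        for g in GROUPS:
            if g in self.data.columns and (self.data[g] < 0).any():
                row = int(self.data.index[self.data[g] < 0][0])
                raise ValidationError(f"negative {g} population in cell {row}")
        resid = self.data["white"] + self.data["minority"] - self.data["total"]
        scale = np.maximum(self.data["total"].to_numpy(), 1.0)
        bad = np.abs(resid.to_numpy()) > PARTITION_RTOL * scale
        if bad.any():
            row = int(self.data.index[bad][0])
            raise ValidationError(
                f"cell {row}: white + minority != total beyond {PARTITION_RTOL:g} relative"
            )

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def counts(self, group: str) -> np.ndarray:
        if group not in self.data.columns:
            raise LabelError(f"unknown population group {group!r}")
        return self.data[group].to_numpy(dtype=float)

    def labels(self, level: str) -> pd.Series:
        if level not in self.data.columns:
            raise LabelError(f"population grid has no {level!r} labels")
        return self.data[level]


def population_weighted_exposure(field: ConcentrationField, pop: PopulationGrid,
                                 group: str, mask: np.ndarray | None = None) -> float:
    """Population-weighted mean concentration (µg/m³) for one group."""
    conc = field.total
    if len(conc) != pop.n_cells:
        raise ShapeError("concentration field and population grid differ in cell count")
    w = pop.counts(group)
    if mask is not None:
        w = np.where(mask, w, 0.0)
    total_pop = w.sum()
    if total_pop <= 0:
        raise UndefinedMetricError(f"zero {group} population in mask; exposure undefined")
    return float((w * conc).sum() / total_pop)


def relative_disparity_from_exposures(e_group: float, e_total: float) -> float:
    """Relative disparity (%) from already-computed exposures."""
    if e_total == 0:
        raise UndefinedMetricError("total exposure is zero; disparity undefined")
    return 100.0 * (e_group - e_total) / e_total


def relative_disparity(field: ConcentrationField, pop: PopulationGrid, group: str,
                       mask: np.ndarray | None = None) -> float:
    """Percentage difference of a group's exposure from the total population's."""
    return relative_disparity_from_exposures(
        population_weighted_exposure(field, pop, group, mask),
        population_weighted_exposure(field, pop, "total", mask),
    )


def disparity_change(policy_field: ConcentrationField, base_field: ConcentrationField,
                     pop: PopulationGrid, group: str,
                     mask: np.ndarray | None = None) -> float:
    """ΔD_g = D_g(policy) − D_g(baseline), in percentage points."""
    return (relative_disparity(policy_field, pop, group, mask)
            - relative_disparity(base_field, pop, group, mask))


def disparity_table(field: ConcentrationField, pop: PopulationGrid,
                    groups: tuple[str, ...] = GROUPS,
                    mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-group exposure (µg/m³) and relative disparity (%).

    Groups with zero population under the mask are omitted.
    """
    rows = {}
    for g in groups:
        if g not in pop.data.columns:
            continue
        try:
            e = population_weighted_exposure(field, pop, g, mask)
        except UndefinedMetricError:
            continue
        rows[g] = e
    e_total = rows.get("total")
    if e_total is None:
        raise UndefinedMetricError("zero total population in mask")
    return pd.DataFrame({
        "exposure": pd.Series(rows),
        "disparity_pct": pd.Series(
            {g: relative_disparity_from_exposures(e, e_total) for g, e in rows.items()}),
    })


def scenario_delta_table(policy_field: ConcentrationField, base_field: ConcentrationField,
                         pop: PopulationGrid,
                         groups: tuple[str, ...] = GROUPS) -> pd.DataFrame:
    """Per-group ΔE (µg/m³) and ΔD (pp), policy minus baseline."""
    t_policy = disparity_table(policy_field, pop, groups)
    t_base = disparity_table(base_field, pop, groups)
    return pd.DataFrame({
        "exposure": t_policy["exposure"],
        "disparity_pct": t_policy["disparity_pct"],
        "d_exposure": t_policy["exposure"] - t_base["exposure"],
        "d_disparity_pp": t_policy["disparity_pct"] - t_base["disparity_pct"],
    })


def subgroup_report(field: ConcentrationField, pop: PopulationGrid,
                    level: str) -> tuple[dict[str, pd.DataFrame], int]:
    """One disparity table per labeled region at ``level`` ("state"|"urban_area").

    Returns (tables, n_omitted): group rows with zero population within a
    region are omitted and counted, with one warning summarizing the count.
    """
    labels = pop.labels(level)
    regions = sorted(x for x in labels.dropna().unique() if x != "")
    if not regions:
        raise LabelError(f"no {level!r} labels present")
    tables: dict[str, pd.DataFrame] = {}
    n_omitted = 0
    for region in regions:
        mask = (labels == region).to_numpy()
        try:
            table = disparity_table(field, pop, mask=mask)
        except UndefinedMetricError:  # region with zero total population
            n_omitted += sum(1 for g in GROUPS if g in pop.data.columns)
            continue
        n_omitted += sum(1 for g in GROUPS if g in pop.data.columns and g not in table.index)
        tables[region] = table
    if n_omitted:
        warnings.warn(f"{n_omitted} group rows omitted for zero population at {level} level",
                      stacklevel=2)
    return tables, n_omitted


def project_population(pop: PopulationGrid, growth: dict[str, float]) -> PopulationGrid:
    """Scale every group count by its state's total-population growth factor.

    A common per-state factor preserves the partition invariant exactly.
    """
    states = pop.labels("state")
    missing = sorted(set(states.dropna().unique()) - set(growth))
    if missing:
        raise LabelError(f"no growth factor for states {missing}")
    factors = states.map(growth).to_numpy(dtype=float)
    data = pop.data.copy()
    for g in GROUPS:
        if g in data.columns:
            data[g] = data[g] * factors
    return PopulationGrid(data)


def top_urban_areas(pop: PopulationGrid, k: int = 20) -> list[str]:
    """The k most populous urban-area labels (ranked by total population)."""
    labels = pop.labels("urban_area")
    totals = pop.data.loc[labels.notna() & (labels != ""), :].groupby(
        labels[labels.notna() & (labels != "")])["total"].sum()
    return list(totals.sort_values(ascending=False).index[:k])
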