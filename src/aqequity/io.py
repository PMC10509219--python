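"""File formats: CSV tables for inventory, population, scaling, incidence,
scenarios and frontier points; the SRM round-trips through its .npz
container (see SourceReceptorMatrix.save/load).  All readers validate
schemas and values and report offending rows.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .exposure import PopulationGrid
from .inventory import ESHLayer, POLLUTANTS, EmissionSource, ScalingTable, StackParams
from .optimize import FrontierPoint, ReductionScenario

logger = logging.getLogger(__name__)

INVENTORY_COLUMNS = [
    "id", "kind", "cell", "x_km", "y_km", "region", "balancing_area", "sector",
    "tier2", "stack_height_m", "stack_diam_m", "stack_velocity_mps", "stack_temp_K",
    "esh_layer", "pm25_t", "so2_t", "nox_t", "nh3_t", "voc_t", "co2_t",
]
_MASS_COLS = {"pm25": "pm25_t", "so2": "so2_t", "nox": "nox_t", "nh3": "nh3_t", "voc": "voc_t"}

POPULATION_COLUMNS = ["cell_id", "state", "urban_area", "asian", "black", "hispanic",
                      "white", "minority", "total"]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required columns {missing}")


def write_inventory(inventory: list[EmissionSource], path) -> None:
    rows = []
    for s in inventory:
        stack = s.stack
        rows.append({
            "id": s.id, "kind": s.kind, "cell": s.cell, "x_km": s.x_km, "y_km": s.y_km,
            "region": s.region, "balancing_area": s.balancing_area or "",
            "sector": s.sector, "tier2": s.tier2,
            "stack_height_m": stack.height_m if stack else "",
            "stack_diam_m": stack.diameter_m if stack else "",
            "stack_velocity_mps": stack.exit_velocity_mps if stack else "",
            "stack_temp_K": stack.exit_temperature_k if stack else "",
            "esh_layer": s.esh_layer.value if s.esh_layer else "",
            **{col: s.mass(p) for p, col in _MASS_COLS.items()},
            "co2_t": s.co2,
        })
    pd.DataFrame(rows, columns=INVENTORY_COLUMNS).to_csv(path, index=False)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, str) and value.strip() == ""):
        return None
    v = float(value)
    return None if math.isnan(v) else v


def read_inventory(path) -> list[EmissionSource]:
    df = pd.read_csv(path)
    _require_columns(df, INVENTORY_COLUMNS, f"inventory {path}")
    if df.empty:
        logger.warning("inventory %s contains only a header; empty inventory", path)
        return []
    inventory = []
    for i, row in df.iterrows():
        for p, col in _MASS_COLS.items():
            if row[col] < 0:
                raise ValidationError(f"inventory {path} row {i}: negative {col} = {row[col]}")
        if row["co2_t"] < 0:
            raise ValidationError(f"inventory {path} row {i}: negative co2_t = {row['co2_t']}")
        height = _opt_float(row["stack_height_m"])
        stack = None
        if height is not None:
            stack = StackParams(
                height_m=height,
                diameter_m=_opt_float(row["stack_diam_m"]),
                exit_velocity_mps=_opt_float(row["stack_velocity_mps"]),
                exit_temperature_k=_opt_float(row["stack_temp_K"]),
            )
        layer = row["esh_layer"]
        ba = row["balancing_area"]
        inventory.append(EmissionSource(
            id=str(row["id"]), kind=str(row["kind"]), cell=int(row["cell"]),
            x_km=float(row["x_km"]), y_km=float(row["y_km"]),
            region=str(row["region"]),
            sector=str(row["sector"]), tier2=str(row["tier2"]),
            pollutants={p: float(row[col]) for p, col in _MASS_COLS.items()},
            co2=float(row["co2_t"]),
            balancing_area=None if (pd.isna(ba) or ba == "") else str(ba),
            stack=stack,
            esh_layer=None if (pd.isna(layer) or layer == "") else ESHLayer(str(layer)),
        ))
    return inventory


def write_population(pop: PopulationGrid, path) -> None:
    df = pop.data.copy()
    df.insert(0, "cell_id", df.index)
    if "state" not in df.columns:
        df["state"] = ""
    if "urban_area" not in df.columns:
        df["urban_area"] = ""
    df[POPULATION_COLUMNS].to_csv(path, index=False)


def read_population(path) -> PopulationGrid:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    _require_columns(df, POPULATION_COLUMNS, f"population {path}")
    for col in ("asian", "black", "hispanic", "white", "minority", "total"):
        df[col] = pd.to_numeric(df[col])
    df = df.set_index(pd.to_numeric(df["cell_id"]).astype(int)).drop(columns=["cell_id"])
    df.index.name = "cell_id"
    return PopulationGrid(df)  # partition invariant validated on construction


def write_scaling(scaling: ScalingTable, path) -> None:
    scaling.factors.to_csv(path, index=False)


def read_scaling(path) -> ScalingTable:
    df = pd.read_csv(path)
    _require_columns(df, ["region", "category", "pollutant_class", "factor"], f"scaling {path}")
    return ScalingTable(factors=df)


def write_incidence(incidence: np.ndarray, path) -> None:
    pd.DataFrame({"cell_id": np.arange(len(incidence)),
                  "incidence_per_person_yr": incidence}).to_csv(path, index=False)


def read_incidence(path) -> np.ndarray:
    df = pd.read_csv(path)
    _require_columns(df, ["cell_id", "incidence_per_person_yr"], f"incidence {path}")
    arr = df.sort_values("cell_id")["incidence_per_person_yr"].to_numpy(dtype=float)
    if (arr < 0).any():
        row = int(np.flatnonzero(arr < 0)[0])
        raise ValidationError(f"incidence {path} row {row}: negative rate")
    return arr


def write_scenario(scenario: ReductionScenario, inventory: list[EmissionSource], path) -> None:
    pd.DataFrame({
        "source_id": [s.id for s in inventory],
        "s": scenario.s,
        "co2_retained_t": scenario.s * np.array([s.co2 for s in inventory]),
    }).to_csv(path, index=False)


def read_scenario(path, inventory: list[EmissionSource]) -> ReductionScenario:
    df = pd.read_csv(path)
    _require_columns(df, ["source_id", "s"], f"scenario {path}")
    order = {s.id: i for i, s in enumerate(inventory)}
    if set(df["source_id"].astype(str)) != set(order):
        raise ValidationError(f"scenario {path}: source ids do not match the inventory")
    s = np.empty(len(inventory))
    for _, row in df.iterrows():
        s[order[str(row["source_id"])]] = float(row["s"])
    if ((s < 0) | (s > 1)).any():
        raise ValidationError(f"scenario {path}: retention factors outside [0, 1]")
    return ReductionScenario(s=s, source_ids=[src.id for src in inventory],
                             objective=float("nan"), provenance="policy-case")


def write_frontier(points: list[FrontierPoint], path) -> None:
    pd.DataFrame([{
        "provenance": p.provenance,
        "d_exposure_minority": p.d_exposure_minority,
        "d_disparity_minority_pp": p.d_disparity_minority_pp,
        "objective": p.objective,
    } for p in points]).to_csv(path, index=False)


def read_frontier(path) -> list[FrontierPoint]:
    df = pd.read_csv(path)
    _require_columns(df, ["provenance", "d_exposure_minority",
                          "d_disparity_minority_pp", "objective"], f"frontier {path}")
    return [FrontierPoint(
        d_exposure_minority=float(r.d_exposure_minority),
        d_disparity_minority_pp=float(r.d_disparity_minority_pp),
        objective=float(r.objective),
        provenance=str(r.provenance),
    ) for r in df.itertuples()]
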