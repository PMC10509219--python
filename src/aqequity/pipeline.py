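"""End-to-end pipeline: from inputs (files or a synthetic world) to a
report bundle of concentration fields, disparity tables, mortality totals,
optimized/sampled scenarios and frontier points.

The pipeline is a pure function of (inputs, config, seed): identical
configurations produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as aqio
from .airquality import apply_srm, concentration_delta
from .errors import ConfigurationError
from .exposure import disparity_table, scenario_delta_table
from .health import CRF, DEFAULT_INCIDENCE, attributable_mortality, source_total_mortality
from .inventory import scale_inventory
from .optimize import (
    ReductionScenario,
    build_constraints,
    evaluate_scenario,
    policy_retention,
    sample_scenarios,
    solve_allocation,
    uncertainty_bounds,
)
from .synth import SyntheticConfig, make_world

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration.

    Exactly one of ``synthetic`` (a SyntheticConfig block) or the file
    paths (inventory/population/srm/scaling, optional incidence) must be
    given.
    """

    synthetic: SyntheticConfig | None = None
    inventory_path: str | None = None
    population_path: str | None = None
    srm_path: str | None = None
    scaling_path: str | None = None
    incidence_path: str | None = None
    crf_beta: float = CRF().beta
    family: str = "nation-total"
    sense: str = "min"
    n_samples: int = 500
    seed: int = 0
    out_dir: str = "aqequity_out"
    log_level: str = "INFO"

    def validate(self) -> None:
        has_files = all(p is not None for p in (
            self.inventory_path, self.population_path, self.srm_path, self.scaling_path))
        if (self.synthetic is None) == (not has_files):
            raise ConfigurationError(
                "exactly one of a synthetic block or the four input file paths is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth_block = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if synth_block is not None:
            if "scenario_pattern" in synth_block:
                synth_block["scenario_pattern"] = {
                    k: tuple(v) for k, v in synth_block["scenario_pattern"].items()}
            if "group_names" in synth_block:
                synth_block["group_names"] = tuple(synth_block["group_names"])
            cfg.synthetic = SyntheticConfig(**synth_block)
        return cfg

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_inputs(config: RunConfig):
    """Resolve inputs from the synthetic block or from files."""
    if config.synthetic is not None:
        return make_world(config.synthetic)
    from .airquality import SourceReceptorMatrix

    inventory = aqio.read_inventory(config.inventory_path)
    population = aqio.read_population(config.population_path)
    srm = SourceReceptorMatrix.load(config.srm_path)
    scaling = aqio.read_scaling(config.scaling_path)
    if config.incidence_path:
        incidence = aqio.read_incidence(config.incidence_path)
    else:
        incidence = np.full(srm.n_cells, DEFAULT_INCIDENCE)
    return None, population, inventory, srm, incidence, scaling


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Emits per-scenario disparity tables, the optimized min/max scenarios
    for the configured constraint family, sampled frontier points, the
    point-source uncertainty ranges, and a machine-readable summary.json.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    logger.info("run config hash %s", config.config_hash())
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _grid, pop, inv_base, srm, incidence, scaling = load_inputs(config)
    inv_policy = scale_inventory(inv_base, scaling)
    crf = CRF(beta=config.crf_beta)

    base_field = apply_srm(inv_base, srm)
    policy_field = apply_srm(inv_policy, srm)
    delta = concentration_delta(policy_field, base_field)

    base_table = disparity_table(base_field, pop)
    policy_table = scenario_delta_table(policy_field, base_field, pop)
    base_table.to_csv(out / "disparity_baseline.csv")
    policy_table.to_csv(out / "disparity_policy.csv")

    tm = source_total_mortality(inv_base, srm, pop, incidence,
                                CRF(beta=crf.beta, form="linear"), group="minority")
    co2 = np.array([s.co2 for s in inv_base])
    spec = build_constraints(inv_base, inv_policy, config.family, tm=tm)

    policy = ReductionScenario(
        s=policy_retention(inv_base, inv_policy),
        source_ids=[s.id for s in inv_base],
        objective=float("nan"), provenance="policy-case")
    opt_min = solve_allocation(tm, co2, spec, sense="min")
    opt_max = solve_allocation(tm, co2, spec, sense="max")
    samples = sample_scenarios(co2, spec, n=config.n_samples, seed=config.seed)

    points = []
    for sc in (policy, opt_min, opt_max, *samples):
        point, _table = evaluate_scenario(sc, inv_base, srm, pop, incidence, crf)
        points.append(point)
    aqio.write_frontier(points, out / "frontier.csv")
    aqio.write_scenario(opt_min, inv_base, out / "scenario_optimized_min.csv")
    aqio.write_scenario(policy, inv_base, out / "scenario_policy.csv")

    bounds = uncertainty_bounds(inv_base, inv_policy, srm, pop, incidence, crf, tm=tm)
    bounds.to_csv(out / "uncertainty_bounds.csv")

    mort_base = attributable_mortality(base_field, pop, incidence, crf, group="total")
    mort_policy = attributable_mortality(policy_field, pop, incidence, crf, group="total")
    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "family": config.family,
        "n_sources": len(inv_base),
        "d_exposure_total": float(policy_table.loc["total", "d_exposure"]),
        "d_exposure_minority": float(policy_table.loc["minority", "d_exposure"]),
        "d_disparity_minority_pp": float(policy_table.loc["minority", "d_disparity_pp"]),
        "disparity_white_pct": float(base_table.loc["white", "disparity_pct"]),
        "disparity_minority_pct": float(base_table.loc["minority", "disparity_pct"]),
        "deaths_baseline_total": mort_base.total,
        "deaths_policy_total": mort_policy.total,
        "objective_policy": points[0].objective,
        "objective_optimized_min": points[1].objective,
        "objective_optimized_max": points[2].objective,
        "mean_total_delta_ug_m3": float(np.mean(delta.total)),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def load_run_config(path) -> RunConfig:
    return RunConfig.from_yaml(path)


def dump_run_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh)
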