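"""Optimal allocation of CO2 emission reductions.

A reduction scenario assigns each eligible source a retention factor
S_i ∈ [0, 1] applied jointly to all of its pollutants.  The allocation
problem minimizes (or maximizes) Σ_i S_i·TM_i — total minority mortality
caused by the retained emissions — subject to equality constraints
Σ_{i∈g} S_i·CO2_i = target_g for each constraint group g, where the groups
come from one of four families (nation-total, nation-sector, state-total,
state-sector) and the targets are the policy case's retained CO2 so every
optimized scenario achieves the same CO2 reductions as the policy it is
compared to.  Sources are eligible when they have non-zero baseline CO2
(and, when a TM vector is supplied, cause PM2.5-related mortality);
ineligible sources stay at baseline.

Because each group imposes a single linear constraint over box-bounded
variables, the single-group optimum has a closed greedy form: zero sources
in order of mortality per ton of CO2 until the reduction target is met,
fractionally retaining the marginal source.  That greedy serves as an
independent oracle for the LP solver.  A seeded sampler generates
non-optimal scenarios satisfying the same constraints, giving the cloud of
feasible outcomes between the min- and max-mortality optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .airquality import SourceReceptorMatrix, apply_srm
from .errors import AlignmentError, ConfigurationError, InfeasibleError, LabelError
from .exposure import PopulationGrid, scenario_delta_table
from .health import CRF, attributable_mortality
from .inventory import BROAD_SECTOR, EmissionSource

CONSTRAINT_FAMILIES = ("nation-total", "nation-sector", "state-total", "state-sector")

#: Relative tolerance on LP constraint residuals.
LP_RTOL = 1e-9
#: Relative tolerance on sampled-scenario constraint residuals.
SAMPLE_RTOL = 1e-6


@dataclass
class ConstraintSpec:
    """Constraint groups and CO2 targets for the allocation problem.

    ``eligible`` is a boolean mask over the inventory ordering; ``groups``
    maps a group key to a boolean mask (a partition of the eligible set);
    ``targets`` maps the same keys to retained-CO2 targets (metric tons/yr),
    computed over eligible sources only.
    """

    family: str
    eligible: np.ndarray
    groups: dict[str, np.ndarray]
    targets: dict[str, float]

    def __post_init__(self) -> None:
        cover = np.zeros_like(self.eligible, dtype=int)
        for mask in self.groups.values():
            cover += mask.astype(int)
        if not np.array_equal(cover > 0, self.eligible) or (cover > 1).any():
            raise ConfigurationError("constraint groups must partition the eligible set")
        for key, t in self.targets.items():
            if t < 0:
                raise InfeasibleError(f"group {key!r}: negative CO2 target {t}")


@dataclass
class ReductionScenario:
    """Per-source retention factors with their CO2 accounting.

    ``s`` is aligned with the inventory ordering; ineligible sources carry
    S = 1 (frozen at baseline).
    """

    s: np.ndarray
    source_ids: list[str]
    objective: float
    co2_by_group: dict[str, float] = field(default_factory=dict)
    provenance: str = "policy-case"


@dataclass
class FrontierPoint:
    """One scenario's position in (minority exposure change, disparity change)."""

    d_exposure_minority: float  # µg/m³ vs baseline
    d_disparity_minority_pp: float  # pp vs baseline
    objective: float  # minority mortality of the realized field (person/yr)
    provenance: str


def _group_key(source: EmissionSource, family: str) -> str:
    broad = BROAD_SECTOR.get(source.sector, source.sector)
    if family == "nation-total":
        return "nation"
    if family == "nation-sector":
        return broad
    if family == "state-total":
        return source.region
    if family == "state-sector":
        return f"{source.region}/{broad}"
    raise LabelError(f"unknown constraint family {family!r}; "
                     f"choose one of {CONSTRAINT_FAMILIES}")


def policy_retention(inv_base: list[EmissionSource],
                     inv_policy: list[EmissionSource]) -> np.ndarray:
    """Per-source CO2 retention of the policy case, S_i = CO2_policy/CO2_base.

    Sources with zero baseline CO2 get S = 1 (they are ineligible and stay
    at baseline in the single-S scenario representation).
    """
    if [s.id for s in inv_base] != [s.id for s in inv_policy]:
        raise AlignmentError("baseline and policy inventories have different source sets")
    out = np.ones(len(inv_base))
    for i, (b, p) in enumerate(zip(inv_base, inv_policy)):
        if b.co2 > 0:
            out[i] = min(max(p.co2 / b.co2, 0.0), 1.0)
    return out


def build_constraints(inv_base: list[EmissionSource], inv_policy: list[EmissionSource],
                      family: str, tm: np.ndarray | None = None) -> ConstraintSpec:
    """Constraint groups with targets equal to the policy case's retained CO2.

    Eligibility: non-zero baseline CO2, and — when ``tm`` is given —
    non-zero PM2.5-related mortality.  Targets are group sums of
    S_policy·CO2_base over eligible sources, so the policy case itself is
    feasible in every family and optimized scenarios match its reductions
    group-wise.
    """
    if family not in CONSTRAINT_FAMILIES:
        raise LabelError(f"unknown constraint family {family!r}; "
                         f"choose one of {CONSTRAINT_FAMILIES}")
    if [s.id for s in inv_base] != [s.id for s in inv_policy]:
        raise AlignmentError("baseline and policy inventories have different source sets")
    co2 = np.array([s.co2 for s in inv_base])
    eligible = co2 > 0
    if tm is not None:
        eligible = eligible & (np.asarray(tm) > 0)
    s_policy = policy_retention(inv_base, inv_policy)
    keys = np.array([_group_key(s, family) for s in inv_base])
    groups: dict[str, np.ndarray] = {}
    targets: dict[str, float] = {}
    for key in sorted(set(keys[eligible])):
        mask = eligible & (keys == key)
        groups[key] = mask
        targets[key] = float((s_policy[mask] * co2[mask]).sum())
    return ConstraintSpec(family=family, eligible=eligible, groups=groups, targets=targets)


def _check_feasible(co2: np.ndarray, spec: ConstraintSpec) -> None:
    for key, mask in spec.groups.items():
        cap = float(co2[mask].sum())
        t = spec.targets[key]
        if t < -LP_RTOL * max(cap, 1.0) or t > cap * (1 + LP_RTOL) + 1e-30:
            raise InfeasibleError(
                f"group {key!r}: target {t} outside feasible range [0, {cap}]")


def solve_allocation(tm: np.ndarray, co2: np.ndarray, spec: ConstraintSpec,
                     sense: str = "min") -> ReductionScenario:
    """Solve the allocation LP: optimize Σ S_i·TM_i s.t. group CO2 equalities.

    Returns a vertex solution with constraints satisfied to 1e-9 relative.
    ``tm`` and ``co2`` are aligned with the full inventory ordering.
    """
    if sense not in ("min", "max"):
        raise ConfigurationError(f"sense must be min|max, got {sense!r}")
    tm = np.asarray(tm, dtype=float)
    co2 = np.asarray(co2, dtype=float)
    _check_feasible(co2, spec)
    idx = np.flatnonzero(spec.eligible)
    keys = sorted(spec.groups)
    a_eq = np.zeros((len(keys), len(idx)))
    b_eq = np.zeros(len(keys))
    for r, key in enumerate(keys):
        a_eq[r] = co2[idx] * spec.groups[key][idx]
        b_eq[r] = spec.targets[key]
    c = tm[idx] if sense == "min" else -tm[idx]
    res = linprog(c, A_eq=a_eq, b_eq=b_eq, bounds=[(0.0, 1.0)] * len(idx), method="highs")
    if not res.success:
        raise InfeasibleError(f"LP failed ({res.message}) for family {spec.family!r}")
    s = np.ones(len(tm))
    s[idx] = np.clip(res.x, 0.0, 1.0)
    co2_by_group = {k: float((s * co2 * spec.groups[k]).sum()) for k in keys}
    return ReductionScenario(
        s=s, source_ids=[], objective=float((s[idx] * tm[idx]).sum()),
        co2_by_group=co2_by_group,
        provenance="optimized-min" if sense == "min" else "optimized-max",
    )


def greedy_ratio_oracle(tm: np.ndarray, co2: np.ndarray, target: float,
                        sense: str = "min") -> ReductionScenario:
    """Closed-form single-constraint optimum by mortality-per-ton ranking.

    For the min sense, sources are zeroed in descending TM_i/CO2_i order
    (worst mortality per retained ton of CO2 first) until remaining CO2
    equals the target, fractionally retaining the marginal source; max sense
    ranks ascending.  Ties broken by ascending position (source id order).
    Independent of the LP path.
    """
    tm = np.asarray(tm, dtype=float)
    co2 = np.asarray(co2, dtype=float)
    if (co2 <= 0).any():
        raise ConfigurationError("greedy oracle requires strictly positive CO2 "
                                 "(ineligible sources must be excluded)")
    cap = co2.sum()
    if target < 0 or target > cap * (1 + LP_RTOL):
        raise InfeasibleError(f"target {target} outside feasible range [0, {cap}]")
    ratio = tm / co2
    order = sorted(range(len(tm)),
                   key=lambda i: (-ratio[i], i) if sense == "min" else (ratio[i], i))
    s = np.ones(len(tm))
    remaining = cap - target  # CO2 still to be removed
    for i in order:
        if remaining <= 0:
            break
        if co2[i] <= remaining:
            s[i] = 0.0
            remaining -= co2[i]
        else:
            s[i] = 1.0 - remaining / co2[i]
            remaining = 0.0
    return ReductionScenario(
        s=s, source_ids=[], objective=float((s * tm).sum()),
        co2_by_group={"nation": float((s * co2).sum())},
        provenance="optimized-min" if sense == "min" else "optimized-max",
    )


def sample_scenarios(co2: np.ndarray, spec: ConstraintSpec, n: int = 5000,
                     seed: int = 0, q: float = 0.5) -> list[ReductionScenario]:
    """Random feasible scenarios spanning the constraint set.

    Per scenario and group: candidate reductions R_i = Bernoulli(q)·U(0,1),
    then a single group-wide multiplier t is bisected so that
    Σ min(t·R_i, 1)·CO2_i equals the required reduction; S = 1 − clip(t·R).
    Spans deep-cuts-at-few-sources through shallow-cuts-everywhere regimes.
    Deterministic given the seed; residuals ≤ 1e-6 relative by construction
    (bisection runs far past that).
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    co2 = np.asarray(co2, dtype=float)
    _check_feasible(co2, spec)
    rng = np.random.default_rng(seed)
    scenarios = []
    for _ in range(n):
        s = np.ones(len(co2))
        for key in sorted(spec.groups):
            mask = spec.groups[key]
            c = co2[mask]
            required = float(c.sum()) - spec.targets[key]
            if required <= 0:
                continue
            r = None
            for _attempt in range(50):
                cand = (rng.random(mask.sum()) < q) * rng.random(mask.sum())
                # feasible iff the selected sources' CO2 can cover the cut
                if float(c[cand > 0].sum()) >= required:
                    r = cand
                    break
            if r is None:  # fall back: every source participates
                r = rng.random(mask.sum()) + 1e-12
            lo, hi = 0.0, 1.0
            def reduction(t: float) -> float:
                return float((np.minimum(t * r, 1.0) * c).sum())
            while reduction(hi) < required:
                hi *= 2.0
                if hi > 1e18:
                    break
            for _it in range(200):
                mid = 0.5 * (lo + hi)
                if reduction(mid) < required:
                    lo = mid
                else:
                    hi = mid
            s[mask] = 1.0 - np.minimum(hi * r, 1.0)
        co2_by_group = {k: float((s * co2 * spec.groups[k]).sum()) for k in spec.groups}
        scenarios.append(ReductionScenario(
            s=s, source_ids=[], objective=float("nan"),
            co2_by_group=co2_by_group, provenance="sampled"))
    return scenarios


def realize_inventory(scenario: ReductionScenario,
                      inv_base: list[EmissionSource]) -> list[EmissionSource]:
    """Apply retention factors: all pollutants and CO2 of source i × S_i."""
    if len(scenario.s) != len(inv_base):
        raise AlignmentError("scenario length does not match inventory")
    out = []
    for s_i, src in zip(scenario.s, inv_base):
        out.append(replace(
            src,
            pollutants={p: m * s_i for p, m in src.pollutants.items()},
            co2=src.co2 * s_i,
        ))
    return out


def evaluate_scenario(scenario: ReductionScenario, inv_base: list[EmissionSource],
                      srm: SourceReceptorMatrix, pop: PopulationGrid,
                      incidence, crf: CRF,
                      group: str = "minority") -> tuple[FrontierPoint, pd.DataFrame]:
    """Realize a scenario and measure its exposure/disparity/mortality outcomes.

    Returns the frontier point (changes vs the S=1 baseline for ``group``)
    and the full per-group delta table.  The objective reported is the
    linear-form group mortality of the realized field, which equals
    Σ S_i·TM_i plus the constant contribution of ineligible sources.
    """
    base_field = apply_srm(inv_base, srm)
    field = apply_srm(realize_inventory(scenario, inv_base), srm)
    table = scenario_delta_table(field, base_field, pop)
    mort = attributable_mortality(field, pop, incidence, CRF(beta=crf.beta, form="linear"),
                                  group=group)
    point = FrontierPoint(
        d_exposure_minority=float(table.loc[group, "d_exposure"]),
        d_disparity_minority_pp=float(table.loc[group, "d_disparity_pp"]),
        objective=mort.total,
        provenance=scenario.provenance,
    )
    return point, table


def uncertainty_bounds(inv_base: list[EmissionSource], inv_policy: list[EmissionSource],
                       srm: SourceReceptorMatrix, pop: PopulationGrid,
                       incidence, crf: CRF, tm: np.ndarray | None = None) -> pd.DataFrame:
    """Exposure/disparity ranges from redistributing point-source reductions.

    Keeps CO2 reductions fixed per (region, broad sector) but lets point
    sources within each group vary; area sources stay at the policy case.
    Solves the min- and max-mortality redistributions and returns, per
    group, the range over {policy, min, max} of ΔE (µg/m³) and ΔD (pp) —
    the error bars around the policy case.
    """
    co2 = np.array([s.co2 for s in inv_base])
    is_point = np.array([s.kind == "point" for s in inv_base])
    s_policy = policy_retention(inv_base, inv_policy)
    spec = build_constraints(inv_base, inv_policy, "state-sector", tm=tm)
    point_eligible = spec.eligible & is_point
    groups, targets = {}, {}
    for key, mask in spec.groups.items():
        pmask = mask & is_point
        if pmask.any():
            groups[key] = pmask
            targets[key] = float((s_policy[pmask] * co2[pmask]).sum())
    pspec = ConstraintSpec(family="state-sector", eligible=point_eligible,
                           groups=groups, targets=targets)
    if tm is None:
        raise ConfigurationError("uncertainty_bounds requires the TM vector")

    results = []
    for sense in ("min", "max"):
        sol = solve_allocation(tm, co2, pspec, sense=sense)
        s = s_policy.copy()
        s[point_eligible] = sol.s[point_eligible]
        results.append(ReductionScenario(s=s, source_ids=[], objective=sol.objective,
                                         provenance=f"uncertainty-{sense}"))
    policy = ReductionScenario(s=s_policy, source_ids=[], objective=float("nan"),
                               provenance="policy-case")

    tables = [evaluate_scenario(sc, inv_base, srm, pop, incidence, crf)[1]
              for sc in (policy, *results)]
    rows = {}
    for g in tables[0].index:
        de = [t.loc[g, "d_exposure"] for t in tables]
        dd = [t.loc[g, "d_disparity_pp"] for t in tables]
        rows[g] = {"d_exposure_lo": min(de), "d_exposure_hi": max(de),
                   "d_disparity_lo": min(dd), "d_disparity_hi": max(dd)}
    return pd.DataFrame(rows).T
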