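# Methods

This note documents the model implemented by `aqequity`: equations,
parameter defaults, the synthetic-world generator, numerical choices,
and limitations. Units are given throughout; all defaults are module
constants that can be overridden at call sites.

## 1. Domain and inventory

The spatial domain is a regular `nx × ny` grid (`aqequity.grid.Grid`)
with square cells of side `cell_km` (default 1 km in the core, 10 km in
the synthetic generator). Cells are indexed row-major; coordinates are
cell-centroid kilometres.

An emission source (`aqequity.inventory.EmissionSource`) carries:

- `kind`: `"point"` (stack at one cell) or `"area"` (ground-level,
  optionally spread across cells with `allocate_area_source`);
- annual pollutant masses in metric tons/yr for the five PM2.5
  precursor/primary species `pm25, so2, nox, nh3, voc`, plus `co2`;
- labels: state/region, one of seven sectors (`electricity-coal`,
  `electricity-other`, `transportation`, `industry`, `residential`,
  `food-agriculture`, `other`; the two electricity sectors share the
  broad sector `electricity`), a detailed `tier2` category, and for
  electricity a `balancing_area`;
- optional stack parameters and/or a pre-assigned release layer.

## 2. Effective stack height

Point sources with stack data get a Holland plume rise:

Δh = (v_s · d / u) · (1.5 + 2.68×10⁻³ · p · d · (T_s − T_a) / T_s)

with exit velocity `v_s` (m/s), stack diameter `d` (m), wind speed `u`
(m/s), ambient pressure `p` (millibar, default 1013.25), stack-gas and
ambient temperatures `T_s`, `T_a` (K). The 2.68×10⁻³ coefficient has
units mb⁻¹·m⁻¹. Effective stack height ESH = physical height + Δh.
Worked case: `v_s=10, d=2, u=5, p=1013, T_s=400, T_a=283` gives
Δh = 12.353 m.

ESH is binned into release layers: **ground** [0, 57) m, **low**
[57, 379] m, **high** (379, ∞) m. Layer assignment rules
(`resolve_layers`): area sources are always ground; a pre-assigned layer
stands; point sources with stacks use the Holland ESH; point sources
without stacks inherit the layer of the nearest source with the same
`tier2` category (ties broken by lexicographically smallest id); if no
such donor exists an `ImputationError` is raised.

## 3. Air quality

Concentrations come from per-(pollutant, layer) source–receptor
matrices `M ∈ ℝ^{n_cells × n_cells}` in µg/m³ per t/yr
(`SourceReceptorMatrix`). Emitted species map one-to-one to PM2.5
components: pm25→primary PM2.5, so2→particulate sulfate, nox→nitrate,
nh3→ammonium, voc→secondary organic aerosol. `apply_srm` accumulates
per-(pollutant, layer) emission vectors over the inventory and computes
`c_p = e_{p,ℓ}ᵀ M_{p,ℓ}` summed over layers; total PM2.5 adds a
spatially uniform background (default 0). The model is strictly linear:
concentrations superpose over sources and scale with emissions, which
the test suite verifies to 1 part in 10⁹. `sector_contribution`
attributes a policy's concentration change to one sector by differencing
only that sector's emissions.

## 4. Exposure and disparity

Demography is a per-cell table of counts for `asian`, `black`,
`hispanic`, `white`, the derived `minority` (= asian + black +
hispanic) and `total` (`PopulationGrid`; the partition
white + minority = total is validated at load with relative tolerance
10⁻⁶). Metrics:

- population-weighted exposure `E_g = Σ_j pop_{g,j} C_j / Σ_j pop_{g,j}`
  (µg/m³);
- relative disparity `D_g = 100·(E_g − E_total)/E_total` (%), undefined
  (raises) when total exposure is zero;
- changes between scenarios are reported as `d_exposure` (µg/m³) and
  `d_disparity_pp` (percentage points).

Exact identities maintained by construction and enforced in tests:
group partition (Σ_g pop_g E_g over {white, minority} equals
pop_total E_total), zero disparity under a spatially uniform field, and
invariance of `D_g` under uniform scaling of concentrations.
Subgroup reports per region skip zero-population slices with a warning
rather than emitting NaNs.

## 5. Health

The concentration–response function (`CRF`) defaults to a log-linear
hazard with relative risk 1.06 per 10 µg/m³, i.e.
β = ln(1.06)/10 ≈ 5.827×10⁻³ per µg/m³, a standard long-term PM2.5
mortality slope from large US cohort studies. Attributable mortality in
cell `j` for group `g` is
`pop_{g,j} · inc_j · (1 − e^{−β C_j})` with baseline incidence `inc_j`
(default 0.008 deaths/person-yr). A linear form
(`pop · inc · β · C`) is provided for uses that require additivity over
sources; with it, the marginal mortality `TM_i` of source `i` is exact
and `Σ_i TM_i` equals whole-field linear mortality. With spatially
uniform incidence, linear group mortality is proportional to that
group's population-weighted exposure, so optimizing one optimizes the
other.

## 6. Allocation optimization

Let `S_i ∈ [0,1]` be the retained fraction of source `i`'s baseline
activity (all pollutants and CO2 scale together). Given a reference
policy inventory, `policy_retention` sets
`S_i = CO2_policy,i / CO2_base,i` (clipped to [0,1]; 1 where baseline
CO2 is zero). `build_constraints` forms equality targets
`T_g = Σ_{i∈g} S_i^{policy} · CO2_i` over **eligible** sources (positive
CO2, and positive marginal mortality when an objective vector is
supplied), for one of four families: `nation-total`, `nation-sector`
(broad sectors), `state-total`, `state-sector`. Because targets are
computed from the feasible policy vector restricted to eligible sources,
the policy case is feasible in every family and the min-sense optima
nest exactly:

nation-total ≤ {nation-sector, state-total} ≤ state-sector ≤ policy.

`solve_allocation` solves `min/max Σ S_i TM_i` subject to the equality
targets and box constraints with `scipy.optimize.linprog`
(method `"highs"`). For a single group the solution is a ratio greedy:
zero out sources in descending `TM_i/CO2_i` order (min sense) until the
target binds, with one fractional marginal source; `greedy_ratio_oracle`
implements this independently and the tests additionally cross-check
both against exhaustive vertex enumeration on instances of ≤ 12 sources,
requiring three-way agreement to 10⁻⁹ relative.

`sample_scenarios` draws random feasible scenarios: per source,
`R_i = Bernoulli(q=0.5)·U(0,1)` proposes a cut, and a per-group scalar
`t` is bisected (200 iterations) so `Σ min(t R_i, 1)·CO2_i` meets the
required reduction; constraint residuals are ≲10⁻¹² relative and every
sampled objective lies inside the [min, max] optimum envelope.

`uncertainty_bounds` brackets each state–sector group's exposure and
disparity changes by re-optimizing its point sources (area sources held
at policy retention) in both senses and reporting the range over
{policy, min, max}.

## 7. Synthetic worlds

`aqequity.synth.make_world(SyntheticConfig)` generates a complete study
— grid, population, inventory, source–receptor matrices, incidence, and
a policy scaling table — from a single integer seed. Named substreams
via `numpy.random.SeedSequence(entropy=seed, spawn_key=(k,))` keep
components independently reproducible.

What it emulates:

- **Transport:** Gaussian kernels
  `amp_p · exp(−d²/2L_p²) · a^layer` with per-pollutant amplitude and
  decay length and layer attenuation `a` (default 0.6 per layer),
  standing in for reduced-form chemical-transport sensitivities. Primary
  PM2.5 has the largest amplitude and shortest range; secondary species
  are weaker and longer-range.
- **Demography:** a segregation dial in [0, 1] blends a minority share
  that decreases with distance-to-source rank (dial = 1: minorities
  concentrated near sources) with an iid random share (dial = 0).
  Minority counts split into asian/black/hispanic by a Dirichlet draw.
  States are vertical stripes `S1..Sn`; top-decile population cells are
  labeled `<state>-urban`.
- **Policy shape:** per-sector retention ranges concentrate the CO2 cut
  in coal electricity (retention 5–8 %) with much milder cuts elsewhere,
  and electricity scaling is applied per balancing area — mimicking the
  cost-ordered pattern of power-sector-led decarbonization. On generated
  worlds, electricity contributes well over half of the total CO2
  reduction.

What it does **not** emulate: real atmospheric chemistry (no
nonlinearity, no meteorology fields, isotropic kernels), real census
geography or income, inter-annual variability, or source entry/exit.
Absolute concentration levels are arbitrary; only structural and
relational properties (linearity, identities, orderings, monotonicity)
are meaningful, and those are what the tests assert.

## 8. Numerical and software choices

- LP solved by HiGHS via SciPy rather than a hand-rolled simplex; the
  greedy oracle and vertex enumeration exist purely as independent
  checks.
- Equality (not ≤) CO2 constraints: makes the policy case feasible by
  construction and the nesting chain exact.
- Tolerances: LP/oracle agreement 10⁻⁹ relative; sampler residuals
  10⁻⁶ relative (achieved ≲10⁻¹²); population partition 10⁻⁶ relative.
- File formats: CSV for tabular data (inventory, population, scaling,
  incidence, scenarios, frontier) with schema and row-level validation;
  source–receptor matrices as NumPy `.npz` (runtime artifact only).
- Determinism: every stochastic routine takes an explicit seed; the
  pipeline writes a byte-identical `summary.json` on rerun.

## 9. Limitations

- The synthetic generator supports methodological validation, not
  empirical claims; no number computed on synthetic worlds should be
  read as an estimate for any real region.
- The linear-CRF objective slightly understates mortality differences
  at high concentrations relative to the log-linear form; the package
  reports log-linear mortality for totals and uses the linear form only
  where source-additivity is required.
- Retention fractions scale all of a source's pollutants and CO2
  together; fuel-switching or control-technology responses that change
  co-pollutant ratios are out of scope.
- Uncertainty bounds cover allocation freedom only, not
  transport-model or CRF parameter uncertainty.
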