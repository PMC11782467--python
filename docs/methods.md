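# Methods

## Model structure

The population is a closed system of 17 ordinary differential equations
over dimensionless densities. Every flux is one of eight demographic
events: productive mating, dependant maturation, dependant death, female
fertility loss, pair break-up, male retirement (frailty), adult death,
and paternity theft at maturation. Each compartment's outflows carry its
own density as a factor, so the non-negative orthant is forward
invariant and a lineage at exactly zero stays at zero.

Females drive mating: a free fertile female conceives at rate ρ and her
partner is multiple-mating with probability M/(M+G), guarding otherwise
(in which case the two form a pair). When no unpaired males exist
(M + G = 0) all mating fluxes, and the theft probability, are defined as
zero — the printed fractions have no limit there, and the biological
reading (no males, no matings) is unambiguous. Paired couples without a
dependant conceive at the same rate ρ. Offspring sex is half and half at
maturation; sons adopt the father's strategy, daughters carry the
dependant's trait into the corresponding free-female pool. A guarded
dependant's maturing son is diverted to the multiple-mating pool with
probability q = q\*·M/(M+G); as printed in the source equations, only
sons are diverted — daughters of guarded dependants always join the
guard-trait female pool. We implement that asymmetry exactly as printed.

Two corrections of obvious typos in the printed system are applied: a
doubled "+" in the recruitment sum of the multiple-mating males'
equation, and a missing time argument on one male death rate. The
printed population list names one pair compartment twice; the model has
the 17 unique compartments listed above. The printed parameter table
gives both dependant death rates as "0.11·k"; per the accompanying text
the guarded rate is fixed at δ_g = 0.11/yr and the unguarded rate is
δ_m = k·δ_g with k ∈ [1, 2] (values outside that range warn but run).

## Mortality and population regulation

The female death rate is max{1/L, (β/2)·Σ carers}: a floor at the
reciprocal lifespan plus a density-dependent term that exactly offsets
the birth flux β·Σ carers when half of newborns are female, holding the
population near its initial size. Because that term uses absolute
densities, results depend on the scale of the initial state; the
canonical initial condition (FM = FG = M = G = 0.5, total 2.0) is the
reference scale, and every equilibrium result records the initial total.
Males die 9% faster (factor 1.09), consistent with the male-biased
mortality of hunter-gatherer demographies.

## Parameters

| name | meaning | default | unit |
|---|---|---|---|
| ρ (`rho`) | conception rate of fertile females | 3 (4-month mean wait) | 1/yr |
| β (`beta`) | dependant-independence rate; 1/β = interbirth interval | 0.25 (human), 0.2 (chimpanzee) | 1/yr |
| δ_g (`delta_g`) | guarded-dependant death rate | 0.11 | 1/yr |
| k | unguarded mortality multiplier, δ_m = k·δ_g | 1 | — |
| q\* (`q_star`) | theft success rate | 0 | probability |
| χ (`chi`) | pair-bond break-up rate; 1/χ = mean bond length | 0 (unbreakable) | 1/yr |
| L | expected adult lifespan | 38 (human), 22 (chimpanzee) | yr |
| `fertility_case` | case1: fertility never ends (ω_F = 0); case2: ends at 45, ω_F = 2/(90−L) | case2 | — |
| `male_mortality_factor` | μ_M/μ_F | 1.09 | — |
| `male_frailty_scale` | ω_M = 1/(scale·L) | 1.6 | — |

The L/2 maturity scaling (humans mature at 19, chimpanzees at 11) and
the δ_g estimate −(1/4)ln 0.65 ≈ 0.11 are exposed as helpers
(`female_maturity_age`, `dependant_death_rate`). Configs accept
`interbirth_interval` and `pair_bond_duration` as aliases that set β and
χ reciprocally; supplying an alias alongside an inconsistent base value
is an error, and a zero pair-bond duration is refused (use χ = 0 for
unbreakable bonds).

## Equilibrium runs and classification

`find_equilibrium` integrates from the canonical initial state until
max_i |dS_i/dt| / (|S_i| + 1e−12) stays below 1e−8 throughout a
sustained 50-year window, or until t_max = 5·10⁵ yr. The horizon is
large because strategy sorting is slow: near the reference parameters
the losing lineage decays at only ~10⁻⁴–10⁻³ per year, so the residual
criterion is met at ~10⁴–10⁵ simulated years depending on distance from
the dominance boundary. Cells still unresolved at t_max are flagged
`converged=False` and excluded from boundary statistics rather than
guessed.

At the final state, guarding-lineage males are G plus all five pair
compartments (every paired male guards) and multiple-mating males are M;
a lineage is extinct below 10⁻⁶ of the summed compartments. Exactly one
survivor gives `guarding` or `multiple_mating`; both give `coexistence`
(reported, never forced to a label — it occurs only in a thin band at
region boundaries); neither gives `extinct`, which genuinely happens at
extreme interbirth intervals where births cannot offset deaths. The
classification uses male compartments only; female trait carriers follow
their sires' lineage, which the tests verify rather than assume.

## Numerical scheme

The default integrator is a package-authored adaptive Dormand–Prince
5(4) stepper, compiled with numba so that multi-thousand-cell sweeps of
10⁵-year runs remain minutes-scale on one CPU; any scipy `solve_ivp`
method can be selected instead (`IntegrationSettings(method="LSODA")`),
and the test suite cross-checks the two routes against each other and
against an independently coded fixed-step RK4 integrator to 10⁻⁶ per
compartment.

Three numerical choices matter:

* **Step tolerances** default to rtol 10⁻¹⁰, atol 10⁻²⁰. The relative
  residual has a noise floor of roughly rtol × (fastest system rate);
  rtol must sit well below convergence_tol/|λ_max| ≈ 3·10⁻⁹ or the
  convergence check flickers near its threshold. The very small atol
  keeps the error controller tracking dying lineages down to the snap
  threshold instead of letting them wander at the atol scale.
* **Negativity handling**: components in (−10⁻¹⁰, 0) after a step are
  treated as integration noise and clamped to zero at outputs; anything
  below −10⁻¹⁰ aborts with an error naming the compartment, since it
  indicates solver failure rather than model behaviour.
* **Lineage snapping**: any component whose magnitude falls below 10⁻¹⁴
  during integration is set to exactly zero. A dying lineage otherwise
  floors at the roundoff scale (~10⁻¹⁵, mixed signs) and the residual
  criterion never settles. Exact zeros are dynamically invariant, and
  10⁻¹⁴ is eight orders below the extinction-classification threshold,
  so the snap cannot change a classification.

## Sweeps, boundaries, curves

`run_grid` runs one equilibrium per cell of a 2-D grid with identical
initial conditions everywhere; per-cell failures are recorded, never
fatal. `extract_boundary` emits every horizontally/vertically adjacent
cell pair whose converged single-strategy labels differ, with the
boundary OSR/ASR taken as the mean of the two cells — matching the
"roughly corresponds" precision of a grid-resolution boundary. An
optional `refine_boundary` pass bisects along the parameter segment
joining the two cells for sub-cell placement. `guarding_fraction`
summarises a map as guarding cells over converged single-strategy cells,
and `osr_curve` traces equilibrium OSR/ASR along one axis.

Default grid ranges (overridable in configs): interbirth interval 1–10
yr × L 20–45 yr for lifespan/interbirth maps; q\* 0–0.3 × pair-bond
duration 1–25 yr for the theft/bond-length map at L = 30, interbirth 5.
Exact grid resolutions behind the published figures are unknown, so all
figure-level checks are band or monotonicity checks, not pixel matching.
The acceptance script uses 41×41 (~1–2 min); the test suite uses 21×21
for the boundary-band check and 6×6–11×11 for monotonicity and case-1
properties, sizes at which every check above is stable.

## What the simulations do and do not show

All experiments are self-contained simulations of the model itself —
there is no external data and no random number generator anywhere, so
every result is exactly reproducible. Inputs are parameter sets,
initial states and sweep specifications. Consequently the tests
demonstrate properties of the model (dominance flips with lifespan,
region monotonicity in q\*, χ, k, OSR growth with interbirth interval
and lifespan, the ~9.2 boundary OSR in the theft/bond plane), not
properties of any empirical population. Known model limitations: no age
structure (chimp-vs-human outcomes are parameter-driven, not emergent),
no female choice, no explicit male-male contests beyond chance, pure
patrilineal strategy inheritance, and constant female fecundity until an
abrupt fertility end at 45. In the no-menopause variant (case 1)
multiple mating dominates wherever the population survives; at extreme
interbirth intervals whole populations go extinct, and such cells are
excluded from strategy-dominance claims since no strategy can survive
there.
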