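# Methods

## Model

`phanerodiv` simulates the diversification of marine invertebrate genera on
a set of Lagrangian seafloor points over Phanerozoic-scale time. Each point
carries a regional genus richness `D` that evolves under one of two models:

- **logistic** — `dD/dt = ρ D (1 − D/K_eff)`, diversity-dependent
  diversification bounded by an effective carrying capacity;
- **exponential** — `dD/dt = ρ D`, the unbounded limit of the logistic
  model (`K_eff → ∞`).

The net per-capita rate couples to the environment as

```
ρ = ρ_max − (ρ_max − ρ_min)(1 − Q_temp · Q_food)
Q_temp = Q10^((T − T_min)/10) / Q10^((T_max − T_min)/10)
Q_food = POC / (K_food + POC)
```

`T_min`/`T_max` are the 0.01/0.99 empirical quantiles of active-point
temperatures, recomputed per time slice (a thermal-adaptation assumption:
organisms track the contemporary climate envelope). The particulate organic
carbon (POC) export envelope is computed once over the whole run, and
`K_eff` maps it linearly onto `[K_min, K_max]`, clamped outside.

Habitat dynamics impose the boundary conditions: every active point starts
at one genus; a continental point that emerges records `D = 0`; on
re-flooding it is seeded with the richness of the nearest (great-circle)
flooded continental point with `D > 1` (coastal recolonization), else 1;
ridge-born ocean points start at 1; subducted points lose their diversity.
A point arriving in an environment whose carrying capacity is below its
accumulated richness is reset to that capacity (local extinction).

Mass extinctions are non-selective external forcings ("field of bullets"):
while an event is active, the environmental rate of every active point is
**replaced** by the event's constant imputed rate `ln(1 − loss)/duration`
(< 0), so that exact exponential decay over the event removes exactly the
scheduled fraction. Whether forcing replaces or adds to the environmental
rate is a design choice; replacement keeps the imputation exact and makes
"deactivating an event" a clean counterfactual.

## Parameters and defaults

| symbol | default | units | meaning |
|---|---|---|---|
| ρ_min, ρ_max | 0.001, 0.035 | Myr⁻¹ | net diversification rate limits |
| Q10 | 1.75 | – | temperature sensitivity of origination |
| K_food | 0.5 | mol C m⁻² yr⁻¹ | half-saturation POC flux |
| K_min, K_max | 12, 123 | genera/cell | calibrated carrying-capacity bounds |
| J_off, J_max | 0.06, 1.0 | – | Jaccard decay offset and maximum |
| λ | 0.0024 | km⁻¹ | distance-decay rate |
| truncation | 555 | km | transect length cap (5° at the equator) |
| land fraction | 0.2 | – | maximum continental share of a transect |
| peak quantile | 0.75 | – | local-maximum retention threshold |
| CCC threshold | 0.70 | – | calibration selection cut |
| ode_step | 1 | Myr | Euler substep |

The defaults are the calibrated values of the source analysis; all are
exposed through `ModelParams`/`DecayParams`.

## Numerical scheme

The ODEs are integrated with **explicit forward Euler** at a fixed substep
(default 1 Myr), with the environment held constant within each time slice
(the arrival slice's fields are used for the interval). Forward Euler keeps
every update auditable — one multiply-add per substep — at the cost of a
truncation error of roughly `ρ²t/2` in the growth phase: at ρ = 0.035 over
100 Myr the trajectory undershoots the analytic logistic solution by ~4%
and the exponential one by ~6%, shrinking linearly with the substep (the
test suite verifies both the exact Euler recursion and the convergence
under refinement). Because extinction forcing acts through the same
stepper, a scheduled loss materializes as the Euler-composed factor
`(1 + ρ_ext Δt)^(duration/Δt)`, which converges on `1 − loss` as the
substep shrinks.

Degenerate cases are defined explicitly: a slice whose temperature envelope
collapses (`T_min = T_max`) has `Q_temp := 1`; a collapsed POC envelope
maps every flux to `K_max`; surviving active points are floored at one
genus after each slice (a genus count below one is not meaningful, and
troughs are defined at `D = 1`); logistic richness is clipped to `K_eff`
at every substep.

## Global integration

Per-slice point richness is rasterized onto the annotated global grid by
nearest-neighbour interpolation within a configurable radius (default
500 km), **independently for ocean and shelf points** — a shelf cell is
never filled from an ocean value or vice versa; co-located points average.
Unpopulated age-zero ocean cells (fresh ridge crust) get richness 1.

Peaks are 8-neighbourhood local maxima (longitude-periodic) whose value
strictly exceeds the 0.75 quantile of all local-maximum values; an
equal-valued plateau contributes its middle cell. If every local maximum
ties (e.g. immediately after a global kill flattens the map), a single
representative cell is kept rather than none or all. Troughs are age-zero
ocean cells. Transects run from each peak to its nearest trough along a
Bresenham raster line in index space, wrapping longitude along the shorter
arc; they are rejected when continental cells exceed 20% of the path and
truncated to the peak-side prefix whose cumulative haversine length
(Earth radius 6,371 km) stays within 555 km. Unpopulated path cells
contribute background richness 1.

Within a transect, `γ_i = α₁ + Σ (1 − V_{n,n+1}) α_{n+1}`, where each
neighbour similarity comes from the Jaccard distance-decay law converted to
the Simpson overlap coefficient `V = (1 + R) J / (1 + J)`,
`R = max(α)/min(α)`, recomputed with `R = 1` whenever the conversion would
exceed one (shared genera cannot outnumber the poorer assemblage). The
formula is applied literally even where α is locally non-monotone along
the path; cells are not re-sorted. Across transects, a zigzag integration
sorts by decreasing `γ` (ties by peak cell index) and discounts each
transect by its overlap with the nearest already-integrated peak, with `R`
taken as the ratio of the two transect diversities. Coincident duplicate
peaks are therefore absorbed exactly. An exact set-theoretic oracle backs
the within-transect formula: for integer overlaps satisfying the nesting
assumption (genera shared by cells two apart are present between), the
integral equals the cardinality of the union of explicitly constructed
genus sets.

## Calibration

Model and reference curves are min–max normalized over their full length,
the reference is linearly interpolated onto the model's slice ages, and
Lin's concordance correlation coefficient (population moments, n-divisor)
is computed on the **concatenation** of the rising inter-extinction
segments — the maximal index runs outside every scheduled event window.
Serial correlation is deliberately ignored; the comparison targets
long-term trends. The carrying-capacity search enumerates all 28 ordered
pairs from {2, 4, …, 256} and averages the pairs with CCC above the
threshold. On a self-generated reference the search recovers the
generating pair exactly (CCC = 1), which is the package's parameter-
recovery check.

## Synthetic worlds

The generator emulates the statistical structure the downstream analysis
assumes, not plate tectonics or climate physics: continental points are
fixed in space, clustered around a few continent centres, and alternate
flooded/emergent stints with geometric (or fixed, for hand-traceable
tests) lengths, resetting seafloor age on re-flooding; ocean points are
born at a ridge meridian, drift zonally at constant speed, and die by
random subduction or on colliding with a continental cell. Temperature
falls linearly with |latitude| between configurable equator and pole
values plus cell-level Gaussian noise; POC flux is lognormal around a
shelf mean (default 3.0 mol C m⁻² yr⁻¹) and a deep-sea mean (0.1),
encoding the shelf-enhanced food supply. One seeded generator is consumed
in a documented fixed order, so a (config, seed) pair reproduces the world
bit-for-bit.

Default problem sizes are desk-scale: 82 evenly spaced slices over
541 Myr, ~300 continental and ~1,200 ocean points on a 2° grid (the real
reconstructions track ~6,000/~44,000 points on 0.5° grids, with 82 uneven
stratigraphic bins). Tests and the acceptance script use 10–30 slices and
a few hundred points on 5–6° grids so the full grid search runs in tens of
seconds. What passing tests show is therefore that the *machinery* — the
rate laws, the stepping, the habitat bookkeeping, the transect estimator
and the calibration loop — is correct and internally consistent; they do
not reproduce the empirical Phanerozoic curves, which depend on the real
paleogeographic reconstructions and Earth-system model fields.

## Known limitations

- No extinction selectivity, no oxygen limitation, no explosive
  post-extinction radiations, and a single global distance-decay function
  (provinciality does not vary in space or time).
- Continental points do not drift; ocean drift is purely zonal. This
  preserves the age/habitat statistics the engine consumes but not
  realistic geography.
- The zigzag estimate depends on the transect census: maps flattened to a
  single value yield one representative transect by convention.
- Forward Euler at 1 Myr carries the truncation bias quantified above;
  reduce `ode_step` where trajectory accuracy matters.
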