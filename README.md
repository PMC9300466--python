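# phanerodiv

Spatially explicit modelling of Phanerozoic marine-invertebrate
diversification. The package asks how much of the history of global marine
genus richness over the last 541 Myr can be explained by three ingredients:
the lifespans of seafloor habitats (time-for-speciation on drifting ocean
crust and flooding/emerging continental shelves), environment-dependent
diversification rates (seawater temperature and food supply), and
externally imposed mass extinctions. It is aimed at macroevolution and
paleobiodiversity researchers who want a fully testable, self-contained
implementation of the model chain — from habitat tracking to a global
diversity curve — runnable on synthetic paleogeography without any data
downloads.

## The model

Regional genus richness `D` on each tracked seafloor point follows

```
dD/dt = ρ D (1 − D/K_eff)        (logistic)
dD/dt = ρ D                      (exponential end member)
```

with the net per-capita diversification rate and carrying capacity set by
the local environment:

```
ρ      = ρ_max − (ρ_max − ρ_min)(1 − Q_temp Q_food)
Q_temp = Q10^((T − T_min)/10) / Q10^((T_max − T_min)/10)
Q_food = POC / (K_food + POC)
K_eff  = linear map of POC onto [K_min, K_max]
```

Mass extinctions impose a constant negative rate `ln(1 − loss)/duration`
on every active point (non-selective "field of bullets"). Regional maps
are turned into a global estimate by tracing transects from diversity
peaks to age-zero ocean troughs, integrating richness with a
distance-decay of taxonomic similarity
`J = J_off + (J_max − J_off) e^(−λ·d)` converted to Simpson overlap, then
zigzag-integrating transects from richest to poorest. Carrying-capacity
bounds are calibrated by a 28-pair grid search scored with Lin's
concordance correlation coefficient against a reference curve. See
`docs/methods.md` for the full account.

## Worked example

```python
from phanerodiv import (WorldConfig, build_world, make_extinction_schedule,
                        ModelParams, simulate, global_diversity_curve,
                        extinction_toggle_experiment)

cfg = WorldConfig(n_slices=20, slice_spacing=5.0, start_age=541.0,
                  grid_resolution=6.0, n_continental_points=40,
                  n_ocean_points=120, seed=42)
world = build_world(cfg)
schedule = make_extinction_schedule([(491.0, 5.0, 0.9)])   # 90% loss over 5 Myr
print("imputed rate:", round(schedule.imputed_rate[0], 4), "Myr^-1")

history = simulate(world, ModelParams(), schedule)
curve = global_diversity_curve(history, world)
print(curve.table.iloc[[0, 9, 10, 11, 19]].round(2))
```

prints

```
imputed rate: -0.4605 Myr^-1
    age_ma  gamma_total  n_transects
0    541.0         1.00            1
9    496.0        35.27           22
10   491.0        40.84           22
11   486.0         1.19            1
19   446.0        31.75           20
```

At 541 Ma every point holds a single genus, so the map is flat and the
global estimate is 1. Diversity accumulates to a global γ of ~41 genera by
491 Ma, collapses to ~1 across the scheduled 90% extinction (486 Ma), and
recovers over the following 40 Myr. Deactivating the event quantifies its
long shadow:

```python
rep = extinction_toggle_experiment(world, ModelParams(), schedule,
                                   disabled_event_ids=[0])
post = rep.curve_table["ratio"].iloc[12:]
print("post-recovery ratio range:", round(post.min(), 2), "-", round(post.max(), 2))
```

```
post-recovery ratio range: 1.94 - 2.41
```

i.e. the unperturbed world stays two to two-and-a-half times more diverse
than the forced one throughout the recovery interval — the same experiment
design used to probe the long-term effect of individual mass extinctions
on diversity-hotspot development.

A command-line interface wraps the same pipeline:

```
phanerodiv world generate --config cfg.yaml --seed 5 --out world/
phanerodiv integrate --world world/ --extinctions extinctions.csv --model logistic --out run/
phanerodiv calibrate --world world/ --reference fossil_curve.csv --out calib/
phanerodiv diagnose --world world/ --extinctions extinctions.csv --disable-extinction 0 --out diag/
```

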