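# envtrace

Quantify how much of the variation in an environmental variable is
traceable in multivariate animal-movement data.

Biologging studies routinely record animal movement at two levels —
trajectories through the landscape (GPS) and movements of body parts
(tri-axial accelerometers) — but analyses usually collapse this richness
into a few descriptors before asking how the environment shapes
behaviour. `envtrace` turns the question around: it extracts a large,
structured feature set from the raw sensor streams, trains a model to
predict an environmental variable *from* the movement features, and reads
the coefficient of determination on a held-out period

&nbsp;&nbsp;&nbsp;&nbsp;R² = 1 − Σᵢ(yᵢ − fᵢ)² / Σᵢ(yᵢ − ȳ)²

as the fraction of that variable's variation that influenced movement
(R² = 0: no influence, the mean-predictor baseline; negative values can
occur and are reported as-is). Fitting the model with only GPS-derived,
only accelerometer-derived, and combined features additionally partitions
the explained variation into family-independent and shared components.

The package is aimed at movement ecologists and precision-livestock
researchers working with grazing herds (the built-in study system is a
small dairy herd on a depleting pasture), but every stage is generic:

* **Preprocessing** — HDOP quality filtering, WGS84→UTM projection, 32 Hz
  accelerometer resampling, gap-aware segmenting and 3 s windowing.
* **Features** — 210 accelerometer features per window (21 geometric
  channels × 10 statistics including DFT descriptors), 27 individual
  trajectory features (speed/turning statistics, a Brownian-motion
  increment-scaling parameter, MSD power-law fit, first-passage-time
  suite) and 11 group-geometry features (neighbour distances and counts,
  elongation, area proxy, direction concentration, periphery index).
* **Activity classification** — a two-stage model (4 main activities,
  then a rumination flag) with hour-blocked splits and a balanced-accuracy
  driven grid search.
* **Hourly dataset** — 548 movement variables per animal-hour,
  standardized per animal × day/night, projected to principal components
  per sensor family, joined to hourly environmental targets.
* **Influence quantification** — ε-insensitive kernel regression or
  random-forest regression, session-held-out scoring, hyperparameter
  search (test-set "paper" mode or nested cross-validated mode), and
  two-set variation partitioning.
* **Synthetic herd** — a seeded simulator (semi-Markov activity bouts,
  herd-cohesive correlated random walks, activity-conditioned 32 Hz
  accelerometer oscillators, depleting grass biomass, a twice-daily
  milking sawtooth, and a behaviourally inert wind process spuriously
  correlated with biomass) so the entire pipeline is testable without
  field data.

See `docs/methods.md` for the full model description and numerical
choices.

## Worked example

Simulate a small herd with full environment–behaviour coupling, build the
hourly dataset, and quantify each environmental variable's influence:

```python
from envtrace import SimConfig, simulate
from envtrace.pipeline import hourly_records_from_sim
from envtrace.influence import quantify

sim = simulate(SimConfig(seed=7, n_cows=3, n_sessions=3, session_hours=24))
records = hourly_records_from_sim(sim)      # 216 animal-hours x 548 variables

for target in ("biomass", "time_since_milking", "wind"):
    p = quantify(records, target, mode="paper")["partition"]
    print(f"{target:>20s}: influence {p['r2_combined']:+.2f} "
          f"(ACC {p['r2_acc']:+.2f}, GPS {p['r2_gps']:+.2f}, "
          f"shared {p['shared']:+.2f})")
```

prints

```
             biomass: influence +0.60 (ACC +0.63, GPS -0.02, shared +0.00)
  time_since_milking: influence +0.32 (ACC +0.27, GPS +0.09, shared +0.04)
                wind: influence -0.71 (ACC -0.67, GPS -0.73, shared -0.69)
```

Read this as: about 60% of the variation in grass biomass and 32% of the
variation in time since milking are traceable in the herd's movement,
carried almost entirely by the accelerometer features (neck movement
during grazing), while the wind-like variable — correlated with biomass
but with no behavioural effect in the simulator — shows no influence
(values at or below the zero baseline mean the model cannot beat
predicting the mean). The shared component is the part of the combined
model's R² explained by both sensor families at once.

A command-line interface mirrors the pipeline (`envtrace simulate`,
`ingest`, `accel-features`, `gps-features`, `train-activity`,
`build-hourly`, `quantify`); run `envtrace --help` for the subcommands.

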