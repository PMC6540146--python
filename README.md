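# neighscale

Scale sensitivity of built-environment / physical-activity associations
across neighbourhood definitions.

## The problem

Studies of how the neighbourhood built environment relates to residents'
physical activity must first decide what "neighbourhood" means. Common
choices — administrative units such as census meshblocks, or road-network
buffers of 500–1500 m around each home — differ in zoning and scale, and
because of the modifiable areal unit problem (MAUP) the choice can decide
whether an association is detected at all. `neighscale` implements the
complete analytical pipeline of such a sensitivity analysis, driven by a
synthetic-city generator so that every stage is testable against known
ground truth:

1. **synthetic_city** — a street network with cul-de-sacs and motorways; a
   meshblock → census area unit → city hierarchy with Poisson dwelling
   counts and residential zoning; walkability-tertile classification and
   selection of contiguous high/low-walkability study neighbourhoods;
   destination points in 8 domains / 31 types; a participant cohort; and
   outcomes simulated from a known log-linear multilevel model.
2. **delineation** — the seven neighbourhood definitions per participant:
   meshblock (MB), study neighbourhood (UN), census area unit (CA) and
   road-network service areas at 500/800/1000/1500 m (B0500–B1500) on the
   pedestrian network (motorways/ramps removed), polygonised by dilating
   the reached street segments.
3. **exposures** — dwelling density (dwellings per residential hectare,
   with area-weighted interpolation of meshblock counts), street
   connectivity (≥3-way intersections per km²) and the neighbourhood
   destination accessibility index (NDAI, 0–31).
4. **accelerometry** — 30-s epoch screening (≥60-min zero runs are
   non-wear, short wear bouts excluded, ≥10-h valid days) and the
   objective outcomes: mean counts/hour and % time in MVPA.
5. **inference** — linear mixed models of log(y+c) with random intercepts
   for city and neighbourhood-in-city (REML), Wald 95% CIs reported as
   percentage change `100·(exp(β)−1)` per unit exposure, the
   likelihood-ratio test of the multilevel structure (50:50
   χ²₁/χ²₂ boundary mixture), adjusted ICCs from null models, and
   marginal/conditional R².
6. **sensitivity** — the 3 exposures × 5 outcomes × 7 definitions model
   grid, its evidence matrix (95% CI excluding zero), per-definition
   consistency counts, and report rendering.

## Model

For participant *i* in study neighbourhood *j* nested in city *k*:

```
log(y_ijk + c) = α + β·x_ijk + γ'z_ijk + u_k + v_jk + ε_ijk
u_k ~ N(0, σ²_city),  v_jk ~ N(0, σ²_nbhd),  ε_ijk ~ N(0, σ²_resid)
```

with exposure *x* measured within one of the seven neighbourhood
definitions and *z* the covariate adjustment set (sex, age, ethnicity,
income, marital status, education, employment, car access, meshblock
deprivation, neighbourhood preference). `100·(exp(β)−1)` is the percent
change in the outcome per unit exposure; ICC = (σ²_city+σ²_nbhd)/total;
R²m = Var(fixed predictor)/total and R²c adds the random-intercept
variances to the numerator.

## Worked example

```python
from neighscale import synthetic_city as sc, delineation as dl
from neighscale import exposures as ex, inference as inf

net = sc.generate_street_network((4480, 4480), 112, culdesac_rate=0.15,
                                 motorway_fraction=0.02, seed=1)
admin, zoning = sc.generate_admin_units(net, 224.0, seed=2)
sc.assign_walkability_and_select(admin, net, n_neigh_per_class=6)
dests = sc.generate_destinations(admin, seed=3)
parts = sc.generate_participants(admin, 300, seed=4)

records, summary = dl.delineate_all(parts, net, admin)
ped = dl.remove_inaccessible_roads(net)
table = ex.exposure_table(records, admin, zoning, ped, dests)

# inject a true effect of dwelling density measured at the 1000-m buffer
wide = table.pivot(index="participant_id", columns="definition",
                   values="dwelling_density")
params = sc.TrueModelParams(beta=0.06, seed=5)
outcomes = sc.outcomes_frame(sc.simulate_outcomes(parts, wide["B1000"].to_dict(), params))
frame = sc.participants_frame(parts, admin).merge(outcomes, on="participant_id")
for d in ("MB", "B1000"):
    sub = table.loc[table.definition == d, ["participant_id", "dwelling_density"]]
    res = inf.fit_lmm(inf.ModelSpec("mean_counts_per_hour", "dwelling_density", d),
                      frame.merge(sub, on="participant_id"))
    print(d, f"{res.pct_change:.2f}% ({res.pct_low:.2f}, {res.pct_high:.2f})",
          res.evidence)
```

prints

```
MB 0.81% (-0.37, 2.00) False
B1000 9.46% (3.66, 15.58) True
```

The same true association (injected at the 1000-m scale) is detected when
the exposure is measured with the 1000-m network buffer but missed at the
meshblock — the MAUP scale effect the package exists to study. The
exposure summary from the same run shows the characteristic patterns:
median dwelling density falls from 13.4 (B0500) to 12.7 (B1500)
dwellings/ha while the presence-based NDAI rises from 0.0 (MB) to 17.3
(B1500).

A command-line interface wraps the pipeline:

```bash
neighscale simulate --config city.yaml --out layers/ --seed 1
neighscale delineate --network layers/network.geojson --admin layers/admin.geojson \
    --participants layers/participants.csv --out delineations/
neighscale run --config study.yaml --out results/ --seed 1
```

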