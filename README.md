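# occutrends

Occupancy-detection trend models for opportunistic biological records,
stratified by cropland cover.

## What this is for

Volunteer recording schemes accumulate millions of verified presence-only
records — what species was seen, where (a 1 km grid cell) and when (a
day).  Because effort is unstructured and absences are never recorded,
raw record counts confound distribution change with recording change.
`occutrends` is for ecologists and biodiversity analysts who want
defensible multi-decade occupancy trends from such data, and in
particular want to compare trends between landscapes with different
cropland cover (a proxy for agricultural intensity).

The pipeline:

1. **records** — standardise records to 1 km / daily precision, build
   visits (unique site × date), infer non-detections of each focal
   species from records of other species in its group (the target-group
   approach), and attach the list-length effort category (1, 2–3, ≥ 4
   species).
2. **stratify** — classify 1 km cells by late-epoch cropland percentage
   into no- (0%), low- (>0–50%) and high-cropland (>50%) regions, after
   excluding cells with >10 percentage-point cropland change between
   epochs or >25% wetland/built-up/other cover.
3. **occmodel** — fit, per species, a hierarchical Bayesian
   occupancy-detection model by MCMC:

       z_it ~ Bernoulli(psi_it)          logit(psi_it) = b_{t, r(i)} + u_i
       y_itv | z_it ~ Bernoulli(p_itv z_it)
       logit(p_itv) = a_t + beta1·[list 2–3] + beta2·[list ≥ 4]

   with a region-specific random-walk prior on the year effects `b_t`,
   site random effects `u_i`, and split-chain Gelman–Rubin (Rhat < 1.1)
   convergence checks on first- and last-year occupancy.
4. **indicators** — per posterior draw: geometric-mean occupancy across
   species, annual growth rates `((f/s)^(1/y) − 1) × 100`, group growth
   as the geometric mean of species multipliers, and high-vs-low effect
   sizes, all summarised by the median and 95% highest-density interval.
5. **synthdata** — a generator of synthetic landscapes, latent occupancy
   dynamics and presence-only records with a full truth ledger, so every
   stage is testable without restricted datasets.

See `docs/methods.md` for the model, priors, sampler and design choices.

## Worked example

Generate a synthetic scenario (12 years, three regions of 30 sites,
8 species declining fastest under high cropland cover) and run the full
pipeline — roughly a minute on one CPU:

```python
import occutrends as ot
from occutrends.pipeline import RunConfig, run

scenario = ot.ScenarioConfig(
    n_sites={"high": 30, "low": 30, "none": 30},
    n_species=8, first_year=2008, last_year=2019,
    growth_pct={"high": -6.0, "low": -2.0, "none": 0.0},
    seed=7,
)
ds = ot.generate_scenario(scenario)

cfg = RunConfig(
    first_year=2008, last_year=2019, seed=17,
    species_subset=[f"sp{k:02d}" for k in range(8)],
    mcmc={"chains": 3, "iterations": 2000, "burnin": 1000, "thin": 3},
)
result = run(cfg, ds.records, ds.cover)
for region, s in result.report["groups"]["synthgroup"]["growth"].items():
    print(f"{region:>5}: {s['median']:+.2f} [{s['hdi_lower']:+.2f}, {s['hdi_upper']:+.2f}] %/yr")
eff = result.report["groups"]["synthgroup"]["effect_size_high_low"]
print(f"high-low effect: {eff['median']:+.2f}, P(<0) = {eff['prob_below_zero']:.2f}")
print("truth:", {r: round(float(g), 2) for r, g in
                 zip(ds.truth.region_names, ds.truth.group_growth())})
```

Output:

```
 high: -8.18 [-10.45, -5.35] %/yr
  low: -2.91 [-4.35, -1.40] %/yr
 none: +0.61 [-0.88, +1.87] %/yr
high-low effect: -5.29, P(<0) = 1.00
truth: {'high': -8.76, 'low': -3.54, 'none': 0.03}
```

Each line is the posterior median and 95% highest-density interval of
the group-level annual occupancy growth rate in one cropland region.
The last line is the ground truth realised by the generator (recomputed
from the latent occupancy states; with 30 sites and 8 species it
fluctuates around the requested −6 / −2 / 0) — the intervals should,
and here do, cover it.  The posterior for the high-minus-low difference
lies entirely below zero: the decline is credibly stronger where
cropland dominates.

The same pipeline is available from the shell:

```bash
occutrends synth --config config.yaml --output data/
occutrends run --records data/records.csv --cover data/cover.csv \
               --config config.yaml --output out/
```

with subcommands `clean`, `stratify`, `fit` and `indicators` for the
individual stages.  `out/report.json` holds the machine-readable report;
draw-level tables land in `out/indicators/`.

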