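# Methods

## The problem

Opportunistic biological records — presence-only observations collected by
volunteer recording schemes — are the only data source with enough spatial
and temporal reach to track invertebrate distributions over decades.  They
come without any survey design: recording effort varies wildly between
sites, years and visits, and a species not being recorded is not evidence
of absence.  `occutrends` implements the standard inferential machinery for
such data — occupancy-detection models on visit-level detection histories —
and stratifies the trend estimates by cropland cover so that declines
inside and outside intensively cropped landscapes can be compared.

## From records to detection histories

Records are standardised to 1 km / single-day precision and restricted to
a study window.  A *visit* is a unique (site, date) pair on which the
taxonomic group was recorded at all.  Non-detections of a focal species are
inferred from visits where other members of its group were recorded (the
target-group approach), and the number of species on a visit (the *list
length*, categorised as 1, 2–3 or ≥ 4) is carried as a proxy for effort.
Names mapped to configured species aggregates are relabelled before any
filtering; duplicates collapse silently but are counted in the cleaning
log.

Sites are classified by their land-cover composition at 1 km resolution in
two epochs.  Cells whose cropland cover changed by more than 10 percentage
points between the epochs, or where wetland, built-up or "other" classes
exceed 25% (evaluated on the late epoch; a flag extends this to both), are
excluded.  The rest are classified on late-epoch cropland cover: 0% →
no-cropland, (0, 50] → low, (50, 100] → high; the boundary values follow
the strict reading of "greater than 50%".

## The model

For species occupancy state `z_it` of site `i` in year `t`:

    z_it ~ Bernoulli(psi_it),   logit(psi_it) = b_{t, r(i)} + u_i

with an independent year-effect trajectory `b_t` per cropland region
`r(i)` and site random effects `u_i ~ N(0, sigma_u^2)`.  Observations on
visit `v`:

    y_itv | z_it ~ Bernoulli(p_itv * z_it)
    logit(p_itv) = a_t + beta1 * [list 2-3] + beta2 * [list >= 4]

A first-order random walk `b_t ~ N(b_{t-1}, sigma_rw^2)` (per region,
anchored by a wide prior on `b_0`) shares information between adjacent
years, so occupancy changes smoothly.

Priors (defaults; all configurable):

| parameter | default prior | notes |
| --- | --- | --- |
| `b_0` | N(0, 10²) | `("logistic", 0, 1)` gives a uniform prior on first-year occupancy — used by conjugate closed-form checks |
| `sigma_rw` | HalfNormal(1) | controls trend smoothness |
| `u_i` | N(0, sigma_u²), sigma_u ~ HalfNormal(2.5) | |
| `a_t` | hierarchical N(mu_a, sigma_a²), mu_a ~ N(0, 10²), sigma_a ~ HalfNormal(2.5) | options: independent `"normal"`, or `"rw"` random walk with its own sd |
| `beta1`, `beta2` | N(0, 10²) | list-length offsets |

The hierarchical default for `a_t` keeps yearly detection effects
partially pooled, which is the convention in occupancy modelling of
recording-scheme data; whether the original analyses used an independent
or random-walk prior on `a_t` is not documented, so all three are exposed.

## Sampling

The posterior is explored by a blocked Metropolis-within-Gibbs sampler
written for this model:

- latent states `z_it` are drawn from their exact full conditional
  (log-odds `logit(psi) + log Pr(no detection | present)`), with
  detections forcing `z = 1`;
- `b` (and `a` under the random-walk option) are updated in even/odd
  column sweeps — given the other parity, components are conditionally
  independent, so whole blocks accept/reject vectorised;
- `u_i` and `a_t` update as vectorised independent Metropolis steps
  (their conditionals factorise across sites / years);
- standard deviations use univariate slice sampling on the log scale;
- `mu_a` has a conjugate Gibbs update.

Proposal scales adapt during burn-in (Robbins–Monro toward 0.44
acceptance) and are frozen afterwards, preserving detailed balance for
the retained draws.  Likelihood evaluations reduce to sufficient
statistics — detection counts per (year, list category) among occupied
site-years, and per-site-year products over visits — so one sweep costs
O(n_visits + n_sites·n_years); a 180-site × 20-year × ~10⁴-visit species
runs three 3000-iteration chains in ~10 s.

Correctness is checked two independent ways: the data-augmented kernel
summed exhaustively over latent configurations must equal the
marginalised kernel on enumerable instances (exact identity), and a
degenerate configuration (one year, no site effects, detection
probability pinned at ~1, logistic prior on `b_0`) must reproduce the
Beta–Bernoulli closed-form posterior.

Retained draws number `chains × floor((iterations − burnin)/thin)`; the
conventional production settings (3 × 32 000, burn-in 30 000, thinning 6)
give 999 draws.  Regional occupancy per draw is the *finite-sample*
occupancy — the fraction of modelled sites in the region with `z_it = 1`
— matching the "proportion of occupied grid cells" definition; computing
it over all classified cells rather than modelled sites is a documented
alternative not taken here.

Convergence is assessed with the split-chain Gelman–Rubin statistic on
first- and last-year regional occupancy (the quantities growth rates
depend on); species with Rhat ≥ 1.1 can be filtered out, but the filter
defaults to off because removing hard-to-estimate (usually rare) species
biases multi-species indicators toward common, robust species.

## Indicators and effect sizes

All derived quantities are computed per posterior draw and summarised
(median, 95% highest-density interval) only at the end.  The group
occupancy indicator is the geometric mean of species occupancy per draw,
region and year.  Annual growth between first-year occupancy `s` and
last-year occupancy `f` over `y = last_year − first_year` annual steps is
`((f/s)^(1/y) − 1) × 100`, the multiplier that compounds `s` to `f`
exactly.  Group growth aggregates species on multipliers `1 + gr/100`
(a literal geometric mean of percentages is undefined for declines);
this makes group growth algebraically identical to the growth rate of
the geometric-mean index, an identity the tests verify to 1e-10.
Zero-occupancy draws (possible with finitely many sites) are floored at
`1/(2·n_sites)` of the region before logs are taken, below the smallest
observable non-zero occupancy.  The high-vs-low effect size is the
draw-wise difference of group growth rates, reported with its posterior
mass below zero.

## The synthetic-data generator

The generator produces a landscape (cover tables whose classification
reproduces requested region counts, plus optional cells violating each
exclusion filter), latent dynamics, and presence-only records, all from a
single seed with byte-identical reproducibility.

Dynamics: the shared region trajectories satisfy `expit(b_{r,t}) = psi0_r
(1 + growth_r/100)^t`; each species gets a logit-scale offset
(sd `species_logit_sd`) and each species × site pair an independent site
effect, and `z` is Bernoulli.  The truth ledger stores `b`, the offsets,
`u`, `z` and everything derivable, so "true" group growth and effect
sizes are recomputed from the realised states — the correct reference for
coverage checks, since the model estimates the finite-sample occupancy of
these sites.

Recording: visit counts per site-year are Poisson (dates unique within a
site-year); each visit draws a list-length category, which sets the
focal-species detection probabilities.  Three features mirror how real
scheme data come about.  First, a visit exists only because records
exist; there are no "empty visits" in real data.  Second, the category is
an effort level and the recorded list realises it: detected focal species
beyond the category's target length go unrecorded (the recorder stopped),
and a pool of background group members (`n_background`, default 40) pads
shorter lists up to the target, so the recomputed list-length covariate
equals the generated one.  Third, recording-scheme groups contain tens to
hundreds of species, so any focal species is a small fraction of each
list; the default per-visit detection probabilities are correspondingly
low, with information accruing over repeat visits.  Setting
`n_background = 0` disables the padding and the cap, producing the
degenerate small-group regime — visits vanish when nothing is detected
and the focal species dominates its own effort covariate — in which
list-length occupancy models visibly attenuate trends; the generator can
produce it deliberately for exactly that demonstration.

What the generator does *not* emulate: recorder spatial bias, detection
heterogeneity beyond the list-length category, taxonomic drift, and
list competition is only partially neutral (the cap binds on a few
percent of single-species lists, making effective detectability drift
slowly with occupancy — variation the detection year effect `a_t`
absorbs only in its region-averaged part).  Passing recovery tests
therefore show the estimator chain is correct under the model's own
assumptions plus mild list-length endogeneity — not that real-data
biases (uneven site selection, phenological effort patterns) are
handled.

Default scenario: 60 sites per region, 20 years, 15 species, initial
occupancy 0.4 everywhere, growth −5 / −2 / 0 %/yr in high / low /
no-cropland, `sigma_u = 0.3`, `species_logit_sd = 0.25`, detection
0.10 / 0.20 / 0.33 for single / short / long lists, 5 visits per
site-year (per-site-year detection ≈ 0.7 at an occupied site).  These
sizes keep a full 15-species recovery (45 chains of 3000 iterations) in
a few minutes while leaving the effect-size posterior clearly resolved.
Because the 15 species share sites, visits and the random-walk
smoothing, their group-level errors are correlated; the group growth
HDI is therefore slightly anti-conservative against the realised truth
of a single replicate, while the high-minus-low effect-size sign is
recovered with essentially full posterior mass across replicates.

## Pipeline conventions

Species are fitted independently, each with a seed derived
deterministically from the master seed and the species name (CRC32-based,
below 2³¹), so results do not depend on fit order.  The `species_subset`
config restricts which species get models while every group record still
builds visits and inferred non-detections — the same separation the
field's standard tooling makes.  Rule-of-thumb data-sufficiency
thresholds (minimum records, sites, years with records) are configurable;
the defaults (10 records, 5 sites, 2 years) are this package's choices
for synthetic-scale data, not published values.

## Numerical notes and limitations

- The HDI is the shortest window over sorted draws containing
  `ceil(mass·n)` of them; at least 20 draws are required.
- `growth_rate` is undefined at `s = 0` (error) and returns −100 at
  `f = 0`; species whose multiplier is non-positive in a draw are dropped
  from that draw's group geometric mean with a log entry.
- Degenerate chains (zero within-chain variance) make the Gelman–Rubin
  statistic undefined; a NaN sentinel is returned and treated as
  non-converged, never silently retained.
- Month-precision records are always dropped, even when the month has a
  single plausible day.
- Partial coastline cells are treated as complete cells.
- The sampler is exact but not gradient-based; for models far larger than
  the scales used here (thousands of sites, hundreds of years) mixing of
  the random-walk year effects would become the bottleneck.
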