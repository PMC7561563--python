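# saprosucc

Succession analysis for saproxylic (dead-wood-dependent) insect
communities sampled with trunk window traps over consecutive years —
for community ecologists studying colonization–extinction dynamics on
ephemeral resources such as experimentally killed aspen high stumps.

The package implements four connected analyses:

1. **Species turnover rates.** For each trap and between-year interval
   (t1, t2), changes in richness are partitioned into gain
   (colonization) and loss (extinction) rates

   ```
   Gp = G / (½ (S_t1 + S_t2)),     Lp = L / (½ (S_t1 + S_t2))
   ```

   where S_t1 and S_t2 are richness at the interval endpoints and G, L
   count *permanent* events: a species is gained in a year only if it
   was absent in all previous study years, and lost only if it is
   absent in all following years. Temporary absences count as neither.

2. **Functional-group trajectory models.** Richness and abundance of
   each group (host-tree specialists/generalists and the trophic guilds
   wood-feeder, fungivore, predator, omnivore/saprophage) are modelled
   with a negative-binomial (NB2) error distribution, gain/loss rates
   with Gaussian errors, with categorical time × environment
   (sun-exposed vs shaded) fixed effects, landscape adjustment, and
   trap-level clustering. The time × environment interaction is tested
   by likelihood ratio; exposed-vs-shaded differences within each
   year/interval are Wald z contrasts. A three-way model (year ×
   environment × specialist/generalist, years 1–2 only) compares the
   early abundance increase of specialists and generalists.

3. **Constrained ordination.** Counts are Hellinger transformed and a
   partial redundancy analysis (RDA) is fitted with year, environment
   and their interaction as predictors, conditioned on landscape.
   Marginal term significance uses Freedman–Lane permutation pseudo-F
   tests; triplot scores use type-II (correlation) scaling.

4. **Variance partitioning.** Explained community variance is
   decomposed among environment, year and fungal diversity into unique
   and shared Ezekiel-adjusted R² fractions by inclusion–exclusion.

A synthetic-data module generates study-shaped datasets (60 traps = 15
per environment per landscape, 4 years, 184 species) from an explicit
colonization–persistence–detection model with known ground truth, so
every stage is testable without field data, including exact/enumerated
expectations for the turnover rates (`true_turnover`).

## Worked example

```python
from saprosucc import (SimulationParams, simulate_study,
                       filter_aspen_associated, turnover_rates,
                       prepare_model_frame, fit_trajectory,
                       interaction_lrt, ModelSpec)

study = simulate_study(SimulationParams.aspen_study(), seed=1)
matrix = filter_aspen_associated(study.community, study.traits)
print(matrix.n_traps, matrix.n_years, matrix.n_species,
      matrix.total_abundance)
# 60 4 184 14882

records = turnover_rates(matrix, study.traits, "all")
frame = prepare_model_frame(records, study.sites, "Gp")
spec = ModelSpec.for_response("Gp")
full = fit_trajectory(frame, spec, interaction=True)
reduced = fit_trajectory(frame, spec, interaction=False)
print(interaction_lrt(full, reduced))
# (69.27395..., 2, 9.065e-16)
```

The simulated community holds 14,882 aspen-associated individuals from
184 species. The likelihood-ratio test compares the gain-rate model
with and without the time × environment interaction: chi² ≈ 69.3 on
2 df (p ≈ 9e-16) — colonization at the sun-exposed stumps is
front-loaded into the first interval while shaded stumps gain species
at a steadier rate, so the temporal pattern differs strongly between
environments.

The same analysis runs from the shell:

```bash
saprosucc simulate --seed 1 --out data/
saprosucc run-all --community data/community.csv --traits data/traits.csv \
    --sites data/sites.csv --seed 1 --out results/
```

which writes `turnover.csv`, one `model_report_<group>.json` per
functional group, `rda_summary.json`, `ordination_scores.csv`,
`varpart.json`, figures and a `run.log`.

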