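# Methods

## Data model

The observational unit is a count of one beetle species in one trunk
window trap in one year of succession. Three tables describe a study:
a long-form community table (trap, year, species, count), a trait table
(host affinity: specialist / generalist / non_aspen; trophic guild:
wood_feeder / fungivore / predator / omnivore_saprophage), and a site
table (environment: exposed / shaded; landscape; fungal diversity, a
small non-negative count of fruit-body morphotypes recorded on the
stump, possibly missing).

Long CSV is canonical because it is unambiguous about sparse zeros: a
missing (trap, year, species) row is an implicit zero *count*, while
every (trap, year) pair of the design is assumed to be an operated
sample. Wide (species-by-sample) matrices are accepted through an
import flag. Calendar years are recoded internally to successional
years 1..T. Duplicate (trap, year, species) keys are an error, never
silently summed, because a duplicate almost always signals a broken
join upstream. Guild membership is single-valued; species not
associated with the host tree are removed before any analysis.

## Turnover rates

Per trap and consecutive-year interval (t1, t2),

    Gp = G / (0.5 (S_t1 + S_t2)),   Lp = L / (0.5 (S_t1 + S_t2)),

with G the number of *permanent* gains (species present at t2 and
absent in all study years before t2) and L the permanent losses
(present at t1, absent in all years after t1). Permanence is assessed
inside the observation window only, so late losses are right-censored:
a species present in the final year can never be counted as lost.
When both endpoint richness values are zero the rates are undefined;
such records are flagged and excluded from model fits rather than
imputed as zero, which would bias sparse early shaded-site intervals
downward. Rates are always computed per trap and never pooled across
traps before modelling.

## Trajectory models

Richness and abundance are overdispersed counts and use an NB2
likelihood (variance μ + μ²/θ); gain and loss rates use Gaussian
errors. Time enters as a categorical factor (years for counts,
intervals for rates), crossed with environment; landscape enters
additively. The scientific question sits in the time × environment
interaction, tested by a likelihood-ratio test between the full model
and the additive reduction (both maximum likelihood; the Gaussian mixed
model is fitted with ML rather than REML for exactly this reason).

Random-effect structure. With only two landscapes a landscape variance
component is weakly identified, so landscape is a fixed covariate
throughout. Gaussian rate models carry a per-trap random intercept
(statsmodels MixedLM); count models use a fixed-effects NB2 maximum
likelihood fit with a cluster-robust (by trap) covariance for Wald
inference — the same target cell means as a trap-intercept mixed NB
model, for which no maintained Python implementation exists. If the NB
dispersion is not identified (near-equidispersed data) the fit falls
back to a Poisson GLM, and a degenerate mixed fit falls back to OLS
with cluster-robust covariance; every fallback is recorded on the
result object and in the pipeline log.

Cell predictions are computed on the link scale at the observed
landscape mix and back-transformed, with delta-method 95% intervals.
Within-time exposed-vs-shaded contrasts are unadjusted two-sided Wald z
tests (a Holm option exists but is off by default, since per-time
comparisons are conventionally reported unadjusted). The
specialist-vs-generalist comparison restricts to years 1–2, adds
functional group as a third crossed factor, reports the single-df
three-way Wald test and each group's predicted year-2/year-1 abundance
ratio per environment.

Residual diagnostics return residuals ordered by time within trap and a
lag-1 autocorrelation summary. The headline statistic is the *pooled*
correlation over all within-trap consecutive residual pairs: per-trap
correlations from series of length 4 carry a small-sample bias of order
−1/(T−1) that swamps the signal, whereas the pooled statistic is
centred at zero for white noise. Measured power note: for the
reference alternative used in the unit tests (exposed cell means
2→8→8→8 vs shaded 2→4→6→8, NB2 θ=5, 30 traps per environment) the
interaction LRT has ≈85% power at α = 0.05.

## Ordination

Counts are Hellinger transformed (square root of row-relative
abundance; zero rows stay zero) so that the Euclidean geometry implicit
in RDA respects relative composition. Partial RDA: the community
matrix is centred column-wise; response and term design are
residualized on the conditioning design (landscape plus intercept) by
orthonormal-basis projection; the SVD of the fitted values of the
residualized regression yields the constrained axes, with eigenvalues
on the sums-of-squares/(n−1) scale. Constrained plus unconstrained
eigenvalues reproduce the residualized total variance to 1e−8
(asserted against a brute-force projection-matrix oracle and against
the reference R implementation in the test suite).

Marginal permutation tests use the pseudo-F
(SS_term/df_term)/(SS_resid/df_resid), where SS_term is the drop in
constrained SS when the term leaves the full model (the interaction is
therefore tested in the presence of both main effects). The null
distribution is Freedman–Lane: residuals of the reduced model
(condition + remaining terms) are permuted as whole rows, the reduced
fit is added back, and the statistic recomputed; p carries the +1
correction. Rows (trap-years) permute freely by default; a `blocks`
argument restricts permutation within groups for repeated-measures
designs. Measured level: ≈0.046 at nominal 0.05 over 1000 null
replicates.

Scores use type-II (correlation) scaling: species scores are right
singular vectors weighted by sqrt(λ_i / total variance), site scores
are data projections standardized to unit variance per axis, both
multiplied/divided by the conventional display constant
((n−1)·total)^¼ so magnitudes match standard triplot output; centroids
are mean site scores per factor level, computed on the original levels
so they are invariant to dummy coding. Species with |score| > 0.2 on
either of the first two axes are flagged for labelling (threshold
configurable). Eigenvalues below 1e−10 × total variance are dropped.

Treatment (first-level reference) coding is used internally; designs
that are rank deficient *on their own* raise an error naming the
aliased columns, while overlap with the conditioning design is allowed
and simply projected out (conditioning away all terms legitimately
yields R² = 0).

## Variance partitioning

RDAs are fitted (no conditioning) for the 7 non-empty subsets of
{environment, year, fungal diversity}, each R² adjusted with the
Ezekiel formula 1 − (1−R²)(n−1)/(n−m−1) with m the design rank, and
unique/shared fractions obtained by inclusion–exclusion. Fungal
diversity is a single numeric covariate (df = 1). Shared fractions of
adjusted R² can be negative; they are reported as computed and only
truncated at zero when the Venn figure is drawn. Rows missing fungal
diversity are dropped with a recorded count. Landscape is not a
partitioning predictor. The percent report rounds to the nearest 1%.

## Synthetic studies

The generator emulates a balanced two-landscape design (15 traps per
environment per landscape, 4 years) over 184 species: 17 host-tree
specialists and 167 generalists, split across guilds as 22
wood-feeders, 73 fungivores, 75 predators and 14 omnivores/saprophages.
Mechanism per trap × species: one colonization episode whose arrival
year is drawn from an environment-specific hazard profile, geometric
persistence afterwards, Bernoulli detection each year, and a
zero-truncated NB2 count when detected (so observed presence is exactly
presence-and-detection, which keeps the ground-truth algebra exact).

Default conditions: exposed arrival profiles are front-loaded
(specialists (0.06, 0.45, 0.08, 0.04); generalists
(0.11, 0.16, 0.05, 0.03)) and shaded profiles flat, reproducing the
hypothesis that favourable sun-exposed sites accumulate species early
while shaded sites change gradually; the specialist profiles imply an
early-abundance fold increase several times that of generalists.
Persistence 0.65 (exposed) / 0.75 (shaded), detection 0.55, μ = 1.2,
θ = 1, exposed count multiplier 1.8 — chosen so a study yields on the
order of 10–15 thousand individuals with realistic sparsity (tens of
individuals per trap-year spread over many rare species).

Species are not exchangeable within groups: each species carries a
latent environment preference (log-normal tilt of its colonization
probability toward sun or shade; sd 1.9 for generalists, 1.0 for
specialists), a timing tilt (early vs late colonizer; sd 1.3 / 0.35),
an abundance multiplier (lognormal, mean 1, sd 0.8) and an abundance
year-trend (sd 0.5/yr, centred so expected counts are year-stationary).
These traits, drawn once from the parameter seed, give the community
the species-level structure that ordination and variance partitioning
measure; replicate studies under different run seeds share one species
pool. A latent per-trap fungal resource (lognormal; higher mean at
exposed sites) scales fungivore colonization and drives the observed
fungal-diversity count through a saturating link, coupling the fungal
covariate to composition the way fruit-body surveys covary with
fungivorous beetles.

`true_turnover` computes expected per-trap Gp/Lp per environment ×
interval. Species-level observed-history distributions over the 2^T
presence patterns are enumerated exactly (arrival × persistence ×
detection); the trap-shared fungal resource is integrated by 15-node
Gauss–Hermite quadrature; and the expectation of the per-trap *ratio*
is taken over Monte-Carlo traps assembled from those distributions
(default 200,000), because the mean of a ratio is not the ratio of
means at finite pool size. The estimator's per-trap averages converge
to these expectations (asserted at 500 traps within 3 Monte-Carlo
standard errors).

What the generator does not emulate: spatially structured dispersal,
within-season phenology or multiple trap emptyings, detection
covariance across years, species interactions, and fungal community
dynamics (the resource is static). Consequently, passing tests
demonstrate correct estimation under the stated mechanism, not
robustness to every feature of field data. In particular the
synthetic fungal covariate explains a smaller unique variance fraction
(~1%) than fungal diversity does in real deadwood systems, because the
single static resource axis competes with heavy detection noise.

## Pipeline and reproducibility

The pipeline (library calls or the `saprosucc` CLI) runs filtering →
aggregation → turnover → trajectory models (per group) → three-way
model → ordination (1000 permutations by default) → variance
partitioning, writing CSV/JSON reports, figures regenerable from those
files, and a log that records every fallback that fired. All
randomness flows from a single configured seed through named child
streams, so reruns with the same config are byte-identical.
`scripts/acceptance.py --seed N --out f.json` regenerates the default
study and recomputes the headline quantities end to end.
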