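# Methods

This note documents the models and procedures implemented in `symbiospec`,
the defaults they run with, and the choices made where the design was open.

## The system being modeled

A lichen thallus is one interaction event between a mycobiont (the
lichen-forming fungus) and a cyanobiont (*Nostoc*-type cyanobacterium),
recorded with the forest it was collected in, the fungus' guild
(cyanolichen: the cyanobacterium is the sole photobiont; cephalolichen:
a green alga is primary and the cyanobacterium, held in cephalodia, mainly
fixes nitrogen), and its observed reproductive mode. Cyanobionts are not
identified to species; they are grouped into *phylogroups* — operational
taxa delimited from marker-sequence distances. Specialization of a
mycobiont is then a statement about the set and proportions of phylogroups
it associates with, relative to what the local community offers.

## Phylogroup delimitation

Pairwise distances use the JC69 correction `d = -(3/4) ln(1 - (4/3) p)`
with `p` the mismatch proportion over sites where both sequences carry an
unambiguous base (A/C/G/T); N and gap columns are excluded pairwise. Pairs
at `p >= 3/4` are saturated (the correction diverges): they are flagged,
reported, and excluded from clustering rather than clamped. Distances in
realistic marker data sit far below that boundary.

The clustering threshold is chosen inside a band of 0.001–0.01
substitutions/site. Candidates are all distinct observed distances inside
the band plus the band endpoints; each candidate is scored by the gap to
the next-larger observed distance and the widest gap wins (ties go to the
smaller threshold). This is a deliberately simple stand-in for full
partition-scoring delimitation methods: when within-group divergence is
capped well below between-group divergence (a "barcode gap"), the widest
gap rule finds the separating threshold, and single-linkage clustering
(connected components of the graph with edges `d <= t`) then reproduces the
groups exactly. Maximum-likelihood/Bayesian tree inference and ranked
partition probabilities are out of scope; on data without a clean barcode
gap the method inherits single linkage's chaining behavior, and the
partition count should not be over-interpreted. Labels are assigned
"1", "2", ... by decreasing cluster size (ties by first occurrence) so
outputs are stable across runs.

## Interaction tables and filters

Counts are indexed by (forest, species, phylogroup). Availability `q_f` is
computed from *all* thalli in a forest, including the focal species' own —
the column-marginal convention of the standard d' implementation — and
species that fail the inclusion filters still contribute to `q` because
they are part of the realized community. The inclusion filters default to
at least 10 thalli along the whole gradient (regional) and at least 4 in a
forest (local); both are configurable.

## Specialization metrics

* **Partner richness** — count of phylogroups with at least one record.
* **Simpson's index** `D_i = Σ_j p_{ij}²` on the species' own use
  frequencies; 1 means a single constant partner, `1/richness` is the
  lower bound at even use. It ignores availability.
* **d'** — the standardized Kullback–Leibler divergence of use from
  availability, `d_i = Σ_j p_{ij} ln(p_{ij}/q_j)`, rescaled by scope-level
  bounds to [0, 1]. The default (continuous) bounds are `d_min = 0`
  (use exactly proportional to availability) and
  `d_max = ln(1/min_j q_j)` (all interactions on the rarest available
  partner, the reciprocal-specialization end). A scope with a single
  phylogroup has `d_max = d_min` and scores 0. An alternative
  integer-constrained mode derives `d_min` from the closest integer
  allocation of `n` thalli to `q` (largest-remainder rounding); it
  approximates the discrete-allocation heuristic of the reference
  implementation and can only lower d'. Both conventions are emitted when
  comparing against externally computed values.
* **Chao1** — bias-corrected form `S_obs + F1(F1-1) / (2(F2+1))` from
  singleton/doubleton counts (scikit-bio's estimator); the classical form
  is available. Sampling efficiency is `S_obs / Chao1`.
* **Rarefaction** — the exact hypergeometric expectation
  `E[S_m] = Σ_j [1 - C(N-n_j, m)/C(N, m)]`, with the thallus as the
  sampling unit.
* **Efficiency test** — Welch's two-sample t between observed richness and
  Chao1 estimates with Welch–Satterthwaite df. A paired test would also be
  defensible; the two-sample form is implemented and the choice is
  documented here because the conventions differ in df.

## Beta diversity and turnover scenarios

For two incidence sets with `a` shared and `b`, `c` unique members:
`β_total = (b+c)/(a+b+c)`, `β_repl = 2 min(b,c)/(a+b+c)`,
`β_rich = |b-c|/(a+b+c)`; the additivity `β_total = β_repl + β_rich` is an
identity. Scenarios: no turnover (`b = c = 0`), nested gain/loss
(`min(b,c) = 0 < max(b,c)`), total replacement (`a = 0`, both sides unique),
partial replacement otherwise. Abundances are deliberately not used — the
partition family and the scenario definitions are incidence-based. Because
a species' local partner set is a subset of its regional set,
forest-vs-regional comparisons can only be no-turnover or nested; this
structural fact is asserted in the tests and explains why nested outcomes
dominate cross-scale comparisons. Forest-vs-forest comparisons, where
replacement is possible, are computed as well.

## Composition drivers

Predictor screening removes, iteratively, one member of the worst
correlated pair (|r| above 0.7 by default), dropping the member with the
larger mean absolute correlation to the rest — deterministic and order-free.

RDA regresses the centered forest × phylogroup matrix on centered,
standardized predictors; the constrained proportion is
`trace(Ŷᵀ Ŷ)/trace(YᵀY)`. The community matrix enters as raw counts by
default (a Hellinger transform is available). Variation partitioning
computes Ezekiel-adjusted R² for every nonempty predictor subset and
derives the `2^k - 1` exclusive Venn fractions by Möbius inversion;
negative adjusted fractions are reported as-is so the fractions sum exactly
to the full-model adjusted R². Per-predictor contributions are reported two
ways — the unique fraction alone, and unique plus equal shares of every
overlap — because published summaries of this kind are often ambiguous
about which is meant. The implementation agrees with vegan's `rda()` and
`varpart()` to six decimals on shared test data.

## Mixed models

Each specialization response is modeled with fixed effects (standardized
bio01, bio06, bio14, DBH; reproductive mode; guild) and crossed random
intercepts for forest and mycobiont species:

* richness — Poisson, log link, untransformed counts;
* Simpson — Gaussian on `ln D`;
* d' — Gaussian on `√d'`.

The Gaussian models are fit by REML through statsmodels `MixedLM`, encoding
the two crossed intercepts as variance components under a single trivial
group; if the default optimizer stalls at a variance boundary the fit is
retried with alternative optimizers before being flagged. The Poisson model
is fit by maximum likelihood with a Laplace approximation: for candidate
log-variances the joint penalized log-likelihood is maximized over
(β, u) by damped Newton iteration, the marginal log-likelihood adds
`-½ log det(ZᵀWZ + D⁻¹) - ½ log det D - ½ uᵀD⁻¹u`, and the two
log-variances are optimized by L-BFGS-B from a fixed start (log 0.1), so
fits are reproducible without seeds. Fixed-effect covariances come from the
Schur complement of the joint Hessian. Both families are cross-checked
against lme4 (`lmer`/`glmer`) in the test suite.

Diagnostics: type-III Wald χ² per fixed term (each term's coefficient block
tested with all others retained); Nakagawa R² with
`R²m = σ²_fixed/(σ²_fixed + σ²_random + σ²_resid)` and R²c adding the
random variance to the numerator — for the Poisson log link the residual
variance uses the lognormal approximation `ln(1 + 1/λ̄)` with λ̄ evaluated
at the mean fixed linear predictor plus half the random variance; VIF per
covariate; and Moran's I with inverse-great-circle-distance weights,
`E[I] = -1/(n-1)` and the normal-approximation variance. Rows sharing a
forest share coordinates, so residuals are averaged per location before
Moran's I (inverse-distance weights are undefined at zero distance). The
post-hoc comparison for categorical terms uses pairwise Wald z-tests with
Holm correction; with a two-level guild factor this is the single contrast
a Tukey test would report.

## Ranges

Distributional range is the maximum pairwise great-circle distance
(haversine, 6371 km sphere) among occupied forests — on a quasi-linear
latitudinal transect this equals the endpoint distance; along-transect
cumulative distance is not used. The partner-limitation screen flags a
species when its range matches its partners' maximum range within 5%, it
uses at most 2 partners, no partner ranges more broadly, and the binding
partner is itself restricted (below 75% of the sampled gradient span —
a gradient-wide partner cannot cap a distribution). These are heuristics
for case-by-case follow-up, exposed as parameters, not tests.

## Synthetic community generator

The generator emulates the sampling design the analysis assumes: 11 forests
evenly spaced over latitudes 38.63–54.96°S; mean annual temperature (bio01)
declining with latitude (25 + 0.35·lat, noise sd 0.5 °C) with correlated
but screenable covariates (bio06 = bio01 − 8 ± 2.5; bio14 with a weak
latitudinal trend ± 6 mm; DBH independent); 60 phylogroups whose forest
availability combines a geometric rank-abundance decay with Gaussian niche
filtering on the temperature axis (optima uniform over the realized range,
breadths 1.5–4 °C); 40 mycobiont species with guild (P(cyanolichen) = 0.6),
reproductive mode (sexual/asexual/both/none at 0.40/0.35/0.20/0.05), and a
latent preference vector `w_i ~ Dirichlet(α_i)` with
`log10 α_i ~ U(-1.5, 1)` — α is the single specialist↔generalist knob.
Per-species forest occupancy is Beta-distributed around a mean of 0.5 so
that some species are widespread and some rare enough to fail the regional
filter, as in real community samples; occupied (species, forest) cells get
4–8 thalli whose phylogroups are drawn with probability ∝ `q_f · w_i`.

The geometric decay parameter (0.80) was set once so that each forest is
dominated by a few abundant phylogroups while most stay locally rare — the
qualitative pattern real cyanobiont communities show. A single geometric
parameter cannot simultaneously reproduce a ~37% top share and a 60-group
tail; the compromise favors a clear dominance structure with ~25–35
realized groups per community.

Sequences evolve i.i.d. per site (Jukes–Cantor generative model, no indels,
no rate heterogeneity): phylogroup roots radiate from one ancestor at ~3×
the between-group floor (rejection-checked against the floor), and each
copy mutates at most `⌊p_cap·L/2⌋` sites so that any within-group pair
stays at or below the within-group cap (default 0.004) and any between-group
pair at or above the floor (default 0.02). This guarantees a barcode gap by
construction — which is exactly what makes the generator a usable oracle
for the delimitation stage, and also what passing recovery tests do *not*
show about real data, where within/between divergences can overlap, ambiguous
sites and recombination exist, and delimitation legitimately requires tree
support. Similarly, the generator has no spatial autocorrelation beyond the
latitudinal axis, no vertical transmission, and no abundance differences
between guilds, so null results for those terms in the synthetic mixed
models are expected, not informative.

## Problem sizes and numerical choices

Default analyses run at the sampling scale above (~1,200–1,400 thalli).
The repeated-measure checks use reduced communities (4–5 forests, 6–8
phylogroups, 6–8 species) for delimitation recovery over 100 seeds, and
direct model simulation at n = 120 (Gaussian, variance scale: species 0.04,
forest ~0, residual 0.02) and n = 500 (Poisson, guild effect 0.3, species
variance 0.1) for coverage over 100 replicates each.

Tolerances: saturation boundary at p = 0.75 exactly; barcode-gap ties break
to the smaller threshold; variance components bounded in
log-space at [-12, 5] (≈ 6e-6 to 150); Newton inner loop to gradient
1e-9 with step halving; linear predictors clipped at ±30 on the log link.
Degenerate inputs (single-phylogroup scopes, empty comparisons, constant
columns, rank-deficient predictors, all-zero pools) raise explicit errors
or return documented limits (d' = 0) rather than NaN.

## Known limitations

* Single-linkage threshold clustering is not a substitute for
  tree-supported delimitation when divergence bands overlap; the number of
  phylogroups found on real data will depend on the band and the gap
  structure.
* The d' bounds follow the continuous convention by default; values are
  comparable across this package's runs but can differ in the second
  decimal from discrete-allocation implementations (the integer mode
  narrows that difference).
* The Poisson Laplace approximation shares lme4's known small-cluster
  biases; with very few levels per random factor, variance estimates are
  noisy and frequently hit the zero boundary.
* Variation partitioning fractions are adjusted R² differences and can be
  negative; they are not clamped.
* Moran's I aggregates residuals per forest, so it tests between-forest
  autocorrelation only.
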