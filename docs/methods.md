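# Methods

## Scope and data model

The analysis operates on three tables: an islands × species matrix of
non-negative integer counts (presence = count > 0), an island attribute
table (area in ha; DNI, distance to nearest island, and DM, distance to
mainland, in m), and an optional species × 8 trait table. The unit of
analysis downstream is the unordered island pair: with n islands there
are n(n−1)/2 pairs, each carrying the responses |ΔS| (richness
variation), β_J and β_RC, and the predictors |Δlog₁₀ area|, |ΔDNI|,
|ΔDM|.

Two reductions of island attributes to pair level are plausible —
absolute differences or pair means. Differences are the default because
they make a positive area coefficient on a dissimilarity directly
interpretable ("pairs that differ more in area are more dissimilar");
means are available via `build_pair_table(..., reduction="mean")`.

Islands are classified by three fixed thresholds (area 1 ha, DNI 50 m,
DM 2,000 m); a boundary value falls in the small / clumped / near class
(strictly greater goes to large / isolated / far).

## The Raup–Crick null model

The null model holds each island's richness at its observed value and
draws species from the pool — every species with positive total count in
the analysed matrix — without replacement, with inclusion probability
proportional to the species' total abundance across the matrix
(`weight_mode="abundance"`; `"occurrence_frequency"` swaps in the number
of occupied islands, the weighting of the classical r1 randomization —
the two conventions coexist in the literature, so both are exposed).
For a pair, with SS_obs the observed shared count and SS_null a null
draw,

    beta_RC = 2·[P(SS_null > SS_obs) + ½·P(SS_null = SS_obs)] − 1.

Ties count at weight ½ and the observed configuration is *not* added as
a pseudo-replicate, which keeps the equal-weight case exactly equal to
the hypergeometric closed form. Implementation notes:

- Sequential weighted sampling without replacement is realized by
  exponential sort keys (E_i/w_i, keep the S smallest), vectorized over
  replicates; inside the assembly generator the same keys are used on
  the log scale so that arbitrarily strong niche filters cannot
  underflow.
- One set of island-level null assemblages is drawn per replicate and
  shared by all pairs. Each pair's marginal null distribution is
  unchanged, the matrix is symmetric by construction, and the cost drops
  by a factor of the island count.
- `raup_crick_exact` enumerates subset probabilities (sum over orderings
  of products of conditional weights) for pools of ≤ 10 species and
  convolves the two islands' subset distributions into the exact law of
  SS_null; it is the oracle against which the sampler is tested, and the
  equal-weight case is additionally checked against
  `scipy.stats.hypergeom`.
- An island with zero species makes its pairs undefined (NaN); when both
  islands hold the entire pool every draw ties and β_RC = 0 exactly.
- With 1,000 replicates the Monte-Carlo standard error of a single β_RC
  is at most 2·(½)/√1000 ≈ 0.032.

The pool definition is the analysed matrix itself; per-PFT analyses
re-pool within the type's species subset. External weights (e.g. a
regional abundance survey) can be supplied via `pool_weights`.

## Synthetic landscapes

The generator emulates a fragmented land-bridge island system: areas
log-uniform on (0.25, 50) ha, DNI uniform on (5, 80) m and DM uniform on
(500, 4000) m — ranges chosen so the three binary classifications split
29 islands roughly as a system of 11 large / 18 small, ~10 isolated /
~19 clumped and ~17 far / ~12 near — with a regional pool of 76 species
whose abundances follow a lognormal (σ = 1.5) species-abundance
distribution, and ~1,000 individuals per island on average.

Richness is deterministic given area, S(A) = round(c·A^z) clipped to
[1, 76] with defaults c = 25, z = 0.25 (richness 18–66 across the area
range): the decomposition under study separates a richness channel from
a turnover channel, so the generator controls them independently.
Composition is drawn without replacement with selection weight =
regional abundance × regime factor:

- **stochastic** — factor 1; this *is* the null process (below).
- **shared_filter** — Gaussian kernel exp(−λ(niche − 0.5)²), identical
  on every island (λ = `filter_strength`, default 30 on a [0,1] niche
  axis).
- **divergent_filter** — kernel centred on an island-specific
  environment: the logistic of standardized log₁₀ area plus N(0, 0.5)
  noise, so habitat divergence grows with area contrast.
- **dispersal_limited** — species fail to enter an island's candidate
  pool with probability (1 − e^(−δ·DM))·(0.3 + 0.7·rarity rank),
  δ = `decay_rate` = 5·10⁻⁴ per m. Thinning must touch common species
  too: island-specific absences of high-weight species are what push
  compositions apart relative to the richness-fixed null, whereas
  excluding only rare species makes every island converge on the same
  common set and flips the sign of β_RC.

Filter strength and decay rate are free knobs describing hypothetical
assembly regimes, not estimates of any particular field system.

**Abundance allocation.** Each species' landscape-wide total is
proportional to its regional weight (grand total split by weight, at
least one individual per occurrence, the remainder spread multinomially
over occupied islands). This is deliberate: the null model weights
species by *observed totals*, so the stochastic regime equals the null
process exactly and β_RC is calibrated at 0 by construction. The obvious
alternative — an independent multinomial of ~1,000 individuals on every
island — amplifies the abundance skew by the number of occupied islands
(common species occupy more islands *and* get large counts on each) and
de-calibrates β_RC by +0.3 to +0.6 on otherwise purely stochastic
landscapes. Abundances feed only the null-model weights; all
dissimilarity metrics are presence/absence-based.

**Trait tables.** Species are split evenly among k latent clusters;
centroids are column-centred, balanced to equal spread on every trait,
and scaled so the *minimum* centroid distance is `separation`
within-cluster standard deviations (unit isotropic noise). Balancing
matters: the classifier z-scores traits, and unbalanced centroid spread
makes standardization anisotropic, silently shrinking the realized
separation. With separation 6 the latent partition is recovered by
k-means with adjusted Rand index ≥ 0.96 in a 200-seed survey (an
occasional boundary species can still be misassigned).

**What the generator does not emulate:** spatially explicit geometry,
temporal succession, within-island habitat structure, sampling error in
the census, or trait–niche covariance (traits and assembly niches are
independent). Passing tests on synthetic landscapes demonstrate that the
machinery measures what it claims to measure under known assembly
processes — not that any particular field system behaves like the
defaults.

## GLMs and model selection

"Gaussian GLM with identity link" is ordinary least squares; it is fitted
as such (statsmodels OLS) and reported GLM-style: estimates, SEs, Wald
two-sided p-values, AIC from the Gaussian likelihood, null/residual
deviance. The candidate set is the three pair contrasts, their three
products and the triple product. Backward selection drops, at each step,
the removable term whose deletion most lowers AIC, stopping when no
deletion lowers it; ties break toward the highest-order term, then
lexicographically. By default marginality is respected (an interaction
must leave before its constituents — `hierarchy=False` lifts this).
Selection is greedy: it never worsens the starting AIC, and on simulated
tables with clear signals it matches exhaustive enumeration over all 19
hierarchy-respecting submodels, but a spuriously strong three-way term
can trap the hierarchical chain at the full model.

Per-term "deviance explained" is sequential — terms enter main effects
first, then two-way, then three-way, each block in canonical order; a
term's share is its drop in residual deviance as % of the null deviance,
so shares telescope exactly to the model total. Drop-one shares are
emitted alongside; the two coincide for orthogonal designs.

Pairwise observations are not independent (each island appears in n−1
pairs). The default p-values ignore this, as is common in the pairwise
GLM tradition; `mantel_pvalues` provides an island-label permutation
test (default 999 permutations) that preserves the dependence structure,
and the pipeline manifest carries a standing note about the issue.

## Variation partitioning

With a single response (β_J per pair), RDA-based partitioning
degenerates to linear regression, so the fractions come from three
coefficients of determination: a = R²(x1,x2) − R²(x2) (unique richness
variation), c = R²(x1,x2) − R²(x1) (unique turnover),
b = R²(x1) + R²(x2) − R²(x1,x2) (shared), d = 1 − R²(x1,x2). Raw
fractions sum to 100% identically; adjusted fractions use the Ezekiel
correction 1 − (1−R²)(n−1)/(n−p−1), may be negative, and are reported as
computed (no clamping in the CSVs). Both sets are always written because
published percentages rarely say which convention they use. Strata
(whole system, each binary island class using within-class pairs, each
PFT with re-pooled metrics) need at least 10 defined pairs; smaller
strata are skipped and logged.

## Pipeline and reproducibility

`run_pipeline` executes: data (simulate or load) → richness and island
groups → PFT classification → β metrics (whole community, then per PFT
with re-pooled nulls) → pair tables → stepwise GLM table → variation
partitioning by stratum → group means with t-based 95% CIs. Every
intermediate is a CSV; the manifest records the config hash, seed,
derived stage seeds and dropped-pair counts. Per-stage seeds are
SHA-256(global_seed:stage_name) mod 2³¹, so adding a stage never
perturbs earlier stages' randomness, and identical configurations
reproduce every output byte for byte.

## Problem sizes used in the shipped checks

Oracle agreement uses 4-species equal-weight pools at 100,000 Monte-Carlo
replicates against exact enumeration. Null calibration pools all pairs of
50 independent 29-island stochastic landscapes (20,300 pairs, 1,000 null
reps each): the pair-mean of a *single* landscape has a standard
deviation near 0.1 even under the exact null, because pairs sharing an
island are correlated, so a pooled design is required to resolve a ±0.05
calibration band (pooled SE ≈ 0.011). Regime sign recovery uses 20
landscapes per regime at default strengths; variance-partition regime
recovery uses 20 richness-driven (shared filter, z = 0.25) and 20
turnover-driven (divergent filter, z = 0.05) 20-island landscapes;
stepwise optimality uses 20 simulated 200-pair tables; trait recovery
uses 10 generator seeds. All of it completes in well under a minute.

## Known limitations

- β_RC inherits the usual null-model caveats: it conditions on observed
  richness and observed abundances, so systematic abundance estimation
  errors propagate into the null weights.
- The greedy stepwise path need not reach the global AIC optimum in
  adversarial designs (see above); the exhaustive enumerator used for
  testing is exported (`hierarchical_submodels`) if certainty is needed
  on the 7-term candidate set.
- Naive pairwise inference overstates certainty; use the permutation
  p-values for anything decision-relevant.
- The exact enumeration oracle is factorial and capped at 10-species
  pools by design.
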