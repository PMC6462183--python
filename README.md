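# islandbeta

Tools for decoupling the two components of β-diversity across a
fragmented (land-bridge island) landscape: **richness variation**
(the α-dependent part of pairwise dissimilarity) and **richness-independent
spatial turnover** (species replacement), for whole plant communities and
for trait-based plant functional types (PFTs).

The package is aimed at community ecologists working with site-by-species
count matrices from patchy or insular systems who want to know *whether
fragmentation shapes β-diversity by changing local richness or by driving
species replacement* — and at anyone who needs a well-tested, seedable
implementation of the abundance-weighted, richness-fixed Raup–Crick null
model.

## The statistics

For every unordered island pair *(i, j)*:

- **Jaccard dissimilarity** on presence sets,
  β_J = 1 − |P_i ∩ P_j| / |P_i ∪ P_j| — confounds richness differences and
  replacement.
- **Raup–Crick metric.** A null model draws, for each island, S_obs
  distinct species from the regional pool (all species observed in the
  matrix) without replacement, with probability proportional to each
  species' total observed abundance. With SS_obs the observed shared-species
  count and SS_null its null counterpart,

  β_RC = 2·[ P(SS_null > SS_obs) + ½·P(SS_null = SS_obs) ] − 1 ∈ [−1, 1].

  β_RC ≈ −1: pairs share *more* species than chance (shared environmental
  filters); β_RC ≈ 0: stochastic assembly; β_RC ≈ +1: *fewer* than chance
  (divergent filtering, dispersal limitation). The Monte-Carlo estimator
  (default 1,000 reps) is backed by an exact enumeration oracle for small
  pools and by the hypergeometric closed form in the equal-weight case.
- **Pairwise GLMs.** Gaussian-family (identity link ≡ OLS) models of
  |ΔS|, β_RC and β_J on the pair contrasts |Δlog₁₀ area|, |ΔDNI|, |ΔDM|
  (DNI = distance to nearest island, DM = distance to mainland), their
  two-way and three-way products, with backward stepwise AIC selection and
  per-term % deviance explained.
- **Variation partitioning.** With one response per pair, redundancy
  analysis reduces to regression, so β_J is partitioned through three R²
  values into a (unique to |ΔS|), c (unique to β_RC), b (shared) and
  d (residual); raw fractions sum to 100% exactly, Ezekiel-adjusted
  fractions are reported alongside.
- **Functional types.** k-means (default k = 4) on eight z-scored traits
  (maximal height, leaf area, SLA, leaf thickness, leaf dry-matter content,
  chlorophyll, twig dry-matter content, wood density); all β analyses are
  repeated per PFT with the null model re-pooled within the type.

Because census data of this kind are rarely deposited, the package ships a
first-class synthetic generator (`islandbeta.simulate`) that emulates a
29-island × 76-species fragmented landscape with a deterministic
species–area richness rule S(A) = round(c·A^z) and four assembly regimes
(stochastic, shared filtering, divergent filtering, dispersal limitation)
with known ground truth, plus a matching clustered trait generator.

## Worked example

```python
from islandbeta import (AssemblyConfig, NullModelConfig, assemble_communities,
                        generate_island_attributes, generate_species_pool, richness,
                        jaccard, raup_crick, build_pair_table, backward_stepwise,
                        varpart2)

attrs = generate_island_attributes(n_islands=29, seed=101)
pool = generate_species_pool(n_species=76, seed=102)
community = assemble_communities(pool, attrs, AssemblyConfig(mode="shared_filter", seed=103))
print("richness range:", int(richness(community).min()), "-", int(richness(community).max()))

beta_j = jaccard(community)
beta_rc = raup_crick(community, NullModelConfig(n_reps=1000, seed=104))
pairs = build_pair_table(community, attrs, beta_j, beta_rc)
print("mean beta_J  = %.3f" % pairs["beta_j"].mean())
print("mean beta_RC = %.3f" % pairs["beta_rc"].mean())

vp = varpart2(pairs["beta_j"], pairs["delta_richness"], pairs["beta_rc"])
print("varpart raw fractions (%):", {k: round(v, 1) for k, v in vp.raw.items()})
```

prints

```
richness range: 18 - 64
mean beta_J  = 0.427
mean beta_RC = -0.345
varpart raw fractions (%): {'a': 43.1, 'b': 3.7, 'c': 0.7, 'd': 52.5}
```

Under shared filtering every island applies the same niche filter: the
communities share more species than the null model expects (mean β_RC
−0.345 < 0), and β_J is dominated by richness variation — its unique
fraction a = 43.1% dwarfs the turnover fraction c = 0.7%. A
`divergent_filter` or `dispersal_limited` landscape inverts both signals.

The same analysis runs end to end from a shell, writing every intermediate
table (richness, group classes, β matrices, pair tables, stepwise-GLM
table, variance fractions, group summaries) plus a JSON manifest:

```bash
islandbeta run --seed 7 -o results/demo            # synthetic defaults
islandbeta analyze --community counts.csv --attributes attrs.csv \
    --traits traits.csv -o results/field           # your own CSVs
```

Re-running an identical configuration reproduces every output
byte-for-byte.

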