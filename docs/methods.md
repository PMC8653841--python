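# Methods

## The mixture model

For one child ("sink") in one body niche, let `x = (x_1..x_J)` be the ASV
count vector with total `N`, and let `y_1..y_K` be the count vectors of the
K family members sampled in the same household and niche. The sink is
modelled as a multinomial draw from a convex combination of the source
communities plus one latent component:

    x ~ Multinomial(N, sum_{i=1..K} alpha_i * gamma_i + alpha_{K+1} * gamma_{K+1})

where `gamma_i` is member i's (latent) community, observed through
`y_i ~ Multinomial(N_i, gamma_i)`, `gamma_{K+1}` is the *unknown source*
absorbing everything the members cannot explain, and `alpha` lies on the
simplex. `1 - alpha_{K+1}` is the child's family-derived (transmitted)
fraction.

### EM updates

Maximum a posteriori EM on the complete-data likelihood with Dirichlet
(pseudocount) smoothing of the sources:

* E-step: `z_ij = alpha_i gamma_ij / sum_i' alpha_i' gamma_i'j`
* M-step: `alpha_i = sum_j x_j z_ij / N`;
  known sources `gamma_ij ∝ y_ij + c + x_j z_ij` (joint refinement — the
  reattributed sink counts sharpen the source estimates);
  unknown source `gamma_{K+1,j} ∝ u_j + x_j z_{K+1,j} + c·1[x_j > 0]`,

with pseudocount `c = 1` by default. The tracked objective is the
observed-data log posterior (sink multinomial term plus the smoothed source
terms); EM guarantees it is non-decreasing, which the tests assert on every
iteration.

### Anchoring the unknown source

A fully free unknown source has J−1 parameters against J observed sink
cells: it can absorb the sink's multinomial sampling noise, and in
experiments it systematically inflated the unknown proportion by 0.2–0.3
while likelihood-based restart selection preferred exactly those solutions.
The unknown is therefore anchored by a residual pseudo-observation `u`,
computed once before the main EM:

1. fit mixing proportions over the known sources only (EM with fixed
   `gamma = (y_i + c)` normalised), giving fitted sink proportions `m_j`;
2. `u_j = N * max(x_j/N − m_j − sqrt(m_j/N), 0)` — the sink mass the known
   sources cannot explain, minus one standard error of multinomial noise so
   that pure sampling fluctuation does not register as "unknown".

`u` enters the M-step and the objective exactly like an observed source
count vector, making the unknown as rigid as the known sources while the
reattribution term still lets it adapt. With the anchor, the separated-source
benchmark (J=200, K=6, depth 2×10^4) recovers the mixing vector with mean L1
error ≈ 0.06, a sink drawn purely from one source yields that source's
proportion ≥ 0.95, and a sink with no overlap with any source yields an
unknown proportion of ~1.0.

### Initialisation, restarts, convergence

Restart 0 is deterministic: uniform `alpha`, smoothed empirical known
sources, unknown initialised to the normalised residual (with a 1e-6 uniform
floor so every taxon stays reachable). Further restarts draw `alpha` from a
flat Dirichlet and blend the residual with Dirichlet noise (80/20). The best
final objective wins; ties go to the lowest restart index. Convergence is a
relative objective change below 1e-6 (default) or 1000 iterations;
non-convergence is logged, not fatal. All restart seeds derive from the
master seed by counter, so runs are exactly reproducible.

Degenerate inputs: an all-zero sink is an error; a known source with zero
total counts is smoothed to the uniform distribution and logged. At the
final E-step the per-ASV attribution `a_ij = x_j z_ij` is computed with the
unknown row defined as the exact remainder, so `sum_i a_ij = x_j` holds to
the last bit.

## Transmission ratios and the transmissible set

Per household `h`, niche `b`, and taxon group `g` (ASVs collapsed to a
taxonomic rank, family by default):

    TR(h, b, g) = sum_{children of h} sum_{j in g} sum_{i known} a_ij
                  / sum_{children of h} sum_{j in g} x_j

TR is undefined — not zero — when the household's children carry no counts
of the taxon. The cohort-level TR of a taxon is the unweighted mean over
households where it is defined; an abundance-weighted mean is available.

A taxon is classified *putative familial transmissible* in a niche when its
cohort TR exceeds epsilon = 0.05; the common set intersects the per-niche
sets. The epsilon is not cosmetic: pseudocount smoothing gives every
sink-supported taxon a strictly positive known-source attribution of order
`c·J/N` relative to the unknown density — around 1e-2 at the default depth
(7,115 reads) and table width (300 ASVs) — so a literal "TR > 0" rule would
classify nearly every detected taxon as transmissible. 0.05 sits well above
the leakage floor and well below the TR of genuinely member-derived taxa
(≈0.9 in the synthetic cohort); the full TR tables are emitted so any other
threshold can be applied downstream. Because detection and transmissibility
are distinct notions, the classifier also reports the set of taxa merely
detected in children of all niches.

## The synthetic cohort

The generator emulates a three-generation household 16S study: 24
households; roles C, M, F, PGM, PGF, MGM, MGF with the unbalanced design
34/24/24/18/19/15/10 (ten households have two children; which households
carry each grandparent is drawn at random but the totals are exact); three
niches (gut, oral, skin); per-subject covariates (age, sex, diet Y/N flags
for eight foods, an antibiotics flag, daily family-time hours for adults,
eight immune indices on adult clinical scales).

Community construction per niche:

* a heavy-tailed base profile over the member-supported ASVs
  (gamma(0.8) weights, normalised) and a separate environment base over the
  environment-only ASVs;
* household profile ~ Dirichlet(30 · base) — the household effect;
* each adult: individual draw ~ Dirichlet(30 · base), blended
  `0.3 · household + 0.7 · individual`, then Dirichlet(200 · blend) for
  within-subject noise. The 30% shared household component is what makes
  households separable (ANOSIM R ≈ 0.4–0.8 on the defaults) while keeping
  members mutually distinguishable enough for source attribution;
* each child: true alpha from the niche template (unknown fractions 0.45 /
  0.39 / 0.23 for gut/oral/skin; known mass mother-heavy, renormalised over
  the roles actually present, tilted by `exp(0.05·(hours − 9))` so members
  who spend more time with the child contribute more), jittered by
  Dirichlet(60 · template); counts drawn multinomially at a log-normal depth
  (median 10^4, sigma 0.3) from the alpha-mixture of the members' *true*
  profiles plus an independent per-child environmental community
  (Dirichlet(50 · env base)) supported only on the environment-only ASVs.

Taxonomy assigns every ASV to one of 30 transmissible or 10 environment-only
synthetic families (present in all three niches), so family-level TR
recovery can be scored exactly. A random rooted binary tree with
exponential(1) branch lengths over all ASVs supports UniFrac.

Planted effects:

* *diet* — 10 ASVs per planted food (meat, vegetables; gut niche) are set to
  a stable baseline relative abundance (1.5e-3) multiplied by the fold size
  (3) in consumers, for adults and children alike. The stable baseline makes
  the Y/N contrast exactly the fold over multinomial noise; leaving the
  taxa on their household-variable baselines drowned a 3-fold effect in
  community dispersion and made the planted screen unusably noisy.
* *immune* — 30 low-abundance-tier gut ASVs are driven in children by
  per-index latent factors `u ~ N(0,1)`: abundance
  `1.2e-3 · exp(0.9·s·u)` with sign `s`, and the child's index value loads
  on the same factor (`lambda = 0.68`) plus independent noise. The loading
  and the abundance scale were calibrated once so the realised Spearman
  correlation at n = 34 children is ≈ 0.6, the planted target.

The same seed yields byte-identical emitted files; every draw comes from one
`numpy` Generator in a fixed order.

What the generator does **not** emulate: sequencing error and chimeras,
taxon-taxon ecological interactions, compositional correlation structure
beyond the mixture itself, strain-level identity (transmission is modelled
at the community level), longitudinal dynamics, and covariate confounding
(diet and household are independent by construction). Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
generative model, not performance on real amplicon data.

## Statistics

* Shannon index in bits (base 2) by default, natural log selectable.
* Bray-Curtis on relative abundances; unweighted UniFrac (scikit-bio) on
  presence/absence over the provided rooted tree.
* ANOSIM implemented directly: R = (mean between − mean within rank) /
  (M/2) on the ranked distances; permutation p with the add-one convention
  (never zero), seeded; an exact mode enumerates all distinct label
  arrangements for small groups. The statistic is cross-checked against
  scikit-bio's implementation in the tests. Pairwise mode runs all group
  pairs. Households with fewer than two samples in a niche are excluded
  from the grouping.
* Kruskal-Wallis per feature with tie correction (scipy), constant features
  skipped and reported; raw p < 0.05 by default, Benjamini-Hochberg by flag.
* Rank-sum comparisons use the exact null when min(n) ≤ 8 without ties,
  otherwise the normal approximation with tie and continuity correction.
* PCoA by double-centering; negative eigenvalues are reported, never
  clipped; explained proportions are relative to the positive spectrum.
* Spearman screens are computed on tie-corrected ranks with the t
  approximation for p; edges filtered at |rho| > 0.3, p < 0.05, "strong"
  flagged at |rho| > 0.5. Constant features/indices are skipped and logged.
* Diet effects: two-sided rank-sum per (taxon, food) on relative abundance,
  antibiotic-exposed subjects excluded first. The rank-sum choice (over a t
  test) is deliberate: abundances are heavily non-normal.
* Picky-eater test: Welch t on the family-derived proportion
  (1 − alpha_unknown), non-consumers minus consumers.
* Family time: similarity = 1 − Bray-Curtis per same-niche child-member
  pair, Spearman against the member's hours/day; zero-variance hours yield
  an explicitly undefined (NaN) correlation.

## Pipeline defaults and problem sizes

Rarefaction depth 7,115 without replacement; samples below depth are dropped
and reported. Source tracking runs on rarefied tables by default
(`rarefy_before_tracking: false` switches to raw counts); note that
rarefaction can drop an adult sample entirely, in which case that member's
contribution is — correctly — absorbed by the unknown source, and the
recovery scorer folds the missing member's true share into the unknown
before comparing.

Default run sizes keep a full pipeline under a minute on one CPU: 24
households (~360 samples), 300 ASVs per niche, 10 EM restarts per child and
niche (~100 fits), 999 ANOSIM permutations globally and 199 in pairwise
mode. The recovery benchmarks in the test suite use J=200, K=6 sources at
depth 2×10^4 with 20 replicates, and 100 small instances (J=20, K=3) for the
monotonicity property.

## Known limitations

* Mixing proportions of near-identical sources are weakly identified; their
  sum is stable but the individual split is noisy (the tests assert exactly
  this). Real households with very similar adult microbiomes will show the
  same behaviour.
* The unknown-source anchor subtracts one standard error of sampling noise;
  genuinely tiny unknown contributions (below sampling noise at the given
  depth) are attributed to the known sources.
* TR epsilon (0.05) trades smoothing leakage against sensitivity to weakly
  transmitted taxa; taxa with true transmitted share below 5% of their
  counts are not classified transmissible.
* All association screens are correlational; no causal reading is intended.
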