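# Methods

mycoflow analyzes how fungal communities move between the aboveground
organs of a plant (leaves, flowers, fruit) and the surrounding air.  It
takes a clustered OTU count table with per-sample environment labels
and runs four connected analyses: community statistics (normalization,
diversity, permutation tests), Bayesian source tracking under an
environment-rotation design, a pairwise exchange statistic with a
per-environment conservation index, and ensemble co-occurrence /
mutual-exclusion network inference.  A synthetic-community generator
with known attribution truth makes every stage testable without
sequencing data.

## Source tracking

The sampler estimates, for a sink community, the fraction of its reads
drawn from each named source environment plus an Unknown source.  Each
sink read i carries a latent label `z_i`; the collapsed conditional is

    P(z_i = v | z_-i)  ∝  P(t_i | v) · (n_v^(-i) + β)

with `P(t | v) = (m_vt + α₁) / (m_v· + T α₁)` for a named source with
fixed training counts m, and
`P(t | Unknown) = (u_t + a₂) / (u· + T a₂)` for the Unknown source,
whose taxon counts u are the sink reads currently assigned to it.
Mixing proportions are posterior means of `n_v / n` over retained draws
and restarts.

**Hyperparameters** (defaults): α₁ = 0.001, α₂ = 0.1, β = 10, burn-in
100 sweeps, 10 draws at delay 10, 10 restarts, sources and sink
rarefied to 1,000 reads.  The Unknown prior count per taxon is
`a₂ = α₂ · n` where n is the sink read count (`unknown_prior_scale=
"reads"`).  This scaling matters: with an unscaled prior
(`unknown_prior_scale=1`) the Unknown distribution is free to refit the
sink to itself and becomes a self-reinforcing attractor — on data whose
true Unknown fraction is below 0.08 it absorbed roughly half the
community in our measurements.  With depth scaling the Unknown stays
close to uniform over taxa unless reads genuinely unexplained by every
named source accumulate, matching the behavior of the standard tool for
this analysis.

**Rotation design.**  `rotation_runs` makes every environment the sink
in turn; the remaining environments are pooled (counts summed per
environment, then rarefied) as sources, each sink sample is estimated
separately, and per-sink proportion vectors are averaged (arithmetic
mean; median optional) into the sink's attribution row.  Sink pooling
before estimation is available (`pool_sinks=True`).  The sampler's
inner sweep is numba-compiled; a fixed seed gives bit-identical output.

## Exchange statistic and conservation index

From an attribution matrix f (rows = sinks, columns = sources +
Unknown), the round-trip exchange fraction for an unordered pair is
`z(A,B) = f[A][B] · f[B][A]`, and an environment's conservation index is
`Σ_B z(E,B)` over its named partners (Unknown has no reciprocal row and
is excluded).  Computation is at full precision; percentages are
rounded only for display (one decimal by default; a mixed style
rounding values ≥ 10% to integers is available).  Published conservation
sums for fruit/leaf/flower derive from unrounded tool output and are
reproducible from a rounded table only to about half a percentage
point; the package documents rather than hides this.  z is a product of
two estimates — no claim is made that true round-trip movement of taxa
is identifiable from it.

## Community statistics

Rarefaction is classical without-replacement subsampling (multivariate
hypergeometric) to 1,000 reads by default; shallower samples are
dropped and logged.  CSS divides each sample's counts by the sum of its
counts up to a quantile of its nonzero count distribution (inclusive
linear interpolation; default 0.5) times 1,000; adaptive mode walks a
0.05 grid and stops when the median scale factor changes by < 10%.
Shannon entropy uses log base 2 (configurable).  Bray-Curtis distances,
classical PCoA (no negative-eigenvalue correction; negatives reported),
ANOSIM with `R = (r̄_between − r̄_within)/(M/2)` on mid-ranks,
Kruskal-Wallis with tie correction, and the Welch-statistic permutation
t test all follow the standard definitions; permutation p-values use
the add-one convention `(b+1)/(B+1)` with 999 permutations by default
and Benjamini-Hochberg correction across taxa.  A subtlety worth
knowing: at very small n the permutation floor is not `1/(B+1)` —
unrestricted label permutation regenerates the original split with
probability `2/C(n, n_a)` (0.1 at n = 3+3), and enumeration, not the
add-one floor, gives the attainable minimum.

## Ensemble association network

OTUs present in fewer than 20 samples are removed first.  Five measures
score every remaining pair: Spearman and Pearson on the value rows,
Bray-Curtis and symmetrized Kullback-Leibler divergence on per-sample
relative abundances (KLD rows renormalized to distributions across
samples with pseudocount 1e-6), and mutual information on
equal-frequency-discretized rows.  MI uses `⌊n^(1/3)⌋` bins with the
Miller-Madow correction `(K_x−1)(K_y−1)/(2n ln 2)` subtracted, left
unclipped: square-root bin growth leaves ~1 sample per joint cell and a
plug-in bias near 0.7 bits at n = 500, so independent rows would never
score near zero, and clipping the corrected estimator at 0 creates a
point mass that distorts null comparisons.

The null shuffles every OTU row independently across samples (marginals
preserved), 100 permutations by default; two-sided p-values use |r| for
correlations and distance from the null mean for dissimilarities and
MI, which also receive their direction there (below the null mean =
co-occurrence).  Candidate edges need p ≤ 0.05 in at least two measures
of one direction; a pair significant in both directions is
contradictory and dropped.  Stability uses 100 bootstrap resamples of
the samples: a measure votes "unstable" when the null expectation lies
inside the central 95% bootstrap interval or the direction flips in
more than 5% of replicates, and an edge is removed when a majority of
its supporting measures vote unstable.  Surviving edges' five p-values
are merged with Brown's method — `X = −2Σ ln p_i`, `E = 2k`,
`Var = 4k + 2Σ_{i<j} cov(−2 ln p_i, −2 ln p_j)` with covariances
estimated from the permutation replicates' empirical p-values, and
`X/c ~ χ²_df` with `c = Var/2E`, `df = 2E²/Var` — then
Benjamini-Hochberg-corrected; edges with q ≤ 0.05 form the final graph.
Components are connected components of the unsigned graph; the global
clustering coefficient is the mean local coefficient with degree-< 2
nodes contributing zero.

## Synthetic communities

The generator emulates a four-environment vineyard survey: air, fruit,
leaf, flower; 300 taxa; 10 samples per environment; fixed depth 2,000
reads (log-normal depths available); Dirichlet-multinomial
overdispersion θ = 0.01 (counts drawn from a Dirichlet with
concentration composition/θ — multinomial alone understates replicate
variance); base compositions from a symmetric Dirichlet with
concentration 0.05 per taxon (a few dominant taxa, long rare tail).
Twenty percent of the taxon axis is reserved as four disjoint blocks,
one exogenous "Unknown" pool per environment, so the Unknown fraction
is identifiable.  Time points and vineyards are assigned as
exchangeable replicate structure (no trend).

**Why the recovery layout designates one sink.**  The published
attribution table cannot be taken as *simultaneous* generative truth
for a single closed system of four communities.  Two constructions fail
for different reasons.  (1) Mixing independent base compositions — each
environment a convex combination of the *other* environments' bases —
makes the truth unrecoverable by rotation, because the tracker's
sources are the observed samples, which contain none of their own base
signal: explaining air's 0.54 fruit-base content from fruit samples
containing zero fruit base is infeasible on the simplex.  (2) The
self-consistent fixed point `Φ = MΦ + diag(u)Ψ` makes the truth hold
exactly for all rows at once, but with the table's strong coupling and
small Unknown fractions all four compositions converge to near-identity
(pairwise correlations above 0.99), and no estimator can identify
weights on near-collinear sources.  The well-posed design — standard in
source-tracking simulation studies — generates one designated sink
environment from its mixing row while the other environments are drawn
from their own distinct bases and act as pure sources
(`make_paper_like_model(sink_env=...)`); the full matrix is assembled
from the four sink-designated datasets.  The closed-system variant
(`sink_env=None`) is kept for completeness and documented as
non-identifiable.  Printed attribution rows summing to 1.01 (rounding)
are renormalized to exact simplex rows for generation.

The planted-network generator uses a Gaussian copula: planted pairs
share a latent factor with correlation ±0.8, log-abundances are
exponentiated into compositions, and counts drawn multinomially, so
detected associations must survive compositional noise.

**What the generator does not emulate:** seasonal succession or any
temporal trend, spatial structure between vineyards, taxonomy beyond
placeholder lineages, chimeras/contamination, and any read-level
process (the pipeline starts from an OTU table).  Passing tests
demonstrate correctness of the estimators under the stated generative
assumptions, not performance on real phyllosphere data.

## Numerical and design choices

- Permutation p-values: add-one convention everywhere; ties count as
  extreme (conservative).
- "Present" means count ≥ 1; prevalence and abundance thresholds are
  inclusive at the boundary.
- Brown's merge clamps p = 0 inputs to 1/(B+1) and floors the estimated
  variance at a small positive value; k = 1 returns the input p.
- Attribution rows are validated to sum to 1 within 1e-6, with printed
  rounded tables (off by up to 0.05) accepted with a warning so a
  hand-written percent table can be loaded.
- Degenerate inputs: all-zero samples are rejected at construction
  (flagged when produced by OTU filtering); constant rows score 0 with
  p = 1 under correlations; identical groups give H = 0, p = 1.
- The CLI expands one global seed into per-stage substreams via
  `SeedSequence([seed, stage_index])`, so stages re-run independently
  yet reproducibly.
- Test problem sizes (e.g. 500-replicate calibrations, 20-seed network
  recovery, depth-2,000 recovery datasets) were chosen so the whole
  suite runs in a couple of minutes on one CPU while keeping Monte
  Carlo error well inside the asserted tolerances.

## Known limitations

- The Gibbs sampler holds source taxon distributions fixed at their
  (rarefied) training counts rather than resampling them; very sparse
  sources therefore push reads toward Unknown.
- The exchange statistic inherits every bias of the attribution
  estimates; its interpretation as "returning" community fraction is
  the definition used here, not an identified flow.
- The ensemble network applies no compositionality correction beyond
  per-sample normalization; strong compositional effects can induce
  spurious negative associations.
- CSS's adaptive quantile rule is an explicit, testable approximation
  of the reference method's stopping statistic, not a reimplementation.
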