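# Methods

This note documents the models implemented in `phylogeodiv`, the choices
made where the underlying procedures admit more than one reasonable
formalization, and what the synthetic-data generator does and does not
emulate.

## Mixed Yule–coalescent delimitation

### Model

An ultrametric gene tree with branch lengths in Myr is decomposed, for a
candidate threshold time T, into internode intervals running from the tips
to the root. Each interval ends at a branching event. Nodes older than T
are events of a diversification process acting on cluster lineages; nodes
younger than T are coalescences inside the cluster subtree hanging from
each lineage that crosses T. Interval i contributes `log r_i − r_i x_i`
with total rate

    r_i = λ_div · n_i^p_div + λ_coal · Σ_j [n_{j,i}(n_{j,i}−1)]^p_coal.

Below T the diversification process runs on the k cluster lineages without
branching (n_i = k); above T, n_i is the number of lineages present and all
coalescent classes have collapsed to single lineages (zero rate). The
exponents p allow sub/super-linear rate scaling and default to being
estimated on larger trees; trees under 8 tips fix both at 1, where the two
rates have nearly closed-form maxima and the exponents are barely
identified.

Two likelihood conventions circulate for the event term: the total interval
rate, and the rate component of the class in which the event occurred. This
package uses the **total rate**. The class-component variant charges every
multi-cluster configuration a per-event classification penalty
(`log` of the event cluster's share of the class rate) that a one-class
model never pays; on data simulated from the mixed model itself it makes
the single-coalescent configuration dominate by tens of log-units, so
cluster structure is never recovered. The total-rate form treats all
threshold positions symmetrically and is the form under which planted
cluster counts are recoverable (see the acceptance suite).

### Maximum-likelihood fit

T is searched over the midpoints between consecutive internal-node depths,
plus the root depth itself. The root-threshold candidate has no
diversification events, and with λ_div free its ML fit coincides with the
single-process null (one coalescent over the whole tree, λ_div = 0), so the
null is nested in the search space and the fitted log-likelihood can never
fall below it. The likelihood-ratio statistic against that null is referred
to χ²(3) (rate, exponent, and threshold of the added process); a fit that
fails the gate is reported as one cluster.

### Bayesian fit and co-assignment

The MCMC samples (threshold position, log λ_div, log λ_coal, p_div,
p_coal) by Metropolis-within-Gibbs. Priors:

* threshold — uniform on threshold **time** over (0, root depth), i.e.
  each discrete candidate carries mass proportional to its internode gap
  width. A uniform prior on the candidate index is available as an option
  but is not the default: on small trees the likelihood barely
  discriminates thresholds, the posterior then reproduces the index prior,
  and co-assignment probabilities become uninformative. The time prior
  expresses that a threshold is a point in time: wide empty spans of the
  tree (typically the stem branch) legitimately carry more of it.
* rates — lognormal, SD 3 on the log scale, after internally rescaling the
  tree to unit root depth so the prior is scale-free.
* exponents — uniform on [0.5, 2].

Cross-threshold moves use independence proposals anchored at each
candidate's ML rates (normal on the log rates, SD 0.6, with the standard
Metropolis–Hastings correction). Without this, the shared rate parameters
act as a pseudo-prior: the chain only accepts thresholds compatible with
rates adapted to the current one and mixes pathologically (acceptance below
0.1, spurious multimodality). Within-threshold moves are tuned random walks
targeting 20–40% acceptance during burn-in.

Post-burn-in samples of the threshold give P(two tips share a cluster); the
partition at probability threshold q ∈ {0.9, 0.8, 0.7} is the connected
components of the graph with edges where P ≥ q (single linkage — the
deterministic reading of "a probability threshold determines the number of
clusters"). Component counts are monotone in q by construction.

Delimitation in the pipeline runs on the gene tree **including the sister
lineage** and counts the clusters that contain focal tips. The deep stem
branch anchors the threshold prior; without it a species with no internal
structure has nowhere to put a one-cluster threshold. Species with fewer
than three haplotypes are recorded as one cluster and flagged.

Defaults follow the study design the package emulates: 250,000 generations,
15,000 burn-in, thresholds 0.9/0.8/0.7. The test and acceptance suites run
12,000-generation chains; on the ≤ 45-tip trees used there the anchored
sampler's acceptance and two-seed agreement (max |ΔP| < 0.1) are reached
well within that length.

## Diversification metrics

* Splitting rate r = ln(N)/t: the pure-birth rate with zero extinction and
  starting diversity one, applied with the stem age (r_s) and the crown age
  (r_c). Starting diversity one is used for the crown as well — the
  convention adopted by the study design, on the argument that there is no
  a-priori reason to start a species at two phylogeographic units; a
  configurable override restores the crown-starts-at-two convention.
* Lineage loss L = (stem − crown)/stem. Dimensionless, scale-invariant,
  in [0, 1).
* Crown branch-length index N/crown, compared against the stem branch
  length (stem − crown). As printed this compares a rate with a time; the
  dimensionally matched inverse (crown/N) is available via
  `invert_index=True`, and both conventions are exercised in tests.

Only the pure-birth formula is offered: the gene trees involved have too
few nodes and too shallow depths for birth–death ML from branching times.

## PGLS

* C[i, j] = shared root-to-MRCA path length; Pagel's λ multiplies the
  off-diagonals. κ and δ are fixed at 1.
* λ is maximized by ML on [1e-6, 1]: a 5-point coarse grid then bounded
  Brent polish in the bracketing interval. Boundary maxima are reported as
  boundary values.
* Fits whiten with the Cholesky factor of C(λ); β̂, profiled σ², and the
  Gaussian log-likelihood follow. A test cross-checks β̂ against the
  explicit (XᵀV⁻¹X)⁻¹XᵀV⁻¹y route at 1e-10.
* AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k = coefficients + σ² + (λ when
  estimated). The convention is recorded with the fit; ΔAICc comparisons
  are internally consistent under any fixed convention.
* Adjusted R² = 1 − (RSS/(n−k_x))/(TSS/(n−1)) with RSS and TSS computed on
  C(λ)-whitened data, TSS against the intercept-only GLS fit at the same λ,
  k_x = number of regression coefficients. This definition is fixed and
  documented because published adjusted-R² values from comparable software
  are not bit-reproducible without knowing its internal convention.
* Drop-one importance fits the full model on every tree of a tree set,
  selects the tree with the median full-model AICc (lower median for even
  counts), refits each reduced model on that tree, and reports
  ΔAICc = AICc_dropped − AICc_full (important when > 2) plus AICc weights
  over the compared set. No model averaging.
* Randomization nulls: the response's family (lognormal; normal for
  lineage loss) is moment-matched — on the log scale for the lognormal —
  and truncated to the empirical [min, max] (to [0, 1] for lineage loss);
  100 replicate responses are drawn by rejection sampling, each refit by
  univariate PGLS, and p = fraction of replicate adjusted R² ≥ the
  empirical value. Ties count against significance; p < 0.05 rejects the
  null. Square-root transforms are applied to cluster counts, ages, range
  sizes, migratory distances, hand-wing indices, and sample sizes before
  modeling (variance stabilization of right-skewed non-negative
  variables).

## Trait and environmental predictors

* Hand-wing index 100·(WL − SL)/SL; species value = mean over specimens
  (specimen-level values are also emitted, since either convention may be
  wanted).
* Modified Melton index (elev_max − elev_min)/log(range size): natural log
  by default, base-10 as an option; "log-converted" does not pin the base.
* Migratory distance |breeding − wintering| latitudinal midpoints, zero for
  sedentary species; degree→km at 111.32 km/°.
* Occurrence filtering keeps checklists with duration < 6 h and distance
  < 5 km (strict inequalities; a 6-hour checklist is excluded), drops
  duplicate coordinates, subsamples to ≤ 1000 records (seeded), and thins
  greedily in seeded-shuffle order until no retained pair lies within 1 km
  great-circle distance (haversine, R = 6371 km). Greedy thinning matches
  GIS practice; exact maximum retention is NP-hard and not attempted.
* Niche breadth = q(0.975) − q(0.025) per layer (central 95% interval;
  the 0.95/0.05 reading is a switch), linear-interpolation quantiles.
* Climatic stability = per-cell current − past difference per layer;
  species values are means over filtered records.
* PCA standardizes columns (mixed units make the correlation matrix the
  only defensible choice), eigendecomposes it, retains eigenvalues > 1
  (Kaiser), and makes each component's largest-magnitude loading positive.
  Retention is flagged unstable when any eigenvalue is within 0.05 of 1.

## Maps

Grids are lon/lat rasters with half-open cells and row 0 at the south edge;
cell membership is by cell-center test. Per-pixel statistics over the
species present in a cell: sum, mean, population SD (0 for one species),
richness; empty cells are missing. Sampling polygons are bounding boxes of
the sampled coordinates clipped to the presence grid; proportion sampled is
area-weighted with cosine-latitude cell areas on geographic grids (planar
weights for synthetic grids). A block-mean aggregation factor is exposed
for coarse-graining maps against range-map uncertainty; the target cell
size is configurable because the original aggregation scale is ambiguous.

## Synthetic data

The generator produces what the pipeline consumes, with ground truth:

* Backbone: forward Yule tree (root age = Σ_{k=2..n} Exp(k·rate)),
  latitudinal midpoints uniform on [0, 60]° absolute by default or
  reflected-Brownian on the tree (real species are phylogenetically
  clumped in latitude; both regimes are exercised).
* Gene trees: the delimitation model run forward. Between-cluster
  divergences form a Yule genealogy conditioned on exactly N lineages at
  the threshold, built backward from T with Exp(j·rate) waits truncated to
  keep the crown below the stem age; within-cluster genealogies are
  Kingman coalescents (timescale θ in Myr) conditioned on MRCA < T; a
  sister tip diverges at the stem age. Stem ages in the full study are
  T + Exp(3.07) Myr, reproducing a ~4.1 Myr mean stem age over a 1 Myr
  threshold; the within-species coalescent timescale is a free parameter
  (default 0.1 Myr) because the data being emulated do not pin it.
* Cluster-count gradient: N_true = 1 + Poisson(exp(1.2 − 0.025·|lat|)),
  capped at 17 — mean ≈ 2.7 clusters per species with a tropical excess,
  the regime the pipeline is meant to detect.
* Traits: response = β_lat·|lat| + MVN(0, σ²·C(λ_true)) noise, enabling
  exact recovery tests for PGLS.
* Occurrences: uniform points in rectangular per-species ranges whose
  latitude follows the species midpoint; checklist duration/distance from
  pass/fail mixtures with configured pass rates (defaults 0.8), so filter
  retention has a known expectation. Environmental layers are latitude
  gradients with cell noise; paleo layers differ more at high latitude.
* Morphology: five specimens per species with species-level hand-wing
  index drawn lognormally in [5, 65].

One integer seed fans out to per-species streams keyed by species index
(`default_rng([seed, index])`), so adding species never perturbs earlier
ones; every generator is bit-reproducible under a fixed seed.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: sequence-level noise and gene-tree
estimation error (trees are observed exactly), non-rectangular ranges and
real geographic projections (planar geometry; great-circle distance only
where a km rule applies), eBird review semantics, taxonomic error, and
within-species sampling heterogeneity (every cluster gets the same number
of tips — which also makes per-species sample size a deterministic function
of the true cluster count, so sample size is an artificially strong
predictor in synthetic multivariate importance runs).

## Problem sizes and numerics

The test suite and acceptance script run deliberately scaled studies: 60-
to 100-species batches, 5 tips per cluster, 12,000-generation chains, 200
PGLS recovery replicates at 200 tips, 200-replicate null-test calibration
at 40 tips. These sizes were chosen so each statistical check has enough
replication to be decisive while the whole suite stays convenient to run;
the delimitation-recovery experiment uses a clearly separated regime
(θ = 0.05 Myr against a 1 Myr threshold, between-rate 0.5/Myr over a 5 Myr
stem) because that is the condition under which exact recovery is the
correct expectation. Ultrametricity is enforced at 1e-6 Myr by default
(dated trees round their branch lengths) and 1e-9 for generated trees.

## Known limitations

* The single-threshold model cannot represent per-cluster thresholds or
  finer structure (significant F_ST without deep breaks is invisible).
* ML cluster counts on very small trees lean on the χ²(3) gate, which is
  approximate at those sizes.
* The co-assignment linkage rule (connected components) is a documented
  choice; average linkage is exposed as an alternative reading.
* Truncation bounds for the null families (empirical min/max; [0, 1] for
  lineage loss) are a convention — the procedure being emulated states the
  families but not the bounds.
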