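# phylogeodiv

Comparative phylogeography at the hemisphere scale: does intraspecific
genetic diversity follow a latitudinal gradient, and why?

`phylogeodiv` is a tested, reusable pipeline for the analysis style used to
answer that question in New World birds: delimit phylogeographic clusters on
time-calibrated mitochondrial gene trees with a mixed Yule–coalescent model,
derive per-species diversification metrics from cluster counts and crown/stem
ages, relate those metrics to latitude and species traits with phylogenetic
generalized least squares (PGLS) and randomization null models, and render
per-pixel diversity maps. A synthetic-data generator with known ground truth
replaces the original GenBank/eBird/GIS inputs, so every stage is testable
offline and parameter recovery can be verified exactly.

It is aimed at phylogeographers and macroecologists who want the full chain —
delimitation → metrics → comparative regression → maps — in one place, with
explicit seeds and provenance.

## The models

**Delimitation (GMYC).** A single threshold time T on an ultrametric gene
tree separates between-cluster branching (a Yule-like process on the k
lineages crossing T) from within-cluster branching (an independent Kingman
coalescent per cluster). Working tipward-to-rootward over internode
intervals, each interval i with waiting time x_i contributes

    log r_i − r_i·x_i,   r_i = λ_div·n_i^p_div + λ_coal·Σ_j [n_{j,i}(n_{j,i}−1)]^p_coal

where n_i counts diversification-class lineages and n_{j,i} the lineages of
cluster j. A maximum-likelihood fit searches all internode thresholds with a
likelihood-ratio gate against the single-process null; a Bayesian MCMC over
(threshold, rates, exponents) yields posterior probabilities that two tips
share a cluster, thresholded at 0.9/0.8/0.7 and clustered by connected
components.

**Diversification metrics.** With N delimited clusters and clade age t, the
pure-birth splitting rate is r = ln(N)/t (starting diversity one; applied to
both stem and crown ages). Lineage loss is the standardized stem branch
L = (stem − crown)/stem ∈ [0, 1): long stems indicate pruned diversity.

**Comparative analysis.** PGLS with residual covariance σ²·C(λ), where C
holds shared root-to-MRCA path lengths from a backbone tree and Pagel's λ
scales the off-diagonals; λ is fitted by bounded maximum likelihood (κ = δ
= 1). Models are compared with AICc; drop-one ΔAICc (> 2 = important) and
AICc weights are reported on the tree with the median full-model AICc across
a tree set. Randomization nulls draw 100 replicate responses from truncated
lognormal fits (truncated normal for lineage loss) and count replicates
whose adjusted R² reaches the empirical one (significant when < 5% do).

## Worked example

```python
from phylogeodiv.simulate import simulate_gene_tree
from phylogeodiv.gmyc import bayes_gmyc, clusters_among
from phylogeodiv.treeio import crown_stem_ages
from phylogeodiv.divmetrics import branch_length_comparison

tree, truth = simulate_gene_tree(
    n_clusters_true=4, threshold_time=1.0, stem_age=5.0,
    tips_per_cluster=5, within_timescale=0.05, seed=42,
    between_rate=0.5, species_id="demo",
)
coas = bayes_gmyc(tree, n_generations=12_000, burnin=2_500, seed=1)
n = clusters_among(coas, threshold=0.9, subset=truth.focal_tips)
ages = crown_stem_ages(tree, truth.focal_tips, truth.sister_tips)
m = branch_length_comparison(n, ages.crown_age, ages.stem_age)
print(f"clusters at 0.9 threshold: {n} (truth: {truth.n_clusters_true})")
print(f"crown age: {ages.crown_age:.3f} Myr, stem age: {ages.stem_age:.3f} Myr")
print(f"stem splitting rate: {m.splitting_rate_stem:.3f} /Myr")
print(f"lineage loss: {m.lineage_loss:.3f}")
```

prints

```
clusters at 0.9 threshold: 4 (truth: 4)
crown age: 4.765 Myr, stem age: 5.000 Myr
stem splitting rate: 0.277 /Myr
lineage loss: 0.047
```

The simulated species carries four planted clusters whose coalescences are
all younger than the 1 Myr threshold; the posterior co-assignment matrix at
the 0.9 threshold recovers exactly four. The stem rate ln(4)/5.0 ≈ 0.277
per Myr is the pure-birth rate implied by four clusters over the stem age,
and the near-zero lineage loss says the crown reaches almost to the stem —
little diversity has been pruned along the stem branch.

## Command line

```sh
phylogeodiv all --seed 1 --outdir runs/demo          # full pipeline
phylogeodiv simulate --config run.yaml               # inputs only
phylogeodiv delimit --gens 250000 --burnin 15000 ...
```

`all` writes `species_table.tsv` (per-species cluster counts at each
threshold, ages, metrics, and trait predictors), `pgls_summary.tsv`
(latitude models with λ, adjusted R², AICc, and null-test p per response),
`importance.tsv` (drop-one ΔAICc and AICc weights for the multivariate
structure model on the median-AICc backbone tree), ASCII-grid maps of
per-pixel sum/mean/SD/richness of phylogeographic structure, and a
`manifest.json` with seeds, config hash, and library versions. Column
definitions are in `docs/data_dictionary.md`; the modelling choices are
documented in `docs/methods.md`.

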