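"""Synthetic inputs for the comparative-phylogeography pipeline.

Every input the pipeline consumes — dated intraspecific gene trees with known
cluster structure, a species backbone tree, trait tables with a planted
latitude effect, occurrence records with checklist metadata, and gridded
range/environment layers — can be generated here with known ground truth, so
each downstream stage is testable without external downloads.

The gene-tree generator is the delimitation model run forward: cluster stem
lineages branch under a Yule process above a threshold time T, and each
cluster's tips coalesce under a Kingman coalescent with a much shorter
timescale below T, so every true cluster MRCA is younger than T and every
between-cluster divergence older.  A single integer seed fans out to
independent per-species streams keyed by species index, so enlarging the
species set never perturbs earlier species.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .treeio import node_depths

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_backbone",
    "simulate_gene_tree",
    "simulate_traits",
    "simulate_occurrences_and_ranges",
    "simulate_morphology",
    "simulate_tree_set",
    "simulate_study",
    "write_study",
]

KM_PER_DEGREE = 111.32


class SimulationError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the conditions of the empirical study being emulated
    where those are stated (210 species, ~2.7 clusters per species on
    average, stem ages averaging ~4.1 Myr, 0.1-degree range grids, 19
    climatic layers, about a quarter of species migratory) and otherwise use
    values a comparative phylogeographer would consider realistic.
    """

    n_species: int = 210
    yule_rate_backbone: float = 0.1       # backbone splits / Myr
    threshold_time: float = 1.0           # T, Myr: cluster MRCAs younger than T
    between_cluster_rate: float = 0.8     # Yule rate above T, events / Myr
    within_cluster_ne_time: float = 0.1   # coalescent timescale, Myr
    tips_per_cluster: int = 5
    beta_lat: float = -0.02               # planted trait effect per degree
    trait_sigma2: float = 0.25            # Brownian rate of the trait noise
    pagel_lambda_true: float = 0.5
    grid_extent: tuple[float, float, float, float] = (-120.0, -40.0, -60.0, 60.0)
    cell_size: float = 0.1
    seed: int = 0
    # cluster-count gradient: N_true = 1 + Poisson(exp(c0 + c1 * |lat|))
    cluster_log_intercept: float = 1.2
    cluster_lat_slope: float = -0.025
    stem_overshoot_mean: float = 3.07     # stem = T + Exp(mean), Myr
    lat_mode: str = "uniform"             # or "brownian"
    n_records_per_species: int = 80
    duration_pass_rate: float = 0.8
    distance_pass_rate: float = 0.8
    n_env_layers: int = 19
    migratory_fraction: float = 0.25
    n_specimens: int = 5

    def __post_init__(self) -> None:
        for name in ("yule_rate_backbone", "between_cluster_rate",
                     "within_cluster_ne_time", "threshold_time"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be > 0")
        if not 0.0 <= self.pagel_lambda_true <= 1.0:
            raise SimulationError("pagel_lambda_true must lie in [0, 1]")
        if self.n_species < 3:
            raise SimulationError("n_species must be >= 3")
        if self.cell_size <= 0:
            raise SimulationError("cell_size must be > 0")
        lon0, lon1, lat0, lat1 = self.grid_extent
        if not (lon1 > lon0 and lat1 > lat0):
            raise SimulationError("grid_extent must be (lon0 < lon1, lat0 < lat1)")


@dataclass
class SimTruth:
    """Ground truth recorded for one simulated species' gene tree."""

    species_id: str
    n_clusters_true: int
    crown_age: float
    stem_age: float
    partition: list[frozenset[str]]
    focal_tips: frozenset[str]
    sister_tips: frozenset[str]

    def __post_init__(self) -> None:
        if self.n_clusters_true < 1:
            raise SimulationError("n_clusters_true must be >= 1")
        if self.crown_age > self.stem_age:
            raise SimulationError("crown age must not exceed stem age")


def _species_rng(seed: int, index: int) -> np.random.Generator:
    """Independent stream for species ``index`` under the global ``seed``."""
    return np.random.default_rng([seed, index])


# ---------------------------------------------------------------------------
# tree assembly helpers


class _SimNode:
    __slots__ = ("age", "children", "label")

    def __init__(self, age=0.0, children=None, label=None):
        self.age = age
        self.children = children or []
        self.label = label


def _to_dendropy(root: _SimNode) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True

    def build(simnode: _SimNode, parent_age: float | None) -> dendropy.Node:
        node = dendropy.Node()
        if parent_age is not None:
            node.edge.length = parent_age - simnode.age
        if not simnode.children:
            node.taxon = taxa.new_taxon(label=simnode.label)
        for child in simnode.children:
            node.add_child(build(child, simnode.age))
        return node

    tree.seed_node = build(root, None)
    return tree


# ---------------------------------------------------------------------------
# backbone


def simulate_backbone(
    n_species: int,
    yule_rate: float = 0.1,
    seed: int | None = None,
    lat_mode: str = "uniform",
    lat_range: tuple[float, float] = (0.0, 60.0),
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Ultrametric Yule backbone tree plus per-species latitudinal midpoints.

    The forward pure-birth process starts from one lineage, splits at rate
    ``yule_rate`` per lineage until ``n_species`` lineages exist, then runs an
    additional Exp(n * rate) tail before the present, so the root age is a
    sum of exponentials sum_{k=2..n} Exp(k * rate).  Latitudinal midpoints
    (absolute degrees) are drawn uniformly on ``lat_range`` by default or by
    reflected Brownian motion on the tree.
    """
    if n_species < 3:
        raise SimulationError("n_species must be >= 3")
    if yule_rate <= 0:
        raise SimulationError("yule_rate must be > 0")
    rng = np.random.default_rng(seed)

    root = _SimNode()
    active = [root]
    t = 0.0
    split_times: dict[int, float] = {}
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * yule_rate))
        i = int(rng.integers(0, k))
        parent = active[i]
        split_times[id(parent)] = t
        c1, c2 = _SimNode(), _SimNode()
        parent.children = [c1, c2]
        active[i] = c1
        active.append(c2)
    t_end = t + rng.exponential(1.0 / (n_species * yule_rate))

    labels = [f"sp{i + 1:03d}" for i in range(n_species)]
    order = rng.permutation(n_species)  # random label placement on tips
    for node, lb_idx in zip(active, order):
        node.label = labels[lb_idx]

    def set_ages(node: _SimNode):
        if node.children:
            node.age = t_end - split_times[id(node)]
            for c in node.children:
                set_ages(c)
        else:
            node.age = 0.0

    set_ages(root)
    tree = _to_dendropy(root)

    lo, hi = lat_range
    if lat_mode == "uniform":
        lats = rng.uniform(lo, hi, size=n_species)
        lat_by_label = dict(zip([n.label for n in active], lats))
    elif lat_mode == "brownian":
        lat_by_label = _brownian_latitudes(root, rng, lo, hi)
    else:
        raise SimulationError(f"unknown lat_mode: {lat_mode!r}")

    df = pd.DataFrame({
        "species_id": labels,
        "lat_midpoint": [lat_by_label[lb] for lb in labels],
    })
    return tree, df


def _brownian_latitudes(root, rng, lo, hi):
    mid = (lo + hi) / 2.0
    span = hi - lo
    sigma = span / max(1.0, math.sqrt(root.age)) / 2.0
    values = {}

    def walk(node, value):
        if node.children:
            for c in node.children:
                dt = node.age - c.age
                walk(c, value + rng.normal(0.0, sigma * math.sqrt(max(dt, 0.0))))
        else:
            v = value
            # reflect into [lo, hi]
            while v < lo or v > hi:
                if v < lo:
                    v = 2 * lo - v
                if v > hi:
                    v = 2 * hi - v
            values[node.label] = v

    walk(root, mid)
    return values


# ---------------------------------------------------------------------------
# gene trees


def _truncated_exponential(rng, rate, upper):
    """Draw from Exp(rate) conditioned on being < upper (inverse CDF)."""
    u = rng.random()
    return -math.log1p(-u * (1.0 - math.exp(-rate * upper))) / rate


def _kingman_subtree(rng, n_tips, timescale, labels, max_age, max_tries=1000):
    """Coalescent genealogy of ``n_tips`` tips, conditioned on TMRCA < max_age."""
    for _ in range(max_tries):
        nodes = [_SimNode(age=0.0, label=lb) for lb in labels]
        t = 0.0
        while len(nodes) > 1:
            k = len(nodes)
            t += rng.exponential(timescale / (k * (k - 1) / 2.0))
            i, j = rng.choice(k, size=2, replace=False)
            merged = _SimNode(age=t, children=[nodes[i], nodes[j]])
            nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)]
            nodes.append(merged)
        if nodes[0].age < max_age:
            return nodes[0]
    raise SimulationError(
        f"could not draw a coalescent tree with TMRCA < {max_age} in "
        f"{max_tries} tries (timescale {timescale})"
    )


def simulate_gene_tree(
    n_clusters_true: int,
    threshold_time: float,
    stem_age: float,
    tips_per_cluster: int,
    within_timescale: float,
    seed: int | None = None,
    between_rate: float = 0.8,
    species_id: str = "sp",
) -> tuple[dendropy.Tree, SimTruth]:
    """Forward simulation of the threshold Yule/coalescent gene-tree model.

    Cluster stem lineages follow a Yule genealogy with rate ``between_rate``
    conditioned on exactly N lineages crossing ``threshold_time``: merges are
    laid down backward from the threshold with Exp(j * rate) waits truncated
    to keep the crown below ``stem_age``, so all between-cluster divergences
    are older than the threshold.  Each cluster then receives an independent
    Kingman coalescent genealogy with timescale ``within_timescale``,
    conditioned on its MRCA being younger than the threshold.  A sister tip
    diverging at ``stem_age`` is included so crown and stem ages are both
    recoverable from the tree.
    """
    if not (stem_age > threshold_time > 0):
        raise SimulationError("require stem_age > threshold_time > 0")
    if n_clusters_true < 1:
        raise SimulationError("n_clusters_true must be >= 1")
    if tips_per_cluster < 2:
        raise SimulationError("tips_per_cluster must be >= 2")
    if within_timescale <= 0 or between_rate <= 0:
        raise SimulationError("rates and timescales must be > 0")
    rng = np.random.default_rng(seed)

    # Between-cluster part: a Yule genealogy conditioned on having exactly
    # N lineages at the threshold, built backward from T.  With j lineages
    # the next merge lies Exp(j * rate) further back, truncated so the crown
    # lands below the stem age; merges therefore bunch toward the threshold,
    # as in a supercritical Yule observed at T.
    cluster_slots = [_SimNode() for _ in range(n_clusters_true)]
    if n_clusters_true == 1:
        focal_root = cluster_slots[0]
    else:
        nodes = list(cluster_slots)
        cur_age = threshold_time
        while len(nodes) > 1:
            j = len(nodes)
            budget = stem_age - cur_age
            w = _truncated_exponential(rng, j * between_rate, budget)
            cur_age += w
            i, jj = rng.choice(j, size=2, replace=False)
            merged = _SimNode(age=cur_age, children=[nodes[i], nodes[jj]])
            nodes = [nd for k_, nd in enumerate(nodes) if k_ not in (i, jj)]
            nodes.append(merged)
        focal_root = nodes[0]
    between_tips = cluster_slots

    partition = []
    cluster_roots = []
    for j in range(n_clusters_true):
        labels = [f"{species_id}_c{j + 1}_t{i + 1}" for i in range(tips_per_cluster)]
        sub = _kingman_subtree(rng, tips_per_cluster, within_timescale,
                               labels, threshold_time)
        partition.append(frozenset(labels))
        cluster_roots.append(sub)

    for slot, sub in zip(between_tips, cluster_roots):
        slot.age = sub.age
        slot.children = sub.children
        slot.label = sub.label
    focal = focal_root

    sister_label = f"{species_id}_sister"
    root = _SimNode(age=stem_age,
                    children=[focal, _SimNode(age=0.0, label=sister_label)])
    tree = _to_dendropy(root)

    crown_age = focal.age
    truth = SimTruth(
        species_id=species_id,
        n_clusters_true=n_clusters_true,
        crown_age=float(crown_age),
        stem_age=float(stem_age),
        partition=partition,
        focal_tips=frozenset().union(*partition),
        sister_tips=frozenset({sister_label}),
    )
    return tree, truth


# ---------------------------------------------------------------------------
# traits


def simulate_traits(
    backbone: dendropy.Tree,
    latitudes: pd.DataFrame,
    beta_lat: float,
    pagel_lambda_true: float,
    trait_sigma2: float,
    seed: int | None = None,
    intercept: float = 0.0,
) -> pd.DataFrame:
    """Trait table: response = beta_lat * |lat| + lambda-Brownian noise.

    The noise is multivariate normal with covariance
    ``trait_sigma2 * C(lambda)`` where C is the backbone's shared-path-length
    matrix with Pagel's lambda transform applied, so downstream PGLS fits can
    be checked against the generating ``beta_lat`` and lambda.
    """
    if not 0.0 <= pagel_lambda_true <= 1.0:
        raise SimulationError("pagel_lambda_true must lie in [0, 1]")
    if trait_sigma2 < 0:
        raise SimulationError("trait_sigma2 must be >= 0")
    from .pgls import phylo_covariance, lambda_transform

    rng = np.random.default_rng(seed)
    species = list(latitudes["species_id"])
    cov = phylo_covariance(backbone, species)
    cmat = lambda_transform(cov, pagel_lambda_true)
    lat = np.abs(latitudes["lat_midpoint"].to_numpy(float))
    mean = intercept + beta_lat * lat
    if trait_sigma2 == 0:
        response = mean
    else:
        chol = np.linalg.cholesky(cmat + 1e-12 * np.eye(len(species)))
        response = mean + math.sqrt(trait_sigma2) * (chol @ rng.standard_normal(len(species)))
    return pd.DataFrame({
        "species_id": species,
        "abs_lat_midpoint": lat,
        "response": response,
    })


# ---------------------------------------------------------------------------
# occurrences, ranges, grids


def _grid_axes(config: SimConfig):
    lon0, lon1, lat0, lat1 = config.grid_extent
    ncols = int(round((lon1 - lon0) / config.cell_size))
    nrows = int(round((lat1 - lat0) / config.cell_size))
    return lon0, lat0, ncols, nrows


def simulate_occurrences_and_ranges(
    config: SimConfig,
    latitudes: pd.DataFrame,
) -> dict:
    """Rectangular ranges, occurrence records, and environment grids.

    Each species receives a rectangular breeding range whose latitudinal
    placement follows its latitudinal midpoint; occurrence records fall
    uniformly inside the range with checklist duration (hr) and distance (km)
    drawn from pass/fail mixtures with configured pass rates, so the
    filtering rules downstream have known expected retention.  Environmental
    layers are latitude-gradient grids with cellwise noise; paleo layers
    differ more at high latitudes, emulating stronger glacial change there.
    """
    lon0, lon1, lat0g, lat1g = config.grid_extent
    rng_env = np.random.default_rng([config.seed, 10_000_000])
    _, _, ncols, nrows = _grid_axes(config)

    cell_lats = lat0g + (np.arange(nrows) + 0.5) * config.cell_size
    env_grids: dict[str, np.ndarray] = {}
    past_grids: dict[str, np.ndarray] = {}
    for l in range(config.n_env_layers):
        slope = rng_env.normal(0.0, 1.0)
        base = slope * cell_lats[:, None] / 30.0 + rng_env.normal(
            0.0, 0.3, size=(nrows, ncols))
        env_grids[f"bio{l + 1}"] = base
        shift = rng_env.normal(0.5, 0.2) * (np.abs(cell_lats[:, None]) / 60.0)
        past_grids[f"bio{l + 1}"] = base - shift + rng_env.normal(
            0.0, 0.1, size=(nrows, ncols))

    ranges = []
    records = []
    species = latitudes["species_id"].tolist()
    lats = latitudes["lat_midpoint"].to_numpy(float)
    for i, (sp, lat_mid) in enumerate(zip(species, lats)):
        rng = _species_rng(config.seed, i)
        width = rng.uniform(5.0, 20.0)
        height = rng.uniform(5.0, 15.0)
        center_lat = float(np.clip(lat_mid, lat0g + height / 2, lat1g - height / 2))
        center_lon = rng.uniform(lon0 + width / 2, lon1 - width / 2)
        r_lon0, r_lon1 = center_lon - width / 2, center_lon + width / 2
        r_lat0, r_lat1 = center_lat - height / 2, center_lat + height / 2
        if r_lon1 <= r_lon0 or r_lat1 <= r_lat0:
            raise SimulationError(f"empty range for species {sp}")
        area_km2 = (width * KM_PER_DEGREE) * (
            height * KM_PER_DEGREE * math.cos(math.radians(center_lat)))
        migratory = rng.random() < config.migratory_fraction
        wintering = center_lat - rng.uniform(5.0, 40.0) if migratory else center_lat
        emin = rng.uniform(0.0, 500.0)
        emax = emin + rng.uniform(100.0, 3000.0)
        ranges.append({
            "species_id": sp, "lon_min": r_lon0, "lon_max": r_lon1,
            "lat_min": r_lat0, "lat_max": r_lat1, "range_size_km2": area_km2,
            "elevation_min": emin, "elevation_max": emax,
            "breeding_lat_midpoint": center_lat,
            "wintering_lat_midpoint": wintering,
            "migratory": migratory,
        })

        n = config.n_records_per_species
        rec_lon = rng.uniform(r_lon0, r_lon1, size=n)
        rec_lat = rng.uniform(r_lat0, r_lat1, size=n)
        dur_pass = rng.random(n) < config.duration_pass_rate
        duration = np.where(dur_pass, rng.uniform(0.0, 6.0, n),
                            rng.uniform(6.0, 12.0, n))
        dist_pass = rng.random(n) < config.distance_pass_rate
        distance = np.where(dist_pass, rng.uniform(0.0, 5.0, n),
                            rng.uniform(5.0, 50.0, n))
        rec = pd.DataFrame({
            "species_id": sp, "lat": rec_lat, "lon": rec_lon,
            "duration_hr": duration, "distance_km": distance,
        })
        col = np.clip(((rec_lon - lon0) / config.cell_size).astype(int), 0, ncols - 1)
        row = np.clip(((rec_lat - lat0g) / config.cell_size).astype(int), 0, nrows - 1)
        for name, grid in env_grids.items():
            rec[name] = grid[row, col]
        records.append(rec)

    return {
        "ranges": pd.DataFrame(ranges),
        "records": pd.concat(records, ignore_index=True),
        "env_grids": env_grids,
        "past_grids": past_grids,
    }


def simulate_morphology(config: SimConfig, species: list[str]) -> pd.DataFrame:
    """Specimen-level wing/secondary/tarsus measurements per species."""
    rows = []
    for i, sp in enumerate(species):
        rng = _species_rng(config.seed, 5_000_000 + i)
        hwi_true = float(np.clip(rng.lognormal(math.log(20.0), 0.6), 5.0, 65.0))
        sl = rng.uniform(40.0, 120.0)
        tarsus = rng.uniform(10.0, 40.0)
        for s in range(config.n_specimens):
            sl_s = sl * (1 + rng.normal(0, 0.02))
            wl_s = sl_s * (1 + hwi_true / 100.0) * (1 + rng.normal(0, 0.01))
            rows.append({
                "specimen_id": f"{sp}_m{s + 1}", "species_id": sp,
                "wing_length_mm": max(wl_s, sl_s),
                "secondary_length_mm": sl_s,
                "tarsus_length_mm": tarsus * (1 + rng.normal(0, 0.03)),
            })
    return pd.DataFrame(rows)


def simulate_tree_set(
    n_species: int,
    n_trees: int,
    yule_rate: float = 0.1,
    seed: int | None = None,
) -> list[dendropy.Tree]:
    """Independent Yule backbone trees sharing one species label set.

    Stands in for a posterior sample of backbone trees when exercising the
    100-tree median-AICc machinery.
    """
    sq = np.random.SeedSequence(seed)
    seeds = sq.generate_state(n_trees)
    trees = []
    for s in seeds:
        tr, _ = simulate_backbone(n_species, yule_rate, seed=int(s) % (2**31))
        trees.append(tr)
    return trees


# ---------------------------------------------------------------------------
# whole-study simulation


def simulate_study(config: SimConfig) -> dict:
    """Generate a complete synthetic study with ground truth.

    Per-species true cluster counts follow the planted latitude gradient
    ``N_true = 1 + Poisson(exp(c0 + c1 * |lat|))`` (capped at 17, the largest
    count a species plausibly shows), stem ages are the threshold time plus
    an exponential overshoot, and every species' gene tree is generated by
    :func:`simulate_gene_tree`.
    """
    backbone, lat_df = simulate_backbone(
        config.n_species, config.yule_rate_backbone,
        seed=config.seed, lat_mode=config.lat_mode,
    )
    gene_trees: dict[str, dendropy.Tree] = {}
    truths: dict[str, SimTruth] = {}
    for i, row in lat_df.iterrows():
        sp = row["species_id"]
        rng = _species_rng(config.seed, 1_000_000 + i)
        mu = math.exp(config.cluster_log_intercept
                      + config.cluster_lat_slope * abs(row["lat_midpoint"]))
        n_true = int(min(1 + rng.poisson(mu), 17))
        stem = config.threshold_time + rng.exponential(config.stem_overshoot_mean)
        tree, truth = simulate_gene_tree(
            n_true, config.threshold_time, stem, config.tips_per_cluster,
            config.within_cluster_ne_time,
            seed=int(rng.integers(0, 2**31)),
            between_rate=config.between_cluster_rate,
            species_id=sp,
        )
        gene_trees[sp] = tree
        truths[sp] = truth

    traits = simulate_traits(
        backbone, lat_df, config.beta_lat, config.pagel_lambda_true,
        config.trait_sigma2, seed=np.random.default_rng([config.seed, 2]).integers(2**31),
    )
    geo = simulate_occurrences_and_ranges(config, lat_df)
    morphology = simulate_morphology(config, lat_df["species_id"].tolist())
    return {
        "config": config,
        "backbone": backbone,
        "latitudes": lat_df,
        "gene_trees": gene_trees,
        "truths": truths,
        "traits": traits,
        "morphology": morphology,
        **geo,
    }


def write_study(study: dict, outdir: str | Path) -> None:
    """Write a simulated study to disk as Newick/TSV/ASCII-grid/JSON files."""
    from .geomaps import write_ascii_grid, GridSpec
    from .treeio import write_tree

    out = Path(outdir)
    (out / "gene_trees").mkdir(parents=True, exist_ok=True)
    (out / "grids").mkdir(exist_ok=True)
    write_tree(study["backbone"], str(out / "backbone.nwk"))
    for sp, tree in study["gene_trees"].items():
        write_tree(tree, str(out / "gene_trees" / f"{sp}.nwk"))
    for name in ("latitudes", "traits", "morphology", "ranges", "records"):
        study[name].to_csv(out / f"{name}.tsv", sep="\t", index=False)

    config = study["config"]
    lon0, lat0, ncols, nrows = _grid_axes(config)
    spec = GridSpec(origin_lon=lon0, origin_lat=lat0,
                    cell_size=config.cell_size, ncols=ncols, nrows=nrows)
    for name, grid in study["env_grids"].items():
        write_ascii_grid(grid, spec, out / "grids" / f"current_{name}.asc")
    for name, grid in study["past_grids"].items():
        write_ascii_grid(grid, spec, out / "grids" / f"past_{name}.asc")

    truth_json = {
        sp: {
            "n_clusters_true": t.n_clusters_true,
            "crown_age": t.crown_age,
            "stem_age": t.stem_age,
            "partition": [sorted(b) for b in t.partition],
            "focal_tips": sorted(t.focal_tips),
            "sister_tips": sorted(t.sister_tips),
        }
        for sp, t in study["truths"].items()
    }
    cfg = asdict(config)
    cfg["grid_extent"] = list(cfg["grid_extent"])
    with open(out / "truth.json", "w") as fh:
        json.dump({"config": cfg, "species": truth_json}, fh, indent=1)
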