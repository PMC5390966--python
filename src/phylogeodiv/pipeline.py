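"""End-to-end orchestration: simulate -> delimit -> metrics -> PGLS -> maps.

Each stage is a pure function of its inputs and explicit seeds, so a rerun
with the same configuration is bit-identical.  The pipeline writes TSV
tables, ASCII-grid maps, and a provenance manifest recording the
configuration, seeds, and library versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .divmetrics import metrics_table
from .geomaps import (
    GridSpec,
    GridStack,
    rasterize_range,
    stack_stats,
    write_ascii_grid,
)
from .gmyc import bayes_gmyc, clusters_among
from .pgls import null_model_test, pgls_fit, phylo_covariance, sqrt_transform
from .simulate import SimConfig, simulate_study, write_study
from .treeio import crown_stem_ages

__all__ = ["RunConfig", "run_pipeline", "delimit_species", "species_table",
           "predictor_table", "comparative_analysis",
           "multivariate_importance", "diversity_maps"]

DEFAULT_THRESHOLDS = (0.9, 0.8, 0.7)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending species."""


@dataclass
class RunConfig:
    """Declarative configuration of a full run."""

    sim: SimConfig = field(default_factory=SimConfig)
    generations: int = 250_000
    burnin: int = 15_000
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    reporting_threshold: float = 0.9
    map_cell_size: float = 1.0
    null_replicates: int = 100
    n_backbone_trees: int = 100
    outdir: str = "run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_kwargs = raw.pop("sim", {})
        if "grid_extent" in sim_kwargs:
            sim_kwargs["grid_extent"] = tuple(sim_kwargs["grid_extent"])
        seed = raw.get("seed", 0)
        sim_kwargs.setdefault("seed", seed)
        cfg = cls(sim=SimConfig(**sim_kwargs), **raw)
        return cfg


# ---------------------------------------------------------------------------
# stages


def delimit_species(
    gene_trees: dict,
    focal_tips: dict[str, frozenset],
    generations: int,
    burnin: int,
    seed: int,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Bayesian GMYC cluster counts per species at each threshold.

    Delimitation runs on the full gene tree including the sister lineage
    (the deep stem span anchors the threshold prior, as in the study's
    per-species trees); the cluster count is taken over clusters containing
    focal tips, so the sister never registers as a focal cluster.  Species
    with fewer than 3 haplotypes cannot be fitted and are recorded as a
    single cluster with a flag.
    """
    rows = []
    for i, (sp, tree) in enumerate(sorted(gene_trees.items())):
        focal = focal_tips[sp]
        try:
            if len(focal) < 3:
                counts = {th: 1 for th in thresholds}
                flagged = True
            else:
                coas = bayes_gmyc(tree, n_generations=generations,
                                  burnin=burnin,
                                  seed=int(np.random.default_rng([seed, i])
                                           .integers(2**31)))
                counts = {th: clusters_among(coas, th, focal)
                          for th in thresholds}
                flagged = False
        except Exception as exc:
            raise PipelineError(f"delimitation failed for species {sp}: {exc}") from exc
        row = {"species_id": sp, "n_sequences": len(focal), "flagged": flagged}
        row.update({f"n_clusters_{th}": counts[th] for th in thresholds})
        rows.append(row)
    return pd.DataFrame(rows)


def species_table(
    study: dict,
    delim: pd.DataFrame,
    reporting_threshold: float = 0.9,
    treatment: str = "AOS",
) -> pd.DataFrame:
    """Join ages, cluster counts, and diversification metrics per species."""
    ages = []
    for sp, tree in sorted(study["gene_trees"].items()):
        truth = study["truths"][sp]
        try:
            pair = crown_stem_ages(tree, truth.focal_tips, truth.sister_tips)
        except Exception as exc:
            raise PipelineError(f"age extraction failed for species {sp}: {exc}") from exc
        ages.append({"species_id": sp, "crown_age": pair.crown_age,
                     "stem_age": pair.stem_age,
                     "n_clusters_true": truth.n_clusters_true})
    table = delim.merge(pd.DataFrame(ages), on="species_id")
    table = table.merge(study["latitudes"], on="species_id")
    table.insert(1, "treatment", treatment)
    table["abs_lat_midpoint"] = table["lat_midpoint"].abs()
    table["n_clusters"] = table[f"n_clusters_{reporting_threshold}"]
    table = metrics_table(table)
    return table.merge(predictor_table(study), on="species_id", how="left")


def predictor_table(study: dict) -> pd.DataFrame:
    """Per-species trait/environment predictors from the study inputs.

    Hand-wing index (species mean over specimens), modified Melton
    ruggedness, migratory distance, range size, and the proportion of each
    range covered by the sampled occurrence records (bounding box of up to
    10 filtered records clipped to the range, area-weighted).
    """
    from .traits import (
        filter_occurrences, hand_wing_index_table, melton_index,
        migratory_distance,
    )

    hwi = (hand_wing_index_table(study["morphology"])
           .groupby("species_id")["hand_wing_index"].mean()
           .rename("hand_wing_index"))

    cfg: SimConfig = study["config"]
    lon0, lon1, lat0, lat1 = cfg.grid_extent
    cell = max(cfg.cell_size, 0.5)  # coarse grid is enough for proportions
    spec = GridSpec(origin_lon=lon0, origin_lat=lat0, cell_size=cell,
                    ncols=int(round((lon1 - lon0) / cell)),
                    nrows=int(round((lat1 - lat0) / cell)))
    records = filter_occurrences(study["records"], seed=cfg.seed)

    from .geomaps import sampling_polygon

    rows = []
    for _, r in study["ranges"].iterrows():
        sp = r["species_id"]
        melton = melton_index(r["elevation_max"], r["elevation_min"],
                              r["range_size_km2"])
        mig = migratory_distance(r["breeding_lat_midpoint"],
                                 r["wintering_lat_midpoint"],
                                 sedentary=not r["migratory"])
        pres = rasterize_range((r["lon_min"], r["lon_max"],
                                r["lat_min"], r["lat_max"]), spec)
        rec = records[records["species_id"] == sp].head(10)
        if len(rec) and pres.sum():
            coords = rec[["lat", "lon"]].to_numpy(float)
            _, prop = sampling_polygon(coords, pres, spec)
        else:
            prop = 0.0
        rows.append({"species_id": sp, "melton_index": melton,
                     "migratory_distance_deg": mig,
                     "range_size_km2": r["range_size_km2"],
                     "proportion_range_sampled": prop})
    out = pd.DataFrame(rows).merge(hwi, on="species_id", how="left")
    return out


def comparative_analysis(
    table: pd.DataFrame,
    backbone,
    seed: int,
    null_replicates: int = 100,
) -> dict:
    """PGLS of each phylogeographic metric on absolute latitude.

    Cluster counts and species ages enter square-root converted (variance
    stabilization); each univariate latitude model is accompanied by a
    randomization null (truncated lognormal, truncated normal for lineage
    loss) and the <5% rule.
    """
    species = table["species_id"].tolist()
    cov = phylo_covariance(backbone, species)
    work = sqrt_transform(
        table.copy(),
        ["n_clusters", "crown_age", "stem_age"],
    )
    lat = work["abs_lat_midpoint"].to_numpy(float)
    X = np.column_stack([np.ones(len(work)), lat])

    responses = {
        "phylogeographic_structure": ("n_clusters", "lognormal"),
        "crown_age": ("crown_age", "lognormal"),
        "stem_age": ("stem_age", "lognormal"),
        "splitting_rate_stem": ("splitting_rate_stem", "lognormal"),
        "splitting_rate_crown": ("splitting_rate_crown", "lognormal"),
        "lineage_loss": ("lineage_loss", "normal"),
    }
    out = {}
    for i, (name, (col, family)) in enumerate(responses.items()):
        y = work[col].to_numpy(float)
        if family == "lognormal" and (y <= 0).any():
            y = y + 1e-6  # splitting rates are 0 for single-cluster species
        fit = pgls_fit(y, X, cov=cov, names=["intercept", "abs_lat"])
        null = null_model_test(
            y, lat, cov, n_rep=null_replicates, family=family,
            seed=int(np.random.default_rng([seed, 77, i]).integers(2**31)),
        )
        out[name] = {"fit": fit, "null": null}
    return out


def multivariate_importance(
    table: pd.DataFrame,
    n_trees: int = 100,
    seed: int = 0,
    yule_rate: float = 0.1,
):
    """Drop-one variable importance for the multivariate structure model.

    Response: sqrt cluster count.  Predictors: absolute latitudinal
    midpoint plus sqrt-transformed stem age, range size, migratory
    distance, hand-wing index and sample size, the Melton index, and the
    proportion of range sampled.  The full model is fitted across a set of
    simulated backbone trees (standing in for a posterior tree sample) and
    reported on the median-AICc tree.
    """
    from .pgls import drop_one_importance
    from .simulate import simulate_tree_set

    species = table["species_id"].tolist()
    trees = simulate_tree_set(len(species), n_trees, yule_rate=yule_rate,
                              seed=seed)
    covs = [phylo_covariance(t, species) for t in trees]
    work = sqrt_transform(
        table.copy(),
        ["n_clusters", "stem_age", "range_size_km2",
         "migratory_distance_deg", "hand_wing_index", "n_sequences"],
    )
    y = work["n_clusters"].to_numpy(float)
    names = ["intercept", "abs_lat", "stem_age", "range_size",
             "migratory_distance", "hand_wing_index", "n_sequences",
             "melton_index", "proportion_range_sampled"]
    X = np.column_stack([
        np.ones(len(work)),
        work["abs_lat_midpoint"], work["stem_age"], work["range_size_km2"],
        work["migratory_distance_deg"], work["hand_wing_index"],
        work["n_sequences"], work["melton_index"],
        work["proportion_range_sampled"],
    ])
    return drop_one_importance(y, X, names, covs)


def importance_summary(imp) -> pd.DataFrame:
    rows = [{"predictor": nm, "delta_aicc": d,
             "important": imp.significant[nm],
             "weight_dropped_model": imp.weights[f"drop_{nm}"]}
            for nm, d in imp.delta_aicc.items()]
    return pd.DataFrame(rows)


def comparative_summary(results: dict) -> pd.DataFrame:
    rows = []
    for name, r in results.items():
        fit, null = r["fit"], r["null"]
        rows.append({
            "response": name,
            "beta_abs_lat": fit.params[1],
            "p_abs_lat": fit.pvalues[1],
            "lambda": fit.lam,
            "adj_r2": fit.adj_r2,
            "aicc": fit.aicc,
            "null_p": null.p_value,
            "null_significant": null.significant,
        })
    return pd.DataFrame(rows)


def diversity_maps(
    study: dict,
    table: pd.DataFrame,
    cell_size: float = 1.0,
) -> tuple[dict[str, np.ndarray], GridSpec]:
    """Per-pixel sum/mean/SD/richness maps of phylogeographic structure."""
    cfg: SimConfig = study["config"]
    lon0, lon1, lat0, lat1 = cfg.grid_extent
    spec = GridSpec(
        origin_lon=lon0, origin_lat=lat0, cell_size=cell_size,
        ncols=int(round((lon1 - lon0) / cell_size)),
        nrows=int(round((lat1 - lat0) / cell_size)),
    )
    ranges = study["ranges"].set_index("species_id")
    presence = {}
    for sp in table["species_id"]:
        r = ranges.loc[sp]
        presence[sp] = rasterize_range(
            (r["lon_min"], r["lon_max"], r["lat_min"], r["lat_max"]), spec
        )
    stack = GridStack(spec=spec, presence=presence)
    metric = dict(zip(table["species_id"], table["n_clusters"].astype(float)))
    return stack_stats(stack, metric), spec


# ---------------------------------------------------------------------------
# orchestration


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, write_inputs: bool = False) -> dict:
    """Run every stage and write tables, maps, and a provenance manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    study = simulate_study(cfg.sim)
    if write_inputs:
        write_study(study, out / "inputs")

    focal = {sp: t.focal_tips for sp, t in study["truths"].items()}
    delim = delimit_species(
        study["gene_trees"], focal, cfg.generations, cfg.burnin,
        cfg.seed, cfg.thresholds,
    )
    table = species_table(study, delim, cfg.reporting_threshold)
    table.to_csv(out / "species_table.tsv", sep="\t", index=False)

    results = comparative_analysis(table, study["backbone"], cfg.seed,
                                   cfg.null_replicates)
    summary = comparative_summary(results)
    summary.to_csv(out / "pgls_summary.tsv", sep="\t", index=False)

    # the multivariate model carries 9 coefficients plus sigma^2 and lambda;
    # AICc needs a sample comfortably larger than that
    if len(table) >= 15:
        importance = multivariate_importance(table, cfg.n_backbone_trees,
                                             cfg.seed)
        importance_summary(importance).to_csv(out / "importance.tsv",
                                              sep="\t", index=False)
    else:
        importance = None

    maps, spec = diversity_maps(study, table, cfg.map_cell_size)
    (out / "maps").mkdir(exist_ok=True)
    for name, grid in maps.items():
        write_ascii_grid(grid, spec, out / "maps" / f"structure_{name}.asc")

    import dendropy
    import scipy

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(cfg),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "dendropy": dendropy.__version__,
        },
        "n_species": int(len(table)),
        "outputs": ["species_table.tsv", "pgls_summary.tsv",
                    "importance.tsv", "maps/"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return {"study": study, "species_table": table, "pgls": results,
            "summary": summary, "importance": importance, "maps": maps,
            "grid_spec": spec, "manifest": manifest}
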