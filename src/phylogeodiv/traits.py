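"""Trait and environmental predictors.

Covers the per-species predictor variables of the comparative analysis:
hand-wing index from museum wing measurements, a modified Melton ruggedness
index, migratory distance from breeding/wintering latitudinal midpoints,
checklist-based occurrence filtering with spatial thinning, niche breadth as
a central 95% quantile range, per-cell climatic-stability differencing, and
PCA of environmental variables with Kaiser-criterion retention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PCAResult",
    "hand_wing_index",
    "hand_wing_index_table",
    "melton_index",
    "migratory_distance",
    "filter_occurrences",
    "haversine_km",
    "niche_breadth",
    "climate_stability",
    "pca_kaiser",
]

KM_PER_DEGREE = 111.32
EARTH_RADIUS_KM = 6371.0


class TraitsError(ValueError):
    """Raised for invalid trait/environment input."""


# ---------------------------------------------------------------------------
# morphology


def hand_wing_index(wing_length: float, secondary_length: float) -> float:
    """Hand-wing index 100 * (WL - SL)/SL, a proxy for dispersal ability."""
    if secondary_length <= 0:
        raise TraitsError("secondary length must be > 0")
    if wing_length < secondary_length:
        raise TraitsError("wing length must be >= secondary length")
    return 100.0 * (wing_length - secondary_length) / secondary_length


def hand_wing_index_table(morphology: pd.DataFrame) -> pd.DataFrame:
    """Specimen-level HWI and species means from a morphology table."""
    req = {"species_id", "wing_length_mm", "secondary_length_mm"}
    if not req <= set(morphology.columns):
        raise TraitsError(f"morphology table needs columns {sorted(req)}")
    hwi = [
        hand_wing_index(w, s)
        for w, s in zip(morphology["wing_length_mm"],
                        morphology["secondary_length_mm"])
    ]
    out = morphology.assign(hand_wing_index=hwi)
    means = (out.groupby("species_id", sort=True)["hand_wing_index"]
             .mean().rename("hand_wing_index_mean").reset_index())
    return out.merge(means, on="species_id")


def melton_index(elevation_max: float, elevation_min: float,
                 range_size_km2: float, base: str = "natural") -> float:
    """Modified Melton ruggedness: elevational relief / log(range size).

    Natural log by default (base-10 available); the log damps the large
    spread in range sizes across species.
    """
    if elevation_max < elevation_min:
        raise TraitsError("elevation_max must be >= elevation_min")
    if range_size_km2 <= 1:
        raise TraitsError("range size must exceed 1 km^2 (log must be positive)")
    log = math.log if base == "natural" else math.log10
    return (elevation_max - elevation_min) / log(range_size_km2)


def migratory_distance(
    breeding_midpoint: float | None,
    wintering_midpoint: float | None,
    sedentary: bool = False,
    units: str = "degrees",
) -> float:
    """Distance between breeding and wintering latitudinal midpoints.

    Zero for sedentary species; otherwise |breeding - wintering| in degrees,
    or converted at 111.32 km/degree when ``units="km"``.
    """
    if sedentary:
        return 0.0
    if breeding_midpoint is None or wintering_midpoint is None:
        raise TraitsError("migratory species needs both latitudinal midpoints")
    d = abs(breeding_midpoint - wintering_midpoint)
    return d * KM_PER_DEGREE if units == "km" else d


# ---------------------------------------------------------------------------
# occurrence filtering


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (haversine, radius 6371 km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (np.asarray(lat1, float),
                                              np.asarray(lon1, float),
                                              np.asarray(lat2, float),
                                              np.asarray(lon2, float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def _thin_greedy(lat: np.ndarray, lon: np.ndarray, min_km: float,
                 order: np.ndarray) -> np.ndarray:
    """Greedy thinning: keep a point if no kept point lies within min_km."""
    kept: list[int] = []
    for i in order:
        if all(haversine_km(lat[i], lon[i], lat[j], lon[j]) >= min_km
               for j in kept):
            kept.append(i)
    return np.array(sorted(kept), dtype=int)


def filter_occurrences(
    records: pd.DataFrame,
    max_duration_hr: float = 6.0,
    max_distance_km: float = 5.0,
    max_records: int = 1000,
    thin_km: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Checklist filtering, deduplication, subsampling, and 1-km thinning.

    Keeps records with duration strictly below 6 hr and distance strictly
    below 5 km, drops exact duplicate (lat, lon) localities per species,
    randomly subsamples to at most 1000 records per species (seeded), and
    greedily thins (in seeded-shuffle order) so no retained pair of
    localities within a species lies within 1 km great-circle distance.
    Idempotent for a fixed seed policy.
    """
    req = {"species_id", "lat", "lon", "duration_hr", "distance_km"}
    if not req <= set(records.columns):
        raise TraitsError(f"records need columns {sorted(req)}")
    rng = np.random.default_rng(seed)
    kept_frames = []
    for sp, grp in records.groupby("species_id", sort=True):
        g = grp[(grp["duration_hr"] < max_duration_hr)
                & (grp["distance_km"] < max_distance_km)]
        g = g.drop_duplicates(subset=["lat", "lon"], keep="first")
        if len(g) > max_records:
            g = g.iloc[np.sort(rng.choice(len(g), size=max_records,
                                          replace=False))]
        if len(g) > 1 and thin_km > 0:
            lat = g["lat"].to_numpy(float)
            lon = g["lon"].to_numpy(float)
            order = rng.permutation(len(g))
            idx = _thin_greedy(lat, lon, thin_km, order)
            g = g.iloc[idx]
        kept_frames.append(g)
    if not kept_frames:
        return records.iloc[0:0]
    return pd.concat(kept_frames).reset_index(drop=True)


# ---------------------------------------------------------------------------
# environment


def niche_breadth(values, central: float = 0.95) -> float:
    """Quantile range of a layer: q(0.975) - q(0.025) for the central 95%.

    ``central`` may be set to 0.90 to use the 0.95/0.05 quantile convention
    instead.  Linear-interpolation quantiles; NaNs are ignored; an all-NaN
    layer yields NaN.
    """
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        return float("nan")
    tail = (1.0 - central) / 2.0
    hi, lo = np.quantile(v, [1.0 - tail, tail])
    return float(hi - lo)


def climate_stability(current: dict[str, np.ndarray],
                      past: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-cell current-minus-past difference grid for each shared layer."""
    diffs = {}
    for name, cur in current.items():
        if name not in past:
            raise TraitsError(f"layer {name!r} missing from past grids")
        old = past[name]
        if cur.shape != old.shape:
            raise TraitsError(
                f"grid shape mismatch for {name!r}: {cur.shape} vs {old.shape}"
            )
        diffs[name] = cur - old
    return diffs


# ---------------------------------------------------------------------------
# PCA with Kaiser retention


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    loadings: np.ndarray          # (n_vars, n_components), columns sorted
    scores: np.ndarray            # (n_obs, n_components)
    retained: int                 # Kaiser criterion: eigenvalue > 1
    explained_fraction: np.ndarray
    unstable_retention: bool      # eigenvalues near 1 make retention fragile
    variable_names: list[str]


def pca_kaiser(matrix: pd.DataFrame | np.ndarray, standardize: bool = True,
               names: list[str] | None = None) -> PCAResult:
    """PCA on the correlation matrix with Kaiser-criterion retention.

    Standardizes columns (mixed measurement units), eigendecomposes the
    correlation matrix, retains components with eigenvalue > 1, and fixes
    each component's sign so its largest-magnitude loading is positive.
    Retention is flagged as unstable when any eigenvalue falls within 0.05
    of the Kaiser cutoff.
    """
    if isinstance(matrix, pd.DataFrame):
        names = names or list(matrix.columns)
        arr = matrix.to_numpy(float)
    else:
        arr = np.asarray(matrix, float)
        names = names or [f"v{i + 1}" for i in range(arr.shape[1])]
    n, p = arr.shape
    if n < 2:
        raise TraitsError("PCA needs at least 2 observations")
    sd = arr.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [names[i] for i in np.where(sd == 0)[0]]
        raise TraitsError(f"constant columns cannot be standardized: {bad}")
    z = (arr - arr.mean(axis=0)) / sd if standardize else arr - arr.mean(axis=0)
    corr = (z.T @ z) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(p):
        i_max = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i_max, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = z @ evecs
    retained = int((evals > 1.0).sum())
    unstable = bool((np.abs(evals - 1.0) < 0.05).any())
    return PCAResult(
        eigenvalues=evals, loadings=evecs, scores=scores,
        retained=retained, explained_fraction=evals / evals.sum(),
        unstable_retention=unstable, variable_names=names,
    )
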