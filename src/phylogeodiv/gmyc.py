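"""Single-threshold mixed Yule-coalescent (GMYC) cluster delimitation.

The model places one threshold time T on an ultrametric gene tree.  Nodes
older than T are branching events of a diversification (Yule-like) process
acting on cluster lineages; nodes younger than T are coalescent events inside
the cluster hanging from each lineage that crosses T.  Working from the tips
rootward, the tree decomposes into internode intervals, each ending at a
branching event.  With per-interval waiting time x_i, diversification lineage
count n_i and per-cluster lineage counts n_{j,i}, the interval's total event
rate is

    r_i = lambda_div * n_i**p_div + lambda_coal * sum_j [n_{j,i}(n_{j,i}-1)]**p_coal

and the log-likelihood sums log(r_i) - r_i * x_i over intervals (every
interval ends at a branching event), the waiting-time form used by the GMYC
literature.  Below T the diversification process runs on the k cluster
lineages without branching (n_i = k); above T all lineages belong to the
diversification class and every coalescent class has collapsed to a single
lineage (zero rate).

Two fitting routes are provided: a maximum-likelihood fit over the discrete
candidate threshold set (internode midpoints, plus the threshold at the root
which recovers the single-process null) with a likelihood-ratio gate against
that null, and a Bayesian MCMC over (threshold index, rates, exponents) whose
post-burn-in samples give the posterior probability that two tips share a
cluster.  Thresholding the co-assignment matrix (0.9 / 0.8 / 0.7) and taking
connected components yields the cluster count used downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize, sparse, stats

from .treeio import TreeError, check_ultrametric, node_depths

__all__ = [
    "IntervalTable",
    "GMYCFit",
    "CoassignmentMatrix",
    "build_intervals",
    "gmyc_loglik",
    "fit_gmyc_ml",
    "bayes_gmyc",
    "clusters_from_coassignment",
    "clusters_among",
]

_EXPONENT_BOUNDS = (0.5, 2.0)
# trees smaller than this have too few events to inform the exponents
_AUTO_FIX_EXPONENT_TIPS = 8


class GMYCError(ValueError):
    """Raised for invalid delimitation input or failed fits."""


@dataclass
class IntervalTable:
    """Internode interval decomposition of a tree for one threshold T.

    Arrays run tipward to rootward; interval i spans (d_{i-1}, d_i] between
    consecutive event depths (d_0 = 0) and ends at the branching event of
    depth d_i.  ``coal_pairs[i, j]`` holds n_{j,i}(n_{j,i}-1) for cluster j.
    """

    threshold: float
    root_depth: float
    x: np.ndarray                # (m,) waiting times
    n_div: np.ndarray            # (m,) diversification-class lineage counts
    coal_pairs: np.ndarray       # (m, k) n(n-1) per cluster per interval
    event_is_div: np.ndarray     # (m,) bool, class of the event ending interval i
    event_count: np.ndarray      # (m,) branching count of the event's own class
    clusters: list[frozenset[str]]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    # sufficient statistics -------------------------------------------------
    def _stats(self) -> "_LikStats":
        div_mask = self.event_is_div
        return _LikStats(
            e_div=int(div_mask.sum()),
            e_coal=int((~div_mask).sum()),
            n_div=self.n_div.astype(float),
            x=self.x.astype(float),
            pairs=self.coal_pairs.astype(float),
        )


@dataclass
class _LikStats:
    """Cached quantities for fast likelihood evaluation at one threshold."""

    e_div: int
    e_coal: int
    n_div: np.ndarray            # (m,)
    x: np.ndarray                # (m,)
    pairs: np.ndarray            # (m, k) n_j(n_j-1); zeros where collapsed

    @property
    def has_coal(self) -> bool:
        return bool(self.pairs.size) and bool(self.pairs.any())

    def interval_rates(self, lam_div: float, p_div: float,
                       lam_coal: float, p_coal: float) -> np.ndarray:
        """Total event rate per interval (diversification + all clusters)."""
        r = lam_div * self.n_div**p_div
        if self.has_coal and lam_coal != 0.0:
            if p_coal == 1.0:
                r = r + lam_coal * self.pairs.sum(axis=1)
            else:
                r = r + lam_coal * (self.pairs**p_coal).sum(axis=1)
        return r

    def loglik(self, lam_div: float, p_div: float,
               lam_coal: float, p_coal: float) -> float:
        """Waiting-time log-likelihood sum_i [log r_i - r_i x_i]."""
        if lam_div < 0 or lam_coal < 0:
            return -np.inf
        r = self.interval_rates(lam_div, p_div, lam_coal, p_coal)
        if (r <= 0).any():
            return -np.inf
        return float(np.log(r).sum() - r @ self.x)

    def ml_rates(self, p_div: float, p_coal: float,
                 allow_div: bool = True) -> tuple[float, float, float]:
        """Maximize over the two rates at fixed exponents.

        Returns (loglik, lam_div, lam_coal).  The per-class event-count /
        class-hazard ratios seed a quasi-Newton search on the log rates.
        ``allow_div=False`` pins lambda_div at 0 (the single-process null).
        """
        hz_div = float(self.x @ self.n_div**p_div)
        pair_sums = (self.pairs**p_coal).sum(axis=1) if self.has_coal else None
        hz_coal = float(self.x @ pair_sums) if self.has_coal else 0.0

        if not self.has_coal:
            if not allow_div:
                raise GMYCError("no coalescent structure and no div process")
            # pure one-class model: closed form lam = m / hazard
            m = len(self.x)
            lam = m / hz_div
            return self.loglik(lam, p_div, 0.0, p_coal), lam, 0.0

        ld0 = max(self.e_div, 0.5) / max(hz_div, 1e-12)
        lc0 = max(self.e_coal, 0.5) / max(hz_coal, 1e-12)

        if not allow_div:
            res = optimize.minimize_scalar(
                lambda z: -self.loglik(0.0, p_div, math.exp(z), p_coal),
                bounds=(math.log(lc0) - 10, math.log(lc0) + 10),
                method="bounded", options={"xatol": 1e-8},
            )
            return -res.fun, 0.0, math.exp(res.x)

        def neg(z):
            return -self.loglik(math.exp(z[0]), p_div, math.exp(z[1]), p_coal)

        res = optimize.minimize(neg, [math.log(ld0), math.log(lc0)],
                                method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-9,
                                         "maxiter": 400})
        ll = -res.fun
        lam_d, lam_c = np.exp(res.x)
        # the boundary lam_div -> 0 may beat the interior optimum
        ll0, _, lc_only = self.ml_rates(p_div, p_coal, allow_div=False)
        if ll0 > ll:
            return ll0, 0.0, lc_only
        return ll, float(lam_d), float(lam_c)


@dataclass
class GMYCFit:
    """Result of a maximum-likelihood GMYC fit."""

    threshold: float
    threshold_index: int
    lambda_div: float
    p_div: float
    lambda_coal: float
    p_coal: float
    loglik: float
    clusters: list[frozenset[str]]
    n_clusters: int
    null_loglik: float
    lr_stat: float
    lr_pvalue: float
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def n_clusters_gated(self, alpha: float = 0.05) -> int:
        """Cluster count after the likelihood-ratio significance gate.

        If the mixed model is not significantly better than the
        single-process null, the tree is treated as one cluster.
        """
        return self.n_clusters if self.lr_pvalue < alpha else 1


@dataclass
class CoassignmentMatrix:
    """Posterior tip-pair co-assignment probabilities from the MCMC."""

    labels: list[str]
    probs: np.ndarray
    n_samples: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = self.probs
        if p.shape != (len(self.labels), len(self.labels)):
            raise GMYCError("co-assignment matrix shape does not match labels")
        if not np.allclose(p, p.T):
            raise GMYCError("co-assignment matrix must be symmetric")
        if not np.allclose(np.diag(p), 1.0):
            raise GMYCError("co-assignment diagonal must be 1")
        if (p < -1e-12).any() or (p > 1 + 1e-12).any():
            raise GMYCError("co-assignment entries must lie in [0, 1]")


# ---------------------------------------------------------------------------
# interval construction


def _tree_arrays(tree: dendropy.Tree):
    """Depths and parent/child structure needed for threshold tables."""
    ok, dev = check_ultrametric(tree, tol=1e-6)
    if not ok:
        raise GMYCError(f"tree is not ultrametric (max deviation {dev:.3g})")
    depths = node_depths(tree)
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    return depths, leaves, labels, internals


def _clusters_for_threshold(tree, depths, threshold):
    """Crossing lineages at ``threshold`` and the event->cluster assignment.

    Returns (clusters, cluster_of_event) where clusters is a list of leaf
    label frozensets (one per lineage crossing T, singletons included) and
    cluster_of_event maps internal nodes below T to their cluster index.
    Threshold at or above the root depth yields the single-cluster layout.
    """
    root = tree.seed_node
    clusters: list[frozenset] = []
    cluster_of_event: dict = {}

    def collect(node, cid):
        for nd in node.preorder_iter():
            if nd.is_leaf():
                continue
            cluster_of_event[nd] = cid

    if depths[root] < threshold:
        clusters.append(frozenset(lf.taxon.label for lf in tree.leaf_node_iter()))
        collect(root, 0)
        return clusters, cluster_of_event

    stack = [root]
    while stack:
        nd = stack.pop()
        if depths[nd] < threshold:  # nd is the top of a cluster subtree
            cid = len(clusters)
            clusters.append(frozenset(lf.taxon.label for lf in nd.leaf_iter()))
            collect(nd, cid)
        else:
            stack.extend(nd.child_nodes())
    return clusters, cluster_of_event


def _table_for_threshold(tree, depths, internals, n_tips, threshold) -> IntervalTable:
    clusters, cluster_of_event = _clusters_for_threshold(tree, depths, threshold)
    k = len(clusters)
    events = sorted(internals, key=lambda nd: depths[nd])
    m = len(events)
    d = np.array([depths[nd] for nd in events])
    x = np.diff(np.concatenate(([0.0], d)))

    total_lineages = n_tips - np.arange(m)  # lineages present in interval i
    event_is_div = d >= threshold
    n_div = np.where(event_is_div, total_lineages, k)

    counts = np.zeros((m, k), dtype=int)
    cur = np.array([len(c) for c in clusters])
    for i, nd in enumerate(events):
        counts[i] = cur
        cid = cluster_of_event.get(nd)
        if cid is not None:
            cur[cid] -= 1
    coal_pairs = counts * (counts - 1)

    event_count = np.empty(m, dtype=int)
    for i, nd in enumerate(events):
        if event_is_div[i]:
            event_count[i] = n_div[i]
        else:
            event_count[i] = counts[i, cluster_of_event[nd]]

    return IntervalTable(
        threshold=float(threshold),
        root_depth=float(depths[tree.seed_node]),
        x=x,
        n_div=n_div.astype(float),
        coal_pairs=coal_pairs,
        event_is_div=event_is_div,
        event_count=event_count,
        clusters=clusters,
    )


def build_intervals(tree: dendropy.Tree, threshold: float) -> IntervalTable:
    """Interval decomposition of ``tree`` at threshold time ``threshold`` (Myr)."""
    depths, leaves, labels, internals = _tree_arrays(tree)
    root = depths[tree.seed_node]
    if not (0.0 < threshold < root):
        raise GMYCError(
            f"threshold must lie in (0, root depth = {root:.6g}), got {threshold}"
        )
    return _table_for_threshold(tree, depths, internals, len(leaves), threshold)


def gmyc_loglik(intervals: IntervalTable, lambda_div: float, p_div: float,
                lambda_coal: float, p_coal: float) -> float:
    """Mixed-model log-likelihood at the given rates and exponents."""
    if lambda_div < 0 or lambda_coal < 0:
        raise GMYCError("rates must be non-negative")
    stats_ = intervals._stats()
    rates = stats_.interval_rates(lambda_div, p_div, lambda_coal, p_coal)
    if (rates <= 0).any():
        raise GMYCError(
            "zero total event rate in an occupied interval; increase the "
            "rate of the class whose events occur there"
        )
    return stats_.loglik(lambda_div, p_div, lambda_coal, p_coal)


# ---------------------------------------------------------------------------
# candidate thresholds


def candidate_thresholds(tree: dendropy.Tree, include_root: bool = True) -> np.ndarray:
    """Candidate threshold times: midpoints between consecutive node depths.

    The first candidate sits halfway between the present and the youngest
    node (every node diversification -> one cluster per tip); successive
    midpoints step the threshold past one node depth at a time.  With
    ``include_root`` the root depth itself is appended: at that threshold no
    node is older than T, the whole tree is a single coalescent cluster, and
    the fit reduces to the single-process null.
    """
    depths, leaves, labels, internals = _tree_arrays(tree)
    d = np.array(sorted({depths[nd] for nd in internals}))
    mids = [d[0] / 2.0]
    mids.extend((d[:-1] + d[1:]) / 2.0)
    if include_root:
        mids.append(depths[tree.seed_node])
    return np.asarray(mids)


def _unique_event_depths(tree) -> list[float]:
    depths, leaves, labels, internals = _tree_arrays(tree)
    return sorted({depths[nd] for nd in internals})


def _tables_for_candidates(tree, candidates):
    depths, leaves, labels, internals = _tree_arrays(tree)
    n_tips = len(leaves)
    root = depths[tree.seed_node]
    tables = []
    for t in candidates:
        # a candidate at the root depth means "no diversification events";
        # nudge it just past the root so every node falls below the threshold
        t_eff = t if t < root else root * (1 + 1e-12) + 1e-30
        tables.append(_table_for_threshold(tree, depths, internals, n_tips, t_eff))
    return tables, labels


# ---------------------------------------------------------------------------
# maximum likelihood


def _ml_at_table(table: IntervalTable, fix_exponents: bool):
    st = table._stats()
    if fix_exponents:
        ll, lam_d, lam_c = st.ml_rates(1.0, 1.0)
        return ll, lam_d, 1.0, lam_c, 1.0, True

    def neg(p):
        return -st.ml_rates(p[0], p[1])[0]

    best = None
    for start in ((1.0, 1.0), (0.7, 1.5), (1.5, 0.7)):
        res = optimize.minimize(
            neg, start, method="Nelder-Mead",
            bounds=[_EXPONENT_BOUNDS, _EXPONENT_BOUNDS],
            options={"xatol": 1e-3, "fatol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
    p_div, p_coal = best.x
    ll, lam_d, lam_c = st.ml_rates(p_div, p_coal)
    return ll, lam_d, p_div, lam_c, p_coal, bool(best.success)


def fit_gmyc_ml(tree: dendropy.Tree, fix_exponents: bool | None = None) -> GMYCFit:
    """Maximum-likelihood GMYC fit over all candidate thresholds.

    Rates (and, unless fixed, exponents) are optimized at each candidate
    threshold; the best-scoring candidate is returned together with a
    likelihood-ratio statistic against the single-process null (one
    coalescent over the whole tree), referred to a chi-square with 3 degrees
    of freedom (rate, exponent, and threshold of the added process).
    """
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    if n_tips < 3:
        raise GMYCError("GMYC fit requires at least 3 tips")
    if fix_exponents is None:
        fix_exponents = n_tips < _AUTO_FIX_EXPONENT_TIPS

    cands = candidate_thresholds(tree, include_root=True)
    tables, _ = _tables_for_candidates(tree, cands)

    fits = [_ml_at_table(tb, fix_exponents) for tb in tables]
    lls = np.array([f[0] for f in fits])
    best_idx = int(np.argmax(lls))
    ll, lam_d, p_div, lam_c, p_coal, ok = fits[best_idx]
    table = tables[best_idx]

    # single-process null: the root-threshold table with lambda_div pinned at 0
    null_st = tables[-1]._stats()
    if fix_exponents:
        null_ll = null_st.ml_rates(1.0, 1.0, allow_div=False)[0]
    else:
        res = optimize.minimize_scalar(
            lambda p: -null_st.ml_rates(1.0, p, allow_div=False)[0],
            bounds=_EXPONENT_BOUNDS, method="bounded",
            options={"xatol": 1e-3},
        )
        null_ll = -res.fun
    lr = max(0.0, 2.0 * (ll - null_ll))
    pval = float(stats.chi2.sf(lr, df=3))

    if not ok:
        diagnostics = {"optimizer": "L-BFGS-B did not report convergence"}
    else:
        diagnostics = {}
    return GMYCFit(
        threshold=table.threshold,
        threshold_index=best_idx,
        lambda_div=lam_d,
        p_div=p_div,
        lambda_coal=lam_c,
        p_coal=p_coal,
        loglik=float(ll),
        clusters=table.clusters,
        n_clusters=table.n_clusters,
        null_loglik=float(null_ll),
        lr_stat=float(lr),
        lr_pvalue=pval,
        converged=ok,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Bayesian MCMC

_PRIOR_LOGRATE_SD = 3.0  # broad lognormal prior on rates (depth-normalized tree)


def bayes_gmyc(
    tree: dendropy.Tree,
    n_generations: int = 250_000,
    burnin: int = 15_000,
    seed: int | None = None,
    fix_exponents: bool = False,
    threshold_prior: str = "time",
) -> CoassignmentMatrix:
    """Bayesian GMYC: MCMC over (threshold position, rates, exponents).

    The sampler is Metropolis-within-Gibbs.  The threshold prior is uniform
    on the threshold TIME over (0, root depth) by default — each discrete
    candidate (one per internode gap) carries prior mass proportional to its
    gap width, so a deep outgroup/sister branch gives the few-cluster
    configurations their natural weight; ``threshold_prior="index"`` weights
    all candidates equally instead.  Rates get broad lognormal priors
    (normal with SD 3 on the log rate, on a tree rescaled to unit root
    depth) and exponents uniform [0.5, 2] priors.  Proposal scales are
    adapted during burn-in toward a 20-40% acceptance rate.  Post-burn-in
    samples of the threshold give the posterior probability that each tip
    pair shares a cluster.
    """
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    if n_tips < 3:
        raise GMYCError("Bayesian GMYC requires at least 3 tips")
    if burnin >= n_generations:
        raise GMYCError("burnin must be smaller than n_generations")
    if threshold_prior not in ("time", "index"):
        raise GMYCError("threshold_prior must be 'time' or 'index'")
    rng = np.random.default_rng(seed)

    include_root = threshold_prior == "index"
    cands = candidate_thresholds(tree, include_root=include_root)
    tables, labels = _tables_for_candidates(tree, cands)
    root = tables[0].root_depth
    if threshold_prior == "time":
        depths_sorted = np.array(_unique_event_depths(tree))
        gaps = np.diff(np.concatenate(([0.0], depths_sorted)))
        log_prior_idx = np.log(np.maximum(gaps, 1e-300) / root)
    else:
        log_prior_idx = np.zeros(len(tables))
    # depth-normalize so rate priors are scale-free
    all_stats = []
    for tb in tables:
        st = tb._stats()
        st.x = st.x / root
        all_stats.append(st)
    n_cand = len(tables)

    def log_post(idx, ld, pd, lc, pc):
        st = all_stats[idx]
        ll = st.loglik(math.exp(ld), pd, math.exp(lc), pc)
        lp = -(ld**2 + lc**2) / (2 * _PRIOR_LOGRATE_SD**2)
        return ll + lp + log_prior_idx[idx]

    # Anchors for cross-threshold moves: per-candidate ML rates (exponents
    # at 1).  A threshold move proposes rates from a normal around the
    # target candidate's anchor (independence proposal, MH-corrected), so
    # the chain is not trapped by rates adapted to the current threshold.
    anchor = np.zeros((n_cand, 2))
    for i, st in enumerate(all_stats):
        _, lam_d, lam_c = st.ml_rates(1.0, 1.0)
        anchor[i, 0] = math.log(max(lam_d, 1e-3))
        anchor[i, 1] = math.log(max(lam_c, 1e-3))
    _ANCHOR_SD = 0.6

    def _q_logpdf(ld, lc, i):
        return -((ld - anchor[i, 0]) ** 2 + (lc - anchor[i, 1]) ** 2) / (
            2 * _ANCHOR_SD**2)

    idx = int(np.argmax([log_post(i, anchor[i, 0], 1.0, anchor[i, 1], 1.0)
                         for i in range(n_cand)]))
    ld, lc = anchor[idx]
    pd_, pc_ = 1.0, 1.0
    cur = log_post(idx, ld, pd_, lc, pc_)

    blocks = ["idx", "ld", "lc"] + ([] if fix_exponents else ["pd", "pc"])
    scales = {"ld": 1.0, "lc": 1.0, "pd": 0.3, "pc": 0.3}
    acc = {b: 0 for b in blocks}
    tries = {b: 0 for b in blocks}

    lo, hi = _EXPONENT_BOUNDS

    def reflect(v):
        while v < lo or v > hi:
            if v < lo:
                v = 2 * lo - v
            if v > hi:
                v = 2 * hi - v
        return v

    idx_counts = np.zeros(n_cand, dtype=np.int64)
    n_samples = 0
    choices = rng.integers(0, len(blocks), size=n_generations)

    for g in range(n_generations):
        b = blocks[choices[g]]
        tries[b] += 1
        if b == "idx":
            prop = int(rng.integers(0, n_cand))
            pld, plc = rng.normal(anchor[prop], _ANCHOR_SD)
            new = log_post(prop, pld, pd_, plc, pc_)
            log_ratio = (new - cur
                         + _q_logpdf(ld, lc, idx)
                         - _q_logpdf(pld, plc, prop))
            if math.log(rng.random() + 1e-300) < log_ratio:
                idx, ld, lc, cur = prop, pld, plc, new
                acc[b] += 1
        else:
            step = rng.normal(0.0, scales[b])
            nld, nlc, npd, npc = ld, lc, pd_, pc_
            if b == "ld":
                nld = ld + step
            elif b == "lc":
                nlc = lc + step
            elif b == "pd":
                npd = reflect(pd_ + step)
            else:
                npc = reflect(pc_ + step)
            new = log_post(idx, nld, npd, nlc, npc)
            if math.log(rng.random() + 1e-300) < new - cur:
                ld, lc, pd_, pc_, cur = nld, nlc, npd, npc, new
                acc[b] += 1

        if g < burnin:
            if (g + 1) % 500 == 0:
                for bb in ("ld", "lc", "pd", "pc"):
                    if bb in blocks and tries[bb] > 0:
                        rate = acc[bb] / tries[bb]
                        if rate < 0.20:
                            scales[bb] *= 0.7
                        elif rate > 0.40:
                            scales[bb] *= 1.4
                        acc[bb] = 0
                        tries[bb] = 0
        else:
            idx_counts[idx] += 1
            n_samples += 1

    total_acc = sum(acc.values())
    if total_acc == 0 and n_generations - burnin > 100:
        rates = {b: (acc[b] / tries[b] if tries[b] else 0.0) for b in blocks}
        raise GMYCError(f"MCMC accepted no proposals after burn-in: {rates}")

    label_index = {lb: i for i, lb in enumerate(labels)}
    probs = np.zeros((n_tips, n_tips))
    freq = idx_counts / n_samples
    for ci, f in enumerate(freq):
        if f == 0:
            continue
        member = np.zeros((n_tips, len(tables[ci].clusters)))
        for j, cl in enumerate(tables[ci].clusters):
            for lb in cl:
                member[label_index[lb], j] = 1.0
        probs += f * (member @ member.T)
    np.fill_diagonal(probs, 1.0)
    probs = np.clip((probs + probs.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(probs, 1.0)

    diagnostics = {
        "acceptance": {b: (acc[b] / tries[b] if tries[b] else float("nan"))
                       for b in blocks},
        "threshold_index_freq": freq,
        "candidate_thresholds": cands,
        "seed": seed,
        "n_generations": n_generations,
        "burnin": burnin,
    }
    return CoassignmentMatrix(labels=labels, probs=probs,
                              n_samples=n_samples, diagnostics=diagnostics)


def clusters_from_coassignment(
    matrix: CoassignmentMatrix, threshold: float = 0.9,
    linkage: str = "single",
) -> tuple[list[frozenset[str]], int]:
    """Partition tips from the co-assignment matrix at a probability threshold.

    ``linkage="single"`` (default) takes connected components of the graph
    with edges where P >= threshold; ``"average"`` cuts an average-linkage
    hierarchical clustering of the dissimilarity 1 - P at 1 - threshold.
    """
    if linkage == "average":
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        d = 1.0 - matrix.probs
        np.fill_diagonal(d, 0.0)
        z = hierarchy.linkage(squareform(d, checks=False), method="average")
        flat = hierarchy.fcluster(z, t=1.0 - threshold, criterion="distance")
        labels = flat - 1
        n_comp = len(set(labels))
    elif linkage == "single":
        adj = sparse.csr_matrix(matrix.probs >= threshold)
        n_comp, labels = sparse.csgraph.connected_components(adj, directed=False)
    else:
        raise GMYCError("linkage must be 'single' or 'average'")
    parts: dict[int, set] = {}
    for lb, comp in zip(matrix.labels, labels):
        parts.setdefault(comp, set()).add(lb)
    partition = [frozenset(parts[c]) for c in sorted(parts)]
    return partition, int(n_comp)


def clusters_among(matrix: CoassignmentMatrix, threshold: float,
                   subset) -> int:
    """Number of delimited clusters containing at least one tip of ``subset``.

    Used to count a focal species' clusters when the analyzed tree also
    carries its sister lineage.
    """
    partition, _ = clusters_from_coassignment(matrix, threshold)
    block_of = {lb: i for i, block in enumerate(partition) for lb in block}
    missing = [lb for lb in subset if lb not in block_of]
    if missing:
        raise GMYCError(f"subset tips not in matrix: {sorted(missing)[:5]}")
    return len({block_of[lb] for lb in subset})
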