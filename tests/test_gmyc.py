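import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylogeodiv.gmyc import (
    CoassignmentMatrix,
    GMYCError,
    bayes_gmyc,
    build_intervals,
    clusters_among,
    clusters_from_coassignment,
    fit_gmyc_ml,
    gmyc_loglik,
)
from phylogeodiv.simulate import simulate_gene_tree
from phylogeodiv.treeio import extract_subtree, node_depths, parse_newick, root_depth

from conftest import random_gene_trees


# ---------------------------------------------------------------------------
# independent oracle: interval likelihood computed by direct tree traversal


def brute_force_loglik(tree, threshold, lam_div, p_div, lam_coal, p_coal):
    """Evaluate the mixed-model likelihood straight from the tree.

    Walks the internode intervals, counting lineages per cluster at each
    interval's midpoint by scanning every edge — no shared code with the
    IntervalTable machinery.
    """
    depths = node_depths(tree)
    events = sorted(
        (depths[nd] for nd in tree.preorder_node_iter() if not nd.is_leaf())
    )
    # cluster id per leaf: the crossing ancestor at the threshold
    leaf_cluster = {}
    cluster_id = [0]

    def assign(node, current):
        if depths[node] < threshold and (current is None):
            cid = cluster_id[0]
            cluster_id[0] += 1
            current = cid
        if node.is_leaf():
            leaf_cluster[node.taxon.label] = current
            return
        for c in node.child_nodes():
            assign(c, current)

    assign(tree.seed_node, None)
    k = cluster_id[0]

    ll = 0.0
    prev = 0.0
    for d in events:
        x = d - prev
        mid = (prev + d) / 2.0
        counts = {}
        total = 0
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            if depths[nd] < mid <= depths[nd.parent_node]:
                total += 1
                labels = {lf.taxon.label for lf in nd.leaf_iter()}
                cids = {leaf_cluster[lb] for lb in labels}
                if len(cids) == 1:
                    c = next(iter(cids))
                    counts[c] = counts.get(c, 0) + 1
        n_div = k if d < threshold else total
        rate = lam_div * n_div**p_div + lam_coal * sum(
            (c * (c - 1)) ** p_coal for c in counts.values()
        )
        if rate <= 0:
            return -math.inf
        ll += math.log(rate) - rate * x
        prev = d
    return ll


# ---------------------------------------------------------------------------
# interval construction


def test_three_tip_partition_and_classes(three_tip_tree):
    table = build_intervals(three_tip_tree, 1.5)
    assert table.n_clusters == 2
    assert sorted(sorted(b) for b in table.clusters) == [["a", "b"], ["c"]]
    assert list(table.event_is_div) == [False, True]
    np.testing.assert_allclose(table.x, [1.0, 1.0])


def test_threshold_just_above_youngest_node():
    tree, _ = simulate_gene_tree(2, 1.0, 4.0, 4, 0.1, seed=1)
    depths = node_depths(tree)
    internal = sorted(depths[nd] for nd in tree.preorder_node_iter()
                      if not nd.is_leaf())
    t = (internal[0] + internal[1]) / 2
    table = build_intervals(tree, t)
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    younger = sum(1 for d in internal if d < t)
    assert table.n_clusters == n_tips - younger


def test_waiting_times_sum_to_root_depth():
    for tree, _ in random_gene_trees(10, seed=5):
        t = 0.5 * root_depth(tree)
        table = build_intervals(tree, t)
        assert table.x.sum() == pytest.approx(root_depth(tree), abs=1e-9)


def test_threshold_outside_tree_rejected(three_tip_tree):
    with pytest.raises(GMYCError):
        build_intervals(three_tip_tree, 0.0)
    with pytest.raises(GMYCError):
        build_intervals(three_tip_tree, 2.5)


# ---------------------------------------------------------------------------
# likelihood


def test_loglik_closed_form_three_tips(three_tip_tree):
    # intervals: (0,1] rate 2*ld + 2*lc ending in the coalescence of {a,b};
    # (1,2] rate 2*ld ending at the root divergence
    ld, lc = 0.4, 3.0
    table = build_intervals(three_tip_tree, 1.5)
    expected = (math.log(2 * ld + 2 * lc) - (2 * ld + 2 * lc)
                + math.log(2 * ld) - 2 * ld)
    assert gmyc_loglik(table, ld, 1.0, lc, 1.0) == pytest.approx(expected)


@pytest.mark.parametrize("p_div,p_coal", [(1.0, 1.0), (0.7, 1.6)])
def test_loglik_matches_brute_force_oracle(p_div, p_coal):
    for tree, _ in random_gene_trees(8, seed=21):
        t = 0.4 * root_depth(tree)
        table = build_intervals(tree, t)
        got = gmyc_loglik(table, 0.6, p_div, 4.0, p_coal)
        want = brute_force_loglik(tree, t, 0.6, p_div, 4.0, p_coal)
        assert got == pytest.approx(want, abs=1e-8)


def test_time_rescaling_changes_loglik_by_jacobian():
    # scaling branch lengths by c and rates by 1/c multiplies each event
    # density by 1/c: loglik shifts by -m log c exactly (exponents at 1)
    c = 3.7
    for tree, _ in random_gene_trees(5, seed=33):
        t = 0.5 * root_depth(tree)
        table = build_intervals(tree, t)
        m = len(table.x)
        ll = gmyc_loglik(table, 0.8, 1.0, 5.0, 1.0)
        scaled = tree.clone(depth=1)
        for e in scaled.preorder_edge_iter():
            if e.length is not None:
                e.length = e.length * c
        table_s = build_intervals(scaled, t * c)
        ll_s = gmyc_loglik(table_s, 0.8 / c, 1.0, 5.0 / c, 1.0)
        assert ll_s - ll == pytest.approx(-m * math.log(c), abs=1e-8)


# ---------------------------------------------------------------------------
# maximum likelihood fit


def test_fitted_loglik_never_below_null():
    for tree, _ in random_gene_trees(10, seed=55, tips_range=(3, 5)):
        fit = fit_gmyc_ml(tree, fix_exponents=True)
        assert fit.loglik >= fit.null_loglik - 1e-9


def test_ml_recovery_single_and_four_clusters():
    # LR-gated cluster counts on cleanly separated simulations
    for n_true, reps, need in ((1, 30, 24), (4, 30, 24)):
        hits = 0
        for rep in range(reps):
            tree, truth = simulate_gene_tree(
                n_true, 1.0, 5.0, 5, 0.05, seed=900 * n_true + rep,
                between_rate=0.5, species_id="s",
            )
            fit = fit_gmyc_ml(tree, fix_exponents=True)
            if fit.lr_pvalue < 0.05:
                block_of = {lb: i for i, b in enumerate(fit.clusters) for lb in b}
                n = len({block_of[lb] for lb in truth.focal_tips})
            else:
                n = 1
            hits += n == n_true
        assert hits >= need, f"N={n_true}: {hits}/{reps}"


def test_too_few_tips_rejected():
    with pytest.raises(GMYCError):
        fit_gmyc_ml(parse_newick("(a:1,b:1);"))


# ---------------------------------------------------------------------------
# Bayesian co-assignment


def test_coassignment_matrix_invariants():
    tree, truth = simulate_gene_tree(2, 1.0, 4.0, 4, 0.1, seed=6)
    co = bayes_gmyc(tree, n_generations=3000, burnin=600, seed=1)
    p = co.probs
    assert np.allclose(p, p.T)
    assert np.allclose(np.diag(p), 1.0)
    assert (p >= 0).all() and (p <= 1).all()


def test_single_cluster_simulation_has_high_coassignment():
    tree, truth = simulate_gene_tree(1, 1.0, 5.0, 5, 0.05, seed=10)
    co = bayes_gmyc(tree, n_generations=6000, burnin=1200, seed=2)
    idx = [co.labels.index(lb) for lb in truth.focal_tips]
    sub = co.probs[np.ix_(idx, idx)]
    assert (sub[~np.eye(len(idx), dtype=bool)] > 0.9).all()


def test_chains_with_different_seeds_agree():
    tree, _ = simulate_gene_tree(4, 1.0, 5.0, 5, 0.05, seed=12,
                                 between_rate=0.5)
    co1 = bayes_gmyc(tree, n_generations=12_000, burnin=2500, seed=100)
    co2 = bayes_gmyc(tree, n_generations=12_000, burnin=2500, seed=200)
    assert np.abs(co1.probs - co2.probs).max() < 0.1


def test_invalid_mcmc_settings_rejected():
    tree, _ = simulate_gene_tree(2, 1.0, 4.0, 4, 0.1, seed=0)
    with pytest.raises(GMYCError):
        bayes_gmyc(tree, n_generations=100, burnin=200, seed=0)


# ---------------------------------------------------------------------------
# clustering from the matrix


def _matrix(p):
    p = np.asarray(p, float)
    return CoassignmentMatrix(labels=[f"t{i}" for i in range(len(p))],
                              probs=p, n_samples=1)


def test_all_ones_is_one_cluster():
    _, n = clusters_from_coassignment(_matrix(np.ones((4, 4))), 0.9)
    assert n == 1


def test_identity_matrix_is_all_singletons():
    _, n = clusters_from_coassignment(_matrix(np.eye(5)), 0.7)
    assert n == 5


@settings(max_examples=40, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_cluster_count_nondecreasing_in_threshold(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 9))
    raw = rng.random((n, n))
    p = (raw + raw.T) / 2
    np.fill_diagonal(p, 1.0)
    m = _matrix(p)
    counts = [clusters_from_coassignment(m, th)[1] for th in (0.7, 0.8, 0.9)]
    assert counts[0] <= counts[1] <= counts[2]


@settings(max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_average_linkage_never_coarser_than_single(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 8))
    raw = rng.random((n, n))
    p = (raw + raw.T) / 2
    np.fill_diagonal(p, 1.0)
    m = _matrix(p)
    _, n_single = clusters_from_coassignment(m, 0.8, linkage="single")
    _, n_avg = clusters_from_coassignment(m, 0.8, linkage="average")
    assert n_avg >= n_single
    _, one = clusters_from_coassignment(_matrix(np.ones((4, 4))), 0.9,
                                        linkage="average")
    assert one == 1


def test_clusters_among_subset():
    p = np.eye(4)
    p[0, 1] = p[1, 0] = 1.0
    m = _matrix(p)
    assert clusters_among(m, 0.9, ["t0", "t1"]) == 1
    assert clusters_among(m, 0.9, ["t0", "t2", "t3"]) == 3
    with pytest.raises(GMYCError):
        clusters_among(m, 0.9, ["nope"])
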