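import numpy as np
import pytest

from phylogeodiv.simulate import simulate_backbone, simulate_gene_tree
from phylogeodiv.treeio import parse_newick


@pytest.fixture
def three_tip_tree():
    """((a:1,b:1):1,c:2); — the canonical worked example."""
    return parse_newick("((a:1,b:1):1,c:2);")


@pytest.fixture
def backbone_50():
    tree, lats = simulate_backbone(50, yule_rate=0.2, seed=1234)
    return tree, lats


def random_gene_trees(n, seed, max_clusters=3, tips_range=(2, 4)):
    """Small random mixed Yule/coalescent trees for oracle checks."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        n_true = int(rng.integers(1, max_clusters + 1))
        tips = int(rng.integers(*tips_range)) + 1
        tree, truth = simulate_gene_tree(
            n_true, 1.0, float(rng.uniform(3.0, 6.0)), tips, 0.1,
            seed=int(rng.integers(2**31)), species_id=f"r{i}",
        )
        out.append((tree, truth))
    return out
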