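"""Reading, writing, and interrogating time-calibrated trees.

Trees are handled as :class:`dendropy.Tree` objects throughout the package.
Branch lengths are in millions of years (Myr) and dated trees are expected to
be ultrametric: every tip sits at depth (time before present) zero.  This
module adds the small layer the pipeline needs on top of dendropy: depth
bookkeeping, ultrametricity checks, and crown/stem age extraction for a focal
species given a tip-to-species mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import dendropy

__all__ = [
    "AgePair",
    "TreeError",
    "read_tree",
    "write_tree",
    "parse_newick",
    "to_newick",
    "node_depths",
    "root_depth",
    "check_ultrametric",
    "crown_stem_ages",
    "extract_subtree",
]


class TreeError(ValueError):
    """Raised for malformed or inconsistent tree input."""


@dataclass(frozen=True)
class AgePair:
    """Crown and stem age of a focal species, in Myr.

    crown_age is the depth of the MRCA of the species' haplotypes (the time at
    which all sampled haplotypes coalesce); stem_age is the depth of the MRCA
    of the haplotypes together with the sister lineage (the divergence from
    the species' last common ancestor).  Optional HPD bounds come from a
    sidecar table, never re-estimated here.
    """

    crown_age: float
    stem_age: float
    crown_hpd: tuple[float, float] | None = None
    stem_hpd: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (self.stem_age >= self.crown_age > 0):
            raise TreeError(
                f"require stem_age >= crown_age > 0, got "
                f"crown={self.crown_age}, stem={self.stem_age}"
            )


def read_tree(path: str, schema: str = "newick") -> dendropy.Tree:
    """Read a single rooted tree from ``path``.

    ``schema`` is ``"newick"`` or ``"nexus"`` (NEXUS translate tables are
    resolved by dendropy).  Duplicate tip labels raise an error.
    """
    if schema not in ("newick", "nexus"):
        raise TreeError(f"unsupported tree format: {schema!r}")
    try:
        tree = dendropy.Tree.get(
            path=path,
            schema=schema,
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"failed to parse {path!r} as {schema}: {exc}") from exc
    _check_tip_labels(tree)
    return tree


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:
        raise TreeError(f"failed to parse newick string: {exc}") from exc
    _check_tip_labels(tree)
    return tree


def _check_tip_labels(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise TreeError(f"duplicate tip labels: {dupes}")


def to_newick(tree: dendropy.Tree) -> str:
    """Canonical Newick string with full-precision branch lengths."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    ).strip()


def write_tree(tree: dendropy.Tree, path: str, schema: str = "newick") -> None:
    if schema not in ("newick", "nexus"):
        raise TreeError(f"unsupported tree format: {schema!r}")
    tree.write(
        path=path,
        schema=schema,
        suppress_rooting=(schema == "newick"),
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    )


def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Depth (time before present) of every node.

    Depth is measured as max root-to-tip distance minus the node's distance
    from the root, so on an ultrametric tree it equals the node's age.
    """
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    height = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    return {nd: height - nd.root_distance for nd in tree.preorder_node_iter()}


def root_depth(tree: dendropy.Tree) -> float:
    depths = node_depths(tree)
    return depths[tree.seed_node]


def check_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> tuple[bool, float]:
    """Return (is_ultrametric, max tip-depth deviation)."""
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    dists = [leaf.root_distance for leaf in tree.leaf_node_iter()]
    deviation = max(dists) - min(dists)
    return deviation <= tol, deviation


def _mrca(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Node:
    labels = list(labels)
    taxa = [tree.taxon_namespace.get_taxon(lb) for lb in labels]
    missing = [lb for lb, tx in zip(labels, taxa) if tx is None]
    if missing:
        raise TreeError(f"tips not in tree: {sorted(missing)}")
    node = tree.mrca(taxa=taxa)
    if node is None:
        raise TreeError(f"no MRCA found for {sorted(labels)}")
    return node


def crown_stem_ages(
    tree: dendropy.Tree,
    focal_tips: Iterable[str],
    sister_tips: Iterable[str],
) -> AgePair:
    """Crown and stem ages for a focal species on a dated gene tree.

    Crown age is the depth of the MRCA of ``focal_tips``; stem age is the
    depth of the MRCA of focal plus sister tips.  The focal set must be
    monophyletic: paraphyletic species are an input-level taxonomy problem
    (resolved upstream by the lumped treatment) and raise here rather than
    silently taking an MRCA that spans other taxa.
    """
    focal = set(focal_tips)
    sister = set(sister_tips)
    if len(focal) < 2:
        raise TreeError("crown age undefined for fewer than 2 focal tips")
    if not sister:
        raise TreeError("sister tip set must be nonempty")
    if focal & sister:
        raise TreeError(f"focal and sister tips overlap: {sorted(focal & sister)}")

    depths = node_depths(tree)
    crown_node = _mrca(tree, focal)
    clade = {lf.taxon.label for lf in crown_node.leaf_iter()}
    if clade != focal:
        raise TreeError(
            "focal tips are not monophyletic; MRCA clade also contains "
            f"{sorted(clade - focal)}"
        )
    stem_node = _mrca(tree, focal | sister)
    crown = depths[crown_node]
    stem = depths[stem_node]
    if not math.isfinite(crown) or not math.isfinite(stem):
        raise TreeError("non-finite node depth encountered")
    return AgePair(crown_age=crown, stem_age=stem)


def read_species_map(path: str) -> dict[tuple[str, str], set[str]]:
    """Read a species-to-tips mapping TSV.

    Columns: species_id, treatment (e.g. AOS or lumped), tip_label.  Returns
    {(species_id, treatment): set of tip labels}.
    """
    import csv

    out: dict[tuple[str, str], set[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"species_id", "treatment", "tip_label"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise TreeError(f"species map needs columns {sorted(required)}")
        for row in reader:
            key = (row["species_id"], row["treatment"])
            out.setdefault(key, set()).add(row["tip_label"])
    return out


def extract_subtree(tree: dendropy.Tree, tips: Iterable[str]) -> dendropy.Tree:
    """Rooted subtree induced by ``tips``, with branch lengths preserved."""
    keep = set(tips)
    taxa = [tree.taxon_namespace.get_taxon(lb) for lb in keep]
    if any(tx is None for tx in taxa):
        missing = [lb for lb, tx in zip(keep, taxa) if tx is None]
        raise TreeError(f"tips not in tree: {sorted(missing)}")
    sub = tree.extract_tree_with_taxa(taxa=taxa)
    sub.is_rooted = True
    return sub
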