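"""Rooted, branch-length phylogenies: Newick I/O, Yule simulation, pruning.

Thin wrappers over :mod:`dendropy`. Trees are time-like (branch lengths in
arbitrary time units); the Brownian-motion machinery in :mod:`csrpipe.origins`
only assumes non-negative branch lengths and unique tip labels.
"""

from __future__ import annotations

import random
from pathlib import Path

import dendropy
from dendropy.simulate import treesim

Phylogeny = dendropy.Tree


def read_newick(path: str | Path) -> Phylogeny:
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    validate_tree(tree)
    return tree


def write_newick(tree: Phylogeny, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
    return path


def tip_labels(tree: Phylogeny) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def validate_tree(tree: Phylogeny) -> None:
    labels = tip_labels(tree)
    if len(labels) != len(set(labels)):
        raise ValueError("tip labels are not unique")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")


def tree_depth(tree: Phylogeny) -> float:
    """Maximum root-to-tip path length."""
    return max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())


def rescale_depth(tree: Phylogeny, depth: float = 1.0) -> Phylogeny:
    """Scale all branch lengths so the deepest tip sits at ``depth``."""
    cur = tree_depth(tree)
    if cur <= 0:
        raise ValueError("tree has zero depth")
    factor = depth / cur
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return tree


def yule_tree(n_tips: int, labels: list[str], birth_rate: float = 1.0,
              seed: int = 0) -> Phylogeny:
    """Pure-birth tree on ``n_tips`` tips, rescaled to unit depth.

    The simulator stops at the n-th speciation event, which leaves the two
    newest tips at zero distance; a single Exp(n*birth_rate) extension is
    appended to every pendant edge so all tips are distinct, preserving
    ultrametricity, before rescaling.
    """
    if len(labels) != n_tips:
        raise ValueError("need exactly one label per tip")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_tips, rng=rng)
    extension = rng.expovariate(n_tips * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extension
    # the simulator may leave a stem edge above the root; drop it
    tree.seed_node.edge.length = None
    rescale_depth(tree, 1.0)
    for leaf, label in zip(tree.leaf_node_iter(), labels):
        leaf.taxon.label = label
    return tree


def prune_to(tree: Phylogeny, keep: set[str]) -> Phylogeny:
    """Return a copy of the tree restricted to the given tip labels."""
    sub = tree.extract_tree_with_taxa_labels(labels=keep)
    sub.purge_taxon_namespace()
    return sub
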