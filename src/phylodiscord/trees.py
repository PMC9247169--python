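"""Newick I/O and small tree utilities on top of dendropy."""

from __future__ import annotations

from pathlib import Path

import dendropy
from dendropy.calculate import treecompare


def read_newick(path, taxon_namespace: dendropy.TaxonNamespace | None = None
                ) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        path=str(path), schema="newick",
        taxon_namespace=taxon_namespace,
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    return tree


def read_newick_list(path, taxon_namespace=None) -> list[dendropy.Tree]:
    """One newick tree per line (gene-tree lists)."""
    trees = dendropy.TreeList.get(
        path=str(path), schema="newick",
        taxon_namespace=taxon_namespace,
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    return list(trees)


def tree_from_string(newick: str, taxon_namespace=None) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick",
        taxon_namespace=taxon_namespace,
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )


def to_newick(tree: dendropy.Tree) -> str:
    """Newick string with branch lengths at 10 significant digits."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    ).strip()
    return s + "\n"


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(to_newick(tree))


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def rf_distance(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Unweighted Robinson-Foulds distance (shared taxon namespace required)."""
    if tree_a.taxon_namespace is not tree_b.taxon_namespace:
        ns = dendropy.TaxonNamespace()
        tree_a = tree_from_string(to_newick(tree_a), ns)
        tree_b = tree_from_string(to_newick(tree_b), ns)
    tree_a.encode_bipartitions()
    tree_b.encode_bipartitions()
    return treecompare.symmetric_difference(tree_a, tree_b)


def find_branch_by_split(tree: dendropy.Tree, side: set[str]):
    """Internal edge whose bipartition separates ``side`` from the rest.

    Returns the child node of that edge, or ``None`` if the split is absent.
    The tree is treated as unrooted: either orientation of the split matches.
    """
    all_leaves = leaf_labels(tree)
    other = all_leaves - side
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = {l.taxon.label for l in node.leaf_iter()}
        if below == side or below == other:
            return node
    return None


def clade_mrca_labels(tree: dendropy.Tree, labels: set[str]) -> set[str]:
    """Leaf labels under the MRCA of ``labels``."""
    taxa = [t for t in tree.taxon_namespace if t.label in labels]
    mrca = tree.mrca(taxa=taxa)
    return {l.taxon.label for l in mrca.leaf_iter()}
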