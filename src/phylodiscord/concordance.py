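"""Site and gene concordance factors around internal branches.

An internal branch splits the tree into four subtrees.  The site
concordance factor (sCF) samples one leaf per subtree and scores alignment
sites that are decisive for that quartet (unambiguous 2+2 state patterns);
the three possible resolutions — the branch itself and its two NNI
alternatives — partition the decisive sites.  The gene concordance factor
(gCF) is the percentage of decisive gene trees whose induced bipartition
contains the branch.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .models import AA_ORDER, NT_ORDER

#: plurality reference line: above 1/3 a resolution beats a uniform split
SCF_PLURALITY_THRESHOLD = 100.0 / 3.0


@dataclass(frozen=True)
class BranchConcordance:
    """Concordance summary for one internal branch."""

    branch: tuple                      # sorted labels on the child side
    scf_main: float | None
    scf_alt1: float | None             # groups A with C
    scf_alt2: float | None             # groups A with D
    n_quartets: int
    n_decisive_sites_mean: float
    gcf: float | None = None
    n_decisive_trees: int | None = None
    groups: tuple | None = None        # the four subtree leaf groups

    @property
    def defined(self) -> bool:
        return self.scf_main is not None


def _internal_branches(tree):
    """(node, groups) for each internal edge with four nonempty subtrees."""
    all_leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        kids = node.child_nodes()
        if len(kids) < 2:
            continue
        group_a = sorted(l.taxon.label for l in kids[0].leaf_iter())
        group_b = sorted(l for k in kids[1:] for l in
                         (x.taxon.label for x in k.leaf_iter()))
        below = set(group_a) | set(group_b)
        parent = node.parent_node
        siblings = [k for k in parent.child_nodes() if k is not node]
        sib_leaves = [sorted(x.taxon.label for x in k.leaf_iter())
                      for k in siblings]
        above_rest = sorted(all_leaves - below -
                            {l for g in sib_leaves for l in g})
        if parent.parent_node is None and not above_rest:
            # root-adjacent edge: split the far side by the sibling subtrees
            if len(sib_leaves) >= 2:
                group_c = sib_leaves[0]
                group_d = sorted(l for g in sib_leaves[1:] for l in g)
            else:
                # bifurcating root: descend into the single sibling
                sib = siblings[0]
                skids = sib.child_nodes()
                if len(skids) < 2:
                    continue
                group_c = sorted(l.taxon.label for l in skids[0].leaf_iter())
                group_d = sorted(l for k in skids[1:] for l in
                                 (x.taxon.label for x in k.leaf_iter()))
        else:
            group_c = sorted(l for g in sib_leaves for l in g)
            group_d = above_rest
        if not (group_a and group_b and group_c and group_d):
            continue
        out.append((node, (group_a, group_b, group_c, group_d)))
    return out


def _branch_seed(seed, groups) -> np.random.SeedSequence:
    tag = "|".join(",".join(g) for g in groups)
    digest = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return np.random.SeedSequence(int.from_bytes(digest[:4], "big"))


def _quartet_site_support(aln: Alignment, quartet, valid_states) -> tuple:
    rows = [aln.matrix[aln.taxa.index(t)] for t in quartet]
    a, b, c, d = rows
    ok = np.ones(aln.n_sites, dtype=bool)
    for r in rows:
        ok &= np.isin(r, valid_states)
    main = ok & (a == b) & (c == d) & (a != c)
    alt1 = ok & (a == c) & (b == d) & (a != b)
    alt2 = ok & (a == d) & (b == c) & (a != b)
    return int(main.sum()), int(alt1.sum()), int(alt2.sum())


def _scf_for_groups(aln, groups, n_quartets, seed, exhaustive=False):
    valid = np.array(list(NT_ORDER if aln.alphabet == "nt" else AA_ORDER))
    if exhaustive:
        quartets = list(itertools.product(*groups))
    else:
        rng = np.random.default_rng(_branch_seed(seed, groups))
        quartets = [tuple(g[i] for g, i in
                          zip(groups, (rng.integers(0, len(g)) for g in groups)))
                    for _ in range(n_quartets)]
    fracs = {"main": [], "alt1": [], "alt2": []}
    decisive_counts = []
    for q in quartets:
        n_main, n_alt1, n_alt2 = _quartet_site_support(aln, q, valid)
        dec = n_main + n_alt1 + n_alt2
        decisive_counts.append(dec)
        if dec > 0:
            fracs["main"].append(100.0 * n_main / dec)
            fracs["alt1"].append(100.0 * n_alt1 / dec)
            fracs["alt2"].append(100.0 * n_alt2 / dec)
    if not fracs["main"]:
        return None, None, None, len(quartets), float(np.mean(decisive_counts))
    return (float(np.mean(fracs["main"])), float(np.mean(fracs["alt1"])),
            float(np.mean(fracs["alt2"])), len(quartets),
            float(np.mean(decisive_counts)))


def scf(aln: Alignment, reference_tree, n_quartets: int = 100,
        seed: int = 0, exhaustive: bool = False
        ) -> dict[frozenset, BranchConcordance]:
    """Site concordance factors for every internal branch of the tree.

    Quartets draw one leaf per subtree uniformly with replacement; the draw
    depends only on the sorted leaf labels around the branch, so taxon
    order in the alignment is irrelevant.  ``exhaustive=True`` enumerates
    every quartet instead.  Branches with no decisive site in any quartet
    come back with undefined (``None``) factors.
    """
    if not exhaustive and n_quartets < 1:
        raise ValueError("n_quartets must be at least 1")
    out = {}
    for node, groups in _internal_branches(reference_tree):
        main, alt1, alt2, nq, dec = _scf_for_groups(
            aln, groups, n_quartets, seed, exhaustive)
        below = tuple(sorted(groups[0] + groups[1]))
        out[frozenset(below)] = BranchConcordance(
            branch=below, scf_main=main, scf_alt1=alt1, scf_alt2=alt2,
            n_quartets=nq, n_decisive_sites_mean=dec,
            groups=tuple(tuple(g) for g in groups))
    return out


def _groups_for_split(reference_tree, split: set[str]):
    """Quartet groups of the branch matching ``split`` (either orientation)."""
    all_leaves = {l.taxon.label for l in reference_tree.leaf_node_iter()}
    targets = (set(split), all_leaves - set(split))
    for node, groups in _internal_branches(reference_tree):
        below = set(groups[0]) | set(groups[1])
        if below in targets:
            return groups
    raise KeyError(f"no internal branch with split {sorted(split)!r}")


def scf_for_split(aln: Alignment, reference_tree, split: set[str],
                  n_quartets: int = 100, seed: int = 0,
                  exhaustive: bool = False) -> BranchConcordance:
    """sCF at the branch whose child side equals ``split`` (or its complement)."""
    groups = _groups_for_split(reference_tree, split)
    main, alt1, alt2, nq, dec = _scf_for_groups(
        aln, groups, n_quartets, seed, exhaustive)
    below = tuple(sorted(groups[0] + groups[1]))
    return BranchConcordance(
        branch=below, scf_main=main, scf_alt1=alt1, scf_alt2=alt2,
        n_quartets=nq, n_decisive_sites_mean=dec,
        groups=tuple(tuple(g) for g in groups))


def scf_per_marker(aln: Alignment, reference_tree, split: set[str],
                   n_quartets: int = 100, seed: int = 0
                   ) -> dict[str, BranchConcordance]:
    """Focal-branch sCF computed separately on each partition's columns.

    Markers with no decisive site in any sampled quartet map to a
    concordance record with undefined factors (missing, never zero).  The
    1/3 plurality threshold is exposed as ``SCF_PLURALITY_THRESHOLD``.
    """
    if not aln.partitions:
        raise ValueError("alignment has no partitions")
    groups = _groups_for_split(reference_tree, split)
    below = tuple(sorted(groups[0] + groups[1]))
    out = {}
    for name in aln.partitions:
        sub = aln.partition_alignment(name)
        main, alt1, alt2, nq, dec = _scf_for_groups(
            sub, groups, n_quartets, seed)
        out[name] = BranchConcordance(
            branch=below, scf_main=main, scf_alt1=alt1, scf_alt2=alt2,
            n_quartets=nq, n_decisive_sites_mean=dec,
            groups=tuple(tuple(g) for g in groups))
    return out


# ---------------------------------------------------------------------------
# gene concordance


def _gene_tree_splits(tree) -> list[frozenset]:
    splits = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        splits.append(frozenset(l.taxon.label for l in node.leaf_iter()))
    return splits


def gcf(gene_trees, reference_tree) -> dict[frozenset, BranchConcordance]:
    """Gene concordance factor for every internal branch of the reference.

    A gene tree is decisive for a branch if it carries at least one taxon
    from each of the branch's four subtrees; it is concordant if one of its
    bipartitions, restricted to its own taxa, groups the two near subtrees
    against the two far ones.  Unresolved (star) gene trees are decisive
    but never concordant.
    """
    gene_trees = list(gene_trees)
    if not gene_trees:
        raise ValueError("empty gene-tree list")
    gene_data = []
    for gt in gene_trees:
        taxa = frozenset(l.taxon.label for l in gt.leaf_node_iter())
        gene_data.append((taxa, _gene_tree_splits(gt)))
    out = {}
    for node, groups in _internal_branches(reference_tree):
        near = frozenset(groups[0] + groups[1])
        far = frozenset(groups[2] + groups[3])
        n_decisive = 0
        n_concordant = 0
        for taxa, splits in gene_data:
            if not all(taxa & frozenset(g) for g in groups):
                continue
            n_decisive += 1
            want = near & taxa
            for s in splits:
                restricted = s & taxa
                if restricted == want or restricted == far & taxa:
                    n_concordant += 1
                    break
        below = tuple(sorted(near))
        out[frozenset(below)] = BranchConcordance(
            branch=below, scf_main=None, scf_alt1=None, scf_alt2=None,
            n_quartets=0, n_decisive_sites_mean=0.0,
            gcf=(100.0 * n_concordant / n_decisive) if n_decisive else None,
            n_decisive_trees=n_decisive)
    return out
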