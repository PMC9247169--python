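"""Shared fixtures: random small trees, brute-force likelihood oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from phylodiscord.alignment import Alignment
from phylodiscord.trees import tree_from_string

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


def random_rooted_newick(n_leaves: int, rng, mean_length: float = 0.2) -> str:
    """Random rooted binary tree over leaves t1..tn with exp branch lengths."""
    items = [f"t{i + 1}" for i in range(n_leaves)]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        la, lb = rng.exponential(mean_length, size=2)
        items.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return items[0] + ";"


def random_alignment(taxa, n_sites, states, rng) -> Alignment:
    mat = rng.choice(list(states), size=(len(taxa), n_sites))
    return Alignment(list(taxa), mat,
                     alphabet="nt" if len(states) == 4 else "aa")


def brute_force_site_ll(newick: str, aln: Alignment, model) -> np.ndarray:
    """Exhaustive sum over all internal-state assignments, gamma-averaged.

    Fully independent of the pruning engine: walks the dendropy tree,
    enumerates every assignment of states to internal nodes and sums the
    product of equilibrium and transition terms, then averages the site
    likelihood over the discrete-gamma categories.
    """
    tree = tree_from_string(newick)
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    leaves = [nd for nd in tree.leaf_node_iter()]
    node_pos = {id(nd): i for i, nd in enumerate(internals)}
    n = model.n_states
    obs = {leaf.taxon.label: [model.states.index(c) for c in
                              aln.sequence(leaf.taxon.label)]
           for leaf in leaves}
    idx = np.indices((n,) * len(internals)).reshape(len(internals), -1)
    pi = model.frequencies
    rates = model.category_rates
    site_like = np.zeros(aln.n_sites)
    for rate in rates:
        pmat = {}
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                t = nd.edge.length or 0.0
                pmat[id(nd)] = model.transition_matrix(t, rate)
        base = pi[idx[node_pos[id(tree.seed_node)]]]
        for nd in internals:
            if nd.parent_node is not None:
                base = base * pmat[id(nd)][idx[node_pos[id(nd.parent_node)]],
                                           idx[node_pos[id(nd)]]]
        for s in range(aln.n_sites):
            acc = base.copy()
            for leaf in leaves:
                state = obs[leaf.taxon.label][s]
                acc = acc * pmat[id(leaf)][idx[node_pos[id(leaf.parent_node)]],
                                           state]
            site_like[s] += acc.sum() / len(rates)
    return np.log(site_like)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
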