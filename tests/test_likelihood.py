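"""Pruning correctness against exhaustive enumeration, and branch fitting."""

import numpy as np
import pytest

from phylodiscord.alignment import Alignment
from phylodiscord.likelihood import (MissingTaxonError, SiteScoreTable,
                                     optimize_branch_lengths, score_topologies,
                                     site_log_likelihoods,
                                     total_log_likelihood)
from phylodiscord.models import build_model
from phylodiscord.trees import tree_from_string

from conftest import brute_force_site_ll, random_alignment, random_rooted_newick


def test_one_leaf_tree_gives_log_equilibrium():
    m = build_model("poisson", alpha=0.5)
    aln = Alignment.from_sequences({"A": "AR"})
    ll = site_log_likelihoods(aln, tree_from_string("A;"), m)
    assert np.allclose(ll, np.log(1.0 / 20.0))


def test_two_identical_leaves_at_zero_distance():
    m = build_model("gtr-like", frequencies=[0.1, 0.2, 0.3, 0.4])
    aln = Alignment.from_sequences({"A": "C", "B": "C"}, alphabet="nt")
    ll = site_log_likelihoods(aln, tree_from_string("(A:0,B:0);"), m)
    assert np.allclose(ll, np.log(0.2), atol=1e-12)


@pytest.mark.parametrize("model_name", ["poisson", "wag"])
def test_pruning_matches_exhaustive_enumeration(model_name, rng):
    m = build_model(model_name, alpha=0.7, n_categories=4)
    for _ in range(10):
        n_leaves = int(rng.integers(3, 6))
        nwk = random_rooted_newick(n_leaves, rng)
        aln = random_alignment([f"t{i + 1}" for i in range(n_leaves)], 10,
                               m.states, rng)
        ours = site_log_likelihoods(aln, tree_from_string(nwk), m)
        oracle = brute_force_site_ll(nwk, aln, m)
        assert np.allclose(ours, oracle, rtol=1e-8, atol=1e-10)


def test_sitewise_sums_to_total_and_rerooting_is_invariant(rng):
    m = build_model("wag", alpha=0.9)
    nwk = random_rooted_newick(6, rng)
    taxa = [f"t{i + 1}" for i in range(6)]
    aln = random_alignment(taxa, 40, m.states, rng)
    tree = tree_from_string(nwk)
    ll = site_log_likelihoods(aln, tree, m)
    assert abs(ll.sum() - total_log_likelihood(aln, tree, m)) < 1e-8
    # reroot on an internal edge: the likelihood must not move
    tree2 = tree_from_string(nwk)
    internal = [nd for nd in tree2.preorder_node_iter()
                if nd.parent_node is not None and not nd.is_leaf()]
    tree2.reroot_at_node(internal[0])
    ll2 = site_log_likelihoods(aln, tree2, m)
    assert np.allclose(ll, ll2, atol=1e-8)


def test_gaps_and_ambiguities_are_missing_data():
    m = build_model("gtr-like", frequencies=[0.1, 0.2, 0.3, 0.4])
    tree = tree_from_string("(A:0.2,B:0.1);")
    full = Alignment.from_sequences({"A": "C", "B": "G"}, alphabet="nt")
    gapped = Alignment.from_sequences({"A": "C", "B": "-"}, alphabet="nt")
    # a fully missing leaf reduces to the single-sequence likelihood
    single = Alignment.from_sequences({"A": "C", "B": "C"}, alphabet="nt")
    ll_gap = site_log_likelihoods(gapped, tree, m)
    assert np.allclose(ll_gap, np.log(0.2), atol=1e-10)
    assert site_log_likelihoods(full, tree, m)[0] < ll_gap[0]


def test_impossible_site_warns_and_returns_neg_inf():
    m = build_model("gtr-like")
    tree = tree_from_string("(A:0,B:0);")
    aln = Alignment.from_sequences({"A": "C", "B": "G"}, alphabet="nt")
    with pytest.warns(UserWarning):
        ll = site_log_likelihoods(aln, tree, m)
    assert np.isneginf(ll[0])


def test_missing_taxon_raises():
    m = build_model("poisson")
    aln = Alignment.from_sequences({"A": "AA"})
    with pytest.raises(MissingTaxonError):
        site_log_likelihoods(aln, tree_from_string("(A:0.1,B:0.1);"), m)


def test_partition_models_must_cover_all_sites():
    m = build_model("poisson")
    aln = Alignment.from_sequences({"A": "AAAA", "B": "RRRR"},
                                   partitions={"p1": (0, 2)})
    with pytest.raises(ValueError):
        site_log_likelihoods(aln, tree_from_string("(A:0.1,B:0.1);"),
                             {"p1": m})


def test_two_taxon_branch_length_matches_closed_form(rng):
    """Poisson MLE has the closed form t = -(19/20) ln(1 - 20/19 p̂)."""
    m = build_model("poisson", alpha=None, n_categories=1)
    t_true = 0.3
    p = m.transition_matrix(t_true)
    root = rng.choice(20, size=3000, p=m.frequencies)
    u = rng.random(3000)
    child = (u[:, None] < p[root].cumsum(axis=1)).argmax(axis=1)
    aln = Alignment.from_sequences({
        "A": "".join(m.states[i] for i in root),
        "B": "".join(m.states[i] for i in child)})
    phat = float(np.mean(root != child))
    closed = -(19.0 / 20.0) * np.log(1.0 - (20.0 / 19.0) * phat)
    res = optimize_branch_lengths(aln, tree_from_string("(A:0.1,B:0.1);"), m)
    fitted = sum(e.length for e in res.tree.preorder_edge_iter()
                 if e.length is not None)
    assert res.converged
    assert abs(fitted - closed) < 1e-4


def test_identical_sequences_drive_lengths_to_lower_bound():
    m = build_model("poisson", alpha=None, n_categories=1)
    aln = Alignment.from_sequences({t: "ARNDCQEGHILK" for t in "ABCD"})
    res = optimize_branch_lengths(
        aln, tree_from_string("((A:0.2,B:0.2):0.1,C:0.2,D:0.2);"), m)
    for e in res.tree.preorder_edge_iter():
        if e.length is not None:
            assert e.length <= 1e-4


def test_optimization_never_decreases_likelihood(rng):
    m = build_model("poisson", alpha=0.6)
    nwk = random_rooted_newick(5, rng)
    taxa = [f"t{i + 1}" for i in range(5)]
    aln = random_alignment(taxa, 60, m.states, rng)
    tree = tree_from_string(nwk)
    before = total_log_likelihood(aln, tree, m)
    res = optimize_branch_lengths(aln, tree, m, max_passes=5)
    assert res.log_likelihood >= before - 1e-9
    assert abs(total_log_likelihood(aln, res.tree, m)
               - res.log_likelihood) < 1e-6


def test_score_table_roundtrip(tmp_path, rng):
    m = build_model("poisson", alpha=0.5)
    taxa = [f"t{i + 1}" for i in range(4)]
    aln = random_alignment(taxa, 12, m.states, rng)
    aln.partitions.update({"g1": (0, 5), "g2": (5, 12)})
    trees = {"mt": tree_from_string("((t1:0.1,t2:0.1):0.05,t3:0.1,t4:0.1);"),
             "nuc": tree_from_string("((t1:0.1,t3:0.1):0.05,t2:0.1,t4:0.1);")}
    table = score_topologies(aln, trees, m)
    path = tmp_path / "scores.tsv"
    table.to_tsv(path)
    back = SiteScoreTable.from_tsv(path)
    for label in table.labels:
        assert np.allclose(back.scores[label], table.scores[label],
                           rtol=1e-9)
    assert list(back.site_partition) == list(table.site_partition)
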