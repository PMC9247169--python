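"""Site and gene concordance factors: oracles, closure, conventions."""

import numpy as np
import pytest

from phylodiscord.alignment import Alignment
from phylodiscord.concordance import gcf, scf, scf_for_split, scf_per_marker
from phylodiscord.trees import tree_from_string

TREE4 = "((A:1,B:1):1,(C:1,D:1):1);"


def _aln(rows: dict[str, str], alphabet="nt", partitions=None):
    return Alignment.from_sequences(rows, alphabet, partitions)


def test_perfectly_concordant_sites_give_scf_100():
    aln = _aln({"A": "AAGG", "B": "AAGG", "C": "TTCC", "D": "TTCC"})
    bc = scf_for_split(aln, tree_from_string(TREE4), {"A", "B"},
                       n_quartets=10, seed=0)
    assert bc.scf_main == pytest.approx(100.0)
    assert bc.scf_alt1 == pytest.approx(0.0)
    assert bc.scf_alt2 == pytest.approx(0.0)


def test_constant_alignment_has_no_decisive_sites():
    aln = _aln({t: "AAAA" for t in "ABCD"})
    bc = scf_for_split(aln, tree_from_string(TREE4), {"A", "B"},
                       n_quartets=10, seed=0)
    assert not bc.defined
    assert bc.scf_main is None


def test_four_leaf_sampling_equals_exhaustive(rng):
    """With one possible quartet, sampling and enumeration must agree exactly."""
    mat = rng.choice(list("ACGT"), size=(4, 200))
    aln = Alignment(list("ABCD"), mat, "nt")
    tree = tree_from_string(TREE4)
    sampled = scf_for_split(aln, tree, {"A", "B"}, n_quartets=25, seed=3)
    exact = scf_for_split(aln, tree, {"A", "B"}, exhaustive=True)
    assert sampled.scf_main == pytest.approx(exact.scf_main)
    assert sampled.scf_alt1 == pytest.approx(exact.scf_alt1)
    assert sampled.scf_alt2 == pytest.approx(exact.scf_alt2)


def test_three_resolutions_close_to_100(rng):
    nwk = "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
    mat = rng.choice(list("ACGT"), size=(8, 300))
    aln = Alignment(list("ABCDEFGH"), mat, "nt")
    table = scf(aln, tree_from_string(nwk), n_quartets=50, seed=1)
    assert table
    for bc in table.values():
        if bc.defined:
            assert bc.scf_main + bc.scf_alt1 + bc.scf_alt2 == \
                pytest.approx(100.0, abs=1e-6)


def test_sampled_scf_converges_to_exhaustive(rng):
    nwk = "(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1,(G:1,H:1):1);"
    mat = rng.choice(list("ACGT"), size=(8, 150))
    aln = Alignment(list("ABCDEFGH"), mat, "nt")
    tree = tree_from_string(nwk)
    split = {"A", "B", "C", "D"}
    exact = scf_for_split(aln, tree, split, exhaustive=True)
    approx = scf_for_split(aln, tree, split, n_quartets=10000, seed=2)
    assert abs(approx.scf_main - exact.scf_main) < 1.0


def test_scf_ignores_taxon_order(rng):
    mat = rng.choice(list("ACGT"), size=(6, 100))
    taxa = list("ABCDEF")
    aln1 = Alignment(taxa, mat, "nt")
    order = [3, 0, 5, 1, 4, 2]
    aln2 = Alignment([taxa[i] for i in order], mat[order], "nt")
    nwk = "((A:1,B:1):1,(C:1,D:1):1,(E:1,F:1):1);"
    t = tree_from_string(nwk)
    bc1 = scf_for_split(aln1, t, {"A", "B"}, n_quartets=40, seed=9)
    bc2 = scf_for_split(aln2, t, {"A", "B"}, n_quartets=40, seed=9)
    assert bc1.scf_main == bc2.scf_main
    assert bc1.scf_alt1 == bc2.scf_alt1


def test_gaps_make_sites_indecisive():
    aln = _aln({"A": "A-", "B": "AN", "C": "TT", "D": "TT"})
    bc = scf_for_split(aln, tree_from_string(TREE4), {"A", "B"},
                       n_quartets=5, seed=0)
    # column 1 decisive (AATT), column 2 is not (gap + ambiguity)
    assert bc.defined
    assert bc.n_decisive_sites_mean == pytest.approx(1.0)


def test_per_marker_scf_duplicate_markers_and_missing(rng):
    mat = rng.choice(list("ACGT"), size=(4, 60))
    mat[:, 40:] = "A"            # constant block: no decisive sites
    aln = Alignment(list("ABCD"), mat, "nt",
                    {"m1": (0, 20), "m2": (20, 40), "m3": (40, 60)})
    aln.matrix[:, 20:40] = aln.matrix[:, 0:20]   # m2 duplicates m1
    out = scf_per_marker(aln, tree_from_string(TREE4), {"A", "B"},
                         n_quartets=10, seed=4)
    assert out["m1"].scf_main == out["m2"].scf_main
    assert not out["m3"].defined


def test_invalid_quartet_count():
    aln = _aln({t: "ACGT" for t in "ABCD"})
    with pytest.raises(ValueError):
        scf(aln, tree_from_string(TREE4), n_quartets=0)


# ---------------------------------------------------------------------------
# gene concordance


def test_gcf_all_identical_trees_is_100():
    ref = tree_from_string(
        "((A:1,B:1):1,(C:1,D:1):1,(E:1,F:1):1);")
    genes = [tree_from_string("((A:1,B:1):1,(C:1,D:1):1,(E:1,F:1):1);")
             for _ in range(6)]
    table = gcf(genes, ref)
    assert table
    for bc in table.values():
        assert bc.gcf == pytest.approx(100.0)
        assert bc.n_decisive_trees == 6


def test_gcf_half_concordant_is_50():
    ref = tree_from_string("((A:1,B:1):1,C:1,D:1);")
    concordant = [tree_from_string("((A:1,B:1):1,C:1,D:1);")] * 3
    nni = [tree_from_string("((A:1,C:1):1,B:1,D:1);")] * 3
    table = gcf(concordant + nni, ref)
    bc = table[frozenset({"A", "B"})]
    assert bc.gcf == pytest.approx(50.0)


def test_star_gene_trees_are_decisive_but_discordant():
    ref = tree_from_string("((A:1,B:1):1,C:1,D:1);")
    stars = [tree_from_string("(A:1,B:1,C:1,D:1);")] * 4
    table = gcf(stars, ref)
    bc = table[frozenset({"A", "B"})]
    assert bc.gcf == pytest.approx(0.0)
    assert bc.n_decisive_trees == 4


def test_gcf_with_missing_taxa_and_empty_list():
    ref = tree_from_string("((A:1,B:1):1,(C:1,D:1):1,(E:1,F:1):1);")
    # D and F absent, but one taxon per subtree remains: still decisive
    partial = tree_from_string("((A:1,B:1):1,C:1,E:1);")
    table = gcf([partial], ref)
    assert table[frozenset({"A", "B"})].gcf == pytest.approx(100.0)
    # a tree missing a whole subtree is indecisive for that branch
    undecided = tree_from_string("((A:1,B:1):1,C:1,D:1);")
    assert gcf([undecided], ref)[frozenset({"A", "B"})].gcf is None
    with pytest.raises(ValueError):
        gcf([], ref)
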