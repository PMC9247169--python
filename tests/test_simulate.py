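"""Synthetic-study generator: topology pairs, simulation, fixtures."""

import json

import numpy as np
import pytest
from scipy.stats import chisquare

from phylodiscord.alignment import read_fasta, read_partitions
from phylodiscord.models import build_model
from phylodiscord.simulate import (InvalidConfigurationError, PartitionSpec,
                                   SimConfig, apply_clade_shift,
                                   make_study_fixture, make_topology_pair,
                                   simulate_alignment, simulate_cds)
from phylodiscord.composition import GeneticCode, gt_content
from phylodiscord.trees import leaf_labels, rf_distance, tree_from_string

CLADES = {"H": ["h1", "h2"], "P": ["p1", "p2"],
          "Pa": ["q1", "q2"], "Out": ["o1", "o2"]}


def test_topology_pair_is_one_nni_apart():
    pair = make_topology_pair(CLADES, seed=1)
    assert rf_distance(pair.tree_a, pair.tree_b) == 2
    assert leaf_labels(pair.tree_a) == leaf_labels(pair.tree_b)
    assert pair.split_a == frozenset(["h1", "h2", "p1", "p2"])
    assert pair.split_b == frozenset(["h1", "h2", "q1", "q2"])


def test_topology_pair_is_deterministic():
    a = make_topology_pair(CLADES, seed=42)
    b = make_topology_pair(CLADES, seed=42)
    assert a.newick_a == b.newick_a and a.newick_b == b.newick_b
    c = make_topology_pair(CLADES, seed=43)
    assert c.newick_a != a.newick_a


def test_topology_pair_rejects_bad_configurations():
    with pytest.raises(InvalidConfigurationError):
        make_topology_pair({"A": ["a"], "B": ["b"], "C": ["c"]}, seed=0)
    with pytest.raises(InvalidConfigurationError):
        make_topology_pair({"A": ["a"], "B": ["b"], "C": ["c"], "D": []},
                           seed=0)
    with pytest.raises(InvalidConfigurationError):
        make_topology_pair({"A": ["a"], "B": ["b"], "C": ["c"], "D": ["d"]},
                           seed=0)  # only 4 leaves


def test_zero_length_branch_copies_states():
    m = build_model("gtr-like", frequencies=[0.1, 0.2, 0.3, 0.4], alpha=0.5)
    aln = simulate_alignment(tree_from_string("(A:0,B:0);"), m, 50, seed=9)
    assert aln.sequence("A") == aln.sequence("B")


def test_long_branch_reaches_equilibrium():
    """At t=100 the child distribution must be the model's equilibrium."""
    m = build_model("gtr-like", frequencies=[0.1, 0.2, 0.3, 0.4], alpha=None,
                    n_categories=1)
    aln = simulate_alignment(tree_from_string("(A:0.0,B:100.0);"), m,
                             10000, seed=4)
    seq = aln.sequence("B")
    counts = [seq.count(b) for b in "ACGT"]
    stat = chisquare(counts, f_exp=np.array([0.1, 0.2, 0.3, 0.4]) * 10000)
    assert stat.pvalue > 0.01


def test_simulation_is_deterministic():
    m = build_model("poisson", alpha=0.5)
    tree = tree_from_string("((A:0.1,B:0.1):0.05,C:0.1,D:0.2);")
    a = simulate_alignment(tree, m, 30, seed=7)
    b = simulate_alignment(tree, m, 30, seed=7)
    assert (a.matrix == b.matrix).all()


def test_clade_shift_arithmetic_and_identity():
    m = build_model("gtr-like")  # uniform frequencies
    shifted = apply_clade_shift(m, 0.2)
    gt_mass = shifted.frequencies[[2, 3]].sum()   # G, T in ACGT order
    assert abs(gt_mass - 0.7) < 1e-12
    assert abs(shifted.frequencies.sum() - 1.0) < 1e-12
    same = apply_clade_shift(m, 0.0)
    assert np.allclose(same.frequencies, m.frequencies)
    with pytest.raises(InvalidConfigurationError):
        apply_clade_shift(m, 0.6)


def test_shifted_clade_has_higher_gt_content():
    """Simulated nucleotide sequences inside the shifted clade carry more G+T."""
    m = build_model("gtr-like", alpha=0.5)
    shifted = apply_clade_shift(m, 0.15)
    pair = make_topology_pair(CLADES, seed=2)
    aln = simulate_alignment(pair.tree_a, m, 3000, seed=11,
                             shift_leaves={"q1", "q2"}, shift_model=shifted)
    gt_shifted = np.mean([gt_content(aln.sequence(t)) for t in ("q1", "q2")])
    gt_rest = np.mean([gt_content(aln.sequence(t))
                       for t in aln.taxa if not t.startswith("q")])
    assert gt_shifted > gt_rest


def test_simulated_cds_is_in_frame_and_stop_free():
    code = GeneticCode.from_table(5)
    cds = simulate_cds(200, [[0.25, 0.15, 0.25, 0.35],
                             [0.20, 0.20, 0.15, 0.45],
                             [0.30, 0.15, 0.15, 0.40]], seed=5, code=code)
    assert len(cds) == 600
    codons = {cds[i:i + 3] for i in range(0, 600, 3)}
    assert not (codons & code.stop_codons)
    assert cds == simulate_cds(200, [[0.25, 0.15, 0.25, 0.35],
                                     [0.20, 0.20, 0.15, 0.45],
                                     [0.30, 0.15, 0.15, 0.40]], seed=5,
                               code=code)


@pytest.fixture(scope="module")
def small_fixture(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    parts = (
        PartitionSpec("cox1", 60, "CIV"), PartitionSpec("atp6", 40, "CV"),
        PartitionSpec("cytb", 50, "CIII"),
        PartitionSpec("nadh2", 40, "CI-ms"), PartitionSpec("nadh4", 40, "CI-ps"),
        PartitionSpec("sdha", 40, "CII", contact="non-contact", signal=0.1,
                      gene_tree="nuc"),
        PartitionSpec("cox4i1", 40, "CIV", contact="contact"),
    )
    cfg = SimConfig(partitions=parts, seed=21)
    return make_study_fixture(cfg, out), out


def test_fixture_round_trips_through_readers(small_fixture):
    fx, out = small_fixture
    aln = read_fasta(out / "concatenated.faa", "aa")
    aln.partitions.update(read_partitions(out / "partitions.txt"))
    assert aln.n_sites == fx.alignment.n_sites
    assert aln.partitions == fx.alignment.partitions
    assert (aln.matrix == fx.alignment.matrix).all()
    tree = tree_from_string((out / "tree_mt.nwk").read_text())
    assert leaf_labels(tree) == set(aln.taxa)


def test_fixture_complex_groups_match_oxphos_layout(small_fixture):
    fx, _ = small_fixture
    assert set(fx.marker_complex.values()) == {
        "CV", "CIV", "CIII", "CII", "CI-ms", "CI-ps"}


def test_default_config_has_the_six_complex_groups():
    cfg = SimConfig()
    groups = {p.group for p in cfg.partitions}
    assert groups == {"CV", "CIV", "CIII", "CII", "CI-ms", "CI-ps"}
    mt = [p for p in cfg.partitions if p.contact == "mt"]
    assert {p.name for p in mt if p.group == "CI-ms"} == \
        {"nadh1", "nadh2", "nadh6"}
    assert {p.name for p in mt if p.group == "CI-ps"} == \
        {"nadh3", "nadh4", "nadh4l", "nadh5"}


def test_fixture_manifests_are_reproducible(tmp_path):
    parts = (PartitionSpec("cox1", 30, "CIV"), PartitionSpec("atp6", 20, "CV"),
             PartitionSpec("cytb", 20, "CIII"),
             PartitionSpec("sdha", 20, "CII", contact="non-contact"),
             PartitionSpec("nadh1", 20, "CI-ms"),
             PartitionSpec("nadh3", 20, "CI-ps"))
    cfg = SimConfig(partitions=parts, seed=77)
    make_study_fixture(cfg, tmp_path / "a")
    make_study_fixture(cfg, tmp_path / "b")
    ma = (tmp_path / "a" / "manifest.json").read_text()
    mb = (tmp_path / "b" / "manifest.json").read_text()
    assert ma == mb
    assert json.loads(ma)["truth"]["generating_topology"] == "mt"
    fa = (tmp_path / "a" / "concatenated.faa").read_text()
    fb = (tmp_path / "b" / "concatenated.faa").read_text()
    assert fa == fb


def test_generated_model_frequencies_sum_to_one():
    for delta in (0.0, 0.05, 0.2, 0.4):
        m = apply_clade_shift(build_model("poisson"), delta)
        assert abs(m.frequencies.sum() - 1.0) < 1e-12
        m2 = apply_clade_shift(build_model("gtr-like"), delta)
        assert abs(m2.frequencies.sum() - 1.0) < 1e-12
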