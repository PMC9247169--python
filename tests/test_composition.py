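"""Composition statistics: worked examples, complement identities, bounds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylodiscord.composition import (GeneticCode, InvalidAnnotationError,
                                      at_skew, composition_table, fourfold_gt3,
                                      gc_skew, gt_content, gt_rich_codon_freq,
                                      reverse_complement, unassigned_regions,
                                      ur_gt_content)
from phylodiscord.simulate import MockAnnotation


@pytest.mark.parametrize("seq,expected", [
    ("AATT", 0.0), ("AAAT", 0.5), ("aaat", 0.5), ("A-A-AT", 0.5),
])
def test_at_skew_examples(seq, expected):
    assert at_skew(seq) == pytest.approx(expected)


def test_at_skew_missing_when_no_at():
    assert at_skew("GGCC") is None


@pytest.mark.parametrize("seq,expected", [("GGCC", 0.0), ("GGGC", 0.5)])
def test_gc_skew_examples(seq, expected):
    assert gc_skew(seq) == pytest.approx(expected)


def test_gc_skew_missing_when_no_gc():
    assert gc_skew("AATT") is None


@pytest.mark.parametrize("seq,expected", [
    ("GTGT", 1.0), ("ACGT", 0.5), ("NNGA", 0.5),
])
def test_gt_content_examples(seq, expected):
    assert gt_content(seq) == pytest.approx(expected)


def test_gt_content_missing_on_empty():
    assert gt_content("NN--") is None


DNA = st.text(alphabet="ACGT", min_size=1, max_size=120)


@settings(max_examples=200, deadline=None)
@given(DNA)
def test_complement_identities(seq):
    rc = reverse_complement(seq)
    if at_skew(seq) is not None:
        assert at_skew(rc) == pytest.approx(-at_skew(seq))
    if gc_skew(seq) is not None:
        assert gc_skew(rc) == pytest.approx(-gc_skew(seq))
    assert gt_content(seq) + gt_content(rc) == pytest.approx(1.0)


@pytest.mark.parametrize("cds,expected", [
    ("TTTAAA", 0.5), ("GTA", 1.0), ("ATG", 0.0),
])
def test_gt_rich_codon_examples(cds, expected):
    assert gt_rich_codon_freq(cds) == pytest.approx(expected)


def test_gt_rich_disjunctive_reading_is_available():
    # ATG has G only at position 3 -> 0 either way; AGG has G at position 2
    assert gt_rich_codon_freq("AGG", conjunctive=False) == pytest.approx(1.0)
    assert gt_rich_codon_freq("AGG", conjunctive=True) == pytest.approx(0.0)
    assert gt_rich_codon_freq("NNNTTT") == pytest.approx(1.0)  # NNN dropped
    assert gt_rich_codon_freq("NNN") is None


@pytest.mark.parametrize("cds,code_id,expected", [
    ("GCTGCA", 1, 0.5),   # two Ala codons: third positions T, A
    ("GCTGCA", 5, 0.5),
    ("GGG", 1, 1.0),      # Gly family
])
def test_fourfold_gt3_examples(cds, code_id, expected):
    code = GeneticCode.from_table(code_id)
    assert fourfold_gt3(cds, code) == pytest.approx(expected)


def test_fourfold_gt3_missing_for_non_fourfold():
    assert fourfold_gt3("TTT", GeneticCode.from_table(1)) is None


def test_fourfold_families_differ_between_codes_1_and_5():
    """Mitochondrial reassignments change the derived four-fold family set."""
    f1 = GeneticCode.from_table(1).fourfold_prefixes
    f5 = GeneticCode.from_table(5).fourfold_prefixes
    assert f1 != f5
    # AGA/AGG are stops in the standard code but Ser in table 5,
    # joining AGC/AGT? (no - AGN encodes one residue only in table 5)
    assert "CT" in f1 and "GT" in f1 and "GC" in f1


def test_unassigned_region_extraction():
    ann = MockAnnotation(10, (("g", 3, 7, "+"),))
    assert unassigned_regions(ann) == [(1, 2), (8, 10)]
    full = MockAnnotation(10, (("a", 1, 6, "+"), ("b", 5, 10, "-")))
    assert unassigned_regions(full) == []
    overlap = MockAnnotation(10, (("a", 1, 5, "+"), ("b", 4, 8, "-")))
    assert unassigned_regions(overlap) == [(9, 10)]
    with pytest.raises(InvalidAnnotationError):
        unassigned_regions([("bad", 5, 20, "+")], genome_length=10)


def test_ur_gt_content():
    genome = "GGGGGAAAAA"
    ann = MockAnnotation(10, (("gene", 1, 5, "+"),))
    assert ur_gt_content(genome, ann) == pytest.approx(0.0)
    empty = MockAnnotation(10, ())
    assert ur_gt_content(genome, empty) == pytest.approx(gt_content(genome))
    covered = MockAnnotation(10, (("gene", 1, 10, "+"),))
    assert ur_gt_content(genome, covered) is None


def test_composition_table_shape_and_labels():
    cds = {"cox1": {"t1": "ATGGTT", "t2": "GTTGTA"}}
    table = composition_table(cds, {"t1": "CladeX"}, 5)
    assert len(table) == 2
    assert set(table.columns) >= {"taxon", "clade", "marker", "at_skew",
                                  "gc_skew", "gt_content",
                                  "gt_rich_codon_freq", "fourfold_gt3"}
    assert table.loc[table.taxon == "t2", "clade"].item() == "unassigned"
    empty = composition_table(cds, {}, 5, markers=[])
    assert empty.empty


@settings(max_examples=100, deadline=None)
@given(st.text(alphabet="ACGTN", min_size=3, max_size=90))
def test_statistics_respect_bounds(seq):
    seq = seq[:len(seq) - len(seq) % 3]
    if not seq:
        return
    for value, lo, hi in [
        (at_skew(seq), -1, 1), (gc_skew(seq), -1, 1),
        (gt_content(seq), 0, 1),
        (gt_rich_codon_freq(seq), 0, 1),
        (fourfold_gt3(seq, GeneticCode.from_table(5)), 0, 1),
    ]:
        if value is not None:
            assert lo <= value <= hi
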