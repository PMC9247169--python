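"""Strand and codon composition statistics.

AT/GC skew and G+T content measure the compositional asymmetry between the
two mitochondrial strands; the codon statistics (GT-rich codon frequency,
G+T at third positions of four-fold degenerate codons) separate the
mutational component visible at synonymous positions from the part that
reaches the protein.  Ambiguous bases and gaps never enter a numerator or a
denominator; a statistic whose denominator is empty is missing (``None``),
not zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import pandas as pd
from Bio.Data import CodonTable

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
STANDARD_BASES = frozenset("ACGT")


class InvalidAnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneticCode:
    """A codon table plus its derived four-fold degenerate codon families."""

    table_id: int
    forward: dict         # codon (DNA, upper) -> amino acid
    stop_codons: frozenset

    @classmethod
    @lru_cache(maxsize=None)
    def from_table(cls, table_id: int = 1) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(table_id, dict(t.forward_table), frozenset(t.stop_codons))

    @property
    def fourfold_prefixes(self) -> frozenset:
        """First-two-base prefixes whose four codons all encode one residue."""
        prefixes = set()
        for b1 in "ACGT":
            for b2 in "ACGT":
                aas = {self.forward.get(b1 + b2 + b3) for b3 in "ACGT"}
                if len(aas) == 1 and None not in aas:
                    prefixes.add(b1 + b2)
        return frozenset(prefixes)

    def is_fourfold(self, codon: str) -> bool:
        return codon[:2] in self.fourfold_prefixes


def _counts(seq: str) -> dict[str, int]:
    seq = seq.upper()
    return {b: seq.count(b) for b in "ACGT"}


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def at_skew(seq: str) -> float | None:
    """(A - T) / (A + T); ``None`` when no A or T is present."""
    c = _counts(seq)
    denom = c["A"] + c["T"]
    return None if denom == 0 else (c["A"] - c["T"]) / denom


def gc_skew(seq: str) -> float | None:
    """(G - C) / (G + C); ``None`` when no G or C is present."""
    c = _counts(seq)
    denom = c["G"] + c["C"]
    return None if denom == 0 else (c["G"] - c["C"]) / denom


def gt_content(seq: str) -> float | None:
    """(G + T) / (A + C + G + T) over unambiguous bases."""
    c = _counts(seq)
    denom = sum(c.values())
    return None if denom == 0 else (c["G"] + c["T"]) / denom


def _clean_codons(cds: str) -> list[str]:
    """In-frame codons after gap removal; ambiguous codons are dropped."""
    seq = cds.upper().replace("-", "").replace(".", "")
    if len(seq) % 3 != 0:
        raise ValueError("CDS length not divisible by 3 after gap removal")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    return [c for c in codons if set(c) <= STANDARD_BASES]


def gt_rich_codon_freq(cds: str, code: GeneticCode | None = None,
                       conjunctive: bool = True) -> float | None:
    """Fraction of codons with G or T at the first two positions.

    ``conjunctive=True`` (default) requires G/T at *both* positions; the
    disjunctive reading (G/T at either) is available behind the flag.
    """
    codons = _clean_codons(cds)
    if not codons:
        return None
    if conjunctive:
        hits = sum(1 for c in codons if c[0] in "GT" and c[1] in "GT")
    else:
        hits = sum(1 for c in codons if c[0] in "GT" or c[1] in "GT")
    return hits / len(codons)


def fourfold_gt3(cds: str, code: GeneticCode | None = None) -> float | None:
    """G+T fraction at third positions of four-fold degenerate codons."""
    code = code or GeneticCode.from_table(1)
    codons = [c for c in _clean_codons(cds) if code.is_fourfold(c)]
    if not codons:
        return None
    return sum(1 for c in codons if c[2] in "GT") / len(codons)


# ---------------------------------------------------------------------------
# unassigned regions


def unassigned_regions(annotation, genome_length: int | None = None
                       ) -> list[tuple[int, int]]:
    """1-based inclusive intervals not covered by any feature, any strand."""
    if genome_length is None:
        genome_length = annotation.genome_length
    features = getattr(annotation, "features", annotation)
    spans = []
    for feat in features:
        name, start, end = feat[0], int(feat[1]), int(feat[2])
        if not (1 <= start <= end <= genome_length):
            raise InvalidAnnotationError(
                f"feature {name!r} [{start}, {end}] exceeds genome bounds")
        spans.append((start, end))
    spans.sort()
    merged: list[list[int]] = []
    for start, end in spans:
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    urs = []
    prev_end = 0
    for start, end in merged:
        if start > prev_end + 1:
            urs.append((prev_end + 1, start - 1))
        prev_end = end
    if prev_end < genome_length:
        urs.append((prev_end + 1, genome_length))
    return urs


def ur_gt_content(genome: str, annotation) -> float | None:
    """G+T content of the concatenated unassigned regions (plus strand)."""
    urs = unassigned_regions(annotation, len(genome))
    joined = "".join(genome[s - 1:e] for s, e in urs)
    if not joined:
        return None
    return gt_content(joined)


# ---------------------------------------------------------------------------
# tidy profile


def composition_table(
    marker_cds: dict[str, dict[str, str]],
    taxon_clade: dict[str, str],
    code_assignments: dict[str, int] | int = 5,
    markers: list[str] | None = None,
) -> pd.DataFrame:
    """One row per taxon x marker with the five composition statistics.

    ``marker_cds`` maps marker -> taxon -> in-frame CDS.  ``markers``
    restricts the marker set (e.g. to the shared-strand set).  Taxa without
    a clade assignment are labeled ``unassigned`` and retained.
    """
    rows = []
    names = list(marker_cds) if markers is None else [m for m in markers
                                                      if m in marker_cds]
    for marker in names:
        table_id = (code_assignments if isinstance(code_assignments, int)
                    else code_assignments.get(marker, 1))
        code = GeneticCode.from_table(table_id)
        for taxon, cds in marker_cds[marker].items():
            rows.append({
                "taxon": taxon,
                "clade": taxon_clade.get(taxon, "unassigned"),
                "marker": marker,
                "at_skew": at_skew(cds),
                "gc_skew": gc_skew(cds),
                "gt_content": gt_content(cds),
                "gt_rich_codon_freq": gt_rich_codon_freq(cds, code),
                "fourfold_gt3": fourfold_gt3(cds, code),
            })
    columns = ["taxon", "clade", "marker", "at_skew", "gc_skew",
               "gt_content", "gt_rich_codon_freq", "fourfold_gt3"]
    return pd.DataFrame(rows, columns=columns)
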