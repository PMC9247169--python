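"""Alignment container plus FASTA and RAxML-style partition-file I/O.

Columns are 0-based half-open internally; partition files use the 1-based
inclusive convention (``NAME, marker = start-end``) and are converted at the
boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class AlignmentFormatError(ValueError):
    pass


@dataclass
class Alignment:
    """Rectangular character matrix with named rows and optional partitions.

    ``partitions`` maps a partition name to a 0-based half-open column range.
    """

    taxa: list[str]
    matrix: np.ndarray                      # (n_taxa, n_sites) of unicode chars
    alphabet: str = "aa"                    # "aa" | "nt"
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype="U1")
        if self.matrix.ndim != 2:
            raise AlignmentFormatError("matrix must be 2-D")
        if len(self.taxa) != self.matrix.shape[0]:
            raise AlignmentFormatError("row count does not match taxon count")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentFormatError(f"duplicate taxa: {', '.join(dupes)}")
        for name, (lo, hi) in self.partitions.items():
            if not (0 <= lo < hi <= self.n_sites):
                raise AlignmentFormatError(
                    f"partition {name!r} range ({lo}, {hi}) out of bounds")
        self._check_disjoint()

    def _check_disjoint(self):
        spans = sorted(self.partitions.values())
        for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
            if b_lo < a_hi:
                raise AlignmentFormatError("partition ranges overlap")

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, taxon: str) -> str:
        return "".join(self.matrix[self.taxa.index(taxon)])

    def site_partition_index(self) -> np.ndarray:
        """Per-site partition name ('' for unassigned sites)."""
        names = np.full(self.n_sites, "", dtype=object)
        for name, (lo, hi) in self.partitions.items():
            names[lo:hi] = name
        return names

    def subset_columns(self, lo: int, hi: int) -> "Alignment":
        return Alignment(list(self.taxa), self.matrix[:, lo:hi], self.alphabet)

    def partition_alignment(self, name: str) -> "Alignment":
        lo, hi = self.partitions[name]
        return self.subset_columns(lo, hi)

    @classmethod
    def from_sequences(cls, records: dict[str, str], alphabet: str = "aa",
                       partitions=None) -> "Alignment":
        taxa = list(records)
        lengths = {len(s) for s in records.values()}
        if len(lengths) > 1:
            raise AlignmentFormatError(
                f"ragged alignment: sequence lengths {sorted(lengths)}")
        matrix = np.array([list(s.upper()) for s in records.values()], dtype="U1")
        return cls(taxa, matrix, alphabet, dict(partitions or {}))

    @classmethod
    def concatenate(cls, parts: dict[str, "Alignment"]) -> "Alignment":
        """Concatenate same-taxa alignments into one partitioned matrix."""
        names = list(parts)
        first = parts[names[0]]
        taxa = list(first.taxa)
        blocks, spans, offset = [], {}, 0
        for name in names:
            aln = parts[name]
            if list(aln.taxa) != taxa:
                raise AlignmentFormatError("taxon sets differ between markers")
            blocks.append(aln.matrix)
            spans[name] = (offset, offset + aln.n_sites)
            offset += aln.n_sites
        return cls(taxa, np.concatenate(blocks, axis=1), first.alphabet, spans)


def read_fasta(path, alphabet: str = "aa") -> Alignment:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise AlignmentFormatError(f"duplicate taxon: {rec.id}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise AlignmentFormatError(f"no sequences in {path}")
    return Alignment.from_sequences(records, alphabet)


def write_fasta(aln: Alignment, path) -> None:
    recs = [SeqRecord(Seq(aln.sequence(t)), id=t, description="") for t in aln.taxa]
    SeqIO.write(recs, str(path), "fasta")


_PARTITION_RE = re.compile(
    r"^\s*(?:(?P<model>[^,]+)\s*,)?\s*(?P<name>\S+)\s*=\s*(?P<ranges>[\d\s,\-]+)\s*$")


def read_partitions(path) -> dict[str, tuple[int, int]]:
    """Parse a RAxML-style partition file into 0-based half-open ranges.

    Lines look like ``WAG, cox1 = 1-516``; the leading model token is
    optional and ignored.  Only single contiguous ranges are supported.
    """
    partitions: dict[str, tuple[int, int]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.strip().startswith("#"):
            continue
        m = _PARTITION_RE.match(line)
        if not m:
            raise AlignmentFormatError(f"unparseable partition line: {line!r}")
        name = m.group("name")
        ranges = m.group("ranges").strip()
        rm = re.fullmatch(r"(\d+)\s*-\s*(\d+)", ranges)
        if not rm:
            raise AlignmentFormatError(
                f"partition {name!r}: expected 'start-end', got {ranges!r}")
        start, end = int(rm.group(1)), int(rm.group(2))
        if start < 1 or end < start:
            raise AlignmentFormatError(f"bad range in partition {name!r}")
        if name in partitions:
            raise AlignmentFormatError(f"duplicate partition {name!r}")
        partitions[name] = (start - 1, end)
    return partitions


def write_partitions(partitions: dict[str, tuple[int, int]], path,
                     model_label: str = "PROT") -> None:
    lines = [f"{model_label}, {name} = {lo + 1}-{hi}"
             for name, (lo, hi) in partitions.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_table(path, columns: list[str]) -> list[dict]:
    """Small TSV reader (header optional) for marker/clade map files."""
    rows = []
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines:
        return rows
    first = lines[0].split("\t")
    start = 1 if [c.strip().lower() for c in first] == columns else 0
    for line in lines[start:]:
        parts = line.split("\t")
        if len(parts) < len(columns):
            raise AlignmentFormatError(f"short row in {path}: {line!r}")
        rows.append(dict(zip(columns, (p.strip() for p in parts))))
    return rows


def read_map(path, key: str, value: str) -> dict[str, str]:
    return {r[key]: r[value] for r in read_table(path, [key, value])}


def write_map(mapping: dict[str, str], path, key: str, value: str) -> None:
    lines = [f"{key}\t{value}"] + [f"{k}\t{v}" for k, v in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")
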