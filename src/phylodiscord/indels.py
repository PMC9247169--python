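"""Simple indel coding of gap runs as binary characters.

Every distinct maximal gap run (same start and end in at least one taxon)
becomes one presence/absence character: a taxon scores 1 when it has
exactly that gap, 0 when it has residues somewhere across the span and no
overlapping gap, and missing (``?``) when a different, overlapping gap
makes the character inapplicable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment

GAP = "-"


def _gap_runs(row: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of gaps in one sequence row, 0-based half-open."""
    is_gap = row == GAP
    if not is_gap.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], is_gap.view(np.int8), [0]])))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


@dataclass
class IndelCoding:
    """Binary gap characters: rows follow the source alignment's taxa."""

    taxa: list[str]
    characters: np.ndarray          # (n_taxa, n_characters) of '0' '1' '?'
    spans: list[tuple[int, int]]    # 0-based half-open column spans

    @property
    def n_characters(self) -> int:
        return self.characters.shape[1]

    def to_tsv(self, path):
        header = "taxon\t" + "\t".join(
            f"gap_{lo + 1}_{hi}" for lo, hi in self.spans)
        lines = [header]
        for i, t in enumerate(self.taxa):
            lines.append(t + "\t" + "\t".join(self.characters[i]))
        from pathlib import Path
        Path(path).write_text("\n".join(lines) + "\n")


def simple_indel_coding(aln: Alignment) -> IndelCoding:
    """Code every distinct gap run of the alignment as one binary character."""
    per_taxon = [_gap_runs(aln.matrix[i]) for i in range(aln.n_taxa)]
    spans = sorted({run for runs in per_taxon for run in runs})
    chars = np.full((aln.n_taxa, len(spans)), "0", dtype="U1")
    for i, runs in enumerate(per_taxon):
        run_set = set(runs)
        for j, (lo, hi) in enumerate(spans):
            if (lo, hi) in run_set:
                chars[i, j] = "1"
            elif any(r_lo < hi and lo < r_hi for r_lo, r_hi in runs):
                chars[i, j] = "?"
    return IndelCoding(list(aln.taxa), chars, spans)
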