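"""Multiple sequence alignment container with a designated reference row.

Positions throughout the pipeline are reported in reference numbering: the
1-based index among the *non-gap* characters of the reference sequence (for
the Ras family, human HRas), labelled with the reference residue, e.g. "Y32".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["MultipleAlignment", "read_alignment"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = set(AMINO_ACIDS) | {GAP, "X"}


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped rows keyed by identifier, plus a reference row."""

    rows: dict[str, str]
    reference_id: str
    ids: tuple[str, ...] = field(init=False)
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        rows = {k: v.upper() for k, v in self.rows.items()}
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows have unequal lengths")
        if self.reference_id not in rows:
            raise ValueError(f"reference {self.reference_id!r} not in alignment")
        bad = set("".join(rows.values())) - ALPHABET
        if bad:
            raise ValueError(f"unknown residue symbols in alignment: {sorted(bad)}")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "ids", tuple(rows))
        object.__setattr__(self, "length", lengths.pop())

    def __getitem__(self, seq_id: str) -> str:
        return self.rows[seq_id]

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered row pairs (the conservation background universe)."""
        ids = sorted(self.ids)
        return [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]

    def reference_columns(self) -> list[int]:
        """Column indices (0-based) where the reference row is non-gap."""
        ref = self.rows[self.reference_id]
        return [i for i, c in enumerate(ref) if c != GAP]

    def to_fasta(self) -> str:
        return "".join(f">{k}\n{v}\n" for k, v in self.rows.items())


def read_alignment(
    path: str | Path, reference_id: str, fmt: str = "fasta"
) -> MultipleAlignment:
    """Read an MSA (FASTA/Stockholm/any Bio.AlignIO format) with a reference row."""
    from Bio import AlignIO

    aln = AlignIO.read(str(path), fmt)
    rows = {rec.id: str(rec.seq) for rec in aln}
    if len(rows) != len(aln):
        raise ValueError("duplicate sequence identifiers in alignment")
    return MultipleAlignment(rows=rows, reference_id=reference_id)
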