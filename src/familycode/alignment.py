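"""Standardized residue coordinates for a TF family.

A family alignment (e.g. the 53-column bHLH domain alignment, or the
57-column homeodomain one) assigns every TF a gapped residue string over
a shared coordinate system, so that "residue position 13" means the same
structural position in every protein.  This module parses alignments,
provides the residue lookup a(f, r), and the sequence distances used by
cross-validation and the closest-paralog baseline.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import edlib
from Bio import AlignIO

__all__ = ["AlignedFamily", "load_alignment", "levenshtein"]

GAP = "-"


@dataclass(frozen=True)
class AlignedFamily:
    """Gapped protein alignment with 1-based standardized positions.

    ``raw_sequences`` optionally stores the unaligned (cloned) protein
    sequences used for Levenshtein distances; when absent, the ungapped
    alignment rows are used instead.
    """

    tf_ids: tuple[str, ...]
    rows: tuple[str, ...]
    raw_sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.tf_ids:
            raise ValueError("empty family")
        if len(self.tf_ids) != len(self.rows):
            raise ValueError("tf_ids and rows differ in length")
        if len(set(self.tf_ids)) != len(self.tf_ids):
            raise ValueError("duplicate tf_ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment rows (lengths {sorted(lengths)})")
        if self.length == 0:
            raise ValueError("zero-length alignment")
        object.__setattr__(self, "tf_ids", tuple(self.tf_ids))
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))
        object.__setattr__(
            self, "_index", {tf: i for i, tf in enumerate(self.tf_ids)}
        )

    @property
    def length(self) -> int:
        """Number of standardized residue positions (columns)."""
        return len(self.rows[0])

    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)

    def row(self, tf_id: str) -> str:
        try:
            return self.rows[self._index[tf_id]]
        except KeyError:
            raise KeyError(f"unknown TF {tf_id!r}") from None

    def residue_at(self, tf_id: str, r: int) -> str:
        """Amino acid (or gap) of ``tf_id`` at 1-based position ``r``."""
        if not 1 <= r <= self.length:
            raise IndexError(
                f"residue position {r} outside 1..{self.length}"
            )
        return self.row(tf_id)[r - 1]

    def column(self, r: int) -> tuple[str, ...]:
        """All residues in 1-based column ``r``, in tf_id order."""
        if not 1 <= r <= self.length:
            raise IndexError(f"residue position {r} outside 1..{self.length}")
        return tuple(row[r - 1] for row in self.rows)

    def sequence(self, tf_id: str) -> str:
        """Unaligned protein sequence (raw if provided, else ungapped row)."""
        if tf_id in self.raw_sequences:
            return self.raw_sequences[tf_id]
        return self.row(tf_id).replace(GAP, "")

    def hamming(self, f1: str, f2: str) -> int:
        """Aligned positions at which two TFs differ (gap is a character)."""
        r1, r2 = self.row(f1), self.row(f2)
        return sum(c1 != c2 for c1, c2 in zip(r1, r2))

    def subset(self, tf_ids) -> "AlignedFamily":
        tf_ids = tuple(tf_ids)
        rows = tuple(self.row(tf) for tf in tf_ids)
        raw = {tf: self.raw_sequences[tf] for tf in tf_ids if tf in self.raw_sequences}
        return AlignedFamily(tf_ids, rows, raw)

    def with_gap_columns(self, positions) -> "AlignedFamily":
        """Insert gap columns before the given 1-based positions.

        Used to reconcile alignments produced with different family
        profiles (e.g. adding two gap columns between positions 34 and
        35 of the bHLH alignment to match a pretrained weight vector).
        Positions refer to the current coordinate system; an index one
        past the last column appends at the end.
        """
        rows = list(self.rows)
        for pos in sorted(positions, reverse=True):
            if not 1 <= pos <= self.length + 1:
                raise IndexError(f"gap-column position {pos} out of range")
            rows = [r[: pos - 1] + GAP + r[pos - 1 :] for r in rows]
        return AlignedFamily(self.tf_ids, tuple(rows), dict(self.raw_sequences))


def _a2m_match_columns(records) -> AlignedFamily:
    # A2M: match states are uppercase letters and '-'; inserts are
    # lowercase and '.'.  Dropping inserts per sequence yields rows of
    # equal length over the match columns.
    ids, rows = [], []
    for rec in records:
        seq = str(rec.seq)
        rows.append("".join(c for c in seq if c.isupper() or c == GAP))
        ids.append(rec.id)
    return AlignedFamily(tuple(ids), tuple(rows))


def load_alignment(path, format: str = "aligned-fasta") -> AlignedFamily:
    """Load a family alignment (Stockholm, aligned FASTA, or A2M)."""
    path = pathlib.Path(path)
    if format == "stockholm":
        msa = AlignIO.read(str(path), "stockholm")
        return AlignedFamily(
            tuple(rec.id for rec in msa), tuple(str(rec.seq) for rec in msa)
        )
    if format == "aligned-fasta":
        msa = AlignIO.read(str(path), "fasta")
        return AlignedFamily(
            tuple(rec.id for rec in msa), tuple(str(rec.seq) for rec in msa)
        )
    if format == "a2m":
        from Bio import SeqIO

        return _a2m_match_columns(SeqIO.parse(str(path), "fasta"))
    raise ValueError(f"unknown alignment format {format!r}")


def levenshtein(s1: str, s2: str) -> int:
    """Unit-cost edit distance between two residue strings."""
    if not s1:
        return len(s2)
    if not s2:
        return len(s1)
    return edlib.align(s1, s2, task="distance")["editDistance"]
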