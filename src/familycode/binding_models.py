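"""DNA binding specificity models: energy matrices, PSAMs and seeds.

Two equivalent representations of a TF's base preference are used:

* :class:`EnergyMatrix` — ddG/RT penalties (dimensionless, in units of
  RT) relative to the preferred base at each binding-site position, so
  every row has minimum exactly 0.
* :class:`PSAM` — position-specific affinity matrix of relative
  affinities ``w = exp(-ddG/RT)`` in [0, 1], so every row has maximum
  exactly 1.

Columns are ordered A, C, G, T everywhere.  Binding frames are imposed
by aligning a model against an IUPAC consensus seed (e.g. NCANNTGN for
the bHLH E-box, NNTDAYNN for homeodomains) under the motif matching
score (MMS).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .tetra import BASES, TetraCloud, tetra_from_affinities

__all__ = [
    "embed_compendium",
    "EnergyMatrix",
    "PSAM",
    "IupacSeed",
    "IUPAC_CODES",
    "psam_from_energy",
    "energy_from_psam",
    "symmetrize_reverse_complement",
    "mms",
    "align_to_seed",
    "read_psam",
    "write_psam",
]

#: IUPAC nucleotide codes -> set of covered bases.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_ROW_TOL = 1e-9


def _check_matrix(values: np.ndarray, n_positions: int) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != 4:
        raise ValueError(f"expected an (n, 4) matrix, got shape {values.shape}")
    if values.shape[0] != n_positions:
        raise ValueError(
            f"{values.shape[0]} rows but {n_positions} position labels"
        )
    return values


@dataclass(frozen=True)
class EnergyMatrix:
    """Per-TF matrix of ddG/RT penalties (positions x bases A,C,G,T).

    The preferred base at each position carries 0; all entries are
    non-negative.  ``metadata`` may carry family/platform/replicate tags
    and a model-quality score.
    """

    tf_id: str
    position_labels: tuple[str, ...]
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        values = _check_matrix(self.values, len(self.position_labels))
        if np.any(values < -_ROW_TOL):
            raise ValueError("ddG/RT values must be non-negative")
        row_min = values.min(axis=1)
        if np.any(np.abs(row_min) > _ROW_TOL):
            raise ValueError(
                "every row of an energy matrix must have minimum 0 "
                "(preferred-base convention)"
            )
        values = np.clip(values, 0.0, None)
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "position_labels", tuple(self.position_labels))

    @property
    def n_positions(self) -> int:
        return len(self.position_labels)


@dataclass(frozen=True)
class PSAM:
    """Position-specific affinity matrix: relative affinities in [0, 1].

    Every row has maximum exactly 1 (the preferred base).
    """

    tf_id: str
    position_labels: tuple[str, ...]
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        values = _check_matrix(self.values, len(self.position_labels))
        if np.any(values < 0) or np.any(values > 1 + _ROW_TOL):
            raise ValueError("relative affinities must lie in [0, 1]")
        row_max = values.max(axis=1)
        if np.any(np.abs(row_max - 1.0) > _ROW_TOL):
            raise ValueError(
                "every row of a PSAM must have maximum 1 "
                "(preferred-base convention)"
            )
        values = np.clip(values, 0.0, 1.0)
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "position_labels", tuple(self.position_labels))

    @property
    def n_positions(self) -> int:
        return len(self.position_labels)


@dataclass(frozen=True)
class IupacSeed:
    """IUPAC consensus pattern with its 4 x L base-coverage indicator."""

    pattern: str
    indicator: np.ndarray = field(init=False)

    def __post_init__(self):
        pattern = self.pattern.upper()
        if not pattern:
            raise ValueError("empty IUPAC pattern")
        indicator = np.zeros((4, len(pattern)))
        for j, symbol in enumerate(pattern):
            try:
                covered = IUPAC_CODES[symbol]
            except KeyError:
                raise ValueError(f"invalid IUPAC symbol {symbol!r}") from None
            for b in covered:
                indicator[BASES.index(b), j] = 1.0
        indicator.setflags(write=False)
        object.__setattr__(self, "pattern", pattern)
        object.__setattr__(self, "indicator", indicator)

    def __len__(self) -> int:
        return len(self.pattern)


def psam_from_energy(E: EnergyMatrix) -> PSAM:
    """``w = exp(-ddG/RT)``; row maxima are 1 by the energy convention."""
    return PSAM(E.tf_id, E.position_labels, np.exp(-E.values), dict(E.metadata))


def energy_from_psam(P: PSAM, floor: float = 0.01) -> EnergyMatrix:
    """``ddG/RT = -ln w`` with affinities floored at ``floor`` first.

    Flooring keeps the log finite for bases with (near-)zero affinity;
    the preferred base (w = 1) maps to 0 exactly.
    """
    w = np.maximum(P.values, floor)
    return EnergyMatrix(P.tf_id, P.position_labels, -np.log(w), dict(P.metadata))


def reverse_complement(P: PSAM) -> PSAM:
    """PSAM read on the opposite strand: reverse positions, swap A<->T, C<->G."""
    values = P.values[::-1, ::-1]
    return PSAM(P.tf_id, tuple(reversed(P.position_labels)), values, dict(P.metadata))


def symmetrize_reverse_complement(P: PSAM) -> PSAM:
    """Impose reverse-complement symmetry on a palindromic-frame PSAM.

    The output is the geometric mean, in affinity space, of the PSAM and
    its reverse complement (equivalently the arithmetic mean of the
    ddG/RT parameters, matching the additive-energy convention), with
    each row renormalized to maximum 1.  The result is a fixed point of
    the operator and invariant under reverse complementation.
    """
    if P.n_positions % 2 != 0:
        raise ValueError(
            "reverse-complement symmetrization requires an even number of "
            f"positions, got {P.n_positions}"
        )
    rc = P.values[::-1, ::-1]
    sym = np.sqrt(P.values * rc)
    sym = sym / sym.max(axis=1, keepdims=True)
    return PSAM(P.tf_id, P.position_labels, sym, dict(P.metadata))


def mms(P: PSAM, seed: IupacSeed, offset: int, strand: str = "+") -> float:
    """Motif matching score of a seed window against a PSAM.

    For each seed position the squared distance ``(1 - w)^2`` to the
    best (highest-affinity) base covered by the IUPAC symbol is taken;
    MMS is the root mean of these over the seed length.  Zero means that
    at every seed position some covered base has relative affinity 1.

    ``offset`` indexes the window start within the chosen strand's
    matrix (the reverse complement of ``P`` for strand ``-``).
    """
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    values = P.values if strand == "+" else P.values[::-1, ::-1]
    J = len(seed)
    if offset < 0 or offset + J > values.shape[0]:
        raise ValueError(
            f"seed window [{offset}, {offset + J}) out of range for a "
            f"{values.shape[0]}-position model"
        )
    window = values[offset : offset + J]  # J x 4
    covered = seed.indicator.T.astype(bool)  # J x 4
    sq = (1.0 - window) ** 2
    per_position = np.where(covered, sq, np.inf).min(axis=1)
    return float(np.sqrt(per_position.mean()))


def align_to_seed(P: PSAM, seed: IupacSeed) -> PSAM:
    """Fix a binding frame: best seed-length window of ``P`` under MMS.

    All offsets on both strands are scored; the window minimizing the
    MMS is returned, trimmed to the seed length and relabeled with the
    seed's coordinates (D1..DJ).  Ties resolve to the smallest offset,
    then to the forward strand.
    """
    J = len(seed)
    if P.n_positions < J:
        raise ValueError(
            f"model has {P.n_positions} positions, shorter than the "
            f"{J}-position seed"
        )
    best = None
    for offset in range(P.n_positions - J + 1):
        for strand in "+-":
            score = mms(P, seed, offset, strand)
            key = (score, offset, 0 if strand == "+" else 1)
            if best is None or key < best[0]:
                best = (key, offset, strand)
    _, offset, strand = best
    values = P.values if strand == "+" else P.values[::-1, ::-1]
    window = values[offset : offset + J]
    window = window / window.max(axis=1, keepdims=True)
    labels = tuple(f"D{j + 1}" for j in range(J))
    meta = dict(P.metadata)
    meta.update(seed=seed.pattern, frame_offset=offset, frame_strand=strand)
    return PSAM(P.tf_id, labels, window, meta)


def embed_compendium(models: list[EnergyMatrix]) -> list[TetraCloud]:
    """Embed a compendium into one tetrahedral point cloud per DNA position.

    All models must share the same position labels; TF order follows the
    input list.
    """
    if not models:
        raise ValueError("empty compendium")
    labels = models[0].position_labels
    for m in models[1:]:
        if m.position_labels != labels:
            raise ValueError(
                f"position labels of {m.tf_id!r} ({m.position_labels}) do not "
                f"match {models[0].tf_id!r} ({labels})"
            )
    tf_ids = [m.tf_id for m in models]
    clouds = []
    for j, label in enumerate(labels):
        coords = np.array(
            [tetra_from_affinities(np.exp(-m.values[j])) for m in models]
        )
        clouds.append(TetraCloud(tf_ids, coords, dna_position=label))
    return clouds


# ---------------------------------------------------------------------------
# I/O: TSV ("pos A C G T") and MEME minimal motif format


def _parse_tsv(text: str, tf_id: str) -> PSAM:
    lines = text.splitlines()
    header_seen = False
    labels, rows = [], []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if not header_seen:
            if [f.strip() for f in fields] != ["pos", "A", "C", "G", "T"]:
                raise ValueError(
                    f"line {lineno}: expected header 'pos\\tA\\tC\\tG\\tT'"
                )
            header_seen = True
            continue
        if len(fields) != 5:
            raise ValueError(
                f"line {lineno}: expected 5 tab-separated fields, got {len(fields)}"
            )
        labels.append(fields[0])
        try:
            rows.append([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
    if not rows:
        raise ValueError("no data rows found")
    return PSAM(tf_id, tuple(labels), np.array(rows))


def _parse_meme_minimal(text: str, tf_id: str | None) -> PSAM:
    from Bio import motifs

    try:
        record = motifs.parse(io.StringIO(text), "minimal")
    except Exception as exc:
        raise ValueError(f"malformed MEME minimal file: {exc}") from None
    if not record:
        raise ValueError("no motifs found in MEME minimal file")
    motif = record[0]
    counts = np.array([motif.counts[b] for b in BASES]).T  # L x 4
    row_max = counts.max(axis=1, keepdims=True)
    if np.any(row_max <= 0):
        raise ValueError("motif contains an all-zero probability row")
    name = tf_id or motif.name or "motif"
    labels = tuple(str(j + 1) for j in range(counts.shape[0]))
    return PSAM(name, labels, counts / row_max)


def read_psam(path, format: str = "tsv", tf_id: str | None = None) -> PSAM:
    """Read a PSAM from a TSV table or a MEME minimal motif file.

    MEME probabilities are converted to relative affinities by dividing
    each row by its maximum.  For TSV the TF identifier defaults to the
    file stem.
    """
    import pathlib

    path = pathlib.Path(path)
    text = path.read_text()
    if format == "tsv":
        return _parse_tsv(text, tf_id or path.stem)
    if format == "meme-minimal":
        return _parse_meme_minimal(text, tf_id)
    raise ValueError(f"unknown PSAM format {format!r}")


def write_psam(P: PSAM, path, format: str = "tsv") -> None:
    """Write a PSAM as TSV or as a MEME minimal motif (frequencies)."""
    import pathlib

    path = pathlib.Path(path)
    if format == "tsv":
        lines = ["pos\tA\tC\tG\tT"]
        for label, row in zip(P.position_labels, P.values):
            lines.append(label + "\t" + "\t".join(repr(float(x)) for x in row))
        path.write_text("\n".join(lines) + "\n")
    elif format == "meme-minimal":
        freqs = P.values / P.values.sum(axis=1, keepdims=True)
        lines = [
            "MEME version 4",
            "",
            "ALPHABET= ACGT",
            "",
            "Background letter frequencies",
            "A 0.25 C 0.25 G 0.25 T 0.25",
            "",
            f"MOTIF {P.tf_id}",
            # large nsites: the minimal-format reader reconstructs counts
            # as round(p * nsites), so a small value would quantize rows
            f"letter-probability matrix: alength= 4 w= {P.n_positions} "
            "nsites= 1000000",
        ]
        for row in freqs:
            lines.append(" " + " ".join(f"{x:.6f}" for x in row))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown PSAM format {format!r}")
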