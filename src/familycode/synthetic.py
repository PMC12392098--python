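"""Synthetic TF families with known specificity determinants.

The generator emulates the statistical structure this package models: a
family alignment in which most residue columns are exchangeable noise,
while designated "determinant" columns carry amino acids whose identity
sets the mean tetrahedral position of the binding model at a designated
DNA position.  Every TF's point at a determinant position is its group
target plus isotropic Gaussian noise in embedding space (resampled to
stay inside the tetrahedron); non-determinant DNA positions scatter
around the tetrahedron centroid, i.e. near-uniform base preference.
Replicate pairs add Gaussian noise in energy space instead, mimicking
assay noise, and mutants swap a residue so the true dddG/RT shift is
known exactly from the group targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignedFamily
from .binding_models import EnergyMatrix
from .family_model import DddgMatrix
from .tetra import (
    VERTICES,
    frequencies_from_tetra,
    psam_column_from_tetra,
    shift_to_dddg,
)

__all__ = [
    "Determinant",
    "SyntheticFamilySpec",
    "GroundTruth",
    "make_family",
    "make_replicates",
    "make_mutant",
]

_INTERIOR_TOL = 1e-12


def _default_targets() -> dict[str, np.ndarray]:
    # three well-separated interior targets: preferences for C, G and T
    # (mirroring, e.g., Arg/Val/Met at bHLH residue 13)
    return {
        "R": 0.5 * VERTICES[1],
        "V": 0.5 * VERTICES[2],
        "M": 0.5 * VERTICES[3],
    }


@dataclass(frozen=True)
class Determinant:
    """One planted determinant: residue position -> DNA position link."""

    residue_position: int
    dna_position: int  # 1-based index into the DNA positions
    targets: dict[str, np.ndarray] = field(default_factory=_default_targets)

    def __post_init__(self):
        for aa, v in self.targets.items():
            v = np.asarray(v, dtype=float)
            if np.any(frequencies_from_tetra(v) < -_INTERIOR_TOL):
                raise ValueError(
                    f"target for amino acid {aa!r} lies outside the tetrahedron"
                )


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Parameters of a synthetic family.

    Defaults describe the standard benchmark family used throughout the
    test suite: 50 TFs over a 53-column (bHLH-length) alignment with 8
    DNA positions, a single determinant linking residue 13 to DNA
    position 3, and tight within-group noise (sd 0.05 in embedding
    space, whose scale is the tetrahedron of circumradius sqrt(3)).
    """

    n_tfs: int = 50
    alignment_length: int = 53
    n_dna_positions: int = 8
    determinants: tuple[Determinant, ...] = (Determinant(13, 3),)
    noise_sd: float = 0.05
    background_alphabet: str = "ACDEFGHIKLMNPQRSTVWY"
    background_frequencies: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_tfs < 1 or self.alignment_length < 1 or self.n_dna_positions < 1:
            raise ValueError("family dimensions must be positive")
        for det in self.determinants:
            if not 1 <= det.residue_position <= self.alignment_length:
                raise ValueError(
                    f"determinant residue {det.residue_position} outside "
                    f"1..{self.alignment_length}"
                )
            if not 1 <= det.dna_position <= self.n_dna_positions:
                raise ValueError(
                    f"determinant DNA position {det.dna_position} outside "
                    f"1..{self.n_dna_positions}"
                )
        if self.background_frequencies is not None and len(
            self.background_frequencies
        ) != len(self.background_alphabet):
            raise ValueError("background frequencies do not match the alphabet")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for scoring recovery."""

    spec: SyntheticFamilySpec
    dna_labels: tuple[str, ...]
    group_of: dict[str, dict[int, str]]  # tf -> {residue position -> aa}
    true_points: dict[str, np.ndarray]  # tf -> (n_dna_positions, 3)

    def determinant_cells(self) -> list[tuple[int, str]]:
        """(residue position, DNA label) of every planted determinant."""
        return [
            (d.residue_position, self.dna_labels[d.dna_position - 1])
            for d in self.spec.determinants
        ]

    def true_energy(self, tf_id: str, floor: float = 0.01) -> EnergyMatrix:
        """Noise-free-pipeline ddG/RT matrix for one TF's true points."""
        rows = []
        for v in self.true_points[tf_id]:
            w = psam_column_from_tetra(v, floor=floor)
            rows.append(-np.log(w / w.max()))
        return EnergyMatrix(tf_id, self.dna_labels, np.array(rows))

    def true_dddg(self, det: Determinant, aa_from: str, aa_to: str) -> DddgMatrix:
        """Planted dddG/RT for a group swap at one determinant."""
        values = np.zeros((len(self.dna_labels), 4))
        values[det.dna_position - 1] = shift_to_dddg(
            det.targets[aa_from], det.targets[aa_to]
        )
        return DddgMatrix(self.dna_labels, values)


def _sample_interior(rng, center: np.ndarray, sd: float, max_tries: int = 1000):
    if sd == 0:
        return center.copy()
    for _ in range(max_tries):
        point = center + rng.normal(scale=sd, size=3)
        if np.all(frequencies_from_tetra(point) >= -_INTERIOR_TOL):
            return point
    raise ValueError(
        f"could not sample an interior point around {center} with sd {sd} "
        f"after {max_tries} tries"
    )


def make_family(
    spec: SyntheticFamilySpec,
) -> tuple[AlignedFamily, list[EnergyMatrix], GroundTruth]:
    """Generate an aligned family, its binding-model compendium and truth.

    Residues are drawn i.i.d. from the background alphabet except at
    determinant columns, where group memberships are balanced across the
    target amino acids.  Binding models are the inverse-mapped PSAMs
    (affinity floor 0.01) of the noisy tetrahedral points, converted to
    ddG/RT.  The same spec and seed reproduce identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n, L, J = spec.n_tfs, spec.alignment_length, spec.n_dna_positions
    tf_ids = [f"TF{i + 1:03d}" for i in range(n)]
    dna_labels = tuple(f"D{j + 1}" for j in range(J))

    freqs = spec.background_frequencies
    if freqs is None:
        freqs = np.full(len(spec.background_alphabet), 1 / len(spec.background_alphabet))
    else:
        freqs = np.asarray(freqs, dtype=float)
        freqs = freqs / freqs.sum()
    alphabet = np.array(list(spec.background_alphabet))

    det_by_residue = {d.residue_position: d for d in spec.determinants}
    det_by_dna = {d.dna_position: d for d in spec.determinants}

    columns = []
    group_of: dict[str, dict[int, str]] = {tf: {} for tf in tf_ids}
    for r in range(1, L + 1):
        if r in det_by_residue:
            det = det_by_residue[r]
            aas = sorted(det.targets)
            assignment = [aas[i % len(aas)] for i in range(n)]
            rng.shuffle(assignment)
            for tf, aa in zip(tf_ids, assignment):
                group_of[tf][r] = aa
            columns.append(assignment)
        else:
            columns.append(list(rng.choice(alphabet, size=n, p=freqs)))
    rows = tuple("".join(columns[r][i] for r in range(L)) for i in range(n))
    fam = AlignedFamily(tuple(tf_ids), rows)

    origin = np.zeros(3)
    true_points: dict[str, np.ndarray] = {}
    compendium = []
    for i, tf in enumerate(tf_ids):
        points = np.empty((J, 3))
        for j in range(1, J + 1):
            if j in det_by_dna:
                det = det_by_dna[j]
                center = np.asarray(det.targets[group_of[tf][det.residue_position]])
            else:
                center = origin
            points[j - 1] = _sample_interior(rng, center, spec.noise_sd)
        true_points[tf] = points
        energy_rows = []
        for v in points:
            w = psam_column_from_tetra(v, floor=0.01)
            energy_rows.append(-np.log(w / w.max()))
        compendium.append(EnergyMatrix(tf, dna_labels, np.array(energy_rows)))

    truth = GroundTruth(
        spec=spec, dna_labels=dna_labels, group_of=group_of, true_points=true_points
    )
    return fam, compendium, truth


def make_replicates(
    compendium: list[EnergyMatrix], energy_noise_sd: float, seed: int = 0
) -> tuple[list[EnergyMatrix], list[EnergyMatrix]]:
    """Two noisy replicates of a compendium, mimicking assay noise.

    Independent Gaussian noise (sd ``energy_noise_sd``) is added to the
    ddG/RT values of the non-preferred bases of each row; the row is
    then re-anchored so its minimum is 0.
    """
    if energy_noise_sd < 0:
        raise ValueError("energy_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)

    def one(models):
        out = []
        for m in models:
            values = m.values.copy()
            for row in values:
                preferred = int(np.argmin(row))
                for b in range(4):
                    if b != preferred:
                        row[b] += rng.normal(scale=energy_noise_sd)
                row -= row.min()
            meta = dict(m.metadata)
            out.append(EnergyMatrix(m.tf_id, m.position_labels, values, meta))
        return out

    return one(compendium), one(compendium)


def make_mutant(
    fam: AlignedFamily,
    tf_id: str,
    mutation: tuple[int, str, str],
    truth: GroundTruth,
) -> tuple[str, DddgMatrix]:
    """Mutant residue string and the planted dddG/RT it should produce.

    A mutation at a determinant column between two target amino acids
    shifts the binding model by the vector between the group targets; a
    mutation at any background column has no planted effect.
    """
    r, aa_from, aa_to = mutation
    if not 1 <= r <= fam.length:
        raise IndexError(f"mutated position {r} outside 1..{fam.length}")
    row = fam.row(tf_id)
    if row[r - 1] != aa_from.upper():
        raise ValueError(
            f"{tf_id} has {row[r - 1]!r} at position {r}, not {aa_from!r}"
        )
    mutant = row[: r - 1] + aa_to.upper() + row[r:]

    for det in truth.spec.determinants:
        if det.residue_position == r:
            if aa_to.upper() not in det.targets:
                raise ValueError(
                    f"{aa_to!r} is not a planted group at determinant "
                    f"position {r}; the true shift is undefined"
                )
            return mutant, truth.true_dddg(det, aa_from.upper(), aa_to.upper())
    zeros = np.zeros((len(truth.dna_labels), 4))
    return mutant, DddgMatrix(truth.dna_labels, zeros)
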