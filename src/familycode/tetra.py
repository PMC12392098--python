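"""Reference-free tetrahedral embedding of base preference.

A single column of a position-specific affinity matrix (PSAM) holds four
relative affinities, one per base.  Normalizing them to frequencies and
multiplying by a fixed 4x3 vertex matrix maps the column to a Cartesian
point inside a regular tetrahedron whose vertices correspond to strict
preference for A, C, G and T.  The mapping is invertible, compresses the
biophysically meaningless variation among strongly disfavored bases
(large ddG/RT values all land near the same face), and turns differences
in specificity between two proteins into 3D shift vectors whose endpoint
can be mapped back to energy space as dddG/RT values.

Base order is A, C, G, T everywhere in this package.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "VERTICES",
    "BASES",
    "TetraCloud",
    "frequencies_from_affinities",
    "tetra_from_frequencies",
    "frequencies_from_tetra",
    "tetra_from_affinities",
    "psam_column_from_tetra",
    "is_interior",
    "regularize",
    "shift_to_dddg",
]

BASES = ("A", "C", "G", "T")

#: Tetrahedron vertices, one row per base (A, C, G, T).  Rows sum to the
#: zero vector; pairwise dot products are -1, self dot products are 3.
VERTICES = np.array(
    [
        [1.0, 1.0, 1.0],    # A
        [1.0, -1.0, -1.0],  # C
        [-1.0, 1.0, -1.0],  # G
        [-1.0, -1.0, 1.0],  # T
    ]
)

#: Default relative-affinity floor used when inverse-mapping points that
#: sit on or outside a face of the tetrahedron.
DEFAULT_FLOOR = 0.01

_INTERIOR_TOL = 1e-12


def frequencies_from_affinities(w: np.ndarray) -> np.ndarray:
    """Normalize a 4-vector of relative affinities to base frequencies.

    Parameters
    ----------
    w
        Relative affinities for bases A, C, G, T; non-negative, not all
        zero.

    Returns
    -------
    numpy.ndarray
        Frequencies summing to 1.
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (4,):
        raise ValueError(f"expected a 4-vector of affinities, got shape {w.shape}")
    if np.any(w < 0):
        raise ValueError("relative affinities must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("relative affinities are all zero; cannot normalize")
    return w / total


def tetra_from_frequencies(f: np.ndarray) -> np.ndarray:
    """Map a base-frequency 4-vector to a point in the tetrahedron.

    The point is ``f @ VERTICES``; one-hot frequency vectors land exactly
    on the corresponding vertex and the uniform vector on the origin.
    """
    f = np.asarray(f, dtype=float)
    return f @ VERTICES


def frequencies_from_tetra(v: np.ndarray) -> np.ndarray:
    """Invert the tetrahedral map: ``f_b = (1 + <v, t_b>) / 4``.

    Exact inverse of :func:`tetra_from_frequencies` for any frequency
    vector.  The result always sums to 1 but has negative entries when
    ``v`` lies outside the tetrahedron; that is the interiority test used
    throughout this module.
    """
    v = np.asarray(v, dtype=float)
    return (1.0 + VERTICES @ v) / 4.0


def tetra_from_affinities(w: np.ndarray) -> np.ndarray:
    """Affinity 4-vector -> frequencies -> tetrahedral point."""
    return tetra_from_frequencies(frequencies_from_affinities(w))


def is_interior(v: np.ndarray, tol: float = _INTERIOR_TOL) -> bool:
    """Whether ``v`` lies inside (or on the boundary of) the tetrahedron.

    A point is interior iff all four reconstructed frequencies are
    non-negative, up to ``tol`` of float noise.
    """
    return bool(np.all(frequencies_from_tetra(v) >= -tol))


def psam_column_from_tetra(v: np.ndarray, floor: float = DEFAULT_FLOOR) -> np.ndarray:
    """Inverse-map a tetrahedral point to a PSAM column.

    Frequencies are reconstructed, scaled so the preferred base has
    relative affinity 1, and any value below ``floor`` (including
    negative values from slightly exterior points) is set to ``floor``.

    Reconstructed frequencies always sum to 1, so the maximum is at
    least 1/4 for any input point and the scaling is always defined.
    """
    f = frequencies_from_tetra(v)
    w = f / f.max()
    return np.maximum(w, floor)


def _affinity_of_base(v: np.ndarray, base_index: int) -> float:
    """Relative affinity of one base at point ``v`` (w = f / max f)."""
    f = frequencies_from_tetra(v)
    return f[base_index] / f.max()


def regularize(
    v: np.ndarray,
    floor: float = DEFAULT_FLOOR,
    max_iter: int = 10,
    tol: float = 1e-10,
) -> np.ndarray:
    """Pull an exterior point back inside the tetrahedron.

    While any reconstructed frequency is negative, the point is moved
    along the straight line connecting it with the vertex of the
    least-preferred base (the most negative frequency) to where that
    line crosses the plane on which the base's relative affinity equals
    ``floor``.  The crossing is found by bisection on the line parameter
    to ``|w - floor| < tol``; moving toward the vertex raises the base's
    affinity monotonically from negative to 1, so the bracket is valid.
    The pass is repeated until the point is fully interior.

    Already-interior points are returned unchanged (the same array
    values; no copy is made in that case).
    """
    v = np.asarray(v, dtype=float)
    if is_interior(v):
        return v
    point = v.copy()
    for _ in range(max_iter):
        f = frequencies_from_tetra(point)
        if np.all(f >= -_INTERIOR_TOL):
            return point
        # ties for most negative frequency resolve in A,C,G,T order
        base = int(np.argmin(f))
        target = VERTICES[base]
        lo, hi = 0.0, 1.0  # w_base(0) < 0 < floor; w_base(1) = 1 > floor
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            w_mid = _affinity_of_base(point + mid * (target - point), base)
            if abs(w_mid - floor) < tol:
                lo = hi = mid
                break
            if w_mid < floor:
                lo = mid
            else:
                hi = mid
        lam = 0.5 * (lo + hi)
        point = point + lam * (target - point)
    if not is_interior(point):
        raise RuntimeError(
            f"regularization did not converge after {max_iter} iterations"
        )
    return point


class TetraCloud:
    """Embedded points for one DNA position across a set of TFs.

    Rows of ``coords`` (n x 3) align with ``tf_ids``.
    """

    def __init__(self, tf_ids, coords, dna_position: str = ""):
        self.tf_ids = tuple(tf_ids)
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.tf_ids), 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match "
                f"{len(self.tf_ids)} TFs"
            )
        self.coords = coords
        self.dna_position = dna_position

    def __len__(self) -> int:
        return len(self.tf_ids)

    def point(self, tf_id: str) -> np.ndarray:
        return self.coords[self.tf_ids.index(tf_id)]

    def to_tsv(self, path) -> None:
        import pathlib

        lines = ["tf_id\tx\ty\tz"]
        for tf, (x, y, z) in zip(self.tf_ids, self.coords):
            lines.append(f"{tf}\t{x!r}\t{y!r}\t{z!r}")
        pathlib.Path(path).write_text("\n".join(lines) + "\n")


def shift_to_dddg(
    v_ref: np.ndarray, v_alt: np.ndarray, floor: float = DEFAULT_FLOOR
) -> np.ndarray:
    """ddd G/RT 4-vector for the shift between two tetrahedral points.

    The shift vector ``v_alt - v_ref`` is placed at the origin and its
    endpoint inverse-mapped to frequencies (after regularization when the
    endpoint falls outside the tetrahedron).  Energies are reported as
    ``-ln(4 f_b)`` so that a null shift gives 0 for every base and
    opposite shifts give values of opposite sign.
    """
    endpoint = np.asarray(v_alt, dtype=float) - np.asarray(v_ref, dtype=float)
    endpoint = regularize(endpoint, floor=floor)
    f = frequencies_from_tetra(endpoint)
    # regularization guarantees f >= 0 with moved bases on the floor
    # plane; a zero frequency can only arise on the boundary, where the
    # floor already prevents it for moved bases.
    f = np.maximum(f, 1e-300)
    return -np.log(4.0 * f)
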