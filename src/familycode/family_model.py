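"""Family-level SVD regression of base preference on protein sequence.

For each DNA position, the tetrahedral points of all training TFs form
an n x 3 cloud.  The cloud is centered and decomposed by SVD, giving a
data-driven basis (principal components) for the variation in base
preference at that position.  For each principal component, residue
positions in the family alignment are ranked by one-way ANOVA of the PC
scores against amino-acid identity, and features are added greedily
while a nested-model F-test shows a significant gain.  A TF's feature
value is the mean PC score of the training TFs sharing its amino acid
at that residue position; during coefficient fitting the focal TF is
excluded from its own group mean, which keeps the encoding unbiased
under the null.  Amino acids unseen at a position fall back to a
BLOSUM62-weighted mean of the observed group means; gaps fall back to
the unweighted mean.

Predicted PC scores are mapped back through the basis to a tetrahedral
point and inverse-mapped to a PSAM.  Mutant effects (dddG/RT) are
predicted by refitting the regression with the mutated residue
positions as the only, mandatory features and taking the tetrahedral
shift between the mutant and wild-type predictions.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alignment import GAP, AlignedFamily
from .binding_models import EnergyMatrix, PSAM, embed_compendium, energy_from_psam
from .tetra import TetraCloud, psam_column_from_tetra, shift_to_dddg

__all__ = [
    "PositionModel",
    "FamilyCodeModel",
    "DddgMatrix",
    "center_and_svd",
    "rank_and_select_features",
    "load_blosum",
]


@dataclass(frozen=True)
class DddgMatrix:
    """Signed dddG/RT values (positions x bases A,C,G,T) for one mutant.

    Unlike :class:`~familycode.binding_models.EnergyMatrix`, rows are not
    anchored at zero: positive entries mean the mutant penalizes the base
    more than the wild type does, negative entries mean a gained
    preference.
    """

    position_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.position_labels), 4):
            raise ValueError(
                f"expected shape ({len(self.position_labels)}, 4), "
                f"got {values.shape}"
            )
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "position_labels", tuple(self.position_labels))

    @property
    def range(self) -> float:
        """Spread (max minus min) over all entries."""
        return float(self.values.max() - self.values.min())

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def load_blosum(path=None):
    """BLOSUM62 substitution matrix (Biopython), or one read from ``path``."""
    from Bio.Align import substitution_matrices

    if path is None:
        return substitution_matrices.load("BLOSUM62")
    return substitution_matrices.read(str(path))


def center_and_svd(M) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Column-center an n x 3 cloud and decompose it: ``M - mu = U D V^T``.

    Returns ``(U, D, V, mu)`` with the columns of ``V`` (the principal
    directions) sign-fixed so that each column's largest-magnitude entry
    is positive; ``U`` is flipped accordingly.  A cloud of identical
    points yields ``D = 0`` and the identity basis.
    """
    X = M.coords if isinstance(M, TetraCloud) else np.asarray(M, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) cloud, got shape {X.shape}")
    mu = X.mean(axis=0)
    C = X - mu
    scale = max(1.0, float(np.abs(X).max()))
    if np.all(np.abs(C) <= 1e-12 * scale):  # all points coincide
        return np.zeros_like(C), np.zeros(3), np.eye(3), mu
    U, D, Vt = np.linalg.svd(C, full_matrices=False)
    # C-contiguous copy: identical BLAS paths before and after a
    # serialization round-trip (the transpose view is F-ordered)
    V = np.ascontiguousarray(Vt.T)
    for k in range(V.shape[1]):
        if V[np.argmax(np.abs(V[:, k])), k] < 0:
            V[:, k] = -V[:, k]
            U[:, k] = -U[:, k]
    return U, D, V, mu


# ---------------------------------------------------------------------------
# group-mean encodings


def _group_stats(column: list[str], y: np.ndarray):
    """Per amino acid: (sum, count) of scores; gaps are left out."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for aa, val in zip(column, y):
        if aa == GAP:
            continue
        sums[aa] = sums.get(aa, 0.0) + float(val)
        counts[aa] = counts.get(aa, 0) + 1
    return sums, counts


def _blosum_fallback(aa: str, means: dict[str, float], blosum) -> float:
    """Mean of observed group means for an aa unseen at this position.

    Observed amino acids are weighted by the inverse of the BLOSUM62
    self-score minus cross-score difference, ``1 / (B[a,a] - B[a,a'])``;
    a non-positive difference gets the largest finite positive weight.
    Gaps, and symbols absent from the matrix, use the unweighted mean.
    """
    if not means:
        raise ValueError("no observed groups to fall back on")
    values = np.array(list(means.values()))
    alphabet = set(str(c) for c in blosum.alphabet)
    if aa == GAP or aa not in alphabet:
        return float(values.mean())
    diffs = np.array(
        [blosum[aa, aa] - blosum[aa, a2] for a2 in means], dtype=float
    )
    weights = np.full(len(diffs), np.nan)
    positive = diffs > 0
    weights[positive] = 1.0 / diffs[positive]
    if positive.any():
        weights[~positive] = weights[positive].max()
    else:
        weights[:] = 1.0
    return float((weights * values).sum() / weights.sum())


def _encode_training(column: list[str], y: np.ndarray, blosum) -> np.ndarray:
    """Leave-one-out group-mean encoding of one residue column.

    The focal TF is excluded from its own group mean; a TF that is the
    only carrier of its amino acid (or carries a gap) falls back as an
    unseen amino acid would.
    """
    sums, counts = _group_stats(column, y)
    means = {a: sums[a] / counts[a] for a in sums}
    x = np.empty(len(column))
    for i, (aa, val) in enumerate(zip(column, y)):
        if aa != GAP and counts.get(aa, 0) >= 2:
            x[i] = (sums[aa] - float(val)) / (counts[aa] - 1)
        else:
            others = {a: m for a, m in means.items() if a != aa}
            x[i] = _blosum_fallback(aa, others or means, blosum)
    return x


def _encode_query(aa: str, means: dict[str, float], blosum) -> float:
    """Full-sample group-mean encoding used at prediction time."""
    if aa in means:
        return means[aa]
    return _blosum_fallback(aa, means, blosum)


# ---------------------------------------------------------------------------
# feature ranking and forward selection


def _column_codes(column: list[str]):
    """Integer group coding of one residue column, gaps masked out."""
    mask = np.array([aa != GAP for aa in column])
    residues = [aa for aa in column if aa != GAP]
    levels = sorted(set(residues))
    index = {aa: i for i, aa in enumerate(levels)}
    codes = np.array([index[aa] for aa in residues], dtype=int)
    return mask, codes, len(levels)


def _anova_p(y: np.ndarray, mask: np.ndarray, codes: np.ndarray, g: int):
    """One-way ANOVA p-value via group bincounts; None when untestable."""
    yk = y[mask]
    n = yk.size
    if g < 2 or n - g < 1:
        return None
    counts = np.bincount(codes, minlength=g)
    sums = np.bincount(codes, weights=yk, minlength=g)
    means = sums / counts
    grand = yk.mean()
    ssb = float((counts * (means - grand) ** 2).sum())
    sst = float(((yk - grand) ** 2).sum())
    ssw = max(sst - ssb, 0.0)
    msb = ssb / (g - 1)
    msw = ssw / (n - g)
    if msw <= 0:
        return 1.0 if msb <= 0 else 0.0
    return float(stats.f.sf(msb / msw, g - 1, n - g))


def _ols(X: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ beta) ** 2).sum())
    return beta, rss, rank


def rank_and_select_features(
    y: np.ndarray,
    columns: dict[int, list[str]],
    blosum,
    alpha: float = 0.05,
    codes: dict[int, tuple] | None = None,
) -> tuple[list[int], np.ndarray]:
    """ANOVA-ranked greedy forward selection for one principal component.

    Parameters
    ----------
    y
        Centered PC scores of the training TFs.
    columns
        Residue position -> list of amino acids (one per TF, aligned
        with ``y``).
    alpha
        Nested-model F-test threshold for keeping a feature.

    Returns
    -------
    (selected, beta)
        Residue positions in inclusion order and their ordinary
        least-squares coefficients on the leave-one-out group-mean
        encodings.  Selection starts from the best-ranked feature and
        continues while the extra-sum-of-squares F-test for the added
        feature has p below ``alpha``; candidates that leave the design
        rank-deficient are skipped without stopping the scan.
    """
    n = len(y)
    if codes is None:
        codes = {r: _column_codes(column) for r, column in columns.items()}
    ranked: list[tuple[float, int]] = []
    for r in columns:
        mask, code, g = codes[r]
        p = _anova_p(y, mask, code, g)
        if p is not None and np.isfinite(p):
            ranked.append((p, r))
    ranked.sort()

    selected: list[int] = []
    X = np.empty((n, 0))
    rss = float((y**2).sum())
    rank = 0
    for _, r in ranked:
        if n - (len(selected) + 1) < 1:
            break
        x = _encode_training(columns[r], y, blosum)
        X_new = np.column_stack([X, x])
        beta_new, rss_new, rank_new = _ols(X_new, y)
        if rank_new <= rank:  # collinear with already-selected features
            continue
        df2 = n - X_new.shape[1]
        if rss_new <= 1e-300:
            p_add = 0.0
        else:
            F = (rss - rss_new) / (rss_new / df2)
            p_add = float(stats.f.sf(F, 1, df2)) if F > 0 else 1.0
        if p_add < alpha:
            selected.append(r)
            X, rss, rank = X_new, rss_new, rank_new
        else:
            break
    if not selected:
        return [], np.zeros(0)
    beta, _, _ = _ols(X, y)
    return selected, beta


# ---------------------------------------------------------------------------
# per-DNA-position model


@dataclass
class PositionModel:
    """Fitted SVD-regression model for one DNA position.

    ``basis`` holds the principal directions as columns; ``selected``,
    ``beta`` and ``group_means`` are per-PC (length 3), with
    ``group_means[c][r]`` mapping amino acid -> full-sample mean PC
    score used for prediction.
    """

    dna_position: str
    mu: np.ndarray
    basis: np.ndarray
    singular_values: np.ndarray
    selected: list[list[int]]
    beta: list[list[float]]
    group_means: list[dict[int, dict[str, float]]]
    coords: np.ndarray  # training cloud, for association plots / refits

    def scores(self) -> np.ndarray:
        """Training PC scores (projections of the centered cloud)."""
        return (self.coords - self.mu) @ self.basis

    def predict_scores(self, residues: str, blosum) -> np.ndarray:
        s = np.zeros(3)
        for c in range(3):
            for r, b in zip(self.selected[c], self.beta[c]):
                aa = residues[r - 1]
                s[c] += b * _encode_query(aa, self.group_means[c][r], blosum)
        return s

    def predict_point(self, residues: str, blosum) -> np.ndarray:
        return self.mu + self.basis @ self.predict_scores(residues, blosum)


# ---------------------------------------------------------------------------
# whole-family model


def _fingerprint(fam: AlignedFamily) -> str:
    payload = "\n".join(f"{tf}\t{row}" for tf, row in zip(fam.tf_ids, fam.rows))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class FamilyCodeModel:
    """Per-family collection of fitted :class:`PositionModel` objects."""

    family: str
    position_models: list[PositionModel]
    training_tf_ids: tuple[str, ...]
    training_rows: tuple[str, ...]
    alignment_fingerprint: str
    config: dict = field(default_factory=dict)
    _blosum: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self._blosum is None:
            self._blosum = load_blosum(self.config.get("blosum_path"))

    # -- fitting ----------------------------------------------------------

    @classmethod
    def fit(
        cls,
        compendium: list[EnergyMatrix],
        fam: AlignedFamily,
        family: str = "",
        selection_alpha: float = 0.05,
        affinity_floor: float = 0.01,
        blosum=None,
        clouds: list[TetraCloud] | None = None,
    ) -> "FamilyCodeModel":
        """Fit one SVD-regression model per DNA position.

        All TFs in the compendium must be present in the alignment and
        share position labels; at least 4 TFs are required.
        """
        if len(compendium) < 4:
            raise ValueError("need at least 4 TFs to fit a family model")
        for m in compendium:
            if m.tf_id not in fam.tf_ids:
                raise ValueError(f"TF {m.tf_id!r} missing from the alignment")
        if blosum is None:
            blosum = load_blosum()
        if clouds is None:
            clouds = embed_compendium(compendium)
        tf_ids = tuple(m.tf_id for m in compendium)
        rows = tuple(fam.row(tf) for tf in tf_ids)
        columns = {
            r: [row[r - 1] for row in rows] for r in range(1, fam.length + 1)
        }
        codes = {r: _column_codes(column) for r, column in columns.items()}
        position_models = []
        for cloud in clouds:
            U, D, V, mu = center_and_svd(cloud)
            S = (cloud.coords - mu) @ V
            selected, beta, gmeans = [], [], []
            for c in range(3):
                y = S[:, c]
                sel, b = rank_and_select_features(
                    y, columns, blosum, alpha=selection_alpha, codes=codes
                )
                selected.append(sel)
                beta.append(list(map(float, b)))
                tables = {}
                for r in sel:
                    sums, counts = _group_stats(columns[r], y)
                    tables[r] = {a: sums[a] / counts[a] for a in sums}
                gmeans.append(tables)
            position_models.append(
                PositionModel(
                    dna_position=cloud.dna_position,
                    mu=mu,
                    basis=V,
                    singular_values=D,
                    selected=selected,
                    beta=beta,
                    group_means=gmeans,
                    coords=cloud.coords.copy(),
                )
            )
        return cls(
            family=family,
            position_models=position_models,
            training_tf_ids=tf_ids,
            training_rows=rows,
            alignment_fingerprint=_fingerprint(fam),
            config=dict(
                selection_alpha=selection_alpha, affinity_floor=affinity_floor
            ),
            _blosum=blosum,
        )

    # -- prediction -------------------------------------------------------

    @property
    def position_labels(self) -> tuple[str, ...]:
        return tuple(pm.dna_position for pm in self.position_models)

    @property
    def alignment_length(self) -> int:
        return len(self.training_rows[0])

    def _check_seq(self, residues: str) -> str:
        residues = residues.upper()
        if len(residues) != self.alignment_length:
            raise ValueError(
                f"query has {len(residues)} residues; the family coordinate "
                f"system has {self.alignment_length}"
            )
        return residues

    def predict_psam(self, residues: str, tf_id: str = "prediction") -> PSAM:
        """Predicted PSAM for an aligned residue string.

        Each DNA position's predicted PC scores are mapped back through
        the basis to a tetrahedral point and inverse-mapped to a PSAM
        column, with affinities floored at the configured value.
        """
        residues = self._check_seq(residues)
        floor = self.config.get("affinity_floor", 0.01)
        rows = []
        for pm in self.position_models:
            v = pm.predict_point(residues, self._blosum)
            w = psam_column_from_tetra(v, floor=floor)
            rows.append(w / w.max())
        return PSAM(tf_id, self.position_labels, np.array(rows))

    def predict_energy(self, residues: str, tf_id: str = "prediction") -> EnergyMatrix:
        """Predicted ddG/RT matrix (natural log of the predicted PSAM)."""
        return energy_from_psam(
            self.predict_psam(residues, tf_id),
            floor=self.config.get("affinity_floor", 0.01),
        )

    def _apply_mutations(
        self, wt_residues: str, mutations: list[tuple[int, str, str]]
    ) -> tuple[str, str]:
        wt = self._check_seq(wt_residues)
        mut = list(wt)
        for r, aa_from, aa_to in mutations:
            if not 1 <= r <= self.alignment_length:
                raise IndexError(f"mutated position {r} out of range")
            if wt[r - 1] != aa_from.upper():
                raise ValueError(
                    f"wild-type sequence has {wt[r - 1]!r} at position {r}, "
                    f"not {aa_from!r}"
                )
            mut[r - 1] = aa_to.upper()
        return wt, "".join(mut)

    def predict_shift(
        self, wt_residues: str, mutations: list[tuple[int, str, str]]
    ) -> np.ndarray:
        """Predicted tetrahedral shift vectors, one 3-vector per DNA position.

        The regression is refit with the mutated residue positions as
        the only, mandatory features (no iterative selection) and the
        difference between the encoded mutant and wild-type predictions
        is returned.  The shift is linear in the feature encodings, so
        independently planted mutation effects combine additively here,
        before the non-linear inverse mapping to energy space.

        ``mutations`` is a list of ``(position, from_aa, to_aa)`` with
        1-based positions in family coordinates.
        """
        wt, mut = self._apply_mutations(wt_residues, mutations)
        shifts = np.zeros((len(self.position_models), 3))
        if not mutations:
            return shifts
        key_positions = sorted({r for r, _, _ in mutations})
        columns = {
            r: [row[r - 1] for row in self.training_rows] for r in key_positions
        }
        for j, pm in enumerate(self.position_models):
            S = pm.scores()
            for c in range(3):
                y = S[:, c]
                X_cols, used = [], []
                for r in key_positions:
                    x = _encode_training(columns[r], y, self._blosum)
                    X_try = np.column_stack(X_cols + [x]) if X_cols else x[:, None]
                    if np.linalg.matrix_rank(X_try) > len(X_cols):
                        X_cols.append(x)
                        used.append(r)
                if not used:
                    continue
                X = np.column_stack(X_cols)
                beta, _, _ = _ols(X, y)
                tables = {}
                for r in used:
                    sums, counts = _group_stats(columns[r], y)
                    tables[r] = {a: sums[a] / counts[a] for a in sums}
                delta = sum(
                    b
                    * (
                        _encode_query(mut[r - 1], tables[r], self._blosum)
                        - _encode_query(wt[r - 1], tables[r], self._blosum)
                    )
                    for r, b in zip(used, beta)
                )
                shifts[j] += delta * pm.basis[:, c]
        return shifts

    def predict_dddg(
        self, wt_residues: str, mutations: list[tuple[int, str, str]]
    ) -> DddgMatrix:
        """Predicted dddG/RT matrix for a set of point mutations.

        The tetrahedral shift from :meth:`predict_shift` is placed at
        the origin and inverse-mapped to energy space per DNA position
        (with regularization when a large shift's endpoint falls outside
        the tetrahedron).  The returned matrix holds signed dddG/RT
        values; its rows are not re-zeroed.
        """
        shifts = self.predict_shift(wt_residues, mutations)
        floor = self.config.get("affinity_floor", 0.01)
        values = np.array(
            [shift_to_dddg(np.zeros(3), shift, floor=floor) for shift in shifts]
        )
        return DddgMatrix(self.position_labels, values)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dict(
            family=self.family,
            training_tf_ids=list(self.training_tf_ids),
            training_rows=list(self.training_rows),
            alignment_fingerprint=self.alignment_fingerprint,
            config=self.config,
            position_models=[
                dict(
                    dna_position=pm.dna_position,
                    mu=pm.mu.tolist(),
                    basis=pm.basis.tolist(),
                    singular_values=pm.singular_values.tolist(),
                    selected=pm.selected,
                    beta=pm.beta,
                    group_means=[
                        {str(r): t for r, t in tables.items()}
                        for tables in pm.group_means
                    ],
                    coords=pm.coords.tolist(),
                )
                for pm in self.position_models
            ],
        )

    @classmethod
    def from_dict(cls, data: dict, blosum=None) -> "FamilyCodeModel":
        pms = [
            PositionModel(
                dna_position=d["dna_position"],
                mu=np.array(d["mu"]),
                basis=np.array(d["basis"]),
                singular_values=np.array(d["singular_values"]),
                selected=[list(map(int, sel)) for sel in d["selected"]],
                beta=[list(map(float, b)) for b in d["beta"]],
                group_means=[
                    {int(r): dict(t) for r, t in tables.items()}
                    for tables in d["group_means"]
                ],
                coords=np.array(d["coords"]),
            )
            for d in data["position_models"]
        ]
        return cls(
            family=data["family"],
            position_models=pms,
            training_tf_ids=tuple(data["training_tf_ids"]),
            training_rows=tuple(data["training_rows"]),
            alignment_fingerprint=data["alignment_fingerprint"],
            config=dict(data["config"]),
            _blosum=blosum,
        )

    def save(self, path) -> None:
        pathlib.Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path, blosum=None) -> "FamilyCodeModel":
        return cls.from_dict(
            json.loads(pathlib.Path(path).read_text()), blosum=blosum
        )


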