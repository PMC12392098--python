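"""Mapping protein-sequence determinants of base preference.

For every pair of a residue position in the family alignment and a DNA
position in the binding model, a one-way MANOVA asks whether TFs that
carry different amino acids at that residue occupy different mean
positions in the tetrahedral embedding of that DNA position.  The
resulting residue x DNA matrix of p-values localizes the family's
specificity-determining residues.  Per-principal-component one-way
ANOVAs provide the univariate analogue used for feature ranking in the
regression model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import GAP, AlignedFamily
from .binding_models import EnergyMatrix, embed_compendium
from .tetra import TetraCloud

__all__ = [
    "AssociationMap",
    "pillai_manova",
    "anova_per_pc",
    "group_centroids",
    "grouping_from_column",
    "scan_associations",
]


def pillai_manova(groups, points) -> tuple[float, float, float, float, float]:
    """One-way MANOVA via the Pillai-Bartlett trace.

    Parameters
    ----------
    groups
        One categorical label per observation.
    points
        Observations, either a :class:`~familycode.tetra.TetraCloud` or
        an (n, p) array.

    Returns
    -------
    (V, F, df1, df2, p)
        Pillai trace ``V = tr(H (H + E)^-1)`` with H/E the between- and
        within-group sum-of-squares-and-cross-products matrices, the
        standard F approximation with ``s = min(p, g - 1)``, its degrees
        of freedom, and the upper-tail p-value.  The null hypothesis is
        that all group mean vectors coincide.
    """
    X = points.coords if isinstance(points, TetraCloud) else np.asarray(points, float)
    groups = np.asarray(groups)
    if X.ndim != 2:
        raise ValueError("points must be a 2-D array")
    if len(groups) != X.shape[0]:
        raise ValueError("group labels and points differ in length")
    labels = pd.unique(groups)
    g = len(labels)
    if g < 2:
        raise ValueError("MANOVA requires at least 2 groups")
    n, p = X.shape
    if n - g < 1:
        raise ValueError("no residual degrees of freedom")
    grand = X.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for lab in labels:
        Xg = X[groups == lab]
        mg = Xg.mean(axis=0)
        d = (mg - grand)[:, None]
        H += len(Xg) * (d @ d.T)
        R = Xg - mg
        E += R.T @ R
    T = H + E
    # scale-aware singularity check before inverting H + E
    if np.linalg.matrix_rank(T, tol=1e-12 * max(np.trace(T), 1.0)) < p:
        raise np.linalg.LinAlgError("singular total SSCP matrix (H + E)")
    V = float(np.trace(H @ np.linalg.inv(T)))
    s = min(p, g - 1)
    m = (abs(p - g + 1) - 1) / 2.0
    nn = (n - g - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom for the Pillai F test")
    if s - V <= 1e-12:
        return V, float("inf"), df1, df2, 0.0
    F = (df2 / df1) * (V / (s - V))
    pval = float(stats.f.sf(F, df1, df2))
    return V, float(F), df1, df2, pval


def anova_per_pc(u, groups) -> tuple[float, float]:
    """One-way ANOVA of scalar scores against a categorical grouping.

    Returns the F statistic and p-value.  Groups of size 1 are allowed
    (they contribute to the between-group but not the within-group sum
    of squares); at least 2 groups and one residual degree of freedom
    are required.
    """
    u = np.asarray(u, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    g = len(labels)
    n = len(u)
    if g < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    if n - g < 1:
        raise ValueError("no residual degrees of freedom")
    grand = u.mean()
    ssb = 0.0
    ssw = 0.0
    for lab in labels:
        ug = u[groups == lab]
        ssb += len(ug) * (ug.mean() - grand) ** 2
        ssw += ((ug - ug.mean()) ** 2).sum()
    msb = ssb / (g - 1)
    msw = ssw / (n - g)
    if msw <= 0:
        if msb <= 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = msb / msw
    return float(F), float(stats.f.sf(F, g - 1, n - g))


def group_centroids(points, groups) -> dict:
    """Arithmetic mean coordinates per group; empty groups are excluded."""
    X = points.coords if isinstance(points, TetraCloud) else np.asarray(points, float)
    groups = np.asarray(groups)
    return {
        lab: X[groups == lab].mean(axis=0) for lab in pd.unique(groups)
    }


def grouping_from_column(column, min_gap_group: int = 2):
    """Group labels (and eligibility mask) from one alignment column.

    Amino acids form one group each, including singletons.  Gap
    characters form their own group only when at least ``min_gap_group``
    TFs share the gap; otherwise those TFs are excluded from the cell.
    """
    column = np.asarray(list(column))
    keep = np.ones(len(column), dtype=bool)
    n_gap = int((column == GAP).sum())
    if 0 < n_gap < min_gap_group:
        keep = column != GAP
    return column, keep


@dataclass
class AssociationMap:
    """Residue-position x DNA-position matrix of MANOVA results.

    Cells with fewer than 2 eligible groups or no residual degrees of
    freedom hold NaN.  ``n_tests`` counts the non-NaN cells used for the
    Bonferroni correction.
    """

    residue_positions: tuple[int, ...]
    dna_positions: tuple[str, ...]
    p_values: np.ndarray
    f_stats: np.ndarray
    pillai_traces: np.ndarray
    n_groups: np.ndarray
    bonferroni_alpha: float = 0.001

    @property
    def n_tests(self) -> int:
        return int(np.sum(~np.isnan(self.p_values)))

    def p_bonferroni(self) -> np.ndarray:
        return np.minimum(self.p_values * self.n_tests, 1.0)

    def significant(self) -> np.ndarray:
        """Boolean mask of cells with Bonferroni-corrected p below alpha."""
        with np.errstate(invalid="ignore"):
            return self.p_bonferroni() < self.bonferroni_alpha

    def best_cell(self) -> tuple[int, str]:
        """(residue position, DNA position) of the smallest p-value."""
        masked = np.where(np.isnan(self.p_values), np.inf, self.p_values)
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        return self.residue_positions[i], self.dna_positions[j]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (residue, DNA position) cell."""
        records = []
        p_bonf = self.p_bonferroni()
        for i, r in enumerate(self.residue_positions):
            for j, d in enumerate(self.dna_positions):
                records.append(
                    dict(
                        residue=r,
                        dna_position=d,
                        pillai=self.pillai_traces[i, j],
                        F=self.f_stats[i, j],
                        n_groups=self.n_groups[i, j],
                        p=self.p_values[i, j],
                        p_bonferroni=p_bonf[i, j],
                    )
                )
        return pd.DataFrame.from_records(records)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def scan_associations(
    compendium: list[EnergyMatrix],
    fam: AlignedFamily,
    alpha: float = 0.001,
    clouds: list[TetraCloud] | None = None,
) -> AssociationMap:
    """MANOVA scan over all (residue position, DNA position) pairs.

    Every model in the compendium must be present in the alignment and
    share position labels.  Cells whose grouping leaves fewer than 2
    groups, or no residual degrees of freedom, are NaN.
    """
    for m in compendium:
        if m.tf_id not in fam.tf_ids:
            raise ValueError(f"TF {m.tf_id!r} missing from the alignment")
    if clouds is None:
        clouds = embed_compendium(compendium)
    tf_ids = [m.tf_id for m in compendium]
    L = fam.length
    J = len(clouds)
    shape = (L, J)
    p_values = np.full(shape, np.nan)
    f_stats = np.full(shape, np.nan)
    pillai = np.full(shape, np.nan)
    n_groups = np.zeros(shape, dtype=int)
    for i in range(L):
        column = [fam.residue_at(tf, i + 1) for tf in tf_ids]
        labels, keep = grouping_from_column(column)
        eligible = labels[keep]
        g = len(pd.unique(eligible))
        if g < 2 or keep.sum() - g < 1:
            continue
        for j, cloud in enumerate(clouds):
            n_groups[i, j] = g
            try:
                V, F, _, _, p = pillai_manova(eligible, cloud.coords[keep])
            except (ValueError, np.linalg.LinAlgError):
                continue
            pillai[i, j] = V
            f_stats[i, j] = F
            p_values[i, j] = p
    return AssociationMap(
        residue_positions=tuple(range(1, L + 1)),
        dna_positions=tuple(c.dna_position for c in clouds),
        p_values=p_values,
        f_stats=f_stats,
        pillai_traces=pillai,
        n_groups=n_groups,
        bonferroni_alpha=alpha,
    )
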