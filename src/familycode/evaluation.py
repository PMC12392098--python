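"""Baseline predictors, cross-validation harnesses and metrics.

Two transfer baselines are provided for comparison with the family
model: *closest paralog* (copy the binding model of the training TF
with the smallest Levenshtein distance) and *similarity regression*
(select the training TF maximizing a per-position identity profile
weighted by a pretrained coefficient vector).  Leave-one-out
cross-validation, optionally with a Hamming-distance exclusion
threshold to control information leakage, scores any of the methods on
held-out ddG/RT values.  The statistics used for method comparison
(paired bootstrap of squared errors, Wilcoxon signed-rank test,
hypergeometric enrichment) and the EMSA band-intensity free-energy
estimate live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import AlignedFamily, levenshtein
from .binding_models import EnergyMatrix
from .family_model import FamilyCodeModel

__all__ = [
    "EvalReport",
    "r2",
    "rmsd",
    "replicate_concordance",
    "dddg_range",
    "effect_enrichment",
    "compare_methods",
    "emsa_ddg",
    "closest_paralog",
    "similarity_regression_predict",
    "loocv",
]


# ---------------------------------------------------------------------------
# metrics


def r2(pred, obs) -> float:
    """Coefficient of determination about the observed mean.

    ``1 - SS_res / SS_tot``; NaN when the observations have zero
    variance (the statistic is undefined there).
    """
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.shape != obs.shape:
        raise ValueError("pred and obs differ in length")
    if len(obs) < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0:
        return float("nan")
    ss_res = float(((obs - pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def rmsd(pred, obs) -> float:
    """Root-mean-squared deviation between two equal-length vectors."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.shape != obs.shape:
        raise ValueError("pred and obs differ in length")
    return float(np.sqrt(((pred - obs) ** 2).mean()))


def replicate_concordance(
    modelA: EnergyMatrix, modelB: EnergyMatrix
) -> tuple[float, float]:
    """(R^2, RMSD) between two replicate ddG/RT models, over all entries."""
    if modelA.position_labels != modelB.position_labels:
        raise ValueError(
            f"position labels differ: {modelA.position_labels} vs "
            f"{modelB.position_labels}"
        )
    return r2(modelA.values, modelB.values), rmsd(modelA.values, modelB.values)


def dddg_range(dddg) -> float:
    """Spread (max minus min) of a dddG/RT matrix over all entries."""
    values = getattr(dddg, "values", dddg)
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty dddG/RT matrix")
    return float(values.max() - values.min())


def effect_enrichment(classifications, ranges, threshold: float = 1.0) -> float:
    """Hypergeometric enrichment of large dddG/RT ranges among changers.

    ``classifications`` labels each mutant as specificity-changing
    (truthy / ``"change"``) or not; ``ranges`` are the matching dddG/RT
    spreads.  Returns the upper-tail probability that at least the
    observed number of mutants with range above ``threshold`` fall in
    the changing class.  Degenerate tables (no changers, or no mutant
    above threshold) return 1.
    """
    labels = np.array(
        [c == "change" if isinstance(c, str) else bool(c) for c in classifications]
    )
    ranges = np.asarray(ranges, dtype=float)
    if labels.shape != ranges.shape:
        raise ValueError("classifications and ranges differ in length")
    M = len(labels)
    K = int(labels.sum())
    big = ranges > threshold
    n = int(big.sum())
    k = int((labels & big).sum())
    if K == 0 or K == M or n == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def compare_methods(
    errsA,
    errsB,
    mode: str = "bootstrap-t",
    seed: int = 0,
    n_boot: int = 10_000,
) -> float:
    """Paired two-sided test that two methods' errors differ.

    ``bootstrap-t`` resamples the paired differences of squared errors
    ``n_boot`` times (seeded), recenters them under the null, and
    returns the fraction of resampled t statistics at least as extreme
    as the observed one.  ``wilcoxon`` is the paired signed-rank test on
    the raw error pairs.  Identical error vectors give p = 1.
    """
    a = np.asarray(errsA, dtype=float).ravel()
    b = np.asarray(errsB, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("error vectors differ in length")
    if len(a) < 5:
        raise ValueError("need at least 5 paired errors")
    if np.allclose(a, b):
        return 1.0
    if mode == "wilcoxon":
        return float(stats.wilcoxon(a, b).pvalue)
    if mode != "bootstrap-t":
        raise ValueError(f"unknown mode {mode!r}")
    d = a**2 - b**2
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        return 1.0
    t_obs = d.mean() / (sd / np.sqrt(n))
    rng = np.random.default_rng(seed)
    centered = d - d.mean()
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = centered[idx]
    means = samples.mean(axis=1)
    sds = samples.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = np.where(sds > 0, means / (sds / np.sqrt(n)), 0.0)
    extreme = int((np.abs(t_null) >= abs(t_obs)).sum())
    return (extreme + 1) / (n_boot + 1)


def emsa_ddg(
    bound_ref: float, unbound_ref: float, bound_alt: float, unbound_alt: float
) -> float:
    """Free-energy difference from EMSA band intensities.

    ``ln[(bound_ref/unbound_ref) / (bound_alt/unbound_alt)]`` — the log
    ratio of bound/unbound intensity ratios between two probes (e.g.
    CACGTG vs CAGCTG lanes).
    """
    intensities = (bound_ref, unbound_ref, bound_alt, unbound_alt)
    if any(x <= 0 for x in intensities):
        raise ValueError("band intensities must be positive")
    return float(
        np.log((bound_ref / unbound_ref) / (bound_alt / unbound_alt))
    )


# ---------------------------------------------------------------------------
# baselines


def closest_paralog(
    test_seq: str, compendium: list[EnergyMatrix], fam: AlignedFamily
) -> EnergyMatrix:
    """Binding model of the training TF nearest in Levenshtein distance.

    Distances are computed on unaligned protein sequences; exact ties
    resolve to the lexicographically smallest tf_id.
    """
    if not compendium:
        raise ValueError("empty training set")
    best = min(
        compendium,
        key=lambda m: (levenshtein(test_seq, fam.sequence(m.tf_id)), m.tf_id),
    )
    return best


def similarity_regression_predict(
    test_row: str,
    weights,
    compendium: list[EnergyMatrix],
    fam: AlignedFamily,
    direction: str = "max",
    gap_columns=None,
) -> EnergyMatrix:
    """Transfer the model of the best neighbor under pretrained weights.

    Each training TF is scored as the weight-vector dot product with the
    per-position identity profile (1 where the aligned residues match
    the query, 0 elsewhere).  ``direction="max"`` selects the highest
    weighted identity (the default); ``"min"`` the lowest.  When the
    weight vector was trained on a longer family profile, ``gap_columns``
    inserts gap columns (1-based) into the alignment rows first.
    """
    if not compendium:
        raise ValueError("empty training set")
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    weights = np.asarray(weights, dtype=float)
    work_fam = fam.with_gap_columns(gap_columns) if gap_columns else fam
    test = test_row
    if gap_columns:
        for pos in sorted(gap_columns, reverse=True):
            test = test[: pos - 1] + "-" + test[pos - 1 :]
    if len(weights) != work_fam.length:
        raise ValueError(
            f"weight vector has {len(weights)} positions but the alignment "
            f"has {work_fam.length}; check the gap-column configuration "
            "(gap_columns) used to reconcile the two coordinate systems"
        )

    def score(m: EnergyMatrix) -> float:
        row = work_fam.row(m.tf_id)
        identity = np.fromiter(
            (1.0 if c1 == c2 else 0.0 for c1, c2 in zip(test, row)),
            dtype=float,
            count=len(test),
        )
        return float(weights @ identity)

    sign = -1.0 if direction == "max" else 1.0
    best = min(compendium, key=lambda m: (sign * score(m), m.tf_id))
    return best


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class EvalReport:
    """Per-TF and pooled prediction metrics from cross-validation."""

    method: str
    threshold: float | None
    per_tf: pd.DataFrame
    aggregate_r2: float
    aggregate_rmsd: float
    evaluated_positions: tuple[str, ...] = ()
    skipped: tuple[str, ...] = field(default_factory=tuple)

    def to_tsv(self, path) -> None:
        frame = self.per_tf.copy()
        summary = pd.DataFrame(
            [
                dict(
                    tf_id="(aggregate)",
                    r2=self.aggregate_r2,
                    rmsd=self.aggregate_rmsd,
                    n=frame["n"].sum() if len(frame) else 0,
                )
            ]
        )
        pd.concat([frame, summary], ignore_index=True).to_csv(
            path, sep="\t", index=False
        )


def _position_indices(labels, positions):
    if positions is None:
        return list(range(len(labels)))
    indices = []
    for p in positions:
        if p not in labels:
            raise ValueError(f"evaluated DNA position {p!r} not in model labels")
        indices.append(labels.index(p))
    return indices


def loocv(
    compendium: list[EnergyMatrix],
    fam: AlignedFamily,
    method: str = "familycode",
    threshold: int | None = None,
    positions=None,
    weights=None,
    gap_columns=None,
    selection_alpha: float = 0.05,
) -> EvalReport:
    """Leave-one-out cross-validation of a specificity predictor.

    Each TF in turn is held out; the remaining TFs (minus any whose
    Hamming distance to the held-out TF is below ``threshold``) form
    the training set for ``method`` (``"familycode"``,
    ``"closest-paralog"``, ``"similarity-regression"``, or a callable
    ``(train_compendium, fam, test_tf_id) -> EnergyMatrix``).  Metrics
    are computed on the ddG/RT entries of the evaluated DNA positions
    (all positions by default), both per TF and pooled across TFs.
    TFs whose training set becomes empty (or too small to fit) are
    reported in ``skipped``.
    """
    if len(compendium) < 5:
        raise ValueError("leave-one-out needs at least 5 TFs")
    labels = compendium[0].position_labels
    idx = _position_indices(list(labels), positions)

    def predict(train, test_tf):
        if callable(method):
            return method(train, fam, test_tf)
        if method == "familycode":
            model = FamilyCodeModel.fit(
                train, fam, selection_alpha=selection_alpha
            )
            return model.predict_energy(fam.row(test_tf), tf_id=test_tf)
        if method == "closest-paralog":
            return closest_paralog(fam.sequence(test_tf), train, fam)
        if method == "similarity-regression":
            if weights is None:
                raise ValueError("similarity regression requires a weight vector")
            return similarity_regression_predict(
                fam.row(test_tf), weights, train, fam, gap_columns=gap_columns
            )
        raise ValueError(f"unknown method {method!r}")

    records = []
    skipped = []
    pooled_pred, pooled_obs = [], []
    for held_out in compendium:
        test_tf = held_out.tf_id
        train = [m for m in compendium if m.tf_id != test_tf]
        if threshold is not None:
            train = [
                m for m in train if fam.hamming(test_tf, m.tf_id) >= threshold
            ]
        min_train = 4 if method == "familycode" else 1
        if len(train) < min_train:
            skipped.append(test_tf)
            continue
        pred = predict(train, test_tf)
        pred_vals = pred.values[idx].ravel()
        obs_vals = held_out.values[idx].ravel()
        pooled_pred.append(pred_vals)
        pooled_obs.append(obs_vals)
        records.append(
            dict(
                tf_id=test_tf,
                r2=r2(pred_vals, obs_vals),
                rmsd=rmsd(pred_vals, obs_vals),
                n=len(obs_vals),
            )
        )
    per_tf = pd.DataFrame.from_records(
        records, columns=["tf_id", "r2", "rmsd", "n"]
    )
    if pooled_pred:
        pooled_pred = np.concatenate(pooled_pred)
        pooled_obs = np.concatenate(pooled_obs)
        agg_r2 = r2(pooled_pred, pooled_obs)
        agg_rmsd = rmsd(pooled_pred, pooled_obs)
    else:
        agg_r2 = float("nan")
        agg_rmsd = float("nan")
    return EvalReport(
        method=method if isinstance(method, str) else getattr(method, "__name__", "custom"),
        threshold=threshold,
        per_tf=per_tf,
        aggregate_r2=agg_r2,
        aggregate_rmsd=agg_rmsd,
        evaluated_positions=tuple(labels[i] for i in idx),
        skipped=tuple(skipped),
    )
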