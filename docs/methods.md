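# Methods

This note documents the models implemented in `familycode`, the numerical
conventions they rely on, and what the synthetic benchmark does and does
not establish.

## Representations and conventions

A TF's specificity is a matrix over binding-site positions × bases
(A, C, G, T — this column order is fixed everywhere). Two equivalent
forms are used: ΔΔG/RT penalties (row minimum exactly 0 at the preferred
base, all entries ≥ 0) and the PSAM of relative affinities
w = exp(−ΔΔG/RT) (row maximum exactly 1). Conversions floor affinities at
0.01 before taking logarithms, so ΔΔG/RT values are capped at
−ln 0.01 ≈ 4.6; penalties beyond that are not biophysically resolvable
from binding data anyway.

Palindromic families (bHLH homodimers binding the CANNTG E-box) may have
reverse-complement symmetry imposed: the symmetrized PSAM is the
geometric mean, in affinity space, of the matrix and its reverse
complement — equivalently the arithmetic mean of the energies, which is
the natural averaging for additive free energies. Binding frames for
non-palindromic families (homeodomains, seed NNTDAYNN) are fixed by
minimizing the motif matching score

MMS = sqrt( (1/J) Σ_j min_{b covered at j} (1 − w_jb)² )

over all windows and both strands; ties resolve to the smallest offset,
then the forward strand (the choice is arbitrary but must be
deterministic).

## Tetrahedral embedding

Each PSAM column is normalized to frequencies f_b = w_b / Σ w and mapped
to v = f · T with vertex rows t_A = (1,1,1), t_C = (1,−1,−1),
t_G = (−1,1,−1), t_T = (−1,−1,1). The inverse is f_b = (1 + ⟨v, t_b⟩)/4,
exact for every 3-vector; a point is interior iff all reconstructed
frequencies are ≥ 0 (tolerance 1e−12 for float noise). Because
frequencies always sum to 1, the maximum reconstructed frequency is at
least 1/4 for *any* point, so the inverse mapping to a PSAM column
(w = f / max f, then flooring at 0.01) is always defined.

The embedding deliberately saturates for strongly disfavored bases: the
columns (0, 5, 9, 9) and (0, 5, 12, 12) in ΔΔG/RT land less than 0.02
apart. This is a feature — the precise magnitude of a large penalty is
dominated by assay noise, and the embedding makes downstream statistics
insensitive to it.

**Regularization.** Shift endpoints (and, in principle, degraded inputs)
may fall outside the tetrahedron, i.e. have a negative reconstructed
frequency. Such a point is moved along the straight line toward the
vertex of its least-preferred base (most negative frequency; ties in
A, C, G, T order) until the base's relative affinity equals the 0.01
floor, found by bisection on the line parameter to |w − 0.01| < 1e−10.
The pass repeats until the point is interior; the procedure is idempotent
and never moves an already-interior point.

**ΔΔΔG/RT convention.** The shift vector between a reference and an
alternative point is placed at the origin and its endpoint e
inverse-mapped: ΔΔΔG_b/RT = −ln(4 f_b(e)). This gives 0 for every base
under a null shift and signed values (negative = the base gained
preference). No signed convention is canonical for this inverse mapping —
max-normalizing w before the log would give only non-negative values,
which cannot represent gains — and −ln 4f is the choice documented here.
One consequence worth knowing: the map is antisymmetric under shift
reversal only to first order (−ln(1+x) vs −ln(1−x)), with an O(|e|²)
discrepancy for large shifts, and it is strongly non-linear near the
tetrahedron faces where the floor engages. Effects of multiple mutations
therefore combine additively in *shift space* (exactly, for a fixed
key-feature set), not in ΔΔΔG space.

## MANOVA association mapping

For each residue position r and DNA position j, TFs are grouped by amino
acid at r and their 3D points at j are compared with a one-way MANOVA
using the Pillai–Bartlett trace V = tr(H(H+E)⁻¹), where H and E are the
between- and within-group SSCP matrices, and the standard F
approximation with s = min(3, g−1). Group rules: singleton amino-acid
groups are allowed (they contribute to H only); gap characters form a
group only when at least two TFs share the gap, otherwise those TFs are
dropped from the cell; cells with fewer than two groups or no residual
degrees of freedom are NA. Significance uses Bonferroni correction over
all non-NA cells at α = 0.001 by default. For reverse-complement
symmetric compendia, mirrored DNA positions give identical p-values,
because complementing bases permutes the tetrahedron's vertices — an
orthogonal transformation MANOVA cannot detect.

## SVD regression and feature selection

Per DNA position, the n×3 coordinate matrix is column-centered and
decomposed M − μ = U D Vᵀ (numpy SVD; each column of V is sign-flipped so
its largest-magnitude entry is positive, making the basis deterministic
and serialization-stable; V is stored C-contiguous so BLAS paths match
across a save/load round-trip). PC scores are S = (M − μ)V.

For each PC, residue positions are ranked by one-way ANOVA p-value of
the scores against amino-acid identity (gaps excluded). Features are
then added greedily in rank order. A TF's feature value is the mean
score of training TFs with the same amino acid, *excluding the TF
itself* — this leave-one-out encoding removes the mechanical correlation
between a TF's own score and its group mean, keeping the inclusion
F-test honest. Each candidate (including the first) must pass an
extra-sum-of-squares F-test at α = 0.05 against the model without it;
candidates that leave the design rank-deficient (e.g. a residue in
perfect linkage disequilibrium with an already-selected one) are skipped
without terminating the scan; the first failed F-test stops it. With
α → 0 nothing is selected and every prediction is the family centroid.
Ranking-then-testing retains some selection bias: on pure-noise
families the top-ranked of 53 features still passes at α = 0.05 in
roughly three quarters of random draws. Such spuriously selected
features carry near-zero coefficients and do not measurably degrade
held-out accuracy on the benchmark below, but the selection count should
not be read as a false-discovery-controlled statistic.

At prediction time the encoding uses full-sample group means. An amino
acid unseen at a position falls back to the mean of observed group
means, weighted by 1/(B[a,a] − B[a,a′]) from BLOSUM62 (non-positive
differences, which do not occur in BLOSUM62 proper, would receive the
largest finite positive weight); gaps and symbols outside the matrix use
the unweighted mean. Predicted scores map back via μ + V·s, then to a
PSAM column with the 0.01 floor, then (optionally) to ΔΔG/RT.

**Mutant mode.** For a set of point mutations, the mutated residue
positions become the only, mandatory features — no iterative selection —
and the coefficients are refit on the full training set (the
alternative, reusing wild-type-fit coefficients, is ill-defined when the
mutated position was never selected). Encodings of the wild-type and
mutant sequences give two predicted points per DNA position; their
difference is the predicted shift, and ΔΔΔG/RT follows by the inverse
mapping above.

## Baselines, cross-validation and statistics

*Closest paralog* transfers the model of the training TF with the
smallest Levenshtein distance on unaligned sequences (ties:
lexicographically smallest identifier). *Similarity regression* scores
each training TF as the dot product of a pretrained per-position weight
vector with the aligned identity profile and transfers the best match;
because published weight vectors may use a longer family profile, gap
columns can be inserted at configured positions first. The selection
direction is exposed (`direction="max"|"min"`) and defaults to the
highest weighted identity.

Leave-one-out cross-validation holds out each TF, optionally excluding
training TFs within a Hamming-distance threshold of it (controlling
information leakage through near-duplicate paralogs), and scores
predictions on the ΔΔG/RT entries of the evaluated DNA positions.
Aggregate R² (about the observed mean) and RMSD pool all
(TF, position, base) entries; per-TF values are also reported, since the
pooled and averaged statistics answer different questions. The paired
"bootstrap-t" comparison resamples the paired differences of squared
errors B = 10,000 times under a recentered null with an explicit seed;
Wilcoxon signed-rank and hypergeometric enrichment (of mutants whose
ΔΔΔG/RT range exceeds a threshold, default 1, among
specificity-changing mutants) use scipy's implementations. The EMSA
estimate is ln[(bound_ref/unbound_ref)/(bound_alt/unbound_alt)] from
band intensities.

## Synthetic benchmark

The generator emulates the statistical structure the model assumes: an
alignment whose background columns are i.i.d. draws from a 20-amino-acid
alphabet, plus designated determinant columns with balanced group
membership; binding models whose embedded point at a determinant's DNA
position is the group target plus isotropic Gaussian noise (truncated to
the tetrahedron interior), and near-uniform preference (origin + noise)
elsewhere. Defaults are the standard benchmark conditions used by the
test suite: 50 TFs, 53 alignment columns (the bHLH domain length), 8 DNA
positions, one determinant linking residue 13 to DNA position 3 with
targets 0.5·t_C, 0.5·t_G and 0.5·t_T for Arg, Val and Met (half-radius
targets keep every group comfortably interior so the 0.01 floor never
distorts the ground truth), and noise sd 0.05 — small relative to the
inter-target distances of ≈1.4, representing high-quality binding
models. Family noise lives in embedding space because that is where the
model operates; replicate noise is instead added to the ΔΔG/RT values of
non-preferred bases (then re-anchoring the row minimum), mimicking assay
noise. The same spec and seed reproduce byte-identical output.

What passing the benchmark shows: the pipeline recovers planted
determinants, held-out specificities (pooled LOOCV R² ≥ 0.9 at these
conditions) and planted mutation effects (RMSD < 0.3) when the family's
true structure matches the model's assumptions. What it does not show:
robustness to misaligned binding frames, correlated residue columns from
real phylogeny, heteroscedastic assay noise, or families whose
determinants act epistatically — real-data performance must be
established on real compendia.

## Known limitations

- The ΔΔΔG/RT sign convention is a documented choice (see above), and
  values for bases pushed onto the 0.01 floor are saturated, not
  measured.
- Feature selection is greedy and marginal; interacting determinants
  that are individually null will be missed.
- The similarity-regression baseline implements the published scoring
  scheme but not its training; weight vectors must be supplied.
- Alignment to a family profile HMM is out of scope: inputs are
  consumed pre-aligned (Stockholm, aligned FASTA or A2M), and
  coordinate mismatches between alignments must be reconciled with the
  gap-column configuration.
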