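"""SVD regression: basis fitting, feature selection, prediction, mutants."""

import numpy as np
import pytest

import familycode as fc
from familycode.family_model import (
    FamilyCodeModel,
    _blosum_fallback,
    _encode_training,
    center_and_svd,
    rank_and_select_features,
)


class TestCenterAndSvd:
    def test_reconstruction(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(10, 3))
        U, D, V, mu = center_and_svd(M)
        assert np.allclose(U @ np.diag(D) @ V.T + mu, M, atol=1e-10)
        assert np.all(np.diff(D) <= 1e-12)
        assert np.allclose(V.T @ V, np.eye(3), atol=1e-10)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(8, 3))
        _, _, V1, _ = center_and_svd(M)
        _, _, V2, _ = center_and_svd(M[::-1])  # row order must not matter
        assert np.allclose(V1, V2)
        for k in range(3):
            assert V1[np.argmax(np.abs(V1[:, k])), k] > 0

    def test_identical_points(self):
        M = np.tile([0.3, -0.2, 0.1], (6, 1))
        U, D, V, mu = center_and_svd(M)
        assert np.allclose(D, 0.0)
        assert np.allclose(mu, [0.3, -0.2, 0.1])
        assert np.allclose(V, np.eye(3))

    def test_collinear_cloud_is_rank_one(self):
        t = np.linspace(0, 1, 7)[:, None]
        M = t * np.array([1.0, 2.0, -1.0])
        _, D, _, _ = center_and_svd(M)
        assert D[0] > 0
        assert np.allclose(D[1:], 0.0, atol=1e-12)

    def test_projection_roundtrip(self):
        """mu + V s reproduces each training point from its scores."""
        rng = np.random.default_rng(2)
        M = rng.normal(size=(12, 3))
        _, _, V, mu = center_and_svd(M)
        S = (M - mu) @ V
        assert np.allclose(mu + S @ V.T, M, atol=1e-10)


class TestFeatureSelection:
    def test_planted_determinant_selected(self, small_family, blosum):
        fam, compendium, truth = small_family
        model = FamilyCodeModel.fit(compendium, fam)
        pm = model.position_models[1]  # D2 carries the determinant
        assert any(5 in sel for sel in pm.selected)

    def test_collinear_duplicate_skipped(self, blosum):
        rng = np.random.default_rng(3)
        n = 40
        groups = np.array(["R", "V"])[rng.integers(0, 2, n)]
        y = np.where(groups == "R", 1.0, -1.0) + rng.normal(scale=0.1, size=n)
        y = y - y.mean()
        # residues 1 and 2 in perfect linkage disequilibrium
        col1 = list(groups)
        col2 = ["K" if g == "R" else "L" for g in groups]
        columns = {1: col1, 2: col2}
        selected, beta = rank_and_select_features(y, columns, blosum)
        assert len(selected) == 1

    def test_alpha_zero_selects_nothing(self, blosum):
        rng = np.random.default_rng(4)
        n = 30
        groups = np.array(["R", "V"])[rng.integers(0, 2, n)]
        y = np.where(groups == "R", 1.0, -1.0)
        y = y - y.mean()
        selected, beta = rank_and_select_features(
            y, {1: list(groups)}, blosum, alpha=0.0
        )
        assert selected == []
        assert beta.size == 0

    def test_loo_encoding_excludes_focal_tf(self, blosum):
        y = np.array([1.0, 3.0, 10.0, 20.0])
        column = ["A", "A", "W", "W"]
        x = _encode_training(column, y, blosum)
        # each TF sees its group mean computed without itself
        assert np.allclose(x, [3.0, 1.0, 20.0, 10.0])

    def test_singleton_falls_back_to_unseen(self, blosum):
        y = np.array([1.0, 3.0, 5.0])
        column = ["A", "A", "W"]
        x = _encode_training(column, y, blosum)
        # the lone W is encoded from the other groups, not itself
        assert x[2] == pytest.approx(2.0)


class TestBlosumFallback:
    def test_weighted_mean_by_hand(self, blosum):
        # query I against observed L and D:
        # B[I,I]=4, B[I,L]=2 -> w_L = 1/2 ; B[I,D]=-3 -> w_D = 1/7
        means = {"L": 10.0, "D": -7.0}
        got = _blosum_fallback("I", means, blosum)
        expected = (0.5 * 10.0 + (1 / 7) * -7.0) / (0.5 + 1 / 7)
        assert got == pytest.approx(expected)

    def test_gap_uses_unweighted_mean(self, blosum):
        means = {"L": 10.0, "D": -8.0}
        assert _blosum_fallback("-", means, blosum) == pytest.approx(1.0)

    def test_symbol_outside_matrix_uses_unweighted_mean(self, blosum):
        means = {"L": 10.0, "D": -8.0}
        assert _blosum_fallback("J", means, blosum) == pytest.approx(1.0)


class TestFitAndPredict:
    def test_identical_family_predicts_shared_psam(self, identical_family):
        fam, compendium = identical_family
        model = FamilyCodeModel.fit(compendium, fam)
        pred = model.predict_energy(fam.row(fam.tf_ids[0]))
        assert np.allclose(pred.values, compendium[0].values, atol=1e-9)
        # any query sequence gets the same answer: nothing was selected
        other = model.predict_energy("W" * fam.length)
        assert np.allclose(other.values, pred.values)

    def test_too_few_tfs_rejected(self, identical_family):
        fam, compendium = identical_family
        with pytest.raises(ValueError):
            FamilyCodeModel.fit(compendium[:3], fam)

    def test_heldout_recovery(self, benchmark_family):
        """A held-out TF's ddG/RT profile is recovered accurately at the
        benchmark noise level."""
        fam, compendium, truth = benchmark_family
        test_tf = compendium[0].tf_id
        model = FamilyCodeModel.fit(compendium[1:], fam)
        pred = model.predict_energy(fam.row(test_tf))
        assert fc.rmsd(pred.values, compendium[0].values) < 0.3
        assert fc.r2(pred.values, compendium[0].values) > 0.9

    def test_order_invariance(self, small_family):
        fam, compendium, _ = small_family
        m1 = FamilyCodeModel.fit(compendium, fam)
        m2 = FamilyCodeModel.fit(compendium[::-1], fam)
        seq = fam.row(fam.tf_ids[3])
        assert np.allclose(
            m1.predict_psam(seq).values, m2.predict_psam(seq).values, atol=1e-9
        )

    def test_all_gap_query_gets_centroid(self, small_family):
        fam, compendium, _ = small_family
        model = FamilyCodeModel.fit(compendium, fam)
        pred = model.predict_psam("-" * fam.length)
        assert pred.n_positions == len(model.position_models)
        assert np.all(np.isfinite(pred.values))

    def test_wrong_length_query(self, small_family):
        fam, compendium, _ = small_family
        model = FamilyCodeModel.fit(compendium, fam)
        with pytest.raises(ValueError):
            model.predict_psam("MKRL")

    def test_save_load_roundtrip(self, small_family, tmp_path):
        fam, compendium, _ = small_family
        model = FamilyCodeModel.fit(compendium, fam)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = FamilyCodeModel.load(path)
        seq = fam.row(fam.tf_ids[7])
        assert np.array_equal(
            model.predict_psam(seq).values, loaded.predict_psam(seq).values
        )
        dddg_a = model.predict_dddg(fam.row(fam.tf_ids[0]),
                                    [(5, fam.residue_at(fam.tf_ids[0], 5), "V")])
        dddg_b = loaded.predict_dddg(fam.row(fam.tf_ids[0]),
                                     [(5, fam.residue_at(fam.tf_ids[0], 5), "V")])
        assert np.array_equal(dddg_a.values, dddg_b.values)


class TestMutantPrediction:
    def test_empty_mutation_list_is_zero(self, small_family):
        fam, compendium, _ = small_family
        model = FamilyCodeModel.fit(compendium, fam)
        dddg = model.predict_dddg(fam.row(fam.tf_ids[0]), [])
        assert np.allclose(dddg.values, 0.0)

    def test_from_aa_mismatch_rejected(self, small_family):
        fam, compendium, _ = small_family
        model = FamilyCodeModel.fit(compendium, fam)
        tf = fam.tf_ids[0]
        wrong = "W" if fam.residue_at(tf, 5) != "W" else "Y"
        with pytest.raises(ValueError):
            model.predict_dddg(fam.row(tf), [(5, wrong, "V")])

    def test_recovers_planted_shift(self, small_family):
        fam, compendium, truth = small_family
        model = FamilyCodeModel.fit(compendium, fam)
        tf = next(t for t in fam.tf_ids if fam.residue_at(t, 5) == "R")
        mut_seq, true_dddg = fc.make_mutant(fam, tf, (5, "R", "V"), truth)
        pred = model.predict_dddg(fam.row(tf), [(5, "R", "V")])
        assert fc.rmsd(pred.values, true_dddg.values) < 0.3

    def test_double_mutant_additivity(self):
        """With two independently planted determinants, the double-mutant
        shift equals the sum of the single-mutant shifts."""
        spec = fc.SyntheticFamilySpec(
            n_tfs=48,
            alignment_length=20,
            n_dna_positions=4,
            determinants=(fc.Determinant(5, 2), fc.Determinant(9, 4)),
            noise_sd=0.03,
            seed=11,
        )
        fam, compendium, truth = fc.make_family(spec)
        model = FamilyCodeModel.fit(compendium, fam)
        tf = next(
            t
            for t in fam.tf_ids
            if fam.residue_at(t, 5) == "R" and fam.residue_at(t, 9) == "R"
        )
        row = fam.row(tf)
        # hold the key-feature set {5, 9} fixed by including the second
        # position as a no-op substitution: shifts are then linear in
        # the encodings and combine exactly additively
        s1 = model.predict_shift(row, [(5, "R", "V"), (9, "R", "R")])
        s2 = model.predict_shift(row, [(5, "R", "R"), (9, "R", "M")])
        s12 = model.predict_shift(row, [(5, "R", "V"), (9, "R", "M")])
        assert np.allclose(s12, s1 + s2, atol=1e-10)
        assert np.abs(s12).max() > 0.3  # the planted effects are there
        # the corresponding dddG/RT recovers both planted shifts
        d12 = model.predict_dddg(row, [(5, "R", "V"), (9, "R", "M")])
        _, t1 = fc.make_mutant(fam, tf, (5, "R", "V"), truth)
        _, t2 = fc.make_mutant(fam, tf, (9, "R", "M"), truth)
        assert fc.rmsd(d12.values, t1.values + t2.values) < 0.3

    def test_background_mutation_has_small_effect(self, small_family):
        fam, compendium, truth = small_family
        model = FamilyCodeModel.fit(compendium, fam)
        tf = fam.tf_ids[0]
        aa = fam.residue_at(tf, 12)
        pred = model.predict_dddg(fam.row(tf), [(12, aa, "W")])
        assert fc.dddg_range(pred) < 0.5
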