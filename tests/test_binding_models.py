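"""Energy/affinity conversions, symmetrization, seed alignment, I/O."""

import numpy as np
import pytest

from familycode import binding_models as bm


def make_energy(rows, tf_id="tf", labels=None):
    rows = np.asarray(rows, dtype=float)
    labels = labels or tuple(str(i + 1) for i in range(len(rows)))
    return bm.EnergyMatrix(tf_id, labels, rows)


def make_psam(rows, tf_id="tf", labels=None):
    rows = np.asarray(rows, dtype=float)
    labels = labels or tuple(str(i + 1) for i in range(len(rows)))
    return bm.PSAM(tf_id, labels, rows)


class TestInvariants:
    def test_energy_requires_zero_row_min(self):
        with pytest.raises(ValueError):
            make_energy([[0.5, 1, 2, 3]])

    def test_energy_rejects_negative(self):
        with pytest.raises(ValueError):
            make_energy([[-1, 0, 2, 3]])

    def test_psam_requires_unit_row_max(self):
        with pytest.raises(ValueError):
            make_psam([[0.5, 0.5, 0.5, 0.5]])

    def test_row_label_mismatch(self):
        with pytest.raises(ValueError):
            bm.EnergyMatrix("tf", ("1", "2"), np.zeros((3, 4)))


class TestConversions:
    def test_energy_to_psam_derived(self):
        E = make_energy([[0, 1.609, 4.605, 4.605]])
        P = bm.psam_from_energy(E)
        assert np.allclose(P.values, [[1, 0.2, 0.01, 0.01]], atol=1e-3)

    def test_flat_row_identity(self):
        E = make_energy([[0, 0, 0, 0]])
        assert np.allclose(bm.psam_from_energy(E).values, 1.0)

    def test_strict_preference_limit(self):
        E = make_energy([[0, 50, 50, 50]])
        P = bm.psam_from_energy(E)
        assert P.values[0, 0] == 1.0
        assert np.all(P.values[0, 1:] < 1e-20)

    def test_psam_to_energy_derived(self):
        P = make_psam([[1, 0.2, 0.01, 0.01]])
        E = bm.energy_from_psam(P)
        assert np.allclose(E.values, [[0, 1.6094, 4.6052, 4.6052]], atol=1e-4)

    def test_floor_applied_before_log(self):
        P = make_psam([[1, 0.001, 1, 1]])
        E = bm.energy_from_psam(P)
        assert np.allclose(E.values, [[0, -np.log(0.01), 0, 0]])

    def test_mutually_inverse_above_floor(self):
        rng = np.random.default_rng(5)
        w = rng.uniform(0.01, 1.0, size=(6, 4))
        w[np.arange(6), rng.integers(0, 4, 6)] = 1.0
        P = make_psam(w)
        back = bm.psam_from_energy(bm.energy_from_psam(P))
        assert np.allclose(back.values, P.values, atol=1e-12)


class TestSymmetrize:
    def test_fixed_point(self):
        w = np.array([[1, 0.5, 0.25, 0.125], [0.125, 0.25, 0.5, 1]])
        P = bm.symmetrize_reverse_complement(make_psam(w))
        # already reverse-complement symmetric -> unchanged
        assert np.allclose(P.values, w)

    def test_output_is_symmetric(self):
        w = np.array([[1, 0.5, 0.25, 0.125], [1, 1, 1, 1]])
        S = bm.symmetrize_reverse_complement(make_psam(w))
        rc = S.values[::-1, ::-1]
        assert np.allclose(S.values, rc)
        assert np.allclose(S.values.max(axis=1), 1.0)

    def test_strand_invariance(self):
        rng = np.random.default_rng(2)
        w = rng.uniform(0.05, 1.0, size=(4, 4))
        w = w / w.max(axis=1, keepdims=True)
        P = make_psam(w)
        rc = bm.reverse_complement(P)
        s1 = bm.symmetrize_reverse_complement(P)
        s2 = bm.symmetrize_reverse_complement(rc)
        assert np.allclose(s1.values, s2.values)

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        w = rng.uniform(0.05, 1.0, size=(6, 4))
        w = w / w.max(axis=1, keepdims=True)
        s1 = bm.symmetrize_reverse_complement(make_psam(w))
        s2 = bm.symmetrize_reverse_complement(s1)
        assert np.allclose(s1.values, s2.values, atol=1e-12)

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError):
            bm.symmetrize_reverse_complement(make_psam([[1, 1, 1, 1]]))


class TestMms:
    def test_perfect_match_is_zero(self):
        P = make_psam([[1, 0.2, 0.2, 0.2], [0.3, 1, 0.1, 0.2]])
        seed = bm.IupacSeed("AC")
        assert bm.mms(P, seed, 0) == 0.0

    def test_uniform_psam_is_zero(self):
        P = make_psam([[1, 1, 1, 1], [1, 1, 1, 1]])
        assert bm.mms(P, bm.IupacSeed("GT"), 0) == 0.0

    def test_hand_computed_single_position(self):
        # seed R covers A and G
        P1 = make_psam(np.array([[1, 0.3, 0.6, 0.2]]))
        assert bm.mms(P1, bm.IupacSeed("R"), 0) == 0.0
        P2 = make_psam(np.array([[0.2, 1, 0.6, 0.1]]))
        # min((1-0.2)^2, (1-0.6)^2) = 0.16 -> sqrt(0.16/1) = 0.4
        assert np.isclose(bm.mms(P2, bm.IupacSeed("R"), 0), 0.4)

    def test_window_out_of_range(self):
        P = make_psam([[1, 1, 1, 1]])
        with pytest.raises(ValueError):
            bm.mms(P, bm.IupacSeed("NN"), 0)


class TestAlignToSeed:
    @staticmethod
    def ebox_psam(offset, total, tf_id="tf"):
        """A PSAM with an exact CANNTG E-box starting at ``offset``.

        Flanking positions prefer A so that only the true E-box window
        matches the seed's fixed symbols perfectly.
        """
        flank = np.array([1.0, 0.05, 0.05, 0.05])
        w = np.tile(flank, (total, 1))
        box = "CANNTG"
        for j, sym in enumerate(box):
            if sym == "N":
                row = np.full(4, 1.0)
            else:
                row = np.full(4, 0.05)
                row["ACGT".index(sym)] = 1.0
            w[offset + j] = row
        return make_psam(w, tf_id)

    def test_exact_ebox_window_selected(self):
        P = self.ebox_psam(offset=3, total=12)
        seed = bm.IupacSeed("NCANNTGN")
        framed = bm.align_to_seed(P, seed)
        assert framed.metadata["frame_offset"] == 2
        assert framed.metadata["frame_strand"] == "+"
        assert framed.n_positions == 8
        assert bm.mms(framed, seed, 0) == 0.0

    def test_identity_when_already_framed(self):
        P = self.ebox_psam(offset=1, total=8)
        framed = bm.align_to_seed(P, bm.IupacSeed("NCANNTGN"))
        assert np.allclose(framed.values, P.values)

    def test_strand_tie_prefers_forward(self):
        # palindromic-symmetric PSAM scores identically on both strands
        rng = np.random.default_rng(4)
        w = rng.uniform(0.2, 1.0, size=(4, 4))
        w = np.sqrt(w * w[::-1, ::-1])
        w = w / w.max(axis=1, keepdims=True)
        framed = bm.align_to_seed(make_psam(w), bm.IupacSeed("NN"))
        assert framed.metadata["frame_strand"] == "+"

    def test_shorter_than_seed_rejected(self):
        with pytest.raises(ValueError):
            bm.align_to_seed(make_psam([[1, 1, 1, 1]]), bm.IupacSeed("NN"))

    def test_exhaustive_minimality(self):
        rng = np.random.default_rng(6)
        w = rng.uniform(0.05, 1.0, size=(10, 4))
        w = w / w.max(axis=1, keepdims=True)
        P = make_psam(w)
        seed = bm.IupacSeed("NNTDAYNN")
        framed = bm.align_to_seed(P, seed)
        best = min(
            bm.mms(P, seed, off, strand)
            for off in range(P.n_positions - len(seed) + 1)
            for strand in "+-"
        )
        assert np.isclose(bm.mms(framed, seed, 0), best)


class TestIupacSeed:
    def test_indicator_shape_and_coverage(self):
        seed = bm.IupacSeed("NNTDAYNN")
        assert seed.indicator.shape == (4, 8)
        assert np.all(seed.indicator.sum(axis=0) >= 1)
        # D = A/G/T, Y = C/T
        assert seed.indicator[:, 3].tolist() == [1, 0, 1, 1]
        assert seed.indicator[:, 5].tolist() == [0, 1, 0, 1]

    def test_invalid_symbol(self):
        with pytest.raises(ValueError):
            bm.IupacSeed("NXN")


class TestIO:
    def test_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(8)
        w = rng.uniform(0.01, 1.0, size=(5, 4))
        w[np.arange(5), rng.integers(0, 4, 5)] = 1.0
        P = make_psam(w, "roundtrip")
        path = tmp_path / "roundtrip.tsv"
        bm.write_psam(P, path)
        back = bm.read_psam(path)
        assert back.tf_id == "roundtrip"
        assert back.position_labels == P.position_labels
        assert np.array_equal(back.values, P.values)

    def test_meme_uniform_row(self, tmp_path):
        text = (
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
            "MOTIF test\n"
            "letter-probability matrix: alength= 4 w= 1\n"
            " 0.25 0.25 0.25 0.25\n"
        )
        path = tmp_path / "m.meme"
        path.write_text(text)
        P = bm.read_psam(path, "meme-minimal")
        assert np.allclose(P.values, 1.0)

    def test_meme_roundtrip(self, tmp_path):
        w = np.array([[1, 0.5, 0.25, 0.125], [0.4, 1.0, 0.9, 0.2]])
        P = make_psam(w, "m1")
        path = tmp_path / "m1.meme"
        bm.write_psam(P, path, "meme-minimal")
        back = bm.read_psam(path, "meme-minimal")
        assert back.tf_id == "m1"
        assert np.allclose(back.values, w, atol=1e-4)

    def test_malformed_tsv_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("pos\tA\tC\tG\tT\n1\t0.1\t0.2\t1.0\n")
        with pytest.raises(ValueError, match="line 2"):
            bm.read_psam(path)

    def test_bad_header(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("position\tA\tC\tG\tT\n")
        with pytest.raises(ValueError, match="line 1"):
            bm.read_psam(path)


class TestEmbedCompendium:
    def test_label_mismatch_rejected(self):
        a = make_energy(np.zeros((2, 4)), "a", ("1", "2"))
        b = make_energy(np.zeros((2, 4)), "b", ("1", "3"))
        with pytest.raises(ValueError):
            bm.embed_compendium([a, b])

    def test_cloud_per_position(self, small_family):
        _, compendium, _ = small_family
        clouds = bm.embed_compendium(compendium)
        assert len(clouds) == compendium[0].n_positions
        assert all(len(c) == len(compendium) for c in clouds)
        # centroid-ish clouds at non-determinant positions sit near origin
        assert np.linalg.norm(clouds[0].coords.mean(axis=0)) < 0.1
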