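import numpy as np
import pytest

import familycode as fc


@pytest.fixture(scope="session")
def small_family():
    """Compact synthetic family: 30 TFs, 20 columns, determinant (5, D2)."""
    spec = fc.SyntheticFamilySpec(
        n_tfs=30,
        alignment_length=20,
        n_dna_positions=4,
        determinants=(fc.Determinant(5, 2),),
        seed=1,
    )
    return fc.make_family(spec)


@pytest.fixture(scope="session")
def benchmark_family():
    """The standard benchmark conditions: 50 TFs, 53 columns, det (13, D3)."""
    return fc.make_family(fc.SyntheticFamilySpec(seed=1))


@pytest.fixture(scope="session")
def identical_family():
    """Six TFs sharing one sequence and one binding model."""
    rng = np.random.default_rng(7)
    energies = rng.uniform(0.2, 3.0, size=(4, 4))
    energies[np.arange(4), rng.integers(0, 4, size=4)] = 0.0
    labels = ("D1", "D2", "D3", "D4")
    seq = "MKRLAQENDS"
    tf_ids = tuple(f"TF{i}" for i in range(6))
    fam = fc.AlignedFamily(tf_ids, tuple(seq for _ in tf_ids))
    compendium = [fc.EnergyMatrix(tf, labels, energies) for tf in tf_ids]
    return fam, compendium


@pytest.fixture(scope="session")
def blosum():
    return fc.load_blosum()
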