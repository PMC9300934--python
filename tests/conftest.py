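import warnings

import numpy as np
import pytest

import allodyn
from allodyn.synthetic import build_toy_complex, path_study_spec, residues_of

warnings.filterwarnings("ignore", message=".*Unit cell dimensions not found.*")
warnings.filterwarnings("ignore", message=".*Found no information for attr.*")


@pytest.fixture(scope="session")
def toy_complex():
    """Deterministic 40-residue receptor + ligand + peptide, with parameters."""
    structure, params = build_toy_complex(40)
    return structure, params


@pytest.fixture(scope="session")
def toy_structure(toy_complex):
    return toy_complex[0]


@pytest.fixture(scope="session")
def toy_params(toy_complex):
    return toy_complex[1]


@pytest.fixture(scope="session")
def small_ensemble(toy_structure):
    """5-frame ensemble: reference plus Gaussian jitter (seeded)."""
    rng = np.random.default_rng(42)
    ref = toy_structure.coordinates
    frames = ref[None] + 0.3 * rng.standard_normal((5, ref.shape[0], 3))
    return allodyn.Ensemble(frames, toy_structure)


@pytest.fixture(scope="session")
def path_fixture():
    """Superposed ensemble with a planted high-correlation contact chain."""
    spec, truth, params = path_study_spec(n_frames=600, seed=5)
    ensemble, truth = allodyn.sample_ensemble(spec, truth)
    fitted = allodyn.superpose(ensemble, spec.reference, "chain A and name CA")
    return fitted, truth, params, spec.reference
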