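import numpy as np
import pytest

from hlhkit import synthetic


# --- printed all-against-all matrices for the published five-algorithm
# --- model comparison (candidates + all-beta negative control)
MODEL_LABELS = ["I-TASSER", "MUSTER", "QUARK", "Pro-sp3", "Chunk-TASSER", "Phf19"]
CONTROL = "Phf19"
RMSD_TABLE = np.array([
    [0.00, 4.99, 4.16, 5.16, 4.76, 8.09],
    [4.99, 0.00, 4.64, 6.08, 6.35, 6.67],
    [4.16, 4.64, 0.00, 4.71, 6.79, 5.17],
    [5.16, 6.08, 4.71, 0.00, 4.88, 5.33],
    [4.76, 6.35, 6.79, 4.88, 0.00, 8.37],
    [8.09, 6.67, 5.17, 5.33, 8.37, 0.00],
])
ZSCORE_TABLE = np.array([
    [6.35, 3.29, 3.70, 4.42, 2.30, 1.24],
    [3.29, 6.35, 3.07, 3.07, 1.99, 1.99],
    [3.70, 3.07, 6.35, 3.70, 3.29, 0.73],
    [4.42, 3.07, 3.70, 6.35, 2.30, 1.24],
    [2.30, 1.99, 3.29, 2.30, 6.35, 1.64],
    [1.24, 1.99, 0.73, 1.24, 1.64, 5.60],
])


@pytest.fixture(scope="session")
def hlh_structure():
    """Ideal helix-loop-helix build of the default 100-residue sequence."""
    return synthetic.build_ideal_helix(
        synthetic.DEFAULT_SEQUENCE, synthetic.DEFAULT_HELIX_SPANS)


@pytest.fixture(scope="session")
def bdna_a10():
    return synthetic.build_bdna("A" * 10)


@pytest.fixture(scope="session")
def showcase():
    return synthetic.build_interaction_showcase()


@pytest.fixture(scope="session")
def score_matrices():
    from hlhkit.modeleval import ScoreMatrix

    rmsd = ScoreMatrix(MODEL_LABELS, RMSD_TABLE, "rmsd", CONTROL)
    zs = ScoreMatrix(MODEL_LABELS, ZSCORE_TABLE, "zscore", CONTROL)
    return rmsd, zs
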