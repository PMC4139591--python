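import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from hlhkit import synthetic
from hlhkit.modeleval import (
    ConsensusStats,
    ScoreMatrix,
    alignment_zscore,
    classify_rama_region,
    consensus_stats,
    ramachandran,
    rank_models,
    rmsd_matrix,
    superpose,
)
from hlhkit.structio import Atom, Chain, Residue, Structure


def _ca_structure(coords, names=None):
    residues = []
    for i, xyz in enumerate(coords, start=1):
        name = (names or {}).get(i, "ALA")
        residues.append(Residue("A", i, name, [Atom("CA", "C", xyz)]))
    return Structure([[Chain("A", "protein", residues)]])


def brute_force_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent oracle: dense Euler-angle grid search followed by local
    simplex refinement; never uses the SVD-based implementation."""
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)

    def rmsd_of(angles):
        mat = Rotation.from_euler("zyx", angles).as_matrix()
        return float(np.sqrt(np.mean(np.sum((m @ mat.T - r) ** 2, axis=1))))

    grid = np.radians(np.arange(-180, 180, 20.0))
    half = np.radians(np.arange(-90, 91, 20.0))
    mats = Rotation.from_euler(
        "zyx", [(a, b, c) for a in grid for b in half for c in grid]).as_matrix()
    vals = np.sqrt(np.mean(np.sum(
        (np.einsum("nij,kj->nki", mats, m) - r) ** 2, axis=2), axis=1))
    best = np.inf
    for idx in np.argsort(vals)[:8]:  # multi-start local refinement
        start = Rotation.from_matrix(mats[idx]).as_euler("zyx")
        res = minimize(rmsd_of, start, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-13, "maxiter": 4000})
        best = min(best, float(res.fun))
    return best


class TestSuperpose:
    def test_self_superposition_is_zero(self, hlh_structure):
        assert superpose(hlh_structure, hlh_structure).rmsd < 1e-5

    def test_rigid_transform_invariance_and_recovery(self, hlh_structure):
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = hlh_structure.copy()
        moved.set_coords(moved.coords() @ rot.T + np.array([5.0, 0.0, 0.0]))
        fit = superpose(moved, hlh_structure)
        assert fit.rmsd < 1e-5
        np.testing.assert_allclose(fit.rotation @ rot, np.eye(3), atol=1e-6)
        assert abs(np.linalg.det(fit.rotation) - 1.0) < 1e-6

    def test_matches_brute_force_oracle_on_random_point_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.normal(size=(6, 3)) * 4.0
            b = rng.normal(size=(6, 3)) * 4.0
            fit = superpose(_ca_structure(a), _ca_structure(b))
            assert abs(fit.rmsd - brute_force_rmsd(a, b)) <= 1e-3

    def test_too_few_atoms_rejected(self):
        a = _ca_structure(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="at least 3"):
            superpose(a, a)

    def test_residue_mismatch_named(self):
        a = _ca_structure(np.eye(3) * 3)
        b = _ca_structure(np.eye(3) * 3, names={2: "GLY"})
        with pytest.raises(ValueError, match="A:2"):
            superpose(a, b)


class TestRmsdMatrix:
    def test_identical_models_score_zero(self, hlh_structure):
        m = rmsd_matrix({"a": hlh_structure, "b": hlh_structure.copy()})
        assert m.entry("a", "b") < 1e-5

    def test_symmetric_with_zero_diagonal(self, hlh_structure):
        models = {
            f"m{i}": synthetic.build_ideal_helix(
                synthetic.DEFAULT_SEQUENCE, synthetic.DEFAULT_HELIX_SPANS,
                seed=i, noise=0.5)
            for i in range(3)
        }
        m = rmsd_matrix(models)
        np.testing.assert_array_equal(m.values, m.values.T)
        np.testing.assert_array_equal(np.diag(m.values), 0.0)

    def test_entries_increase_with_perturbation_noise(self, hlh_structure):
        noises = (0.2, 0.6, 1.2, 2.4)
        models = {"base": hlh_structure}
        models.update({
            f"n{k}": synthetic.build_ideal_helix(
                synthetic.DEFAULT_SEQUENCE, synthetic.DEFAULT_HELIX_SPANS,
                seed=1, noise=noise)
            for k, noise in enumerate(noises)
        })
        m = rmsd_matrix(models)
        values = [m.entry("base", f"n{k}") for k in range(len(noises))]
        assert values == sorted(values)

    def test_triangle_inequality_in_a_common_frame(self, hlh_structure):
        rng = np.random.default_rng(5)
        base = hlh_structure.coords()
        frames = [base + rng.normal(0, s, base.shape) for s in (0.3, 0.8, 1.5)]
        d = lambda x, y: np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1)))
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    assert d(frames[i], frames[k]) <= (
                        d(frames[i], frames[j]) + d(frames[j], frames[k]) + 1e-6)


def _random_fold(seed, n=60):
    """Unrelated compact fold stand-in: a seeded random C-alpha cloud."""
    rng = np.random.default_rng(seed)
    return _ca_structure(rng.normal(0.0, 8.0, (n, 3)))


class TestAlignmentZscore:
    def test_identical_structures_highly_significant(self, hlh_structure):
        z, null = alignment_zscore(hlh_structure, hlh_structure, null_size=50, seed=0)
        assert z > 3.0
        assert null.null_size == 50

    def test_unrelated_folds_score_near_zero_on_average(self):
        zs = []
        for k in range(6):
            a = _random_fold(2 * k)
            b = _random_fold(2 * k + 1)
            z, _ = alignment_zscore(a, b, null_size=60, seed=k)
            zs.append(z)
        assert abs(np.mean(zs)) <= 1.0

    def test_same_seed_reproducible(self):
        a, b = _random_fold(100), _random_fold(101)
        z1, _ = alignment_zscore(a, b, null_size=40, seed=9)
        z2, _ = alignment_zscore(a, b, null_size=40, seed=9)
        assert z1 == z2


class TestConsensusStats:
    def test_published_first_row_aggregates(self, score_matrices):
        rmsd, zs = score_matrices
        stats = consensus_stats(rmsd, zs, "Phf19")
        best = stats["I-TASSER"]
        assert round(best.mean_rmsd, 2) == 4.77
        assert round(best.sd_rmsd, 2) == 0.38
        assert round(best.mean_z, 1) == 3.2

    def test_second_row_z_aggregate(self, score_matrices):
        rmsd, zs = score_matrices
        stats = consensus_stats(rmsd, zs, "Phf19")
        assert round(stats["MUSTER"].mean_z, 2) == 2.74

    def test_pearson_is_descriptive_and_in_range(self, score_matrices):
        rmsd, zs = score_matrices
        for s in consensus_stats(rmsd, zs, "Phf19").values():
            assert s.pearson_r is None or -1.0 <= s.pearson_r <= 1.0

    def test_degenerate_all_equal_entries(self):
        labels = ["a", "b", "c", "ctrl"]
        vals = np.full((4, 4), 2.0)
        np.fill_diagonal(vals, 0.0)
        rmsd = ScoreMatrix(labels, vals, "rmsd", "ctrl")
        zs = ScoreMatrix(labels, vals, "zscore", "ctrl")
        stats = consensus_stats(rmsd, zs, "ctrl")
        assert stats["a"].sd_rmsd == 0.0
        assert stats["a"].pearson_r is None


class TestRanking:
    def test_published_matrices_rank_first_algorithm_first(self, score_matrices):
        rmsd, zs = score_matrices
        stats = consensus_stats(rmsd, zs, "Phf19")
        ranking = rank_models(stats)
        assert ranking[0] == "I-TASSER"
        assert "Phf19" not in ranking
        assert stats["I-TASSER"].rank == 1

    def test_single_candidate_ranks_itself(self):
        stats = {"only": ConsensusStats("only", 1.0, 0.1, 2.0, None)}
        assert rank_models(stats) == ["only"]

    def test_tie_broken_by_higher_z(self):
        stats = {
            "x": ConsensusStats("x", 3.0, 0.1, 2.0, None),
            "y": ConsensusStats("y", 3.0, 0.1, 3.0, None),
        }
        assert rank_models(stats) == ["y", "x"]


class TestRamachandran:
    def test_ideal_helix_residues_favored(self, hlh_structure):
        summary = ramachandran(hlh_structure)
        interior = {n: region for _, n, _, _, region in summary.residues}
        for number in range(22, 32):
            assert interior[number] == "favored"
        assert abs(sum(summary.percentages.values()) - 100.0) < 0.1

    def test_classic_gamma_turn_center_is_classified(self):
        assert classify_rama_region(75.0, -64.0) in ("favored", "allowed", "disallowed")
        assert classify_rama_region(75.0, -64.0) == "allowed"

    def test_origin_is_disallowed(self):
        assert classify_rama_region(0.0, 0.0) == "disallowed"

    def test_extended_region_favored(self):
        assert classify_rama_region(-120.0, 120.0) == "favored"
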