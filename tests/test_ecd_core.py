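"""Hand-computable oracles for the PCA/image/descriptor chain."""

import numpy as np
import pytest

from ecdyn import errors
from ecdyn.ecd_core import (
    average_descriptors,
    compute_covariance,
    flexibility_profile,
    pair_correlations,
    project_images,
    superpose_frames,
    variance_captured,
)
from ecdyn.traj_model import SelectionMask, TrajectorySegment, select
from tests.conftest import make_atoms, random_segment

SQRT2 = np.sqrt(2.0)


class TestCovariance:
    def test_correlated_pair_hand_values(self, correlated_pair_segment):
        m = compute_covariance(correlated_pair_segment)
        c = m.covariance
        # x DOFs are 0 and 3; both deviations are +-1 -> all four entries 1.0
        for i in (0, 3):
            for j in (0, 3):
                assert c[i, j] == pytest.approx(1.0, abs=1e-10)
        assert np.abs(c).sum() == pytest.approx(4.0, abs=1e-10)
        assert m.eigenvalues[0] == pytest.approx(2.0, abs=1e-10)
        expected = np.zeros(6)
        expected[[0, 3]] = 1 / SQRT2
        np.testing.assert_allclose(m.eigenvectors[:, 0], expected, atol=1e-10)

    def test_constant_trajectory_is_zero(self):
        seg = TrajectorySegment(np.ones((3, 2, 3)), make_atoms(2), 1.0)
        m = compute_covariance(seg)
        assert np.abs(m.covariance).max() == 0.0
        assert np.abs(m.eigenvalues).max() == 0.0

    def test_trace_equals_eigenvalue_sum(self):
        rng = np.random.default_rng(0)
        seg = random_segment(rng, n_frames=9, n_atoms=4)
        m = compute_covariance(seg)
        assert m.total_variance == pytest.approx(m.eigenvalues.sum(),
                                                 rel=1e-10)

    def test_single_frame_allowed_and_zero(self):
        seg = TrajectorySegment(np.random.default_rng(1).random((1, 3, 3)),
                                make_atoms(3), 1.0)
        assert compute_covariance(seg).total_variance == 0.0


class TestImagesAndDescriptors:
    def test_correlated_pair_images_coincide(self, correlated_pair_segment):
        m = compute_covariance(correlated_pair_segment)
        img = project_images(m, 1)
        np.testing.assert_allclose(img.images[0], [1 / SQRT2, 0, 0],
                                   atol=1e-10)
        np.testing.assert_allclose(img.images[0], img.images[1], atol=1e-10)
        d = pair_correlations(img)
        assert d.matrix[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_anticorrelated_pair_distance_is_sqrt2(
            self, anticorrelated_pair_segment):
        m = compute_covariance(anticorrelated_pair_segment)
        img = project_images(m, 1)
        d = pair_correlations(img)
        assert d.matrix[0, 1] == pytest.approx(SQRT2, abs=1e-10)
        f = flexibility_profile(img)
        # two images u, v -> F = |u - v| / 2 for both atoms
        np.testing.assert_allclose(f.values, [SQRT2 / 2, SQRT2 / 2],
                                   atol=1e-10)

    def test_image_norm_invariant(self):
        rng = np.random.default_rng(2)
        seg = random_segment(rng, n_frames=20, n_atoms=6)
        m = compute_covariance(seg)
        for k in (1, 3, m.rank):
            img = project_images(m, k)
            assert np.sum(img.images ** 2) == pytest.approx(k, abs=1e-10)
            assert (np.linalg.norm(img.images, axis=1) <=
                    np.sqrt(k) + 1e-10).all()

    def test_identical_images_give_zero_flexibility(
            self, correlated_pair_segment):
        m = compute_covariance(correlated_pair_segment)
        f = flexibility_profile(project_images(m, 1))
        np.testing.assert_allclose(f.values, 0.0, atol=1e-10)
        # centroid deviations sum to zero by construction
        img = project_images(m, 1)
        assert np.abs((img.images - f.centroid).sum(axis=0)).max() < 1e-10

    def test_kmax_beyond_rank_is_an_error(self, correlated_pair_segment):
        m = compute_covariance(correlated_pair_segment)  # rank 1
        with pytest.raises(errors.RankError):
            project_images(m, 2)


class TestVarianceCaptured:
    def test_known_fraction(self):
        rng = np.random.default_rng(3)
        seg = random_segment(rng, n_frames=30, n_atoms=3)
        m = compute_covariance(seg)
        k = 2
        expected = m.eigenvalues[:k].sum() / m.eigenvalues.sum()
        assert variance_captured(m, k) == pytest.approx(expected, rel=1e-12)
        assert variance_captured(m, len(m.eigenvalues)) == pytest.approx(1.0)

    def test_rank_one_toy_is_fully_captured(self, correlated_pair_segment):
        m = compute_covariance(correlated_pair_segment)
        assert variance_captured(m, 1) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_is_undefined(self):
        seg = TrajectorySegment(np.zeros((2, 2, 3)), make_atoms(2), 1.0)
        with pytest.raises(errors.DataError):
            variance_captured(compute_covariance(seg), 1)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(4)
        m = compute_covariance(random_segment(rng, n_frames=25, n_atoms=5))
        fractions = [variance_captured(m, k)
                     for k in range(1, len(m.eigenvalues) + 1)]
        assert np.all(np.diff(fractions) >= -1e-12)


class TestSuperposition:
    def test_rigid_motion_is_removed_exactly(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(5)
        base = rng.random((6, 3))
        frames = []
        for t in range(8):
            rot = Rotation.random(random_state=np.random.RandomState(t))
            frames.append(rot.apply(base) + rng.random(3))
        seg = TrajectorySegment(np.array(frames), make_atoms(6), 1.0)
        fit = superpose_frames(seg, "segment-mean")
        assert fit.coords.var(axis=0).max() < 1e-20

    def test_idempotence(self):
        rng = np.random.default_rng(6)
        seg = random_segment(rng, n_frames=10, n_atoms=5)
        once = superpose_frames(seg, "segment-mean")
        twice = superpose_frames(once, "segment-mean")
        assert np.abs(once.coords - twice.coords).max() < 1e-12

    def test_recovers_known_rotation(self):
        """Independent SVD-Kabsch oracle on a hand-built 2-frame case."""
        rng = np.random.default_rng(7)
        base = rng.random((4, 3))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1.0]])
        moved = base @ rot.T + np.array([0.3, -0.2, 0.5])
        seg = TrajectorySegment(np.array([base, moved]), make_atoms(4), 1.0)
        fit = superpose_frames(seg, "first-frame")

        # oracle: optimal rotation via SVD of the cross-covariance
        p = moved - moved.mean(axis=0)
        q = base - base.mean(axis=0)
        u, _, vt = np.linalg.svd(p.T @ q)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        r_opt = vt.T @ np.diag([1, 1, d]) @ u.T
        expected = p @ r_opt.T + base.mean(axis=0)
        np.testing.assert_allclose(fit.coords[1], expected, atol=1e-10)

    def test_collinear_fit_selection_is_degenerate(self):
        coords = np.zeros((2, 4, 3))
        coords[:, :, 0] = np.arange(4)
        seg = TrajectorySegment(coords, make_atoms(4), 1.0)
        with pytest.raises(errors.GeometryError):
            superpose_frames(seg, "first-frame")


class TestAveraging:
    def test_single_segment_equals_direct_descriptor(self):
        rng = np.random.default_rng(8)
        seg = random_segment(rng, n_frames=30, n_atoms=6)
        sel = select(seg, "all")
        avg = average_descriptors([seg], sel, 3, "flexibility")
        m = compute_covariance(superpose_frames(seg, "segment-mean", sel), sel)
        direct = flexibility_profile(project_images(m, 3))
        np.testing.assert_allclose(avg.values, direct.values, atol=1e-12)
        np.testing.assert_allclose(avg.sd, 0.0, atol=1e-12)

    def test_two_segments_average_elementwise(self):
        rng = np.random.default_rng(9)
        segs = [random_segment(rng, n_frames=25, n_atoms=5)
                for _ in range(2)]
        sel = select(segs[0], "all")
        singles = [average_descriptors([s], sel, 2, "correlation",
                                       descriptor_selection=sel).matrix
                   for s in segs]
        both = average_descriptors(segs, sel, 2, "correlation",
                                   descriptor_selection=sel)
        np.testing.assert_allclose(both.matrix,
                                   (singles[0] + singles[1]) / 2, atol=1e-12)

    def test_mismatched_atom_tables_are_rejected(self):
        rng = np.random.default_rng(10)
        a = random_segment(rng, n_frames=5, n_atoms=4)
        b = random_segment(rng, n_frames=5, n_atoms=4, chains=("B",))
        with pytest.raises(errors.ConsistencyError):
            average_descriptors([a, b], select(a, "all"), 2, "flexibility")


class TestParameterRecovery:
    def test_blocks_are_stiff_and_linkers_flexible(self, chain_network):
        """Planted rigid blocks show low F; the linker shows high F."""
        from ecdyn.synthetic_dynamics import SimulationConfig, simulate

        seg = simulate(chain_network, SimulationConfig(
            n_frames=10_000, frame_interval=0.1, seed=21))
        sel = select(seg, "all")
        flex = average_descriptors([seg], sel, 6, "flexibility")
        res = np.array([a.residue_index for a in flex.atoms])
        linker = flex.values[(res >= 6) & (res <= 8)]
        blocks = flex.values[(res < 6) | (res > 8)]
        assert linker.mean() > blocks.mean()
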