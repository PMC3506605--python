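"""Ensemble analyses: superposition, PCA, overlap, RMSF, decomposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ringsym import (
    KB_KCAL_PER_MOL_K,
    TrajectoryEnsemble,
    TrajectorySpec,
    covariance_from_modes,
    decompose_fluctuations,
    intra_subunit_rmsf,
    mode_overlap,
    pca,
    sample_trajectory,
    subspace_overlap,
    subunit_com_axis_covariance,
    superpose_frames,
    variance_by_irrep,
)
from ringsym.ensemble_analysis import PrincipalModeSet

from conftest import modes_by_wavenumber


def _rigid_translation_traj(ring, n_frames=20, seed=0):
    rng = np.random.default_rng(seed)
    shifts = rng.normal(0, 2.0, (n_frames, 1, 3))
    return TrajectoryEnsemble(ring.coords[None] + shifts, ring.n)


class TestSuperpose:
    def test_translations_removed(self, ring12):
        ring, _, _, _ = ring12
        traj = _rigid_translation_traj(ring)
        aligned = superpose_frames(traj, scope="global")
        spread = aligned.frames.std(axis=0).max()
        assert spread < 1e-9

    def test_rotations_removed(self, ring12):
        ring, _, _, _ = ring12
        rng = np.random.default_rng(1)
        frames = np.stack(
            [ring.coords @ Rotation.random(rng=rng).as_matrix().T for _ in range(10)]
        )
        aligned = superpose_frames(TrajectoryEnsemble(frames, ring.n), scope="global")
        assert aligned.frames.std(axis=0).max() < 1e-9

    def test_idempotent(self, ring12):
        ring, enm, modes, _ = ring12
        traj = sample_trajectory(modes, ring, TrajectorySpec(n_frames=50, seed=3))
        once = superpose_frames(traj, scope="global")
        twice = superpose_frames(once, scope="global")
        np.testing.assert_allclose(twice.frames, once.frames, atol=1e-10)

    def test_single_frame_rejected(self, ring12):
        ring, _, _, _ = ring12
        with pytest.raises(ValueError, match="F >= 2"):
            TrajectoryEnsemble(ring.coords[None], ring.n)


class TestPca:
    def test_recovers_single_mode(self, ring12):
        ring, _, modes, _ = ring12
        k = modes.nonrigid_indices()[0]
        traj = sample_trajectory(
            modes, ring, TrajectorySpec(n_frames=500, mode_indices=[k], seed=4)
        )
        principal = pca(traj)
        u = modes.cartesian_vector(k)
        assert abs(principal.vectors[:, 0] @ u) > 0.99
        assert principal.variances[0] / max(principal.variances[1], 1e-300) > 100

    def test_identical_frames_zero_variance(self, ring12):
        ring, _, _, _ = ring12
        traj = TrajectoryEnsemble(np.repeat(ring.coords[None], 5, axis=0), ring.n,
                                  alignment_state="global")
        principal = pca(traj)
        np.testing.assert_allclose(principal.variances, 0.0, atol=1e-16)

    def test_total_variance_identity(self, ring12):
        ring, enm, modes, _ = ring12
        traj = sample_trajectory(modes, ring, TrajectorySpec(n_frames=200, seed=5))
        principal = pca(traj)
        x = traj.frames.reshape(200, -1)
        msd = np.mean(np.sum((x - x.mean(axis=0)) ** 2, axis=1))
        assert principal.variances.sum() == pytest.approx(msd, rel=1e-10)

    def test_unaligned_rejected(self, ring12):
        ring, _, _, _ = ring12
        traj = _rigid_translation_traj(ring)
        with pytest.raises(ValueError, match="align"):
            pca(traj)

    def test_sampled_msf_matches_analytic_covariance(self, ring12):
        """Monte-Carlo fluctuations agree with kB T H^+ on the diagonal."""
        ring, _, modes, _ = ring12
        temperature = 328.0
        traj = sample_trajectory(
            modes, ring, TrajectorySpec(n_frames=20000, temperature=temperature, seed=6)
        )
        sampled = traj.frames.var(axis=0).sum(axis=1)  # per-atom MSF
        cov = covariance_from_modes(modes, temperature)
        analytic = np.diag(cov).reshape(-1, 3).sum(axis=1)
        rel = np.abs(sampled - analytic) / analytic
        assert rel.mean() < 0.05


class TestModeOverlap:
    def test_identity_for_same_set(self, ring12):
        _, _, modes, _ = ring12
        nr = modes.nonrigid_indices()[:10]
        vectors = np.column_stack([modes.cartesian_vector(k) for k in nr])
        principal = PrincipalModeSet(
            mean=np.zeros((modes.vectors.shape[0] // 3, 3)),
            vectors=vectors,
            variances=np.ones(10),
        )
        overlap = mode_overlap(principal, modes, k_pca=10, k_nma=10)
        np.testing.assert_allclose(overlap, np.eye(10), atol=1e-10)

    def test_dimension_mismatch_rejected(self, ring12, ring11):
        _, _, modes12, _ = ring12
        _, _, modes11, _ = ring11
        principal = PrincipalModeSet(
            mean=np.zeros((modes11.vectors.shape[0] // 3, 3)),
            vectors=np.eye(modes11.vectors.shape[0], 4),
            variances=np.ones(4),
        )
        with pytest.raises(ValueError, match="different spaces"):
            mode_overlap(principal, modes12)

    def test_degenerate_pair_recovered_as_subspace(self, ring12):
        """PC1 may mix a degenerate pair, but the 2-subspace overlap is ~1."""
        ring, _, modes, basis = ring12
        pair = list(modes.degenerate_pairs[0])
        traj = sample_trajectory(
            modes, ring, TrajectorySpec(n_frames=10000, mode_indices=pair, seed=7)
        )
        principal = pca(traj)
        upair = np.column_stack([modes.cartesian_vector(k) for k in pair])
        assert subspace_overlap(principal.vectors[:, :2], upair) > 0.95


class TestRmsf:
    def test_requires_per_subunit_alignment(self, ring12):
        ring, _, _, _ = ring12
        traj = _rigid_translation_traj(ring)
        with pytest.raises(ValueError, match="per-subunit"):
            intra_subunit_rmsf(traj)

    def test_identical_frames_zero(self, ring12):
        ring, _, _, _ = ring12
        traj = TrajectoryEnsemble(
            np.repeat(ring.coords[None], 4, axis=0), ring.n,
            alignment_state="per-subunit",
        )
        np.testing.assert_allclose(intra_subunit_rmsf(traj), 0.0, atol=1e-12)

    def test_scales_with_sqrt_temperature(self, ring12):
        # stiff modes keep displacements small, where alignment is linear
        ring, _, modes, _ = ring12
        stiff = list(modes.nonrigid_indices()[-6:])
        r1 = intra_subunit_rmsf(superpose_frames(
            sample_trajectory(modes, ring, TrajectorySpec(
                n_frames=3000, temperature=100.0, mode_indices=stiff, seed=8)),
            scope="per-subunit"))
        r2 = intra_subunit_rmsf(superpose_frames(
            sample_trajectory(modes, ring, TrajectorySpec(
                n_frames=3000, temperature=200.0, mode_indices=stiff, seed=8)),
            scope="per-subunit"))
        np.testing.assert_allclose(r2, np.sqrt(2) * r1, rtol=1e-3)


class TestComCovariance:
    def test_rigid_z_translation_gives_constant_matrix(self, ring12):
        ring, _, _, _ = ring12
        rng = np.random.default_rng(9)
        frames = ring.coords[None] + np.zeros((30, 1, 3))
        frames = frames + np.concatenate(
            [np.zeros((30, 1, 2)), rng.normal(0, 1, (30, 1, 1))], axis=2
        )
        cov = subunit_com_axis_covariance(TrajectoryEnsemble(frames, ring.n))
        np.testing.assert_allclose(cov, cov[0, 0], atol=1e-12)

    def test_gamma2_sampling_reproduces_sign_pattern(self, ring12):
        ring, enm, modes, basis = ring12
        traj = sample_trajectory(
            modes, ring,
            TrajectorySpec(n_frames=5000, wavenumbers=[2], seed=10), enm=enm,
        )
        cov = subunit_com_axis_covariance(traj, axis="z")
        n = ring.n
        for i in range(n):
            assert cov[i, (i + 3) % n] < 0
            assert cov[i, (i + 6) % n] > 0
        w = np.linalg.eigvalsh((cov + cov.T) / 2)
        assert w[0] > -1e-10 * abs(w[-1])


class TestDecomposition:
    def test_per_subunit_translation_is_purely_translational(self, ring12):
        ring, _, _, _ = ring12
        rng = np.random.default_rng(11)
        n, N = ring.n, ring.n_atoms_per_subunit
        shifts = rng.normal(0, 1.0, (40, n, 1, 3))
        frames = (ring.coords.reshape(1, n, N, 3) + shifts).reshape(40, -1, 3)
        d = decompose_fluctuations(TrajectoryEnsemble(frames, n))
        np.testing.assert_allclose(d.internal, 0.0, atol=1e-12)
        np.testing.assert_allclose(d.rotational, 0.0, atol=1e-8)
        np.testing.assert_allclose(d.total, d.translational, atol=1e-8)

    def test_com_preserving_jitter_has_no_translation(self, ring12):
        ring, _, _, _ = ring12
        rng = np.random.default_rng(12)
        n, N = ring.n, ring.n_atoms_per_subunit
        jitter = rng.normal(0, 0.3, (40, n, N, 3))
        jitter -= jitter.mean(axis=2, keepdims=True)  # keep each subunit COM fixed
        frames = (ring.coords.reshape(1, n, N, 3) + jitter).reshape(40, -1, 3)
        d = decompose_fluctuations(TrajectoryEnsemble(frames, n))
        np.testing.assert_allclose(d.translational, 0.0, atol=1e-12)

    def test_rocking_subunits_are_rotational(self, ring12):
        ring, _, _, _ = ring12
        rng = np.random.default_rng(13)
        n, N = ring.n, ring.n_atoms_per_subunit
        blocks = ring.coords.reshape(n, N, 3)
        coms = blocks.mean(axis=1, keepdims=True)
        frames = np.empty((60, n, N, 3))
        for f in range(60):
            for m in range(n):
                angle = rng.normal(0, 0.15)
                rot = Rotation.from_rotvec([angle, 0, 0]).as_matrix()
                frames[f, m] = (blocks[m] - coms[m]) @ rot.T + coms[m]
        d = decompose_fluctuations(
            TrajectoryEnsemble(frames.reshape(60, -1, 3), n)
        )
        assert d.rotational.sum() > 5 * d.internal.sum()
        assert d.rotational.sum() > 5 * d.translational.sum()

    def test_additivity_exact(self, ring12):
        ring, _, modes, _ = ring12
        traj = sample_trajectory(modes, ring, TrajectorySpec(n_frames=300, seed=14))
        d = decompose_fluctuations(traj)
        np.testing.assert_allclose(
            d.total, d.internal + d.translational + d.rotational, atol=1e-12
        )
        assert np.all(d.internal >= 0) and np.all(d.translational >= 0)


class TestVarianceByIrrep:
    def test_shares_sum_to_one_and_match_definition(self, ring12):
        _, _, modes, basis = ring12
        temperature = 328.0
        shares = variance_by_irrep(modes, basis, temperature)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)
        idx0 = modes_by_wavenumber(modes, basis, 0)
        raw0 = sum(KB_KCAL_PER_MOL_K * temperature / modes.eigenvalues[k] for k in idx0)
        total = sum(
            KB_KCAL_PER_MOL_K * temperature / modes.eigenvalues[k]
            for k in modes.nonrigid_indices()
        )
        assert shares[0] == pytest.approx(raw0 / total, rel=1e-10)
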