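"""Conformational-ensemble analysis: PCA, RMSF, COM covariance, decomposition.

These routines take a trajectory of ring conformations (synthetic harmonic
samples here; molecular dynamics in general) and extract the collective
motions: principal components of the Cartesian covariance, their overlap
with elastic-network normal modes, per-residue intra-subunit fluctuations,
the covariance of subunit centers of mass along the symmetry axis, and the
split of each subunit's fluctuation into internal, translational and
rotational parts.

Covariances are maximum-likelihood (divide by F). The rotational part of
the fluctuation decomposition is defined by subtraction and may come out
slightly negative from finite sampling; it is reported as computed.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .elastic_network import KB_KCAL_PER_MOL_K, NormalModeSet
from .cyclic_symmetry import SymmetryBasis, classify_mode
from .ring_geometry import kabsch_superpose

__all__ = [
    "TrajectoryEnsemble",
    "PrincipalModeSet",
    "FluctuationDecomposition",
    "superpose_frames",
    "pca",
    "mode_overlap",
    "subspace_overlap",
    "intra_subunit_rmsf",
    "subunit_com_axis_covariance",
    "decompose_fluctuations",
    "variance_by_irrep",
]

_AXES = {"x": 0, "y": 1, "z": 2}


def _axis_index(axis) -> int:
    return _AXES[axis] if isinstance(axis, str) else int(axis)


@dataclasses.dataclass
class TrajectoryEnsemble:
    """Frames of ring conformations: (F, M, 3) Å with a subunit partition."""

    frames: np.ndarray
    n_subunits: int
    alignment_state: str = "none"  # none | global | per-subunit

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, M, 3)")
        if len(self.frames) < 2:
            raise ValueError("F >= 2 required")
        if self.frames.shape[1] % self.n_subunits:
            raise ValueError("atom count not divisible by the subunit count")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def n_atoms_per_subunit(self) -> int:
        return self.n_atoms // self.n_subunits

    def subunit_frames(self, m: int) -> np.ndarray:
        N = self.n_atoms_per_subunit
        return self.frames[:, m * N : (m + 1) * N]

    def mean_structure(self) -> np.ndarray:
        return self.frames.mean(axis=0)


def superpose_frames(
    traj: TrajectoryEnsemble,
    reference: np.ndarray | None = None,
    scope: str = "global",
) -> TrajectoryEnsemble:
    """Remove rigid-body motion by least-squares superposition.

    ``scope='global'`` fits every frame onto the reference (default: the
    ensemble mean, refined iteratively until it stops moving, which makes
    the operation idempotent); ``scope='per-subunit'`` fits each subunit of
    each frame onto that subunit's average structure, which isolates the
    internal deformations of the subunits.
    """
    if scope not in ("global", "per-subunit"):
        raise ValueError("scope must be 'global' or 'per-subunit'")
    frames = traj.frames

    def _fit_all(frames: np.ndarray, ref: np.ndarray) -> np.ndarray:
        # batched Kabsch: one SVD of a 3x3 per frame
        fc = frames - frames.mean(axis=1, keepdims=True)
        ref_com = ref.mean(axis=0)
        cov = np.einsum("fni,nj->fij", fc, ref - ref_com)
        u, _, vt = np.linalg.svd(cov)
        det = np.linalg.det(np.einsum("fij,fjk->fik", np.transpose(vt, (0, 2, 1)),
                                      np.transpose(u, (0, 2, 1))))
        flip = np.ones((len(frames), 3))
        flip[:, 2] = np.sign(det)
        rot = np.einsum("fji,fj,fjk->fik", vt, flip, np.transpose(u, (0, 2, 1)))
        return np.einsum("fni,fki->fnk", fc, rot) + ref_com

    def _fit_converged(frames: np.ndarray, ref: np.ndarray) -> np.ndarray:
        aligned = _fit_all(frames, ref)
        for _ in range(50):
            mean = aligned.mean(axis=0)
            new = _fit_all(aligned, mean)
            if np.abs(new - aligned).max() < 1e-13:
                return new
            aligned = new
        return aligned

    if scope == "global":
        ref = frames.mean(axis=0) if reference is None else np.asarray(reference)
        if ref.shape != frames.shape[1:]:
            raise ValueError("reference atom count mismatch")
        return TrajectoryEnsemble(_fit_converged(frames, ref), traj.n_subunits, "global")

    N = traj.n_atoms_per_subunit
    aligned = np.empty_like(frames)
    for m in range(traj.n_subunits):
        sub = frames[:, m * N : (m + 1) * N]
        ref = sub.mean(axis=0) if reference is None else np.asarray(reference)[m * N : (m + 1) * N]
        aligned[:, m * N : (m + 1) * N] = _fit_converged(sub, ref)
    return TrajectoryEnsemble(aligned, traj.n_subunits, "per-subunit")


@dataclasses.dataclass
class PrincipalModeSet:
    """PCA of an aligned ensemble: orthonormal vectors, variances descending."""

    mean: np.ndarray
    vectors: np.ndarray  # (3M, K) columns
    variances: np.ndarray  # (K,) Å^2


def pca(traj: TrajectoryEnsemble, n_components: int | None = None) -> PrincipalModeSet:
    """Principal component analysis of the Cartesian covariance of frames."""
    if traj.alignment_state == "none":
        raise ValueError("align the trajectory before PCA")
    f = traj.n_frames
    x = traj.frames.reshape(f, -1)
    mean = x.mean(axis=0)
    xc = x - mean
    rank = min(f - 1, x.shape[1])
    if n_components is not None and n_components > rank:
        warnings.warn(
            f"requested {n_components} components, only {rank} available"
        )
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    variances = s**2 / f
    k = rank if n_components is None else min(n_components, rank)
    return PrincipalModeSet(
        mean=mean.reshape(-1, 3),
        vectors=vt[:k].T.copy(),
        variances=variances[:k].copy(),
    )


def mode_overlap(
    principal: PrincipalModeSet,
    modes: NormalModeSet,
    k_pca: int = 20,
    k_nma: int = 20,
) -> np.ndarray:
    """|dot| overlap matrix between principal modes and non-rigid normal modes.

    Entry (a, b) is the absolute inner product of principal vector a with
    the b-th lowest non-rigid normal mode (Cartesian, unit norm); values lie
    in [0, 1].
    """
    if principal.vectors.shape[0] != modes.vectors.shape[0]:
        raise ValueError("principal and normal modes live in different spaces")
    k_pca = min(k_pca, principal.vectors.shape[1])
    nr = modes.nonrigid_indices()[:k_nma]
    u = np.column_stack([modes.cartesian_vector(k) for k in nr])
    return np.abs(principal.vectors[:, :k_pca].T @ u)


def subspace_overlap(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square of the singular values of A^T B.

    With orthonormal columns this is 1 when the spans coincide and 0 when
    they are orthogonal; for a single vector against a degenerate pair it is
    the root of the summed squared inner products, scaled to [0, 1].
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    if a.shape[0] == 1:
        a = a.T
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if b.shape[0] == 1:
        b = b.T
    s = np.linalg.svd(a.T @ b, compute_uv=False)
    return float(np.sqrt(np.mean(s**2)))


def intra_subunit_rmsf(traj: TrajectoryEnsemble) -> np.ndarray:
    """Per-residue RMSF after per-subunit superposition, averaged over subunits.

    Requires ``alignment_state == 'per-subunit'`` so that rigid-body motion
    of each subunit has been removed and only internal deformation remains.
    """
    if traj.alignment_state != "per-subunit":
        raise ValueError("intra-subunit RMSF requires per-subunit alignment")
    delta = traj.frames - traj.mean_structure()
    msf = np.mean(np.sum(delta**2, axis=2), axis=0)  # (M,)
    return msf.reshape(traj.n_subunits, -1).mean(axis=0) ** 0.5


def _subunit_coms(traj: TrajectoryEnsemble) -> np.ndarray:
    """(F, n, 3) center of mass of each subunit in each frame."""
    f, _, _ = traj.frames.shape
    return traj.frames.reshape(f, traj.n_subunits, -1, 3).mean(axis=2)


def subunit_com_axis_covariance(traj: TrajectoryEnsemble, axis="z") -> np.ndarray:
    """n x n covariance of the subunit-COM coordinates along one axis.

    Computed on globally aligned (or raw) frames so that genuine subunit
    motion is preserved. Standing waves of wavenumber p leave the imprint
    cov(i, j) ∝ cos(p * (theta_i - theta_j)): for p = 2 on a 12-ring,
    cov(i, i+3) < 0 and cov(i, i+6) > 0.
    """
    if traj.alignment_state == "per-subunit":
        raise ValueError("per-subunit alignment destroys subunit COM motion")
    z = _subunit_coms(traj)[:, :, _axis_index(axis)]  # (F, n)
    zc = z - z.mean(axis=0)
    return zc.T @ zc / traj.n_frames


@dataclasses.dataclass
class FluctuationDecomposition:
    """Per-subunit variance split along one axis (Å^2): totals and parts.

    total = internal + translational + rotational per subunit, exactly by
    construction; the rotational part is the remainder and can be slightly
    negative under finite sampling. ``per_atom_*`` are the same numbers
    divided by the subunit atom count.
    """

    axis: int
    total: np.ndarray
    internal: np.ndarray
    translational: np.ndarray
    rotational: np.ndarray

    def summary(self) -> dict[str, float]:
        return {
            "total": float(self.total.mean()),
            "internal": float(self.internal.mean()),
            "translational": float(self.translational.mean()),
            "rotational": float(self.rotational.mean()),
        }


def decompose_fluctuations(traj: TrajectoryEnsemble, axis="z") -> FluctuationDecomposition:
    """Split each subunit's fluctuation along an axis into three parts.

    total: sum over the subunit's atoms of the variance of the axis
    coordinate (no superposition). internal: the same after superposing
    each subunit onto its average structure. translational:
    N_subunit * var(subunit COM axis coordinate). rotational: the
    remainder, total - internal - translational.
    """
    if traj.alignment_state == "per-subunit":
        raise ValueError("decomposition needs raw or globally aligned frames")
    ax = _axis_index(axis)
    n, N = traj.n_subunits, traj.n_atoms_per_subunit
    coords = traj.frames[:, :, ax]  # (F, M)
    var_atom = coords.var(axis=0)  # ML variance per atom
    total = var_atom.reshape(n, N).sum(axis=1)

    internal = np.empty(n)
    aligned = superpose_frames(traj, scope="per-subunit")
    var_int = aligned.frames[:, :, ax].var(axis=0)
    internal[:] = var_int.reshape(n, N).sum(axis=1)

    coms = _subunit_coms(traj)[:, :, ax]  # (F, n)
    translational = N * coms.var(axis=0)
    rotational = total - internal - translational
    return FluctuationDecomposition(
        axis=ax,
        total=total,
        internal=internal,
        translational=translational,
        rotational=rotational,
    )


def variance_by_irrep(
    modes: NormalModeSet,
    basis: SymmetryBasis,
    temperature: float,
) -> dict[int, float]:
    """Share of the total thermal variance carried by each Gamma_p subspace.

    Each non-rigid mode contributes kB T / lambda; shares are normalized to
    sum to 1. Gamma_0 and (for even n) Gamma_(n/2) have half the dimension
    of the paired subspaces, so their shares sit on a half-size footing.
    Mixed modes are assigned to their maximum-weight subspace with a warning.
    """
    shares = {p: 0.0 for p in basis.wavenumbers}
    mixed = 0
    for k in modes.nonrigid_indices():
        p, weights = classify_mode(modes.cartesian_vector(k), basis)
        if weights[p] <= 0.99:
            mixed += 1
        shares[p] += KB_KCAL_PER_MOL_K * temperature / modes.eigenvalues[k]
    if mixed:
        warnings.warn(f"{mixed} modes were not pure; assigned by max weight")
    norm = sum(shares.values())
    return {p: v / norm for p, v in shares.items()}
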