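"""Elastic network model (ENM) and normal mode analysis.

The potential is a sum of Hookean pair terms V = sum_{|r0_ij| < Rc}
(K/2) (|r_ij| - |r0_ij|)^2 over all node pairs closer than the cutoff Rc in
the reference structure. Normal modes are eigenpairs of the mass-weighted
Hessian at the reference; thermal covariances follow from equipartition,
C = kB T H^+ (pseudo-inverse over the non-rigid modes).

Units: lengths in Å, spring constants in kcal mol^-1 Å^-2, kB in
kcal mol^-1 K^-1. Node masses are uniform (unit) by default, so mode
frequencies sqrt(lambda) are in the arbitrary unit sqrt(K/m).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .ring_geometry import RingStructure

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "ElasticNetworkModel",
    "NormalModeSet",
    "build_enm",
    "build_hessian",
    "normal_modes",
    "covariance_from_modes",
]

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL_PER_MOL_K = 0.0019872

#: Eigenvalues below this fraction of the largest are rigid-body modes.
RIGID_TOL = 1e-8

#: Relative gap below which two eigenvalues count as degenerate.
DEGENERACY_RTOL = 1e-6


@dataclasses.dataclass
class ElasticNetworkModel:
    """Hookean network on a reference structure.

    ``contacts`` holds unordered index pairs with |r0_ij| < cutoff;
    ``contact_k`` the per-contact spring constant (uniform K times
    ``core_stiffness`` for intra-subunit pairs when a subunit partition is
    known, which makes subunit cores stiff and interfaces soft).
    """

    reference_coords: np.ndarray
    cutoff: float
    spring_constant: float
    masses: np.ndarray
    contacts: np.ndarray
    contact_k: np.ndarray
    n_subunits: int | None = None
    core_stiffness: float = 1.0

    @property
    def n_atoms(self) -> int:
        return len(self.reference_coords)

    def is_intra_subunit(self) -> np.ndarray:
        """Boolean mask over contacts: both endpoints in the same subunit."""
        if self.n_subunits is None:
            raise ValueError("model has no subunit partition")
        N = self.n_atoms // self.n_subunits
        return (self.contacts[:, 0] // N) == (self.contacts[:, 1] // N)

    def contact_energies(self, coords: np.ndarray) -> np.ndarray:
        """Per-contact strain energy (kcal/mol) of a deformed configuration."""
        coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        i, j = self.contacts.T
        d = np.linalg.norm(coords[i] - coords[j], axis=1)
        d0 = np.linalg.norm(
            self.reference_coords[i] - self.reference_coords[j], axis=1
        )
        return 0.5 * self.contact_k * (d - d0) ** 2

    def potential_energy(self, coords: np.ndarray) -> float:
        return float(self.contact_energies(coords).sum())


def build_enm(
    structure: RingStructure | np.ndarray,
    cutoff: float = 12.0,
    spring_constant: float = 1.0,
    n_subunits: int | None = None,
    core_stiffness: float = 1.0,
    masses: np.ndarray | None = None,
) -> ElasticNetworkModel:
    """Build the contact network with a strict distance cutoff |r0_ij| < Rc.

    Raises ``ValueError("disconnected network")`` when the contact graph is
    not a single connected component (a disconnected network adds spurious
    zero modes).
    """
    if cutoff <= 0 or spring_constant <= 0:
        raise ValueError("cutoff and spring_constant must be positive")
    if isinstance(structure, RingStructure):
        coords = structure.coords
        if n_subunits is None:
            n_subunits = structure.n
    else:
        coords = np.asarray(structure, dtype=float)
    m = len(coords)
    tree = cKDTree(coords)
    pairs = np.array(sorted(tree.query_pairs(r=cutoff)), dtype=int)
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < cutoff]  # strict inequality
    if len(pairs) == 0:
        raise ValueError("disconnected network: no contacts under the cutoff")
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m)
    )
    ncomp, _ = connected_components(adj, directed=False)
    if ncomp != 1:
        raise ValueError(
            f"disconnected network: {ncomp} components under cutoff {cutoff} Å"
        )
    contact_k = np.full(len(pairs), float(spring_constant))
    model = ElasticNetworkModel(
        reference_coords=coords.copy(),
        cutoff=float(cutoff),
        spring_constant=float(spring_constant),
        masses=np.ones(m) if masses is None else np.asarray(masses, float),
        contacts=pairs,
        contact_k=contact_k,
        n_subunits=n_subunits,
        core_stiffness=float(core_stiffness),
    )
    if core_stiffness != 1.0:
        model.contact_k = np.where(
            model.is_intra_subunit(),
            spring_constant * core_stiffness,
            spring_constant,
        )
    return model


def build_hessian(model: ElasticNetworkModel) -> np.ndarray:
    """Mass-weighted analytic Hessian of the ENM at the reference structure.

    At the reference the pair term contributes the 3x3 block
    -k * (d_hat d_hat^T) between i and j, with the diagonal blocks equal to
    minus the sum of the off-diagonal blocks (translation invariance).
    """
    coords = model.reference_coords
    m = model.n_atoms
    h = np.zeros((3 * m, 3 * m))
    i, j = model.contacts.T
    dvec = coords[i] - coords[j]
    dist = np.linalg.norm(dvec, axis=1)
    dhat = dvec / dist[:, None]
    blocks = model.contact_k[:, None, None] * (
        dhat[:, :, None] * dhat[:, None, :]
    )
    for (a, b), blk in zip(model.contacts, blocks):
        sa, sb = slice(3 * a, 3 * a + 3), slice(3 * b, 3 * b + 3)
        h[sa, sb] -= blk
        h[sb, sa] -= blk
        h[sa, sa] += blk
        h[sb, sb] += blk
    w = 1.0 / np.sqrt(np.repeat(model.masses, 3))
    return h * np.outer(w, w)


@dataclasses.dataclass
class NormalModeSet:
    """Eigenpairs of the mass-weighted Hessian, eigenvalues ascending.

    ``vectors`` holds orthonormal eigenvectors as columns; ``rigid_body``
    flags the six zero modes of a connected 3-D network;
    ``degenerate_pairs`` lists index pairs with matching eigenvalues.
    """

    eigenvalues: np.ndarray
    vectors: np.ndarray
    rigid_body: np.ndarray
    degenerate_pairs: list[tuple[int, int]]
    masses: np.ndarray

    @property
    def frequencies(self) -> np.ndarray:
        """sqrt(lambda), ascending, in the arbitrary unit sqrt(K/m)."""
        return np.sqrt(np.clip(self.eigenvalues, 0.0, None))

    @property
    def n_modes(self) -> int:
        return self.vectors.shape[1]

    def nonrigid_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.rigid_body)

    def cartesian_vector(self, k: int) -> np.ndarray:
        """Mode k as unit-norm Cartesian displacements (mass-unweighted)."""
        v = self.vectors[:, k] / np.sqrt(np.repeat(self.masses, 3))
        return v / np.linalg.norm(v)


def normal_modes(
    hessian: np.ndarray, masses: np.ndarray | None = None
) -> NormalModeSet:
    """Diagonalize a mass-weighted Hessian into a :class:`NormalModeSet`.

    Exactly six near-zero eigenvalues (relative tolerance ``RIGID_TOL``)
    are expected for a connected network; anything else raises
    ``ValueError("ill-conditioned network...")``.
    """
    hessian = np.asarray(hessian, dtype=float)
    if hessian.ndim != 2 or hessian.shape[0] != hessian.shape[1]:
        raise ValueError("hessian must be square")
    if not np.allclose(hessian, hessian.T, atol=1e-10):
        raise ValueError("hessian must be symmetric")
    m = hessian.shape[0] // 3
    if masses is None:
        masses = np.ones(m)
    w, v = np.linalg.eigh(hessian)
    lam_max = max(float(w[-1]), 1e-300)
    rigid = w < RIGID_TOL * lam_max
    if int(rigid.sum()) != 6:
        raise ValueError(
            f"ill-conditioned network: {int(rigid.sum())} near-zero modes, expected 6"
        )
    w = np.where(rigid, 0.0, w)
    pairs: list[tuple[int, int]] = []
    k = 6
    while k < len(w) - 1:
        if abs(w[k + 1] - w[k]) <= DEGENERACY_RTOL * max(abs(w[k]), abs(w[k + 1])):
            pairs.append((k, k + 1))
            k += 2
        else:
            k += 1
    return NormalModeSet(
        eigenvalues=w,
        vectors=v,
        rigid_body=rigid,
        degenerate_pairs=pairs,
        masses=np.asarray(masses, dtype=float),
    )


def covariance_from_modes(
    modes: NormalModeSet,
    temperature: float,
    mode_subset: Sequence[int] | None = None,
) -> np.ndarray:
    """Thermal covariance C = sum_k (kB T / lambda_k) u_k u_k^T (Å^2).

    Restricted to ``mode_subset`` when given (rigid modes are rejected);
    the result is mass-unweighted back to Cartesian fluctuations.
    """
    if mode_subset is None:
        idx = modes.nonrigid_indices()
    else:
        idx = np.asarray(mode_subset, dtype=int)
        if np.any(modes.rigid_body[idx]):
            raise ValueError("mode subset contains a rigid-body mode")
    lam = modes.eigenvalues[idx]
    u = modes.vectors[:, idx] / np.sqrt(np.repeat(modes.masses, 3))[:, None]
    return (u * (KB_KCAL_PER_MOL_K * temperature / lam)) @ u.T
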