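"""Cyclic-group machinery: characters, symmetry coordinates, irreps, nodes.

The cyclic group C_n acting on a ring of n subunits has n one-dimensional
complex irreducible representations T_k (k = 1..n) with characters
T_k(R^m) = omega^((k-1) m), omega = exp(2 pi i / n). On the 3 n N_subunit
conformation space the projection-operator construction

    U_j^(k) = n^(-1/2) sum_m conj(T_k(R^m)) R^m e_j

builds a unitary basis of symmetry coordinates, where R permutes subunit
blocks (m -> m+1) AND rotates every 3-vector by 2 pi / n about +z. Complex
conjugate irreps T_(p+1) and T_(n-p+1) combine into the real, physically
meaningful subspace labelled here by its wavenumber p:

    Gamma_0     = T_1              (dim 3 N, totally symmetric, 0 nodes)
    Gamma_p     = T_(p+1) + T_(n-p+1)  (dim 6 N, doubly degenerate, 2p nodes)
    Gamma_(n/2) = T_(n/2+1)        (dim 3 N, even n only, n nodes)

A mode in Gamma_p is a stationary wave cos(p theta + phase) around the
ring, with 2p nodes of zero displacement and maximal deformation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .ring_geometry import RingStructure, rotation_z

__all__ = [
    "CharacterTable",
    "SymmetryBasis",
    "StationaryWaveProfile",
    "character_table",
    "symmetry_basis",
    "block_diagonalize",
    "classify_mode",
    "stationary_wave_profile",
]


@dataclasses.dataclass
class CharacterTable:
    """Complex character table of C_n: rows T_k, columns group elements R^m."""

    n: int
    omega: complex
    table: np.ndarray  # (n, n) complex, table[k-1, m] = omega**((k-1) m)

    def character(self, k: int, m: int) -> complex:
        """Character T_k(R^m) with 1-based irrep index k."""
        if not 1 <= k <= self.n:
            raise ValueError(f"irrep index k must be in 1..{self.n}")
        return complex(self.table[k - 1, m % self.n])


def character_table(n: int) -> CharacterTable:
    """Character table of the cyclic group C_n (n >= 2)."""
    if n < 2:
        raise ValueError("cyclic group order must be >= 2")
    omega = np.exp(2j * np.pi / n)
    k, m = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return CharacterTable(n=n, omega=complex(omega), table=omega ** (k * m))


class SymmetryBasis:
    """Symmetry-coordinate bases of C_n on a ring of n subunits.

    ``n_subunit_atoms`` is the number of Cα atoms per subunit; the full
    conformation space has dimension 3 * n * n_subunit_atoms.
    """

    def __init__(self, n: int, n_subunit_atoms: int):
        if n < 2 or n_subunit_atoms < 1:
            raise ValueError("need n >= 2 subunits and >= 1 atom per subunit")
        self.n = n
        self.n_subunit_atoms = n_subunit_atoms
        self.subunit_dim = 3 * n_subunit_atoms
        self.dim = n * self.subunit_dim
        self.characters = character_table(n)
        self._real_cache: dict[int, np.ndarray] = {}

    # -- wavenumber bookkeeping -------------------------------------------
    @property
    def wavenumbers(self) -> list[int]:
        """Valid wavenumbers p = 0 .. floor(n/2)."""
        return list(range(self.n // 2 + 1))

    def subspace_dim(self, p: int) -> int:
        self._check_p(p)
        return self.subunit_dim if (p == 0 or 2 * p == self.n) else 2 * self.subunit_dim

    def _check_p(self, p: int) -> None:
        if p not in self.wavenumbers:
            raise ValueError(
                f"wavenumber {p} does not exist for C_{self.n} "
                f"(valid: 0..{self.n // 2})"
            )

    # -- operators and bases ----------------------------------------------
    def rotation_operator(self, m: int = 1) -> np.ndarray:
        """Matrix of R^m: block permutation (subunit s -> s+m) composed with
        rotation of every 3-vector by 2 pi m / n about +z."""
        d, n = self.subunit_dim, self.n
        rz = np.kron(np.eye(self.n_subunit_atoms), rotation_z(2 * np.pi * m / n))
        op = np.zeros((self.dim, self.dim))
        for s in range(n):
            t = (s + m) % n
            op[t * d : (t + 1) * d, s * d : (s + 1) * d] = rz
        return op

    def complex_basis(self, k: int) -> np.ndarray:
        """(dim, 3N) unitary basis of the complex irrep T_k (1-based k)."""
        if not 1 <= k <= self.n:
            raise ValueError(f"irrep index k must be in 1..{self.n}")
        n, d = self.n, self.subunit_dim
        u = np.zeros((self.dim, d), dtype=complex)
        for m in range(n):
            chi = self.characters.table[k - 1, m]
            rz = np.kron(
                np.eye(self.n_subunit_atoms), rotation_z(2 * np.pi * m / n)
            )
            u[m * d : (m + 1) * d] = np.conj(chi) * rz / np.sqrt(n)
        return u

    def real_basis(self, p: int) -> np.ndarray:
        """Orthonormal real basis of the Gamma_p subspace (wavenumber p).

        For 1 <= p with 2p != n this pairs T_(p+1) with its conjugate
        T_(n-p+1): columns are sqrt(2) Re U and -sqrt(2) Im U of T_(p+1)
        (real parts first, deterministic ordering).
        """
        self._check_p(p)
        if p not in self._real_cache:
            if p == 0 or 2 * p == self.n:
                b = self.complex_basis(p + 1).real.copy()
            else:
                u = self.complex_basis(p + 1)
                b = np.hstack([np.sqrt(2) * u.real, -np.sqrt(2) * u.imag])
            self._real_cache[p] = b
        return self._real_cache[p]

    def full_real_basis(self) -> np.ndarray:
        """Complete orthogonal matrix: all Gamma_p bases side by side."""
        return np.hstack([self.real_basis(p) for p in self.wavenumbers])


def symmetry_basis(n: int, n_subunit_atoms: int) -> SymmetryBasis:
    """Construct the C_n symmetry-coordinate basis."""
    return SymmetryBasis(n, n_subunit_atoms)


def block_diagonalize(
    hessian: np.ndarray,
    basis: SymmetryBasis,
    leak_tol: float = 1e-8,
) -> dict[int, np.ndarray]:
    """Represent a C_n-symmetric Hessian on the symmetry coordinates.

    Returns one real block per wavenumber p; the union of the block spectra
    equals the full spectrum. Off-block leakage above
    ``leak_tol * ||H||_F`` means the structure behind the Hessian is not
    C_n-symmetric and raises ``ValueError``.
    """
    hessian = np.asarray(hessian, dtype=float)
    if hessian.shape != (basis.dim, basis.dim):
        raise ValueError("hessian dimension does not match the basis")
    b = basis.full_real_basis()
    ht = b.T @ hessian @ b
    blocks: dict[int, np.ndarray] = {}
    mask = np.ones_like(ht, dtype=bool)
    start = 0
    for p in basis.wavenumbers:
        dim = basis.subspace_dim(p)
        sl = slice(start, start + dim)
        blocks[p] = ht[sl, sl].copy()
        mask[sl, sl] = False
        start += dim
    leakage = np.linalg.norm(ht[mask])
    scale = max(np.linalg.norm(hessian), 1e-300)
    if leakage > leak_tol * scale:
        raise ValueError(
            "structure not C_n-symmetric: off-block leakage "
            f"{leakage / scale:.2e} exceeds {leak_tol:.0e}"
        )
    return blocks


def classify_mode(
    mode_vector: np.ndarray, basis: SymmetryBasis
) -> tuple[int, np.ndarray]:
    """Assign a unit-norm mode to a wavenumber p by subspace projection.

    Returns ``(p, weights)`` where ``weights[p]`` is the squared projection
    onto Gamma_p (summing to 1 by completeness). Labels within 0.01 of the
    maximum tie-break toward the lower wavenumber; a mode is conventionally
    "pure" when its top weight exceeds 0.99.
    """
    v = np.asarray(mode_vector, dtype=float).ravel()
    if v.shape != (basis.dim,):
        raise ValueError("mode vector dimension does not match the basis")
    weights = np.array(
        [np.sum((self_b.T @ v) ** 2) for self_b in map(basis.real_basis, basis.wavenumbers)]
    )
    best = float(weights.max())
    label = int(min(p for p in basis.wavenumbers if weights[p] >= best - 0.01))
    return label, weights


@dataclasses.dataclass
class StationaryWaveProfile:
    """Per-subunit amplitude of a mode viewed as a standing wave on the ring.

    ``amplitudes[m]`` is the signed displacement of subunit m along the
    dominant collective direction; a pure Gamma_p mode follows
    A cos(p theta + phase) with 2p nodes.
    """

    amplitudes: np.ndarray
    subunit_angles: np.ndarray
    wavenumber: int
    amplitude: float
    phase_deg: float
    node_angles: np.ndarray
    node_count: int
    mixed: bool
    weights: np.ndarray


def _raw_sign_changes(values: np.ndarray, zero_tol: float) -> int:
    """Cyclic sign changes, skipping entries below ``zero_tol`` in magnitude."""
    signs = [np.sign(v) for v in values if abs(v) > zero_tol]
    if len(signs) < 2:
        return 0
    changes = sum(a != b for a, b in zip(signs, signs[1:] + signs[:1]))
    return int(changes)


def stationary_wave_profile(
    mode_vector: np.ndarray,
    ring: RingStructure,
    basis: SymmetryBasis | None = None,
    purity: float = 0.99,
) -> StationaryWaveProfile:
    """Standing-wave view of a mode: per-subunit amplitudes, fit and nodes.

    The subunit amplitude is the signed projection of the subunit's summed
    displacement onto its dominant collective direction (the z axis for
    out-of-plane modes). For a pure Gamma_p mode the profile is fitted by
    least squares to A cos(p theta + phase) and the 2p node angles are the
    zeros of the fit; mixed modes fall back to raw cyclic sign changes and
    carry ``mixed=True``.
    """
    if basis is None:
        basis = SymmetryBasis(ring.n, ring.n_atoms_per_subunit)
    v = np.asarray(mode_vector, dtype=float).ravel()
    p, weights = classify_mode(v, basis)
    pure = bool(weights[p] > purity)

    disp = v.reshape(-1, 3)
    n, N = ring.n, ring.n_atoms_per_subunit
    sums = disp.reshape(n, N, 3).sum(axis=1)  # (n, 3) per-subunit net motion
    _, _, vt = np.linalg.svd(sums, full_matrices=False)
    direction = vt[0]
    # Deterministic sign: prefer +z, else first significant component > 0.
    if abs(direction[2]) > 1e-8:
        direction = direction * np.sign(direction[2])
    else:
        lead = direction[np.argmax(np.abs(direction))]
        direction = direction * np.sign(lead)
    amps = sums @ direction
    theta = ring.subunit_com_angles

    if pure and p == 0:
        return StationaryWaveProfile(
            amplitudes=amps,
            subunit_angles=theta,
            wavenumber=0,
            amplitude=float(np.mean(amps)),
            phase_deg=0.0,
            node_angles=np.array([]),
            node_count=0,
            mixed=False,
            weights=weights,
        )

    th = np.radians(theta)
    if pure:
        design = np.column_stack([np.cos(p * th), np.sin(p * th)])
        (c1, c2), *_ = np.linalg.lstsq(design, amps, rcond=None)
        amp = float(np.hypot(c1, c2))
        phase = float(np.arctan2(-c2, c1))
        # Zeros of A cos(p theta + phase): p theta + phase = pi/2 + k pi.
        k = np.arange(2 * p)
        nodes = np.degrees((np.pi / 2 - phase + k * np.pi) / p) % 360.0
        return StationaryWaveProfile(
            amplitudes=amps,
            subunit_angles=theta,
            wavenumber=p,
            amplitude=amp,
            phase_deg=float(np.degrees(phase)),
            node_angles=np.sort(nodes),
            node_count=2 * p,
            mixed=False,
        weights=weights,
        )

    zero_tol = 1e-6 * max(np.abs(amps).max(), 1e-300)
    changes = _raw_sign_changes(amps, zero_tol)
    # Node positions: subunit-gap midpoints where the sign flips.
    nodes = []
    sig = [(t, np.sign(a)) for t, a in zip(theta, amps) if abs(a) > zero_tol]
    for (t0, s0), (t1, s1) in zip(sig, sig[1:] + sig[:1]):
        if s0 != s1:
            gap = (t1 - t0) % 360.0
            nodes.append((t0 + gap / 2.0) % 360.0)
    return StationaryWaveProfile(
        amplitudes=amps,
        subunit_angles=theta,
        wavenumber=p,
        amplitude=float(np.abs(amps).max()),
        phase_deg=float("nan"),
        node_angles=np.sort(np.array(nodes)),
        node_count=changes,
        mixed=True,
        weights=weights,
    )
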