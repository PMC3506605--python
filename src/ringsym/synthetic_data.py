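"""Synthetic C_n rings and Boltzmann-distributed harmonic trajectories.

The generator builds exactly symmetric toy rings of bead subunits whose
intra-subunit springs are stiffer than the inter-subunit ones — the
characteristic architecture of ring homooligomers, with rigid cores and
soft interfaces — and samples conformational ensembles from the thermal
(Boltzmann) distribution of the elastic network: each mode k receives
independent Gaussian amplitudes of variance kB T / lambda_k per frame.

Frames are statistically independent; the analyses downstream use only
static covariances, for which independent harmonic sampling is exact.
An optional Gaussian perturbation of the reference emulates the
pseudo-symmetry of a thermally distorted ring.

All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .elastic_network import (
    KB_KCAL_PER_MOL_K,
    ElasticNetworkModel,
    NormalModeSet,
    build_enm,
    build_hessian,
    normal_modes,
)
from .cyclic_symmetry import SymmetryBasis, classify_mode
from .ensemble_analysis import TrajectoryEnsemble
from .ring_geometry import RingStructure, rotation_z

__all__ = [
    "ToyRingSpec",
    "TrajectorySpec",
    "make_toy_ring",
    "sample_trajectory",
    "perturb_symmetry",
]

#: Default temperature (K): the growth temperature of the thermophile the
#: reference ring proteins come from.
DEFAULT_TEMPERATURE = 328.0


@dataclasses.dataclass
class ToyRingSpec:
    """Geometry and stiffness of a synthetic C_n bead ring.

    ``radius=None`` picks the radius so adjacent subunit centers sit 6 Å
    apart; under the default 12 Å cutoff, next-nearest subunits then touch
    as well, which keeps the network connected and well-conditioned for
    any n (like real rings, where the cutoff spans several subunits).
    ``core_stiffness`` multiplies intra-subunit spring constants, making
    interfaces the soft spots (>= 1).
    """

    n: int = 12
    beads_per_subunit: int = 3
    radius: float | None = None
    subunit_extent: float = 4.0
    core_stiffness: float = 10.0
    cutoff: float = 12.0
    spring_constant: float = 1.0
    seed: int = 0

    def resolved_radius(self) -> float:
        if self.radius is not None:
            return float(self.radius)
        return 3.0 / np.sin(np.pi / self.n)


@dataclasses.dataclass
class TrajectorySpec:
    """Sampling conditions for a harmonic ensemble.

    ``wavenumbers`` restricts sampling to the Gamma_p subspaces listed;
    ``mode_indices`` selects explicit modes instead; both None means all
    non-rigid modes. ``symmetry_perturbation`` (Å) jitters the reference
    before sampling and recomputes the modes on the perturbed structure.
    """

    temperature: float = DEFAULT_TEMPERATURE
    n_frames: int = 1000
    wavenumbers: Sequence[int] | None = None
    mode_indices: Sequence[int] | None = None
    symmetry_perturbation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("F >= 2 required")
        if self.symmetry_perturbation < 0:
            raise ValueError("symmetry_perturbation must be >= 0")


def make_toy_ring(spec: ToyRingSpec) -> tuple[RingStructure, ElasticNetworkModel]:
    """Generate an exactly C_n-symmetric bead ring and its elastic network.

    Subunit-0 beads are drawn uniformly (seeded) inside a cube of side
    ``subunit_extent`` centered on the ring radius, re-drawn until no two
    beads come closer than 1 Å; the ring is built from exact rotation
    images, so the symmetry residual is at machine precision.
    """
    if spec.n < 3 or spec.beads_per_subunit < 1:
        raise ValueError("need n >= 3 subunits and >= 1 bead per subunit")
    if spec.core_stiffness < 1:
        raise ValueError("core_stiffness must be >= 1")
    rng = np.random.default_rng(spec.seed)
    radius = spec.resolved_radius()
    b = spec.beads_per_subunit
    last_err = "no contacts"
    for _ in range(100):
        offsets = rng.uniform(-spec.subunit_extent / 2, spec.subunit_extent / 2, (b, 3))
        base = np.array([radius, 0.0, 0.0]) + offsets
        if b > 1:
            d = np.linalg.norm(base[:, None] - base[None, :], axis=2)
            if d[np.triu_indices(b, 1)].min() <= 1.0:
                continue
        # Re-zero the subunit COM angle exactly so the ring is born canonical.
        com = base.mean(axis=0)
        sub = base @ rotation_z(-np.arctan2(com[1], com[0])).T
        sub = sub - [0.0, 0.0, sub[:, 2].mean()]
        coords = np.concatenate(
            [sub @ rotation_z(2 * np.pi * m / spec.n).T for m in range(spec.n)]
        )
        ring = RingStructure.from_coords(coords, spec.n)
        try:
            enm = build_enm(
                ring,
                cutoff=spec.cutoff,
                spring_constant=spec.spring_constant,
                n_subunits=spec.n,
                core_stiffness=spec.core_stiffness,
            )
            # reject floppy geometries: softest genuine mode must clear the
            # rigid-mode tolerance with a 10x margin
            modes = normal_modes(build_hessian(enm), enm.masses)
            if modes.eigenvalues[6] < 1e-7 * modes.eigenvalues[-1]:
                last_err = "near-singular soft mode"
                continue
        except ValueError as err:
            last_err = str(err)
            continue
        return ring, enm
    raise ValueError(
        f"{last_err}; increase the cutoff or subunit_extent, or reduce the radius"
    )


def _select_modes(
    modes: NormalModeSet,
    ring: RingStructure,
    spec: TrajectorySpec,
) -> np.ndarray:
    if spec.mode_indices is not None:
        idx = np.asarray(spec.mode_indices, dtype=int)
        if np.any(modes.rigid_body[idx]):
            raise ValueError("explicit mode subset contains a rigid-body mode")
    elif spec.wavenumbers is not None:
        basis = SymmetryBasis(ring.n, ring.n_atoms_per_subunit)
        wanted = set()
        for p in spec.wavenumbers:
            basis._check_p(p)  # rejects e.g. Gamma_6 for an 11-ring
            wanted.add(int(p))
        idx = np.array(
            [
                k
                for k in modes.nonrigid_indices()
                if classify_mode(modes.cartesian_vector(k), basis)[0] in wanted
            ],
            dtype=int,
        )
    else:
        idx = modes.nonrigid_indices()
    if len(idx) == 0:
        raise ValueError("empty mode subset")
    return idx


def sample_trajectory(
    modes: NormalModeSet,
    ring: RingStructure,
    spec: TrajectorySpec,
    enm: ElasticNetworkModel | None = None,
) -> TrajectoryEnsemble:
    """Draw independent frames from the harmonic Boltzmann distribution.

    Frame f is reference + sum_k a_k u_k with a_k ~ N(0, kB T / lambda_k).
    With ``symmetry_perturbation > 0`` the reference is jittered first and
    the modes are recomputed on the perturbed network (``enm`` required to
    supply the network parameters).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.symmetry_perturbation > 0:
        if enm is None:
            raise ValueError("perturbed sampling needs the elastic network model")
        pseed = int(rng.integers(2**31 - 1))
        ring = perturb_symmetry(ring, spec.symmetry_perturbation, pseed)
        enm = build_enm(
            ring.coords,
            cutoff=enm.cutoff,
            spring_constant=enm.spring_constant,
            n_subunits=enm.n_subunits,
            core_stiffness=enm.core_stiffness,
        )
        modes = normal_modes(build_hessian(enm), enm.masses)
    idx = _select_modes(modes, ring, spec)
    lam = modes.eigenvalues[idx]
    sigma = np.sqrt(KB_KCAL_PER_MOL_K * spec.temperature / lam)
    u = np.column_stack([modes.cartesian_vector(k) for k in idx])  # (3M, K)
    amp = rng.standard_normal((spec.n_frames, len(idx))) * sigma
    disp = amp @ u.T
    frames = ring.coords[None, :, :] + disp.reshape(spec.n_frames, -1, 3)
    # No rigid-body modes are sampled, so the frames share one global frame.
    return TrajectoryEnsemble(frames, ring.n, alignment_state="global")


def perturb_symmetry(ring: RingStructure, sigma: float, seed: int) -> RingStructure:
    """Add i.i.d. Gaussian displacements (Å) to every atom of the ring.

    Emulates a pseudo-symmetric, thermally distorted reference; sigma = 0
    returns an identical structure.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return ring
    rng = np.random.default_rng(seed)
    coords = ring.coords + rng.normal(0.0, sigma, ring.coords.shape)
    return RingStructure(
        n=ring.n,
        coords=coords,
        interface_angles=ring.interface_angles.copy(),
        is_exactly_symmetric=False,
        axis_frame=ring.axis_frame,
        subunit=ring.subunit,
        symmetry_tol=ring.symmetry_tol,
    )
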