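"""Shared fixtures: synthetic rings, their modes, and tiny PDB builders."""

from __future__ import annotations

import numpy as np
import pytest

from ringsym import (
    ToyRingSpec,
    build_hessian,
    make_toy_ring,
    normal_modes,
    symmetry_basis,
)


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    xyz,
    altloc: str = " ",
    icode: str = " ",
    element: str = "C",
    record: str = "ATOM",
) -> str:
    x, y, z = xyz
    name_field = f" {name:<3}" if len(name) < 4 else name
    return (
        f"{record:<6}{serial:>5} {name_field}{altloc}{resname:>3} {chain}"
        f"{resseq:>4}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
        f"          {element:>2}"
    )


def make_pdb(lines) -> str:
    return "\n".join(lines + ["END"]) + "\n"


@pytest.fixture(scope="session")
def three_residue_pdb() -> str:
    """Chain A with Cα at (0,0,0), (1,0,0), (2,0,0)."""
    lines = [
        pdb_atom_line(i + 1, "CA", "GLY", "A", i + 1, (float(i), 0.0, 0.0))
        for i in range(3)
    ]
    return make_pdb(lines)


@pytest.fixture(scope="session")
def ring12():
    """Exactly symmetric C12 toy ring with its network, modes and basis."""
    ring, enm = make_toy_ring(ToyRingSpec(n=12, beads_per_subunit=10, seed=1))
    modes = normal_modes(build_hessian(enm), enm.masses)
    basis = symmetry_basis(ring.n, ring.n_atoms_per_subunit)
    return ring, enm, modes, basis


@pytest.fixture(scope="session")
def ring11():
    """Exactly symmetric C11 toy ring (prime subunit count)."""
    ring, enm = make_toy_ring(ToyRingSpec(n=11, beads_per_subunit=10, seed=2))
    modes = normal_modes(build_hessian(enm), enm.masses)
    basis = symmetry_basis(ring.n, ring.n_atoms_per_subunit)
    return ring, enm, modes, basis


def ideal_ring_coords(n: int, radius: float = 30.0, points_per_subunit: int = 1):
    """Perfectly planar ring of point subunits in the xy-plane."""
    angles = 2 * np.pi * np.arange(n * points_per_subunit) / (n * points_per_subunit)
    return np.column_stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros_like(angles)]
    )


def modes_by_wavenumber(modes, basis, p: int):
    """Indices of non-rigid modes classified to Gamma_p."""
    from ringsym import classify_mode

    return [
        k
        for k in modes.nonrigid_indices()
        if classify_mode(modes.cartesian_vector(k), basis)[0] == p
    ]
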