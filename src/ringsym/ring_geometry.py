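"""Ring geometry: Cα structure input, ring detection and the canonical frame.

A ring homooligomer with C_n symmetry is handled in a canonical coordinate
frame throughout the package: the center of mass sits at the origin, the
symmetry axis is +z, subunits are indexed 0..n-1 counterclockwise (viewed
from +z), and the center of mass of subunit 0 lies at angular position
phi = 0. All angles are degrees in [0, 360); all lengths are Angstrom.
"""

from __future__ import annotations

import dataclasses
import string
import warnings
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "SubunitStructure",
    "AxisFrame",
    "RingStructure",
    "read_calpha_structure",
    "read_ring_chains",
    "measure_planarity",
    "detect_symmetry_frame",
    "symmetrize_ring",
    "all_atom_rmsd",
    "kabsch_superpose",
    "rotation_z",
    "write_ring_pdb",
    "planarity_report",
    "RING_PLANARITY_THRESHOLD",
]

#: Third-principal-component threshold (Angstrom) below which a subunit-COM
#: cloud is flat enough to count as a ring.
RING_PLANARITY_THRESHOLD = 2.0


def rotation_z(angle_rad: float) -> np.ndarray:
    """3x3 rotation matrix about +z by ``angle_rad`` (counterclockwise)."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray):
    """Optimal least-squares superposition of ``mobile`` onto ``target``.

    Returns ``(aligned, rmsd)`` where ``aligned = (mobile - com) @ R.T + com_t``.
    Both inputs are (N, 3). Uses the Kabsch algorithm via scipy.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError("point sets differ in shape")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    aligned = rot.apply(mobile - mc) + tc
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - target) ** 2, axis=1))))
    return aligned, rmsd


@dataclasses.dataclass
class SubunitStructure:
    """Cα trace of one subunit (the asymmetric unit of the ring).

    ``residue_ids`` are author residue numbers (insertion codes appended),
    one Cα per residue, strictly increasing. ``heavy_atoms`` optionally maps
    residue id -> {atom name -> xyz} for all-atom RMSD.
    """

    residue_ids: list[str]
    calpha_coords: np.ndarray
    chain_id: str = ""
    heavy_atoms: dict[str, dict[str, np.ndarray]] | None = None

    def __post_init__(self):
        self.calpha_coords = np.asarray(self.calpha_coords, dtype=float)
        if len(self.residue_ids) != len(self.calpha_coords):
            raise ValueError("one Calpha per residue required")
        if len(self.residue_ids) < 3:
            raise ValueError("a subunit needs at least 3 residues")
        keys = [_residue_sort_key(r) for r in self.residue_ids]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError("residue_ids must be strictly increasing")

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)


def _residue_sort_key(rid: str) -> tuple[int, str]:
    num = rid
    icode = ""
    if rid and rid[-1].isalpha():
        num, icode = rid[:-1], rid[-1]
    return int(num), icode


def read_calpha_structure(
    pdb_text: str,
    chain: str,
    residue_range: tuple[int, int],
    keep_heavy_atoms: bool = True,
) -> SubunitStructure:
    """Extract one chain's Cα trace from PDB-format text.

    Only the first MODEL is used; for each residue the first alternate
    location (blank or 'A') is kept; residue numbering follows the author
    numbering in the file, with insertion codes appended to the id.

    Raises ``ValueError("chain not found...")`` if the chain is absent and
    ``ValueError("incomplete backbone...")`` listing residues in the range
    that lack a Cα.
    """
    lo, hi = residue_range
    if hi < lo:
        raise ValueError("residue_range is empty")
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no models in PDB input")
    model = st[0]
    ch = model.find_chain(chain)
    if ch is None:
        raise ValueError(f"chain not found: {chain!r}")

    residue_ids: list[str] = []
    coords: list[np.ndarray] = []
    heavy: dict[str, dict[str, np.ndarray]] = {}
    seen_nums: set[int] = set()
    for res in ch:
        num = res.seqid.num
        if num < lo or num > hi:
            continue
        if res.het_flag == "H" and res.name == "HOH":
            continue
        ca = None
        atoms: dict[str, np.ndarray] = {}
        for atom in res:
            if atom.altloc not in ("", "\x00", "A"):
                continue
            if atom.element.is_hydrogen:
                continue
            pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            if atom.name == "CA" and ca is None:
                ca = pos
            atoms.setdefault(atom.name, pos)
        if ca is None:
            continue
        rid = f"{num}{res.seqid.icode.strip()}"
        seen_nums.add(num)
        residue_ids.append(rid)
        coords.append(ca)
        if keep_heavy_atoms:
            heavy[rid] = atoms

    missing = [str(i) for i in range(lo, hi + 1) if i not in seen_nums]
    if missing:
        raise ValueError(
            "incomplete backbone: residues without Calpha in chain "
            f"{chain}: {', '.join(missing)}"
        )
    return SubunitStructure(
        residue_ids=residue_ids,
        calpha_coords=np.array(coords),
        chain_id=chain,
        heavy_atoms=heavy if keep_heavy_atoms else None,
    )


def read_ring_chains(
    pdb_text: str,
    chains: Sequence[str] | None = None,
    residue_range: tuple[int, int] | None = None,
) -> list[SubunitStructure]:
    """Read all (or the named) chains of a ring assembly as subunits.

    Chains are taken in file order when ``chains`` is None; the residue
    range defaults to the numbers common to every chain.
    """
    st = gemmi.read_pdb_string(pdb_text)
    model = st[0]
    names = [ch.name for ch in model] if chains is None else list(chains)
    if residue_range is None:
        common: set[int] | None = None
        for name in names:
            ch = model.find_chain(name)
            if ch is None:
                raise ValueError(f"chain not found: {name!r}")
            nums = {r.seqid.num for r in ch if any(a.name == "CA" for a in r)}
            common = nums if common is None else (common & nums)
        if not common:
            raise ValueError("chains share no residues with Calpha atoms")
        residue_range = (min(common), max(common))
    return [read_calpha_structure(pdb_text, c, residue_range) for c in names]


def measure_planarity(calpha_coords: np.ndarray) -> float:
    """Spread (standard deviation, Å) of a point cloud along its thinnest axis.

    This is the square root of the smallest eigenvalue of the coordinate
    covariance, i.e. the third principal component of the cloud. Ring
    assemblies are flat: the value stays below
    :data:`RING_PLANARITY_THRESHOLD` (2.0 Å).
    """
    coords = np.asarray(calpha_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) < 4:
        raise ValueError("need at least 4 points of shape (M, 3)")
    x = coords - coords.mean(axis=0)
    cov = x.T @ x / len(x)
    w = np.linalg.eigvalsh(cov)
    return float(np.sqrt(max(w[0], 0.0)))


@dataclasses.dataclass
class AxisFrame:
    """Orthonormal frame: ``origin`` plus rows x, y, z of ``axes``.

    ``to_local`` maps original coordinates into the canonical frame where
    z is the symmetry axis.
    """

    origin: np.ndarray
    axes: np.ndarray

    def to_local(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords, dtype=float) - self.origin) @ self.axes.T

    def to_global(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.axes + self.origin


def _subunit_coms(coords: np.ndarray, n: int) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if len(coords) % n:
        raise ValueError("subunit size mismatch: atom count not divisible by n")
    return coords.reshape(n, -1, 3).mean(axis=1)


def detect_symmetry_frame(coords: np.ndarray, n: int) -> AxisFrame:
    """Locate the ring plane and symmetry axis from subunit centers of mass.

    The origin is the global center of mass; z is the thinnest principal
    axis of the subunit-COM cloud, oriented so that subunit indices advance
    counterclockwise viewed from +z; x points toward the subunit-0 COM.
    """
    coords = np.asarray(coords, dtype=float)
    if n < 3:
        raise ValueError("need at least 3 subunits")
    coms = _subunit_coms(coords, n)
    origin = coords.mean(axis=0)
    x = coms - coms.mean(axis=0)
    w, v = np.linalg.eigh(x.T @ x / n)
    scale = max(w[-1], 1e-30)
    if w[1] / scale < 1e-12:
        raise ValueError("no ring plane: subunit centers are collinear")
    z = v[:, 0]
    # Orient z so subunit order is counterclockwise.
    phis = np.arctan2(x @ v[:, 1], x @ v[:, 2])  # any in-plane axes
    steps = np.angle(np.exp(1j * np.diff(phis)))
    mean_step = float(np.mean(steps))
    cross = np.cross(v[:, 2], v[:, 1])  # handedness of the trial frame
    ccw = mean_step * np.sign(np.dot(cross, z))
    if abs(mean_step) < 1e-12:
        # Degenerate ordering signal: deterministic lexicographic tie-break.
        if tuple(z) < tuple(-z):
            z = -z
    elif ccw < 0:
        z = -z
    # x toward subunit-0 COM, projected into the ring plane.
    r0 = coms[0] - origin
    xv = r0 - np.dot(r0, z) * z
    nrm = np.linalg.norm(xv)
    if nrm < 1e-12:
        raise ValueError("subunit 0 center of mass lies on the symmetry axis")
    xv = xv / nrm
    yv = np.cross(z, xv)
    return AxisFrame(origin=origin, axes=np.vstack([xv, yv, z]))


@dataclasses.dataclass
class RingStructure:
    """A C_n ring of n identical subunits in the canonical frame.

    ``coords`` is (n*N, 3) with subunit m occupying block m; the structure
    is ``is_exactly_symmetric`` when rotating by 360/n degrees and shifting
    the subunit index reproduces the coordinates to ``symmetry_tol``.
    """

    n: int
    coords: np.ndarray
    interface_angles: np.ndarray
    is_exactly_symmetric: bool
    axis_frame: AxisFrame
    subunit: SubunitStructure | None = None
    symmetry_tol: float = 1e-10

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def n_atoms_per_subunit(self) -> int:
        return len(self.coords) // self.n

    def subunit_coords(self, m: int) -> np.ndarray:
        N = self.n_atoms_per_subunit
        return self.coords[m * N : (m + 1) * N]

    def subunit_indices(self, m: int) -> np.ndarray:
        N = self.n_atoms_per_subunit
        return np.arange(m * N, (m + 1) * N)

    @property
    def subunit_com_angles(self) -> np.ndarray:
        """Angular positions (degrees, [0, 360)) of the subunit COMs."""
        coms = _subunit_coms(self.coords, self.n)
        ang = np.degrees(np.arctan2(coms[:, 1], coms[:, 0]))
        return np.mod(ang, 360.0)

    def symmetry_residual(self) -> float:
        """Max deviation (Å) of R(360/n) + index shift from the identity."""
        blocks = self.coords.reshape(self.n, -1, 3)
        rot = blocks @ rotation_z(2 * np.pi / self.n).T
        shifted = np.roll(blocks, -1, axis=0)
        return float(np.abs(rot - shifted).max())

    @classmethod
    def from_coords(
        cls,
        coords: np.ndarray,
        n: int,
        subunit: SubunitStructure | None = None,
        symmetry_tol: float = 1e-10,
    ) -> "RingStructure":
        """Canonicalize raw ring coordinates (any frame) into a RingStructure."""
        coords = np.asarray(coords, dtype=float)
        frame = detect_symmetry_frame(coords, n)
        local = frame.to_local(coords)
        # Exact re-zeroing of the subunit-0 COM angle.
        com0 = local.reshape(n, -1, 3).mean(axis=1)[0]
        phi0 = np.arctan2(com0[1], com0[0])
        if abs(phi0) > 0:
            rz = rotation_z(-phi0)
            local = local @ rz.T
            frame = AxisFrame(origin=frame.origin, axes=rz @ frame.axes)
        coms = _subunit_coms(local, n)
        ang = np.mod(np.degrees(np.arctan2(coms[:, 1], coms[:, 0])), 360.0)
        gaps = np.mod(np.roll(ang, -1) - ang, 360.0)
        interfaces = np.mod(ang + gaps / 2.0, 360.0)
        ring = cls(
            n=n,
            coords=local,
            interface_angles=interfaces,
            is_exactly_symmetric=False,
            axis_frame=frame,
            subunit=subunit,
            symmetry_tol=symmetry_tol,
        )
        ring.is_exactly_symmetric = ring.symmetry_residual() < symmetry_tol
        return ring


def symmetrize_ring(
    coords: np.ndarray,
    n: int,
    subunit: SubunitStructure | None = None,
) -> RingStructure:
    """Project a near-symmetric ring onto exact C_n symmetry.

    Each subunit is mapped into the subunit-0 frame by the inverse rotation,
    the n images are averaged, and the ring is regenerated by rotating the
    average back. This is the orthogonal projection onto the C_n-symmetric
    subspace (idempotent; reduces the distance to any symmetric structure).
    """
    ring = RingStructure.from_coords(coords, n, subunit=subunit)
    blocks = ring.coords.reshape(n, -1, 3)
    alpha = 2 * np.pi / n
    images = [blocks[m] @ rotation_z(-m * alpha).T for m in range(n)]
    avg = np.mean(images, axis=0)
    rebuilt = np.concatenate([avg @ rotation_z(m * alpha).T for m in range(n)])
    out = RingStructure.from_coords(rebuilt, n, subunit=subunit)
    if not out.is_exactly_symmetric:  # pragma: no cover - construction guarantee
        warnings.warn("symmetrization residual above tolerance")
    return out


def all_atom_rmsd(
    a: SubunitStructure,
    b: SubunitStructure,
    shared_residues: Sequence[str] | None = None,
) -> float:
    """Heavy-atom RMSD between two subunits after optimal superposition.

    Atoms are matched by (residue id, atom name) over ``shared_residues``
    (default: ids present in both structures).
    """
    if a.heavy_atoms is None or b.heavy_atoms is None:
        raise ValueError("both subunits must carry heavy atoms")
    if shared_residues is None:
        shared_residues = [r for r in a.residue_ids if r in b.heavy_atoms]
    pa, pb = [], []
    for rid in shared_residues:
        ra = a.heavy_atoms.get(rid)
        rb = b.heavy_atoms.get(rid)
        if ra is None or rb is None:
            continue
        for name, xyz in ra.items():
            if name in rb:
                pa.append(xyz)
                pb.append(rb[name])
    if not pa:
        raise ValueError("no shared heavy atoms between subunits")
    _, rmsd = kabsch_superpose(np.array(pa), np.array(pb))
    return rmsd


_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def write_ring_pdb(ring: RingStructure, path=None) -> str:
    """Write the canonical ring as PDB text, one chain per subunit."""
    st = gemmi.Structure()
    st.name = "ring"
    model = gemmi.Model("1")
    N = ring.n_atoms_per_subunit
    rids = ring.subunit.residue_ids if ring.subunit is not None else [
        str(i + 1) for i in range(N)
    ]
    for m in range(ring.n):
        chain = gemmi.Chain(_CHAIN_IDS[m % len(_CHAIN_IDS)])
        block = ring.subunit_coords(m)
        for i in range(N):
            res = gemmi.Residue()
            res.name = "GLY"
            num, icode = _residue_sort_key(rids[i])
            res.seqid = gemmi.SeqId(num, icode or " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.occ = 1.0
            atom.pos = gemmi.Position(*block[i])
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    text = st.make_pdb_string()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def planarity_report(
    structures: dict[str, np.ndarray],
    threshold: float = RING_PLANARITY_THRESHOLD,
) -> pd.DataFrame:
    """Planarity table: (structure_id, third_pc_A, is_ring) per structure."""
    rows = []
    for sid, coords in structures.items():
        val = measure_planarity(coords)
        rows.append({"structure_id": sid, "third_pc_A": val, "is_ring": val < threshold})
    return pd.DataFrame(rows)
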