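"""Trajectory I/O: plain multi-frame XYZ and multi-model PDB."""

from __future__ import annotations

import numpy as np
import gemmi

__all__ = ["read_xyz_frames", "write_xyz_frames", "read_pdb_frames", "write_pdb_frames"]


def write_xyz_frames(frames: np.ndarray, path, element: str = "C") -> None:
    """Write (F, M, 3) coordinates as concatenated XYZ blocks."""
    frames = np.asarray(frames, dtype=float)
    with open(path, "w") as fh:
        for f, frame in enumerate(frames):
            fh.write(f"{len(frame)}\nframe {f}\n")
            for x, y, z in frame:
                fh.write(f"{element} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz_frames(path) -> np.ndarray:
    """Read concatenated XYZ blocks into an (F, M, 3) array."""
    frames = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = int(line)
        block = lines[i + 2 : i + 2 + m]
        coords = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in block]
        )
        if coords.shape != (m, 3):
            raise ValueError(f"malformed XYZ frame at line {i + 1}")
        frames.append(coords)
        i += 2 + m
    if not frames:
        raise ValueError("no frames in XYZ file")
    out = np.array(frames)
    if out.ndim != 3:
        raise ValueError("frames differ in atom count")
    return out


def read_pdb_frames(path) -> np.ndarray:
    """Read all MODELs of a PDB file into an (F, M, 3) array (file order)."""
    st = gemmi.read_structure(str(path))
    frames = []
    for model in st:
        coords = [
            [a.pos.x, a.pos.y, a.pos.z]
            for chain in model
            for res in chain
            for a in res
        ]
        frames.append(coords)
    arr = np.array(frames, dtype=float)
    if arr.ndim != 3:
        raise ValueError("PDB models differ in atom count")
    return arr


def write_pdb_frames(frames: np.ndarray, path, n_subunits: int = 1) -> None:
    """Write (F, M, 3) Cα coordinates as a multi-model PDB."""
    frames = np.asarray(frames, dtype=float)
    _, m, _ = frames.shape
    if m % n_subunits:
        raise ValueError("atom count not divisible by subunit count")
    n_per = m // n_subunits
    with open(path, "w") as fh:
        for f, frame in enumerate(frames, start=1):
            fh.write(f"MODEL     {f:>4}\n")
            serial = 1
            for s in range(n_subunits):
                chain = chr(ord("A") + s % 26)
                for i in range(n_per):
                    x, y, z = frame[s * n_per + i]
                    fh.write(
                        f"ATOM  {serial:>5}  CA  GLY {chain}{i + 1:>4}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                    )
                    serial += 1
                fh.write("TER\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")
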