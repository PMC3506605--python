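"""Angular correlation of mode displacements around the ring.

C(theta) correlates the displacements of the atoms near the subunit-0
center of mass (angular window |phi| <= allowance) with the displacements
of atoms near angle theta, after rotating the reference displacements by
theta about the symmetry axis:

    C(theta) = (Rz(theta) s0) . s(theta) / (|s0| |s(theta)|)

where s0 and s(theta) are the summed displacement vectors of the two
windows. This normalization gives C(0) = 1 exactly and |C| <= 1 everywhere
(Cauchy-Schwarz). For a standing wave of wavenumber p, C changes sign 2p
times per turn; its zeros locate the wave nodes, which in highly symmetric
rings coincide with the subunit interfaces.

The root-mean-square of C over the grid (excluding the self window at
theta = 0) summarizes how cooperative — how ring-wide — a mode's motion is;
0.5 is the conventional cooperativity threshold.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .ring_geometry import RingStructure, rotation_z

__all__ = [
    "CorrelationProfile",
    "angular_positions",
    "correlation_profile",
    "rms_correlation",
    "node_interface_match",
    "cyclic_distance_deg",
]


def cyclic_distance_deg(a, b) -> np.ndarray:
    """Smallest angular separation |a - b| on the circle, in degrees."""
    d = np.abs(np.mod(np.asarray(a) - np.asarray(b) + 180.0, 360.0) - 180.0)
    return d


def angular_positions(ring: RingStructure, axis_tol: float = 1e-9) -> np.ndarray:
    """Angular position phi (degrees, [0, 360)) of every atom about +z.

    The canonical frame already puts the subunit-0 COM at phi = 0; the
    positions are re-shifted by that COM angle so the convention holds
    exactly even for perturbed rings. Atoms on the z axis have no defined
    angle and are returned as NaN with a warning.
    """
    xy = ring.coords[:, :2]
    r = np.linalg.norm(xy, axis=1)
    phi = np.degrees(np.arctan2(xy[:, 1], xy[:, 0]))
    com0 = ring.subunit_coords(0).mean(axis=0)
    phi0 = np.degrees(np.arctan2(com0[1], com0[0]))
    phi = np.mod(phi - phi0, 360.0)
    on_axis = r < axis_tol
    if on_axis.any():
        warnings.warn(f"{int(on_axis.sum())} atoms on the symmetry axis excluded")
        phi = np.where(on_axis, np.nan, phi)
    return phi


@dataclasses.dataclass
class CorrelationProfile:
    """C(theta) on an angular grid, with gaps (NaN) where a window is empty."""

    theta_grid: np.ndarray
    values: np.ndarray
    allowance: float
    reference_window: np.ndarray
    node_angles: np.ndarray

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


def _zero_crossings(theta: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Cyclic sign-change angles of a sampled profile (linear interpolation)."""
    good = ~np.isnan(values)
    t, v = theta[good], values[good]
    if len(t) < 2:
        return np.array([])
    nodes = []
    for i in range(len(t)):
        j = (i + 1) % len(t)
        a, b = v[i], v[j]
        if a == 0.0 or b == 0.0 or np.sign(a) == np.sign(b):
            continue
        gap = (t[j] - t[i]) % 360.0
        frac = abs(a) / (abs(a) + abs(b))
        nodes.append((t[i] + frac * gap) % 360.0)
    return np.sort(np.array(nodes))


def correlation_profile(
    mode_vector: np.ndarray,
    ring: RingStructure,
    allowance: float = 4.0,
    grid_step: float = 1.0,
    widen_to_nearest: bool = False,
) -> CorrelationProfile:
    """Angular correlation function of a unit-norm mode on the ring.

    ``allowance`` is the half-width (degrees) of both the reference window
    at phi = 0 and the moving window at theta; grid points whose window
    holds no atoms are reported as gaps (NaN). On sparse models no atom may
    fall inside the reference window; ``widen_to_nearest`` then grows the
    allowance just enough to reach the nearest atom instead of raising.
    """
    disp = np.asarray(mode_vector, dtype=float).reshape(-1, 3)
    if len(disp) != ring.n_atoms:
        raise ValueError("mode vector does not match the ring atom count")
    phi = angular_positions(ring)
    ok = ~np.isnan(phi)
    dist0 = cyclic_distance_deg(phi, 0.0)
    if widen_to_nearest and not (ok & (dist0 <= allowance)).any():
        allowance = float(np.nanmin(np.where(ok, dist0, np.nan))) + 0.5
    ref = ok & (dist0 <= allowance)
    if not ref.any():
        raise ValueError("no reference atoms within the allowance of phi = 0")
    s0 = disp[ref].sum(axis=0)
    n0 = np.linalg.norm(s0)
    theta_grid = np.arange(0.0, 360.0, grid_step)
    values = np.full_like(theta_grid, np.nan)
    tiny = 1e-12 * max(np.abs(disp).max(), 1e-300)
    for idx, theta in enumerate(theta_grid):
        win = ok & (cyclic_distance_deg(phi, theta) <= allowance)
        if not win.any():
            continue
        st = disp[win].sum(axis=0)
        nt = np.linalg.norm(st)
        if n0 < tiny or nt < tiny:
            continue
        values[idx] = float((rotation_z(np.radians(theta)) @ s0) @ st / (n0 * nt))
    nodes = _zero_crossings(theta_grid, values)
    return CorrelationProfile(
        theta_grid=theta_grid,
        values=values,
        allowance=float(allowance),
        reference_window=np.flatnonzero(ref),
        node_angles=nodes,
    )


def rms_correlation(profile: CorrelationProfile) -> float:
    """Root mean square of C(theta) excluding the self window at theta = 0."""
    keep = profile.defined() & (
        cyclic_distance_deg(profile.theta_grid, 0.0) > profile.allowance
    )
    if not keep.any():
        raise ValueError("profile has no defined values outside the self window")
    return float(np.sqrt(np.mean(profile.values[keep] ** 2)))


def node_interface_match(
    profile: CorrelationProfile,
    ring: RingStructure,
    tolerance: float = 4.0,
) -> tuple[int, int]:
    """Count wave nodes lying within ``tolerance`` degrees of an interface.

    Returns ``(matched, total_nodes)``; interfaces are the angular midpoints
    between adjacent subunit centers of mass.
    """
    nodes = profile.node_angles
    if len(nodes) == 0:
        return 0, 0
    d = cyclic_distance_deg(nodes[:, None], ring.interface_angles[None, :])
    matched = int(np.sum(d.min(axis=1) <= tolerance))
    return matched, len(nodes)
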