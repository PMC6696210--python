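"""Scanner and source geometry: helical source trajectory, cylindrical
detector ring, and line-of-response (LOR) math.

Conventions
-----------
All coordinates are in millimeters in a right-handed frame with the origin
at the scanner isocenter and ``z`` along the bore axis.  Attenuation values
elsewhere in the package are in cm^-1; the unit conversion happens in one
place (the ray tracer in :mod:`helix_txac.forward_sim`).

The transmission source is a small radioactive pellet pumped through a hose
wound helically around the outside of the receive coil, so its position is
a deterministic function of time.  :class:`SourceTrajectory` models that
path; :class:`DetectorRing` models a conventional cylindrical PET crystal
block arrangement (rings of crystals stacked along ``z``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SourceTrajectory",
    "DetectorRing",
    "LOR",
    "source_position",
    "lor_endpoints",
    "point_line_distance",
    "emit_pair_to_crystals",
]


@dataclass(frozen=True)
class SourceTrajectory:
    """Deterministic helical path of the transmission pellet.

    Parameters
    ----------
    helix_radius:
        Radius of the helix in mm.  Must clear the imaged object and stay
        inside the detector ring.
    z_start, z_end:
        Axial extent covered by the helix (mm).  ``z_start == z_end`` gives
        a planar circular orbit (useful for static-axial tests).
    pitch:
        Axial advance per full turn (mm / turn).
    speed:
        Pellet speed along the hose arc (mm/s).
    phase0:
        Azimuth at ``t = 0`` (rad).
    direction:
        +1 for counter-clockwise rotation (seen from +z), -1 for clockwise.
    mode:
        ``"loop"``: on reaching ``z_end`` the pellet re-enters at
        ``z_start`` (a closed hydraulic loop).  ``"bounce"``: the axial
        motion reverses (back-and-forth).
    """

    helix_radius: float
    z_start: float
    z_end: float
    pitch: float
    speed: float
    phase0: float = 0.0
    direction: int = 1
    mode: str = "loop"

    def __post_init__(self) -> None:
        if self.helix_radius <= 0:
            raise ValueError("helix_radius must be > 0")
        if self.pitch == 0:
            raise ValueError("pitch must be nonzero")
        if self.speed <= 0:
            raise ValueError("speed must be > 0")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if self.mode not in ("loop", "bounce"):
            raise ValueError("mode must be 'loop' or 'bounce'")

    @property
    def turn_length(self) -> float:
        """Arc length of the hose per full turn (mm)."""
        return float(np.hypot(2.0 * np.pi * self.helix_radius, self.pitch))

    @property
    def period(self) -> float:
        """Time for one full turn (s)."""
        return self.turn_length / self.speed

    @property
    def z_span(self) -> float:
        return self.z_end - self.z_start


def source_position(traj: SourceTrajectory, t_s):
    """Pellet position at time(s) ``t_s`` (scalar or array), in mm.

    The pellet advances along the hose at constant arc speed, so azimuth
    and z advance linearly with time; after one full turn the azimuth is
    back to its start and z has advanced by exactly one pitch.
    """
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    turns = t / traj.period
    phi = traj.phase0 + traj.direction * 2.0 * np.pi * turns
    dz = traj.pitch * turns
    span = traj.z_span
    if span == 0:
        z = np.full_like(t, traj.z_start)
    elif traj.mode == "loop":
        z = traj.z_start + np.mod(dz, span) * np.sign(span)
    else:  # bounce: triangular wave over [z_start, z_end]
        span = abs(span)
        saw = np.mod(np.abs(dz), 2.0 * span)
        tri = np.where(saw <= span, saw, 2.0 * span - saw)
        z = traj.z_start + tri * np.sign(traj.z_span)
    x = traj.helix_radius * np.cos(phi)
    y = traj.helix_radius * np.sin(phi)
    out = np.stack([x, y, z], axis=-1)
    return out if out.ndim > 1 else out.reshape(3) if np.ndim(t_s) == 0 else out


@dataclass(frozen=True)
class DetectorRing:
    """Cylindrical PET detector: ``n_rings`` crystal rings stacked along z.

    Crystal ``(ring, idx)`` sits at azimuth ``2*pi*idx / crystals_per_ring``
    on the cylinder of radius ``ring_radius``; ring ``r`` is centered at
    ``z = (r + 0.5) * ring_spacing - axial_extent / 2``.

    The default geometry (``DetectorRing.default()``) is representative of a
    whole-body PET/MR scanner; the ``desk()`` preset is a smaller ring used
    for fast simulation studies.  All dimensions are configurable.
    """

    ring_radius: float = 328.0
    n_rings: int = 64
    ring_spacing: float = 4.0
    crystals_per_ring: int = 504

    def __post_init__(self) -> None:
        if self.ring_radius <= 0:
            raise ValueError("ring_radius must be > 0")
        if self.n_rings < 1 or self.crystals_per_ring < 2:
            raise ValueError("need at least 1 ring and 2 crystals per ring")
        if self.crystals_per_ring % 2 != 0:
            raise ValueError("crystals_per_ring must be even")
        if self.ring_spacing <= 0:
            raise ValueError("ring_spacing must be > 0")

    @classmethod
    def default(cls) -> "DetectorRing":
        return cls()

    @classmethod
    def desk(cls) -> "DetectorRing":
        """Small ring for desk-scale simulations (fast, coarse axially)."""
        return cls(ring_radius=150.0, n_rings=8, ring_spacing=12.0,
                   crystals_per_ring=240)

    @property
    def axial_extent(self) -> float:
        return self.n_rings * self.ring_spacing

    @property
    def z_min(self) -> float:
        return -0.5 * self.axial_extent

    @property
    def z_max(self) -> float:
        return 0.5 * self.axial_extent

    @property
    def crystal_pitch(self) -> float:
        """Transaxial crystal center-to-center spacing (mm)."""
        return 2.0 * np.pi * self.ring_radius / self.crystals_per_ring

    def ring_z(self, ring_index):
        """Axial center (mm) of crystal ring(s) ``ring_index``."""
        return self.z_min + (np.asarray(ring_index) + 0.5) * self.ring_spacing

    def crystal_angle(self, idx):
        return 2.0 * np.pi * np.asarray(idx) / self.crystals_per_ring


@dataclass(frozen=True)
class LOR:
    """A line of response between two crystals."""

    ring_a: int
    idx_a: int
    ring_b: int
    idx_b: int

    def endpoints(self, ring: DetectorRing):
        return lor_endpoints(ring, (self.ring_a, self.idx_a, self.ring_b, self.idx_b))


def _check_crystal(ring: DetectorRing, r: int, i: int) -> None:
    if not (0 <= r < ring.n_rings):
        raise IndexError(f"ring index {r} out of range [0, {ring.n_rings})")
    if not (0 <= i < ring.crystals_per_ring):
        raise IndexError(f"crystal index {i} out of range [0, {ring.crystals_per_ring})")


def lor_endpoints(ring: DetectorRing, crystal_pair):
    """3D endpoints (mm) of the LOR through a crystal pair.

    ``crystal_pair`` is ``(ring_a, idx_a, ring_b, idx_b)``.  Raises on
    out-of-range indices or a degenerate pair (same crystal twice).
    """
    ra, ia, rb, ib = crystal_pair
    _check_crystal(ring, ra, ia)
    _check_crystal(ring, rb, ib)
    if ra == rb and ia == ib:
        raise ValueError("LOR endpoints must be two distinct crystals")
    pts = []
    for r, i in ((ra, ia), (rb, ib)):
        phi = ring.crystal_angle(i)
        pts.append(np.array([ring.ring_radius * np.cos(phi),
                             ring.ring_radius * np.sin(phi),
                             ring.ring_z(r)]))
    return pts[0], pts[1]


def crystal_positions(ring: DetectorRing, rings, idxs):
    """Vectorized crystal centers; ``rings``/``idxs`` are integer arrays."""
    phi = ring.crystal_angle(idxs)
    return np.stack([ring.ring_radius * np.cos(phi),
                     ring.ring_radius * np.sin(phi),
                     ring.ring_z(rings)], axis=-1)


def point_line_distance(point, p1, p2):
    """Perpendicular distance from ``point`` to the infinite line through
    ``p1``/``p2``.  Broadcasts over leading axes (last axis = xyz)."""
    p = np.asarray(point, dtype=float)
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    d = b - a
    dn = np.linalg.norm(d, axis=-1)
    if np.any(dn == 0):
        raise ValueError("degenerate zero-length line")
    cr = np.cross(p - a, d / dn[..., None])
    return np.linalg.norm(cr, axis=-1)


def intersect_cylinder(ring: DetectorRing, origins, directions):
    """Both intersections of lines with the detector cylinder surface.

    Parameters are ``(n, 3)`` arrays (origins strictly inside the cylinder
    radially).  Returns ``(hit, ra, ia, rb, ib, pa, pb)`` where ``hit`` is a
    boolean mask of lines whose *both* intersections fall inside the axial
    crystal stack; crystal indices are the nearest crystals to the geometric
    intersection points ``pa``/``pb`` (``(n, 3)`` mm).  Lines parallel to
    the axis never hit the barrel.
    """
    o = np.atleast_2d(np.asarray(origins, dtype=float))
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    a = d[:, 0] ** 2 + d[:, 1] ** 2
    b = o[:, 0] * d[:, 0] + o[:, 1] * d[:, 1]
    c = o[:, 0] ** 2 + o[:, 1] ** 2 - ring.ring_radius ** 2
    if np.any(c >= 0):
        raise ValueError("all origins must lie inside the detector cylinder")
    ok = a > 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        sq = np.sqrt(np.maximum(b * b - a * c, 0.0))
        s_plus = (-b + sq) / a
        s_minus = (-b - sq) / a
    z_plus = o[:, 2] + s_plus * d[:, 2]
    z_minus = o[:, 2] + s_minus * d[:, 2]
    inside = (z_plus >= ring.z_min) & (z_plus < ring.z_max) \
        & (z_minus >= ring.z_min) & (z_minus < ring.z_max)
    hit = ok & inside

    def to_crystal(s, z):
        x = o[:, 0] + s * d[:, 0]
        y = o[:, 1] + s * d[:, 1]
        phi = np.arctan2(y, x)
        idx = np.mod(np.rint(phi / (2.0 * np.pi) * ring.crystals_per_ring),
                     ring.crystals_per_ring).astype(np.int32)
        rr = np.clip(((z - ring.z_min) / ring.ring_spacing).astype(np.int32),
                     0, ring.n_rings - 1)
        return rr, idx, np.stack([x, y, z], axis=-1)

    ra, ia, pa = to_crystal(s_plus, z_plus)
    rb, ib, pb = to_crystal(s_minus, z_minus)
    return hit, ra, ia, rb, ib, pa, pb


def emit_pair_to_crystals(ring: DetectorRing, origin_point, direction_unit):
    """Map a back-to-back annihilation photon pair to its crystal pair.

    The two photons travel along ``+direction`` and ``-direction`` from the
    origin; both must strike the crystal stack.  Returns
    ``(ring_a, idx_a, ring_b, idx_b)`` or ``None`` if either photon escapes
    axially (or the line is parallel to the bore axis).
    """
    hit, ra, ia, rb, ib, _, _ = intersect_cylinder(
        ring, np.asarray(origin_point, float)[None, :],
        np.asarray(direction_unit, float)[None, :])
    if not hit[0]:
        return None
    return int(ra[0]), int(ia[0]), int(rb[0]), int(ib[0])
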