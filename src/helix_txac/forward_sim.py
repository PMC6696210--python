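"""List-mode Monte-Carlo simulation of blank, transmission, and emission
scans.

Physics model
-------------
Each radioactive decay produces one back-to-back 511 keV photon pair with
an isotropic direction.  A coincidence is recorded when both photons reach
the crystal stack; the pair survives attenuation with probability
``exp(-optical_depth)`` where the optical depth is the exact (Siddon)
line integral of mu along the photon path, and is additionally thinned by
``detection_efficiency**2``.  Scatter, randoms, dead time, positron range
and isotope decay over the scan are not modeled (documented limitations);
counts therefore follow ideal Poisson statistics.

Decays are drawn as a homogeneous Poisson process: the total count from
``Poisson(activity * duration)``, decay times uniform over the scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import (DetectorRing, SourceTrajectory, crystal_positions,
                       intersect_cylinder, source_position)
from .phantoms import ActivityVolume, AttenuationVolume

try:  # numba accelerates the voxel traversal ~100x; a pure-python
    from numba import njit  # fallback keeps small runs working without it
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap(args[0]) if args and callable(args[0]) else wrap

log = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "ListModeData",
    "EVENT_DTYPE",
    "TAG_TRANSMISSION",
    "TAG_EMISSION",
    "siddon_line_integral",
    "siddon_batch",
    "simulate_transmission_scan",
    "simulate_emission_scan",
    "merge_scans",
]

TAG_TRANSMISSION = 0
TAG_EMISSION = 1

#: List-mode record: timestamp, crystal pair, ground-truth tag and true
#: decay origin (the latter two exist for validation only — a real scanner
#: records only (t, crystal pair)).
EVENT_DTYPE = np.dtype([
    ("t", np.float64),
    ("ring_a", np.int16), ("idx_a", np.int16),
    ("ring_b", np.int16), ("idx_b", np.int16),
    ("tag", np.int8),
    ("x", np.float32), ("y", np.float32), ("z", np.float32),
])


@dataclass(frozen=True)
class ScanConfig:
    """Acquisition parameters for one scan.

    ``activity_bq * duration_s`` sets the expected number of simulated
    decays, the knob that controls counting statistics; desk-scale runs use
    far fewer decays than a physical scan and state so in their provenance.
    """

    activity_bq: float
    duration_s: float
    seed: int
    time_step_s: float = 0.1
    detection_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.activity_bq <= 0 or self.duration_s <= 0 or self.time_step_s <= 0:
            raise ValueError("activity, duration and time_step must be > 0")
        if not (0.0 < self.detection_efficiency <= 1.0):
            raise ValueError("detection_efficiency must be in (0, 1]")

    @property
    def exposure(self) -> float:
        """activity x duration: expected decay count (used to normalize
        blank against transmission scans)."""
        return self.activity_bq * self.duration_s


class ListModeData:
    """Array container for list-mode coincidences.

    ``events`` is a structured array with fields
    ``(t, ring_a, idx_a, ring_b, idx_b, tag, x, y, z)`` sorted by time.
    ``exposure`` carries activity x duration for downstream normalization;
    ``n_decays`` the number of simulated decays.
    """

    def __init__(self, events: np.ndarray, ring: DetectorRing,
                 exposure: float, n_decays: int = 0):
        if events.dtype != EVENT_DTYPE:
            raise ValueError("events must have EVENT_DTYPE")
        self.events = events
        self.ring = ring
        self.exposure = float(exposure)
        self.n_decays = int(n_decays)

    def __len__(self) -> int:
        return len(self.events)

    def endpoints(self):
        """Crystal-center LOR endpoints, two (n, 3) arrays (mm)."""
        e = self.events
        p1 = crystal_positions(self.ring, e["ring_a"].astype(np.int64),
                               e["idx_a"].astype(np.int64))
        p2 = crystal_positions(self.ring, e["ring_b"].astype(np.int64),
                               e["idx_b"].astype(np.int64))
        return p1, p2

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({k: self.events[k] for k in self.events.dtype.names}) \
            .to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, ring: DetectorRing, exposure: float = 0.0):
        import pandas as pd
        df = pd.read_csv(path)
        ev = np.zeros(len(df), dtype=EVENT_DTYPE)
        for k in EVENT_DTYPE.names:
            ev[k] = df[k].to_numpy()
        return cls(ev, ring, exposure)


# ---------------------------------------------------------------------------
# Exact line integrals through the voxel grid (Siddon traversal)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _siddon_kernel(mu, ox, oy, oz, vx, vy, vz, p1, p2, out):  # pragma: no cover
    nx, ny, nz = mu.shape
    tiny = 1e-12
    for n in range(p1.shape[0]):
        x1, y1, z1 = p1[n, 0], p1[n, 1], p1[n, 2]
        dx = p2[n, 0] - x1
        dy = p2[n, 1] - y1
        dz = p2[n, 2] - z1
        length = (dx * dx + dy * dy + dz * dz) ** 0.5
        if length < tiny:
            out[n] = 0.0
            continue
        amin = 0.0
        amax = 1.0
        miss = False
        for axis in range(3):
            if axis == 0:
                d, s, lo, hi = dx, x1, ox, ox + nx * vx
            elif axis == 1:
                d, s, lo, hi = dy, y1, oy, oy + ny * vy
            else:
                d, s, lo, hi = dz, z1, oz, oz + nz * vz
            if abs(d) > tiny:
                a0 = (lo - s) / d
                a1 = (hi - s) / d
                if a0 > a1:
                    a0, a1 = a1, a0
                if a0 > amin:
                    amin = a0
                if a1 < amax:
                    amax = a1
            elif s <= lo or s >= hi:
                miss = True
                break
        if miss or amin >= amax:
            out[n] = 0.0
            continue

        # next plane-crossing parameter per axis, stepping from amin
        def_next = 2.0  # sentinel beyond amax
        if abs(dx) > tiny:
            dax = abs(vx / dx)
            k = int(np.floor((x1 + amin * dx - ox) / vx))
            plane = ox + (k + 1) * vx if dx > 0 else ox + k * vx
            ax_next = (plane - x1) / dx
            while ax_next <= amin + 1e-15:
                ax_next += dax
        else:
            dax = 0.0
            ax_next = def_next
        if abs(dy) > tiny:
            day = abs(vy / dy)
            k = int(np.floor((y1 + amin * dy - oy) / vy))
            plane = oy + (k + 1) * vy if dy > 0 else oy + k * vy
            ay_next = (plane - y1) / dy
            while ay_next <= amin + 1e-15:
                ay_next += day
        else:
            day = 0.0
            ay_next = def_next
        if abs(dz) > tiny:
            daz = abs(vz / dz)
            k = int(np.floor((z1 + amin * dz - oz) / vz))
            plane = oz + (k + 1) * vz if dz > 0 else oz + k * vz
            az_next = (plane - z1) / dz
            while az_next <= amin + 1e-15:
                az_next += daz
        else:
            daz = 0.0
            az_next = def_next

        acc = 0.0
        a = amin
        while a < amax - 1e-12:
            an = amax
            if ax_next < an:
                an = ax_next
            if ay_next < an:
                an = ay_next
            if az_next < an:
                an = az_next
            mid = 0.5 * (a + an)
            i = int((x1 + mid * dx - ox) / vx)
            j = int((y1 + mid * dy - oy) / vy)
            k = int((z1 + mid * dz - oz) / vz)
            if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz:
                acc += mu[i, j, k] * (an - a)
            if ax_next <= an + 1e-15:
                ax_next += dax
            if ay_next <= an + 1e-15:
                ay_next += day
            if az_next <= an + 1e-15:
                az_next += daz
            a = an
        out[n] = acc * length * 0.1  # mu [cm^-1] x length [mm] -> dimensionless
    return out


def siddon_batch(volume: AttenuationVolume, p1, p2) -> np.ndarray:
    """Optical depths (dimensionless) along lines ``p1[i] -> p2[i]`` (mm)."""
    p1 = np.ascontiguousarray(np.atleast_2d(p1), dtype=np.float64)
    p2 = np.ascontiguousarray(np.atleast_2d(p2), dtype=np.float64)
    if p1.shape != p2.shape or p1.shape[1] != 3:
        raise ValueError("p1/p2 must be matching (n, 3) arrays")
    if not (np.all(np.isfinite(p1)) and np.all(np.isfinite(p2))):
        raise ValueError("endpoints must be finite")
    out = np.empty(p1.shape[0], dtype=np.float64)
    g = volume.grid
    _siddon_kernel(np.ascontiguousarray(volume.values),
                   float(g.origin[0]), float(g.origin[1]), float(g.origin[2]),
                   float(g.voxel_size[0]), float(g.voxel_size[1]),
                   float(g.voxel_size[2]), p1, p2, out)
    return out


def siddon_line_integral(volume: AttenuationVolume, p1, p2) -> float:
    """Exact line integral of mu between two points (mm); result is the
    dimensionless optical depth (mu in cm^-1 times path length in cm).
    Lines missing the grid integrate to 0."""
    return float(siddon_batch(volume, np.asarray(p1, float)[None, :],
                              np.asarray(p2, float)[None, :])[0])


# ---------------------------------------------------------------------------
# Scan simulation
# ---------------------------------------------------------------------------

_CHUNK = 1 << 21


def _isotropic_directions(rng, n):
    cos_t = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(1.0 - cos_t * cos_t)
    return np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=-1)


def _check_source_clear(volume: AttenuationVolume | None,
                        traj: SourceTrajectory, ring: DetectorRing) -> None:
    if traj.helix_radius >= ring.ring_radius:
        raise ValueError("helix radius must be inside the detector ring")
    if volume is None:
        return
    # sample the path densely over several turns spanning the axial range
    n_turns = max(2.0, abs(traj.z_span / traj.pitch) + 1.0)
    t = np.linspace(0.0, n_turns * traj.period, 4096)
    pos = source_position(traj, t)
    g = volume.grid
    idx = ((pos - np.asarray(g.origin)) / np.asarray(g.voxel_size)).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(g.shape)), axis=1)
    if inside.any():
        ii = idx[inside]
        if np.any(volume.values[ii[:, 0], ii[:, 1], ii[:, 2]] > 0):
            raise ValueError("source path intersects the phantom; "
                             "physically invalid configuration")


def iter_pair_chunks(origins_fn, n_decays: int, duration: float,
                     ring: DetectorRing, rng, chunk: int = _CHUNK):
    """Yield per-chunk accepted pair geometry for ``n_decays`` decays.

    ``origins_fn(t)`` maps sorted decay times to (n, 3) decay positions.
    Yields ``(t, pos, ra, ia, rb, ib, pa, pb)`` for pairs whose both
    photons geometrically reach the crystal stack.
    """
    times = rng.uniform(0.0, duration, n_decays)
    times.sort()
    for lo in range(0, n_decays, chunk):
        t = times[lo:lo + chunk]
        pos = origins_fn(t)
        dirs = _isotropic_directions(rng, len(t))
        hit, ra, ia, rb, ib, pa, pb = intersect_cylinder(ring, pos, dirs)
        yield (t[hit], pos[hit], ra[hit], ia[hit], rb[hit], ib[hit],
               pa[hit], pb[hit])


def _assemble(parts, ring, exposure, n_decays, tag):
    n = sum(len(p[0]) for p in parts)
    ev = np.zeros(n, dtype=EVENT_DTYPE)
    at = 0
    for (t, pos, ra, ia, rb, ib) in parts:
        sl = slice(at, at + len(t))
        ev["t"][sl] = t
        ev["ring_a"][sl] = ra
        ev["idx_a"][sl] = ia
        ev["ring_b"][sl] = rb
        ev["idx_b"][sl] = ib
        ev["x"][sl] = pos[:, 0]
        ev["y"][sl] = pos[:, 1]
        ev["z"][sl] = pos[:, 2]
        at += len(t)
    ev["tag"] = tag
    return ListModeData(ev, ring, exposure, n_decays)


def simulate_transmission_scan(volume_or_none: AttenuationVolume | None,
                               traj: SourceTrajectory, ring: DetectorRing,
                               scan_config: ScanConfig) -> ListModeData:
    """Simulate a transmission scan (or a blank scan if no volume).

    Every decay happens at the pellet position at its decay time; the pair
    direction is isotropic; detection requires both photons inside the
    crystal stack and survival of attenuation along the photon path
    (``exp(-tau)``, tau from the Siddon integral over the full LOR — for a
    source outside the object this equals the object-crossing segment).
    All events are tagged transmission.
    """
    _check_source_clear(volume_or_none, traj, ring)
    rng = np.random.default_rng(scan_config.seed)
    n_decays = int(rng.poisson(scan_config.exposure))
    eff2 = scan_config.detection_efficiency ** 2

    parts = []
    for (t, pos, ra, ia, rb, ib, pa, pb) in iter_pair_chunks(
            lambda tt: source_position(traj, tt), n_decays,
            scan_config.duration_s, ring, rng):
        if volume_or_none is not None and len(t):
            tau = siddon_batch(volume_or_none, pa, pb)
            p_det = eff2 * np.exp(-tau)
        else:
            p_det = np.full(len(t), eff2)
        keep = rng.random(len(t)) < p_det
        parts.append((t[keep], pos[keep], ra[keep], ia[keep],
                      rb[keep], ib[keep]))
    data = _assemble(parts, ring, scan_config.exposure, n_decays,
                     TAG_TRANSMISSION)
    log.info("transmission scan: %d decays -> %d events", n_decays, len(data))
    return data


def simulate_emission_scan(activity_volume: ActivityVolume,
                           attenuation_volume: AttenuationVolume | None,
                           ring: DetectorRing,
                           scan_config: ScanConfig) -> ListModeData:
    """Simulate the emission contamination: decays sampled proportionally
    to the activity distribution, attenuated along the full LOR, tagged
    emission.  ``scan_config.activity_bq`` is ignored in favor of the
    volume's total activity."""
    if np.any(activity_volume.values < 0):
        raise ValueError("negative activity")
    rng = np.random.default_rng(scan_config.seed)
    total = activity_volume.total_activity_bq
    n_decays = int(rng.poisson(total * scan_config.duration_s)) if total > 0 else 0
    g = activity_volume.grid
    pdf = activity_volume.values.ravel()
    cdf = np.cumsum(pdf)
    eff2 = scan_config.detection_efficiency ** 2

    def origins(t):
        flat = np.searchsorted(cdf, rng.uniform(0.0, cdf[-1], len(t)))
        ijk = np.stack(np.unravel_index(flat, g.shape), axis=-1).astype(float)
        jitter = rng.random((len(t), 3))
        return np.asarray(g.origin) + (ijk + jitter) * np.asarray(g.voxel_size)

    parts = []
    if n_decays:
        for (t, pos, ra, ia, rb, ib, pa, pb) in iter_pair_chunks(
                origins, n_decays, scan_config.duration_s, ring, rng):
            if attenuation_volume is not None and len(t):
                tau = siddon_batch(attenuation_volume, pa, pb)
                p_det = eff2 * np.exp(-tau)
            else:
                p_det = np.full(len(t), eff2)
            keep = rng.random(len(t)) < p_det
            parts.append((t[keep], pos[keep], ra[keep], ia[keep],
                          rb[keep], ib[keep]))
    data = _assemble(parts, ring, total * scan_config.duration_s, n_decays,
                     TAG_EMISSION)
    log.info("emission scan: %d decays -> %d events", n_decays, len(data))
    return data


def merge_scans(events_a: ListModeData, events_b: ListModeData) -> ListModeData:
    """Time-sorted, tag-preserving merge of two scans on the same ring."""
    if events_a.ring != events_b.ring:
        raise ValueError("scans must share the ring geometry")
    ev = np.concatenate([events_a.events, events_b.events])
    order = np.argsort(ev["t"], kind="stable")
    return ListModeData(ev[order], events_a.ring,
                        events_a.exposure + events_b.exposure,
                        events_a.n_decays + events_b.n_decays)
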