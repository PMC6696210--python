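"""Sinogram binning, single-slice rebinning, blank/transmission log-ratio,
and filtered back projection of attenuation maps.

Pipeline: list-mode events are histogrammed into a 3D sinogram stack over
(radial offset s, azimuth psi, crystal-ring pair); single-slice rebinning
(SSRB) assigns each ring pair (r1, r2) to the 2D plane at the axial
midpoint (r1 + r2) / 2, giving 2*n_rings - 1 planes; the per-bin log-ratio
of the (exposure-normalized) blank over the transmission sinogram is the
line integral of mu along that bin's LOR; filtered back projection then
inverts the Radon transform plane by plane, yielding a mu-map in cm^-1.

Arc correction of the radial bins is omitted: at the crystal counts used
here the chord-vs-arc difference is sub-bin across the imaging field (a
small-angle approximation, noted in the methods documentation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .forward_sim import ListModeData, siddon_batch, iter_pair_chunks
from .geometry import DetectorRing, SourceTrajectory, source_position
from .phantoms import AttenuationVolume, GridSpec

log = logging.getLogger(__name__)

__all__ = [
    "SinogramGeometry",
    "SinogramStack",
    "ReconConfig",
    "MuMapResult",
    "bin_events",
    "ssrb",
    "acf_sinogram",
    "fbp",
    "reconstruct_mumap",
    "expected_transmission_sinograms",
]


@dataclass(frozen=True)
class SinogramGeometry:
    """Radial/angular binning.  ``n_radial`` is odd so the central bin is
    centered on s = 0 (bins symmetric about the axis); azimuth covers
    [0, pi) in ``n_angles`` equal bins."""

    n_radial: int = 101
    radial_width_mm: float = 2.0
    n_angles: int = 96

    def __post_init__(self) -> None:
        if self.n_radial < 3 or self.n_radial % 2 == 0:
            raise ValueError("n_radial must be odd and >= 3")
        if self.n_angles < 2 or self.radial_width_mm <= 0:
            raise ValueError("need n_angles >= 2 and positive radial width")

    @property
    def s_centers(self) -> np.ndarray:
        half = (self.n_radial - 1) // 2
        return (np.arange(self.n_radial) - half) * self.radial_width_mm

    @property
    def angle_centers(self) -> np.ndarray:
        return (np.arange(self.n_angles) + 0.5) * np.pi / self.n_angles


@dataclass
class SinogramStack:
    """Counts (or log-ratio values) over (plane, angle, radial).

    ``kind`` is ``"3d"`` (planes indexed by ring pair, see ``ring_pairs``),
    ``"2d"`` (SSRB planes at ``plane_z`` mm), or ``"ratio"`` (log-ratio,
    float).  ``exposure`` carries activity x duration for normalization.
    """

    counts: np.ndarray
    geom: SinogramGeometry
    kind: str
    ring_pairs: Optional[np.ndarray] = None   # (n_pairs, 2) for kind="3d"
    plane_z: Optional[np.ndarray] = None      # (n_planes,) mm for 2d/ratio
    plane_spacing_mm: float = 0.0
    exposure: float = 0.0
    n_discarded: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


def _triangular_pairs(n_rings: int, max_ring_difference: int):
    """Ordered ring pairs (ra <= rb) with |rb - ra| <= mrd, and a lookup
    table pair_index[ra, rb]."""
    pairs = []
    lut = -np.ones((n_rings, n_rings), dtype=np.int64)
    for ra in range(n_rings):
        for rb in range(ra, min(n_rings, ra + max_ring_difference + 1)):
            lut[ra, rb] = len(pairs)
            lut[rb, ra] = lut[ra, rb]
            pairs.append((ra, rb))
    return np.asarray(pairs, dtype=np.int64), lut


def _project_to_bins(ring: DetectorRing, geom: SinogramGeometry,
                     idx_a, idx_b):
    """Map crystal index pairs to (angle_bin, radial_bin, in_range)."""
    phi_a = ring.crystal_angle(idx_a)
    phi_b = ring.crystal_angle(idx_b)
    R = ring.ring_radius
    x1, y1 = R * np.cos(phi_a), R * np.sin(phi_a)
    x2, y2 = R * np.cos(phi_b), R * np.sin(phi_b)
    dx, dy = x2 - x1, y2 - y1
    norm = np.hypot(dx, dy)
    # unit normal n = (-dy, dx)/|d|; line satisfies x*cos(psi)+y*sin(psi)=s
    with np.errstate(invalid="ignore", divide="ignore"):
        nx_, ny_ = -dy / norm, dx / norm
    psi = np.arctan2(ny_, nx_)
    s = x1 * nx_ + y1 * ny_
    flip = psi < 0
    psi = np.where(flip, psi + np.pi, psi)
    s = np.where(flip, -s, s)
    psi = np.where(psi >= np.pi, psi - np.pi, psi)

    a_bin = np.clip((psi / (np.pi / geom.n_angles)).astype(np.int64),
                    0, geom.n_angles - 1)
    half = (geom.n_radial - 1) // 2
    r_bin = np.rint(s / geom.radial_width_mm).astype(np.int64) + half
    in_range = (r_bin >= 0) & (r_bin < geom.n_radial) & (norm > 0)
    return a_bin, r_bin, in_range


def _bin_core(ring, geom, ring_a, idx_a, ring_b, idx_b,
              max_ring_difference, weights=None):
    n_rings = ring.n_rings
    pairs, lut = _triangular_pairs(n_rings, max_ring_difference)
    a_bin, r_bin, ok = _project_to_bins(ring, geom, idx_a, idx_b)
    p_idx = lut[ring_a, ring_b]
    ok = ok & (p_idx >= 0)
    flat = (p_idx[ok] * geom.n_angles + a_bin[ok]) * geom.n_radial + r_bin[ok]
    size = len(pairs) * geom.n_angles * geom.n_radial
    w = None if weights is None else weights[ok]
    counts = np.bincount(flat, weights=w, minlength=size).reshape(
        len(pairs), geom.n_angles, geom.n_radial)
    if weights is None:
        counts = counts.astype(np.int64)
    n_disc = int(np.count_nonzero(~ok))
    return counts, pairs, n_disc


def bin_events(events: ListModeData, ring: DetectorRing,
               sinogram_geometry: SinogramGeometry,
               max_ring_difference: int | None = None) -> SinogramStack:
    """Histogram list-mode events into a 3D sinogram stack.

    Events whose radial offset falls outside the sinogram, or whose ring
    difference exceeds ``max_ring_difference`` (default: all pairs), are
    counted in ``n_discarded`` and logged; retained counts are conserved
    exactly.
    """
    if events.ring != ring:
        raise ValueError("events were recorded on a different ring geometry")
    mrd = ring.n_rings - 1 if max_ring_difference is None else max_ring_difference
    e = events.events
    # the pair LUT and the transaxial projection are both symmetric under
    # endpoint swap, so no reordering is needed
    counts, pairs, n_disc = _bin_core(
        ring, sinogram_geometry, e["ring_a"].astype(np.int64),
        e["idx_a"].astype(np.int64), e["ring_b"].astype(np.int64),
        e["idx_b"].astype(np.int64), mrd)
    if n_disc:
        log.info("bin_events: %d / %d events out of range", n_disc, len(e))
    return SinogramStack(counts=counts, geom=sinogram_geometry, kind="3d",
                         ring_pairs=pairs, exposure=events.exposure,
                         n_discarded=n_disc,
                         meta={"ring_spacing_mm": ring.ring_spacing,
                               "z_min_mm": ring.z_min,
                               "n_rings": ring.n_rings})


def ssrb(sino3d: SinogramStack, max_ring_difference: int | None = None
         ) -> SinogramStack:
    """Single-slice rebinning: ring pair (r1, r2) -> plane (r1 + r2)/2.

    Half-integer planes are kept as their own slices, giving
    ``2 * n_rings - 1`` output planes spaced at half the ring spacing.
    Pairs with ``|r1 - r2| > max_ring_difference`` are discarded (counted).
    """
    if sino3d.kind != "3d" or sino3d.ring_pairs is None:
        raise ValueError("ssrb expects a 3D sinogram stack")
    n_rings = int(sino3d.meta["n_rings"])
    spacing = float(sino3d.meta["ring_spacing_mm"])
    z_min = float(sino3d.meta["z_min_mm"])
    mrd = n_rings - 1 if max_ring_difference is None else max_ring_difference
    if mrd > n_rings - 1:
        raise ValueError("max_ring_difference exceeds n_rings - 1")

    n_planes = 2 * n_rings - 1
    out = np.zeros((n_planes,) + sino3d.counts.shape[1:],
                   dtype=sino3d.counts.dtype)
    discarded = 0
    for k, (r1, r2) in enumerate(sino3d.ring_pairs):
        if abs(int(r2) - int(r1)) > mrd:
            discarded += int(sino3d.counts[k].sum())
            continue
        out[int(r1) + int(r2)] += sino3d.counts[k]
    if discarded:
        log.info("ssrb: discarded %d counts beyond ring difference %d",
                 discarded, mrd)
    # plane p sits at the mean of the two ring centers
    plane_z = z_min + (np.arange(n_planes) / 2.0 + 0.5) * spacing
    return SinogramStack(counts=out, geom=sino3d.geom, kind="2d",
                         plane_z=plane_z, plane_spacing_mm=spacing / 2.0,
                         exposure=sino3d.exposure,
                         n_discarded=sino3d.n_discarded + discarded,
                         meta=dict(sino3d.meta))


def acf_sinogram(blank2d: SinogramStack, trans2d: SinogramStack,
                 zero_policy: str = "pseudocount",
                 blank_scale: float | None = None) -> SinogramStack:
    """Log attenuation-correction-factor sinogram: ln(blank / trans).

    The blank is scaled by ``(activity x duration)_trans / (...)_blank``
    (taken from the stacks' ``exposure`` unless given explicitly) so both
    scans are on the same counting scale.  ``zero_policy``:

    - ``"pseudocount"`` (default): add 0.5 to both raw counts before the
      log — finite everywhere, small bias at very low counts;
    - ``"mask"``: bins with zero transmission counts are filled by linear
      interpolation along the radial axis.
    """
    if blank2d.counts.shape != trans2d.counts.shape:
        raise ValueError("blank and transmission sinograms must match")
    if blank2d.total_counts == 0:
        raise ValueError("all-zero blank sinogram: cannot normalize")
    if blank_scale is None:
        if blank2d.exposure <= 0 or trans2d.exposure <= 0:
            raise ValueError("exposures unknown; pass blank_scale explicitly")
        blank_scale = trans2d.exposure / blank2d.exposure
    b = blank2d.counts.astype(np.float64)
    t = trans2d.counts.astype(np.float64)
    if zero_policy == "pseudocount":
        with np.errstate(divide="ignore"):
            vals = np.log(blank_scale * (b + 0.5)) - np.log(t + 0.5)
    elif zero_policy == "mask":
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log(blank_scale * b) - np.log(t)
        bad = ~np.isfinite(vals)
        vals[bad] = 0.0
        ns = vals.shape[-1]
        xs = np.arange(ns)
        flatv = vals.reshape(-1, ns)
        flatb = bad.reshape(-1, ns)
        for row in range(flatv.shape[0]):
            m = flatb[row]
            if m.any() and not m.all():
                flatv[row, m] = np.interp(xs[m], xs[~m], flatv[row, ~m])
        vals = flatv.reshape(vals.shape)
    else:
        raise ValueError("zero_policy must be 'pseudocount' or 'mask'")
    return SinogramStack(counts=vals, geom=blank2d.geom, kind="ratio",
                         plane_z=trans2d.plane_z,
                         plane_spacing_mm=trans2d.plane_spacing_mm,
                         exposure=trans2d.exposure,
                         meta={"blank_scale": blank_scale,
                               "zero_policy": zero_policy,
                               **trans2d.meta})


@dataclass(frozen=True)
class ReconConfig:
    """FBP settings: output grid and ramp-filter apodization.  The ramp is
    multiplied by a Hann half-window up to ``cutoff`` x Nyquist (cutoff
    ``>= 1`` with ``window="ramp"`` gives the bare ramp)."""

    n_pixels: int = 100
    pixel_size_mm: float = 2.0
    window: str = "hann"
    cutoff: float = 0.9

    def __post_init__(self) -> None:
        if self.n_pixels < 2 or self.pixel_size_mm <= 0:
            raise ValueError("invalid image grid")
        if not (0 < self.cutoff <= 1.0):
            raise ValueError("cutoff must be in (0, 1]")
        if self.window not in ("ramp", "hann"):
            raise ValueError("window must be 'ramp' or 'hann'")


def _ramp_filter(m: int, ds: float, window: str, cutoff: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(m, d=ds)          # cycles/mm
    filt = np.abs(freqs)
    f_nyq = 1.0 / (2.0 * ds)
    fc = cutoff * f_nyq
    if window == "hann":
        apod = np.where(freqs <= fc,
                        0.5 * (1.0 + np.cos(np.pi * freqs / fc)), 0.0)
        filt = filt * apod
    else:
        filt = np.where(freqs <= fc, filt, 0.0)
    return filt


def fbp(sino2d_plane: np.ndarray, geom: SinogramGeometry,
        recon_config: ReconConfig | None = None) -> np.ndarray:
    """Filtered back projection of one 2D sinogram plane.

    ``sino2d_plane`` has shape (n_angles, n_radial) and holds line
    integrals of mu (dimensionless, i.e. cm^-1 x cm); the returned image
    is mu in cm^-1 on an ``n_pixels`` square grid centered on the axis.
    """
    cfg = recon_config or ReconConfig()
    p = np.asarray(sino2d_plane, dtype=np.float64)
    if p.ndim != 2 or p.shape != (geom.n_angles, geom.n_radial):
        raise ValueError("sinogram plane shape must be (n_angles, n_radial)")
    ds = geom.radial_width_mm
    m = 1 << int(np.ceil(np.log2(max(2 * geom.n_radial, 16))))
    filt = _ramp_filter(m, ds, cfg.window, cfg.cutoff)
    q = np.fft.irfft(np.fft.rfft(p, m, axis=1) * filt, m, axis=1)[:, :geom.n_radial]

    npix = cfg.n_pixels
    half_img = npix * cfg.pixel_size_mm / 2.0
    xs = (np.arange(npix) + 0.5) * cfg.pixel_size_mm - half_img
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    s_axis = geom.s_centers
    img = np.zeros((npix, npix))
    for a, psi in enumerate(geom.angle_centers):
        s = X * np.cos(psi) + Y * np.sin(psi)
        img += np.interp(s, s_axis, q[a], left=0.0, right=0.0)
    img *= np.pi / geom.n_angles      # mu per mm
    return img * 10.0                 # -> cm^-1


@dataclass
class MuMapResult:
    """Reconstructed attenuation volume (cm^-1) with provenance.

    ``values`` keeps the raw FBP output (noise can dip below zero, which
    matters for null checks); :meth:`attenuation_volume` returns the
    physical, non-negative clipped version.
    """

    values: np.ndarray
    grid: GridSpec
    acf: SinogramStack
    provenance: dict

    def attenuation_volume(self) -> AttenuationVolume:
        return AttenuationVolume(values=np.clip(self.values, 0.0, None),
                                 grid=self.grid)

    def to_nifti(self, path) -> None:
        from .io import save_nifti
        save_nifti(path, self.values, self.grid)


def reconstruct_mumap(blank_events: ListModeData, trans_events: ListModeData,
                      ring: DetectorRing,
                      geometry: SinogramGeometry | None = None,
                      recon_config: ReconConfig | None = None,
                      max_ring_difference: int | None = None,
                      zero_policy: str = "pseudocount",
                      blank_scale: float | None = None) -> MuMapResult:
    """Full chain: bin both scans, SSRB, log-ratio, per-plane FBP.

    The output volume sits on a grid with the FBP pixel size transaxially
    and half the ring spacing axially (one voxel slab per SSRB plane).
    """
    if blank_events.ring != trans_events.ring:
        raise ValueError("blank and transmission scans must share geometry")
    geom = geometry or SinogramGeometry()
    cfg = recon_config or ReconConfig()
    b3 = bin_events(blank_events, ring, geom, max_ring_difference)
    t3 = bin_events(trans_events, ring, geom, max_ring_difference)
    b2 = ssrb(b3, max_ring_difference)
    t2 = ssrb(t3, max_ring_difference)
    acf = acf_sinogram(b2, t2, zero_policy=zero_policy, blank_scale=blank_scale)

    n_planes = acf.counts.shape[0]
    vol = np.empty((cfg.n_pixels, cfg.n_pixels, n_planes))
    for p in range(n_planes):
        vol[:, :, p] = fbp(acf.counts[p], geom, cfg)
    half = cfg.n_pixels * cfg.pixel_size_mm / 2.0
    dz = acf.plane_spacing_mm
    grid = GridSpec(shape=vol.shape,
                    voxel_size=(cfg.pixel_size_mm, cfg.pixel_size_mm, dz),
                    origin=(-half, -half, float(acf.plane_z[0]) - dz / 2.0))
    prov = {
        "sinogram_geometry": vars(geom).copy() if hasattr(geom, "__dict__")
        else {f: getattr(geom, f) for f in ("n_radial", "radial_width_mm", "n_angles")},
        "recon_config": {f: getattr(cfg, f)
                         for f in ("n_pixels", "pixel_size_mm", "window", "cutoff")},
        "blank": {"n_events": len(blank_events), "exposure": blank_events.exposure},
        "transmission": {"n_events": len(trans_events),
                         "exposure": trans_events.exposure},
        "zero_policy": zero_policy,
        "blank_scale": acf.meta.get("blank_scale"),
    }
    return MuMapResult(values=vol, grid=grid, acf=acf, provenance=prov)


def expected_transmission_sinograms(volume: AttenuationVolume,
                                    traj: SourceTrajectory,
                                    ring: DetectorRing,
                                    geom: SinogramGeometry,
                                    n_decays: int, seed: int,
                                    duration_s: float = 60.0,
                                    max_ring_difference: int | None = None):
    """Noise-free paired blank/transmission expectation sinograms.

    The same sampled decays and pair directions feed both sinograms: each
    geometrically accepted pair contributes weight 1 to the blank and
    ``exp(-tau)`` to the transmission stack.  Because the Poisson thinning
    is replaced by its expectation and the sampling noise is common to the
    two stacks, the per-bin log-ratio directly estimates the bin-averaged
    optical depth — the forward-model consistency reference for the
    reconstruction chain.

    Returns SSRB'd 2D stacks ``(blank2d, trans2d, tau_mean2d)``, the last
    holding the per-bin mean forward-projected optical depth of the same
    contributing LORs (the direct Siddon reference the log-ratio should
    reproduce up to within-bin averaging).
    """
    rng = np.random.default_rng(seed)
    mrd = ring.n_rings - 1 if max_ring_difference is None else max_ring_difference
    pairs, _ = _triangular_pairs(ring.n_rings, mrd)
    shape = (len(pairs), geom.n_angles, geom.n_radial)
    blank = np.zeros(shape)
    trans = np.zeros(shape)
    tausum = np.zeros(shape)
    for (t, pos, ra, ia, rb, ib, pa, pb) in iter_pair_chunks(
            lambda tt: source_position(traj, tt), n_decays, duration_s,
            ring, rng):
        if not len(t):
            continue
        tau = siddon_batch(volume, pa, pb)
        cb, _, _ = _bin_core(ring, geom, ra.astype(np.int64), ia,
                             rb.astype(np.int64), ib, mrd)
        ct, _, _ = _bin_core(ring, geom, ra.astype(np.int64), ia,
                             rb.astype(np.int64), ib, mrd,
                             weights=np.exp(-tau))
        ck, _, _ = _bin_core(ring, geom, ra.astype(np.int64), ia,
                             rb.astype(np.int64), ib, mrd, weights=tau)
        blank += cb
        trans += ct
        tausum += ck
    mk = {"ring_spacing_mm": ring.ring_spacing, "z_min_mm": ring.z_min,
          "n_rings": ring.n_rings}

    def _to2d(arr):
        s3 = SinogramStack(counts=arr, geom=geom, kind="3d", ring_pairs=pairs,
                           exposure=float(n_decays), meta=mk)
        return ssrb(s3, mrd)

    b2, t2 = _to2d(blank), _to2d(trans)
    k2 = _to2d(tausum)
    with np.errstate(invalid="ignore", divide="ignore"):
        k2.counts = np.where(b2.counts > 0, k2.counts / b2.counts, 0.0)
    return b2, t2, k2
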