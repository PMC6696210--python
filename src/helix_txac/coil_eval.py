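"""MR receive-array evaluation on synthetic multi-channel data: noise
correlation, pseudo-multiple-replica SNR maps, GRAPPA reconstruction, and
g-factor maps.

Synthetic channel sensitivities come from the quasi-static magnetic field
of circular loops (exact off-axis expressions via complete elliptic
integrals), arranged on a circle around the 2D imaging plane.  Channel
noise is complex Gaussian with a configurable Hermitian covariance; the
pseudo-multiple-replica method estimates per-pixel noise by repeatedly
adding fresh correlated noise to the k-space data, reconstructing, and
taking statistics across replicas.  The g-factor at acceleration R is the
replica noise of the GRAPPA reconstruction relative to the unaccelerated
reconstruction, divided by sqrt(R), smoothed with a 3 x 3 mean filter.

FFTs use the orthonormal ("ortho") convention throughout so that white
noise of variance sigma^2 per k-space sample maps to variance sigma^2 per
image pixel, and k-space is stored centered (DC at the array center), the
usual MRI raw-data layout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, special

log = logging.getLogger(__name__)

__all__ = [
    "ImagingGrid",
    "NoiseModel",
    "SensitivitySet",
    "GrappaKernel",
    "loop_sensitivity",
    "make_loop_array",
    "simulate_multicoil_kspace",
    "noise_correlation",
    "rss_combine",
    "pseudo_replica_snr",
    "grappa_reconstruct",
    "decimate_kspace",
    "gfactor_map",
    "snr_ratio",
]


@dataclass(frozen=True)
class ImagingGrid:
    """Square 2D imaging plane: n x n pixels of ``pixel_mm``, centered on
    the origin; axes (x, y) with y the phase-encode direction."""

    n: int = 64
    pixel_mm: float = 4.0

    def coords(self):
        half = self.n * self.pixel_mm / 2.0
        ax = (np.arange(self.n) + 0.5) * self.pixel_mm - half
        return np.meshgrid(ax, ax, indexing="ij")


def _loop_field(rho, z, a):
    """Magnetic field (B_rho, B_z) of a unit-current circular loop of
    radius ``a`` centered at the origin with axis along z (arbitrary but
    consistent units; the on-axis limit is a^2 / (2 (a^2+z^2)^{3/2}))."""
    rho = np.asarray(rho, dtype=float)
    z = np.asarray(z, dtype=float)
    eps = 1e-9 * a
    rho_s = np.maximum(rho, eps)
    denom1 = (a + rho_s) ** 2 + z ** 2
    denom2 = (a - rho_s) ** 2 + z ** 2
    denom2 = np.maximum(denom2, (1e-3 * a) ** 2)   # clip on-wire singularity
    k2 = np.clip(4.0 * a * rho_s / denom1, 0.0, 1.0 - 1e-12)
    K = special.ellipk(k2)
    E = special.ellipe(k2)
    pref = 1.0 / (2.0 * np.pi * np.sqrt(denom1))
    bz = pref * (K + (a ** 2 - rho_s ** 2 - z ** 2) / denom2 * E)
    brho = pref * (z / rho_s) * (-K + (a ** 2 + rho_s ** 2 + z ** 2) / denom2 * E)
    brho = np.where(rho < eps, 0.0, brho)
    return brho, bz


def loop_sensitivity(loop_center, loop_radius: float,
                     grid: ImagingGrid, normal=None,
                     phase_ramp_per_mm: float = 0.01) -> np.ndarray:
    """Complex receive sensitivity of one circular loop over the grid.

    ``loop_center`` is the loop center in mm in the imaging plane's 3D
    frame (z = 0 plane is imaged); ``normal`` is the loop axis (default:
    pointing from the loop center toward the origin).  The magnitude is
    the quasi-static |B| of the loop; the phase is a smooth ramp along the
    loop axis direction, a stand-in for the spatially slowly varying
    receive phase of a real channel.
    """
    if loop_radius <= 0:
        raise ValueError("loop_radius must be > 0")
    c = np.asarray(loop_center, dtype=float)
    if normal is None:
        normal = -c
    nrm = np.asarray(normal, dtype=float)
    ln = np.linalg.norm(nrm)
    if ln == 0:
        raise ValueError("degenerate loop normal")
    nrm = nrm / ln

    X, Y = grid.coords()
    P = np.stack([X, Y, np.zeros_like(X)], axis=-1) - c
    z = P @ nrm
    rho = np.linalg.norm(P - z[..., None] * nrm, axis=-1)
    brho, bz = _loop_field(rho, z, loop_radius)
    mag = np.hypot(brho, bz)
    phase = phase_ramp_per_mm * (X * nrm[0] + Y * nrm[1])
    return mag * np.exp(1j * phase)


@dataclass
class SensitivitySet:
    """Per-channel complex sensitivities, shape (n_channels, n, n)."""

    maps: np.ndarray
    grid: ImagingGrid

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.complex128)
        if self.maps.ndim != 3 or self.maps.shape[0] < 1:
            raise ValueError("maps must be (n_channels, ny, nx) with >= 1 channel")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("sensitivities must be finite")

    @property
    def n_channels(self) -> int:
        return self.maps.shape[0]


def make_loop_array(n_loops: int = 8, array_radius_mm: float = 140.0,
                    loop_radius_mm: float = 50.0,
                    grid: ImagingGrid | None = None,
                    standoff_mm: float = 0.0) -> SensitivitySet:
    """Circular array of identical loops around the imaging plane, each
    loop axis pointing at the isocenter.

    The stacked maps are normalized to unit peak magnitude so that object
    signal and noise-model sigma live on comparable scales regardless of
    the loop geometry (the raw quasi-static field amplitude is
    arbitrary-units anyway)."""
    grid = grid or ImagingGrid()
    maps = []
    for k in range(n_loops):
        phi = 2.0 * np.pi * k / n_loops
        c = np.array([(array_radius_mm + standoff_mm) * np.cos(phi),
                      (array_radius_mm + standoff_mm) * np.sin(phi), 0.0])
        maps.append(loop_sensitivity(c, loop_radius_mm, grid))
    stacked = np.stack(maps)
    stacked /= np.abs(stacked).max()
    return SensitivitySet(maps=stacked, grid=grid)


@dataclass
class NoiseModel:
    """Hermitian positive semi-definite channel noise covariance.

    ``scale`` multiplies the covariance; noise samples are circular
    complex Gaussian with per-channel variance ``scale * diag``.
    """

    covariance: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        c = np.asarray(self.covariance, dtype=np.complex128)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(c, c.conj().T, atol=1e-10):
            raise ValueError("covariance must be Hermitian")
        ev = np.linalg.eigvalsh(c)
        if ev.min() < -1e-10 * max(ev.max(), 1.0):
            raise ValueError("covariance must be positive semi-definite")
        self.covariance = c

    @classmethod
    def white(cls, n_channels: int, sigma: float = 1.0) -> "NoiseModel":
        return cls(covariance=np.eye(n_channels), scale=sigma ** 2)

    @classmethod
    def exponential(cls, n_channels: int, rho: float = 0.3,
                    sigma: float = 1.0) -> "NoiseModel":
        """Neighbor-decaying correlation ``rho^|i-j|`` — a simple stand-in
        for the coupling structure of a physical array."""
        idx = np.arange(n_channels)
        cov = rho ** np.abs(idx[:, None] - idx[None, :])
        return cls(covariance=cov.astype(complex), scale=sigma ** 2)

    def cholesky(self) -> np.ndarray:
        c = self.covariance * self.scale
        # tiny jitter keeps semi-definite covariances factorizable
        jitter = 1e-12 * np.trace(c).real / c.shape[0]
        return np.linalg.cholesky(c + jitter * np.eye(c.shape[0]))

    def sample(self, rng, shape) -> np.ndarray:
        """Correlated complex Gaussian noise of shape (n_channels, *shape)."""
        L = self.cholesky()
        nc = self.covariance.shape[0]
        flat = int(np.prod(shape))
        white = (rng.standard_normal((nc, flat))
                 + 1j * rng.standard_normal((nc, flat))) / np.sqrt(2.0)
        return (L @ white).reshape((nc,) + tuple(shape))


def simulate_multicoil_kspace(object_image: np.ndarray,
                              sensitivities: SensitivitySet,
                              noise_model: NoiseModel | None,
                              seed: int) -> np.ndarray:
    """Fully sampled multi-channel k-space of ``object x sensitivity``
    plus (optionally) correlated complex Gaussian noise."""
    obj = np.asarray(object_image, dtype=np.complex128)
    if obj.shape != sensitivities.maps.shape[1:]:
        raise ValueError("object and sensitivity grids must match")
    imgs = sensitivities.maps * obj[None]
    ks = np.fft.fftshift(np.fft.fft2(imgs, axes=(-2, -1), norm="ortho"),
                         axes=(-2, -1))
    if noise_model is not None:
        if noise_model.covariance.shape[0] != sensitivities.n_channels:
            raise ValueError("noise covariance channel count mismatch")
        rng = np.random.default_rng(seed)
        ks = ks + noise_model.sample(rng, obj.shape)
    return ks


def noise_correlation(noise_samples: np.ndarray) -> np.ndarray:
    """Channel noise correlation matrix from (n_channels, n_samples) data:
    the sample covariance normalized to unit diagonal (Hermitian, entries
    bounded by 1 in magnitude)."""
    x = np.asarray(noise_samples)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need (n_channels, n_samples >= 2)")
    x = x - x.mean(axis=1, keepdims=True)
    cov = (x @ x.conj().T) / (x.shape[1] - 1)
    dg = np.real(np.diag(cov))
    if np.any(dg <= 0):
        raise ValueError("zero-variance channel")
    corr = cov / np.sqrt(np.outer(dg, dg))
    np.fill_diagonal(corr, 1.0)
    return 0.5 * (corr + corr.conj().T)


def rss_combine(channel_images: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares channel combination (real, non-negative)."""
    return np.sqrt(np.sum(np.abs(channel_images) ** 2, axis=0))


def _reconstruct(ks: np.ndarray) -> np.ndarray:
    return np.fft.ifft2(np.fft.ifftshift(ks, axes=(-2, -1)),
                        axes=(-2, -1), norm="ortho")


def pseudo_replica_snr(kspace: np.ndarray, noise_model: NoiseModel,
                       n_replicas: int = 128, seed: int = 0,
                       combiner: str = "rss") -> np.ndarray:
    """Pseudo-multiple-replica SNR map of fully sampled k-space.

    Each replica adds fresh correlated noise, reconstructs, and combines
    channels; SNR(pixel) = mean over replicas / std over replicas of the
    combined magnitude.
    """
    if n_replicas < 2:
        raise ValueError("need at least 2 replicas")
    if combiner != "rss":
        raise ValueError("only the 'rss' combiner is implemented")
    rng = np.random.default_rng(seed)
    stack = np.empty((n_replicas,) + kspace.shape[1:])
    for r in range(n_replicas):
        ks = kspace + noise_model.sample(rng, kspace.shape[1:])
        stack[r] = rss_combine(_reconstruct(ks))
    mean = stack.mean(axis=0)
    std = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(std > 0, mean / std, 0.0)
    return snr


@dataclass(frozen=True)
class GrappaKernel:
    """GRAPPA kernel: ``ky_taps`` sampled phase-encode lines by ``kx_taps``
    readout columns, fit with Tikhonov regularization ``reg`` (scaled by
    the mean diagonal of the normal matrix)."""

    ky_taps: int = 2
    kx_taps: int = 5
    reg: float = 1e-4

    def __post_init__(self) -> None:
        if self.ky_taps < 2 or self.kx_taps < 1 or self.kx_taps % 2 == 0:
            raise ValueError("need ky_taps >= 2 and odd kx_taps >= 1")


#: Kernel used for g-factor mapping: a minimal 2 x 1 interpolation kernel
#: with light regularization.  Wider kernels average noise across many
#: k-space samples ("noise apodization"), which depresses the measured
#: g-factor well below the unaliasing-theory value; the minimal kernel
#: keeps the pseudo-replica g-map close to that theory.
GFACTOR_KERNEL = GrappaKernel(ky_taps=2, kx_taps=1, reg=1e-6)


def _grappa_weights(acs: np.ndarray, kernel: GrappaKernel, R: int):
    """Fit per-offset GRAPPA weights on the fully sampled ACS block.

    Returns ``weights[m]`` of shape (nc, nc, ky_taps, kx_taps) predicting
    the line at offset ``m`` (1..R-1) above a sampled line from the
    ``ky_taps`` nearest sampled lines.
    """
    nc, ny, nx = acs.shape
    T, W = kernel.ky_taps, kernel.kx_taps
    hw = W // 2
    j0 = (T - 1) // 2
    weights = {}
    for m in range(1, R):
        dys = [(-m) + (j - j0) * R for j in range(T)]
        ys = [y for y in range(ny) if all(0 <= y + dy < ny for dy in dys)]
        xs = list(range(hw, nx - hw))
        if not ys or not xs:
            raise ValueError("ACS region smaller than the GRAPPA kernel")
        A = np.empty((len(ys) * len(xs), nc * T * W), dtype=complex)
        b = np.empty((len(ys) * len(xs), nc), dtype=complex)
        row = 0
        for y in ys:
            for x in xs:
                feat = [acs[c, y + dy, x - hw:x + hw + 1]
                        for c in range(nc) for dy in dys]
                A[row] = np.concatenate(feat)
                b[row] = acs[:, y, x]
                row += 1
        AhA = A.conj().T @ A
        lam = kernel.reg * np.trace(AhA).real / AhA.shape[0]
        w = np.linalg.solve(AhA + lam * np.eye(AhA.shape[0]), A.conj().T @ b)
        weights[m] = w  # (nc*T*W, nc)
    return weights


def _grappa_apply(ks_under: np.ndarray, weights: dict,
                  kernel: GrappaKernel, R: int,
                  sampled_mask: np.ndarray) -> np.ndarray:
    """Synthesize missing phase-encode lines (periodic in ky via roll)."""
    nc, ny, nx = ks_under.shape
    T, W = kernel.ky_taps, kernel.kx_taps
    hw = W // 2
    j0 = (T - 1) // 2
    out = ks_under.copy()
    sampled_rows = np.flatnonzero(sampled_mask)
    for m in range(1, R):
        target_rows = sampled_rows + m
        target_rows = target_rows[target_rows < ny]
        if len(target_rows) == 0:
            continue
        dys = [(-m) + (j - j0) * R for j in range(T)]
        # feature tensor via rolls: (nc*T*W, ny, nx) evaluated at targets
        feats = []
        for c in range(nc):
            for dy in dys:
                for dx in range(-hw, hw + 1):
                    feats.append(np.roll(ks_under[c], (-dy, -dx), axis=(0, 1)))
        F = np.stack(feats)[:, target_rows, :]          # (ncTW, nt, nx)
        w = weights[m]                                   # (ncTW, nc)
        synth = np.tensordot(w.T, F, axes=1)             # (nc, nt, nx)
        out[:, target_rows, :] = synth
    return out


def grappa_reconstruct(undersampled_kspace: np.ndarray, acs_region: np.ndarray,
                       kernel_spec: GrappaKernel | None = None,
                       R: int = 2) -> np.ndarray:
    """GRAPPA: fill skipped phase-encode lines, return channel images.

    ``undersampled_kspace`` holds the sampled lines at ky = 0, R, 2R, ...
    (missing lines zero); ``acs_region`` is a fully sampled (nc, ny_acs,
    nx) calibration block.  ``R = 1`` returns the input unchanged.
    """
    if R < 1 or int(R) != R:
        raise ValueError("R must be a positive integer")
    ks = np.asarray(undersampled_kspace, dtype=complex)
    if ks.ndim != 3:
        raise ValueError("kspace must be (nc, ny, nx)")
    if R == 1:
        return _reconstruct(ks)
    kernel = kernel_spec or GrappaKernel()
    nc = ks.shape[0]
    if R > nc:
        warnings.warn(f"acceleration R={R} exceeds the channel count ({nc}); "
                      "the reconstruction is under-determined",
                      RuntimeWarning, stacklevel=2)
    weights = _grappa_weights(np.asarray(acs_region, dtype=complex),
                              kernel, R)
    mask = np.zeros(ks.shape[1], dtype=bool)
    mask[::R] = True
    filled = _grappa_apply(ks, weights, kernel, R, mask)
    return _reconstruct(filled)


def decimate_kspace(kspace: np.ndarray, R: int) -> np.ndarray:
    """Zero out phase-encode lines not on the ky = 0 mod R lattice."""
    out = np.array(kspace, dtype=complex, copy=True)
    mask = np.zeros(out.shape[1], dtype=bool)
    mask[::R] = True
    out[:, ~mask, :] = 0.0
    return out


def gfactor_map(fully_sampled_kspace: np.ndarray, noise_model: NoiseModel,
                R: int, n_replicas: int = 128, seed: int = 0,
                kernel_spec: GrappaKernel | None = None,
                acs_lines: int = 24, smooth: bool = True) -> np.ndarray:
    """Pseudo-replica g-factor map at acceleration R.

    g(pixel) = [replica noise-std of the R-accelerated GRAPPA + RSS
    reconstruction / replica noise-std of the unaccelerated RSS
    reconstruction] / sqrt(R).  GRAPPA weights are calibrated once on the
    central ``acs_lines`` of the noise-free data; each replica adds fresh
    correlated noise to the acquired samples only.  The map is smoothed
    with a 3 x 3 mean filter (disable with ``smooth=False``).

    Uses :data:`GFACTOR_KERNEL` unless ``kernel_spec`` is given; GRAPPA's
    intrinsic noise averaging can still push isolated pixels a few percent
    below 1.
    """
    if R < 1 or int(R) != R:
        raise ValueError("R must be a positive integer")
    ks = np.asarray(fully_sampled_kspace, dtype=complex)
    nc, ny, nx = ks.shape
    if R > nc:
        warnings.warn(f"R={R} exceeds channel count {nc}: g-factors are "
                      "undefined outside SENSE/GRAPPA theory",
                      RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    kernel = kernel_spec or GFACTOR_KERNEL

    weights = None
    mask = np.zeros(ny, dtype=bool)
    mask[::R] = True
    if R > 1:
        y0 = (ny - acs_lines) // 2
        acs = ks[:, y0:y0 + acs_lines, :]
        weights = _grappa_weights(acs, kernel, R)

    full_stack = np.empty((n_replicas, ny, nx))
    acc_stack = np.empty((n_replicas, ny, nx))
    for r in range(n_replicas):
        noise = noise_model.sample(rng, (ny, nx))
        noisy = ks + noise
        full_stack[r] = rss_combine(_reconstruct(noisy))
        if R == 1:
            acc_stack[r] = full_stack[r]
        else:
            under = noisy.copy()
            under[:, ~mask, :] = 0.0
            filled = _grappa_apply(under, weights, kernel, R, mask)
            acc_stack[r] = rss_combine(_reconstruct(filled))
    std_full = full_stack.std(axis=0, ddof=1)
    std_acc = acc_stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(std_full > 0, std_acc / std_full, 0.0) / np.sqrt(R)
    if smooth:
        g = ndimage.uniform_filter(g, size=3, mode="nearest")
    return g


def snr_ratio(snr_a: np.ndarray, snr_b: np.ndarray) -> np.ndarray:
    """Pixelwise SNR ratio of two arrays' maps (the synthetic analogue of
    comparing a new coil against a reference coil)."""
    a = np.asarray(snr_a, float)
    b = np.asarray(snr_b, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(b > 0, a / b, 0.0)
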