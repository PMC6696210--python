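"""Scoring of reconstructed attenuation maps: ROI statistics and air-cavity
recovery.

A cavity counts as "recovered" when the mean reconstructed mu inside its
ground-truth mask falls below ``contrast_threshold`` (default 50%) of the
surrounding water background mean — a simple, stated operationalization of
visual detectability that is used consistently across the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["RoiReport", "roi_stats", "cavity_recovery", "cavity_report",
           "eroded_cylinder_roi"]


@dataclass(frozen=True)
class RoiReport:
    """Summary statistics of a mu-map over one mask."""

    label: str
    mean: float
    std: float
    n_voxels: int

    def __str__(self) -> str:
        return (f"{self.label}: mu = {self.mean:.4f} +/- {self.std:.4f} cm^-1 "
                f"({self.n_voxels} voxels)")


def roi_stats(mumap: np.ndarray, mask: np.ndarray, label: str = "roi") -> RoiReport:
    """Mean/std of the map over the mask voxels (population std)."""
    mumap = np.asarray(mumap)
    mask = np.asarray(mask, dtype=bool)
    if mumap.shape != mask.shape:
        raise ValueError("mask and map must share the grid")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty ROI mask")
    vals = mumap[mask]
    return RoiReport(label=label, mean=float(vals.mean()),
                     std=float(vals.std()), n_voxels=n)


def eroded_cylinder_roi(mask: np.ndarray, erosion_voxels: int = 2,
                        axial_trim: int = 0) -> np.ndarray:
    """Erode a cylindrical object mask transaxially (and optionally trim
    end slices) to exclude FBP edge ringing from mu statistics."""
    out = np.asarray(mask, dtype=bool).copy()
    if erosion_voxels > 0:
        struct = ndimage.generate_binary_structure(2, 1)
        for k in range(out.shape[2]):
            out[:, :, k] = ndimage.binary_erosion(
                out[:, :, k], struct, iterations=erosion_voxels)
    if axial_trim > 0:
        out[:, :, :axial_trim] = False
        out[:, :, -axial_trim:] = False
    return out


def cavity_report(mumap: np.ndarray, cavity_masks: dict,
                  background_mask: np.ndarray,
                  contrast_threshold: float = 0.5):
    """Per-cavity recovery table.

    ``cavity_masks`` maps diameter (mm) -> boolean mask.  Returns a pandas
    DataFrame with the cavity mean, the background mean, their ratio, and
    the recovery verdict, sorted by diameter.
    """
    import pandas as pd
    if not (0 < contrast_threshold < 1):
        raise ValueError("contrast_threshold must be in (0, 1)")
    bg = roi_stats(mumap, background_mask, "background")
    rows = []
    occupied = np.zeros_like(np.asarray(background_mask, bool))
    for d in sorted(cavity_masks):
        m = np.asarray(cavity_masks[d], dtype=bool)
        if np.any(occupied & m) or np.any(m & np.asarray(background_mask, bool)):
            raise ValueError("cavity/background masks must be disjoint")
        occupied |= m
        st = roi_stats(mumap, m, f"cavity_{d:g}mm")
        ratio = st.mean / bg.mean if bg.mean > 0 else np.inf
        rows.append({"diameter_mm": float(d), "mean_mu": st.mean,
                     "background_mu": bg.mean, "contrast_ratio": ratio,
                     "recovered": bool(ratio < contrast_threshold)})
    return pd.DataFrame(rows)


def cavity_recovery(mumap: np.ndarray, cavity_masks: dict,
                    background_mask: np.ndarray,
                    contrast_threshold: float = 0.5):
    """Smallest recovered cavity diameter (mm), or ``None`` if no cavity
    meets the contrast criterion."""
    df = cavity_report(mumap, cavity_masks, background_mask, contrast_threshold)
    rec = df[df["recovered"]]
    if rec.empty:
        return None
    return float(rec["diameter_mm"].min())
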