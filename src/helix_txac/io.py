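"""NIfTI-1 volume I/O.

Volumes live on a :class:`~helix_txac.phantoms.GridSpec`; the affine is
diagonal (voxel size on the diagonal) with the translation placing voxel
(0,0,0) *center* at ``origin + voxel/2`` in scanner coordinates.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib


def save_nifti(path, values: np.ndarray, grid) -> None:
    vs = np.asarray(grid.voxel_size, dtype=float)
    origin = np.asarray(grid.origin, dtype=float)
    affine = np.diag([vs[0], vs[1], vs[2], 1.0])
    affine[:3, 3] = origin + vs / 2.0
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    img.header.set_zooms(tuple(vs))
    nib.save(img, str(path))


def load_nifti(path):
    from .phantoms import GridSpec

    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=np.float64)
    affine = img.affine
    vs = tuple(float(affine[i, i]) for i in range(3))
    origin = tuple(float(affine[i, 3] - vs[i] / 2.0) for i in range(3))
    grid = GridSpec(shape=values.shape, voxel_size=vs, origin=origin)
    return values, grid
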