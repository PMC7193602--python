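"""3D volume container with physical field-of-view metadata.

All volumes in this package share one anatomical axis convention for the
supine rat: axis 0 runs left-right, axis 1 anterior-posterior (anterior =
low index; in the supine animal the anterior lung is gravitationally
dependent), axis 2 superior-inferior.  NIfTI I/O encodes the voxel size in
the affine so volumes round-trip through standard viewers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

AXIS_LABELS = ("left-right", "anterior-posterior", "superior-inferior")


@dataclass
class VolumeImage:
    """A 3D scalar or complex image on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values; real or complex.
    fov_mm : tuple of float
        Physical field of view along each axis in millimetres.
    """

    data: np.ndarray
    fov_mm: tuple[float, float, float] = (50.0, 50.0, 50.0)
    axes: tuple[str, str, str] = field(default=AXIS_LABELS, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if np.isscalar(self.fov_mm):
            self.fov_mm = (float(self.fov_mm),) * 3
        self.fov_mm = tuple(float(f) for f in self.fov_mm)
        if any(f <= 0 for f in self.fov_mm):
            raise ValueError("fov_mm entries must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_mm(self) -> tuple[float, float, float]:
        return tuple(f / n for f, n in zip(self.fov_mm, self.data.shape))

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        """Same grid, new voxel values."""
        return VolumeImage(np.asarray(data), self.fov_mm, self.axes)

    def astype_bool(self) -> "VolumeImage":
        return self.with_data(self.data.astype(bool))

    # ------------------------------------------------------------------ I/O
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_mm) + [1.0])
        return aff

    def save_nifti(self, path) -> None:
        """Write as NIfTI-1; complex data is written as two files
        (``*_re``/``*_im`` inserted before the extension) by
        :func:`save_complex_nifti` instead."""
        if np.iscomplexobj(self.data):
            raise TypeError("complex volume: use save_complex_nifti")
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine())
        nib.save(img, str(path))

    @classmethod
    def load_nifti(cls, path) -> "VolumeImage":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(float)
        vox = img.header.get_zooms()[:3]
        fov = tuple(v * n for v, n in zip(vox, data.shape))
        return cls(data, fov)


def save_complex_nifti(vol: VolumeImage, path_re, path_im) -> None:
    vol.with_data(vol.data.real).save_nifti(path_re)
    vol.with_data(vol.data.imag).save_nifti(path_im)


def load_complex_nifti(path_re, path_im) -> VolumeImage:
    re = VolumeImage.load_nifti(path_re)
    im = VolumeImage.load_nifti(path_im)
    if re.shape != im.shape:
        raise ValueError("real/imaginary volumes have different shapes")
    return re.with_data(re.data + 1j * im.data)


def resample_to_grid(vol: VolumeImage, target: VolumeImage, order: int = 1) -> VolumeImage:
    """FOV-aware resampling of ``vol`` onto the grid of ``target``.

    Voxel centres are mapped through physical coordinates (mm), so a volume
    acquired at twice the field of view lands on the central half of the
    target grid.  Trilinear by default; constant images are value-preserving
    wherever the grids overlap.  Voxels outside the source FOV are zero.
    """
    coords = []
    for ax in range(3):
        n_t, n_s = target.shape[ax], vol.shape[ax]
        d_t, d_s = target.fov_mm[ax] / n_t, vol.fov_mm[ax] / n_s
        # physical position of target voxel centres, FOVs centred on each other
        x = (np.arange(n_t) - (n_t - 1) / 2) * d_t
        coords.append(x / d_s + (n_s - 1) / 2)
    grid = np.meshgrid(*coords, indexing="ij")
    if np.iscomplexobj(vol.data):
        out = ndimage.map_coordinates(vol.data.real, grid, order=order, cval=0.0) + 1j * ndimage.map_coordinates(vol.data.imag, grid, order=order, cval=0.0)
    else:
        out = ndimage.map_coordinates(vol.data.astype(float), grid, order=order, cval=0.0)
    return target.with_data(out)
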