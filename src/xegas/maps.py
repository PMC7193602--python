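"""Quantitative ventilation, barrier:gas and RBC:gas maps.

The map stage takes the proton anatomy, the gas-phase (ventilation) image
and the Dixon-separated barrier/RBC volumes and produces the three
quantitative maps the binning stage consumes:

* a thoracic lung mask segmented from the proton image (Otsu threshold,
  interior connected component, hole filling), refined by removing
  conducting airways and ventilation-defect voxels so only gas-exchanging
  lung is analysed;
* flip-angle and T2* signal corrections so compartment ratios reflect
  magnetization ratios;
* ventilation normalised by its top-percentile value into [0, 1];
* voxelwise barrier:gas and RBC:gas ratio maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.filters import threshold_otsu

from .params import AcqParams
from .volume import VolumeImage, resample_to_grid


class SegmentationError(RuntimeError):
    pass


class RegistrationError(RuntimeError):
    pass


@dataclass
class GasExchangeMaps:
    ventilation_norm: VolumeImage
    barrier_to_gas: VolumeImage
    rbc_to_gas: VolumeImage
    analysis_mask: VolumeImage
    thorax_mask: VolumeImage
    provenance: dict = field(default_factory=dict)


def _as_bool(mask) -> np.ndarray:
    m = mask.data if isinstance(mask, VolumeImage) else np.asarray(mask)
    return m.astype(bool)


def segment_thorax(proton: VolumeImage, mask: np.ndarray | VolumeImage | None = None) -> VolumeImage:
    """Lung mask from the proton image.

    Lungs are air-filled, hence dark on proton MRI.  Otsu splits air from
    tissue; of the sub-threshold (air) voxels, components touching the
    volume border are background, and the largest interior component is the
    lung.  Holes (vessels, noise) are filled.  An externally supplied mask
    is passed through verbatim.
    """
    if mask is not None:
        return proton.with_data(_as_bool(mask))
    data = proton.data
    if np.ptp(data) == 0:
        raise SegmentationError("constant proton image; no air-tissue contrast")
    thr = threshold_otsu(data)
    air = data < thr
    if not air.any() or air.all():
        raise SegmentationError("thresholding produced a degenerate mask")
    labels, n = ndimage.label(air)
    if n == 0:
        raise SegmentationError("no connected air regions found")
    border_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=axis)
            border_labels |= set(np.unique(face[face > 0]))
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    for lab in border_labels:
        counts[lab] = 0
    if counts.max() == 0:
        raise SegmentationError("no interior air component (lung) found")
    lung = labels == int(np.argmax(counts))
    lung = ndimage.binary_fill_holes(lung)
    return proton.with_data(lung)


def _to_sitk(vol: VolumeImage) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.astype(np.float64).T))
    img.SetSpacing(tuple(vol.voxel_mm))
    return img


def register_rigid(moving: VolumeImage, fixed: VolumeImage,
                   resample_masks: list[VolumeImage] | None = None):
    """6-parameter rigid registration of ``moving`` onto ``fixed``.

    FOV metadata drives physical-space alignment, so grids with different
    fields of view (e.g. the 2x-FOV dissolved acquisition) are handled.
    Returns ``(params, resampled, resampled_masks)`` where ``params`` is
    (rx, ry, rz, tx, ty, tz) in radians/mm.
    """
    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)
    f_phys = [s * v for s, v in zip(fixed.shape, fixed.voxel_mm)]
    m_phys = [s * v for s, v in zip(moving.shape, moving.voxel_mm)]
    if any(mp < 0.25 * fp for mp, fp in zip(m_phys, f_phys)):
        raise RegistrationError("fields of view barely overlap; cannot register")

    tx0 = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=200,
        gradientMagnitudeTolerance=1e-8)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(sitk.Euler3DTransform(tx0), inPlace=False)
    tx = reg.Execute(f_img, m_img)

    def _resample(vol: VolumeImage) -> VolumeImage:
        img = _to_sitk(vol)
        out = sitk.Resample(img, f_img, tx, sitk.sitkLinear, 0.0)
        return fixed.with_data(sitk.GetArrayFromImage(out).T)

    euler = sitk.Euler3DTransform(tx.GetNthTransform(0) if hasattr(tx, "GetNthTransform") else tx)
    params = tuple(euler.GetParameters())
    resampled = _resample(moving)
    masks_out = None
    if resample_masks is not None:
        masks_out = [m.with_data(_resample(m.with_data(m.data.astype(float))).data > 0.5)
                     for m in resample_masks]
    return params, resampled, masks_out


def refine_mask(thorax_mask, airway_mask=None, vent_defect_mask=None) -> VolumeImage:
    """Analysis mask = thorax minus conducting airways minus ventilation
    defects (set semantics: overlaps removed once)."""
    thorax = thorax_mask if isinstance(thorax_mask, VolumeImage) else VolumeImage(np.asarray(thorax_mask))
    out = _as_bool(thorax).copy()
    if airway_mask is not None:
        out &= ~_as_bool(airway_mask)
    if vent_defect_mask is not None:
        out &= ~_as_bool(vent_defect_mask)
    if not out.any():
        raise SegmentationError(
            "analysis mask empty after removing airways/defects; "
            "check segmentation inputs")
    return thorax.with_data(out)


def correct_signals(gas: VolumeImage, barrier: VolumeImage, rbc: VolumeImage,
                    acq: AcqParams) -> tuple[VolumeImage, VolumeImage, VolumeImage, dict]:
    """Divide each volume by sin(flip) * exp(-TE/T2*) of its own acquisition.

    The gas image uses the gas-excitation flip angle and gas T2*; the
    Dixon-separated volumes use the dissolved flip angle and the short
    dissolved-phase T2* (~0.5 ms).  After correction, voxelwise ratios
    reflect magnetization ratios rather than acquisition settings.
    """
    te_ms = acq.te_us * 1e-3
    if acq.t2star_gas_ms <= 0 or acq.t2star_dissolved_ms <= 0 or te_ms <= 0:
        raise ValueError("TE and T2* values must be positive")
    f_gas = np.sin(np.radians(acq.flip_gas_deg)) * np.exp(-te_ms / acq.t2star_gas_ms)
    f_dis = np.sin(np.radians(acq.flip_dissolved_deg)) * np.exp(-te_ms / acq.t2star_dissolved_ms)
    prov = {"gas_correction_divisor": float(f_gas), "dissolved_correction_divisor": float(f_dis),
            "te_ms": te_ms, "flip_gas_deg": acq.flip_gas_deg,
            "flip_dissolved_deg": acq.flip_dissolved_deg,
            "t2star_gas_ms": acq.t2star_gas_ms, "t2star_dissolved_ms": acq.t2star_dissolved_ms}
    return (gas.with_data(gas.data / f_gas),
            barrier.with_data(barrier.data / f_dis),
            rbc.with_data(rbc.data / f_dis), prov)


def normalize_ventilation(vent: VolumeImage, mask, percentile: float = 99.0) -> VolumeImage:
    """Rescale ventilation into [0, 1] by its masked top-percentile value.

    Dividing by a high percentile rather than the maximum compensates for
    the long high-intensity tail; supra-percentile voxels are clipped to 1.
    Scale-invariant: multiplying the input by any c > 0 leaves the output
    unchanged.
    """
    m = _as_bool(mask)
    if not m.any():
        raise ValueError("empty mask")
    p = float(np.percentile(vent.data[m], percentile))
    if p <= 0:
        raise ValueError(f"non-positive {percentile}th percentile; cannot normalize")
    return vent.with_data(np.clip(vent.data / p, 0.0, 1.0))


def ratio_maps(barrier: VolumeImage, rbc: VolumeImage, gas: VolumeImage,
               analysis_mask) -> tuple[VolumeImage, VolumeImage, int]:
    """Voxelwise barrier:gas and RBC:gas inside the analysis mask.

    Voxels with non-positive gas signal inside the mask are excluded (NaN)
    and counted; everything outside the mask is NaN.
    """
    m = _as_bool(analysis_mask)
    bad = m & (gas.data <= 0)
    valid = m & ~bad
    b2g = np.full(gas.shape, np.nan)
    r2g = np.full(gas.shape, np.nan)
    b2g[valid] = barrier.data[valid] / gas.data[valid]
    r2g[valid] = rbc.data[valid] / gas.data[valid]
    return gas.with_data(b2g), gas.with_data(r2g), int(bad.sum())
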