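"""1-point Dixon separation of the dissolved-phase image.

At the echo time TE90 the RBC and barrier magnetizations are 90 degrees out
of phase, so one global phase rotation places barrier signal on the real
channel and RBC signal on the imaginary channel.  The rotation angle is
fixed by requiring the masked channel-sum ratio to equal the
spectroscopically measured RBC:barrier; with M = sum(dissolved) over the
mask written as |M| e^{i phiM} and psi = arctan(target ratio), the
closed-form answer is  phase = psi - phiM,  which makes
sum(imag)/sum(real) = tan(psi) = target with both sums positive (resolving
the pi ambiguity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .volume import VolumeImage


class DixonError(RuntimeError):
    pass


@dataclass
class DixonResult:
    phase_deg: float
    barrier_img: VolumeImage
    rbc_img: VolumeImage
    achieved_ratio: float
    negative_voxels: int  # noise-driven negative values retained, but counted


def dixon_phase(dissolved: VolumeImage, mask: np.ndarray | VolumeImage,
                target_ratio: float, noise_floor_frac: float = 1e-6) -> float:
    """Global phase (degrees) aligning the masked sums with the target
    RBC:barrier ratio.  Fails if the coherent masked sum is below
    ``noise_floor_frac`` of the total masked magnitude (nothing to phase)."""
    if not np.isfinite(target_ratio) or target_ratio <= 0:
        raise DixonError("target ratio must be a positive finite number")
    m = mask.data if isinstance(mask, VolumeImage) else np.asarray(mask)
    m = m.astype(bool)
    if not m.any():
        raise DixonError("empty mask")
    vals = dissolved.data[m]
    M = vals.sum()
    if abs(M) == 0 or abs(M) < noise_floor_frac * np.abs(vals).sum():
        raise DixonError("masked sum below noise floor; cannot phase")
    psi = math.atan(target_ratio)
    phase = math.degrees(psi - np.angle(M))
    # verification pass
    rot = vals * np.exp(1j * math.radians(phase))
    achieved = rot.imag.sum() / rot.real.sum()
    if not math.isclose(achieved, target_ratio, rel_tol=1e-6):
        raise DixonError(f"phasing failed to verify: achieved {achieved!r}")
    return (phase + 180.0) % 360.0 - 180.0


def dixon_split(dissolved: VolumeImage, phase_deg: float,
                mask: np.ndarray | VolumeImage | None = None) -> tuple[VolumeImage, VolumeImage, int]:
    """Rotate by ``phase_deg`` and split into (barrier, rbc) channels.

    Returns the two real-valued volumes and the count of negative voxels
    (inside the mask if given) — negatives are retained as noise, only
    flagged."""
    rot = dissolved.data * np.exp(1j * math.radians(phase_deg))
    barrier = dissolved.with_data(rot.real)
    rbc = dissolved.with_data(rot.imag)
    if mask is not None:
        m = mask.data if isinstance(mask, VolumeImage) else np.asarray(mask)
        m = m.astype(bool)
        neg = int((barrier.data[m] < 0).sum() + (rbc.data[m] < 0).sum())
    else:
        neg = int((barrier.data < 0).sum() + (rbc.data < 0).sum())
    return barrier, rbc, neg


def separate(dissolved: VolumeImage, mask, target_ratio: float) -> DixonResult:
    """Convenience wrapper: phase, split, and report the achieved ratio."""
    phase = dixon_phase(dissolved, mask, target_ratio)
    barrier, rbc, neg = dixon_split(dissolved, phase, mask)
    m = mask.data if isinstance(mask, VolumeImage) else np.asarray(mask)
    m = m.astype(bool)
    achieved = float(rbc.data[m].sum() / barrier.data[m].sum())
    return DixonResult(phase_deg=phase, barrier_img=barrier, rbc_img=rbc,
                       achieved_ratio=achieved, negative_voxels=neg)
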