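"""End-to-end subject and cohort processing.

Wires the stages together in the order the analysis runs in vivo:

1. spectroscopy fit -> steady-state RBC:barrier ratio;
2. proton segmentation -> thoracic lung mask;
3. Dixon separation of the complex dissolved volume using the
   spectroscopic ratio;
4. flip-angle/T2* correction, ventilation normalisation;
5. ventilation binning -> defect mask -> analysis-mask refinement;
6. ratio maps and barrier/RBC binning -> per-animal metrics.

Reference distributions are built from a healthy cohort in two passes:
ventilation first (no defect mask exists yet), then the ratio maps with
ventilation defects excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import binning, dixon, maps, spectro
from .phantom import SubjectData
from .volume import VolumeImage, resample_to_grid


@dataclass
class References:
    ventilation: binning.ReferenceDistribution
    barrier: binning.ReferenceDistribution | None = None
    rbc: binning.ReferenceDistribution | None = None


@dataclass
class SubjectResult:
    fit: spectro.SpectrumFitResult
    dixon: dixon.DixonResult
    thorax_mask: VolumeImage
    analysis_mask: VolumeImage | None
    ventilation_norm: VolumeImage
    barrier_to_gas: VolumeImage | None
    rbc_to_gas: VolumeImage | None
    metrics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _prepare(data: SubjectData, use_truth_masks: bool):
    """Masks, spectral fit, Dixon split and corrected volumes for a subject."""
    if use_truth_masks and data.truth is not None:
        thorax = data.truth.thorax_mask.astype_bool()
        airway = data.truth.airway_mask
    else:
        thorax = maps.segment_thorax(data.proton)
        airway = None

    fit = spectro.fit_spectrum(data.fid, data.acq)

    dis = data.dissolved
    if dis.shape != data.ventilation.shape or dis.fov_mm != data.ventilation.fov_mm:
        dis = resample_to_grid(dis, data.ventilation)
    dx = dixon.separate(dis, thorax, fit.rbc_barrier)

    gas_c, barrier_c, rbc_c, prov = maps.correct_signals(
        data.ventilation, dx.barrier_img, dx.rbc_img, data.acq)
    vent_norm = maps.normalize_ventilation(data.ventilation, thorax)
    return thorax, airway, fit, dx, gas_c, barrier_c, rbc_c, vent_norm, prov


def process_subject(data: SubjectData, references: References | None = None,
                    use_truth_masks: bool = True) -> SubjectResult:
    """Run the full pipeline on one subject.

    Without references, produces the spectroscopic fit, Dixon separation
    and the normalised/corrected volumes; with references, additionally
    bins the three maps and computes VDP, low-ventilation %, barrier_high %
    and RBC_defect %.
    """
    thorax, airway, fit, dx, gas_c, barrier_c, rbc_c, vent_norm, prov = _prepare(
        data, use_truth_masks)

    result = SubjectResult(
        fit=fit, dixon=dx, thorax_mask=thorax, analysis_mask=None,
        ventilation_norm=vent_norm, barrier_to_gas=None, rbc_to_gas=None,
        provenance={"corrections": prov,
                    "ratio_maps_use": "corrected un-normalized gas image"})
    if references is None:
        return result

    binned = {}
    vent_binned = binning.bin_map(vent_norm, thorax, references.ventilation)
    binned["ventilation"] = vent_binned
    defect_mask = thorax.with_data(vent_binned.labels.data == 1)
    analysis = maps.refine_mask(thorax, airway, defect_mask)
    b2g, r2g, n_bad = maps.ratio_maps(barrier_c, rbc_c, gas_c, analysis)
    # non-positive Dixon-channel voxels (noise) cannot enter the Box-Cox bins
    valid = analysis.with_data(analysis.data & (b2g.data > 0) & (r2g.data > 0)
                               & np.isfinite(b2g.data) & np.isfinite(r2g.data))
    if references.barrier is not None:
        binned["barrier"] = binning.bin_map(b2g, valid, references.barrier)
    if references.rbc is not None:
        binned["rbc"] = binning.bin_map(r2g, valid, references.rbc)
    result.analysis_mask = analysis
    result.barrier_to_gas = b2g
    result.rbc_to_gas = r2g
    result.metrics = binning.metrics(binned)
    result.provenance["n_gas_nonpositive"] = n_bad
    result.binned = binned
    return result


def build_references(healthy: list[SubjectData],
                     use_truth_masks: bool = True) -> References:
    """Two-pass reference construction from a healthy cohort.

    Pass 1 pools normalised ventilation over the thorax masks and fits the
    ventilation reference.  Pass 2 removes each animal's ventilation-defect
    bin (and airways), recomputes the ratio maps on the refined masks, and
    fits the barrier:gas and RBC:gas references.
    """
    prepped = [_prepare(d, use_truth_masks) for d in healthy]

    vent_pool = [(vent_norm, thorax)
                 for thorax, _aw, _f, _dx, _g, _b, _r, vent_norm, _p in prepped]
    vent_ref = binning.build_reference(vent_pool, "ventilation")

    barrier_pool, rbc_pool = [], []
    for thorax, airway, _fit, _dx, gas_c, barrier_c, rbc_c, vent_norm, _p in prepped:
        vent_binned = binning.bin_map(vent_norm, thorax, vent_ref)
        defect = thorax.with_data(vent_binned.labels.data == 1)
        analysis = maps.refine_mask(thorax, airway, defect)
        b2g, r2g, _n = maps.ratio_maps(barrier_c, rbc_c, gas_c, analysis)
        valid = analysis.data & (b2g.data > 0) & (r2g.data > 0)
        barrier_pool.append((b2g, valid))
        rbc_pool.append((r2g, valid))
    barrier_ref = binning.build_reference(barrier_pool, "barrier")
    rbc_ref = binning.build_reference(rbc_pool, "rbc")
    return References(ventilation=vent_ref, barrier=barrier_ref, rbc=rbc_ref)
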