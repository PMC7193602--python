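"""Masking, registration, signal corrections, normalisation, ratio maps."""

import numpy as np
import pytest

from xegas.params import AcqParams
from xegas.maps import (
    SegmentationError,
    correct_signals,
    normalize_ventilation,
    ratio_maps,
    refine_mask,
    register_rigid,
    segment_thorax,
)
from xegas.phantom import Lesion, PhantomConfig, make_phantom
from xegas.volume import VolumeImage


def _dice(a, b):
    a, b = a.astype(bool), b.astype(bool)
    return 2 * (a & b).sum() / (a.sum() + b.sum())


class TestSegmentThorax:
    def test_phantom_dice(self, healthy_cohort):
        sub = healthy_cohort[0]
        seg = segment_thorax(sub.proton)
        assert _dice(seg.data, sub.truth.thorax_mask.data) >= 0.95

    def test_constant_image_rejected(self):
        with pytest.raises(SegmentationError):
            segment_thorax(VolumeImage(np.ones((32, 32, 32))))

    def test_external_mask_passthrough(self):
        proton = VolumeImage(np.zeros((8, 8, 8)))
        mask = np.zeros((8, 8, 8), bool)
        mask[2:5, 2:5, 2:5] = True
        out = segment_thorax(proton, mask=mask)
        np.testing.assert_array_equal(out.data, mask)


class TestRegisterRigid:
    def test_identity_for_identical_volumes(self, healthy_cohort):
        vol = healthy_cohort[0].proton
        params, resampled, _ = register_rigid(vol, vol)
        trans_mm = params[3:]
        vox = vol.voxel_mm[0]
        assert all(abs(t) < 0.1 * vox for t in trans_mm)

    def test_translation_recovered(self, healthy_cohort):
        vol = healthy_cohort[0].proton
        shifted = vol.with_data(np.roll(vol.data, 3, axis=0))
        params, resampled, _ = register_rigid(shifted, vol)
        vox = vol.voxel_mm[0]
        # the 3-voxel axis-0 shift must be undone to within half a voxel
        assert params[3] == pytest.approx(3 * vox, abs=0.5 * vox)
        assert abs(params[4]) < 0.5 * vox and abs(params[5]) < 0.5 * vox


class TestRefineMask:
    def test_no_airways_no_defects_is_identity(self):
        thorax = np.zeros((10, 10, 10), bool)
        thorax[2:8, 2:8, 2:8] = True
        out = refine_mask(VolumeImage(thorax))
        np.testing.assert_array_equal(out.data, thorax)

    def test_defect_fraction_removed(self):
        thorax = np.zeros((10, 10, 10), bool)
        thorax[2:8, 2:8, 2:8] = True
        defect = np.zeros_like(thorax)
        defect[2:8, 2:8, 2:4] = True  # a third of the cube
        out = refine_mask(VolumeImage(thorax), vent_defect_mask=defect)
        assert out.data.sum() == thorax.sum() - (thorax & defect).sum()

    def test_overlapping_masks_removed_once(self):
        thorax = np.zeros((8, 8, 8), bool)
        thorax[1:7, 1:7, 1:7] = True
        airway = np.zeros_like(thorax); airway[3, 3, 1:7] = True
        defect = airway.copy()  # same voxels
        out = refine_mask(VolumeImage(thorax), airway, defect)
        assert out.data.sum() == thorax.sum() - airway.sum()

    def test_empty_result_fails(self):
        thorax = np.zeros((8, 8, 8), bool)
        thorax[2:4, 2:4, 2:4] = True
        with pytest.raises(SegmentationError):
            refine_mask(VolumeImage(thorax), vent_defect_mask=thorax)


class TestCorrectSignals:
    def _vols(self, value=1.0):
        v = VolumeImage(np.full((4, 4, 4), value))
        return v, v, v

    def test_equal_settings_leave_ratios_unchanged(self):
        acq = AcqParams(flip_gas_deg=20, flip_dissolved_deg=20,
                        t2star_gas_ms=0.5, t2star_dissolved_ms=0.5)
        gas, barrier, rbc = self._vols()
        g, b, r, _ = correct_signals(gas, barrier, rbc, acq)
        np.testing.assert_allclose(b.data / g.data, 1.0, rtol=1e-12)

    def test_flip_angle_ratio_scaling(self):
        """Dissolved/gas flips of 20/15 degrees scale the dissolved:gas
        ratio by sin(15)/sin(20) = 0.7568 (T2* terms matched out)."""
        acq = AcqParams(flip_gas_deg=15, flip_dissolved_deg=20,
                        t2star_gas_ms=1.0, t2star_dissolved_ms=1.0)
        gas, barrier, _ = self._vols()
        g, b, _r, prov = correct_signals(gas, barrier, barrier, acq)
        assert (b.data / g.data)[0, 0, 0] == pytest.approx(0.7568, abs=1e-4)

    def test_t2star_correction_factor(self):
        """TE 248 us against the 0.5 ms dissolved T2* multiplies the
        dissolved signal by exp(0.248/0.5) = 1.642."""
        acq = AcqParams(te_us=248.0, t2star_dissolved_ms=0.5)
        _, barrier, _ = self._vols()
        _g, b, _r, prov = correct_signals(barrier, barrier, barrier, acq)
        divisor = prov["dissolved_correction_divisor"]
        expected = np.sin(np.radians(20.0)) / np.exp(0.248 / 0.5)
        assert divisor == pytest.approx(expected, rel=1e-9)
        assert np.exp(0.248 / 0.5) == pytest.approx(1.642, abs=1e-3)

    def test_provenance_logged(self, acq):
        gas, barrier, rbc = self._vols()
        *_, prov = correct_signals(gas, barrier, rbc, acq)
        assert {"gas_correction_divisor", "dissolved_correction_divisor"} <= prov.keys()


class TestNormalizeVentilation:
    def test_constant_image_becomes_ones(self):
        vent = VolumeImage(np.full((8, 8, 8), 5.0))
        mask = np.ones((8, 8, 8), bool)
        np.testing.assert_allclose(normalize_ventilation(vent, mask).data, 1.0)

    def test_outlier_tail_clipped(self, rng):
        """A hot tail (just over 1% of voxels at 10, the rest at 1): the
        99th-percentile scale is the tail value, so the body lands near 0.1
        and the outliers clip to 1."""
        vals = np.ones(64 * 64 * 64)
        hot = rng.choice(vals.size, int(vals.size * 0.012), replace=False)
        vals[hot] = 10.0
        vent = VolumeImage(vals.reshape(64, 64, 64))
        mask = np.ones(vent.shape, bool)
        out = normalize_ventilation(vent, mask)
        body = out.data[out.data < 0.5]
        assert body.mean() == pytest.approx(0.1, rel=0.05)
        assert out.data.max() == 1.0

    def test_scale_invariance(self, rng):
        vent = VolumeImage(rng.random((16, 16, 16)) + 0.1)
        mask = np.ones(vent.shape, bool)
        a = normalize_ventilation(vent, mask).data
        b = normalize_ventilation(vent.with_data(7.3 * vent.data), mask).data
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_zero_percentile_rejected(self):
        vent = VolumeImage(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError):
            normalize_ventilation(vent, np.ones((8, 8, 8), bool))


class TestRatioMaps:
    def test_uniform_phantom_constant_map(self):
        cfg = PhantomConfig(vent_cv=0, barrier_cv=0, rbc_cv=0, barrier_to_gas=0.01)
        truth = make_phantom(cfg)
        mask = truth.thorax_mask.data.astype(bool) & ~truth.airway_mask.data.astype(bool)
        b2g, r2g, n_bad = ratio_maps(truth.barrier, truth.rbc, truth.ventilation,
                                     mask)
        assert n_bad == 0
        np.testing.assert_allclose(b2g.data[mask], 0.01, rtol=1e-9)

    def test_lesion_multiplier_visible_in_map(self):
        cfg = PhantomConfig(seed=11, vent_cv=0, barrier_cv=0, rbc_cv=0,
                            lesions=[Lesion("barrier_high", "peripheral", 0.1, 2.0)])
        truth = make_phantom(cfg)
        mask = truth.thorax_mask.data.astype(bool) & ~truth.airway_mask.data.astype(bool)
        b2g, _, _ = ratio_maps(truth.barrier, truth.rbc, truth.ventilation, mask)
        lesion = truth.lesion_masks[0] & mask
        background = mask & ~lesion
        ratio = np.median(b2g.data[lesion]) / np.median(b2g.data[background])
        assert ratio == pytest.approx(2.0, rel=1e-6)

    def test_common_scale_leaves_maps_unchanged(self, rng):
        shape = (12, 12, 12)
        gas = VolumeImage(rng.random(shape) + 0.5)
        barrier = VolumeImage(rng.random(shape))
        rbc = VolumeImage(rng.random(shape))
        mask = np.ones(shape, bool)
        a = ratio_maps(barrier, rbc, gas, mask)[0].data
        c = 4.2
        b = ratio_maps(barrier.with_data(c * barrier.data),
                       rbc.with_data(c * rbc.data),
                       gas.with_data(c * gas.data), mask)[0].data
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_nonpositive_gas_excluded_and_counted(self):
        shape = (6, 6, 6)
        gas = np.ones(shape); gas[0, 0, 0] = 0.0
        mask = np.ones(shape, bool)
        b2g, _, n_bad = ratio_maps(VolumeImage(np.ones(shape)),
                                   VolumeImage(np.ones(shape)),
                                   VolumeImage(gas), mask)
        assert n_bad == 1
        assert np.isnan(b2g.data[0, 0, 0])
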