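import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import full_roiset, make_stack
from lipidquant.errors import AlignmentError, SpectralDivisionError, ValidationError
from lipidquant.phantom import ROISet, human_preset, generate_stack
from lipidquant.ratio_spectra import (
    group_spectrum,
    ratio_spectrum,
    roi_mean,
    value_at,
)


def brute_force_ratio(stack, roi_mask, bgr_mask):
    """Independent per-pixel loop oracle for the ratio spectrum."""
    n_wl = stack.pixels.shape[2]
    raw = np.empty(n_wl)
    for k in range(n_wl):
        roi_sum = roi_n = bgr_sum = bgr_n = 0.0
        for i in range(stack.pixels.shape[0]):
            for j in range(stack.pixels.shape[1]):
                v = stack.pixels[i, j, k]
                if roi_mask[i, j]:
                    roi_sum += v
                    roi_n += 1
                if bgr_mask[i, j]:
                    bgr_sum += v
                    bgr_n += 1
        raw[k] = (roi_sum / roi_n) / (bgr_sum / bgr_n)
    return raw, raw / raw.max()


def toy_roiset(shape, roi_rows):
    roi = np.zeros(shape, dtype=bool)
    roi[roi_rows] = True
    bgr = np.ones(shape, dtype=bool)
    return ROISet(masks={"liver": roi, "BGR": bgr}, skin_row=0)


class TestRoiMean:
    def test_constant_checkerboard_and_arithmetic(self):
        stack = make_stack(np.full((4, 4, 2), 3.0))
        mask = np.ones((4, 4), dtype=bool)
        assert roi_mean(stack, mask, 700) == 3.0

        checker = np.indices((4, 4)).sum(axis=0) % 2 * 2.0
        stack = make_stack(np.dstack([checker, checker]))
        assert roi_mean(stack, mask, 700) == 1.0

        px = np.zeros((1, 3, 2))
        px[0, :, 0] = [1, 2, 6]
        stack = make_stack(px)
        assert roi_mean(stack, np.ones((1, 3), bool), 700) == 3.0

    def test_empty_mask_rejected(self):
        stack = make_stack(np.ones((4, 4, 2)))
        with pytest.raises(ValidationError):
            roi_mean(stack, np.zeros((4, 4), bool), 700)


class TestRatioSpectrum:
    def test_roi_equal_bgr_gives_unity(self):
        stack = make_stack(np.random.default_rng(0).uniform(1, 2, (6, 6, 4)))
        rois = toy_roiset((6, 6), slice(None))
        spec = ratio_spectrum(stack, rois, "liver")
        np.testing.assert_allclose(spec.raw_ratio, 1.0, rtol=1e-15)
        np.testing.assert_allclose(spec.normalized_ratio, 1.0, rtol=1e-15)

    def test_two_wavelength_arithmetic(self):
        px = np.zeros((2, 1, 2))
        px[0, 0] = [2, 4]   # ROI row
        px[1, 0] = [6, 4]   # rest of BGR
        stack = make_stack(px)
        rois = toy_roiset((2, 1), 0)
        spec = ratio_spectrum(stack, rois, "liver")
        np.testing.assert_allclose(spec.raw_ratio, [0.5, 1.0])
        np.testing.assert_allclose(spec.normalized_ratio, [0.5, 1.0])

    def test_normalized_max_is_exactly_one(self):
        rng = np.random.default_rng(7)
        stack = make_stack(rng.uniform(0.1, 5, (8, 8, 6)))
        rois = toy_roiset((8, 8), slice(0, 3))
        spec = ratio_spectrum(stack, rois, "liver")
        assert spec.normalized_ratio.max() == 1.0

    def test_zero_background_reported_per_wavelength(self):
        px = np.ones((4, 4, 3))
        px[:, :, 1] = 0.0
        stack = make_stack(px)
        rois = toy_roiset((4, 4), slice(0, 2))
        with pytest.raises(SpectralDivisionError) as err:
            ratio_spectrum(stack, rois, "liver")
        assert err.value.wavelengths_nm == [710.0]

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(42)
        for _ in range(3):
            stack = make_stack(rng.uniform(0.01, 3, (16, 16, 5)))
            roi = rng.uniform(size=(16, 16)) < 0.3
            roi[0, 0] = True  # ensure non-empty
            rois = ROISet(
                masks={"liver": roi, "BGR": np.ones((16, 16), bool)}, skin_row=0
            )
            expected_raw, expected_norm = brute_force_ratio(
                stack, roi, rois.mask("BGR")
            )
            spec = ratio_spectrum(stack, rois, "liver")
            np.testing.assert_allclose(spec.raw_ratio, expected_raw, rtol=1e-12)
            np.testing.assert_allclose(
                spec.normalized_ratio, expected_norm, rtol=1e-12
            )

    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_global_scale_invariance(self, scale):
        rng = np.random.default_rng(1)
        px = rng.uniform(0.1, 2, (6, 6, 4))
        rois = toy_roiset((6, 6), slice(0, 2))
        base = ratio_spectrum(make_stack(px), rois, "liver")
        scaled = ratio_spectrum(make_stack(px * scale), rois, "liver")
        np.testing.assert_allclose(scaled.raw_ratio, base.raw_ratio, rtol=1e-12)
        np.testing.assert_allclose(
            scaled.normalized_ratio, base.normalized_ratio, rtol=1e-12
        )

    def test_single_wavelength_scale_cancels(self):
        # scaling one plane multiplies ROI and BGR means alike: the raw ratio
        # at that wavelength is unchanged (the laser-energy compensation)
        rng = np.random.default_rng(2)
        px = rng.uniform(0.1, 2, (6, 6, 4))
        rois = toy_roiset((6, 6), slice(0, 2))
        base = ratio_spectrum(make_stack(px), rois, "liver")
        px2 = px.copy()
        px2[:, :, 2] *= 7.5
        mod = ratio_spectrum(make_stack(px2), rois, "liver")
        np.testing.assert_allclose(mod.raw_ratio[2], base.raw_ratio[2], rtol=1e-12)

    def test_value_at_contract(self):
        px = np.ones((2, 2, 3))
        spec = ratio_spectrum(make_stack(px), toy_roiset((2, 2), 0), "liver")
        assert value_at(spec, 710) == 1.0
        with pytest.raises(ValidationError):
            value_at(spec, 715)

    def test_lipid_rich_liver_scores_higher_at_930(self):
        healthy = replace(
            human_preset("healthy", seed=0, reduced=True),
            noise_sd=0.0, pulse_jitter_cv=0.0,
        )
        steatosis = replace(
            human_preset("steatosis", seed=0, reduced=True),
            noise_sd=0.0, pulse_jitter_cv=0.0,
        )
        vals = {}
        for name, spec in (("healthy", healthy), ("steatosis", steatosis)):
            stack, rois = generate_stack(spec)
            rs = ratio_spectrum(stack, rois, "liver")
            vals[name] = rs.value_at(930)
            if name == "healthy":
                # healthy liver peaks in the hemoglobin band, not at 930
                assert rs.value_at(930) < 1.0
                peak_wl = rs.wavelengths_nm[np.argmax(rs.normalized_ratio)]
                assert peak_wl <= 900
        assert vals["steatosis"] > vals["healthy"]


class TestGroupSpectrum:
    def _spectra(self, values_at_wl):
        out = []
        for v in values_at_wl:
            px = np.ones((2, 2, 2))
            px[0, :, 1] = v  # ROI row, second wavelength
            px[1, :, 1] = 2 - v
            stack = make_stack(px)
            out.append(ratio_spectrum(stack, toy_roiset((2, 2), 0), "liver"))
        return out

    def test_identical_spectra_have_zero_sem(self):
        gs = group_spectrum(self._spectra([0.5, 0.5]))
        np.testing.assert_array_equal(gs.sem, 0.0)

    def test_mean_and_sem_arithmetic(self):
        # normalized values {0.2, 0.4} -> mean 0.3, SEM sd/sqrt(2) = 0.1
        gs = group_spectrum(self._spectra([0.2, 0.4]))
        np.testing.assert_allclose(gs.mean[1], 0.3)
        np.testing.assert_allclose(gs.sem[1], 0.1)
        assert gs.n == 2

    def test_mixed_grids_rejected(self):
        a = self._spectra([0.5])[0]
        px = np.ones((2, 2, 3))
        b = ratio_spectrum(make_stack(px), toy_roiset((2, 2), 0), "liver")
        with pytest.raises(AlignmentError):
            group_spectrum([a, b])

    def test_group_mean_close_to_noise_free_subject(self, human_cohort):
        specs = [
            ratio_spectrum(s, r, "liver") for s, r in human_cohort["healthy"]
        ]
        gs = group_spectrum(specs, cohort="healthy")
        noise_free = replace(
            human_preset("healthy", seed=0, reduced=True),
            noise_sd=0.0, pulse_jitter_cv=0.0,
        )
        stack, rois = generate_stack(noise_free)
        ref = ratio_spectrum(stack, rois, "liver")
        # sampling error: subjects carry +/-15% composition/thickness jitter
        assert np.max(np.abs(gs.mean - ref.normalized_ratio)) < 0.1
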