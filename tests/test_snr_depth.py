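import numpy as np
import pytest
from dataclasses import replace

from conftest import make_stack
from lipidquant.errors import DegenerateDataError, ValidationError
from lipidquant.phantom import (
    ROISet,
    generate_raw_noise_stack,
    generate_stack,
    human_preset,
)
from lipidquant.snr_depth import (
    estimate_noise,
    partition_liver,
    percent_decrease,
    snr_profile,
)
from lipidquant.snr_depth import SNRProfile, SNRSegment


def liver_roiset(shape, rows, skin_row=0):
    liver = np.zeros(shape, dtype=bool)
    liver[rows] = True
    bgr = np.zeros(shape, dtype=bool)
    bgr[skin_row:] = True
    return ROISet(masks={"liver": liver, "BGR": bgr}, skin_row=skin_row)


def profile_from(snrs, depths, noise=1.0, sat=None):
    segs = []
    if sat is not None:
        segs.append(SNRSegment("SAT", sat[1], sat[0], 20 * np.log10(sat[0]), 10))
    segs += [
        SNRSegment(f"liver-{i}", d, s, 20 * np.log10(s) if s > 0 else -np.inf, 10)
        for i, (s, d) in enumerate(zip(snrs, depths))
    ]
    return SNRProfile("S0", 930.0, noise, tuple(segs))


class TestEstimateNoise:
    def test_constant_standoff_gives_zero(self):
        img = np.zeros((20, 10))
        assert estimate_noise(img, skin_row=10) == 0.0

    def test_alternating_unit_noise(self):
        img = np.empty((10, 20))
        img[:, ::2], img[:, 1::2] = 1.0, -1.0
        assert estimate_noise(img, skin_row=10) == 1.0

    def test_too_few_standoff_pixels(self):
        with pytest.raises(ValidationError):
            estimate_noise(np.zeros((20, 10)), skin_row=4)

    def test_recovers_generator_noise_without_truncation(self):
        hits = 0
        for seed in range(100):
            spec = replace(
                human_preset("healthy", seed=seed, reduced=True), noise_sd=0.05
            )
            raw = generate_raw_noise_stack(spec)
            idx = spec.grid.index_of(930)
            est = estimate_noise(raw[:, :, idx], spec.skin_row)
            hits += abs(est - 0.05) / 0.05 < 0.10
        assert hits >= 95


class TestPartitionLiver:
    def test_three_slab_tiling(self):
        # liver spanning depths 2.25-3.65 cm at 0.01 cm pitch, 0.5 cm slabs
        shape = (380, 4)
        rois = liver_roiset(shape, slice(225, 366), skin_row=0)
        slabs = partition_liver(rois, 0.01, 0.5)
        assert len(slabs) == 3
        assert [s.top_depth_cm for s in slabs] == pytest.approx([2.25, 2.75, 3.25])
        assert slabs[-1].bottom_depth_cm == pytest.approx(3.65)

    def test_single_slab(self):
        rois = liver_roiset((100, 4), slice(10, 60), skin_row=0)
        slabs = partition_liver(rois, 0.01, 0.5)
        assert len(slabs) == 1

    def test_slabs_partition_liver_mask_exactly(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            mask = rng.uniform(size=(120, 8)) < 0.25
            mask[rng.integers(0, 120), 0] = True
            rois = ROISet(
                masks={"liver": mask, "BGR": np.ones((120, 8), bool)}, skin_row=0
            )
            slabs = partition_liver(rois, 0.01, 0.3)
            union = np.zeros_like(mask)
            total = 0
            for s in slabs:
                assert not (union & s.mask).any()  # pairwise disjoint
                union |= s.mask
                total += s.mask.sum()
            np.testing.assert_array_equal(union, mask)
            assert total == mask.sum()

    def test_empty_liver_rejected(self):
        rois = ROISet(
            masks={"liver": np.zeros((10, 4), bool), "BGR": np.ones((10, 4), bool)},
            skin_row=0,
        )
        with pytest.raises(ValidationError):
            partition_liver(rois, 0.01, 0.5)


class TestSnrProfile:
    def _stack_with_noise(self, slab_value, noise_amp=1.0):
        # standoff rows alternate +/- noise_amp -> sd exactly noise_amp
        px = np.zeros((120, 20, 2))
        px[:60, ::2, :], px[:60, 1::2, :] = noise_amp, 0.0
        px[60:, :, :] = slab_value
        return make_stack(px, skin_row=60)

    def test_forced_snr_value(self):
        # standoff alternates 0/1 -> noise sd 0.5; slab mean 4.97*0.5 -> SNR 4.97
        stack = self._stack_with_noise(slab_value=4.97 * 0.5, noise_amp=1.0)
        rois = liver_roiset((120, 20), slice(60, 120), skin_row=60)
        prof = snr_profile(stack, rois, 700, slab_thickness_cm=1.0)
        seg = prof.liver_segments()[0]
        assert seg.snr_linear == pytest.approx(4.97, rel=1e-12)
        assert seg.snr_db == pytest.approx(20 * np.log10(4.97), rel=1e-12)

    def test_zero_slab_gives_zero_snr(self):
        stack = self._stack_with_noise(slab_value=0.0)
        rois = liver_roiset((120, 20), slice(60, 120), skin_row=60)
        prof = snr_profile(stack, rois, 700, slab_thickness_cm=1.0)
        assert prof.liver_segments()[0].snr_linear == 0.0

    def test_zero_noise_rejected(self):
        px = np.ones((120, 20, 2))
        px[:60] = 0.0
        stack = make_stack(px, skin_row=60)
        rois = liver_roiset((120, 20), slice(60, 120), skin_row=60)
        with pytest.raises(DegenerateDataError):
            snr_profile(stack, rois, 700)

    def test_db_linear_roundtrip(self, human_cohort):
        stack, rois = human_cohort["healthy"][0]
        prof = snr_profile(stack, rois, 930)
        for seg in prof.segments:
            assert 10 ** (seg.snr_db / 20) == pytest.approx(
                seg.snr_linear, rel=1e-12
            )

    def test_monotone_decrease_on_attenuation_phantom(self):
        spec = replace(
            human_preset("healthy", seed=0),
            noise_sd=0.0, pulse_jitter_cv=0.0,
        )
        stack, rois = generate_stack(spec)
        # noise-free standoff would break SNR; inject known standoff noise
        px = stack.pixels.copy()
        rng = np.random.default_rng(0)
        px[: stack.skin_row] = np.abs(
            rng.normal(0, 1e-4, px[: stack.skin_row].shape)
        )
        stack2 = make_stack(
            px, grid=stack.grid, skin_row=stack.skin_row
        )
        prof = snr_profile(stack2, rois, 930)
        snrs = [s.snr_linear for s in prof.liver_segments()]
        assert all(a > b for a, b in zip(snrs, snrs[1:]))


class TestPercentDecrease:
    def test_halving_is_fifty_percent(self):
        prof = profile_from([10, 5], [3.0, 3.5])
        out = percent_decrease(prof)
        assert out["step_decreases_pct"] == [pytest.approx(50.0)]

    def test_constant_snr_is_zero_decrease(self):
        prof = profile_from([4, 4, 4], [2.0, 2.5, 3.0])
        out = percent_decrease(prof)
        assert out["mean_step_decrease_pct"] == pytest.approx(0.0)
        assert out["mean_per_cm_decrease_pct"] == pytest.approx(0.0)

    def test_exponential_per_cm_closed_form(self):
        depths = np.array([2.0, 2.5, 3.0, 3.5])
        snrs = 100 * np.exp(-1.5 * depths)
        out = percent_decrease(profile_from(list(snrs), list(depths)))
        assert out["mean_per_cm_decrease_pct"] == pytest.approx(
            100 * (1 - np.exp(-1.5)), rel=1e-9
        )

    def test_zero_snr_step_flagged(self):
        prof = profile_from([10, 0, 0], [2.0, 2.5, 3.0])
        out = percent_decrease(prof)
        assert out["undefined_steps"] == [1]
        assert out["step_decreases_pct"] == [pytest.approx(100.0)]

    def test_sat_drop_reported(self):
        prof = profile_from([10, 5], [2.5, 3.0], sat=(50.0, 0.4))
        out = percent_decrease(prof)
        assert out["sat_to_first_liver_decrease_pct"] == pytest.approx(80.0)
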