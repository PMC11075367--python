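"""SUV conversion, clip/scale, and Nyul histogram standardization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petac.preprocess import (
    AcquisitionMeta,
    NyulModel,
    clip_scale,
    image_landmarks,
    nyul_apply,
    nyul_fit,
    preprocess_pair,
    suv_convert,
    unscale,
)
from petac.volume import PETVolume

COHORT_MEAN_DOSE_BQ = 271.10e6  # mean injected activity of the cohort


def counts_volume(values):
    return PETVolume(np.asarray(values, dtype=float), value_space="counts")


class TestSuvConvert:
    def test_cohort_mean_dose_gives_unit_suv(self):
        # 3872.9 Bq/mL at 271.10 MBq into 70 kg, no decay -> SUV 1.0
        meta = AcquisitionMeta(COHORT_MEAN_DOSE_BQ, 70_000.0, 0.0, 0.0)
        vol = suv_convert(counts_volume([[3872.9]]), meta)
        assert vol.voxels[0, 0, 0] == pytest.approx(1.0, abs=1e-4)
        assert vol.value_space == "SUV"

    def test_zero_counts_zero_suv(self):
        meta = AcquisitionMeta(COHORT_MEAN_DOSE_BQ, 70_000.0, 0.0, 100.0)
        vol = suv_convert(counts_volume(np.zeros((2, 4, 4))), meta)
        assert (vol.voxels == 0).all()

    def test_one_half_life_doubles_suv(self):
        meta0 = AcquisitionMeta(COHORT_MEAN_DOSE_BQ, 70_000.0, 0.0, 0.0)
        meta1 = AcquisitionMeta(COHORT_MEAN_DOSE_BQ, 70_000.0, 0.0, 6586.2)
        v0 = suv_convert(counts_volume([[3872.9]]), meta0)
        v1 = suv_convert(counts_volume([[3872.9]]), meta1)
        assert v1.voxels[0, 0, 0] == pytest.approx(2 * v0.voxels[0, 0, 0])

    def test_missing_or_invalid_meta_named(self):
        with pytest.raises(ValueError, match="injected_dose"):
            AcquisitionMeta(-1.0, 70_000.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="patient_weight"):
            AcquisitionMeta.from_json(
                '{"injected_dose": 1e6, "injection_time": 0, "scan_time": 0}'
            )

    def test_rejects_wrong_value_space(self):
        meta = AcquisitionMeta(COHORT_MEAN_DOSE_BQ, 70_000.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="counts"):
            suv_convert(PETVolume(np.ones((1, 2, 2)), value_space="SUV"), meta)


class TestClipScale:
    @pytest.mark.parametrize("suv,expected", [(150.0, 1.0), (50.0, 0.5), (0.0, 0.0)])
    def test_threshold_and_scaling(self, suv, expected):
        out = clip_scale(PETVolume(np.full((1, 2, 2), suv)))
        assert out.voxels[0, 0, 0] == pytest.approx(expected)
        assert out.value_space == "scaled"

    @given(st.lists(st.floats(0, 100), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_exact_below_threshold(self, vals):
        vol = PETVolume(np.array(vals).reshape(1, 2, 2))
        back = unscale(clip_scale(vol))
        # clip at 100 then x100 restores values <= 100 bit-for-bit up to /100*100
        np.testing.assert_allclose(back.voxels, vol.voxels, rtol=0, atol=1e-13)


class TestNyul:
    def make_vol(self, rng, scale=1.0, n=4000):
        vals = np.concatenate([np.zeros(n // 2), rng.gamma(2.0, 2.0, n // 2) * scale])
        rng.shuffle(vals)
        return PETVolume(vals.reshape(1, -1, 50))

    def test_default_percentile_grid_is_unit_spaced(self):
        model = NyulModel()
        np.testing.assert_allclose(model.percentile_grid, np.arange(80, 100))

    def test_single_image_standard_equals_own_landmarks(self, rng):
        vol = self.make_vol(rng)
        model = nyul_fit([vol])
        np.testing.assert_allclose(
            model.standard_landmarks, image_landmarks(vol, model)
        )

    def test_mean_of_image_and_triple(self, rng):
        vol = self.make_vol(rng)
        tripled = vol.with_voxels(3.0 * vol.voxels)
        model = nyul_fit([vol, tripled])
        np.testing.assert_allclose(
            model.standard_landmarks,
            2.0 * image_landmarks(vol, model),
            rtol=1e-12,
        )

    def test_identity_when_landmarks_match_standard(self, rng):
        vol = self.make_vol(rng)
        model = nyul_fit([vol])
        out = nyul_apply(vol, model)
        lm = image_landmarks(vol, model)
        inside = (vol.voxels >= lm[0]) & (vol.voxels <= lm[-1])
        np.testing.assert_allclose(out.voxels[inside], vol.voxels[inside], rtol=1e-9)

    def test_doubled_image_maps_landmarks_back(self, rng):
        vol = self.make_vol(rng)
        model = nyul_fit([vol])
        doubled = vol.with_voxels(2.0 * vol.voxels)
        out = nyul_apply(doubled, model)
        np.testing.assert_allclose(
            image_landmarks(out, model), model.standard_landmarks, rtol=1e-6
        )

    def test_idempotent_on_landmarks_linear_case(self, rng):
        # when the image is a global rescaling of the standard histogram the
        # landmark map is exactly linear, so reapplication is a no-op
        base = self.make_vol(rng)
        model = nyul_fit([base])
        target = base.with_voxels(2.7 * base.voxels)
        once = nyul_apply(target, model)
        twice = nyul_apply(once, model)
        np.testing.assert_allclose(
            image_landmarks(once, model), image_landmarks(twice, model), atol=1e-6
        )

    def test_idempotent_on_landmarks_generic_within_interp_tolerance(self, rng):
        # for a generic image the knots straddle percentile interpolation
        # gaps, leaving an error of order (order-statistic gap), ~1e-3 at
        # a few thousand foreground voxels
        train = [self.make_vol(rng) for _ in range(3)]
        model = nyul_fit(train)
        target = self.make_vol(rng, scale=2.5)
        once = nyul_apply(target, model)
        twice = nyul_apply(once, model)
        np.testing.assert_allclose(
            image_landmarks(once, model), image_landmarks(twice, model), atol=5e-3
        )

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_mapping_is_monotone(self, seed):
        rng = np.random.default_rng(seed)
        vol = self.make_vol(rng)
        model = nyul_fit([self.make_vol(rng, scale=1.7)])
        out = nyul_apply(vol, model)
        order = np.argsort(vol.voxels.ravel(), kind="stable")
        mapped = out.voxels.ravel()[order]
        assert (np.diff(mapped) >= -1e-9).all()

    def test_constant_image_rejected(self):
        vol = PETVolume(np.full((1, 10, 10), 5.0))
        with pytest.raises(ValueError, match="degenerate|non-increasing"):
            nyul_fit([vol])

    def test_unfitted_model_rejected(self, rng):
        with pytest.raises(ValueError, match="not fitted"):
            nyul_apply(self.make_vol(rng), NyulModel())

    def test_model_json_roundtrip(self, rng):
        model = nyul_fit([self.make_vol(rng)])
        back = NyulModel.from_json(model.to_json())
        np.testing.assert_allclose(back.standard_landmarks, model.standard_landmarks)


class TestPreprocessPair:
    def test_v2_standardizes_only_nac(self, rng):
        nac = TestNyul().make_vol(rng)
        ac = TestNyul().make_vol(rng, scale=1.3)
        model = nyul_fit([TestNyul().make_vol(rng, scale=2.0)])
        nac2, ac2 = preprocess_pair(nac, ac, strategy="v2", nyul=model)
        _, ac1 = preprocess_pair(nac, ac, strategy="v1")
        np.testing.assert_array_equal(ac1.voxels, ac2.voxels)  # AC always V1-style
        assert nac2.value_space == "scaled"
        with pytest.raises(ValueError, match="NyulModel"):
            preprocess_pair(nac, ac, strategy="v2")
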