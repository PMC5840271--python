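import math

import numpy as np
import pytest

import topouptake as tu
from topouptake.preprocess import decay_factor, gaussian_kernel_1d


def make_image(values, hour=0.0):
    return tu.RawImage(values=np.asarray(values, dtype=float), hour=hour)


class TestDecayCorrection:
    @pytest.mark.parametrize(
        "value, hour, tau, expected",
        [
            (1.0, 0.0, 67.32, 1.0),  # no time elapsed, no correction
            (1.0, 67.32, 67.32, 2.0),  # one half-life doubles
            (2.5, 24.0, 67.32, 2.5 * math.exp(math.log(2) * 24 / 67.32)),
        ],
    )
    def test_scalar_values(self, value, hour, tau, expected):
        img = make_image(np.full((2, 2, 2), value), hour=hour)
        out = tu.decay_correct(img, half_life_hours=tau)
        assert np.allclose(out.values, expected, rtol=1e-12)

    def test_24h_in111_value(self):
        # independent scalar evaluation: 2.5 * e^{ln2 * 24 / 67.32} ≈ 3.2010
        img = make_image(np.full((1, 1, 1), 2.5), hour=24.0)
        out = tu.decay_correct(img, half_life_hours=67.32)
        assert out.values[0, 0, 0] == pytest.approx(3.2010, abs=5e-4)

    def test_nonpositive_half_life_rejected(self):
        with pytest.raises(ValueError):
            tu.decay_correct(make_image(np.ones((1, 1, 1))), half_life_hours=0.0)
        with pytest.raises(ValueError):
            decay_factor(1.0, half_life_hours=-1.0)


class TestGaussianSmoothing:
    def test_kernel_weights_match_closed_form(self):
        w = gaussian_kernel_1d(box=3, sigma=0.69)
        e = math.exp(-1.0 / (2 * 0.69**2))
        expected = np.array([e, 1.0, e]) / (1.0 + 2 * e)
        assert np.allclose(w, expected, rtol=1e-12)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_constant_preserved(self):
        img = make_image(np.full((6, 6, 6), 3.7))
        out = tu.gaussian_smooth(img)
        interior = out.values[1:-1, 1:-1, 1:-1]
        assert np.allclose(interior, 3.7, rtol=1e-12)

    def test_impulse_center_weight(self):
        arr = np.zeros((5, 5, 5))
        arr[2, 2, 2] = 1.0
        out = tu.gaussian_smooth(make_image(arr))
        e = math.exp(-1.0 / (2 * 0.69**2))
        center_1d = 1.0 / (1.0 + 2 * e)
        assert out.values[2, 2, 2] == pytest.approx(center_1d**3, rel=1e-12)
        assert out.values[2, 2, 2] == pytest.approx(0.2036, abs=1e-3)

    def test_mass_preserved_for_interior_support(self):
        rng = np.random.default_rng(0)
        arr = np.zeros((9, 9, 9))
        arr[2:-2, 2:-2, 2:-2] = rng.uniform(0.1, 1.0, size=(5, 5, 5))
        out = tu.gaussian_smooth(make_image(arr))
        assert out.values.sum() == pytest.approx(arr.sum(), rel=1e-9)

    def test_adjacent_equal_impulses_leave_no_strict_maximum(self):
        arr = np.zeros((5, 5, 5))
        arr[2, 2, 2] = arr[2, 2, 3] = 1.0
        out = tu.gaussian_smooth(make_image(arr))
        maxima = tu.find_local_maxima(out.values)
        assert maxima == []  # exact ties: plateau voxels are not strict maxima

    def test_bad_parameters_rejected(self):
        img = make_image(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            tu.gaussian_smooth(img, sigma=0.0)
        with pytest.raises(ValueError):
            tu.gaussian_smooth(img, box=4)


class TestRoiAndNormalization:
    def test_apply_roi_postcondition(self):
        rng = np.random.default_rng(1)
        arr = rng.uniform(0.1, 1.0, size=(4, 4, 4))
        mask = rng.uniform(size=(4, 4, 4)) > 0.5
        mask[0, 0, 0] = True  # keep non-empty
        f = tu.apply_roi(make_image(arr), tu.RoiMask(mask=mask))
        assert np.array_equal(f.f[mask], arr[mask])
        assert np.all(f.f[~mask] == 0.0)

    def test_full_mask_is_identity(self):
        arr = np.random.default_rng(2).uniform(0.1, 1.0, size=(3, 3, 3))
        f = tu.apply_roi(make_image(arr), tu.RoiMask(mask=np.ones((3, 3, 3), bool)))
        assert np.array_equal(f.f, arr)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            tu.RoiMask(mask=np.zeros((2, 2, 2), bool), kind="tumor")

    def test_h24_reference_is_roi_mean(self):
        mask = np.zeros((1, 1, 2), bool)
        mask[0, 0, :] = True
        f24 = tu.IntensityFunction(f=np.array([[[2.0, 4.0]]]), mask=mask, hour=24.0)
        f48 = tu.IntensityFunction(f=np.array([[[9.0, 9.0]]]), mask=mask, hour=48.0)
        assert tu.h24_reference([f48, f24]) == pytest.approx(3.0)

    def test_h24_reference_requires_hour_24(self):
        mask = np.ones((1, 1, 1), bool)
        f = tu.IntensityFunction(f=np.ones((1, 1, 1)), mask=mask, hour=48.0)
        with pytest.raises(ValueError, match="hour-24"):
            tu.h24_reference([f])

    def test_heart_reference_mean(self):
        img = make_image(np.array([[[1.0, 3.0, 9.0]]]))
        hmask = np.array([[[True, True, False]]])
        assert tu.heart_reference(img, tu.RoiMask(mask=hmask, kind="heart")) == 2.0

    def test_normalize_examples(self):
        mask = np.ones((1, 1, 3), bool)
        f = tu.IntensityFunction(f=np.array([[[2.0, 4.0, 6.0]]]), mask=mask)
        out = tu.normalize(f, 2.0, "h24")
        assert np.allclose(out.f, [[[1.0, 2.0, 3.0]]])
        assert out.normalization == "h24"
        same = tu.normalize(f, 1.0, "heart")
        assert np.array_equal(same.f, f.f)
        with pytest.raises(ValueError):
            tu.normalize(f, 0.0, "h24")

    def test_h24_self_normalization_gives_unit_mean(self):
        mask = np.ones((2, 2, 2), bool)
        f = tu.IntensityFunction(
            f=np.random.default_rng(3).uniform(0.5, 2.0, (2, 2, 2)), mask=mask, hour=24.0
        )
        ref = tu.h24_reference([f])
        assert tu.normalize(f, ref, "h24").roi_mean == pytest.approx(1.0, rel=1e-12)

    def test_normalize_roundtrip_exact(self):
        mask = np.ones((2, 2, 2), bool)
        arr = np.random.default_rng(4).uniform(0.5, 2.0, (2, 2, 2))
        f = tu.IntensityFunction(f=arr.copy(), mask=mask)
        back = tu.normalize(f, 3.7, "heart").f * 3.7
        assert np.allclose(back, arr, atol=1e-12)


def test_operations_commute_up_to_float_tolerance():
    """Decay correction, smoothing, and scalar normalization are all linear."""
    rng = np.random.default_rng(5)
    arr = rng.uniform(0.1, 1.0, size=(6, 6, 6))
    img = make_image(arr, hour=48.0)
    a = tu.gaussian_smooth(tu.decay_correct(img)).values / 3.0
    b = tu.decay_correct(tu.gaussian_smooth(img)).values / 3.0
    c = tu.decay_correct(make_image(tu.gaussian_smooth(img).values / 3.0, hour=48.0)).values
    assert np.allclose(a, b, atol=1e-12)
    assert np.allclose(a, c, atol=1e-12)


def test_invalid_voxels_rejected_at_load():
    with pytest.raises(ValueError):
        make_image(np.full((2, 2, 2), -1.0))
    arr = np.ones((2, 2, 2))
    arr[0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        make_image(arr)
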