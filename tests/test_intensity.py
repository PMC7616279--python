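import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spheroidquant import intensity
from spheroidquant.intensity import NormalizationParams


def quantile_oracle(values, q):
    """Sorted linear interpolation at rank q * (n - 1), written from scratch."""
    s = sorted(values)
    r = q * (len(s) - 1)
    i = math.floor(r)
    f = r - i
    return s[i] if f == 0 else s[i] + f * (s[i + 1] - s[i])


def _stack(pixels_per_plane):
    """Build a (z, 1, n) stack with trivial spheroid/nuclei masks from lists."""
    n = max(len(p) for p in pixels_per_plane)
    arr = np.zeros((len(pixels_per_plane), 1, n))
    sph = np.zeros_like(arr, dtype=bool)
    for z, p in enumerate(pixels_per_plane):
        arr[z, 0, : len(p)] = p
        sph[z, 0, : len(p)] = True
    return arr, sph, np.zeros_like(sph)


class TestBackgroundCorrect:
    def test_constant_background_removed(self):
        arr, sph, nuc = _stack([[50.0] * 8])
        corrected, b_z, skipped = intensity.background_correct_stack(arr, sph, nuc)
        assert b_z[0] == 50.0
        assert np.all(corrected[sph] == 0.0)
        assert skipped == []

    def test_interpolated_quantile_example(self):
        """{10,20,30,40} at q=0.75 gives 32.5 under rank 0.75*(n-1) interpolation."""
        arr, sph, nuc = _stack([[10.0, 20.0, 30.0, 40.0]])
        _, b_z, _ = intensity.background_correct_stack(arr, sph, nuc)
        assert b_z[0] == pytest.approx(quantile_oracle([10, 20, 30, 40], 0.75))
        assert b_z[0] == pytest.approx(32.5)

    @given(
        st.lists(st.floats(0, 1e4, allow_nan=False, width=32), min_size=1, max_size=40),
        st.floats(0.05, 0.95),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_handwritten_quantile(self, values, q):
        arr, sph, nuc = _stack([values])
        _, b_z, _ = intensity.background_correct_stack(
            arr, sph, nuc, NormalizationParams(background_quantile=q)
        )
        assert b_z[0] == pytest.approx(quantile_oracle(values, q), abs=1e-9)

    def test_shift_equivariance_corrected_background_is_zero(self):
        rng = np.random.default_rng(0)
        arr = rng.uniform(10, 200, size=(4, 6, 6))
        sph = np.ones_like(arr, dtype=bool)
        nuc = np.zeros_like(sph)
        nuc[:, :2, :2] = True
        corrected, _, _ = intensity.background_correct_stack(arr, sph, nuc)
        _, b2, _ = intensity.background_correct_stack(corrected + 0, sph, nuc)
        np.testing.assert_allclose(b2, 0.0, atol=1e-12)

    def test_empty_spheroid_rejected(self):
        arr = np.zeros((2, 4, 4))
        with pytest.raises(ValueError, match="empty"):
            intensity.background_correct_stack(arr, np.zeros_like(arr), np.zeros_like(arr))

    def test_all_nuclear_plane_skipped_with_warning(self):
        arr = np.ones((2, 3, 3))
        sph = np.ones_like(arr, dtype=bool)
        nuc = np.zeros_like(sph)
        nuc[1] = True  # plane 1 entirely nuclear
        with pytest.warns(UserWarning, match="plane 1"):
            _, b_z, skipped = intensity.background_correct_stack(arr, sph, nuc)
        assert skipped == [1]
        assert np.isnan(b_z[1]) and b_z[0] == 1.0

    def test_clip_negative_flag(self):
        arr, sph, nuc = _stack([[10.0, 20.0, 30.0, 40.0]])
        corrected, _, _ = intensity.background_correct_stack(
            arr, sph, nuc, NormalizationParams(clip_negative=True)
        )
        assert corrected.min() == 0.0


class TestDapiNormalize:
    def test_plane_mean_division(self):
        marker = np.full((1, 2, 2), 100.0)
        dapi = np.full((1, 2, 2), 200.0)
        nuc = np.ones((1, 2, 2), dtype=np.uint16)
        norm, means, excl = intensity.dapi_normalize_stack(marker, dapi, nuc)
        assert means[0] == 200.0
        assert np.all(norm == 0.5)
        assert excl == []

    def test_joint_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        marker = rng.uniform(0, 50, size=(3, 5, 5))
        dapi = rng.uniform(50, 150, size=(3, 5, 5))
        nuc = (rng.uniform(size=(3, 5, 5)) > 0.5).astype(np.uint16)
        n1, _, _ = intensity.dapi_normalize_stack(marker, dapi, nuc)
        n3, _, _ = intensity.dapi_normalize_stack(3 * marker, 3 * dapi, nuc)
        np.testing.assert_allclose(n1[np.isfinite(n1)], n3[np.isfinite(n3)], rtol=1e-9)

    def test_plane_without_nuclei_excluded(self):
        marker = np.ones((2, 2, 2))
        dapi = np.ones((2, 2, 2))
        nuc = np.zeros((2, 2, 2), dtype=np.uint16)
        nuc[0] = 1
        norm, _, excl = intensity.dapi_normalize_stack(marker, dapi, nuc)
        assert excl == [1]
        assert np.isnan(norm[1]).all() and np.isfinite(norm[0]).all()


class TestNuclearMean:
    def test_uniform_nucleus(self):
        arr = np.zeros((1, 4, 4))
        lab = np.zeros_like(arr, dtype=np.uint16)
        lab[0, 1:3, 1:3] = 2
        arr[lab == 2] = 7.5
        means = intensity.nuclear_mean(arr, lab)
        assert means[2] == 7.5

    def test_missing_id_rejected(self):
        arr = np.zeros((1, 4, 4))
        lab = np.zeros_like(arr, dtype=np.uint16)
        lab[0, 0, 0] = 1
        with pytest.raises(KeyError, match="99"):
            intensity.nuclear_mean(arr, lab, ids=[99])

    def test_depth_attenuation_cancelled_on_phantom(self, spheroid_phantom):
        """Planted a_z attenuation leaves normalized per-cell means depth-independent."""
        spec, img, labels, truth = spheroid_phantom
        params = NormalizationParams()
        dapi_c, _, _ = intensity.background_correct_stack(
            img.channel("dapi"), labels.spheroid, labels.nuclei, params
        )
        mk_c, _, _ = intensity.background_correct_stack(
            img.channel("nuclear_marker"), labels.spheroid, labels.nuclei, params
        )
        norm, _, _ = intensity.dapi_normalize_stack(mk_c, dapi_c, labels.nuclei)
        means = intensity.nuclear_mean(norm, labels.nuclei)
        t = truth.cells.set_index("cell_id")
        # negatives only, divided by planted per-cell expression: the residual
        # should not correlate with depth
        neg = [i for i in means.index if not t.marker_positive[i]]
        z = np.array([np.argwhere(labels.nuclei == i)[:, 0].mean() for i in neg])
        resid = np.array([means[i] / t.expression[i] for i in neg])
        r = np.corrcoef(z, resid)[0, 1]
        assert abs(r) < 0.5


class TestLognormBatch:
    def test_two_value_example(self):
        out, n_ex = intensity.lognorm_batch(pd.Series([2.0, 8.0]), "a")
        np.testing.assert_allclose(out.to_numpy(), [0.5, 2.0])
        assert n_ex == 0

    def test_singleton_batch(self):
        out, _ = intensity.lognorm_batch(pd.Series([17.3]), "a")
        assert out.iloc[0] == pytest.approx(1.0)

    @given(st.lists(st.floats(1e-3, 1e3, allow_nan=False), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_output_geometric_mean_is_one(self, values):
        out, _ = intensity.lognorm_batch(pd.Series(values), "b")
        gm = np.exp(np.log(out.to_numpy()).mean())
        assert gm == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_excluded_and_counted(self):
        out, n_ex = intensity.lognorm_batch(pd.Series([4.0, -1.0, 0.0]), "a")
        assert n_ex == 2
        assert out.iloc[0] == pytest.approx(1.0) and out.isna().sum() == 2

    def test_unusable_batch_rejected(self):
        with pytest.raises(ValueError, match="no usable"):
            intensity.lognorm_batch(pd.Series([-1.0, 0.0]), "a")

    def test_batches_normalized_independently(self):
        vals = pd.Series([2.0, 8.0, 5.0])
        out, _ = intensity.lognorm_batch(vals, pd.Series(["a", "a", "b"]))
        np.testing.assert_allclose(out.to_numpy(), [0.5, 2.0, 1.0])


class TestCytoMean:
    def test_uniform_cytoplasm(self):
        marker = np.zeros((6, 6))
        cells = np.zeros((6, 6), np.uint16)
        nuc = np.zeros((6, 6), np.uint16)
        cells[1:5, 1:5] = 1
        nuc[2:4, 2:4] = 1
        marker[(cells == 1) & (nuc == 0)] = 40.0
        dapi = np.where(nuc > 0, 80.0, 0.0)
        vals = intensity.cyto_mean(marker, cells, nuc, dapi)
        assert vals[1] == pytest.approx(0.5)

    def test_fully_nuclear_cell_flagged(self):
        cells = np.ones((3, 3), np.uint16)
        nuc = np.ones((3, 3), np.uint16)
        with pytest.warns(UserWarning, match="fully nuclear"):
            vals = intensity.cyto_mean(np.ones((3, 3)), cells, nuc, np.ones((3, 3)))
        assert np.isnan(vals[1])


class TestClassifyMarker:
    def test_fixed_threshold_example(self):
        calls, b = intensity.classify_marker(
            pd.Series([0.1, 0.1, 0.9]), "fixed_threshold", threshold=0.5
        )
        assert calls.tolist() == [False, False, True]
        assert b == 0.5

    @pytest.mark.parametrize("method", ["otsu", "gmm2"])
    def test_degenerate_values_rejected(self, method):
        with pytest.raises(ValueError, match="fixed_threshold"):
            intensity.classify_marker(pd.Series([1.0, 1.0, 1.0]), method)

    @pytest.mark.parametrize("method", ["otsu", "gmm2"])
    def test_well_separated_populations_exact(self, method, spheroid_phantom):
        """Planted positives at 4x separation are recovered exactly by any method."""
        spec, img, labels, truth = spheroid_phantom
        dapi_c, _, _ = intensity.background_correct_stack(
            img.channel("dapi"), labels.spheroid, labels.nuclei
        )
        mk_c, _, _ = intensity.background_correct_stack(
            img.channel("nuclear_marker"), labels.spheroid, labels.nuclei
        )
        norm, _, _ = intensity.dapi_normalize_stack(mk_c, dapi_c, labels.nuclei)
        means = intensity.nuclear_mean(norm, labels.nuclei)
        calls, _ = intensity.classify_marker(means, method)
        t = truth.cells.set_index("cell_id").marker_positive
        assert all(calls[i] == t[i] for i in calls.index)


class TestSplitLowHigh:
    def test_four_value_example(self):
        out = intensity.split_low_high(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert out.tolist() == ["low", "low", "high", "high"]

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=41, unique=True))
    @settings(max_examples=100, deadline=None)
    def test_balanced_split(self, values):
        out = intensity.split_low_high(pd.Series(values))
        n_low = (out == "low").sum()
        n_high = (out == "high").sum()
        assert abs(n_low - n_high) <= 1


class TestMonolayerCorrect:
    def _fixture(self, bright_ids=()):
        rng = np.random.default_rng(0)
        marker = np.full((40, 40), 30.0)
        nuc = np.zeros((40, 40), np.uint16)
        k = 1
        for cy in range(5, 40, 10):
            for cx in range(5, 40, 10):
                nuc[cy - 2 : cy + 3, cx - 2 : cx + 3] = k
                level = 90.0 if k in bright_ids else 45.0
                marker[cy - 2 : cy + 3, cx - 2 : cx + 3] = level
                k += 1
        dapi = np.where(nuc > 0, 120.0, 5.0)
        return marker, nuc, dapi

    def test_background_level_nuclei_zeroed(self):
        marker, nuc, dapi = self._fixture()
        out = intensity.monolayer_correct(marker, nuc, dapi)
        np.testing.assert_allclose(out[nuc > 0], 0.0, atol=1e-12)

    def test_bright_minority_stays_positive(self):
        marker, nuc, dapi = self._fixture(bright_ids={1, 2})
        out = intensity.monolayer_correct(marker, nuc, dapi)
        assert out[nuc == 1].mean() > 0
        assert out[nuc == 5].mean() == pytest.approx(0.0, abs=1e-12)

    def test_joint_scale_invariance(self):
        marker, nuc, dapi = self._fixture(bright_ids={3})
        out1 = intensity.monolayer_correct(marker, nuc, dapi)
        out3 = intensity.monolayer_correct(3 * marker, nuc, 3 * dapi)
        np.testing.assert_allclose(out1, out3, rtol=1e-9, atol=1e-12)
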