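import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from musselsite.grid import GridError, RasterLayer, make_grid
from musselsite.suitability import (DEFAULT_WEIGHTS, SAATY_RI, SSS_PARAMS,
                                    SPM_PARAMS, AHPResult, CHLResponseParams,
                                    PolynomialResponseParams, SSTResponseParams,
                                    WeightVector, ahp_weights, chl_score,
                                    classify_si, consistent_matrix_from_weights,
                                    mean_factor_score, spm_score, sss_score,
                                    sst_score, weighted_overlay)
from conftest import daily_stack


def sst_oracle(t, tmax=30.0, topt=15.8, c=0.393):
    """Direct transcription of the thermal response for scalar input."""
    if t >= tmax:
        return 0.0
    return ((tmax - t) / (tmax - topt)) ** (c * (tmax - topt)) * math.exp(c * (t - topt))


class TestSSTScore:
    def test_optimum_and_ceiling(self):
        assert sst_score(15.8) == pytest.approx(1.0, abs=1e-12)
        assert sst_score(30.0) == 0.0
        assert sst_score(35.0) == 0.0

    def test_against_scalar_oracle(self):
        for t in (-2.0, 5.0, 12.5, 20.0, 27.0, 29.9):
            assert sst_score(t) == pytest.approx(sst_oracle(t), rel=1e-12)

    def test_unimodal_on_fine_grid(self):
        t = np.arange(0.0, 30.0, 0.01)
        s = sst_score(t)
        peak = np.searchsorted(t, 15.8)
        assert (np.diff(s[:peak]) > 0).all()
        assert (np.diff(s[peak:]) < 0).all()
        assert s.max() == pytest.approx(1.0, abs=1e-9)

    def test_bounded_on_dense_grid(self):
        s = sst_score(np.linspace(-5, 45, 20001))
        assert (s >= 0).all() and (s <= 1).all()

    def test_nan_propagates(self):
        assert np.isnan(sst_score(np.array([np.nan]))[0])


class TestCHLScore:
    def test_half_saturation_by_definition(self):
        assert chl_score(0.0) == 0.0
        assert chl_score(1.06) == pytest.approx(0.5, abs=1e-15)
        assert chl_score(10 * 1.06) == pytest.approx(10 / 11, abs=1e-12)

    def test_strictly_increasing_below_one(self):
        s = chl_score(np.linspace(0, 50, 5001))
        assert (np.diff(s) > 0).all() and (s < 1).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            chl_score(np.array([-0.1]))


class TestSSSScore:
    def test_printed_intercept(self):
        assert SSS_PARAMS.raw(0.0) == pytest.approx(-0.875038, abs=1e-12)

    def test_argmax_standardizes_to_one(self):
        s = np.linspace(*SSS_PARAMS.domain, 40001)
        scores = sss_score(s)
        assert scores.max() == pytest.approx(1.0, abs=1e-9)
        assert (scores >= 0).all() and (scores <= 1).all()

    def test_against_brute_force_standardization_oracle(self):
        # oracle: clamp the quartic on a dense grid and min–max rescale
        grid = np.linspace(0, 40, 2_000_001)
        y = np.maximum(np.polyval([-9e-6, 6.91e-4, -2.087e-2, 0.296816, -0.875038],
                                  grid), 0.0)
        lo, hi = y.min(), y.max()
        for s in (0.0, 5.0, 20.0, 27.5, 35.0):
            raw = max(np.polyval([-9e-6, 6.91e-4, -2.087e-2, 0.296816, -0.875038], s),
                      0.0)
            assert sss_score(s) == pytest.approx((raw - lo) / (hi - lo), abs=1e-9)

    def test_out_of_domain_clipped(self):
        assert sss_score(45.0) == sss_score(40.0)


class TestSPMScore:
    def test_printed_intercept(self):
        assert SPM_PARAMS.raw(0.0) == pytest.approx(0.8273, abs=1e-12)

    def test_monotone_non_increasing(self):
        s = spm_score(np.linspace(0, 100, 10001))
        assert (np.diff(s) <= 1e-12).all()
        assert spm_score(10.0) > spm_score(40.0)

    def test_zero_at_and_beyond_positive_root(self):
        a, b, c = -2e-4, -4.2e-3, 0.8273
        root = (-b - math.sqrt(b * b - 4 * a * c)) / (2 * a)
        assert spm_score(root) == pytest.approx(0.0, abs=1e-9)
        assert spm_score(min(root + 5, 100.0)) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            spm_score(np.array([-1.0]))


@given(st.floats(min_value=-5, max_value=45, allow_nan=False))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_sst_membership_always_in_unit_interval(t):
    assert 0.0 <= sst_score(t) <= 1.0


@given(st.floats(min_value=0, max_value=40, allow_nan=False))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_sss_membership_always_in_unit_interval(s):
    assert 0.0 <= sss_score(s) <= 1.0


class TestMeanFactorScore:
    def test_constant_stack(self, unit_grid):
        stack = daily_stack(unit_grid, np.full((5,) + unit_grid.shape, 20.0))
        out = mean_factor_score(stack, sst_score)
        assert np.allclose(out.values, sst_oracle(20.0))

    def test_two_slice_average(self, unit_grid):
        v = np.empty((2,) + unit_grid.shape)
        v[0], v[1] = 15.8, 30.0
        out = mean_factor_score(daily_stack(unit_grid, v), sst_score)
        assert np.allclose(out.values, 0.5)

    def test_random_stack_matches_slice_loop(self, unit_grid, rng):
        v = rng.uniform(5, 32, (20,) + unit_grid.shape)
        v[3, 1, 1] = np.nan
        out = mean_factor_score(daily_stack(unit_grid, v), sst_score)
        for i in range(unit_grid.nlat):
            for j in range(unit_grid.nlon):
                scores = [sst_oracle(v[t, i, j]) for t in range(20)
                          if np.isfinite(v[t, i, j])]
                assert out.values[i, j] == pytest.approx(np.mean(scores), rel=1e-12)

    def test_all_missing_cell_is_missing(self, unit_grid):
        v = np.full((4,) + unit_grid.shape, 10.0)
        v[:, 0, 0] = np.nan
        out = mean_factor_score(daily_stack(unit_grid, v), sst_score)
        assert np.isnan(out.values[0, 0])
        assert np.isfinite(out.values[1:, :]).all()


class TestAHP:
    def test_recovers_published_weights_from_ratio_matrix(self):
        res = ahp_weights(consistent_matrix_from_weights(DEFAULT_WEIGHTS))
        for name, w in DEFAULT_WEIGHTS.items():
            assert res.weights.as_dict()[name] == pytest.approx(w, abs=1e-9)
        assert res.cr == pytest.approx(0.0, abs=1e-9)
        assert res.cr < 0.1 and res.consistent

    def test_all_ones_matrix_gives_equal_weights(self):
        res = ahp_weights(np.ones((4, 4)))
        assert np.allclose(list(res.weights.as_dict().values()), 0.25)
        assert res.cr == pytest.approx(0.0, abs=1e-12)

    def test_random_reciprocal_matches_eigensolver(self, rng):
        for _ in range(20):
            u = np.exp(rng.normal(0, 0.5, (4, 4)))
            a = np.triu(u, 1) + np.eye(4)
            with np.errstate(divide="ignore"):
                a = a + np.where(np.tri(4, k=-1) > 0, 1.0 / a.T, 0.0)
            res = ahp_weights(a)
            eigval, eigvec = np.linalg.eig(a)
            k = np.argmax(eigval.real)
            w = np.abs(eigvec[:, k].real)
            w /= w.sum()
            assert res.lambda_max == pytest.approx(eigval[k].real, abs=1e-8)
            np.testing.assert_allclose(list(res.weights.as_dict().values()), w,
                                       atol=1e-8)

    def test_known_inconsistent_matrix_flagged(self):
        # classic strongly intransitive judgments
        a = np.array([[1, 9, 1 / 9.0, 1],
                      [1 / 9.0, 1, 9, 1],
                      [9, 1 / 9.0, 1, 1],
                      [1, 1, 1, 1]])
        res = ahp_weights(a)
        assert res.cr >= 0.1 and not res.consistent

    @pytest.mark.parametrize("bad", [
        np.array([[1.0, 2.0], [3.0, 1.0]]),       # not reciprocal
        np.array([[1.0, -2.0], [-0.5, 1.0]]),     # not positive
        np.ones((1, 1)),                          # n < 2
    ])
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(ValueError):
            ahp_weights(bad, names=tuple("ab"[:len(bad)]))

    def test_ri_table_values(self):
        assert SAATY_RI[4] == 0.90


class TestWeightVector:
    def test_published_weights_accepted(self):
        wv = WeightVector.from_mapping(DEFAULT_WEIGHTS)
        assert sum(wv.weights) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("weights", [(0.5, 0.6), (-0.1, 1.1)])
    def test_invalid_weights_rejected(self, weights):
        with pytest.raises(ValueError):
            WeightVector(("a", "b"), weights)


class TestWeightedOverlay:
    def _means(self, grid, values):
        return {name: RasterLayer(grid, np.full(grid.shape, float(v)))
                for name, v in zip(DEFAULT_WEIGHTS, values)}

    def test_all_ones_gives_one(self, unit_grid):
        si = weighted_overlay(self._means(unit_grid, [1, 1, 1, 1]),
                              WeightVector.from_mapping(DEFAULT_WEIGHTS))
        assert np.allclose(si.values, 1.0)

    def test_single_factor_returns_its_weight(self, unit_grid):
        si = weighted_overlay(self._means(unit_grid, [1, 0, 0, 0]),
                              WeightVector.from_mapping(DEFAULT_WEIGHTS))
        assert np.allclose(si.values, 0.45)

    def test_random_fields_match_dot_product(self, unit_grid, rng):
        fields = {n: RasterLayer(unit_grid, rng.random(unit_grid.shape))
                  for n in DEFAULT_WEIGHTS}
        si = weighted_overlay(fields, WeightVector.from_mapping(DEFAULT_WEIGHTS))
        for i in range(unit_grid.nlat):
            for j in range(unit_grid.nlon):
                dot = sum(DEFAULT_WEIGHTS[n] * fields[n].values[i, j]
                          for n in DEFAULT_WEIGHTS)
                assert si.values[i, j] == pytest.approx(dot, abs=1e-12)

    def test_missing_factor_gives_missing_si(self, unit_grid):
        means = self._means(unit_grid, [1, 1, 1, 1])
        means["CHL"].values[0, 0] = np.nan
        si = weighted_overlay(means, WeightVector.from_mapping(DEFAULT_WEIGHTS))
        assert np.isnan(si.values[0, 0]) and np.isfinite(si.values[1, 1])

    def test_monotone_in_each_factor(self, unit_grid, rng):
        base = {n: RasterLayer(unit_grid, rng.uniform(0, 0.9, unit_grid.shape))
                for n in DEFAULT_WEIGHTS}
        wv = WeightVector.from_mapping(DEFAULT_WEIGHTS)
        si0 = weighted_overlay(base, wv).values
        for n in DEFAULT_WEIGHTS:
            bumped = {k: v for k, v in base.items()}
            bumped[n] = RasterLayer(unit_grid, base[n].values + 0.1)
            assert (weighted_overlay(bumped, wv).values >= si0 - 1e-12).all()

    def test_name_mismatch_rejected(self, unit_grid):
        means = self._means(unit_grid, [1, 1, 1, 1])
        means["XYZ"] = means.pop("SPM")
        with pytest.raises(ValueError):
            weighted_overlay(means, WeightVector.from_mapping(DEFAULT_WEIGHTS))


class TestClassifySI:
    @pytest.mark.parametrize("value,cls", [
        (0.0, 0), (0.19, 0), (0.2, 1), (0.39, 1), (0.4, 2), (0.6, 3),
        (0.79, 3), (0.8, 4), (0.85, 4), (1.0, 4),
    ])
    def test_band_assignment(self, unit_grid, value, cls):
        layer = RasterLayer(unit_grid, np.full(unit_grid.shape, value))
        assert classify_si(layer).values[0, 0] == cls

    def test_exhaustive_and_exclusive_over_unit_interval(self):
        g = make_grid([0, 0.1, 0, 0.1], 0.1)
        vals = np.linspace(0, 1, 10001)
        classes = [classify_si(RasterLayer(g, np.full(g.shape, v))).values[0, 0]
                   for v in vals]
        assert set(classes) == {0, 1, 2, 3, 4}
        # non-decreasing class index along increasing SI → bins are exclusive
        assert (np.diff(classes) >= 0).all()

    def test_out_of_range_rejected(self, unit_grid):
        with pytest.raises(ValueError):
            classify_si(RasterLayer(unit_grid, np.full(unit_grid.shape, 1.2)))

    def test_missing_stays_missing(self, unit_grid):
        v = np.full(unit_grid.shape, 0.5)
        v[0, 0] = np.nan
        out = classify_si(RasterLayer(unit_grid, v))
        assert np.isnan(out.values[0, 0]) and out.values[1, 1] == 2
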