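"""Three-band and two-band indices, stepwise tuning, ratio matrix."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hyperchla import (BandPair, BandTriplet, SpectrumSet, calibrate_linear,
                       ratio_matrix, three_band_value, tune_three_band,
                       tune_two_band, two_band_value)


def make_set(values, start=400, kind="RL"):
    values = np.atleast_2d(values)
    wl = start + np.arange(values.shape[1])
    ids = [f"s{i}" for i in range(values.shape[0])]
    return SpectrumSet(wavelengths=wl, values=values, sample_ids=ids, kind=kind)


def spectrum_with(bands: dict[int, float], n_bands=501, start=400, fill=0.01):
    vals = np.full(n_bands, fill)
    for b, v in bands.items():
        vals[b - start] = v
    return vals


class TestIndexValues:
    def test_three_band_hand_arithmetic(self):
        # (1/0.01 - 1/0.02) * 0.005 = (100 - 50) * 0.005 = 0.25
        vals = spectrum_with({664: 0.01, 695: 0.02, 736: 0.005})
        s = make_set(vals)
        np.testing.assert_allclose(
            three_band_value(s, BandTriplet(664, 695, 736)), 0.25)

    def test_three_band_flat_spectrum_is_zero(self):
        s = make_set(np.full(501, 0.02))
        np.testing.assert_allclose(
            three_band_value(s, BandTriplet(664, 695, 736)), 0.0)

    def test_two_band_hand_arithmetic(self):
        vals = spectrum_with({670: 0.010, 705: 0.012})
        s = make_set(vals)
        np.testing.assert_allclose(
            two_band_value(s, BandPair(red=670, nir=705)), 1.2)

    def test_two_band_same_band_is_unity(self):
        s = make_set(np.random.default_rng(0).uniform(0.01, 0.05, (3, 501)))
        np.testing.assert_allclose(
            two_band_value(s, BandPair(red=650, nir=650)), 1.0)

    def test_zero_reflectance_flags_sample(self):
        vals = np.stack([spectrum_with({664: 0.0}),
                         spectrum_with({664: 0.01})])
        s = make_set(vals)
        tb = three_band_value(s, BandTriplet(664, 695, 736))
        assert np.isnan(tb[0]) and np.isfinite(tb[1])
        twob = two_band_value(s, BandPair(red=664, nir=705))
        assert np.isnan(twob[0]) and np.isfinite(twob[1])

    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scaling_invariance(self, scale):
        rng = np.random.default_rng(42)
        s = make_set(rng.uniform(0.005, 0.05, (4, 501)))
        scaled = s.with_values(s.values * scale)
        t, p = BandTriplet(664, 695, 736), BandPair(red=670, nir=705)
        np.testing.assert_allclose(three_band_value(scaled, t),
                                   three_band_value(s, t), rtol=1e-9)
        np.testing.assert_allclose(two_band_value(scaled, p),
                                   two_band_value(s, p), rtol=1e-9)


class TestTuning:
    def test_three_band_recovers_red_absorption_center(self, rl_noisefree,
                                                       campaign_noisefree):
        res = tune_three_band(rl_noisefree, campaign_noisefree.chl)
        assert abs(res.selected.l1 - 670) <= 10
        assert res.selected.l1 < res.selected.l2 < res.selected.l3

    def test_two_band_recovers_red_absorption_center(self, rl_noisefree,
                                                     campaign_noisefree):
        res = tune_two_band(rl_noisefree, campaign_noisefree.chl)
        assert abs(res.selected.red - 670) <= 10
        assert res.selected.red < res.selected.nir

    def test_trace_lengths_match_candidate_counts(self, rl_noisefree,
                                                  campaign_noisefree):
        res = tune_three_band(rl_noisefree, campaign_noisefree.chl)
        assert res.n_stages == 3
        assert len(res.traces["lambda1"]) == 101  # 600..700
        l1, l2 = res.selected.l1, res.selected.l2
        assert len(res.traces["lambda2"]) == sum(1 for w in range(680, 741) if w > l1)
        assert len(res.traces["lambda3"]) == sum(1 for w in range(700, 801) if w > l2)

    def test_correlations_bounded_by_one(self, rl_noisefree, campaign_noisefree):
        res = tune_two_band(rl_noisefree, campaign_noisefree.chl)
        for trace in res.traces.values():
            assert np.all(np.abs(trace["r"]) <= 1 + 1e-12)

    def test_degenerate_single_candidate_ranges(self, rl_noisefree,
                                                campaign_noisefree):
        res = tune_two_band(rl_noisefree, campaign_noisefree.chl,
                            red_range=(666, 666), nir_range=(700, 700))
        assert res.selected == BandPair(red=666, nir=700)

    def test_iterated_tuning_reaches_fixed_point(self, rl_noisefree,
                                                 campaign_noisefree):
        chl = campaign_noisefree.chl
        first = tune_three_band(rl_noisefree, chl, iterate=True)
        again = tune_three_band(rl_noisefree, chl, iterate=True,
                                init_l2=first.selected.l2,
                                init_l3=first.selected.l3)
        assert again.selected == first.selected
        pair = tune_two_band(rl_noisefree, chl, iterate=True)
        pair2 = tune_two_band(rl_noisefree, chl, iterate=True,
                              init_nir=pair.selected.nir)
        assert pair2.selected == pair.selected

    def test_constant_chl_rejected(self, rl_noisefree):
        with pytest.raises(ValueError, match="constant chl"):
            tune_two_band(rl_noisefree, np.full(rl_noisefree.n_samples, 3.0))


class TestCalibrateLinear:
    def test_exact_affine_relation(self):
        index = np.linspace(0.0, 1.0, 20)
        chl = 4.0 * index + 1.5
        fit = calibrate_linear(index, chl)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)
        assert fit.a == pytest.approx(4.0) and fit.b == pytest.approx(1.5)

    def test_training_bias_is_zero(self):
        rng = np.random.default_rng(5)
        index = rng.uniform(0, 1, 30)
        chl = 3 * index + rng.normal(0, 0.5, 30) + 2
        fit = calibrate_linear(index, chl)
        assert fit.bias == pytest.approx(0.0, abs=1e-12)

    def test_two_points_exact(self):
        fit = calibrate_linear(np.array([0.0, 1.0]), np.array([2.0, 5.0]))
        assert fit.a == pytest.approx(3.0) and fit.b == pytest.approx(2.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_closed_form_simple_regression(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        fit = calibrate_linear(x, y)
        # closed-form oracle: a = cov(x, y)/var(x), b = ybar - a xbar
        a = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert fit.a == pytest.approx(a, rel=1e-9)
        assert fit.b == pytest.approx(y.mean() - a * x.mean(), rel=1e-9, abs=1e-9)

    def test_constant_index_rejected(self):
        with pytest.raises(ValueError, match="constant index"):
            calibrate_linear(np.ones(5), np.arange(5.0))


class TestRatioMatrix:
    def test_shape_and_diagonal_on_analysis_grid(self, rl_analysis, campaign):
        m = ratio_matrix(rl_analysis, campaign.chl)
        assert m.shape == (501, 501)
        assert np.all(np.isnan(np.diag(m.to_numpy())))

    def test_values_bounded(self, rl_analysis, campaign):
        vals = ratio_matrix(rl_analysis, campaign.chl).to_numpy()
        finite = vals[np.isfinite(vals)]
        assert np.all(finite >= -1e-12) and np.all(finite <= 1 + 1e-12)

    def test_constructed_maximum_at_known_pair(self):
        # chl made exactly proportional to R(700)/R(670)
        rng = np.random.default_rng(3)
        n = 25
        wl = 650 + np.arange(81)
        vals = rng.uniform(0.01, 0.05, (n, wl.size))
        s = SpectrumSet(wavelengths=wl, values=vals,
                        sample_ids=[f"s{i}" for i in range(n)])
        chl = 5.0 * vals[:, wl == 700].ravel() / vals[:, wl == 670].ravel()
        m = ratio_matrix(s, chl)
        assert m.loc[700, 670] == pytest.approx(1.0)
        peak = m.stack().idxmax()
        assert peak == (700, 670)
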