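import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breathdyn.dynamics import (MSEParams, SampEnParams, autocorr_window,
                                compute_dynamics, harmonize_sites,
                                lempel_ziv_complexity, log_transform_features,
                                multiscale_entropy, psd_slope, sample_entropy,
                                series_cv, series_mean, series_sd)
from breathdyn.io import FEATURE_COLUMNS, make_feature_table
from breathdyn.synthetic import gen_ar1_series, gen_powerlaw_series
from conftest import lz76_bruteforce, make_breath_series, sampen_bruteforce


class TestBasicStats:
    def test_constant_series(self):
        assert series_mean([2, 2, 2]) == 2
        assert series_sd([2, 2, 2]) == 0
        assert series_cv([2, 2, 2]) == 0

    def test_two_point_arithmetic(self):
        assert series_sd([1, 3]) == pytest.approx(np.sqrt(2))
        assert series_cv([1, 3]) == pytest.approx(np.sqrt(2) / 2)

    def test_cv_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero-mean"):
            series_cv([-1.0, 1.0])

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_cv_scale_invariant(self, a):
        x = np.array([1.0, 2.0, 4.5, 3.2, 2.2])
        assert series_cv(a * x) == pytest.approx(series_cv(x), rel=1e-9)


class TestAutocorrWindow:
    def test_iid_noise_acw_is_one(self, rng):
        prof = autocorr_window(rng.standard_normal(1000))
        assert prof.acw50 == 1

    def test_ar1_closed_form(self):
        # smallest k with 0.9^k < 0.5 is 7
        x = gen_ar1_series(0.9, 100_000, seed=42)
        assert autocorr_window(x).acw50 == 7

    def test_ar1_phi06_closed_form(self):
        # 0.6 >= 0.5 > 0.36 -> acw50 = 2
        x = gen_ar1_series(0.6, 100_000, seed=43)
        assert autocorr_window(x).acw50 == 2

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            autocorr_window(np.ones(100))

    def test_never_below_half_capped_and_flagged(self):
        # a near-linear ramp stays self-similar over the first few lags
        prof = autocorr_window(np.arange(40.0), max_lag=4)
        assert prof.capped
        assert prof.acw50 == 4

    def test_acf_normalization(self, rng):
        prof = autocorr_window(rng.standard_normal(500))
        assert prof.acf[0] == pytest.approx(1.0)
        assert np.all(np.abs(prof.acf) <= 1 + 1e-9)


class TestPsdSlope:
    def test_white_noise_flat(self, rng):
        est = psd_slope(rng.standard_normal(4096))
        assert abs(est.beta) < 0.15

    @pytest.mark.parametrize("beta", [1.0, 2.0])
    def test_powerlaw_recovery(self, beta):
        x = gen_powerlaw_series(beta, 4096, seed=7)
        est = psd_slope(x)
        assert est.beta == pytest.approx(beta, abs=0.2)

    def test_sign_convention(self):
        # beta > 0 reports low-frequency dominance; raw slope is negative
        x = gen_powerlaw_series(1.5, 2048, seed=1)
        est = psd_slope(x)
        assert est.beta > 0
        assert est.raw_slope == pytest.approx(-est.beta)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(512)
        assert psd_slope(5.0 * x).beta == pytest.approx(psd_slope(x).beta, abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="32"):
            psd_slope(np.arange(10.0))


class TestLempelZiv:
    def test_constant_series_single_phrase(self):
        res = lempel_ziv_complexity(np.ones(1000))
        assert res.pattern_count == 1
        assert res.normalized == pytest.approx(np.log2(1000) / 1000, rel=1e-6)

    def test_fair_coin_normalized_near_one(self, rng):
        x = rng.integers(0, 2, 10_000).astype(float)
        res = lempel_ziv_complexity(x - 0.5 + 0.25)  # mean-split preserved
        assert 0.85 <= res.normalized <= 1.15

    def test_alternating_less_than_half_of_coin(self, rng):
        n = 4096
        alt = np.tile([0.0, 1.0], n // 2)
        coin = rng.integers(0, 2, n).astype(float)
        assert (lempel_ziv_complexity(alt).normalized
                < 0.5 * lempel_ziv_complexity(coin).normalized)

    def test_matches_bruteforce_on_all_short_strings(self):
        from breathdyn.dynamics import _lz76_count
        for length in range(1, 13):
            for v in range(2 ** length):
                bits = format(v, f"0{length}b")
                assert _lz76_count(bits.encode()) == lz76_bruteforce(bits), bits

    def test_binarization_tie_maps_to_one(self):
        # values equal to the mean count as "above"
        x = np.array([0.0, 2.0] * 16)  # mean 1.0; no value equals it
        y = np.array([1.0, 1.0, 0.0, 2.0] * 8)  # values equal to mean 1.0
        assert lempel_ziv_complexity(x).pattern_count >= 1
        assert lempel_ziv_complexity(y).pattern_count >= 1


class TestSampleEntropy:
    def test_matches_bruteforce_exactly(self, rng):
        for n in (50, 120, 200):
            x = rng.standard_normal(n)
            ours = sample_entropy(x)
            brute = sampen_bruteforce(x)
            assert ours == pytest.approx(brute, abs=1e-12)

    def test_ar1_matches_bruteforce(self):
        x = gen_ar1_series(0.8, 150, seed=9)
        assert sample_entropy(x) == pytest.approx(sampen_bruteforce(x), abs=1e-12)

    def test_period_two_alternation_is_zero(self):
        x = np.tile([1.0, -1.0], 100)
        assert sample_entropy(x) == pytest.approx(0.0, abs=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="zero-SD"):
            sample_entropy(np.ones(100))

    @given(st.floats(min_value=0.1, max_value=50.0),
           st.floats(min_value=-5.0, max_value=5.0))
    @settings(max_examples=15, deadline=None)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(77)
        x = rng.standard_normal(120)
        assert sample_entropy(a * x + b) == pytest.approx(sample_entropy(x), rel=1e-9)


class TestMultiscaleEntropy:
    def test_scale_one_equals_sample_entropy(self, rng):
        x = rng.standard_normal(300)
        prof = multiscale_entropy(x, MSEParams(scales=(1,)))
        assert prof.summary == pytest.approx(sample_entropy(x), abs=1e-12)

    def test_iid_profile_decreasing(self):
        # expectation property: average the per-scale profile over draws
        scales = tuple(range(1, 9))
        profs = [multiscale_entropy(np.random.default_rng(k).standard_normal(4000),
                                    MSEParams(scales=scales)).sampen
                 for k in range(5)]
        mean_prof = np.mean(profs, axis=0)
        assert np.all(np.diff(mean_prof) < 0)

    def test_pink_profile_flatter_than_white(self):
        white = gen_powerlaw_series(0.0, 2000, seed=5)
        pink = gen_powerlaw_series(1.0, 2000, seed=5)
        scales = tuple(range(1, 11))
        pw = multiscale_entropy(white, MSEParams(scales=scales)).sampen
        pp = multiscale_entropy(pink, MSEParams(scales=scales)).sampen
        assert np.ptp(pp[np.isfinite(pp)]) < np.ptp(pw[np.isfinite(pw)])

    def test_too_short_for_scales_rejected(self, rng):
        with pytest.raises(ValueError, match="too short"):
            multiscale_entropy(rng.standard_normal(50), MSEParams(scales=(10,)))

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(400)
        a = multiscale_entropy(3.0 * x + 2.0).summary
        b = multiscale_entropy(x).summary
        assert a == pytest.approx(b, rel=1e-9)


class TestComputeDynamics:
    def test_all_sixteen_features_populated(self, rng):
        series = make_breath_series(
            15 + rng.standard_normal(80), np.exp(rng.normal(0, 0.2, 80)))
        feats = compute_dynamics(series)
        assert set(feats) == set(FEATURE_COLUMNS)
        assert all(np.isfinite(v) for v in feats.values())

    def test_short_series_rejected(self, rng):
        series = make_breath_series(15 + rng.standard_normal(10), np.ones(10) + 0.1)
        with pytest.raises(ValueError, match="quality"):
            compute_dynamics(series)

    def test_error_carries_feature_name(self):
        series = make_breath_series(np.full(40, 15.0), np.full(40, 1.0))
        with pytest.raises(ValueError, match="_rate"):
            compute_dynamics(series)  # constant rate: zero variance metrics


def _table(values, sites=None, conditions=None):
    n = len(values)
    sites = sites or ["siteA"] * n
    conditions = conditions or ["rest"] * n
    rows = []
    for i, v in enumerate(values):
        row = {"subject": f"s{i}", "condition": conditions[i], "site": sites[i]}
        row.update({c: v[j % len(v)] if isinstance(v, (list, tuple)) else v
                    for j, c in enumerate(FEATURE_COLUMNS)})
        rows.append(row)
    return make_feature_table(rows)


class TestLogTransform:
    def test_ln_one_is_zero(self):
        t = log_transform_features(_table([1.0, 1.0, 1.0]))
        assert np.allclose(t.features.to_numpy(), 0.0)
        assert t.transform_state == "logged"

    def test_nonpositive_column_passed_through(self):
        table = _table([2.0, 3.0, 4.0])
        df = table.df.copy()
        df.loc[0, "psd_slope_rate"] = -0.3
        table = make_feature_table(df.to_dict("records"))
        with pytest.warns(UserWarning, match="untransformed"):
            t = log_transform_features(table)
        assert "psd_slope_rate" in t.untransformed
        assert t.df.loc[0, "psd_slope_rate"] == pytest.approx(-0.3)

    def test_exp_round_trip(self, rng):
        vals = rng.uniform(0.5, 4.0, size=5)
        table = _table(list(vals))
        t = log_transform_features(table)
        assert np.allclose(np.exp(t.features.to_numpy()),
                           table.features.to_numpy())


class TestHarmonizeSites:
    def test_single_site_identity(self, rng):
        table = _table(list(rng.uniform(1, 2, 6)))
        logged = log_transform_features(table)
        harm = harmonize_sites(logged)
        pd.testing.assert_frame_equal(harm.df, logged.df)

    def test_site_means_equalized(self, rng):
        vals = list(rng.uniform(1, 2, 4)) + list(rng.uniform(5, 6, 4))
        sites = ["siteA"] * 4 + ["siteB"] * 4
        logged = log_transform_features(_table(vals, sites=sites))
        harm = harmonize_sites(logged)
        for col in FEATURE_COLUMNS:
            a = harm.df.loc[harm.df["site"] == "siteA", col].mean()
            b = harm.df.loc[harm.df["site"] == "siteB", col].mean()
            grand = harm.df[col].mean()
            assert a == pytest.approx(grand, abs=1e-9)
            assert b == pytest.approx(grand, abs=1e-9)

    def test_between_site_variance_collapses(self, rng):
        n = 20
        base = rng.uniform(1, 2, 2 * n)
        vals = list(base[:n]) + list(base[n:] * 3.0)  # planted site offset
        sites = ["siteA"] * n + ["siteB"] * n
        logged = log_transform_features(_table(vals, sites=sites))
        harm = harmonize_sites(logged)
        for col in ("mean_rate",):
            def between_var(df):
                return df.groupby("site")[col].mean().var()
            assert between_var(harm.df) < 0.1 * between_var(logged.df)

    def test_small_site_rejected(self, rng):
        vals = list(rng.uniform(1, 2, 5))
        sites = ["siteA"] * 3 + ["siteB"] * 2
        logged = log_transform_features(_table(vals, sites=sites))
        with pytest.raises(ValueError, match="fewer than"):
            harmonize_sites(logged)

    def test_requires_logged_state(self, rng):
        with pytest.raises(ValueError, match="logged"):
            harmonize_sites(_table(list(rng.uniform(1, 2, 6))))


class TestMSEProfileExport:
    def test_long_format_scales(self):
        from breathdyn.pipeline import mse_profile_table
        from breathdyn.synthetic import SyntheticCohortSpec, gen_cohort
        bundle = gen_cohort(SyntheticCohortSpec(n_subjects=2, include_task=False,
                                                seed=8))
        df = mse_profile_table(bundle.recordings)
        assert list(df.columns) == ["subject", "condition", "scale", "sampen"]
        assert df.groupby("subject")["scale"].min().eq(1).all()
        # scale-1 value equals plain sample entropy of the rate series
        from breathdyn.dynamics import sample_entropy
        from breathdyn.preprocess import process_recording
        rec = bundle.recordings[0]
        s1 = df[(df.subject == rec.subject_id) & (df.scale == 1)]["sampen"].iloc[0]
        assert s1 == pytest.approx(sample_entropy(process_recording(rec).rate))
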