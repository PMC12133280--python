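"""Bias estimation chain: rates, clamping, smoothing, inversion."""

import warnings

import numpy as np
import pytest

import fraggc as fg
from fraggc.bias import (
    BiasTable,
    clamp_percentiles,
    correction_factors,
    fragment_rates,
    gc_only_correction,
    loess_smooth,
    normalize_and_smooth,
)
from fraggc.counting import CountMatrix, fixed_window_observed, fixed_window_expected


def _matrix(values):
    values = np.asarray(values, dtype=float)
    return CountMatrix(51, 51 + values.shape[0] - 1, values)


def _uniform_exp(n_lengths=5, value=1000.0):
    c = np.zeros((n_lengths, 101))
    c[:, 10:91] = value
    return _matrix(c)


class TestFragmentRates:
    def test_identical_matrices_give_unit_bias(self):
        exp = _uniform_exp()
        b = fragment_rates(exp, exp)
        defined = b.values[np.isfinite(b.values)]
        assert np.allclose(defined, 1.0)
        assert np.all(np.isnan(b.values[:, :10]))
        assert np.all(np.isnan(b.values[:, 91:]))

    def test_uniform_scaling_gives_flat_bias(self):
        exp = _uniform_exp()
        obs = _matrix(exp.counts * 2)
        b = fragment_rates(obs, exp)
        defined = b.values[np.isfinite(b.values)]
        assert np.allclose(defined, defined[0])  # flat; scale is arbitrary

    def test_low_support_bins_are_undefined(self):
        c = np.zeros((1, 101))
        c[0, 20:81] = 10_000.0
        c[0, 30] = 1.0  # far below 1e-3 of the row max
        exp = _matrix(c)
        obs = _matrix(np.where(c > 0, 5.0, 0.0))
        b = fragment_rates(obs, exp)
        assert np.isnan(b.values[0, 30])
        assert np.isfinite(b.values[0, 40])

    def test_bell_acceptance_curve_is_recovered_deterministically(self, tiny_genome):
        # noiseless construction: observed = expected * bell(g)
        exp = fg.expected_counts(
            tiny_genome["ref"], tiny_genome["regions"], lengths=(150, 160)
        )
        g = np.arange(101, dtype=float)
        bell = np.exp(-((g - 50.0) ** 2) / (2 * 10.0**2))
        obs = CountMatrix(150, 160, exp.counts * bell[None, :])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, final = fg.fit_correction(obs, exp)
        row = final.row(155)
        peak = np.nanargmax(row)
        assert abs(peak - 50) <= 2
        ok = np.isfinite(row[25:76])
        r = np.corrcoef(row[25:76][ok], bell[25:76][ok])[0, 1]
        assert r > 0.995


class TestClampPercentiles:
    def test_constant_table_is_unchanged(self):
        t = BiasTable(51, 55, np.full((5, 101), 2.0), stage="raw")
        out = clamp_percentiles(t)
        assert np.allclose(out.values, 2.0)

    def test_single_outlier_is_pulled_to_p97(self):
        rng = np.random.default_rng(3)
        vals = np.full((10, 101), np.nan)
        vals[:, 10:91] = 1.0 + 0.01 * rng.random((10, 81))
        vals[4, 50] = 1000.0
        t = BiasTable(51, 60, vals, stage="raw")
        out = clamp_percentiles(t)
        row = vals[4][np.isfinite(vals[4])]
        p97 = np.percentile(row, 97)  # brute-force oracle, linear interpolation
        assert out.values[4, 50] == pytest.approx(p97)
        assert np.nanmax(out.values[4]) <= p97

    def test_interior_order_is_preserved(self):
        vals = np.full((1, 101), np.nan)
        vals[0, 10:91] = np.linspace(1, 100, 81)
        t = BiasTable(51, 51, vals, stage="raw")
        out = clamp_percentiles(t)
        d = out.values[0, 10:91]
        assert np.all(np.diff(d) >= 0)
        assert d[0] == pytest.approx(np.percentile(vals[0, 10:91], 3))
        assert d[-1] == pytest.approx(np.percentile(vals[0, 10:91], 97))

    def test_sparse_table_warns(self):
        vals = np.full((1, 101), np.nan)
        vals[0, 40:50] = 1.0
        with pytest.warns(UserWarning, match="clamp"):
            clamp_percentiles(BiasTable(51, 51, vals, stage="raw"))


class TestNormalizeAndSmooth:
    def test_constant_row_becomes_unit(self):
        vals = np.full((1, 101), np.nan)
        vals[0, 10:91] = 7.0
        out = normalize_and_smooth(BiasTable(51, 51, vals, stage="clamped"))
        assert np.allclose(out.values[0, 20:81], 1.0)
        assert np.all(np.isnan(out.values[0, :20]))
        assert np.all(np.isnan(out.values[0, 81:]))

    def test_noiseless_quadratic_survives_smoothing(self):
        g = np.arange(101, dtype=float)
        quad = 1.0 + ((g - 50.0) / 40.0) ** 2
        vals = np.full((1, 101), np.nan)
        vals[0, 10:91] = quad[10:91]
        out = normalize_and_smooth(BiasTable(51, 51, vals, stage="clamped"))
        target = quad[20:81] / quad[20:81].mean()
        got = out.values[0, 20:81]
        rel = np.abs(got[5:56] - target[5:56]) / target[5:56]  # bins 25..75
        assert rel.max() < 0.02

    def test_final_row_mean_is_exactly_one(self, bell_sim):
        final = bell_sim["final"]
        for row in final.values:
            d = row[np.isfinite(row)]
            if d.size:
                assert abs(d.mean() - 1.0) < 1e-9

    def test_final_normalization_is_idempotent(self, bell_sim):
        vals = bell_sim["final"].values.copy()
        for row in vals:
            d = np.isfinite(row)
            if d.any():
                row[d] = row[d] / row[d].mean()
        assert np.allclose(
            vals[np.isfinite(vals)], bell_sim["final"].values[np.isfinite(vals)]
        )

    def test_thin_rows_pass_through_with_warning(self):
        vals = np.full((1, 101), np.nan)
        vals[0, [40, 60]] = [2.0, 4.0]
        with pytest.warns(UserWarning, match="unsmoothed"):
            out = normalize_and_smooth(BiasTable(51, 51, vals, stage="clamped"))
        d = out.values[0][np.isfinite(out.values[0])]
        assert d.size == 2
        assert d.mean() == pytest.approx(1.0)


class TestLoessSmoother:
    def test_unweighted_fit_matches_statsmodels_lowess(self):
        from statsmodels.nonparametric.smoothers_lowess import lowess

        rng = np.random.default_rng(5)
        x = np.arange(10, 91, dtype=float)
        y = np.sin(x / 20.0) + 0.05 * rng.standard_normal(x.size)
        xout = np.arange(20, 81, dtype=float)
        mine = loess_smooth(x, y, xout, frac=0.2)
        theirs = lowess(y, x, frac=0.2, it=0, xvals=xout)
        assert np.allclose(mine, theirs, atol=0.02)

    def test_weights_shift_fit_toward_heavy_points(self):
        x = np.array([0.0, 1, 2, 3, 4, 5, 6, 7, 8, 9])
        y = np.array([0.0, 0, 0, 0, 0, 10, 0, 0, 0, 0])
        w_flat = np.ones(10)
        w_down = np.ones(10)
        w_down[5] = 1e-6  # the spike carries almost no evidence
        at5_flat = loess_smooth(x, y, np.array([5.0]), frac=0.5, weights=w_flat)[0]
        at5_down = loess_smooth(x, y, np.array([5.0]), frac=0.5, weights=w_down)[0]
        assert at5_down < at5_flat


class TestCorrectionFactors:
    def test_inversion(self):
        vals = np.full((1, 101), np.nan)
        vals[0, 20:81] = 2.0
        t = correction_factors(BiasTable(51, 51, vals, stage="final"))
        assert np.allclose(t.factors[0, 20:81], 0.5)

    def test_cap_applies_at_default_twenty(self):
        vals = np.full((17, 101), np.nan)
        vals[:, 20:81] = 1.0  # 1037 defined entries
        vals[0, 50] = 0.01
        t = correction_factors(BiasTable(51, 67, vals, stage="final"))
        assert t.factors[0, 50] == 20.0
        assert t.cap == 20.0

    def test_extreme_samples_raise_the_cap_to_p99(self):
        vals = np.full((1, 101), np.nan)
        vals[0, 20:81] = 0.02  # all factors would be 50
        t = correction_factors(BiasTable(51, 51, vals, stage="final"))
        assert t.cap == pytest.approx(50.0)
        assert np.allclose(t.factors[0, 20:81], 50.0)

    def test_out_of_range_bins_are_zero_regardless_of_bias(self):
        vals = np.full((1, 101), 1.0)
        t = correction_factors(BiasTable(51, 51, vals, stage="final"))
        assert np.all(t.factors[0, :20] == 0)
        assert np.all(t.factors[0, 81:] == 0)
        assert t.factor(51, 10) == 0.0
        assert t.factor(51, 90) == 0.0

    def test_factors_are_finite_bounded_and_zero_outside_range(self, bell_sim):
        f = bell_sim["table"].factors
        assert np.all(np.isfinite(f))
        assert np.all(f >= 0)
        assert np.all(f <= bell_sim["table"].cap + 1e-12)
        assert np.all(f[:, :20] == 0)
        assert np.all(f[:, 81:] == 0)

    def test_csv_round_trip(self, tmp_path, bell_sim):
        path = str(tmp_path / "factors.csv")
        bell_sim["table"].to_csv(path)
        header = open(path).readline().strip().split(",")
        assert header[:3] == ["length", "0", "1"] and header[-1] == "100"
        back = fg.CorrectionTable.from_csv(path)
        assert np.allclose(back.factors, bell_sim["table"].factors, atol=1e-6)


class TestGCOnlyVariant:
    def test_length_invariant_bias_matches_per_length_chain(self):
        # same bias at all lengths, same window: the pooled single-curve
        # chain and the per-length chain agree up to smoothing tolerance
        g = np.arange(101, dtype=float)
        bell = np.exp(-((g - 50.0) ** 2) / (2 * 12.0**2))
        exp = np.zeros((21, 101))
        exp[:, 10:91] = 10_000.0
        obs = exp * bell[None, :]
        exp_m, obs_m = CountMatrix(100, 120, exp), CountMatrix(100, 120, obs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_len, _ = fg.fit_correction(obs_m, exp_m)
            pooled, _ = gc_only_correction(
                obs.sum(axis=0), exp.sum(axis=0), lengths=(100, 120)
            )
        a = per_len.factors[10, 25:76]
        b = pooled.factors[10, 25:76]
        assert np.allclose(a, b, rtol=0.05)

    def test_unbiased_sample_yields_flat_factors(self, small_sim):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            obs_curve = fixed_window_observed(
                small_sim["bam"], small_sim["ref"], small_sim["regions"]
            )
            exp_curve = fixed_window_expected(
                small_sim["ref"], small_sim["regions"], window=400
            )
            table, final = gc_only_correction(obs_curve, exp_curve)
        row = final.values[0]
        d = row[np.isfinite(row)]
        assert d.size > 30
        assert np.all(np.abs(d - 1.0) < 0.25)

    def test_length_specific_correction_beats_gc_only_under_length_bias(
        self, bell_sim
    ):
        # the fixed 400 bp window only weakly reflects each fragment's own
        # context GC, so the single broadcast curve corrects less than the
        # per-length chain even when the injected bias is length-invariant
        import fraggc.metrics as fm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            obs_curve = fixed_window_observed(
                bell_sim["bam"], bell_sim["ref"], bell_sim["regions"]
            )
            exp_curve = fixed_window_expected(
                bell_sim["ref"], bell_sim["regions"], window=400
            )
            gc_only, _ = gc_only_correction(obs_curve, exp_curve)
        worse = 0
        for grp in [(51, 100), (101, 150), (151, 250), (251, 400)]:
            q = fm.gc_density(bell_sim["exp"], grp)
            js_full = fm.js_divergence(
                fm.gc_density(bell_sim["obs"], grp, weights=bell_sim["table"]), q
            )
            js_gconly = fm.js_divergence(
                fm.gc_density(bell_sim["obs"], grp, weights=gc_only), q
            )
            if js_full < js_gconly:
                worse += 1
        assert worse >= 3  # per-length wins in (at least) most groups
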