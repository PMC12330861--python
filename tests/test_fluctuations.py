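"""Distribution-modeling toolkit: Morlet TFR, alpha-power series,
exponential and mixture fits, BIC/KS comparison, normalization,
cross-likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from alphaflux.containers import RegionTimeSeries
from alphaflux.fluctuations import (
    DegenerateInputError,
    PowerSeries,
    alpha_power_series,
    bic,
    compare_fits,
    cross_loglik,
    fit_alternatives,
    fit_biexponential,
    fit_exponential,
    ks_distance,
    morlet_tfr,
    normalize_power,
    power_histogram,
)


def _ps(values, dt=0.004):
    return PowerSeries(values=np.asarray(values, float), dt=dt)


# ------------------------------------------------------------------ TFR


class TestMorletTFR:
    def test_stationary_tone_row_is_constant(self, tone_ts):
        tfr = morlet_tfr(tone_ts)
        i = int(np.argmin(np.abs(tfr.freqs - 10.0)))
        row = tfr.power[i][tfr.valid[i]]
        assert row.std() / row.mean() < 1e-3

    def test_peak_row_matches_tone_frequency(self, tone_ts):
        tfr = morlet_tfr(tone_ts)
        common = tfr.valid.all(axis=0)
        means = tfr.power[:, common].mean(axis=1)
        assert tfr.freqs[np.argmax(means)] == pytest.approx(10.0, abs=0.25)

    def test_tone_peak_power_constant_documented(self, tone_ts):
        """The wavelet convention yields a stable peak value for a
        unit-amplitude tone; freeze it as the package's amplitude
        reference (value measured from this fixture)."""
        tfr = morlet_tfr(tone_ts)
        i = int(np.argmin(np.abs(tfr.freqs - 10.0)))
        peak = tfr.power[i][tfr.valid[i]].mean()
        assert peak == pytest.approx(49.366, rel=1e-3)

    def test_white_noise_bandpower_matches_parseval_oracle(self, rng):
        """Mean TFR power per row equals the input periodogram filtered
        by the wavelet's squared frequency response (direct FFT
        evaluation, independent of the convolution path)."""
        from mne.time_frequency import morlet as mne_morlet

        fs = 250.0
        x = rng.standard_normal(int(60 * fs))
        ts = RegionTimeSeries(x[None, :], fs=fs)
        tfr = morlet_tfr(ts)
        Xp = np.abs(np.fft.fft(x)) ** 2
        for fi in (20, 60, 120):
            W = mne_morlet(fs, [tfr.freqs[fi]], n_cycles=7.0, zero_mean=False)[0]
            pred = np.sum(np.abs(np.fft.fft(W, x.size)) ** 2 * Xp) / x.size**2
            meas = tfr.power[fi][tfr.valid[fi]].mean()
            assert meas == pytest.approx(pred, rel=0.10)

    def test_too_short_signal_rejected(self):
        ts = RegionTimeSeries(np.zeros((1, 200)), fs=250.0)
        with pytest.raises(ValueError):
            morlet_tfr(ts)  # shorter than the 3.5 s wavelet at 2 Hz

    def test_low_sampling_rate_rejected(self, tone_ts):
        ts = RegionTimeSeries(tone_ts.data, fs=60.0)
        with pytest.raises(ValueError):
            morlet_tfr(ts)


class TestAlphaPowerSeries:
    class _TFR:
        def __init__(self, freqs, power, times, valid=None, fs=250.0):
            self.freqs, self.power, self.times, self.fs = freqs, power, times, fs
            self.valid = np.ones_like(power, bool) if valid is None else valid

    def _mk(self, power):
        freqs = np.arange(2, 40.01, 0.25)
        times = np.arange(power.shape[1]) / 250.0
        return self._TFR(freqs, power, times)

    def test_constant_tfr_gives_constant_series(self):
        tfr = self._mk(np.full((153, 100), 7.0))
        ps = alpha_power_series(tfr, iaf=10.0, scale=1.0)
        np.testing.assert_allclose(ps.values, 7.0)

    def test_halfwidth_zero_extracts_single_row(self, rng):
        power = rng.uniform(1, 2, (153, 50))
        tfr = self._mk(power)
        ps = alpha_power_series(tfr, iaf=10.0, halfwidth=0.0)
        i = int(np.argmin(np.abs(tfr.freqs - 10.0)))
        np.testing.assert_allclose(ps.values, power[i])

    def test_matches_band_mean_oracle(self, rng):
        power = rng.uniform(1, 2, (153, 50))
        tfr = self._mk(power)
        ps = alpha_power_series(tfr, iaf=10.0, halfwidth=2.0)
        band = np.abs(tfr.freqs - 10.0) <= 2.0
        np.testing.assert_allclose(ps.values, power[band].mean(axis=0))

    def test_scale_factor_applied(self):
        tfr = self._mk(np.full((153, 50), 2.0))
        ps = alpha_power_series(tfr, iaf=10.0, scale=1e-19)
        np.testing.assert_allclose(ps.values, 2e-19)
        assert ps.scale_applied == 1e-19

    def test_band_outside_grid_rejected(self):
        tfr = self._mk(np.ones((153, 10)))
        with pytest.raises(ValueError):
            alpha_power_series(tfr, iaf=60.0)


class TestPowerHistogram:
    def test_uniform_values_fill_bins_evenly(self):
        ps = _ps(np.linspace(0, 1, 4000))
        h = power_histogram(ps, n_bins=200)
        assert h.counts.sum() == 4000
        assert h.counts.min() >= 15 and h.counts.max() <= 25

    def test_counts_conserved(self, rng):
        ps = _ps(rng.exponential(1.0, 5000))
        assert power_histogram(ps).counts.sum() == 5000

    def test_exponential_density_matches_theory(self, rng):
        lam = 2.0
        ps = _ps(rng.exponential(1 / lam, 200_000))
        h = power_histogram(ps)
        sel = h.centers < np.quantile(ps.values, 0.99)
        theory = lam * np.exp(-lam * h.centers[sel])
        assert np.corrcoef(h.density[sel], theory)[0, 1] > 0.999

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            power_histogram(_ps(np.full(500, 3.0)))


# ------------------------------------------------------------- fitting


class TestExponentialFit:
    def test_constant_values_closed_form(self):
        fit = fit_exponential(_ps(np.full(100, 4.0)))
        assert fit.lam == pytest.approx(0.25)

    def test_rate_recovery_within_one_percent(self):
        rng = np.random.default_rng(7)
        fit = fit_exponential(rng.exponential(1 / 2.0, 100_000))
        assert fit.lam == pytest.approx(2.0, rel=0.01)

    def test_loglik_matches_brute_force(self, rng):
        x = rng.exponential(0.5, 2000)
        fit = fit_exponential(x)
        brute = np.sum(np.log(fit.lam) - fit.lam * x)
        assert fit.loglik == pytest.approx(brute, rel=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_exponential(np.zeros(50))


class TestBiexponentialFit:
    def test_parameter_recovery(self):
        """Well-separated mixture (w=0.3, lam1=5, lam2=0.5) recovered
        within 5% relative error at n = 2e5."""
        rng = np.random.default_rng(42)
        n = 200_000
        hot = rng.random(n) < 0.3
        x = np.where(hot, rng.exponential(1 / 5.0, n), rng.exponential(1 / 0.5, n))
        fit = fit_biexponential(x)
        assert fit.w == pytest.approx(0.3, rel=0.05)
        assert fit.lam1 == pytest.approx(5.0, rel=0.05)
        assert fit.lam2 == pytest.approx(0.5, rel=0.05)
        assert fit.lam1 > fit.lam2

    def test_nesting_loglik_never_below_unimodal(self, rng):
        for _ in range(5):
            x = rng.exponential(1.0, 2000)
            uni = fit_exponential(x)
            bi = fit_biexponential(x)
            assert bi.loglik >= uni.loglik - 1e-6 * abs(uni.loglik)

    def test_single_component_limit_recovers_unimodal_rate(self, rng):
        x = rng.exponential(1 / 3.0, 50_000)
        fit = fit_biexponential(x)
        uni_lam = fit_exponential(x).lam
        # mixture mean rate must match; components may split around it
        mix_mean = fit.w / fit.lam1 + (1 - fit.w) / fit.lam2
        assert 1.0 / mix_mean == pytest.approx(uni_lam, rel=0.01)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_biexponential(np.ones(5))


class TestBIC:
    def test_reference_values(self):
        assert bic(0.0, 1, 1) == 0.0
        assert bic(0.0, 3, int(np.e**1)) == pytest.approx(3 * np.log(int(np.e)))

    @given(st.floats(-1e5, 1e5), st.integers(1, 5), st.integers(1, 10**7))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_formula(self, ll, k, n):
        assert bic(ll, k, n) == pytest.approx(k * np.log(n) - 2 * ll)

    def test_model_selection_on_fits(self, rng):
        x = rng.exponential(1.0, 20_000)
        uni, bi_fit = fit_exponential(x), fit_biexponential(x)
        assert bic(uni.loglik, 1, uni.n) == pytest.approx(
            1 * np.log(x.size) - 2 * uni.loglik
        )
        assert bic(bi_fit.loglik, 3, bi_fit.n) >= bic(uni.loglik, 1, uni.n) - 1e-9


def _ks_brute_force(x, cdf):
    """Two-loop sup over the empirical step function."""
    xs = np.sort(x)
    n = xs.size
    d = 0.0
    for i, v in enumerate(xs):
        F = cdf(np.array([v]))[0] if callable(cdf) else cdf(v)
        d = max(d, abs((i + 1) / n - F), abs(i / n - F))
    return d


class TestKSDistance:
    def test_exact_quantile_placement(self):
        """Points at F^-1((i-0.5)/n) give D = 1/(2n) exactly."""
        lam, n = 1.5, 64
        q = (np.arange(1, n + 1) - 0.5) / n
        x = -np.log(1 - q) / lam
        cdf = lambda v: 1 - np.exp(-lam * np.asarray(v))  # noqa: E731
        res = ks_distance(x, cdf)
        assert res["D"] == pytest.approx(1 / (2 * n), abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            x = rng.exponential(1.0, 200)
            fit = fit_exponential(x)
            res = ks_distance(x, fit.cdf)
            assert res["D"] == pytest.approx(_ks_brute_force(x, fit.cdf), abs=1e-12)

    @given(st.lists(st.floats(0.001, 50.0), min_size=3, max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_and_oracle_exact(self, values):
        x = np.asarray(values)
        fit = fit_exponential(x)
        res = ks_distance(x, fit.cdf)
        assert 0.0 <= res["D"] <= 1.0
        assert res["D"] == pytest.approx(_ks_brute_force(x, fit.cdf), abs=1e-12)

    def test_flags_estimated_params(self, rng):
        x = rng.exponential(1.0, 100)
        assert ks_distance(x, fit_exponential(x).cdf)["estimated_params"]


class TestAlternativeFits:
    def test_gamma_shape_near_one_on_exponential_data(self, rng):
        x = rng.exponential(1.0, 50_000)
        alts = fit_alternatives(x)
        assert alts["gamma"]["params"][0] == pytest.approx(1.0, abs=0.05)

    def test_lognormal_wins_on_lognormal_data(self, rng):
        x = rng.lognormal(0.0, 0.8, 50_000)
        alts = fit_alternatives(x)
        d_exp = ks_distance(x, fit_exponential(x).cdf)["D"]
        assert alts["lognormal"]["ksd"]["D"] < d_exp

    def test_constant_data_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_alternatives(np.full(100, 2.0))

    def test_nonpositive_values_filtered_for_lognormal(self, rng):
        x = np.concatenate([rng.exponential(1.0, 1000), [0.0]])
        with pytest.warns(UserWarning, match="non-positive"):
            alts = fit_alternatives(x)
        assert np.isfinite(alts["lognormal"]["loglik"])


class TestCompareFits:
    def test_unimodal_data_prefers_unimodal(self, rng):
        comp = compare_fits(rng.exponential(1.0, 50_000))
        assert comp.best == "unimodal"
        assert comp.delta_bic < 0

    def test_separated_mixture_prefers_bimodal(self, rng):
        n = 50_000
        hot = rng.random(n) < 0.4
        x = np.where(hot, rng.exponential(1 / 5.0, n), rng.exponential(1 / 0.5, n))
        comp = compare_fits(x)
        assert comp.best == "bimodal"
        assert comp.delta_bic > 10

    def test_delta_bic_sign_convention(self, rng):
        comp = compare_fits(rng.exponential(1.0, 5000))
        assert comp.delta_bic == pytest.approx(comp.bic_uni - comp.bic_bi)

    def test_model_selection_consistency(self):
        """BIC picks the true family in >= 95% of seeded runs for both
        generators (unimodal exponential; well-separated mixture).
        Reduced seed count here; the full 100-seed study runs in the
        acceptance suite."""
        n_runs, n = 30, 100_000
        uni_correct = bi_correct = 0
        for s in range(n_runs):
            rng = np.random.default_rng(1000 + s)
            if compare_fits(rng.exponential(1.0, n)).best == "unimodal":
                uni_correct += 1
            rng = np.random.default_rng(5000 + s)
            hot = rng.random(20_000) < 0.5
            x = np.where(hot, rng.exponential(1 / 5.0, 20_000),
                         rng.exponential(1.0, 20_000))
            if compare_fits(x).best == "bimodal":
                bi_correct += 1
        assert uni_correct >= int(np.ceil(0.95 * n_runs))
        assert bi_correct >= int(np.ceil(0.95 * n_runs))


class TestNormalizeAndCrossLikelihood:
    def test_normalization_sets_unit_rate(self, rng):
        ps = normalize_power(_ps(rng.exponential(7.3, 10_000)))
        assert fit_exponential(ps).lam == pytest.approx(1.0, rel=1e-9)

    def test_normalization_idempotent(self, rng):
        ps = _ps(rng.exponential(2.0, 1000))
        once = normalize_power(ps)
        twice = normalize_power(once)
        np.testing.assert_allclose(once.values, twice.values)

    def test_scale_equivariance_of_fits(self, rng):
        """Scaling the series by c scales lam by 1/c and leaves KSD and
        delta BIC unchanged."""
        x = rng.exponential(1.0, 20_000)
        c = 37.0
        f1, f2 = fit_exponential(x), fit_exponential(c * x)
        assert f2.lam == pytest.approx(f1.lam / c, rel=1e-9)
        assert ks_distance(c * x, f2.cdf)["D"] == pytest.approx(
            ks_distance(x, f1.cdf)["D"], abs=1e-9
        )
        d1, d2 = compare_fits(x).delta_bic, compare_fits(c * x).delta_bic
        assert d2 == pytest.approx(d1, abs=0.2)

    def test_cross_loglik_identity(self, rng):
        x = rng.exponential(1.0, 5000)
        fit = fit_exponential(x)
        assert cross_loglik(x, fit) == pytest.approx(fit.loglik, rel=1e-12)

    def test_cross_loglik_analytic_expectation(self):
        """Series drawn from the reference itself: per-sample expected
        value is ln(lam) - 1."""
        lam_ref = 2.5
        vals = []
        for s in range(20):
            rng = np.random.default_rng(s)
            x = rng.exponential(1 / lam_ref, 20_000)
            ref = fit_exponential(np.asarray(x))
            vals.append(cross_loglik(x, ref) / x.size)
        assert np.mean(vals) == pytest.approx(np.log(lam_ref) - 1.0, abs=0.01)

    def test_constant_high_power_scores_far_below_matched(self, rng):
        """A limit-cycle-like series (constant high power) is far less
        plausible under the reference than matched samples."""
        ref = fit_exponential(rng.exponential(1.0, 50_000))
        matched = cross_loglik(rng.exponential(1.0, 1000), ref) / 1000
        constant = cross_loglik(np.full(1000, 50.0), ref) / 1000
        assert constant < matched - 10
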