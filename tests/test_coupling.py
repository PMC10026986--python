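"""Directional brain-heart coupling estimators (both directions)."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from svsdg.coupling import (
    BrainHeartModel,
    HeartToBrainFit,
    brain_to_heart_coupling,
    estimate_modulation,
    fit_brain_to_heart,
    fit_heart_to_brain,
    heart_to_brain_coupling,
)
from svsdg.series import AutonomicSeries, BandPowerSeries, ModulationSeries, RRSeries
from svsdg.synthetic import synthesize_rr_integrate_and_fire


def autonomic_on_grid(grid, sai, pai):
    return AutonomicSeries(beat_times=grid, sai=sai, pai=pai)


def single_band_power(grid, values, channel="Cz", band="alpha"):
    return BandPowerSeries(grid, (channel,), (band,), np.asarray(values)[:, None, None])


class TestModulation:
    def test_constant_rr_gives_zero_modulation(self):
        rr = RRSeries.from_intervals(np.full(100, 0.8))
        grid = np.arange(5.0, 70.0)
        m = estimate_modulation(rr, grid)
        assert np.allclose(m.baseline, 1.25, atol=1e-9)
        assert np.allclose(m.m, 0.0, atol=1e-9)

    def test_grid_beyond_coverage_rejected(self):
        rr = RRSeries.from_intervals(np.full(20, 0.8))
        with pytest.raises(ValueError, match="coverage"):
            estimate_modulation(rr, np.arange(0.0, 30.0))

    def test_integrate_and_fire_round_trip(self):
        """A sinusoidal rate modulation fed through the heartbeat generator is
        recovered from the RR series with correlation >= 0.95."""
        t = np.arange(0.0, 300.5, 1.0)  # endpoints included: 301 samples
        m_true = 0.2 * np.sin(2 * np.pi * 0.1 * t)
        rr = synthesize_rr_integrate_and_fire(m_true, 1.1, 300.0)
        grid = np.arange(2.0, 298.0)
        m_est = estimate_modulation(rr, grid)
        c = np.corrcoef(m_est.m, 0.2 * np.sin(2 * np.pi * 0.1 * grid))[0, 1]
        assert c >= 0.95


class TestBrainToHeart:
    def test_noiseless_identifiability_exact(self, rng):
        grid = np.arange(120.0)
        sai = 40 + gaussian_filter1d(rng.standard_normal(120), 2) * 3
        pai = 45 + gaussian_filter1d(rng.standard_normal(120), 2) * 3
        m = ModulationSeries(grid, rate=2.0 * sai, baseline=np.zeros(120), window_s=15)
        fit = fit_brain_to_heart(m, autonomic_on_grid(grid, sai, pai))
        ok = fit.valid
        assert ok.any()
        assert np.max(np.abs(fit.c_sai[ok] - 2.0)) < 1e-8
        assert np.max(np.abs(fit.c_pai[ok])) < 1e-8

    def test_windowed_estimates_unbiased_under_noise(self, rng):
        grid = np.arange(600.0)
        sai = 40 + gaussian_filter1d(rng.standard_normal(600), 2) * 3
        pai = 45 + gaussian_filter1d(rng.standard_normal(600), 2) * 3
        signal = 2.0 * sai + 0.5 * pai
        noise = rng.normal(0, 0.1 * signal.std(), 600)
        m = ModulationSeries(grid, rate=signal + noise, baseline=np.zeros(600), window_s=15)
        fit = fit_brain_to_heart(m, autonomic_on_grid(grid, sai, pai))
        assert abs(np.mean(fit.c_sai[fit.valid]) - 2.0) < 0.1  # within 5%
        assert abs(np.mean(fit.c_pai[fit.valid]) - 0.5) < 0.1

    def test_collinear_window_masked(self):
        grid = np.arange(60.0)
        sai = 40 + np.sin(grid / 5)
        pai = 2.0 * sai  # exactly proportional
        m = ModulationSeries(grid, rate=sai.copy(), baseline=np.zeros(60), window_s=15)
        fit = fit_brain_to_heart(m, autonomic_on_grid(grid, sai, pai))
        assert not fit.valid.any()

    def test_coupling_ratio_unit_denominator(self, rng):
        grid = np.arange(60.0)
        sai = 40 + gaussian_filter1d(rng.standard_normal(60), 2)
        pai = 45 + gaussian_filter1d(rng.standard_normal(60), 2)
        m = ModulationSeries(grid, rate=1.5 * sai, baseline=np.zeros(60), window_s=15)
        fit = fit_brain_to_heart(m, autonomic_on_grid(grid, sai, pai))
        bp = single_band_power(grid, np.ones(60))
        cs = brain_to_heart_coupling(fit, bp, "alpha", "Cz", "SAI")
        ok = cs.valid
        assert np.allclose(cs.sdg[ok], fit.c_sai[fit.valid & ok[: fit.valid.size]][: ok.sum()], atol=1e-9)

    def test_coupling_ratio_matches_elementwise_division(self, rng):
        grid = np.arange(80.0)
        sai = 40 + gaussian_filter1d(rng.standard_normal(80), 2) * 2
        pai = 45 + gaussian_filter1d(rng.standard_normal(80), 2) * 2
        m = ModulationSeries(grid, rate=sai + 0.5 * pai, baseline=np.zeros(80), window_s=15)
        fit = fit_brain_to_heart(m, autonomic_on_grid(grid, sai, pai))
        power = 5 + rng.random(80)
        bp = single_band_power(grid, power)
        cs = brain_to_heart_coupling(fit, bp, "alpha", "Cz", "PAI")
        step = grid[1] - grid[0]
        for i in np.flatnonzero(cs.valid)[:20]:
            t = cs.grid[i]
            j = int(round(t - step - grid[0]))
            assert cs.sdg[i] == pytest.approx(fit.c_pai[i] / power[j], rel=1e-12)

    def test_zero_coefficients_give_zero_sdg(self):
        grid = np.arange(40.0)
        from svsdg.coupling import BrainToHeartFit

        fit = BrainToHeartFit(
            grid=grid, c_sai=np.zeros(40), c_pai=np.zeros(40),
            valid=np.ones(40, bool), window_s=15.0,
        )
        bp = single_band_power(grid, 1 + np.arange(40.0))
        cs = brain_to_heart_coupling(fit, bp, "alpha", "Cz", "SAI")
        assert np.allclose(cs.sdg[cs.valid], 0.0)


class TestHeartToBrain:
    def test_ar1_kappa_recovery(self, rng):
        """Pure zero-mean AR(1), kappa = 0.7, noise sd 0.05, n = 300."""
        n = 300
        y = np.zeros(n)
        eps = rng.normal(0, 0.05, n)
        for i in range(1, n):
            y[i] = 0.7 * y[i - 1] + eps[i]
        fit = fit_heart_to_brain(y, window_s=n - 1)
        assert abs(fit.kappa[0] - 0.7) <= 0.05

    def test_residual_identity_constant_power(self):
        grid = np.arange(40.0)
        bp = single_band_power(grid, np.full(40, 7.5))
        fit = fit_heart_to_brain(bp, "alpha", "Cz")
        ok = fit.psi_valid
        y = bp.series("Cz", "alpha")
        kap = fit.kappa[np.clip(np.round(fit.psi_grid - fit.kappa_grid[0]).astype(int),
                                0, fit.kappa.size - 1)]
        recon = kap * y[:-1] + fit.psi
        assert np.allclose(recon[ok], y[1:][ok], atol=1e-12)

    def test_zero_power_window_masked(self):
        grid = np.arange(40.0)
        bp = single_band_power(grid, np.zeros(40) + 0.0)
        fit = fit_heart_to_brain(bp, "alpha", "Cz")
        assert not fit.kappa_valid.any()

    def test_planted_drive_recovery(self, rng):
        """EEG generated with a heart drive 0.3*SAI on kappa = 0.7 yields a
        residual drive estimate correlating >= 0.9 with the planted drive."""
        n = 800
        grid = np.arange(float(n))
        sai = 45 + rng.normal(0, 6.0, n)
        drive = 0.3 * sai
        eps = rng.normal(0, 0.01, n)
        y = np.empty(n)
        y[0] = drive[0] / 0.3
        for i in range(1, n):
            y[i] = 0.7 * y[i - 1] + drive[i - 1] + eps[i]
        bp = single_band_power(grid, y)
        fit = fit_heart_to_brain(bp, "alpha", "Cz", window_s=120)
        ok = fit.psi_valid
        c = np.corrcoef(fit.psi[ok], drive[:-1][ok])[0, 1]
        assert c >= 0.9

    def test_sdg_with_unit_index_equals_drive(self):
        grid = np.arange(30.0)
        psi = np.sin(grid / 3)
        fit = HeartToBrainFit(
            band="alpha", channel="Cz", kappa_grid=grid, kappa=np.full(30, 0.7),
            kappa_valid=np.ones(30, bool), psi_grid=grid, psi=psi,
            psi_valid=np.ones(30, bool), window_s=15.0,
        )
        au = autonomic_on_grid(grid, np.ones(30), np.ones(30))
        cs = heart_to_brain_coupling(fit, au, "SAI")
        assert np.allclose(cs.sdg[cs.valid], psi[cs.valid])

    def test_sdg_constant_gain_construction(self):
        """Planted Psi = 0.3 * X gives sdg = 0.3 at every valid point."""
        grid = np.arange(50.0)
        x = 40 + np.sin(grid / 4)
        fit = HeartToBrainFit(
            band="alpha", channel="Cz", kappa_grid=grid, kappa=np.full(50, 0.7),
            kappa_valid=np.ones(50, bool), psi_grid=grid, psi=0.3 * x,
            psi_valid=np.ones(50, bool), window_s=15.0,
        )
        au = autonomic_on_grid(grid, x, x)
        cs = heart_to_brain_coupling(fit, au, "SAI")
        assert cs.valid.all()
        assert np.allclose(cs.sdg, 0.3, atol=1e-12)

    def test_zero_drive_gives_zero_sdg(self):
        grid = np.arange(30.0)
        fit = HeartToBrainFit(
            band="alpha", channel="Cz", kappa_grid=grid, kappa=np.full(30, 0.7),
            kappa_valid=np.ones(30, bool), psi_grid=grid, psi=np.zeros(30),
            psi_valid=np.ones(30, bool), window_s=15.0,
        )
        au = autonomic_on_grid(grid, 40 + np.sin(grid), 40 + np.cos(grid))
        cs = heart_to_brain_coupling(fit, au, "PAI")
        assert np.allclose(cs.sdg[cs.valid], 0.0)


class TestRoundTripAndControls:
    def test_grid_level_round_trip(self, rng):
        """Coupled data with known slowly varying C_SAI(t), C_PAI(t), kappa
        and a constant heart-drive gain: the pipeline recovers the C's with
        correlation >= 0.8, kappa within 0.05 and the gain within 10%."""
        n = 900
        grid = np.arange(float(n))
        sai = 42 + gaussian_filter1d(rng.standard_normal(n), 2) * 3
        pai = 47 + gaussian_filter1d(rng.standard_normal(n), 2) * 3

        def slow(scale):  # slow unit-sd process (C varies little within a window)
            x = gaussian_filter1d(rng.standard_normal(n), 40)
            return scale * x / x.std()

        c_sai = 1.0 + slow(2.0)
        c_pai = -1.0 + slow(2.0)
        # the modulation couples to the autonomic *fluctuations* (m is a
        # fluctuation about baseline by construction)
        m_sig = c_sai * (sai - sai.mean()) + c_pai * (pai - pai.mean())
        noise = rng.normal(0, 0.05 * m_sig.std(), n)
        m = ModulationSeries(grid, rate=m_sig + noise, baseline=np.zeros(n), window_s=15)
        fit = fit_brain_to_heart(m, autonomic_on_grid(grid, sai, pai))
        ok = fit.valid
        cs_t = np.interp(fit.grid, grid, c_sai)
        cp_t = np.interp(fit.grid, grid, c_pai)
        assert np.corrcoef(fit.c_sai[ok], cs_t[ok])[0, 1] >= 0.8
        assert np.corrcoef(fit.c_pai[ok], cp_t[ok])[0, 1] >= 0.8
        # ascending side: zero-mean AR(1) fluctuation with constant gain drive
        # (white autonomic fluctuation: an autocorrelated drive is partially
        # absorbed into kappa by the lag-1 fit, which is a property of the
        # as-printed estimator)
        gain = 0.25
        sai_w = 45 + rng.normal(0, 4.0, n)
        drive = gain * (sai_w - sai_w.mean())
        eps = rng.normal(0, 0.1, n)
        y = np.zeros(n)
        for i in range(1, n):
            y[i] = 0.7 * y[i - 1] + drive[i - 1] + eps[i]
        h = fit_heart_to_brain(y, window_s=n - 1)
        assert abs(h.kappa[0] - 0.7) <= 0.05
        slope = np.polyfit((sai_w - sai_w.mean())[:-1][h.psi_valid], h.psi[h.psi_valid], 1)[0]
        assert abs(slope - gain) / gain <= 0.10

    def test_directionality_control_against_surrogates(self, rng):
        """With no planted heart drive, the ascending coupling MAD does not
        exceed the noise floor set by time-shifted surrogates (95th pct)."""
        n = 300
        grid = np.arange(float(n))
        y = np.empty(n)
        y[0] = 10.0
        eps = rng.normal(0, 0.5, n)
        for i in range(1, n):
            y[i] = 0.7 * y[i - 1] + 3.0 + eps[i]
        bp = single_band_power(grid, y)
        fit = fit_heart_to_brain(bp, "alpha", "Cz")
        sai = 45 + gaussian_filter1d(rng.standard_normal(n), 3) * 2
        au = autonomic_on_grid(grid, sai, sai)
        cs = heart_to_brain_coupling(fit, au, "SAI")
        def _mad(v):
            return float(np.median(np.abs(v - np.median(v))))
        observed = _mad(cs.valid_values())
        floor = []
        for shift in range(1, 101):
            sai_s = np.roll(sai, shift * 2)
            au_s = autonomic_on_grid(grid, sai_s, sai_s)
            floor.append(_mad(heart_to_brain_coupling(fit, au_s, "SAI").valid_values()))
        assert observed <= np.percentile(floor, 95)

    def test_masked_points_never_enter_condensations(self):
        grid = np.arange(30.0)
        from svsdg.series import CouplingSeries

        sdg = np.concatenate([np.ones(15), np.full(15, np.nan)])
        cs = CouplingSeries(
            "heart_to_brain", "SAI", "alpha", "Cz", grid, sdg,
            valid=np.concatenate([np.ones(15, bool), np.zeros(15, bool)]),
        )
        assert cs.valid_values().size == 15
        assert np.isfinite(cs.valid_values()).all()


def test_model_facade_produces_full_series_set(rng):
    from svsdg.synthetic import SyntheticConfig, generate_protocol_dataset

    cfg = SyntheticConfig(n_subjects=1, seed=9).scaled(1, 90.0, channels=("Cz", "Fz"), rest_s=90)
    ds = generate_protocol_dataset(cfg)
    s = ds.subjects[0]
    res = BrainHeartModel(s.full_rr(), s.bandpower["stress1"],
                          autonomic=s.truth.autonomic).fit()
    assert res.n_series == 2 * 2 * 5 * 2
    assert "coupling series" in res.summary()
    df = res.to_frame()
    assert set(df["direction"]) == {"heart_to_brain", "brain_to_heart"}
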