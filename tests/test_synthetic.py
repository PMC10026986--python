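"""Protocol generator and its elementary forward models."""

import logging

import numpy as np
import pytest

from svsdg.laguerre import convolve_rr
from svsdg.series import RRSeries
from svsdg.synthetic import (
    SyntheticConfig,
    generate_protocol_dataset,
    surrogate_stress_reports,
    synthesize_bandpower,
    synthesize_rr_from_coeffs,
    synthesize_rr_integrate_and_fire,
)


class TestIntegrateAndFire:
    def test_constant_rate_exact_intervals(self):
        rr = synthesize_rr_integrate_and_fire(np.zeros(11), 1.0, 10.0)
        assert np.allclose(rr.intervals, 1.0, atol=1e-12)
        assert rr.intervals.size == 10

    def test_constant_modulation_closed_form(self):
        # RR = 1 / (mu + c)
        rr = synthesize_rr_integrate_and_fire(np.full(11, 0.25), 1.0, 10.0)
        assert np.allclose(rr.intervals, 0.8, atol=1e-12)

    def test_beat_count_matches_rate_integral(self):
        """Sinusoidal modulation: beat count within +-1 of the integral of
        the instantaneous rate (numeric quadrature oracle)."""
        t = np.arange(0.0, 300.5, 1.0)
        m = 0.2 * np.sin(2 * np.pi * 0.1 * t)
        rr = synthesize_rr_integrate_and_fire(m, 1.1, 300.0)
        expected = np.trapezoid(1.1 + m, t)
        assert abs(rr.intervals.size - expected) <= 1.0

    def test_callable_modulation(self):
        rr = synthesize_rr_integrate_and_fire(lambda t: 0.0, 1.25, 8.0)
        assert np.allclose(rr.intervals, 0.8, atol=1e-9)

    def test_non_positive_rate_names_offending_time(self):
        m = np.zeros(21)
        m[10] = -2.0  # rate crosses zero at t = 10 s
        with pytest.raises(ValueError, match="t = 10"):
            synthesize_rr_integrate_and_fire(m, 1.0, 20.0)


class TestCoefficientGenerator:
    def test_degenerate_model_constant_intervals(self, basis):
        rr = synthesize_rr_from_coeffs(0.8, np.zeros(9), basis,
                                       init_intervals=[0.8], n_beats=20)
        assert np.allclose(rr.intervals, 0.8, atol=1e-12)

    def test_self_consistency_oracle(self, basis):
        """Regenerating the regressors from the output and applying the
        expansion model reproduces each generated interval exactly."""
        g0, g1 = 0.3, np.full(9, 0.4)
        init = [0.85] * 10
        rr = synthesize_rr_from_coeffs(g0, g1, basis, init, obs_noise_sd=0.0,
                                       n_beats=60)
        L = convolve_rr(rr, basis)
        x = rr.intervals
        for k in range(len(init), x.size):
            assert x[k] == pytest.approx(g0 + g1 @ L[k - 1], abs=1e-10)

    def test_seed_determinism(self, basis):
        a = synthesize_rr_from_coeffs(0.3, np.full(9, 0.4), basis, [0.85] * 10,
                                      obs_noise_sd=0.01, n_beats=50, rng=42)
        b = synthesize_rr_from_coeffs(0.3, np.full(9, 0.4), basis, [0.85] * 10,
                                      obs_noise_sd=0.01, n_beats=50, rng=42)
        assert np.array_equal(a.intervals, b.intervals)

    def test_infeasible_configuration_raises(self, basis):
        with pytest.raises(ValueError, match="infeasible"):
            synthesize_rr_from_coeffs(-0.5, np.zeros(9), basis, [0.8], n_beats=5)


class TestBandpowerGenerator:
    def test_kappa_one_no_innovation_is_constant(self):
        grid = np.arange(20.0)
        bp = synthesize_bandpower(1.0, np.zeros(19), 0.0, grid, start_power=5.0)
        assert np.allclose(bp.power, 5.0)

    def test_kappa_zero_drops_to_zero(self):
        grid = np.arange(10.0)
        bp = synthesize_bandpower(0.0, np.zeros(9), 0.0, grid, start_power=5.0)
        assert np.allclose(bp.power[1:, 0, 0], 0.0)

    def test_negative_power_floored_and_logged(self, caplog):
        grid = np.arange(30.0)
        with caplog.at_level(logging.INFO, logger="svsdg.synthetic"):
            bp = synthesize_bandpower(0.5, np.full(29, -1.0), 0.0, grid,
                                      start_power=0.5)
        assert np.min(bp.power) == pytest.approx(1e-6)
        assert any("floored" in r.message for r in caplog.records)

    def test_non_uniform_grid_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            synthesize_bandpower(0.5, np.zeros(2), 0.0, [0.0, 0.5, 1.0],
                                 start_power=1.0)

    def test_stationarity_bound_enforced(self):
        with pytest.raises(ValueError, match="kappa"):
            synthesize_bandpower(1.2, np.zeros(9), 0.0, np.arange(10.0),
                                 start_power=1.0)

    def test_drive_round_trip(self, rng):
        """A planted drive 0.3*SAI on kappa = 0.7 is recovered from the fit
        with correlation >= 0.9."""
        from svsdg.coupling import fit_heart_to_brain

        n = 800
        grid = np.arange(float(n))
        sai = 45 + rng.normal(0, 6.0, n)
        drive = 0.3 * (sai - sai.mean())
        bp = synthesize_bandpower(0.7, drive[:-1], 0.01, grid,
                                  start_power=0.0, rng=1,
                                  channels=("Cz",), bands=("alpha",))
        fit = fit_heart_to_brain(bp.series("Cz", "alpha") - bp.power.mean(),
                                 window_s=120)
        ok = fit.psi_valid
        assert np.corrcoef(fit.psi[ok], drive[:-1][ok])[0, 1] >= 0.9


class TestStressReports:
    def test_group_medians_follow_profile(self):
        cfg = SyntheticConfig(seed=4)
        r = surrogate_stress_reports(cfg)
        assert r.shape == (37, 3)
        assert np.array_equal(np.median(r, axis=0), [1, 4, 5])
        assert r.min() >= 1 and r.max() <= 7

    def test_zero_dispersion_all_report_median(self):
        cfg = SyntheticConfig(seed=4, report_dispersion=0.0)
        r = surrogate_stress_reports(cfg)
        assert np.array_equal(r, np.tile([1, 4, 5], (37, 1)))

    def test_fixed_seed_reproducible(self):
        cfg = SyntheticConfig(seed=4)
        assert np.array_equal(surrogate_stress_reports(cfg),
                              surrogate_stress_reports(cfg))


@pytest.fixture(scope="module")
def small_dataset():
    cfg = SyntheticConfig(n_subjects=2, seed=6).scaled(2, 90.0, rest_s=90)
    return generate_protocol_dataset(cfg)


class TestProtocolDataset:
    def test_structure(self, small_dataset):
        cfg = small_dataset.config
        assert len(small_dataset.subjects) == 2
        for subj in small_dataset.subjects:
            assert set(subj.rr) == set(cfg.condition_labels)
            for cond in cfg.condition_labels:
                bp = subj.bandpower[cond]
                assert bp.power.shape[1:] == (9, 5)
            assert set(subj.reports) == set(cfg.stressors)

    def test_condition_windows_contain_their_series(self, small_dataset):
        windows = small_dataset.condition_windows
        for subj in small_dataset.subjects:
            for cond, (lo, hi) in windows.items():
                close = subj.rr[cond].observation_times
                assert close[0] > lo and close[-1] <= hi
                g = subj.bandpower[cond].grid
                assert g[0] >= lo and g[-1] < hi

    def test_same_seed_bit_identical(self):
        cfg = SyntheticConfig(n_subjects=1, seed=8).scaled(1, 90.0, rest_s=90)
        a = generate_protocol_dataset(cfg)
        b = generate_protocol_dataset(cfg)
        sa, sb = a.subjects[0], b.subjects[0]
        assert np.array_equal(sa.full_rr().intervals, sb.full_rr().intervals)
        assert np.array_equal(sa.full_bandpower().power, sb.full_bandpower().power)

    def test_adding_subjects_preserves_existing(self):
        c2 = SyntheticConfig(n_subjects=2, seed=8).scaled(2, 90.0, rest_s=90)
        c3 = SyntheticConfig(n_subjects=3, seed=8).scaled(3, 90.0, rest_s=90)
        a = generate_protocol_dataset(c2)
        b = generate_protocol_dataset(c3)
        for i in range(2):
            assert np.array_equal(a.subjects[i].full_rr().intervals,
                                  b.subjects[i].full_rr().intervals)

    def test_autonomic_truth_is_estimator_consistent(self, small_dataset):
        """The stored ground-truth SAI/PAI equal what the analysis stage
        recomputes from the concatenated per-condition RR series."""
        from svsdg.autonomic import AutonomicIndexModel

        subj = small_dataset.subjects[0]
        res = AutonomicIndexModel(subj.full_rr()).fit(
            q=small_dataset.config.kalman_q,
            warmup_beats=small_dataset.config.warmup_beats,
        )
        au = subj.truth.autonomic
        assert np.allclose(res.autonomic.sai, au.sai, atol=1e-12)
        assert np.allclose(res.autonomic.pai, au.pai, atol=1e-12)

    def test_modulation_round_trip(self, small_dataset):
        """The planted modulation is recovered from the generated RR series
        with correlation >= 0.95."""
        from svsdg.coupling import estimate_modulation

        subj = small_dataset.subjects[0]
        tr = subj.truth
        rr = subj.full_rr()
        grid = np.arange(np.ceil(rr.beat_times[0] + 2),
                         np.floor(rr.observation_times[-1] - 2))
        m = estimate_modulation(rr, grid)
        m_true = np.interp(m.grid, tr.grid, tr.modulation)
        # compare against the window-demeaned planted modulation
        w = np.convolve(m_true, np.ones(15) / 15, "same")
        assert np.corrcoef(m.m, m_true - w)[0, 1] >= 0.95

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_subjects=0)
        with pytest.raises(ValueError):
            SyntheticConfig(baseline_rate_hz=0.3)
        with pytest.raises(ValueError):
            SyntheticConfig(condition_plan=(("rest", 60.0), ("rest", 300.0)))
        with pytest.raises(ValueError):
            SyntheticConfig(condition_plan=(("rest", -5.0), ("s", 300.0)))
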