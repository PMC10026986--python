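"""Forward simulation of protocol-structured brain-heart datasets.

Emulates a graded mental-stress protocol (a short rest followed by three
stressor blocks) for a cohort of subjects, producing per condition an
RR-interval series, an EEG band-power series and the ground-truth coupling
trajectories that generated them, so every downstream stage of the analysis is
testable without any recording.

Generation model
----------------
* Latent sympathovagal dynamics: two independent band-limited low-frequency
  oscillation processes S*(t) and P*(t) (Mayer-wave scale) stand for the
  fluctuating sympathetic and parasympathetic outflows. Their amplitude grows
  with the stress level -- the planted autonomic-variability effect.
* Heartbeats come from an integrate-and-fire generator: a beat is emitted
  whenever the running integral of the instantaneous rate ``mu + m(t)`` since
  the previous beat reaches 1 (so RR = 1/(mu + m) exactly for constant
  modulation). The modulation is the planted brain-to-heart control

      m(t) = C_SAI(t) * S*(t) + C_PAI(t) * P*(t) + eta(t)

  with slowly fluctuating control coefficients (condition-invariant variance)
  and smoothed fast rate noise eta.
* The autonomic indices SAI/PAI entering the ascending direction are the
  package's own Laguerre/Kalman estimates of the generated RR series -- by
  construction identical to what the analysis stage recovers.
* Band power follows the lag-1 adaptive Markov model
  ``EEG_F(t) = kappa_F * EEG_F(t-1) + Psi_F(t-1) + eps_F`` with heart drive
  ``Psi_F(t) = gS(t) * SAI(t) + gP(t) * PAI(t)``. For the *planted* bands the
  relative fluctuation of the gains gS, gP grows with the stress level; for
  null bands it is condition-invariant. Negative generated power is floored
  at a small positive epsilon with a logged count.

Condition effects are planted on coupling variances, not means: variability,
not central tendency, is what separates the conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .autonomic import compute_sai_pai
from .kalman import kalman_estimate_coeffs
from .laguerre import LaguerreBasis, OnlineLaguerreExpander, convolve_rr, laguerre_basis
from .series import BANDS, DEFAULT_CHANNELS, AutonomicSeries, BandPowerSeries, RRSeries

__all__ = [
    "SyntheticConfig",
    "ProtocolSubject",
    "ProtocolDataset",
    "synthesize_rr_integrate_and_fire",
    "synthesize_rr_from_coeffs",
    "synthesize_bandpower",
    "surrogate_stress_reports",
    "generate_protocol_dataset",
]

logger = logging.getLogger(__name__)

POWER_FLOOR = 1e-6  # uV^2; the AR model is on power, which must stay positive

DEFAULT_CONDITION_PLAN: tuple[tuple[str, float], ...] = (
    ("rest", 60.0),
    ("stress1", 300.0),
    ("stress2", 300.0),
    ("stress3", 300.0),
)

#: per-band mean power target, uV^2 (plausible low-density montage values)
_BAND_POWER_TARGET = {"delta": 12.0, "theta": 8.0, "alpha": 10.0, "beta": 6.0, "gamma": 4.0}


def _default_eta_sd() -> dict[str, float]:
    # Hz; smoothed fast heart-rate noise, graded with stress level
    # (same relative grading as the latent oscillation amplitude)
    return {"rest": 0.004, "stress1": 0.006, "stress2": 0.0084, "stress3": 0.0096}


def _default_autonomic_amp() -> dict[str, float]:
    # a.u.; sd of the latent sympathovagal LF oscillations, graded with stress
    return {"rest": 1.0, "stress1": 1.5, "stress2": 2.1, "stress3": 2.4}


def _default_gain_rel_sd() -> dict[str, float]:
    # relative sd of the ascending drive gains for *planted* bands, per condition
    return {"rest": 0.30, "stress1": 0.45, "stress2": 0.70, "stress3": 0.80}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters for the protocol generator.

    ``coupling_means`` holds the planted means (c_sai, c_pai in Hz per a.u.;
    kappa dimensionless). ``c_sd`` is the condition-invariant sd of the slow
    control-coefficient fluctuations. ``autonomic_amp``, ``eta_sd`` and
    ``gain_rel_sd`` carry the condition-graded planted variability.
    ``planted_bands`` are the bands whose ascending drive variability follows
    the stress grading; the remaining bands stay at the ``rest`` level
    throughout (null bands).
    """

    n_subjects: int = 37
    condition_plan: tuple[tuple[str, float], ...] = DEFAULT_CONDITION_PLAN
    lead_in_s: float = 360.0  # pre-protocol recording: lets the Kalman filter
    # pass both its warm-up and its covariance-equilibration transient (~300
    # beats) before the first condition starts; not a condition
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    bands: tuple[str, ...] = tuple(BANDS)
    baseline_rate_hz: float = 1.2
    coupling_means: dict = field(
        default_factory=lambda: {"c_sai": 0.012, "c_pai": -0.012, "kappa": 0.7}
    )
    c_sd: float = 0.004
    c_smooth_s: float = 10.0
    autonomic_amp: dict = field(default_factory=_default_autonomic_amp)
    eta_sd: dict = field(default_factory=_default_eta_sd)
    eta_smooth_s: float = 1.5
    planted_bands: tuple[str, ...] = ("alpha", "beta", "gamma")
    gain_rel_sd: dict = field(default_factory=_default_gain_rel_sd)
    gain_smooth_s: float = 3.0
    eps_sd_frac: float = 0.05  # EEG innovation sd as a fraction of band power target
    band_power_target: dict = field(default_factory=lambda: dict(_BAND_POWER_TARGET))
    report_medians: tuple[int, ...] = (1, 4, 5)
    report_dispersion: float = 0.25
    m_clamp_frac: float = 0.45  # |m| safety ceiling as a fraction of the baseline rate
    warmup_beats: int = 50
    kalman_q: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        labels = [c for c, _ in self.condition_plan]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")
        if any(d <= 0 for _, d in self.condition_plan):
            raise ValueError("all condition durations must be > 0")
        if not 0.5 < self.baseline_rate_hz < 3.0:
            raise ValueError("baseline_rate_hz must lie in (0.5, 3.0)")
        for m in (self.eta_sd, self.gain_rel_sd, self.autonomic_amp):
            if any(v < 0 for v in m.values()):
                raise ValueError("all planted variances must be >= 0")

    @property
    def condition_labels(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.condition_plan)

    @property
    def condition_windows(self) -> dict[str, tuple[float, float]]:
        out, t = {}, float(self.lead_in_s)
        for label, dur in self.condition_plan:
            out[label] = (t, t + dur)
            t += dur
        return out

    @property
    def total_duration(self) -> float:
        """Recording length: lead-in plus all condition blocks."""
        return float(self.lead_in_s + sum(d for _, d in self.condition_plan))

    @property
    def stressors(self) -> tuple[str, ...]:
        return self.condition_labels[1:]

    def scaled(
        self, n_subjects: int, stressor_s: float, channels=None, rest_s: float | None = None
    ) -> "SyntheticConfig":
        """A smaller replicate of the same study design (for Monte-Carlo runs).

        ``rest_s`` overrides the rest-block length; equal-length blocks keep
        the sampling properties of the per-condition MAD estimates uniform.
        """
        rest_s = self.condition_plan[0][1] if rest_s is None else float(rest_s)
        plan = ((self.condition_plan[0][0], rest_s),) + tuple(
            (label, float(stressor_s)) for label, _ in self.condition_plan[1:]
        )
        return replace(
            self,
            n_subjects=n_subjects,
            condition_plan=plan,
            channels=tuple(channels) if channels is not None else self.channels,
        )


# ---------------------------------------------------------------------------
# elementary generators
# ---------------------------------------------------------------------------

def synthesize_rr_integrate_and_fire(
    modulation, baseline_rate_hz: float, duration: float, *, dt: float | None = None,
    t0: float = 0.0,
) -> RRSeries:
    """Integrate-and-fire heartbeat generation with threshold 1.

    ``modulation`` is either a callable m(t) or a sequence sampled uniformly
    over [0, duration] (endpoints included) and linearly interpolated. Beats
    are emitted at the times where the running integral of
    ``baseline_rate_hz + m`` since the previous beat first reaches 1; the
    integral of the piecewise-linear rate is evaluated in closed form.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if callable(modulation):
        dt = 0.01 if dt is None else float(dt)
        t = np.arange(0.0, duration + dt / 2, dt)
        t[-1] = min(t[-1], duration)
        m = np.asarray([modulation(ti) for ti in t], float)
    else:
        m = np.asarray(modulation, float)
        if m.ndim != 1 or m.size < 2:
            raise ValueError("modulation sequence needs at least 2 samples")
        t = np.linspace(0.0, duration, m.size)
    rate = baseline_rate_hz + m
    bad = rate <= 0
    if np.any(bad):
        t_bad = t[int(np.argmax(bad))]
        raise ValueError(
            f"instantaneous rate non-positive at t = {t_bad:.3f} s "
            f"(baseline {baseline_rate_hz} + m = {rate[bad][0]:.4f} Hz)"
        )
    # cumulative integral of the piecewise-linear rate (trapezoid is exact)
    cum = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2 * np.diff(t))])
    n_beats = int(np.floor(cum[-1]))
    if n_beats < 1:
        raise ValueError("duration too short: no beat emitted")
    thresholds = np.arange(1, n_beats + 1, dtype=float)
    seg = np.searchsorted(cum, thresholds, side="left") - 1
    seg = np.clip(seg, 0, t.size - 2)
    # within segment: residual = a*tau + 0.5*b*tau^2, solve for tau
    a = rate[seg]
    b = (rate[seg + 1] - rate[seg]) / (t[seg + 1] - t[seg])
    resid = thresholds - cum[seg]
    with np.errstate(invalid="ignore"):
        tau = np.where(
            np.abs(b) > 1e-12 * np.maximum(np.abs(a), 1.0),
            (-a + np.sqrt(np.maximum(a * a + 2 * b * resid, 0.0))) / np.where(b == 0, 1.0, b),
            resid / a,
        )
    beat_times = t[seg] + tau
    beat_times = np.concatenate([[0.0], beat_times]) + t0
    return RRSeries(beat_times=beat_times, intervals=np.diff(beat_times))


def synthesize_rr_from_coeffs(
    g0,
    g1,
    basis: LaguerreBasis,
    init_intervals,
    obs_noise_sd: float = 0.0,
    n_beats: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> RRSeries:
    """Run the Laguerre expansion model forward as an RR generator.

    ``g0`` (s) and ``g1`` (rows = beats, columns = Laguerre orders) may be
    scalars / single rows, in which case they are broadcast over ``n_beats``.
    Each new interval is ``RR(k) = g0(k) + sum_j g1_j(k) L_j(k) + eps`` with
    the regressors L computed from the already-generated past (strictly
    causal). Raises if a generated interval is non-positive.
    """
    rng = np.random.default_rng(rng)
    init = np.asarray(init_intervals, float)
    if init.size < 1:
        raise ValueError("need at least one initial interval")
    g0 = np.atleast_1d(np.asarray(g0, float))
    g1 = np.atleast_2d(np.asarray(g1, float))
    if n_beats is None:
        n_beats = max(g0.size, g1.shape[0])
    if g0.size == 1:
        g0 = np.full(n_beats, g0[0])
    if g1.shape[0] == 1:
        g1 = np.repeat(g1, n_beats, axis=0)
    if g0.size != n_beats or g1.shape[0] != n_beats:
        raise ValueError("g0/g1 lengths inconsistent with n_beats")
    expander = OnlineLaguerreExpander(basis)
    for v in init:
        expander.push(v)
    out = list(init)
    for k in range(n_beats):
        L = expander.regressors()[: g1.shape[1]]
        rr = g0[k] + float(g1[k] @ L)
        if obs_noise_sd > 0:
            rr += rng.normal(0.0, obs_noise_sd)
        if rr <= 0:
            raise ValueError(
                f"generated interval {rr:.4f} s <= 0 at beat {k}: "
                "coefficient/noise configuration infeasible"
            )
        out.append(rr)
        expander.push(rr)
    return RRSeries.from_intervals(np.asarray(out))


def synthesize_bandpower(
    kappa,
    heart_drive,
    noise_sd,
    grid,
    *,
    start_power=None,
    rng: np.random.Generator | int | None = None,
    channels: tuple[str, ...] = ("Cz",),
    bands: tuple[str, ...] = ("alpha",),
    floor_eps: float = POWER_FLOOR,
) -> BandPowerSeries:
    """Realise the lag-1 adaptive Markov band-power model forward.

    ``EEG(t) = kappa * EEG(t-1) + Psi(t-1) + eps`` applied sequentially on the
    uniform 1-s ``grid``. ``kappa``, ``noise_sd`` and ``start_power`` are
    scalars or dicts keyed ``(channel, band)``; ``heart_drive`` maps
    ``(channel, band)`` to the drive sequence Psi(t) (length ``len(grid)-1``),
    or is a single sequence for the single-series case. Negative generated
    power is floored at ``floor_eps`` with a logged count.
    """
    grid = np.asarray(grid, float)
    if grid.size < 2 or np.max(np.abs(np.diff(grid) - 1.0)) > 1e-9:
        raise ValueError("grid must be uniform at 1 s")
    rng = np.random.default_rng(rng)

    def _get(obj, key, default=None):
        if isinstance(obj, dict):
            return obj[key]
        return default if obj is None else obj

    if not isinstance(heart_drive, dict):
        heart_drive = {(channels[0], bands[0]): np.asarray(heart_drive, float)}
    n = grid.size
    power = np.empty((n, len(channels), len(bands)))
    n_floored = 0
    for ci, ch in enumerate(channels):
        for bi, band in enumerate(bands):
            k = float(_get(kappa, (ch, band)))
            if abs(k) > 1.0:
                raise ValueError(f"|kappa| must be <= 1 for stationarity, got {k}")
            sd = float(_get(noise_sd, (ch, band)))
            drive = np.asarray(heart_drive[(ch, band)], float)
            if drive.size != n - 1:
                raise ValueError(
                    f"drive for {(ch, band)} has length {drive.size}, expected {n - 1}"
                )
            x = np.empty(n)
            x[0] = float(_get(start_power, (ch, band), 0.0 if start_power is None else None))
            eps = rng.normal(0.0, sd, n - 1) if sd > 0 else np.zeros(n - 1)
            for i in range(1, n):
                v = k * x[i - 1] + drive[i - 1] + eps[i - 1]
                if v < 0:
                    v = floor_eps
                    n_floored += 1
                x[i] = v
            power[:, ci, bi] = x
    if n_floored:
        logger.info("synthesize_bandpower: floored %d negative power values", n_floored)
    return BandPowerSeries(grid=grid, channels=channels, bands=bands, power=power)


def surrogate_stress_reports(
    config: SyntheticConfig, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Integer self-report stress scores (1-7), one row per subject, one
    column per stressor, with condition medians following the configured
    monotone profile."""
    if len(config.stressors) < 3:
        raise ValueError("need three stressor conditions")
    rng = np.random.default_rng(config.seed + 1_000_003 if rng is None else rng)
    p = config.report_dispersion
    out = np.empty((config.n_subjects, len(config.stressors)), dtype=int)
    for j, med in enumerate(config.report_medians):
        offsets = rng.choice([-1, 0, 1], size=config.n_subjects, p=[p, 1 - 2 * p, p])
        out[:, j] = np.clip(med + offsets, 1, 7)
    return out


# ---------------------------------------------------------------------------
# smoothed-noise helpers
# ---------------------------------------------------------------------------

def _smooth_noise(rng: np.random.Generator, n: int, sigma_s: float) -> np.ndarray:
    """Unit-variance Gaussian noise smoothed to a ~sigma_s correlation scale (1-s grid)."""
    x = gaussian_filter1d(rng.standard_normal(n + 40), sigma_s, mode="reflect")[20:-20]
    s = x.std()
    return x / s if s > 0 else x


def _lf_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance band-limited noise with energy around ~0.05-0.2 Hz.

    Emulates low-frequency sympathovagal rhythms (Mayer-wave scale) as the
    difference of two Gaussian smoothings of the same white-noise stream.
    """
    w = rng.standard_normal(n + 60)
    x = (gaussian_filter1d(w, 1.5, mode="reflect") - gaussian_filter1d(w, 8.0, mode="reflect"))[30:-30]
    s = x.std()
    return x / s if s > 0 else x


# ---------------------------------------------------------------------------
# protocol dataset
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted trajectories for one subject, on the protocol 1-s grid."""

    grid: np.ndarray
    c_sai: np.ndarray
    c_pai: np.ndarray
    s_star: np.ndarray  # latent sympathetic oscillation, a.u.
    p_star: np.ndarray  # latent parasympathetic oscillation, a.u.
    modulation: np.ndarray  # planted m(t), Hz
    eta_sd: np.ndarray
    kappa: float
    gains: dict  # (channel, band) -> {"sai": array, "pai": array} drive gains over grid
    autonomic: AutonomicSeries  # estimator-consistent SAI/PAI used for the EEG drive


@dataclass
class ProtocolSubject:
    subject_id: int
    rr: dict  # condition -> RRSeries
    bandpower: dict  # condition -> BandPowerSeries
    truth: GroundTruth
    reports: dict  # stressor condition -> int
    rr_lead: RRSeries | None = None  # pre-protocol lead-in (filter warm-up)
    bandpower_lead: BandPowerSeries | None = None

    def full_rr(self) -> RRSeries:
        """Concatenate lead-in and per-condition series back into the full recording."""
        parts = ([self.rr_lead] if self.rr_lead is not None else []) + list(self.rr.values())
        bt = [parts[0].beat_times]
        rr = [parts[0].intervals]
        for p in parts[1:]:
            bt.append(p.beat_times[1:])
            rr.append(p.intervals)
        return RRSeries(np.concatenate(bt), np.concatenate(rr))

    def full_bandpower(self) -> BandPowerSeries:
        parts = ([self.bandpower_lead] if self.bandpower_lead is not None else []) + list(
            self.bandpower.values()
        )
        return BandPowerSeries(
            np.concatenate([p.grid for p in parts]),
            parts[0].channels,
            parts[0].bands,
            np.concatenate([p.power for p in parts]),
        )


@dataclass
class ProtocolDataset:
    config: SyntheticConfig
    subjects: list

    @property
    def condition_windows(self) -> dict:
        return self.config.condition_windows

    def reports_matrix(self) -> np.ndarray:
        return np.asarray(
            [[s.reports[c] for c in self.config.stressors] for s in self.subjects]
        )


def _condition_of(t: float, windows: dict[str, tuple[float, float]], labels) -> str:
    for label in labels:
        lo, hi = windows[label]
        if lo <= t < hi:
            return label
    # lead-in inherits the first (rest) condition's variability levels
    return labels[0] if t < windows[labels[0]][0] else labels[-1]


def _simulate_subject(
    config: SyntheticConfig,
    ss: np.random.SeedSequence,
    basis: LaguerreBasis,
    subject_id: int,
) -> ProtocolSubject:
    rng_eta, rng_c, rng_lat, rng_eeg = [np.random.default_rng(s) for s in ss.spawn(4)]
    windows = config.condition_windows
    labels = config.condition_labels
    T = config.total_duration
    grid = np.arange(0.0, T + 0.5, 1.0)
    n = grid.size
    cond_of_t = np.array([_condition_of(t, windows, labels) for t in grid])

    # planted control-coefficient trajectories (slow, condition-invariant sd)
    mu_c = config.coupling_means
    c_sai = mu_c["c_sai"] + config.c_sd * _smooth_noise(rng_c, n, config.c_smooth_s)
    c_pai = mu_c["c_pai"] + config.c_sd * _smooth_noise(rng_c, n, config.c_smooth_s)

    # latent sympathovagal LF oscillations, amplitude graded with stress level
    amp_t = np.asarray([config.autonomic_amp[c] for c in cond_of_t])
    s_star = amp_t * _lf_noise(rng_lat, n)
    p_star = amp_t * _lf_noise(rng_lat, n)

    # graded fast heart-rate noise
    eta_sd_t = np.asarray([config.eta_sd[c] for c in cond_of_t])
    eta = _smooth_noise(rng_eta, n, config.eta_smooth_s) * eta_sd_t

    # planted brain-to-heart modulation, safety-clamped to keep the rate positive
    mu = config.baseline_rate_hz
    m = c_sai * s_star + c_pai * p_star + eta
    clamp = config.m_clamp_frac * mu
    n_clamped = int(np.sum(np.abs(m) > clamp))
    if n_clamped:
        logger.info("subject %d: clamped modulation at %d grid points", subject_id, n_clamped)
        m = np.clip(m, -clamp, clamp)

    rr_full = synthesize_rr_integrate_and_fire(m, mu, T)

    # estimator-consistent autonomic indices (exactly what the analysis recovers)
    regressors = convolve_rr(rr_full, basis)
    coeffs = kalman_estimate_coeffs(
        rr_full, regressors, basis=basis,
        q=config.kalman_q, warmup_beats=config.warmup_beats,
    )
    autonomic = compute_sai_pai(coeffs, rr_full)

    # --- band-power generation ------------------------------------------
    sai_g, pai_g = autonomic.interp(grid)
    kappa = float(mu_c["kappa"])
    rel_rest = config.gain_rel_sd[labels[0]]
    power = np.empty((n, len(config.channels), len(config.bands)))
    gains: dict = {}
    ch_factor = rng_eeg.lognormal(mean=0.0, sigma=0.1, size=len(config.channels))
    n_floored = 0
    for ci, ch in enumerate(config.channels):
        for bi, band in enumerate(config.bands):
            target = config.band_power_target[band] * ch_factor[ci]
            # Planted (faster) bands are driven by both autonomic branches,
            # each weighted by the inverse of its mean so the composite drive
            # tracks *relative* autonomic state (the opposite-signed
            # mechanical rate sensitivities of SAI and PAI then cancel to
            # first order). The slow null bands carry a vagally-dominated
            # drive (parasympathetic branch only).
            if band in config.planted_bands:
                gs_mean = target * (1.0 - kappa) / (2.0 * np.mean(sai_g))
                gp_mean = target * (1.0 - kappa) / (2.0 * np.mean(pai_g))
                rel_sd_t = np.asarray([config.gain_rel_sd[c] for c in cond_of_t])
            else:
                gs_mean = 0.0
                gp_mean = target * (1.0 - kappa) / np.mean(pai_g)
                rel_sd_t = np.full(n, rel_rest)
            gs = gs_mean * (1.0 + rel_sd_t * _smooth_noise(rng_eeg, n, config.gain_smooth_s))
            gp = gp_mean * (1.0 + rel_sd_t * _smooth_noise(rng_eeg, n, config.gain_smooth_s))
            if band in config.planted_bands:
                drive = gs * sai_g + gp * pai_g
            else:
                # slow null bands: largely non-cardiac power whose weak drive
                # varies with its gain process, not with beat-to-beat
                # autonomic input (a true null for the directional battery)
                drive = gp * float(np.mean(pai_g))
            eps_sd = config.eps_sd_frac * target
            eps = rng_eeg.normal(0.0, eps_sd, n - 1)
            x = np.empty(n)
            x[0] = target
            for i in range(1, n):
                v = kappa * x[i - 1] + drive[i - 1] + eps[i - 1]
                if v < 0:
                    v = POWER_FLOOR
                    n_floored += 1
                x[i] = v
            power[:, ci, bi] = x
            gains[(ch, band)] = {"sai": gs, "pai": gp}
    if n_floored:
        logger.info("subject %d: floored %d negative power values", subject_id, n_floored)
    bp_full = BandPowerSeries(grid, config.channels, config.bands, power)

    truth = GroundTruth(
        grid=grid,
        c_sai=c_sai,
        c_pai=c_pai,
        s_star=s_star,
        p_star=p_star,
        modulation=m,
        eta_sd=eta_sd_t,
        kappa=kappa,
        gains=gains,
        autonomic=autonomic,
    )
    rr_by_cond, bp_by_cond = {}, {}
    close = rr_full.observation_times
    lead_lo = windows[labels[0]][0]

    def _segment(lo, hi, label):
        # interval belongs to the segment containing its closing beat, so the
        # segments partition the recording and concatenate exactly
        keep = (close > lo) & (close <= hi)
        if keep.sum() < 2:
            raise ValueError(f"segment {label} too short: fewer than 2 intervals")
        i0 = int(np.argmax(keep))
        i1 = len(keep) - int(np.argmax(keep[::-1]))
        return RRSeries(rr_full.beat_times[i0 : i1 + 1], rr_full.intervals[i0:i1])

    rr_lead = _segment(-1.0, lead_lo, "lead-in") if lead_lo > 0 else None
    bp_lead = bp_full.crop(0.0, lead_lo) if lead_lo > 1 else None
    for label in labels:
        lo, hi = windows[label]
        rr_by_cond[label] = _segment(lo, hi, label)
        bp_by_cond[label] = bp_full.crop(lo, hi)
    return ProtocolSubject(
        subject_id=subject_id,
        rr=rr_by_cond,
        bandpower=bp_by_cond,
        truth=truth,
        reports={},
        rr_lead=rr_lead,
        bandpower_lead=bp_lead,
    )


def generate_protocol_dataset(config: SyntheticConfig) -> ProtocolDataset:
    """Simulate the full cohort; reproducible from ``config.seed``.

    The master seed expands to one child seed per subject (spawned in subject
    order), so enlarging the cohort leaves existing subjects untouched.
    """
    basis = laguerre_basis()
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.n_subjects)
    subjects = []
    for sid, ss in enumerate(children):
        subjects.append(_simulate_subject(config, ss, basis, sid))
    reports = surrogate_stress_reports(config)
    for sid, subj in enumerate(subjects):
        subj.reports = {c: int(reports[sid, j]) for j, c in enumerate(config.stressors)}
    return ProtocolDataset(config=config, subjects=subjects)
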