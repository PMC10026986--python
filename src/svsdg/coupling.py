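"""Directional brain-heart coupling estimation (SV-SDG coefficients).

Descending (brain -> heart): the heart-rate modulation m(t) — fluctuation of
the instantaneous rate about a sliding 15-s baseline — is regressed, with no
intercept, on the sympathetic and parasympathetic indices inside each sliding
window:

    m(t) = C_SAI(t) * SAI(t) + C_PAI(t) * PAI(t)

and the coupling from a cortical band to branch X is the ratio
``SDG_{EEG_F -> X}(t) = C_X(t) / EEG_F(t-1)``.

Ascending (heart -> brain): band power follows a lag-1 adaptive Markov model
``EEG_F(t) = kappa_F * EEG_F(t-1) + Psi_F(t-1) + eps_F``; kappa_F is fitted by
windowed no-intercept least squares, the drive Psi_F is identified with the
pointwise lag-1 residual, and ``SDG_{X -> EEG_F}(t) = Psi_F(t) / X(t)``.

The windowed regressions are solved on within-window *centered* series
(fluctuation components) with no intercept column: m is a baseline-removed
fluctuation by construction, so the autonomic regressors enter through their
within-window fluctuations as well. Denominators are guarded, not clipped:
points whose denominator magnitude falls below ``1e-6 * median`` are masked
invalid and excluded from every downstream condensation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .series import AutonomicSeries, BandPowerSeries, CouplingSeries, ModulationSeries, RRSeries

__all__ = [
    "estimate_modulation",
    "fit_brain_to_heart",
    "brain_to_heart_coupling",
    "fit_heart_to_brain",
    "heart_to_brain_coupling",
    "BrainToHeartFit",
    "HeartToBrainFit",
    "BrainHeartModel",
    "BrainHeartResults",
]

logger = logging.getLogger(__name__)

DENOM_EPS = 1e-6  # relative denominator guard
COND_LIMIT = 1e8  # window design-matrix condition limit


def _window_length(window_s: float) -> int:
    w = int(round(window_s))
    if w < 3:
        raise ValueError("window_s must span at least 3 grid points")
    return w


def estimate_modulation(
    rr: RRSeries, grid: np.ndarray, window_s: float = 15.0
) -> ModulationSeries:
    """Instantaneous-rate fluctuation about the sliding-window baseline.

    The instantaneous rate 1/RR(k) -- the average rate over interval k -- is
    stamped at the interval midpoint (avoiding a systematic half-beat lag)
    and linearly interpolated onto the 1-s grid; the baseline at each stamp
    is the mean rate over the centred ``window_s`` window (truncated at the
    edges) and m = rate - baseline.
    """
    grid = np.asarray(grid, float)
    t_obs = rr.observation_times
    if grid[0] < t_obs[0] - 1e-9 or grid[-1] > t_obs[-1] + 1e-9:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] extends beyond RR coverage "
            f"[{t_obs[0]:.3f}, {t_obs[-1]:.3f}]"
        )
    t_mid = rr.beat_times[:-1] + rr.intervals / 2.0
    rate = np.interp(grid, t_mid, 1.0 / rr.intervals)
    w = _window_length(window_s)
    half = w // 2
    baseline = np.empty_like(rate)
    for i in range(rate.size):
        lo, hi = max(0, i - half), min(rate.size, i + half + 1)
        baseline[i] = rate[lo:hi].mean()
    return ModulationSeries(grid=grid, rate=rate, baseline=baseline, window_s=float(window_s))


@dataclass(frozen=True)
class BrainToHeartFit:
    """Windowed no-intercept regression of m on (SAI, PAI): C_X at window centres."""

    grid: np.ndarray  # window-centre stamps
    c_sai: np.ndarray
    c_pai: np.ndarray
    valid: np.ndarray
    window_s: float


def fit_brain_to_heart(
    m: ModulationSeries,
    autonomic: AutonomicSeries,
    window_s: float = 15.0,
) -> BrainToHeartFit:
    """Fit C_SAI(t), C_PAI(t) per sliding window (step 1 s).

    Windows whose centred design matrix has condition number above 1e8
    (e.g. collinear SAI/PAI or constant segments) are masked invalid and
    logged, never raised.
    """
    sai, pai = autonomic.interp(m.grid)
    w = _window_length(window_s)
    n = m.grid.size
    if n < w:
        raise ValueError(f"grid has {n} points, shorter than one {w}-point window")
    mw = sliding_window_view(m.rate, w)          # (n - w + 1, w)
    sw = sliding_window_view(sai, w)
    pw = sliding_window_view(pai, w)
    ms = mw - mw.mean(axis=1, keepdims=True)
    ss = sw - sw.mean(axis=1, keepdims=True)
    ps = pw - pw.mean(axis=1, keepdims=True)
    # normal equations per window
    a = np.einsum("ij,ij->i", ss, ss)
    b = np.einsum("ij,ij->i", ss, ps)
    d = np.einsum("ij,ij->i", ps, ps)
    u = np.einsum("ij,ij->i", ss, ms)
    v = np.einsum("ij,ij->i", ps, ms)
    det = a * d - b * b
    # condition number of the 2x2 Gram matrix = (ratio of its eigenvalues);
    # cond(X) = sqrt(cond(X'X))
    tr = a + d
    disc = np.sqrt(np.maximum((a - d) ** 2 + 4 * b * b, 0.0))
    lam_max = (tr + disc) / 2
    lam_min = (tr - disc) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.sqrt(np.where(lam_min > 0, lam_max / lam_min, np.inf))
    valid = np.isfinite(cond) & (cond <= COND_LIMIT)
    c_sai = np.full(mw.shape[0], np.nan)
    c_pai = np.full(mw.shape[0], np.nan)
    ok = valid & (det > 0)
    c_sai[ok] = (d[ok] * u[ok] - b[ok] * v[ok]) / det[ok]
    c_pai[ok] = (a[ok] * v[ok] - b[ok] * u[ok]) / det[ok]
    valid &= ok
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("fit_brain_to_heart: %d / %d windows masked invalid", n_bad, valid.size)
    centers = m.grid[: mw.shape[0]] + (w - 1) / 2.0 * (m.grid[1] - m.grid[0])
    return BrainToHeartFit(
        grid=centers, c_sai=c_sai, c_pai=c_pai, valid=valid, window_s=float(window_s)
    )


def _align_lagged(grid_c: np.ndarray, grid_e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices pairing each coefficient stamp t with the band-power stamp t-1."""
    step = 1.0
    off0 = grid_c[0] - step - grid_e[0]
    idx_e = np.round((grid_c - step - grid_e[0]) / step).astype(int)
    if abs(off0 - round(off0)) > 1e-6:
        raise ValueError("coefficient and band-power grids are not 1-s aligned")
    ok = (idx_e >= 0) & (idx_e < grid_e.size)
    return idx_e, ok


def brain_to_heart_coupling(
    fit: BrainToHeartFit,
    bandpower: BandPowerSeries,
    band: str,
    channel: str,
    branch: str = "SAI",
) -> CouplingSeries:
    """Descending coupling SDG_{EEG_F -> X}(t) = C_X(t) / EEG_F(t-1)."""
    c = fit.c_sai if branch == "SAI" else fit.c_pai
    eeg = bandpower.series(channel, band)
    idx_e, in_range = _align_lagged(fit.grid, bandpower.grid)
    med = np.median(np.abs(eeg))
    sdg = np.full(fit.grid.size, np.nan)
    valid = fit.valid & in_range
    denom = np.full(fit.grid.size, np.nan)
    denom[in_range] = eeg[idx_e[in_range]]
    small = np.abs(denom) < DENOM_EPS * med
    valid &= ~small & np.isfinite(denom)
    sdg[valid] = c[valid] / denom[valid]
    return CouplingSeries(
        direction="brain_to_heart",
        branch=branch,
        band=band,
        channel=channel,
        grid=fit.grid,
        sdg=sdg,
        valid=valid,
    )


@dataclass(frozen=True)
class HeartToBrainFit:
    """Windowed AR(1) fit of one band-power series: kappa at window centres and
    the pointwise drive Psi(t) = EEG(t+1) - kappa * EEG(t)."""

    band: str
    channel: str
    kappa_grid: np.ndarray
    kappa: np.ndarray
    kappa_valid: np.ndarray
    psi_grid: np.ndarray  # stamps t of Psi(t)
    psi: np.ndarray
    psi_valid: np.ndarray
    window_s: float


def fit_heart_to_brain(
    bandpower: BandPowerSeries | np.ndarray,
    band: str = "series",
    channel: str = "series",
    window_s: float = 15.0,
) -> HeartToBrainFit:
    """Fit the lag-1 adaptive Markov model per sliding window.

    kappa_F per window is the no-intercept least-squares slope of EEG(t) on
    EEG(t-1); the drive is identified with the pointwise residual (the
    adjusted error eps_F is absorbed into Psi_F, the only identification
    computable from the lag-1 model alone). Windows with (near) all-zero power
    are masked invalid.

    ``bandpower`` may also be a plain 1-d sequence on an implicit 1-s grid
    (useful for fitting the autoregression to a single fluctuation series).
    """
    if isinstance(bandpower, BandPowerSeries):
        y = bandpower.series(channel, band)
        grid = bandpower.grid
    else:
        y = np.asarray(bandpower, float)
        grid = np.arange(y.size, dtype=float)
    w = _window_length(window_s)
    if y.size < w + 1:
        raise ValueError(f"need at least {w + 1} grid points, got {y.size}")
    x_lag = y[:-1]
    x_now = y[1:]
    xw = sliding_window_view(x_lag, w)  # predictor windows
    yw = sliding_window_view(x_now, w)
    sxx = np.einsum("ij,ij->i", xw, xw)
    sxy = np.einsum("ij,ij->i", xw, yw)
    scale = np.einsum("ij,ij->i", yw, yw) + sxx
    valid_w = sxx > 1e-24 * np.maximum(scale, 1.0)
    kappa = np.full(xw.shape[0], np.nan)
    kappa[valid_w] = sxy[valid_w] / sxx[valid_w]
    n_bad = int((~valid_w).sum())
    if n_bad:
        logger.info(
            "fit_heart_to_brain[%s/%s]: %d / %d windows masked invalid",
            channel, band, n_bad, valid_w.size,
        )
    # centre stamp of window i covers transitions grid[i]..grid[i+w]
    centers = grid[1:][: xw.shape[0]] + (w - 1) / 2.0
    # pointwise drive: Psi(t) = EEG(t+1) - kappa_near(t) * EEG(t)
    psi_grid = grid[:-1]
    near = np.clip(
        np.round((psi_grid - centers[0])).astype(int), 0, centers.size - 1
    )
    kap_t = kappa[near]
    psi = y[1:] - kap_t * y[:-1]
    psi_valid = valid_w[near] & np.isfinite(psi)
    return HeartToBrainFit(
        band=band,
        channel=channel,
        kappa_grid=centers,
        kappa=kappa,
        kappa_valid=valid_w,
        psi_grid=psi_grid,
        psi=psi,
        psi_valid=psi_valid,
        window_s=float(window_s),
    )


def heart_to_brain_coupling(
    fit: HeartToBrainFit,
    autonomic: AutonomicSeries,
    branch: str = "SAI",
) -> CouplingSeries:
    """Ascending coupling SDG_{X -> EEG_F}(t) = Psi_F(t) / X(t)."""
    x_sai, x_pai = autonomic.interp(fit.psi_grid)
    x = x_sai if branch == "SAI" else x_pai
    med = np.median(np.abs(x))
    small = np.abs(x) < DENOM_EPS * med
    valid = fit.psi_valid & ~small
    sdg = np.full(fit.psi_grid.size, np.nan)
    sdg[valid] = fit.psi[valid] / x[valid]
    return CouplingSeries(
        direction="heart_to_brain",
        branch=branch,
        band=fit.band,
        channel=fit.channel,
        grid=fit.psi_grid,
        sdg=sdg,
        valid=valid,
        extras={"kappa_grid": fit.kappa_grid, "kappa": fit.kappa},
    )


class BrainHeartModel:
    """Bidirectional brain-heart coupling model for one recording segment.

    Built from an RR series and a band-power series on a shared protocol
    clock; ``fit`` estimates the autonomic indices (unless provided), the
    heart-rate modulation, the descending control coefficients and, per
    (channel, band), the ascending adaptive Markov fit, then assembles the
    full set of directional coupling series
    (2 directions x 2 branches x n_bands x n_channels).
    """

    def __init__(
        self,
        rr: RRSeries,
        bandpower: BandPowerSeries,
        *,
        autonomic: AutonomicSeries | None = None,
        window_s: float = 15.0,
        autonomic_kwargs: dict | None = None,
    ) -> None:
        self.rr = rr
        self.bandpower = bandpower
        self.window_s = float(window_s)
        self._autonomic = autonomic
        self._autonomic_kwargs = autonomic_kwargs or {}

    def fit(self) -> "BrainHeartResults":
        from .autonomic import AutonomicIndexModel

        if self._autonomic is None:
            res = AutonomicIndexModel(self.rr).fit(**self._autonomic_kwargs)
            autonomic = res.autonomic
        else:
            autonomic = self._autonomic
        # grid restricted to joint RR / band-power coverage
        g = self.bandpower.grid
        t_obs = self.rr.observation_times
        keep = (g >= max(g[0], autonomic.beat_times[0], t_obs[0])) & (
            g <= min(g[-1], t_obs[-1])
        )
        if keep.sum() < _window_length(self.window_s) + 1:
            raise ValueError("joint RR / band-power coverage shorter than one window")
        bp = BandPowerSeries(
            g[keep], self.bandpower.channels, self.bandpower.bands,
            self.bandpower.power[keep],
        )
        modulation = estimate_modulation(self.rr, bp.grid, self.window_s)
        b2h = fit_brain_to_heart(modulation, autonomic, self.window_s)
        couplings: dict[str, CouplingSeries] = {}
        kappas: dict[tuple[str, str], np.ndarray] = {}
        for ch in bp.channels:
            for band in bp.bands:
                h2b = fit_heart_to_brain(bp, band, ch, self.window_s)
                kappas[(ch, band)] = h2b.kappa
                for branch in ("SAI", "PAI"):
                    asc = heart_to_brain_coupling(h2b, autonomic, branch)
                    desc = brain_to_heart_coupling(b2h, bp, band, ch, branch)
                    couplings[asc.key] = asc
                    couplings[desc.key] = desc
        return BrainHeartResults(
            model=self,
            autonomic=autonomic,
            modulation=modulation,
            brain_to_heart=b2h,
            couplings=couplings,
            kappas=kappas,
        )


@dataclass
class BrainHeartResults:
    """Full set of fitted coupling series plus the intermediate estimates."""

    model: BrainHeartModel
    autonomic: AutonomicSeries
    modulation: ModulationSeries
    brain_to_heart: BrainToHeartFit
    couplings: dict[str, CouplingSeries]
    kappas: dict[tuple[str, str], np.ndarray]

    @property
    def n_series(self) -> int:
        return len(self.couplings)

    def series(self, direction: str, branch: str, band: str, channel: str) -> CouplingSeries:
        return self.couplings[f"{direction}.{branch}.{band}.{channel}"]

    def to_frame(self):
        """Long-format DataFrame (t_s, direction, branch, band, channel, value, valid)."""
        import pandas as pd

        rows = []
        for cs in self.couplings.values():
            rows.append(
                pd.DataFrame(
                    {
                        "t_s": cs.grid,
                        "direction": cs.direction,
                        "branch": cs.branch,
                        "band": cs.band,
                        "channel": cs.channel,
                        "value": cs.sdg,
                        "valid": cs.valid,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> str:
        n_valid = sum(c.n_valid for c in self.couplings.values())
        n_total = sum(c.grid.size for c in self.couplings.values())
        kap = np.concatenate([k[np.isfinite(k)] for k in self.kappas.values()])
        lines = [
            "Bidirectional brain-heart coupling (SV-SDG)",
            "=" * 52,
            f"coupling series       : {self.n_series} "
            f"(2 directions x 2 branches x {len(self.model.bandpower.bands)} bands "
            f"x {len(self.model.bandpower.channels)} channels)",
            f"window length         : {self.model.window_s:.0f} s (1-s step)",
            f"valid points          : {n_valid} / {n_total} "
            f"({100 * n_valid / max(n_total, 1):.1f}%)",
            f"kappa median [IQR]    : {np.median(kap):.3f} "
            f"[{np.percentile(kap, 25):.3f}, {np.percentile(kap, 75):.3f}]",
            f"C_SAI median          : {np.nanmedian(self.brain_to_heart.c_sai):+.4g}",
            f"C_PAI median          : {np.nanmedian(self.brain_to_heart.c_pai):+.4g}",
        ]
        return "\n".join(lines)

    def plot(self, direction: str, branch: str, band: str, channel: str, ax=None):
        import matplotlib.pyplot as plt

        cs = self.series(direction, branch, band, channel)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(cs.grid[cs.valid], cs.sdg[cs.valid], lw=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel(f"SDG {cs.key}")
        return ax
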