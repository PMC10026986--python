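"""Kalman tracking of the time-varying Laguerre coefficients.

State model: random walk g(k) = g(k-1) + eps_g with diagonal covariance q*I;
observation: RR(k) = h(k)^T g(k) + eps_RR with h(k) = [1, L_0(k), ..., L_J(k)]
(the leading 1 carries the baseline term g0). The observation matrix is
time-varying because the Laguerre regressors change every beat.

The filter is exposed both as a batch function (:func:`kalman_estimate_coeffs`)
and as an online class (:class:`KalmanCoeffTracker`) so the synthetic generator
can run the *same* estimator beat by beat inside its generation loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .laguerre import LaguerreBasis, convolve_rr
from .series import RRSeries

__all__ = ["CoeffTrajectory", "KalmanCoeffTracker", "kalman_estimate_coeffs"]

_ADAPT_WINDOW = 30  # innovation window used for the adaptive observation-noise estimate


@dataclass(frozen=True)
class CoeffTrajectory:
    """Filtered coefficient estimates, one row per analysed beat.

    ``g0`` is the baseline term (s); ``g1`` has one column per Laguerre order
    (dimensionless). ``beat_index`` maps each row to the interval index k of
    the RR series it was estimated at (k >= warmup). ``innovations`` are the
    one-step prediction errors RR(k) - h(k)^T g(k|k-1), in seconds.
    """

    beat_index: np.ndarray
    g0: np.ndarray
    g1: np.ndarray
    innovations: np.ndarray
    q: float
    r_init: float
    warmup_beats: int

    @property
    def n_orders(self) -> int:
        return self.g1.shape[1]


class KalmanCoeffTracker:
    """Online random-walk Kalman filter over the Laguerre expansion.

    Initialisation: the first ``warmup_beats`` observations are buffered and a
    batch (ridge-stabilised) least-squares solve provides g(0); the state
    covariance starts at ``10 * r_init * I``. The observation-noise variance r
    is re-estimated adaptively from the innovations of the last 30 beats
    (clipped below at ``1e-8 * r_init`` so a noise-free stream stays well
    posed).

    With q = 0 and fixed r the filter reduces to recursive least squares.
    """

    def __init__(
        self,
        basis: LaguerreBasis,
        q: float = 1e-5,
        r_init: float = 1e-3,
        warmup_beats: int = 50,
        adaptive_r: bool = True,
        anchor_lambda: float = 0.005,
    ) -> None:
        if warmup_beats < 20:
            raise ValueError("warmup_beats must be >= 20")
        if not (np.isfinite(q) and q >= 0):
            raise ValueError("q must be finite and >= 0")
        if not (np.isfinite(r_init) and r_init > 0):
            raise ValueError("r_init must be finite and > 0")
        self.basis = basis
        self.q = float(q)
        self.r_init = float(r_init)
        self.warmup_beats = int(warmup_beats)
        self.adaptive_r = adaptive_r
        self.anchor_lambda = float(anchor_lambda)
        self._anchor: np.ndarray | None = None
        self._dim = basis.n_functions + 1
        self._buf_h: list[np.ndarray] = []
        self._buf_y: list[float] = []
        self._k = 0  # next observation index
        self.g: np.ndarray | None = None
        self.P: np.ndarray | None = None
        self._r = self.r_init
        self._innov: list[float] = []
        self.beat_index: list[int] = []
        self.g_hist: list[np.ndarray] = []
        self.innovations: list[float] = []

    def _init_from_buffer(self) -> None:
        H = np.asarray(self._buf_h)
        y = np.asarray(self._buf_y)
        # tiny ridge keeps the warm-up solve defined even if H is short/collinear
        A = H.T @ H + 1e-10 * np.eye(self._dim)
        self.g = np.linalg.solve(A, H.T @ y)
        self._anchor = self.g.copy()
        self.P = 10.0 * self.r_init * np.eye(self._dim)

    def update(self, h: np.ndarray, rr_value: float) -> None:
        """Process one observation RR(k) with regressor vector h(k) (without the leading 1)."""
        hv = np.concatenate([[1.0], np.asarray(h, float)])
        self._k += 1
        k = self._k
        if k <= self.warmup_beats:
            self._buf_h.append(hv)
            self._buf_y.append(float(rr_value))
            if k == self.warmup_beats:
                self._init_from_buffer()
            return
        # predict: random walk with a very weak pull toward the warm-up
        # solution, which suppresses slow coefficient wander along the
        # unobservable (collinear) directions without affecting tracking
        lam = self.anchor_lambda
        if lam > 0 and self._anchor is not None:
            g_pred = self.g + lam * (self._anchor - self.g)
            P = (1.0 - lam) ** 2 * self.P + self.q * np.eye(self._dim)
        else:
            g_pred = self.g
            P = self.P + self.q * np.eye(self._dim)
        self.g = g_pred
        nu = float(rr_value) - float(hv @ self.g)
        s = float(hv @ P @ hv) + self._r
        if not np.isfinite(s) or s <= 0:
            raise FloatingPointError(
                f"numerically singular innovation variance at beat {k}"
            )
        K = (P @ hv) / s
        self.g = self.g + K * nu
        self.P = P - np.outer(K, hv @ P)
        self._innov.append(nu)
        if self.adaptive_r and len(self._innov) >= 5:
            window = np.asarray(self._innov[-_ADAPT_WINDOW:])
            # innovation variance = h P h + r; subtract the state part
            r_hat = float(np.mean(window**2)) - float(hv @ self.P @ hv)
            self._r = max(r_hat, 1e-8 * self.r_init)
        self.beat_index.append(k)
        self.g_hist.append(self.g.copy())
        self.innovations.append(nu)

    @property
    def n_obs(self) -> int:
        """Number of observations processed so far."""
        return self._k

    @property
    def current_g(self) -> np.ndarray | None:
        return None if self.g is None else self.g.copy()

    def trajectory(self) -> CoeffTrajectory:
        if not self.g_hist:
            raise ValueError("no post-warm-up observations processed yet")
        G = np.asarray(self.g_hist)
        return CoeffTrajectory(
            beat_index=np.asarray(self.beat_index, int),
            g0=G[:, 0],
            g1=G[:, 1:],
            innovations=np.asarray(self.innovations),
            q=self.q,
            r_init=self.r_init,
            warmup_beats=self.warmup_beats,
        )


def kalman_estimate_coeffs(
    rr: RRSeries,
    regressors: np.ndarray | None = None,
    *,
    basis: LaguerreBasis | None = None,
    q: float = 1e-5,
    r_init: float = 1e-3,
    warmup_beats: int = 50,
    adaptive_r: bool = True,
    anchor_lambda: float = 0.005,
) -> CoeffTrajectory:
    """Filter the full RR series and return the coefficient trajectory.

    ``regressors`` is the matrix from :func:`svsdg.laguerre.convolve_rr`
    (row i pairs with interval i + 1); if omitted it is computed from
    ``basis``.
    """
    if regressors is None:
        if basis is None:
            raise ValueError("provide either regressors or basis")
        regressors = convolve_rr(rr, basis)
    else:
        basis = basis  # regressors given explicitly
    if basis is None:
        raise ValueError("basis is required (used for dimensioning)")
    tracker = KalmanCoeffTracker(
        basis, q=q, r_init=r_init, warmup_beats=warmup_beats,
        adaptive_r=adaptive_r, anchor_lambda=anchor_lambda,
    )
    y = rr.intervals[1:]
    if y.size <= warmup_beats:
        raise ValueError(
            f"series has {y.size} usable observations but warmup_beats={warmup_beats}"
        )
    for i in range(y.size):
        tracker.update(regressors[i], y[i])
    return tracker.trajectory()
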