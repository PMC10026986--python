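"""Discrete orthonormal Laguerre basis and the causal RR-history expansion.

The discrete Laguerre functions phi_j(n) with discount alpha in (0, 1) form an
orthonormal family over n = 0, 1, 2, ... with geometric decay; convolving the
RR history with them compresses long heartbeat memory into a handful of
regressors

    L_j(k) = sum_{n=0}^{k-1} phi_j(n) * RR(k - n - 1),

which is strictly causal: L_j(k) depends on RR(0..k-1) only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import RRSeries

__all__ = ["LaguerreBasis", "laguerre_basis", "convolve_rr"]


@dataclass(frozen=True)
class LaguerreBasis:
    """Orthonormal discrete Laguerre family phi_0..phi_max_order sampled at n = 0..length-1."""

    alpha: float
    max_order: int
    length: int
    functions: np.ndarray  # shape (max_order + 1, length)

    @property
    def n_functions(self) -> int:
        return self.max_order + 1


def laguerre_basis(alpha: float = 0.2, max_order: int = 8, length: int = 500) -> LaguerreBasis:
    """Build the discrete orthonormal Laguerre family.

    Parameters
    ----------
    alpha
        Geometric discount in (0, 1); larger alpha means longer memory.
    max_order
        Highest order j; the family has ``max_order + 1`` functions.
    length
        Number of samples n = 0..length-1; must be >= 10 * max_order so the
        family is effectively complete (the functions decay to ~0).

    Notes
    -----
    Uses the stable two-term recursion

        phi_0(n) = sqrt(alpha) * phi_0(n-1),              phi_0(0) = sqrt(1 - alpha)
        phi_j(n) = sqrt(alpha) * (phi_j(n-1) + phi_{j-1}(n)) - phi_{j-1}(n-1)

    which reproduces the closed form
    phi_j(n) = alpha^((n-j)/2) (1-alpha)^(1/2)
               sum_i (-1)^i C(n,i) C(j,i) alpha^(j-i) (1-alpha)^i.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    if length < 10 * max(max_order, 1):
        raise ValueError(f"length {length} < 10 * max_order = {10 * max_order}")

    sa = np.sqrt(alpha)
    phi = np.zeros((max_order + 1, length))
    phi[0] = np.sqrt(1.0 - alpha) * sa ** np.arange(length)
    for j in range(1, max_order + 1):
        phi[j, 0] = sa * phi[j - 1, 0]
        for n in range(1, length):
            phi[j, n] = sa * (phi[j, n - 1] + phi[j - 1, n]) - phi[j - 1, n - 1]
    return LaguerreBasis(alpha=alpha, max_order=max_order, length=length, functions=phi)


def convolve_rr(rr: RRSeries, basis: LaguerreBasis) -> np.ndarray:
    """Expand the RR history onto the Laguerre family.

    Returns the regressor matrix ``L`` of shape ``(n_intervals, n_functions)``
    where row k holds L_j(k) for the observation RR(k), k >= 1 (row 0 is the
    first predictable beat, i.e. L[i] pairs with interval index i+1). The sum
    is truncated at the available history and at the basis length.
    """
    if rr.intervals.size < 2:
        raise ValueError("need at least 2 intervals to form regressors")
    x = rr.intervals
    n_obs = x.size - 1  # observations k = 1 .. size-1
    phi = basis.functions
    L = np.empty((n_obs, phi.shape[0]))
    for i in range(n_obs):
        k = i + 1
        depth = min(k, basis.length)
        # RR(k-1), RR(k-2), ..., aligned with phi_j(0), phi_j(1), ...
        hist = x[k - 1 :: -1][:depth]
        L[i] = phi[:, :depth] @ hist
    return L


class OnlineLaguerreExpander:
    """Incremental version of :func:`convolve_rr` for beat-by-beat generation.

    Feed intervals one at a time; :meth:`regressors` returns L_j(k) for the
    *next* observation, computed from the history pushed so far.
    """

    def __init__(self, basis: LaguerreBasis) -> None:
        self.basis = basis
        self._hist: list[float] = []  # most recent first

    def push(self, rr_value: float) -> None:
        self._hist.insert(0, float(rr_value))
        if len(self._hist) > self.basis.length:
            self._hist.pop()

    @property
    def n_pushed(self) -> int:
        return len(self._hist)

    def regressors(self) -> np.ndarray:
        if not self._hist:
            raise ValueError("no history yet")
        hist = np.asarray(self._hist)
        return self.basis.functions[:, : hist.size] @ hist
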