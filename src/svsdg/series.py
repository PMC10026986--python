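"""Typed containers for the beat-domain and grid-domain series the pipeline moves around.

Conventions used throughout the package:

* all times are seconds from recording start;
* RR intervals are in seconds, band power in microvolt-squared (uV^2);
* grid-domain series (band power, modulation, coupling coefficients) live on a
  uniform 1-s grid; beat-domain series (RR, SAI, PAI) are indexed by the beat
  that closes each interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RRSeries",
    "AutonomicSeries",
    "BandPowerSeries",
    "ModulationSeries",
    "CouplingSeries",
    "BANDS",
    "DEFAULT_CHANNELS",
]

#: canonical EEG band edges, Hz (half-open intervals [low, high))
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: 9-channel frontal/central/parietal montage
DEFAULT_CHANNELS: tuple[str, ...] = (
    "F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "POz", "P4",
)

_RR_MIN, _RR_MAX = 0.2, 3.0


@dataclass(frozen=True)
class RRSeries:
    """A series of heartbeat times and the R-to-R intervals between them.

    ``beat_times`` has one more element than ``intervals``;
    ``intervals[k] = beat_times[k+1] - beat_times[k]`` and RR(k) is taken to be
    *observed* at ``beat_times[k+1]``, the beat that closes it.
    """

    beat_times: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        rr = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "intervals", rr)
        if bt.ndim != 1 or rr.ndim != 1 or bt.size != rr.size + 1:
            raise ValueError(
                "beat_times must be 1-d with exactly one more element than intervals"
            )
        if rr.size == 0:
            raise ValueError("RRSeries needs at least one interval")
        diffs = np.diff(bt)
        if np.any(diffs <= 0):
            k = int(np.argmax(diffs <= 0))
            raise ValueError(f"beat_times not strictly increasing at index {k + 1}")
        if np.max(np.abs(diffs - rr)) > 1e-9:
            k = int(np.argmax(np.abs(diffs - rr) > 1e-9))
            raise ValueError(
                f"intervals inconsistent with beat-time differences at interval {k} "
                f"(|diff| = {abs(diffs[k] - rr[k]):.3e} s > 1e-9 s)"
            )
        bad = (rr <= _RR_MIN) | (rr >= _RR_MAX)
        if np.any(bad):
            k = int(np.argmax(bad))
            raise ValueError(
                f"interval {k} = {rr[k]:.4f} s outside physiological range "
                f"({_RR_MIN}, {_RR_MAX}) s"
            )

    @classmethod
    def from_intervals(cls, intervals, t0: float = 0.0) -> "RRSeries":
        """Build from intervals alone, placing the first beat at ``t0``."""
        rr = np.asarray(intervals, dtype=float)
        bt = t0 + np.concatenate([[0.0], np.cumsum(rr)])
        return cls(beat_times=bt, intervals=rr)

    @property
    def n_beats(self) -> int:
        return self.beat_times.size

    @property
    def observation_times(self) -> np.ndarray:
        """Time of the beat closing each interval (one per interval)."""
        return self.beat_times[1:]

    def crop(self, t_start: float, t_stop: float) -> "RRSeries":
        """Intervals fully contained in the half-open window [t_start, t_stop)."""
        keep = (self.beat_times[:-1] >= t_start) & (self.beat_times[1:] < t_stop)
        if not np.any(keep):
            raise ValueError(f"no complete intervals in [{t_start}, {t_stop})")
        i0 = int(np.argmax(keep))
        i1 = len(keep) - int(np.argmax(keep[::-1]))
        return RRSeries(self.beat_times[i0 : i1 + 1], self.intervals[i0:i1])


@dataclass(frozen=True)
class AutonomicSeries:
    """Time-resolved sympathetic (SAI) and parasympathetic (PAI) activity indices.

    One sample per analysed beat; ``beat_times`` is the time at which each
    index value becomes available (the beat closing the RR interval used).
    Units are arbitrary (a.u.).
    """

    beat_times: np.ndarray
    sai: np.ndarray
    pai: np.ndarray

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        s = np.asarray(self.sai, dtype=float)
        p = np.asarray(self.pai, dtype=float)
        for name, arr in (("beat_times", bt), ("sai", s), ("pai", p)):
            object.__setattr__(self, name, arr)
        if not (bt.size == s.size == p.size):
            raise ValueError("beat_times, sai, pai must have equal length")
        if not (np.all(np.isfinite(s)) and np.all(np.isfinite(p))):
            raise ValueError("SAI/PAI must be finite everywhere")

    def interp(self, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linear interpolation of both indices onto a time grid."""
        grid = np.asarray(grid, dtype=float)
        return (
            np.interp(grid, self.beat_times, self.sai),
            np.interp(grid, self.beat_times, self.pai),
        )


@dataclass(frozen=True)
class BandPowerSeries:
    """EEG band power on a uniform 1-s grid: power[time, channel, band], uV^2."""

    grid: np.ndarray
    channels: tuple[str, ...]
    bands: tuple[str, ...]
    power: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        p = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "power", p)
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "bands", tuple(self.bands))
        if g.ndim != 1 or g.size < 2:
            raise ValueError("grid must be 1-d with at least 2 stamps")
        step = np.diff(g)
        if np.max(np.abs(step - 1.0)) > 1e-9:
            raise ValueError("grid step must be exactly 1 s")
        if p.shape != (g.size, len(self.channels), len(self.bands)):
            raise ValueError(
                f"power shape {p.shape} does not match "
                f"(n_times={g.size}, n_channels={len(self.channels)}, "
                f"n_bands={len(self.bands)})"
            )
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise ValueError("band power must be finite and non-negative")

    def series(self, channel: str, band: str) -> np.ndarray:
        return self.power[:, self.channels.index(channel), self.bands.index(band)]

    def crop(self, t_start: float, t_stop: float) -> "BandPowerSeries":
        keep = (self.grid >= t_start) & (self.grid < t_stop)
        if keep.sum() < 2:
            raise ValueError(f"fewer than 2 grid points in [{t_start}, {t_stop})")
        return BandPowerSeries(
            self.grid[keep], self.channels, self.bands, self.power[keep]
        )


@dataclass(frozen=True)
class ModulationSeries:
    """Heart-rate fluctuation m(t) about a sliding-window baseline, on a 1-s grid.

    ``rate`` is the interpolated instantaneous rate 1/RR (Hz); ``baseline`` is
    the window-mean rate assigned to each window centre, and ``m = rate -
    baseline``. Within any single window, the demeaned segment used by the
    regression stage has mean exactly zero by construction.
    """

    grid: np.ndarray
    rate: np.ndarray
    baseline: np.ndarray
    window_s: float

    def __post_init__(self) -> None:
        for name in ("grid", "rate", "baseline"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if not (self.grid.size == self.rate.size == self.baseline.size):
            raise ValueError("grid, rate, baseline must have equal length")

    @property
    def m(self) -> np.ndarray:
        return self.rate - self.baseline


@dataclass(frozen=True)
class CouplingSeries:
    """One directional coupling coefficient series on the 1-s grid.

    ``direction`` is ``"brain_to_heart"`` (descending, SDG = C_X / EEG_F(t-1))
    or ``"heart_to_brain"`` (ascending, SDG = Psi_F(t) / X(t)); ``branch`` is
    the autonomic side X in {SAI, PAI}; points where a denominator guard or a
    rank-deficient window made the estimate unreliable are masked out via
    ``valid`` and excluded from every condensation.
    """

    direction: str
    branch: str
    band: str
    channel: str
    grid: np.ndarray
    sdg: np.ndarray
    valid: np.ndarray
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in ("brain_to_heart", "heart_to_brain"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.branch not in ("SAI", "PAI"):
            raise ValueError(f"unknown branch {self.branch!r}")
        object.__setattr__(self, "grid", np.asarray(self.grid, float))
        object.__setattr__(self, "sdg", np.asarray(self.sdg, float))
        object.__setattr__(self, "valid", np.asarray(self.valid, bool))
        if not (self.grid.size == self.sdg.size == self.valid.size):
            raise ValueError("grid, sdg, valid must have equal length")
        if not np.all(np.isfinite(self.sdg[self.valid])):
            raise ValueError("sdg must be finite wherever valid")

    @property
    def key(self) -> str:
        return f"{self.direction}.{self.branch}.{self.band}.{self.channel}"

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_values(self) -> np.ndarray:
        return self.sdg[self.valid]
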