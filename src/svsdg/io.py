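"""Delimited-text readers and writers for the pipeline's data streams.

Dialects (all CSV with a header row, times in seconds from recording start):

* ``rr.csv``: ``t_beat_s, rr_s`` -- one row per beat; ``rr_s`` is the
  interval *closing* at that beat (empty for the first beat).
* ``power.csv``: ``t_s, channel, band, power_uv2`` (long format, 1-s grid).
* ``conditions.csv``: ``label, onset_s, duration_s``.
* ``coupling.csv``: ``t_s, direction, branch, band, channel, value, valid``.
* ``features.csv``: one row per subject x condition, canonical feature
  identifiers like ``heart_to_brain.SAI.beta.Cz.mad`` as columns.
* raw EEG: ``t_s`` column plus one column per channel (uV), uniform
  sampling; EDF files are read through :mod:`mne` when available.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .bandpower import EEGRecording
from .series import BandPowerSeries, RRSeries

__all__ = [
    "load_rr",
    "write_rr",
    "load_bandpower",
    "write_bandpower",
    "load_conditions",
    "write_conditions",
    "load_eeg",
]


def load_rr(path) -> RRSeries:
    """Read an RR series, validating monotonicity and cumulative consistency.

    Malformed rows are reported with their line number (header = line 1).
    """
    df = pd.read_csv(path)
    for col in ("t_beat_s", "rr_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    t = df["t_beat_s"].to_numpy(float)
    rr = df["rr_s"].to_numpy(float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 beats")
    bad = np.where(~np.isfinite(rr[1:]) | (rr[1:] <= 0))[0]
    if bad.size:
        raise ValueError(
            f"{path}: line {int(bad[0]) + 3}: non-positive or missing rr_s"
        )
    dt = np.diff(t)
    bad = np.where(dt <= 0)[0]
    if bad.size:
        raise ValueError(f"{path}: line {int(bad[0]) + 3}: beat times not increasing")
    mism = np.abs(dt - rr[1:])
    bad = np.where(mism > 1e-9)[0]
    if bad.size:
        raise ValueError(
            f"{path}: line {int(bad[0]) + 3}: beat time vs cumulative interval "
            f"mismatch of {mism[bad[0]]:.3e} s (> 1e-9 s)"
        )
    return RRSeries(beat_times=t, intervals=rr[1:])


def write_rr(rr: RRSeries, path) -> None:
    df = pd.DataFrame(
        {
            "t_beat_s": rr.beat_times,
            "rr_s": np.concatenate([[np.nan], rr.intervals]),
        }
    )
    df.to_csv(path, index=False, float_format="%.12f")


def load_bandpower(path) -> BandPowerSeries:
    """Read a long-format band-power file into the (time, channel, band) cube."""
    df = pd.read_csv(path)
    need = {"t_s", "channel", "band", "power_uv2"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    channels = tuple(pd.unique(df["channel"]))
    bands = tuple(pd.unique(df["band"]))
    grid = np.sort(pd.unique(df["t_s"]).astype(float))
    cube = np.full((grid.size, len(channels), len(bands)), np.nan)
    ti = {t: i for i, t in enumerate(grid)}
    ci = {c: i for i, c in enumerate(channels)}
    bi = {b: i for i, b in enumerate(bands)}
    cube[
        df["t_s"].map(ti).to_numpy(),
        df["channel"].map(ci).to_numpy(),
        df["band"].map(bi).to_numpy(),
    ] = df["power_uv2"].to_numpy(float)
    if np.isnan(cube).any():
        t_bad, c_bad, b_bad = np.argwhere(np.isnan(cube))[0]
        raise ValueError(
            f"{path}: missing power for t={grid[t_bad]}, "
            f"channel={channels[c_bad]}, band={bands[b_bad]}"
        )
    return BandPowerSeries(grid=grid, channels=channels, bands=bands, power=cube)


def write_bandpower(bp: BandPowerSeries, path) -> None:
    t_idx, c_idx, b_idx = np.meshgrid(
        np.arange(bp.grid.size),
        np.arange(len(bp.channels)),
        np.arange(len(bp.bands)),
        indexing="ij",
    )
    df = pd.DataFrame(
        {
            "t_s": bp.grid[t_idx.ravel()],
            "channel": np.asarray(bp.channels)[c_idx.ravel()],
            "band": np.asarray(bp.bands)[b_idx.ravel()],
            "power_uv2": bp.power.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def load_conditions(path) -> dict[str, tuple[float, float]]:
    df = pd.read_csv(path)
    need = {"label", "onset_s", "duration_s"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    out = {}
    for _, row in df.iterrows():
        if row["label"] in out:
            raise ValueError(f"{path}: duplicate condition label {row['label']!r}")
        onset, dur = float(row["onset_s"]), float(row["duration_s"])
        if dur <= 0:
            raise ValueError(f"{path}: non-positive duration for {row['label']!r}")
        out[row["label"]] = (onset, onset + dur)
    return out


def write_conditions(windows: dict[str, tuple[float, float]], path) -> None:
    df = pd.DataFrame(
        [
            {"label": k, "onset_s": lo, "duration_s": hi - lo}
            for k, (lo, hi) in windows.items()
        ]
    )
    df.to_csv(path, index=False)


def load_eeg(path, sampling_rate: float | None = None) -> EEGRecording:
    """Read raw multichannel EEG from delimited text or EDF.

    Text files need a ``t_s`` column (uniform sampling enforced) plus one
    column per channel in uV. ``.edf`` files are read through mne.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return EEGRecording(
            sampling_rate=float(raw.info["sfreq"]),
            channels=tuple(raw.ch_names),
            samples=raw.get_data() * 1e6,  # volts -> microvolts
            start_time=0.0,
        )
    df = pd.read_csv(path)
    if "t_s" not in df.columns:
        raise ValueError(f"{path}: missing column 't_s'")
    t = df["t_s"].to_numpy(float)
    dt = np.diff(t)
    if t.size < 2 or np.max(np.abs(dt - dt[0])) > 1e-6:
        raise ValueError(f"{path}: non-uniform sampling")
    fs = 1.0 / dt[0]
    if sampling_rate is not None and abs(fs - sampling_rate) > 1e-6:
        raise ValueError(f"{path}: sampling rate {fs:.3f} != expected {sampling_rate}")
    channels = tuple(c for c in df.columns if c != "t_s")
    return EEGRecording(
        sampling_rate=fs,
        channels=channels,
        samples=df[list(channels)].to_numpy(float).T,
        start_time=float(t[0]),
    )
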