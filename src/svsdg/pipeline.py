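"""End-to-end pipeline: band power -> autonomic -> coupling -> features -> stats.

The pipeline operates on a protocol dataset (synthetic or loaded from the
delimited-text dialects in :mod:`svsdg.io`), estimates the autonomic indices
once per subject over the whole recording, fits the bidirectional coupling
per condition, condenses every coupling series into its per-condition MAD
(the variability feature the condition statistics discriminate on), and runs
the Friedman battery, MRMR ranking and cross-validated stress models.

Stress coding: rest = 0, stressor1 = 1, stressor2 = 4, stressor3 = 5
(matching the group-median self reports); the binary class is low stress
(rest + stressor1) vs high stress (stressors 2 and 3).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as svio
from .autonomic import AutonomicIndexModel
from .coupling import BrainHeartModel
from .mrmr import MRMRResult, mrmr_rank
from .series import RRSeries
from .stats import (
    CVResult,
    bonferroni_threshold,
    condense_markers,
    kernel_nb_classify_cv,
    kernel_regression_cv,
)
from .synthetic import ProtocolDataset, SyntheticConfig, generate_protocol_dataset

__all__ = [
    "RunConfig",
    "run_pipeline",
    "build_feature_table",
    "autonomic_condition_stats",
    "coupling_friedman_battery",
    "nested_cv",
    "write_dataset",
    "STRESS_LEVELS",
]

logger = logging.getLogger(__name__)

#: stress-level encoding of the four conditions, in protocol order
STRESS_LEVELS = (0.0, 1.0, 4.0, 5.0)


@dataclass
class RunConfig:
    """Fully serialisable pipeline configuration (provenance first)."""

    output_dir: str
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    input_dir: str | None = None  # per-subject rr.csv / power.csv / conditions.csv
    window_s: float = 15.0
    laguerre_alpha: float = 0.2
    kalman_q: float = 1e-5
    warmup_beats: int = 50
    regression_lambda: float = 0.027
    n_folds: int = 5
    alpha: float = 0.05
    nested_selection: bool = True
    write_coupling_series: bool = False
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.synthetic is None and self.input_dir is None:
            self.synthetic = SyntheticConfig(seed=self.seed)

    def to_flat(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if k == "synthetic":
                if v is not None:
                    for sk, sv in v.__dict__.items():
                        out[f"synthetic.{sk}"] = repr(sv)
            else:
                out[k] = repr(v)
        return out


def _feature_key(direction: str, branch: str, band: str, channel: str, tag: str = "mad") -> str:
    return f"{direction}.{branch}.{band}.{channel}.{tag}"


def build_feature_table(
    dataset: ProtocolDataset,
    window_s: float = 15.0,
    kalman_q: float | None = None,
    warmup_beats: int | None = None,
    condensation: str = "mad",
) -> tuple[pd.DataFrame, dict]:
    """Subject x condition table of condensed coupling features.

    Returns ``(table, fits)`` where the table has one row per subject and
    condition with the full set of ``direction.branch.band.channel.mad``
    columns plus ``subject``, ``condition``, ``stress_level`` and
    ``stress_class``, and ``fits`` maps subjects to their per-condition
    coupling results (reused by the statistics stage).
    """
    if condensation not in ("mad", "median"):
        raise ValueError("condensation must be 'mad' or 'median'")
    cfg = dataset.config
    kalman_q = cfg.kalman_q if kalman_q is None else kalman_q
    warmup_beats = cfg.warmup_beats if warmup_beats is None else warmup_beats
    labels = cfg.condition_labels
    levels = dict(zip(labels, STRESS_LEVELS))
    rows, fits = [], {}
    for subj in dataset.subjects:
        rr = subj.full_rr()
        res_auto = AutonomicIndexModel(rr).fit(q=kalman_q, warmup_beats=warmup_beats)
        fits[subj.subject_id] = {"autonomic": res_auto, "conditions": {}}
        for ci, cond in enumerate(labels):
            bhm = BrainHeartModel(
                rr, subj.bandpower[cond],
                autonomic=res_auto.autonomic, window_s=window_s,
            )
            res = bhm.fit()
            fits[subj.subject_id]["conditions"][cond] = res
            row = {
                "subject": subj.subject_id,
                "condition": cond,
                "stress_level": levels[cond],
                "stress_class": int(ci >= 2),
            }
            for cs in res.couplings.values():
                x = cs.valid_values()
                if x.size < 10:
                    raise ValueError(
                        f"subject {subj.subject_id}, condition {cond}: only "
                        f"{x.size} valid points for {cs.key}"
                    )
                med = float(np.median(x))
                val = float(np.median(np.abs(x - med))) if condensation == "mad" else med
                row[f"{cs.key}.{condensation}"] = val
            rows.append(row)
    table = pd.DataFrame(rows)
    return table, fits


def autonomic_condition_stats(dataset: ProtocolDataset, fits: dict) -> pd.DataFrame:
    """Per-subject, per-condition median and MAD of z-scored RR, SAI and PAI."""
    windows = dataset.condition_windows
    rows = []
    for subj in dataset.subjects:
        res = fits[subj.subject_id]["autonomic"]
        au = res.autonomic
        rr = subj.full_rr()
        for name, values, times in (
            ("rr", rr.intervals, rr.observation_times),
            ("sai", au.sai, au.beat_times),
            ("pai", au.pai, au.beat_times),
        ):
            df = condense_markers(values, times, windows, normalize=True)
            for cond, r in df.iterrows():
                rows.append(
                    {
                        "subject": subj.subject_id,
                        "marker": name,
                        "condition": cond,
                        "median": r["median"],
                        "mad": r["mad"],
                        "n": r["n"],
                    }
                )
    return pd.DataFrame(rows)


def coupling_friedman_battery(
    table: pd.DataFrame,
    channels: tuple[str, ...],
    bands: tuple[str, ...],
    conditions: tuple[str, ...],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Friedman test across conditions per (direction, branch, band, channel).

    The test input is the subjects x conditions matrix of MAD features; the
    per-channel threshold is Bonferroni-corrected for the number of channels,
    mirroring the channel-wise multiple-comparison control.
    """
    thr = bonferroni_threshold(alpha, len(channels))
    out = []
    subjects = sorted(table["subject"].unique())
    for direction in ("heart_to_brain", "brain_to_heart"):
        for branch in ("SAI", "PAI"):
            for band in bands:
                for ch in channels:
                    col = _feature_key(direction, branch, band, ch)
                    mat = np.empty((len(subjects), len(conditions)))
                    for si, s in enumerate(subjects):
                        for ci, c in enumerate(conditions):
                            cell = table[
                                (table["subject"] == s) & (table["condition"] == c)
                            ][col]
                            mat[si, ci] = float(cell.iloc[0])
                    from .stats import friedman_test

                    stat, p = friedman_test(mat)
                    out.append(
                        {
                            "direction": direction,
                            "branch": branch,
                            "band": band,
                            "channel": ch,
                            "statistic": stat,
                            "p": p,
                            "significant": p < thr,
                            "threshold": thr,
                        }
                    )
    return pd.DataFrame(out)


def nested_cv(
    table: pd.DataFrame,
    mode: str,
    n_top: int = 5,
    lam: float = 0.027,
    n_folds: int = 5,
    seed: int = 0,
    nested: bool = True,
) -> tuple[CVResult, MRMRResult]:
    """MRMR selection + cross-validated model.

    With ``nested=True`` (default) the MRMR ranking is recomputed inside each
    training fold and the reported ranking is the one from the full table
    (for inspection only); with ``nested=False`` the full-table top features
    are used in every fold.
    """
    feature_cols = [c for c in table.columns if c.endswith(".mad") or c.endswith(".median")]
    target = "stress_level" if mode == "regression" else "stress_class"
    full_rank = mrmr_rank(table, target, feature_cols, mode=mode, seed=seed)
    if not nested:
        selected = full_rank.top(n_top)
        if mode == "regression":
            cv = kernel_regression_cv(table, selected, lam=lam, n_folds=n_folds, seed=seed)
        else:
            cv = kernel_nb_classify_cv(table, selected, n_folds=n_folds, seed=seed)
        return cv, full_rank

    # nested: selection re-done per training fold
    rng = np.random.default_rng(seed)
    subjects = table["subject"].to_numpy()
    uniq = np.unique(subjects)
    perm = rng.permutation(uniq)
    folds = {s: i % n_folds for i, s in enumerate(perm)}
    fold_idx = np.asarray([folds[s] for s in subjects])
    y = table[target].to_numpy(float)
    pred = np.full(y.size, np.nan)
    for f in range(n_folds):
        tr = table[fold_idx != f]
        te = table[fold_idx == f]
        rank = mrmr_rank(tr, target, feature_cols, mode=mode, seed=seed)
        sel = rank.top(n_top)
        if mode == "regression":
            from sklearn.kernel_ridge import KernelRidge

            X = tr[sel].to_numpy(float)
            mu, sd = X.mean(0), X.std(0)
            sd[sd == 0] = 1.0
            Xtr = (X - mu) / sd
            Xte = (te[sel].to_numpy(float) - mu) / sd
            d = np.sqrt(((Xtr[:, None, :] - Xtr[None, :, :]) ** 2).sum(-1))
            bw = np.median(d[np.triu_indices_from(d, k=1)])
            model = KernelRidge(alpha=lam, kernel="rbf", gamma=1.0 / (2 * bw**2))
            model.fit(Xtr, tr[target].to_numpy(float))
            pred[fold_idx == f] = model.predict(Xte)
        else:
            # train the kernel naive Bayes on tr, predict te
            from scipy.stats import gaussian_kde

            ytr = tr[target].to_numpy(int)
            classes = np.unique(ytr)
            log_post = np.zeros((len(te), classes.size))
            for ci, c in enumerate(classes):
                rows_c = tr[ytr == c]
                log_post[:, ci] += np.log(len(rows_c) / len(tr))
                for col in sel:
                    x_tr = rows_c[col].to_numpy(float)
                    if np.std(x_tr) == 0:
                        x_tr = x_tr + rng.normal(0, 1e-9, x_tr.size)
                    kde = gaussian_kde(x_tr, bw_method="silverman")
                    log_post[:, ci] += np.log(
                        np.maximum(kde(te[col].to_numpy(float)), 1e-300)
                    )
            pred[fold_idx == f] = classes[np.argmax(log_post, axis=1)]
    frame = pd.DataFrame(
        {"subject": subjects, "fold": fold_idx, "y_true": y, "y_pred": pred}
    )
    if mode == "regression":
        metrics = {"rmse": float(np.sqrt(np.mean((pred - y) ** 2)))}
    else:
        pos = y == 1
        metrics = {
            "accuracy": float(np.mean(pred == y)),
            "sensitivity": float(np.mean(pred[pos] == y[pos])),
            "specificity": float(np.mean(pred[~pos] == y[~pos])),
        }
    cv = CVResult(
        fold_of_subject=folds,
        predictions=frame,
        metrics=metrics,
        params={"mode": mode, "nested": True, "n_folds": n_folds, "seed": seed,
                "lambda": lam if mode == "regression" else None},
    )
    return cv, full_rank


# ---------------------------------------------------------------------------
# dataset serialisation
# ---------------------------------------------------------------------------

def write_dataset(dataset: ProtocolDataset, outdir) -> list[Path]:
    """Write the synthetic dataset as delimited text per stream plus sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    cfgfile = outdir / "config.txt"
    with open(cfgfile, "w") as fh:
        for k, v in dataset.config.__dict__.items():
            fh.write(f"{k} = {v!r}\n")
    written.append(cfgfile)
    condfile = outdir / "conditions.csv"
    svio.write_conditions(dataset.condition_windows, condfile)
    written.append(condfile)
    for subj in dataset.subjects:
        sdir = outdir / f"subject_{subj.subject_id:02d}"
        sdir.mkdir(exist_ok=True)
        svio.write_rr(subj.full_rr(), sdir / "rr.csv")
        svio.write_bandpower(subj.full_bandpower(), sdir / "power.csv")
        tr = subj.truth
        gt = pd.DataFrame(
            {
                "t_s": tr.grid,
                "c_sai": tr.c_sai,
                "c_pai": tr.c_pai,
                "s_star": tr.s_star,
                "p_star": tr.p_star,
                "modulation_hz": tr.modulation,
                "eta_sd": tr.eta_sd,
            }
        )
        gt.to_csv(sdir / "ground_truth.csv", index=False, float_format="%.9g")
        written += [sdir / "rr.csv", sdir / "power.csv", sdir / "ground_truth.csv"]
    return written


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in order, writing every artifact plus a manifest.

    Returns the output directory. Deterministic stages are bit-identical on
    rerun with the same configuration.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    # provenance first
    with open(out / "run_config.txt", "w") as fh:
        for k, v in config.to_flat().items():
            fh.write(f"{k} = {v}\n")
    t_start = time.time()
    stage_times = {}

    def tick(stage):
        stage_times[stage] = time.time()
        logger.info("stage %s ...", stage)

    try:
        tick("simulate/load")
        if config.input_dir is not None:
            dataset = _load_dataset(config)
        else:
            dataset = generate_protocol_dataset(config.synthetic)
        cfg = dataset.config

        tick("features")
        table, fits = build_feature_table(dataset, window_s=config.window_s)
        table.to_csv(out / "features.csv", index=False)

        tick("autonomic")
        auto_stats = autonomic_condition_stats(dataset, fits)
        auto_stats.to_csv(out / "autonomic_stats.csv", index=False)
        for subj in dataset.subjects:
            au = fits[subj.subject_id]["autonomic"].autonomic
            pd.DataFrame(
                {"t_beat_s": au.beat_times, "sai": au.sai, "pai": au.pai}
            ).to_csv(out / f"autonomic_subject_{subj.subject_id:02d}.csv", index=False)

        if config.write_coupling_series:
            tick("coupling-series")
            for subj in dataset.subjects:
                frames = [
                    fits[subj.subject_id]["conditions"][c].to_frame()
                    for c in cfg.condition_labels
                ]
                pd.concat(frames, ignore_index=True).to_csv(
                    out / f"coupling_subject_{subj.subject_id:02d}.csv", index=False
                )

        tick("stats")
        battery = coupling_friedman_battery(
            table, cfg.channels, cfg.bands, cfg.condition_labels, alpha=config.alpha
        )
        battery.to_csv(out / "friedman_coupling.csv", index=False)

        tick("mrmr+cv")
        cv_reg, rank_reg = nested_cv(
            table, "regression", lam=config.regression_lambda,
            n_folds=config.n_folds, seed=config.seed, nested=config.nested_selection,
        )
        cv_cls, rank_cls = nested_cv(
            table, "classification", n_folds=config.n_folds,
            seed=config.seed, nested=config.nested_selection,
        )
        rank_reg.to_frame().to_csv(out / "mrmr_regression.csv", index=False)
        rank_cls.to_frame().to_csv(out / "mrmr_classification.csv", index=False)
        cv_reg.predictions.to_csv(out / "cv_regression.csv", index=False)
        cv_cls.predictions.to_csv(out / "cv_classification.csv", index=False)
        with open(out / "cv_metrics.json", "w") as fh:
            json.dump({"regression": cv_reg.metrics, "classification": cv_cls.metrics}, fh, indent=2)

        with open(out / "summary.txt", "w") as fh:
            fh.write(cv_reg.summary() + "\n\n" + cv_cls.summary() + "\n")
    except Exception as err:
        stage = list(stage_times)[-1] if stage_times else "init"
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline finished in %.1f s", time.time() - t_start)
    return out


def _load_dataset(config: RunConfig) -> ProtocolDataset:
    """Assemble a ProtocolDataset from per-subject text files."""
    from .synthetic import GroundTruth, ProtocolSubject

    root = Path(config.input_dir)
    windows = svio.load_conditions(root / "conditions.csv")
    labels = tuple(windows)
    subjects = []
    lead_lo = min(lo for lo, _ in windows.values())
    for sdir in sorted(root.glob("subject_*")):
        rr_full = svio.load_rr(sdir / "rr.csv")
        bp_full = svio.load_bandpower(sdir / "power.csv")
        rr_by, bp_by = {}, {}
        close = rr_full.observation_times

        def _segment(lo, hi):
            keep = (close > lo) & (close <= hi)
            i0 = int(np.argmax(keep))
            i1 = len(keep) - int(np.argmax(keep[::-1]))
            return RRSeries(
                rr_full.beat_times[i0 : i1 + 1], rr_full.intervals[i0:i1]
            )

        for label in labels:
            lo, hi = windows[label]
            rr_by[label] = _segment(lo, hi)
            bp_by[label] = bp_full.crop(lo, hi)
        subjects.append(
            ProtocolSubject(
                subject_id=int(sdir.name.split("_")[1]),
                rr=rr_by,
                bandpower=bp_by,
                truth=None,
                reports={},
                rr_lead=_segment(-1.0, lead_lo) if lead_lo > 0 else None,
                bandpower_lead=bp_full.crop(0.0, lead_lo) if lead_lo > 1 else None,
            )
        )
    # reconstruct a config shell carrying the protocol structure
    lead_in = min(lo for lo, _ in windows.values())
    plan = tuple((label, hi - lo) for label, (lo, hi) in windows.items())
    shell = SyntheticConfig(
        n_subjects=len(subjects),
        condition_plan=plan,
        lead_in_s=lead_in,
        channels=subjects[0].bandpower[labels[0]].channels,
        bands=subjects[0].bandpower[labels[0]].bands,
        seed=config.seed,
    )
    return ProtocolDataset(config=shell, subjects=subjects)
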