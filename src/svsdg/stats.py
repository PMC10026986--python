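"""Condition-wise statistics and cross-validated stress models.

Time-resolved markers are condensed per condition into median and MAD
(median absolute deviation, no consistency constant -- a descriptive
variability measure). Condition-wise comparisons use the Friedman test
(4 paired conditions) and the Wilcoxon signed-rank test (2 paired
conditions), with a Bonferroni-corrected significance threshold across
channels. Multivariate stress models are a Gaussian-kernel ridge regression
onto the stress level and a kernel naive Bayes classifier for low vs high
stress, both evaluated in subject-stratified five-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "condense_markers",
    "friedman_test",
    "wilcoxon_signed_rank",
    "bonferroni_threshold",
    "friedman_by_channel",
    "kernel_regression_cv",
    "kernel_nb_classify_cv",
    "StatsReport",
    "CVResult",
]

MIN_POINTS_PER_CONDITION = 10


def condense_markers(
    values: np.ndarray,
    times: np.ndarray,
    condition_windows: dict[str, tuple[float, float]],
    valid: np.ndarray | None = None,
    normalize: bool = False,
) -> pd.DataFrame:
    """Per-condition median and MAD of a time-resolved marker.

    With ``normalize=True`` the series is z-scored over the whole protocol
    duration first (using valid points only). A condition with fewer than
    10 valid points gets NaN cells and a warning.

    Returns a DataFrame indexed by condition with columns median, mad, n.
    """
    import warnings

    v = np.asarray(values, float)
    t = np.asarray(times, float)
    ok = np.ones(v.size, bool) if valid is None else np.asarray(valid, bool)
    ok = ok & np.isfinite(v)
    if normalize:
        mu, sd = v[ok].mean(), v[ok].std()
        v = (v - mu) / (sd if sd > 0 else 1.0)
    rows = {}
    for cond, (lo, hi) in condition_windows.items():
        sel = ok & (t >= lo) & (t < hi)
        n = int(sel.sum())
        if n < MIN_POINTS_PER_CONDITION:
            warnings.warn(
                f"condition {cond!r}: only {n} valid points (< {MIN_POINTS_PER_CONDITION}); "
                "cell marked missing",
                stacklevel=2,
            )
            rows[cond] = (np.nan, np.nan, n)
            continue
        x = v[sel]
        med = float(np.median(x))
        mad = float(np.median(np.abs(x - med)))
        rows[cond] = (med, mad, n)
    return pd.DataFrame(rows, index=["median", "mad", "n"]).T


def friedman_test(block_matrix: np.ndarray) -> tuple[float, float]:
    """Friedman rank test over a subjects x conditions block matrix.

    Within-row average ranks with the standard tie correction; the statistic
    is referred to a chi-square distribution with k - 1 degrees of freedom.
    A matrix whose rows are all completely tied (e.g. identical columns)
    yields statistic 0 and p = 1.
    """
    x = np.asarray(block_matrix, float)
    if x.ndim != 2:
        raise ValueError("block_matrix must be 2-d (subjects x conditions)")
    n, k = x.shape
    if k < 3 or n < 5:
        raise ValueError(f"need >= 3 conditions and >= 5 subjects, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells: listwise deletion is the caller's job")
    ranks = np.apply_along_axis(sps.rankdata, 1, x)
    rank_sums = ranks.sum(axis=0)
    stat_raw = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    # tie correction
    tie_term = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (n * k * (k**2 - 1))
    if denom <= 0:
        return 0.0, 1.0
    stat = stat_raw / denom
    p = float(sps.chi2.sf(stat, k - 1))
    return float(stat), p


def wilcoxon_signed_rank(a, b) -> tuple[float, float, int]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (their count is returned). For n <= 25
    retained pairs the p-value comes from exact enumeration of the signed
    rank-sum null distribution (ties handled by average ranks); above that a
    normal approximation with tie correction is used.

    Returns (W, p, n_zeros_dropped) where W is the smaller signed rank sum.
    """
    import warnings

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-d sequences")
    d = a - b
    nz = d != 0
    n_zero = int((~nz).sum())
    d = d[nz]
    n = d.size
    if n == 0:
        warnings.warn("all differences zero; p = 1", stacklevel=2)
        return 0.0, 1.0, n_zero
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= 25:
        # exact null: enumerate the distribution of W+ over all 2^n sign
        # assignments by dynamic programming on doubled (integer) ranks
        r2 = np.round(2 * ranks).astype(int)
        total = int(r2.sum())
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: total + 1 - r]
            dist = dist + shifted
        dist /= dist.sum()
        wp2 = int(round(2 * w_plus))
        cdf_le = dist[: wp2 + 1].sum()
        cdf_ge = dist[wp2:].sum()
        p = float(min(1.0, 2.0 * min(cdf_le, cdf_ge)))
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie = float(np.sum(counts**3 - counts))
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie / 48.0
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return w, p, n_zero


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Corrected per-test significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class StatsReport:
    """Friedman results per (marker, channel) with the corrected threshold."""

    alpha: float
    n_tests: int
    threshold: float
    table: pd.DataFrame  # columns: marker, channel, statistic, p, significant

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary(self) -> str:
        lines = [
            "Condition-wise Friedman tests",
            "=" * 52,
            f"alpha = {self.alpha}, {self.n_tests} channels, "
            f"corrected threshold = {self.threshold:.4f}",
            f"{len(self.significant())} / {len(self.table)} tests significant",
        ]
        return "\n".join(lines)


def friedman_by_channel(
    blocks: dict[str, np.ndarray], alpha: float = 0.05, n_tests: int | None = None
) -> StatsReport:
    """Run a Friedman test per channel (or per any keyed block matrix)."""
    n_tests = len(blocks) if n_tests is None else n_tests
    thr = bonferroni_threshold(alpha, n_tests)
    rows = []
    for key, mat in blocks.items():
        stat, p = friedman_test(mat)
        rows.append({"channel": key, "statistic": stat, "p": p, "significant": p < thr})
    return StatsReport(
        alpha=alpha, n_tests=n_tests, threshold=thr, table=pd.DataFrame(rows)
    )


# ---------------------------------------------------------------------------
# cross-validated stress models
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Held-out predictions and metrics from subject-stratified K-fold CV."""

    fold_of_subject: dict
    predictions: pd.DataFrame  # columns: subject, fold, y_true, y_pred
    metrics: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Cross-validated stress model", "=" * 52]
        for k, v in self.params.items():
            lines.append(f"{k:22s}: {v}")
        for k, v in self.metrics.items():
            lines.append(f"{k:22s}: {v:.4f}" if isinstance(v, float) else f"{k:22s}: {v}")
        return "\n".join(lines)


def _subject_folds(subjects: np.ndarray, n_folds: int, rng: np.random.Generator) -> dict:
    uniq = np.unique(subjects)
    if uniq.size < n_folds:
        raise ValueError(f"need >= {n_folds} subjects, got {uniq.size}")
    perm = rng.permutation(uniq)
    return {s: i % n_folds for i, s in enumerate(perm)}


def kernel_regression_cv(
    table: pd.DataFrame,
    selected: list[str],
    target: str = "stress_level",
    subject_col: str = "subject",
    lam: float = 0.027,
    n_folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Gaussian-kernel ridge regression of the stress level, subject-stratified CV.

    Features are z-scored per training fold; the kernel bandwidth is the
    median pairwise training distance; ``lam`` is the ridge regularisation
    strength. RMSE is computed on pooled held-out predictions.
    """
    from sklearn.kernel_ridge import KernelRidge

    missing = [c for c in selected if c not in table.columns]
    if missing:
        raise KeyError(f"selected features missing from table: {missing}")
    rng = np.random.default_rng(seed)
    subjects = table[subject_col].to_numpy()
    folds = _subject_folds(subjects, n_folds, rng)
    fold_idx = np.asarray([folds[s] for s in subjects])
    X = table[selected].to_numpy(float)
    y = table[target].to_numpy(float)
    pred = np.full(y.size, np.nan)
    for f in range(n_folds):
        tr, te = fold_idx != f, fold_idx == f
        mu, sd = X[tr].mean(0), X[tr].std(0)
        sd[sd == 0] = 1.0
        Xtr, Xte = (X[tr] - mu) / sd, (X[te] - mu) / sd
        d = np.sqrt(((Xtr[:, None, :] - Xtr[None, :, :]) ** 2).sum(-1))
        bw = np.median(d[np.triu_indices_from(d, k=1)])
        if not np.isfinite(bw) or bw <= 0:
            raise ValueError(f"degenerate kernel matrix in fold {f}")
        gamma = 1.0 / (2.0 * bw**2)
        model = KernelRidge(alpha=lam, kernel="rbf", gamma=gamma)
        model.fit(Xtr, y[tr])
        pred[te] = model.predict(Xte)
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    frame = pd.DataFrame(
        {"subject": subjects, "fold": fold_idx, "y_true": y, "y_pred": pred}
    )
    return CVResult(
        fold_of_subject=folds,
        predictions=frame,
        metrics={"rmse": rmse},
        params={"lambda": lam, "n_folds": n_folds, "seed": seed, "features": selected},
    )


def kernel_nb_classify_cv(
    table: pd.DataFrame,
    selected: list[str],
    target: str = "stress_class",
    subject_col: str = "subject",
    n_folds: int = 5,
    seed: int = 0,
    positive_label: int = 1,
) -> CVResult:
    """Kernel naive Bayes (Gaussian kernel densities per feature and class).

    Per training fold, each selected feature gets a 1-d Gaussian KDE per
    class (Silverman bandwidth); class priors come from the training rows;
    held-out rows are classified by the Bayes rule. Reports accuracy,
    sensitivity (detection of the positive/high-stress class) and
    specificity. A fold whose training part lacks a class triggers one
    reseeded refold, then an error.
    """
    from scipy.stats import gaussian_kde

    missing = [c for c in selected if c not in table.columns]
    if missing:
        raise KeyError(f"selected features missing from table: {missing}")
    subjects = table[subject_col].to_numpy()
    X = table[selected].to_numpy(float)
    y = table[target].to_numpy(int)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")

    def run(seed_try: int):
        rng = np.random.default_rng(seed_try)
        folds = _subject_folds(subjects, n_folds, rng)
        fold_idx = np.asarray([folds[s] for s in subjects])
        for f in range(n_folds):
            if np.unique(y[fold_idx != f]).size < 2:
                return None, None
        pred = np.empty(y.size, int)
        for f in range(n_folds):
            tr, te = fold_idx != f, fold_idx == f
            log_post = np.zeros((int(te.sum()), classes.size))
            for ci, c in enumerate(classes):
                rows = tr & (y == c)
                log_post[:, ci] += np.log(rows.sum() / tr.sum())
                for j in range(X.shape[1]):
                    x_tr = X[rows, j]
                    if np.std(x_tr) == 0:
                        x_tr = x_tr + rng.normal(0, 1e-9, x_tr.size)
                    kde = gaussian_kde(x_tr, bw_method="silverman")
                    dens = np.maximum(kde(X[te, j]), 1e-300)
                    log_post[:, ci] += np.log(dens)
            pred[te] = classes[np.argmax(log_post, axis=1)]
        return folds, pred

    folds, pred = run(seed)
    if folds is None:
        folds, pred = run(seed + 1)
        if folds is None:
            raise ValueError("single-class training fold after refold")
    fold_idx = np.asarray([folds[s] for s in subjects])
    pos = y == positive_label
    acc = float(np.mean(pred == y))
    sens = float(np.mean(pred[pos] == y[pos])) if pos.any() else np.nan
    spec = float(np.mean(pred[~pos] == y[~pos])) if (~pos).any() else np.nan
    frame = pd.DataFrame(
        {"subject": subjects, "fold": fold_idx, "y_true": y, "y_pred": pred}
    )
    return CVResult(
        fold_of_subject=folds,
        predictions=frame,
        metrics={"accuracy": acc, "sensitivity": sens, "specificity": spec},
        params={"n_folds": n_folds, "seed": seed, "features": selected},
    )
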