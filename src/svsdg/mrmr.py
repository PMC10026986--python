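"""Minimum-redundancy maximum-relevance (MRMR) feature ranking.

Features are ranked by a staged greedy procedure driven by plug-in mutual
information on equal-width bins:

1. seed the selected set S with the single most relevant feature
   (relevance V_x = I(x, y));
2. while any unselected feature has nonzero relevance and *zero* redundancy
   with S, admit the most relevant such feature;
3. (loop of step 2)
4. while any unselected feature has nonzero relevance, admit the one with
   the largest mutual information quotient
   MIQ = V_x / [ (1/|S|) * sum_{z in S} I(x, z) ];
5. (loop of step 4)
6. append the zero-relevance leftovers in seeded-random order.

"Zero" means below 1e-12 bits, absorbing floating-point noise. A variant in
which the relevance of a candidate is replaced by the running mean relevance
of the selected set is available behind ``literal_relevance=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["mutual_information", "mrmr_rank", "MRMRResult"]

ZERO_BITS = 1e-12
DEFAULT_BINS = 10


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width binning; categorical (few-valued or non-numeric) data pass through."""
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.number):
        _, codes = np.unique(x, return_inverse=True)
        return codes
    uniq = np.unique(x)
    if uniq.size <= n_bins:
        return np.searchsorted(uniq, x)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.size, dtype=int)
    edges = np.linspace(lo, hi, n_bins + 1)
    return np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)


def mutual_information(x, y, n_bins: int = DEFAULT_BINS) -> float:
    """Plug-in mutual information in bits between two sequences.

    Continuous variables are discretised on ``n_bins`` equal-width bins;
    sequences with at most ``n_bins`` distinct values (or non-numeric ones)
    are used as categories directly. A constant sequence yields 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 8:
        raise ValueError("need at least 8 observations")
    xi = _discretize(x, n_bins)
    yi = _discretize(y, n_bins)
    if np.unique(xi).size < 2 or np.unique(yi).size < 2:
        return 0.0
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


@dataclass
class MRMRResult:
    """Full feature ranking with per-feature scores and selection phase."""

    ranking: list  # feature names, best first
    relevance: dict  # feature -> V_x (bits)
    redundancy: dict  # feature -> W_x at selection time (bits; 0 for step-1/2)
    miq: dict  # feature -> MIQ at selection time (NaN if not selected by MIQ)
    phase: dict  # feature -> "step-1" | "step-2" | "step-4" | "step-6"

    def top(self, k: int = 5) -> list:
        return self.ranking[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.ranking,
                "relevance": [self.relevance[f] for f in self.ranking],
                "redundancy": [self.redundancy[f] for f in self.ranking],
                "miq": [self.miq[f] for f in self.ranking],
                "phase": [self.phase[f] for f in self.ranking],
            }
        )


def mrmr_rank(
    table: pd.DataFrame,
    target,
    feature_cols: list | None = None,
    mode: str = "regression",
    n_bins: int = DEFAULT_BINS,
    seed: int = 0,
    literal_relevance: bool = False,
) -> MRMRResult:
    """Rank features by the staged MRMR procedure.

    ``target`` is a column name in ``table`` or an array-like; ``mode`` is
    kept for interface clarity ("regression" bins a numeric target,
    "classification" treats it as categories -- discretisation handles both
    transparently). The full ranking is a permutation of all features.
    """
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c != target]
    if len(feature_cols) < 1:
        raise ValueError("need at least one feature")
    y = table[target].to_numpy() if isinstance(target, str) else np.asarray(target)
    if mode not in ("regression", "classification"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)

    X = {f: table[f].to_numpy() for f in feature_cols}
    relevance = {f: mutual_information(X[f], y, n_bins) for f in feature_cols}
    pair_cache: dict[tuple, float] = {}

    def pair_mi(f: str, g: str) -> float:
        key = (f, g) if f <= g else (g, f)
        if key not in pair_cache:
            pair_cache[key] = mutual_information(X[f], X[g], n_bins)
        return pair_cache[key]

    selected: list = []
    redundancy: dict = {}
    miq: dict = {}
    phase: dict = {}

    def current_relevance(f: str) -> float:
        if not literal_relevance or not selected:
            return relevance[f]
        # literal variant: mean relevance over the selected set
        return float(np.mean([relevance[z] for z in selected]))

    remaining = list(feature_cols)

    # step 1: most relevant feature seeds S (all-zero relevance short-circuits
    # straight to the seeded-random step-6 order)
    first = max(remaining, key=lambda f: (relevance[f], f))
    if relevance[first] > ZERO_BITS:
        selected.append(first)
        remaining.remove(first)
        redundancy[first] = 0.0
        miq[first] = np.nan
        phase[first] = "step-1"

    # steps 2-3: zero-redundancy, nonzero-relevance features by relevance
    while remaining:
        zero_red = [
            f
            for f in remaining
            if relevance[f] > ZERO_BITS
            and np.mean([pair_mi(f, z) for z in selected]) / len(selected) <= ZERO_BITS
        ]
        if not zero_red:
            break
        f = max(zero_red, key=lambda g: (current_relevance(g), g))
        selected.append(f)
        remaining.remove(f)
        redundancy[f] = 0.0
        miq[f] = np.nan
        phase[f] = "step-2"

    # steps 4-5: nonzero relevance by largest MIQ
    while remaining:
        candidates = [f for f in remaining if relevance[f] > ZERO_BITS]
        if not candidates:
            break
        scores = {}
        for f in candidates:
            w = float(np.mean([pair_mi(f, z) for z in selected]))
            scores[f] = (current_relevance(f) / w if w > ZERO_BITS else np.inf, w)
        f = max(candidates, key=lambda g: (scores[g][0], g))
        selected.append(f)
        remaining.remove(f)
        redundancy[f] = scores[f][1]
        miq[f] = scores[f][0]
        phase[f] = "step-4"

    # step 6: zero-relevance leftovers in seeded-random order
    leftovers = list(remaining)
    rng.shuffle(leftovers)
    for f in leftovers:
        selected.append(f)
        redundancy[f] = np.nan
        miq[f] = np.nan
        phase[f] = "step-6"

    return MRMRResult(
        ranking=selected,
        relevance=relevance,
        redundancy=redundancy,
        miq=miq,
        phase=phase,
    )
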