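"""Permutation-based moderated t-statistics (SAM) with permutation FDR.

For each protein the statistic is

    d_i = (mean2_i - mean1_i) / (s_i + s0)

where s_i is the two-sample pooled-SD standard error and the fudge factor
s0 is chosen by the Tusher procedure: among the percentiles 0, 5, ..., 100
of the s_i, pick the candidate minimizing the coefficient of variation of
the median absolute deviation of d across s-quantile windows. Significance
comes from balanced group-label permutations (exhaustive when the number
of distinct assignments fits the permutation budget, otherwise a seeded
uniform draw without replacement): p-values pool the permuted d across
proteins, and q-values estimate, per |d| threshold, the median permuted
exceedance count scaled by pi0 over the observed exceedance count.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant import AbundanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GroupDesign",
    "sam_statistics",
    "permutation_fdr",
    "fold_changes",
    "run_de",
]


@dataclass
class GroupDesign:
    """Two-condition sample assignment: ``condition2`` is tested against
    the reference ``condition1`` (d > 0 means higher in condition2)."""

    groups: pd.Series  # sample_id -> condition label
    condition1: str
    condition2: str
    name: str = ""

    def __post_init__(self) -> None:
        self.groups = self.groups[self.groups.isin([self.condition1, self.condition2])]
        n1 = (self.groups == self.condition1).sum()
        n2 = (self.groups == self.condition2).sum()
        if n1 < 2 or n2 < 2:
            raise ValueError("each condition needs at least two samples")
        if not self.name:
            self.name = f"{self.condition2}_vs_{self.condition1}"

    def masks(self, columns) -> tuple[np.ndarray, np.ndarray]:
        labels = self.groups.reindex(columns)
        return (
            (labels == self.condition1).to_numpy(),
            (labels == self.condition2).to_numpy(),
        )


def _group_stats(x: np.ndarray, mask: np.ndarray):
    """NaN-aware per-row count, mean and within-group sum of squares."""
    sub = x[:, mask]
    obs = ~np.isnan(sub)
    n = obs.sum(axis=1)
    filled = np.where(obs, sub, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = filled.sum(axis=1) / n
        ss = (np.where(obs, (sub - mean[:, None]) ** 2, 0.0)).sum(axis=1)
    return n, mean, ss


def _d_and_s(x: np.ndarray, m1: np.ndarray, m2: np.ndarray):
    """Raw difference and pooled-SD standard error per row (NaN-aware)."""
    n1, mean1, ss1 = _group_stats(x, m1)
    n2, mean2, ss2 = _group_stats(x, m2)
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = (ss1 + ss2) / (n1 + n2 - 2)
        s = np.sqrt((1.0 / n1 + 1.0 / n2) * pooled)
    diff = mean2 - mean1
    diff[~valid] = np.nan
    s[~valid] = np.nan
    return diff, s


def _tusher_s0(diff: np.ndarray, s: np.ndarray, n_windows: int = 20) -> float:
    """Fudge-factor search minimizing the CV of window-wise MAD of d."""
    ok = ~np.isnan(s) & ~np.isnan(diff)
    s_ok, diff_ok = s[ok], diff[ok]
    if s_ok.size == 0:
        return 0.0
    candidates = np.percentile(s_ok, np.arange(0, 101, 5))
    # windows bounded by s-quantiles; digitize against interior edges
    edges = np.quantile(s_ok, np.linspace(0, 1, n_windows + 1)[1:-1])
    window = np.digitize(s_ok, edges)
    best, best_cv = float(candidates[0]), np.inf
    for s0 in candidates:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = diff_ok / (s_ok + s0)
        mads = []
        for w in range(n_windows):
            dw = d[window == w]
            if dw.size >= 2:
                mads.append(np.median(np.abs(dw - np.median(dw))))
        mads = np.asarray(mads)
        if mads.size < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv:
            best_cv, best = cv, float(s0)
    return best


def sam_statistics(
    matrix: AbundanceMatrix,
    design: GroupDesign,
    s0: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-protein SAM (d, s) plus the fudge factor s0.

    Proteins with fewer than two observed values in either group are
    reported with NaN statistics (untested) and logged. Pass ``s0`` to
    bypass the Tusher search with a fixed value.
    """
    if matrix.scale != "log2":
        raise ValueError("SAM expects log2-scale abundances")
    x = matrix.data.to_numpy(dtype=float)
    m1, m2 = design.masks(matrix.data.columns)
    diff, s = _d_and_s(x, m1, m2)
    untested = int(np.isnan(s).sum())
    if untested:
        logger.info("%d proteins untested (<2 observations in a group)", untested)
    if s0 is None:
        s0 = _tusher_s0(diff, s)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = diff / (s + s0)
        # constant proteins: zero difference over zero spread is a zero effect
        d[(diff == 0) & (s + s0 == 0)] = 0.0
    stats = pd.DataFrame({"d": d, "s": s, "diff": diff}, index=matrix.data.index)
    return stats, float(s0)


def _balanced_assignments(
    n: int, n1: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Distinct group-1 index subsets as a boolean (B, n) matrix.

    Exhaustive when C(n, n1) <= n_perm (or fewer than 10 distinct
    assignments exist); otherwise a seeded uniform sample of distinct
    subsets, always including the observed labelling first.
    """
    total = math.comb(n, n1)
    if total <= max(n_perm, 10):
        masks = np.zeros((total, n), dtype=bool)
        for b, combo in enumerate(itertools.combinations(range(n), n1)):
            masks[b, list(combo)] = True
        return masks
    seen = {tuple(range(n1))}  # observed labelling: group 1 first by construction
    masks = [np.isin(np.arange(n), range(n1))]
    while len(masks) < n_perm:
        combo = tuple(sorted(rng.choice(n, size=n1, replace=False).tolist()))
        if combo in seen:
            continue
        seen.add(combo)
        masks.append(np.isin(np.arange(n), combo))
    return np.asarray(masks)


def permutation_fdr(
    matrix: AbundanceMatrix,
    design: GroupDesign,
    n_perm: int = 1000,
    seed: int | None = 0,
    s0: float | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Permutation p- and q-values for the SAM statistic.

    p_i is the proportion of permuted d (pooled across proteins) with
    |d*| >= |d_i|. For each threshold t = |d_i|, the q-value is
    pi0 * median_b(#{|d*_b| >= t}) / #{|d| >= t}, clipped to [0, 1] and
    made monotone non-increasing in |d|. pi0 is the standard IQR
    estimator: the share of observed d inside the interquartile range of
    the pooled null, divided by 0.5 and capped at 1. s0 is held fixed at
    its observed-data value across permutations.

    Returns ``(DataFrame(d, s, p, q), s0, pi0)``.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable q-values")
    stats, s0 = sam_statistics(matrix, design, s0=s0)
    x = matrix.data.to_numpy(dtype=float)
    m1, m2 = design.masks(matrix.data.columns)
    # canonical column order (group 1 first, each group sorted by sample id)
    # so the sampled permutation set is invariant to input column order
    labels = matrix.data.columns
    order1 = sorted(np.flatnonzero(m1), key=lambda i: str(labels[i]))
    order2 = sorted(np.flatnonzero(m2), key=lambda i: str(labels[i]))
    cols = np.asarray(order1 + order2)
    xs = x[:, cols]
    n, n1 = cols.size, int(m1.sum())

    rng = np.random.default_rng(seed)
    masks = _balanced_assignments(n, n1, n_perm, rng)
    null_d = np.empty((masks.shape[0], xs.shape[0]))
    for b, g1 in enumerate(masks):
        diff_b, s_b = _d_and_s(xs, g1, ~g1)
        with np.errstate(invalid="ignore", divide="ignore"):
            db = diff_b / (s_b + s0)
            db[(diff_b == 0) & (s_b + s0 == 0)] = 0.0
            null_d[b] = db

    d_obs = stats["d"].to_numpy()
    tested = ~np.isnan(d_obs)
    abs_obs = np.abs(d_obs[tested])
    null_abs = np.abs(null_d[:, tested])
    null_abs = null_abs[:, ~np.isnan(null_abs).all(axis=0)] if np.isnan(null_abs).any() else null_abs

    pooled = np.sort(null_abs[~np.isnan(null_abs)])
    n_pool = pooled.size
    p = np.full(d_obs.shape, np.nan)
    p[tested] = (n_pool - np.searchsorted(pooled, abs_obs, side="left")) / n_pool

    # pi0 from the IQR of the pooled null on the signed scale
    signed_null = null_d[:, tested]
    signed_null = signed_null[~np.isnan(signed_null)]
    q25, q75 = np.percentile(signed_null, [25, 75])
    d_tested = d_obs[tested]
    pi0 = min(1.0, np.mean((d_tested >= q25) & (d_tested <= q75)) / 0.5)

    # per-threshold exceedance counts, median over permutations
    order = np.argsort(abs_obs)
    thresholds = abs_obs[order]
    counts = np.empty((null_abs.shape[0], thresholds.size))
    for b in range(null_abs.shape[0]):
        row = np.sort(null_abs[b][~np.isnan(null_abs[b])])
        counts[b] = row.size - np.searchsorted(row, thresholds, side="left")
    med_fp = np.median(counts, axis=0)
    observed_exceed = thresholds.size - np.arange(thresholds.size)
    q_sorted = np.clip(pi0 * med_fp / observed_exceed, 0.0, 1.0)
    # q-value convention: the minimum estimated FDR over all rejection
    # regions containing the protein — a running min over thresholds at or
    # below its |d|, which makes q monotone non-increasing in |d|
    q_sorted = np.minimum.accumulate(q_sorted)
    q = np.full(d_obs.shape, np.nan)
    q_tested = np.empty_like(abs_obs)
    q_tested[order] = q_sorted
    q[tested] = q_tested

    out = stats.copy()
    out["p"] = p
    out["q"] = q
    return out, s0, pi0


def fold_changes(
    matrix: AbundanceMatrix,
    design: GroupDesign,
    method: str = "linear-means",
) -> pd.Series:
    """Per-protein fold change, condition2 / condition1.

    ``linear-means`` (default) is the ratio of linear-scale group means;
    ``log-means`` exponentiates the difference of mean log2 abundances.
    Zero or missing reference means yield missing ratios.
    """
    if method not in ("linear-means", "log-means"):
        raise ValueError(f"unknown method {method!r}")
    m1, m2 = design.masks(matrix.data.columns)
    if method == "linear-means":
        linear = matrix.to_linear().data
        ref = linear.loc[:, m1].mean(axis=1, skipna=True)
        case = linear.loc[:, m2].mean(axis=1, skipna=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            fc = case / ref
        fc[ref <= 0] = np.nan
    else:
        log2 = matrix.to_log2().data
        fc = np.exp2(log2.loc[:, m2].mean(axis=1) - log2.loc[:, m1].mean(axis=1))
    fc.name = "fold_change"
    return fc


def run_de(
    matrix: AbundanceMatrix,
    design: GroupDesign,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = 0,
    s0: float | None = None,
    fc_method: str = "linear-means",
) -> pd.DataFrame:
    """Full differential-expression result for one two-group comparison.

    Returns a DataFrame with fold_change, d, s, p, q, significant
    (q < alpha) and direction ('higher' / 'lower' for significant
    proteins, by fold change relative to 1).
    """
    stats, s0, pi0 = permutation_fdr(matrix, design, n_perm=n_perm, seed=seed, s0=s0)
    fc = fold_changes(matrix, design, method=fc_method)
    out = stats.join(fc)
    out["significant"] = out["q"] < alpha
    out["direction"] = ""
    out.loc[out["significant"] & (out["fold_change"] > 1), "direction"] = "higher"
    out.loc[out["significant"] & (out["fold_change"] < 1), "direction"] = "lower"
    out.attrs.update({"s0": s0, "pi0": pi0, "alpha": alpha, "comparison": design.name})
    return out


def de_partition(de: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Split significant proteins into higher/lower expressed lists."""
    higher = de.index[de["direction"] == "higher"].tolist()
    lower = de.index[de["direction"] == "lower"].tolist()
    return higher, lower
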