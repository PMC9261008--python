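"""Expression-weighted cell type enrichment and composition diagnostics.

Given a labelled single-cell expression reference, each gene's specificity
for a cell type is the share of its summed per-type mean expression
attributable to that type (rows sum to 1). A protein list's cell-type
enrichment compares the summed specificity of the list against same-size
random lists drawn from the quantified background (EWCE). Proteins whose
specificity for one type is >= 0.5 are classified as highly enriched for
it, and the composition-change diagnostic asks whether their disease/control
fold changes exceed the +/-2 SD band of control-vs-control variation —
distinguishing protein regulation from mere shifts in cell-type ratios.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .quant import AbundanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "compute_specificity",
    "ewce_bootstrap",
    "classify_highly_enriched",
    "ndc_variation_sd",
    "composition_check",
]

NEURON_TYPES = ("excitatory", "inhibitory")


def compute_specificity(
    matrix: pd.DataFrame,
    labels: pd.Series,
    exclude: tuple[str, ...] = ("unknown",),
) -> pd.DataFrame:
    """Gene x cell-type specificity from a cell x gene expression matrix.

    Expression is library-size normalized per cell, averaged within each
    cell type (cells labelled in ``exclude`` are ignored), and each gene's
    type means are scaled to sum to 1. Genes with zero total expression
    are dropped; cell types with zero cells are dropped with a warning.
    """
    labels = labels.reindex(matrix.index)
    if labels.isna().any():
        raise ValueError("every cell must carry a label")
    keep = ~labels.isin(exclude)
    matrix, labels = matrix.loc[keep], labels[keep]
    if labels.nunique() < 2:
        raise ValueError("need at least two cell types")
    totals = matrix.sum(axis=1)
    empty = totals <= 0
    if empty.any():
        warnings.warn(f"dropping {int(empty.sum())} cells with zero counts")
        matrix, labels, totals = matrix[~empty], labels[~empty], totals[~empty]
    norm = matrix.div(totals, axis=0)
    type_means = norm.groupby(labels.to_numpy()).mean().T  # gene x type
    row_sum = type_means.sum(axis=1)
    spec = type_means[row_sum > 0].div(row_sum[row_sum > 0], axis=0)
    spec.index.name = "gene"
    return spec


def _harmonize(ids, universe, what: str) -> list[str]:
    upper = {str(g).upper(): g for g in universe}
    found, dropped = [], 0
    for g in ids:
        hit = upper.get(str(g).upper())
        if hit is None:
            dropped += 1
        else:
            found.append(hit)
    if dropped:
        logger.info("%d %s identifiers absent from the specificity matrix", dropped, what)
    return found


def ewce_bootstrap(
    target: list[str],
    background: list[str],
    spec: pd.DataFrame,
    n_boot: int = 20000,
    seed: int | None = 0,
    exact: bool = False,
    exact_limit: int = 20000,
) -> pd.DataFrame:
    """Expression-weighted cell type enrichment of a protein/gene list.

    The observed statistic per cell type is the summed specificity over
    the target; the null is ``n_boot`` same-size uniform draws without
    replacement from the background. p = (#{boot >= obs} + 1)/(n_boot + 1)
    (never exactly 0; results at the floor are flagged ``at_floor``),
    fold = observed / bootstrap mean, z = (observed - mean)/SD, and p is
    BH-adjusted across cell types. With ``exact=True`` and a small enough
    C(|background|, |target|), the null is enumerated exhaustively and p
    is the exact tail proportion.
    """
    background = _harmonize(dict.fromkeys(background), spec.index, "background")
    target = _harmonize(dict.fromkeys(target), spec.index, "target")
    target = [t for t in target if t in set(background)]
    if len(target) == 0:
        raise ValueError("target has no overlap with background/specificity rows")
    if len(target) < 5:
        warnings.warn("target list has fewer than 5 genes; enrichment is unstable")

    bg = spec.loc[background].to_numpy()
    t_idx = pd.Index(background).get_indexer(pd.Index(target).drop_duplicates())
    observed = bg[t_idx].sum(axis=0)
    n, k = len(background), len(t_idx)

    if exact:
        total = math.comb(n, k)
        if total > exact_limit:
            raise ValueError(f"C({n},{k}) = {total} exceeds exact_limit")
        sums = np.array(
            [bg[list(combo)].sum(axis=0) for combo in itertools.combinations(range(n), k)]
        )
        boot_mean, boot_sd = sums.mean(axis=0), sums.std(axis=0, ddof=1)
        p = (sums >= observed[None, :] - 1e-12).mean(axis=0)
        at_floor = p <= 1.0 / total
    else:
        rng = np.random.default_rng(seed)
        keys = rng.random((n_boot, n))
        picks = np.argpartition(keys, k - 1, axis=1)[:, :k]
        sums = bg[picks].sum(axis=1)
        boot_mean, boot_sd = sums.mean(axis=0), sums.std(axis=0, ddof=1)
        # epsilon guards against summation-order float jitter when a draw
        # reproduces the target exactly
        exceed = (sums >= observed[None, :] - 1e-9).sum(axis=0)
        p = (exceed + 1.0) / (n_boot + 1.0)
        at_floor = exceed == 0

    with np.errstate(invalid="ignore", divide="ignore"):
        fold = observed / boot_mean
        z = (observed - boot_mean) / boot_sd
    p_adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "observed": observed,
            "boot_mean": boot_mean,
            "boot_sd": boot_sd,
            "fold": fold,
            "z": z,
            "p": p,
            "p_adj": p_adj,
            "at_floor": at_floor,
        },
        index=spec.columns,
    )
    out.index.name = "cell_type"
    out.attrs.update({"n_target": k, "n_background": n,
                      "n_boot": (math.comb(n, k) if exact else n_boot), "exact": exact})
    return out


def merge_neuron_columns(
    spec: pd.DataFrame, neuron_types: tuple[str, ...] = NEURON_TYPES
) -> pd.DataFrame:
    """Sum excitatory/inhibitory specificity columns into one 'neuron' column."""
    present = [c for c in neuron_types if c in spec.columns]
    if not present:
        return spec
    merged = spec.drop(columns=present)
    merged["neuron"] = spec[present].sum(axis=1)
    return merged


def classify_highly_enriched(
    spec: pd.DataFrame,
    proteins: list[str],
    threshold: float = 0.5,
    merge_neurons: bool = False,
    neuron_types: tuple[str, ...] = NEURON_TYPES,
) -> pd.Series:
    """Assign each protein the cell type it is highly enriched for, if any.

    A protein is assigned the type with specificity >= ``threshold``
    (after optionally merging excitatory+inhibitory into 'neuron'); at a
    threshold above 0.5 the assignment is unique by construction, and
    post-merge ties are broken by the larger specificity then column
    order. Proteins below threshold everywhere (or absent from the
    matrix) map to None.
    """
    table = merge_neuron_columns(spec, neuron_types) if merge_neurons else spec
    ids = _harmonize(proteins, table.index, "protein")
    out = pd.Series([None] * len(proteins), index=pd.Index(proteins, name="protein_id"),
                    dtype=object)
    if not ids:
        return out
    sub = table.loc[ids]
    best = sub.idxmax(axis=1)
    best_val = sub.max(axis=1)
    assigned = best.where(best_val >= threshold, None)
    # map back onto the caller's identifiers (harmonization preserves order
    # of the found subset)
    found_mask = [str(p).upper() in {str(i).upper() for i in ids} for p in proteins]
    out.loc[np.asarray(found_mask)] = assigned.to_numpy()
    return out


def ndc_variation_sd(
    matrix: AbundanceMatrix,
    ndc_samples: list[str],
    n_splits: int = 100,
    seed: int | None = 0,
) -> float:
    """Pooled SD of control-vs-control log2 fold changes.

    The control samples are repeatedly split into two balanced halves; for
    each split the per-protein log2 ratio of half-means (linear scale) is
    computed, and the SD is pooled across proteins and splits. All
    distinct splits are enumerated when there are at most ``n_splits`` of
    them, otherwise ``n_splits`` seeded random draws are used.
    """
    ndc = [s for s in ndc_samples if s in matrix.data.columns]
    if len(ndc) < 4:
        raise ValueError("need at least 4 control samples")
    linear = matrix.to_linear().data[ndc]
    n = len(ndc)
    k = n // 2
    # unordered partitions: fix the first sample in half A when n is even
    if n % 2 == 0:
        combos = [c for c in itertools.combinations(range(n), k) if 0 in c]
    else:
        combos = list(itertools.combinations(range(n), k))
    if len(combos) > n_splits:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(combos), size=n_splits, replace=False)
        combos = [combos[i] for i in idx]
    x = linear.to_numpy(dtype=float)
    ratios = []
    for combo in combos:
        a = np.zeros(n, dtype=bool)
        a[list(combo)] = True
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.log2(np.nanmean(x[:, a], axis=1) / np.nanmean(x[:, ~a], axis=1))
        ratios.append(r)
    pooled = np.concatenate(ratios)
    pooled = pooled[np.isfinite(pooled)]
    return float(np.std(pooled, ddof=1))


def composition_check(
    de: pd.DataFrame,
    assignments: pd.Series,
    sd: float,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare cell-type-linked fold changes against the control band.

    For each cell-type protein set (from :func:`classify_highly_enriched`),
    reports the fraction of log2 fold changes inside the +/-2 SD band of
    control variation and the fraction of significant (q < alpha) proteins
    outside it. Returns ``(summary, detail)`` where ``detail`` is a tidy
    density-plot-ready table of per-protein fold changes.
    """
    bound = 2.0 * sd
    with np.errstate(invalid="ignore", divide="ignore"):
        log2fc = np.log2(de["fold_change"])
    detail = pd.DataFrame(
        {
            "log2fc": log2fc,
            "q": de["q"],
            "significant": de["q"] < alpha,
            "cell_type": assignments.reindex(de.index),
        }
    ).dropna(subset=["cell_type"])
    rows = []
    for ct, sub in detail.groupby("cell_type"):
        fc = sub["log2fc"].dropna()
        if fc.empty:
            continue
        inside = (fc.abs() <= bound).mean()
        sig = sub.loc[sub["significant"], "log2fc"].dropna()
        rows.append(
            {
                "cell_type": ct,
                "n_proteins": len(fc),
                "n_significant": len(sig),
                "sd_bound": bound,
                "frac_inside": float(inside),
                "frac_outside": float(1.0 - inside),
                "frac_sig_outside": float((sig.abs() > bound).mean()) if len(sig) else np.nan,
            }
        )
    summary = pd.DataFrame(rows).set_index("cell_type") if rows else pd.DataFrame(
        columns=["n_proteins", "n_significant", "sd_bound", "frac_inside",
                 "frac_outside", "frac_sig_outside"]
    )
    return summary, detail
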