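"""Peptide-level quality filtering, normalization and abundance rollup.

The DIA quantification chain: per-(peptide, fraction) quality-value
filtering with a presence rule, fast cyclic-loess normalization of the
log2 peptide-fraction matrix, summation of each peptide's top two gel
fractions, summation of each protein's top five peptides, and the
technical-replicate coefficient of variation used as the reproducibility
summary.

Abundances travel as an :class:`AbundanceMatrix` — a features x samples
DataFrame with NaN as the explicit missingness mask plus level/scale tags.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceMatrix",
    "filter_peptides",
    "peptide_fraction_matrix",
    "normalize_cyclic_loess",
    "rollup_fractions",
    "rollup_proteins",
    "compute_replicate_cov",
]


@dataclass
class AbundanceMatrix:
    """Rectangular feature x sample abundance matrix with a missingness mask.

    ``data`` holds linear abundances (or their log2, per ``scale``) with NaN
    marking missing entries; ``level`` tags the feature level
    (``"peptide-fraction"``, ``"peptide"`` or ``"protein"``).
    """

    data: pd.DataFrame
    level: str = "protein"
    scale: str = "linear"

    def to_log2(self) -> "AbundanceMatrix":
        if self.scale == "log2":
            return self
        with np.errstate(divide="ignore"):
            out = np.log2(self.data.where(self.data > 0))
        return AbundanceMatrix(out, self.level, "log2")

    def to_linear(self) -> "AbundanceMatrix":
        if self.scale == "linear":
            return self
        return AbundanceMatrix(np.exp2(self.data), self.level, "linear")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def filter_peptides(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    mode: str = "pairwise",
    qcut: float = 1e-3,
    presence: float = 0.5,
) -> pd.DataFrame:
    """Apply the quality-value presence filter per (peptide, fraction) stratum.

    ``mode="global"`` keeps a stratum iff the share of all samples with
    qvalue <= qcut is >= ``presence`` (inclusive); ``mode="pairwise"``
    keeps it iff that share is reached within at least one of the two
    conditions. Measurements failing the cut inside a retained stratum
    have their peak area set to missing (the row is kept, so the filter is
    idempotent).
    """
    if mode not in ("global", "pairwise"):
        raise ValueError(f"unknown mode {mode!r}")
    if "group" not in metadata.columns:
        raise ValueError("metadata must carry a 'group' column")
    groups = metadata["group"]
    if groups.nunique() == 0 or len(metadata) == 0:
        raise ValueError("metadata assigns no conditions")
    unknown = set(table["sample_id"]) - set(metadata.index)
    if unknown:
        raise ValueError(f"samples missing from metadata: {sorted(unknown)[:5]}")
    if mode == "pairwise" and groups.nunique() != 2:
        raise ValueError("pairwise mode requires exactly two conditions")

    tab = table.copy()
    passed = tab["qvalue"] <= qcut

    # denominators are the full per-(group) sample counts, not just samples
    # present in the table stratum: an absent measurement counts as failing
    if mode == "global":
        n_total = len(metadata)
        n_pass = passed.groupby([tab["peptide_id"], tab["fraction"]]).sum()
        keep = n_pass / n_total >= presence
    else:
        grp = tab["sample_id"].map(groups)
        n_per_group = groups.value_counts()
        n_pass = (
            passed.groupby([tab["peptide_id"], tab["fraction"], grp]).sum().unstack(fill_value=0)
        )
        share = n_pass.div(n_per_group, axis=1)
        keep = (share >= presence).any(axis=1)

    key = pd.MultiIndex.from_frame(tab[["peptide_id", "fraction"]])
    retained = keep.reindex(key, fill_value=False).to_numpy()
    out = tab.loc[retained].copy()
    out.loc[out["qvalue"] > qcut, "peak_area"] = np.nan
    return out.reset_index(drop=True)


def peptide_fraction_matrix(table: pd.DataFrame, samples: list[str] | None = None) -> AbundanceMatrix:
    """Pivot a long peptide table into a (peptide, fraction) x sample matrix."""
    dup = table.duplicated(["peptide_id", "sample_id", "fraction"])
    if dup.any():
        raise ValueError("duplicate (peptide, sample, fraction) records")
    wide = table.pivot_table(
        index=["peptide_id", "fraction"], columns="sample_id", values="peak_area",
        dropna=False, aggfunc="first",
    )
    if samples is not None:
        wide = wide.reindex(columns=samples)
    wide.columns.name = None
    return AbundanceMatrix(wide, level="peptide-fraction", scale="linear")


def normalize_cyclic_loess(
    matrix: AbundanceMatrix,
    iterations: int = 3,
    span: float = 0.7,
) -> AbundanceMatrix:
    """Fast cyclic loess normalization on a log2 matrix.

    For each pass, every sample column is loess-adjusted against the
    row-mean reference column: M = sample - reference is smoothed against
    A = (sample + reference)/2 with a degree-1 local regression and the
    fitted trend subtracted. Missing entries are ignored in fitting and
    stay missing. The reference is recomputed at each of the (default 3)
    iterations.
    """
    if matrix.scale != "log2":
        raise ValueError("cyclic loess expects a log2-scale matrix")
    x = matrix.data.to_numpy(dtype=float).copy()
    all_missing = np.isnan(x).all(axis=1)
    if all_missing.any():
        warnings.warn(f"dropping {all_missing.sum()} all-missing rows before normalization")
        x = x[~all_missing]
        index = matrix.data.index[~all_missing]
    else:
        index = matrix.data.index
    if x.shape[1] < 2:
        warnings.warn("single-sample matrix: cyclic loess is the identity")
        return AbundanceMatrix(pd.DataFrame(x, index=index, columns=matrix.data.columns),
                               matrix.level, "log2")

    for _ in range(iterations):
        ref = np.nanmean(x, axis=1)
        for j in range(x.shape[1]):
            obs = ~np.isnan(x[:, j]) & ~np.isnan(ref)
            if obs.sum() < 10:
                continue
            a = (x[obs, j] + ref[obs]) / 2.0
            m = x[obs, j] - ref[obs]
            # robust local regression (3 bisquare reweightings) so strongly
            # differential features do not drag the trend onto null features;
            # delta interpolates across near-duplicate abscissae for speed
            delta = 0.01 * (a.max() - a.min())
            fitted = lowess(m, a, frac=span, it=3, delta=delta, return_sorted=False)
            x[obs, j] = x[obs, j] - fitted
    out = pd.DataFrame(x, index=index, columns=matrix.data.columns)
    return AbundanceMatrix(out, matrix.level, "log2")


def _topk_sum(values: pd.DataFrame, group_key, k: int, tie_labels=None) -> pd.DataFrame:
    """Sum, per group and sample, the k member rows with highest overall mean.

    Selection is global per group (mean linear abundance across samples,
    NaN-skipping); ties broken by ascending ``tie_labels`` (default: the
    stringified row label). Within the selected rows, missing entries
    contribute 0; a group whose selected rows are all missing in a sample
    stays missing there.
    """
    if tie_labels is None:
        tie_labels = values.index.astype(str)
    order = pd.DataFrame(
        {
            "group": np.asarray(group_key),
            "mean": values.mean(axis=1, skipna=True).to_numpy(),
            "label": np.asarray(tie_labels).astype(str),
        }
    )
    order = order.sort_values(
        ["group", "mean", "label"], ascending=[True, False, True], kind="mergesort"
    )
    rank = order.groupby("group").cumcount()
    sel_pos = order.index[(rank < k).to_numpy()].to_numpy()
    sel = values.iloc[sel_pos]
    sel_groups = order.loc[sel_pos, "group"].to_numpy()
    summed = sel.fillna(0.0).groupby(sel_groups).sum()
    n_obs = sel.notna().groupby(sel_groups).sum()
    summed = summed.where(n_obs > 0)
    summed.index.name = None
    return summed.sort_index()


def rollup_fractions(matrix: AbundanceMatrix, k: int = 2) -> AbundanceMatrix:
    """Sum each peptide's top-k fractions (by mean linear abundance) per sample."""
    if matrix.level != "peptide-fraction":
        raise ValueError("expects a (peptide, fraction)-level matrix")
    linear = matrix.to_linear().data
    out = _topk_sum(
        linear,
        linear.index.get_level_values(0),
        k,
        tie_labels=linear.index.get_level_values(1),
    )
    out = out.dropna(how="all")
    out.index.name = "peptide_id"
    return AbundanceMatrix(out, level="peptide", scale="linear")


def rollup_proteins(
    matrix: AbundanceMatrix,
    pep2prot: pd.DataFrame,
    k: int = 5,
    shared_policy: str = "error",
) -> AbundanceMatrix:
    """Sum each protein's top-k peptides (by mean linear abundance) per sample.

    ``shared_policy`` governs peptides mapping to more than one protein:
    ``error`` (default), ``drop`` (discard them), or ``assign-all`` (count
    them toward every mapped protein).
    """
    if shared_policy not in ("error", "drop", "assign-all"):
        raise ValueError(f"unknown shared_policy {shared_policy!r}")
    linear = matrix.to_linear().data
    mapping = pep2prot[["peptide_id", "protein_id"]].drop_duplicates()
    unmapped = set(linear.index) - set(mapping["peptide_id"])
    if unmapped:
        raise ValueError(f"{len(unmapped)} peptides lack a protein mapping")
    counts = mapping["peptide_id"].value_counts()
    shared = counts.index[counts > 1]
    if len(shared) > 0:
        if shared_policy == "error":
            raise ValueError(
                f"{len(shared)} peptides map to multiple proteins (policy 'error')"
            )
        if shared_policy == "drop":
            logger.info("dropping %d shared peptides", len(shared))
            mapping = mapping[~mapping["peptide_id"].isin(shared)]
    mapping = mapping[mapping["peptide_id"].isin(linear.index)]
    expanded = linear.loc[mapping["peptide_id"]].reset_index(drop=True)
    out = _topk_sum(
        expanded,
        mapping["protein_id"].to_numpy(),
        k,
        tie_labels=mapping["peptide_id"].to_numpy(),
    )
    out = out.dropna(how="all")
    out.index.name = "protein_id"
    return AbundanceMatrix(out, level="protein", scale="linear")


def compute_replicate_cov(
    matrix: AbundanceMatrix, replicate_groups: dict[str, list[str]]
) -> tuple[pd.Series, float]:
    """Technical-replicate coefficient of variation per protein.

    CoV = SD/mean of the linear abundances within each replicate group,
    averaged over groups per protein; the summary statistic is the median
    over proteins.
    """
    linear = matrix.to_linear().data
    per_group = {}
    for name, samples in replicate_groups.items():
        samples = [s for s in samples if s in linear.columns]
        if len(samples) < 2:
            warnings.warn(f"replicate group {name!r} has <2 samples; skipped")
            continue
        sub = linear[samples]
        with np.errstate(invalid="ignore", divide="ignore"):
            per_group[name] = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    if not per_group:
        raise ValueError("no usable replicate groups")
    cov = pd.DataFrame(per_group).mean(axis=1, skipna=True)
    return cov, float(cov.median(skipna=True))
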