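"""Cross-cohort comparison of differential-expression profiles.

Two cohorts analysed with the same pipeline (e.g. a tauopathy FTD subtype
and an Alzheimer cohort from the same brain region) are compared on their
jointly quantified protein set: which significant proteins are shared,
which are cohort-specific, whether shared hits move in the same direction,
and how paired effect sizes (SAM d) distribute between cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CohortDE", "OverlapResult", "joint_quantified", "overlap_de",
           "effect_size_scatter"]


@dataclass
class CohortDE:
    """One cohort's quantified protein universe and DE results."""

    name: str
    quantified: set[str]
    de: pd.DataFrame  # indexed by protein: q, fold_change, d at minimum

    def __post_init__(self) -> None:
        extra = set(self.de.index) - self.quantified
        if extra:
            raise ValueError(f"{len(extra)} DE proteins outside the quantified set")


@dataclass
class OverlapResult:
    """Shared/distinct DE partition on the joint-quantified set."""

    joint: set[str]
    shared: set[str]
    distinct_a: set[str]
    distinct_b: set[str]
    concordant: set[str]
    unrestricted_de_a: int = 0
    unrestricted_de_b: int = 0
    excluded: list[str] = field(default_factory=list)

    @property
    def concordance(self) -> float:
        return len(self.concordant) / len(self.shared) if self.shared else float("nan")


def joint_quantified(a: CohortDE, b: CohortDE) -> set[str]:
    """Proteins quantified in both cohorts (exact ID intersection)."""
    joint = a.quantified & b.quantified
    if not joint:
        warnings.warn("cohorts share no quantified proteins")
    return joint


def overlap_de(a: CohortDE, b: CohortDE, alpha: float = 0.05) -> OverlapResult:
    """Shared and cohort-distinct significant proteins on the joint set.

    A joint protein is shared when q < alpha in both cohorts and
    distinct-to-one when significant there only. Direction concordance
    among shared proteins compares fold changes on the same side of 1.
    Joint proteins lacking a q-value in either cohort are excluded and
    logged.
    """
    joint = joint_quantified(a, b)
    qa = a.de["q"].reindex(list(joint))
    qb = b.de["q"].reindex(list(joint))
    missing = qa.index[qa.isna() | qb.isna()].tolist()
    if missing:
        logger.info("excluding %d joint proteins without q in both cohorts", len(missing))
    ok = qa.index[~(qa.isna() | qb.isna())]
    sig_a = set(ok[(qa[ok] < alpha)])
    sig_b = set(ok[(qb[ok] < alpha)])
    shared = sig_a & sig_b
    fa = a.de["fold_change"]
    fb = b.de["fold_change"]
    concordant = {p for p in shared if (fa[p] - 1.0) * (fb[p] - 1.0) > 0}
    return OverlapResult(
        joint=joint,
        shared=shared,
        distinct_a=sig_a - sig_b,
        distinct_b=sig_b - sig_a,
        concordant=concordant,
        unrestricted_de_a=int((a.de["q"] < alpha).sum()),
        unrestricted_de_b=int((b.de["q"] < alpha).sum()),
        excluded=missing,
    )


def effect_size_scatter(
    a: CohortDE, b: CohortDE, protein_group: list[str]
) -> tuple[pd.DataFrame, float]:
    """Paired SAM effect sizes for a protein group quantified in both cohorts.

    Returns the plot-ready (d_a, d_b) table and the share of proteins with
    a stronger absolute effect in cohort A; exact ties contribute half, so
    identical cohorts score 0.5.
    """
    present = [p for p in protein_group
               if p in a.de.index and p in b.de.index
               and np.isfinite(a.de.loc[p, "d"]) and np.isfinite(b.de.loc[p, "d"])]
    dropped = len(protein_group) - len(present)
    if dropped:
        logger.info("dropping %d proteins absent from one cohort", dropped)
    table = pd.DataFrame(
        {"d_a": a.de.loc[present, "d"], "d_b": b.de.loc[present, "d"]},
        index=pd.Index(present, name="protein_id"),
    )
    if table.empty:
        return table, float("nan")
    stronger = (table["d_a"].abs() > table["d_b"].abs()).sum()
    ties = (table["d_a"].abs() == table["d_b"].abs()).sum()
    share = (stronger + 0.5 * ties) / len(table)
    return table, float(share)
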