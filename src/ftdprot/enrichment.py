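"""Hypergeometric overrepresentation with ontology-aware filtering.

Term membership is intersected with the quantified background before
sizing; terms with fewer than five background proteins are skipped; the
upper-tail hypergeometric p is BH-adjusted per namespace (the web tool the
field typically uses applies a server-specific correction tied to its own
term ensemble, so the standard Benjamini-Hochberg procedure is used here
and recorded in the result metadata). For presentation, the best-per-parent
rule keeps a significant term iff it attains the minimum p among at least
one of its parents' significant children. A generic subtree partition
(e.g. pre-/postsynaptic roots) covers location-style splits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "hypergeometric_enrichment",
    "best_per_parent",
    "partition_by_subtree",
]


def hypergeometric_enrichment(
    target: list[str],
    background: list[str],
    sets: dict[str, tuple[str, list[str]]],
    min_size: int = 5,
    namespaces: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided overrepresentation of ``target`` within gene-set terms.

    ``sets`` maps term_id -> (name, members). p is the upper-tail
    hypergeometric probability of the observed overlap given the
    background-restricted term size; BH adjustment is applied within each
    namespace (all terms share one namespace when ``namespaces`` is None).
    """
    background_set = set(background)
    target_set = set(target)
    if not target_set <= background_set:
        raise ValueError("target must be a subset of the background")
    n_bg, n_t = len(background_set), len(target_set)
    rows = []
    for term_id, (name, members) in sets.items():
        in_bg = set(members) & background_set
        size = len(in_bg)
        if size < min_size:
            continue
        overlap = len(in_bg & target_set)
        p = float(hypergeom.sf(overlap - 1, n_bg, size, n_t))
        rows.append(
            {
                "term_id": term_id,
                "name": name,
                "namespace": (namespaces or {}).get(term_id, "all"),
                "overlap": overlap,
                "term_size": size,
                "p": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["name", "namespace", "overlap", "term_size", "p", "p_adj",
                     "significant"]
        ).rename_axis("term_id")
    out = pd.DataFrame(rows).set_index("term_id")
    out["p_adj"] = np.nan
    for ns, sub in out.groupby("namespace"):
        out.loc[sub.index, "p_adj"] = multipletests(sub["p"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < alpha
    out.attrs["correction"] = "benjamini-hochberg (per namespace)"
    return out.sort_values("p")


def best_per_parent(
    results: pd.DataFrame,
    dag: nx.DiGraph,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Keep each parent's strongest significant child term.

    A significant term is retained iff for at least one of its parents it
    attains the minimum p among that parent's significant children
    (ties broken by larger overlap, then lexicographic term id).
    Significant terms with no parent in the DAG (roots/orphans) are always
    retained. Input significance is the BH-adjusted p at ``alpha``.
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("ontology graph must be acyclic")
    sig = results[results["p_adj"] < alpha] if "p_adj" in results else results[
        results["p"] < alpha]
    if sig.empty:
        return sig.assign(best_per_parent=pd.Series(dtype=bool))

    def sort_key(tid: str):
        row = sig.loc[tid]
        return (row["p"], -row["overlap"], tid)

    retained = set()
    for tid in sig.index:
        parents = list(dag.predecessors(tid)) if dag.has_node(tid) else []
        if not parents:
            retained.add(tid)
            continue
        for parent in parents:
            siblings = [c for c in dag.successors(parent) if c in sig.index]
            if tid == min(siblings, key=sort_key):
                retained.add(tid)
                break
    out = sig.copy()
    out["best_per_parent"] = out.index.isin(retained)
    return out[out["best_per_parent"]]


def partition_by_subtree(
    target: list[str],
    dag: nx.DiGraph,
    sets: dict[str, tuple[str, list[str]]],
    root_ids: list[str],
) -> tuple[dict[str, list[str]], list[str]]:
    """Assign target genes to ontology subtrees rooted at ``root_ids``.

    A gene belongs to a root's partition iff some term in that root's
    subtree (root included) annotates it; genes may belong to several
    partitions, and genes in none are returned as unannotated.
    """
    missing = [r for r in root_ids if not dag.has_node(r)]
    if missing:
        raise ValueError(f"roots not in ontology: {missing}")
    partitions: dict[str, list[str]] = {}
    covered: set[str] = set()
    target_set = set(target)
    for root in root_ids:
        terms = {root} | nx.descendants(dag, root)
        members = set()
        for t in terms:
            if t in sets:
                members |= set(sets[t][1])
        hits = sorted(target_set & members)
        partitions[root] = hits
        covered |= set(hits)
    unannotated = sorted(target_set - covered)
    return partitions, unannotated
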