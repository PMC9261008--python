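"""Plain-text formats: peptide/abundance/metadata TSV, GMT, OBO, MTX, JSON.

All formats round-trip (write then read recovers the object, including the
missingness mask); malformed input is reported with the offending column
or line.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import obonet
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .quant import AbundanceMatrix

__all__ = [
    "read_peptide_table", "write_peptide_table",
    "read_metadata", "write_metadata",
    "read_map", "write_map",
    "read_abundance", "write_abundance",
    "read_gene_list", "write_gene_list",
    "read_gmt", "write_gmt",
    "read_obo", "write_obo",
    "read_sc_matrix", "write_sc_matrix",
    "read_ground_truth_json", "write_ground_truth_json",
]

PEPTIDE_COLUMNS = ["peptide_id", "sample_id", "fraction", "peak_area", "qvalue"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def read_peptide_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, PEPTIDE_COLUMNS, path)
    bad = df.index[(df["qvalue"] < 0) | (df["qvalue"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: qvalue outside [0,1] at line {bad[0] + 2}")
    bad = df.index[df["peak_area"].notna() & (df["peak_area"] < 0)]
    if len(bad):
        raise ValueError(f"{path}: negative peak_area at line {bad[0] + 2}")
    return df[PEPTIDE_COLUMNS]


def write_peptide_table(table: pd.DataFrame, path) -> None:
    table[PEPTIDE_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample_id", "group"], path)
    return df.set_index("sample_id")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.reset_index().to_csv(path, sep="\t", index=False)


def read_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["peptide_id", "protein_id"], path)
    return df


def write_map(pep2prot: pd.DataFrame, path) -> None:
    pep2prot.to_csv(path, sep="\t", index=False)


def read_abundance(path, level: str = "protein", scale: str = "linear") -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.columns.empty:
        raise ValueError(f"{path}: no sample columns")
    index_cols = df.index
    if level == "peptide-fraction":
        # index serialized as "peptide|fraction"
        parts = index_cols.astype(str).str.rsplit("|", n=1)
        df.index = pd.MultiIndex.from_tuples(
            [(p[0], int(p[1])) for p in parts], names=["peptide_id", "fraction"]
        )
    return AbundanceMatrix(df, level=level, scale=scale)


def write_abundance(matrix: AbundanceMatrix, path) -> None:
    df = matrix.data
    if isinstance(df.index, pd.MultiIndex):
        df = df.copy()
        df.index = [f"{a}|{b}" for a, b in df.index]
    df.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id")


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_gene_list(genes: list[str], path) -> None:
    Path(path).write_text("\n".join(genes) + ("\n" if genes else ""))


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT gene-set file; duplicate genes within a set are dropped
    with a warning, keeping first occurrence order."""
    sets: dict[str, tuple[str, list[str]]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: line {ln}: GMT rows need id, description, >=1 gene")
        term_id, name, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        unique = list(dict.fromkeys(genes))
        if len(unique) != len(genes):
            warnings.warn(f"{path}: line {ln}: duplicate genes in {term_id} deduplicated")
        sets[term_id] = (name, unique)
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path) -> None:
    lines = [
        "\t".join([term_id, name, *members]) for term_id, (name, members) in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_obo(path) -> nx.DiGraph:
    """Read an OBO subset into a parent->child DAG; cyclic input is rejected."""
    g = obonet.read_obo(path)
    dag = nx.DiGraph()
    for node, data in g.nodes(data=True):
        dag.add_node(node, name=data.get("name", node),
                     namespace=data.get("namespace", "all"))
    # obonet edges run child -> parent along is_a; flip them
    for child, parent, key in g.edges(keys=True):
        if key == "is_a":
            dag.add_edge(parent, child)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ValueError(f"ontology contains a cycle through {cycle[0][0]}")
    return dag


def write_obo(dag: nx.DiGraph, path) -> None:
    lines = ["format-version: 1.2", ""]
    for node in sorted(dag.nodes):
        data = dag.nodes[node]
        lines += [
            "[Term]",
            f"id: {node}",
            f"name: {data.get('name', node)}",
            f"namespace: {data.get('namespace', 'all')}",
        ]
        for parent in sorted(dag.predecessors(node)):
            lines.append(f"is_a: {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_sc_matrix(prefix) -> tuple[pd.DataFrame, pd.Series]:
    """Read a single-cell reference written by :func:`write_sc_matrix`.

    ``prefix.mtx`` holds the sparse cell x gene counts, ``prefix.cells.tsv``
    the cell labels, ``prefix.genes.txt`` the gene order.
    """
    prefix = Path(prefix)
    counts = mmread(f"{prefix}.mtx").toarray()
    cells = pd.read_csv(f"{prefix}.cells.tsv", sep="\t").set_index("cell_id")
    genes = read_gene_list(f"{prefix}.genes.txt")
    if counts.shape != (len(cells), len(genes)):
        raise ValueError(f"{prefix}: matrix shape {counts.shape} does not match labels")
    matrix = pd.DataFrame(counts, index=cells.index, columns=genes)
    return matrix, cells["cell_type"]


def write_sc_matrix(matrix: pd.DataFrame, labels: pd.Series, prefix) -> None:
    prefix = Path(prefix)
    mmwrite(f"{prefix}.mtx", csr_matrix(matrix.to_numpy()))
    labels.rename("cell_type").rename_axis("cell_id").reset_index().to_csv(
        f"{prefix}.cells.tsv", sep="\t", index=False
    )
    write_gene_list(list(matrix.columns), f"{prefix}.genes.txt")


def write_ground_truth_json(truth, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, default=default))


def read_ground_truth_json(path):
    from .simulate import GroundTruth

    raw = json.loads(Path(path).read_text())

    def frame(d, index_col):
        df = pd.DataFrame(d)
        return df.set_index(index_col) if index_col in df.columns else df

    return GroundTruth(
        proteins=frame(raw["proteins"], "protein_id"),
        samples=frame(raw["samples"], "sample_id"),
        markers=frame(raw["markers"], "gene"),
        config=raw.get("config", {}),
    )
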