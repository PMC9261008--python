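"""Synthetic DIA cohorts, single-cell references and ontology fixtures.

Everything downstream of raw spectra is exercisable on data produced here:
fraction-resolved peptide peak areas with identification quality values,
sample metadata, peptide->protein maps, a labelled single-cell count matrix,
gene-set collections and a rooted ontology DAG — all with planted ground
truth (which proteins are differential, in which direction, linked to which
cell type) so recovery can be measured exactly.

All planted effects live on the log2 scale; linear peak areas are ``2**x``
of the latent value. Identification quality values are a two-point mixture
(pass 1e-4 / fail 1e-2) whose pass probability rises logistically with the
latent abundance, so low-abundance measurements fail the downstream
``q <= 1e-3`` filter more often — abundance-dependent missingness realised
through filtering rather than absence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_dia_cohort",
    "generate_sc_reference",
    "generate_ontology_fixture",
    "QVALUE_PASS",
    "QVALUE_FAIL",
]

# two-point quality-value mixture: one side of the 1e-3 cut each
QVALUE_PASS = 1e-4
QVALUE_FAIL = 1e-2


@dataclass
class SimConfig:
    """Parameters of a simulated two-group DIA cohort.

    Defaults emulate a brain-tissue case/control comparison of realistic
    depth at a size that keeps simulation cheap: ~10 subjects per group
    (the study cohorts range 8-13), proteins carrying 1-8 peptides measured
    in 4 gel fractions, a minority of proteins planted as differential.
    ``noise_sd`` (log2 measurement noise of technical origin) defaults to
    0.35, calibrated so that after top-2-fraction and top-5-peptide rollup
    the technical-replicate coefficient of variation at the protein level
    is ~0.13, the reproducibility typical of DIA brain-tissue experiments.
    """

    n_samples_per_group: int = 10
    n_proteins: int = 300
    peptides_per_protein_range: tuple[int, int] = (1, 8)
    n_fractions: int = 4
    de_fraction: float = 0.15
    de_log2fc: float = 2.0
    celltype_link: dict[str, tuple[list[int], int]] | None = None
    sample_scale_sd: float = 0.25
    noise_sd: float = 0.35
    missingness_midpoint: float = 16.0
    missingness_scale: float = 1.5
    n_tech_replicates: int = 0
    shared_peptide_fraction: float = 0.0
    group_labels: tuple[str, str] = ("NDC", "FTD")
    protein_base_mean: float = 20.0
    protein_base_sd: float = 2.0
    peptide_offset_sd: float = 1.0
    fraction_offset_step: float = -1.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.peptides_per_protein_range
        if self.n_samples_per_group < 1 or self.n_proteins < 1 or self.n_fractions < 1:
            raise ValueError("counts must be >= 1")
        if not (1 <= lo <= hi <= 50):
            raise ValueError("peptides_per_protein_range must lie within [1, 50]")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.n_tech_replicates < 0:
            raise ValueError("n_tech_replicates must be >= 0")


@dataclass
class GroundTruth:
    """Planted simulation parameters enabling recovery tests.

    ``proteins`` has one row per protein: is_de, direction (+1/-1/0),
    log2fc, linked cell type (or None). ``samples`` has one row per sample:
    group label and log2 scale bias. ``markers`` (single-cell reference
    only) records each marker gene's cell type and enrichment factor.
    """

    proteins: pd.DataFrame
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    markers: pd.DataFrame = field(default_factory=pd.DataFrame)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "proteins": self.proteins.reset_index().to_dict(orient="list"),
            "samples": self.samples.reset_index().to_dict(orient="list"),
            "markers": self.markers.reset_index().to_dict(orient="list"),
            "config": self.config,
        }


def _protein_ids(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(n)]


def generate_dia_cohort(
    config: SimConfig, protein_names: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a two-group, fraction-resolved peptide quantification table.

    Per-measurement latent log2 abundance is

        protein base + peptide offset + fraction offset
        + group effect * is_de * direction + sample scale bias + noise,

    and the linear peak area is 2**latent. Technical replicates share every
    effect except the measurement noise. The identification quality value
    passes (1e-4) with probability sigmoid((latent - midpoint)/scale),
    else fails (1e-2); failed measurements still carry a (noisier) peak
    area, so the quality filter — not absence — removes them.

    Returns ``(peptide_table, metadata, pep2prot, truth)``; the table is in
    long format with columns peptide_id, sample_id, fraction, peak_area,
    qvalue.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_prot = config.n_proteins
    proteins = list(protein_names) if protein_names is not None else _protein_ids(n_prot)
    if len(proteins) != n_prot:
        raise ValueError("protein_names length must equal n_proteins")

    # planted differential set, optionally tied to cell types
    is_de = np.zeros(n_prot, dtype=bool)
    direction = np.zeros(n_prot, dtype=int)
    linked = np.array([None] * n_prot, dtype=object)
    if config.celltype_link:
        for ct, (idx, sign) in config.celltype_link.items():
            idx = np.asarray(idx, dtype=int)
            is_de[idx] = True
            direction[idx] = sign
            linked[idx] = ct
    n_extra = int(round(config.de_fraction * n_prot)) - int(is_de.sum())
    if n_extra > 0:
        pool = np.flatnonzero(~is_de)
        chosen = rng.choice(pool, size=min(n_extra, pool.size), replace=False)
        is_de[chosen] = True
        # equal split of directions among the planted set
        signs = np.where(np.arange(chosen.size) % 2 == 0, 1, -1)
        direction[chosen] = signs
    log2fc = np.where(is_de, direction * config.de_log2fc, 0.0)

    # peptide -> protein structure
    lo, hi = config.peptides_per_protein_range
    n_pep_per = rng.integers(lo, hi + 1, size=n_prot)
    pep_protein_idx = np.repeat(np.arange(n_prot), n_pep_per)
    n_pep = int(n_pep_per.sum())
    peptides = [f"pep{i:06d}" for i in range(n_pep)]
    map_rows = [
        {"peptide_id": peptides[i], "protein_id": proteins[pep_protein_idx[i]]}
        for i in range(n_pep)
    ]
    if config.shared_peptide_fraction > 0:
        n_shared = int(round(config.shared_peptide_fraction * n_pep))
        for i in rng.choice(n_pep, size=n_shared, replace=False):
            other = int(rng.integers(0, n_prot))
            if proteins[other] != proteins[pep_protein_idx[i]]:
                map_rows.append({"peptide_id": peptides[i], "protein_id": proteins[other]})
    pep2prot = pd.DataFrame(map_rows)

    # samples: two groups, plus technical replicates of the first subjects
    g1, g2 = config.group_labels
    n = config.n_samples_per_group
    sample_ids = [f"{g1}_{i:02d}" for i in range(n)] + [f"{g2}_{i:02d}" for i in range(n)]
    groups = [g1] * n + [g2] * n
    replicate_of = list(sample_ids)
    for r in range(config.n_tech_replicates):
        src = sample_ids[r % (2 * n)]
        sample_ids.append(f"{src}_rep")
        groups.append(groups[r % (2 * n)])
        replicate_of.append(src)
    n_samples = len(sample_ids)
    # biological effects indexed by the underlying subject, shared by replicates
    subject_scale = rng.normal(0.0, config.sample_scale_sd, size=2 * n)
    subj_index = np.array(
        [sample_ids.index(replicate_of[i]) if replicate_of[i] != sample_ids[i] else i
         for i in range(n_samples)]
    )
    scale_bias = subject_scale[np.minimum(subj_index, 2 * n - 1)]
    is_case = np.array([g == g2 for g in groups])

    metadata = pd.DataFrame(
        {"sample_id": sample_ids, "group": groups, "replicate_of": replicate_of}
    ).set_index("sample_id")

    # latent structure
    prot_base = rng.normal(config.protein_base_mean, config.protein_base_sd, size=n_prot)
    pep_offset = rng.normal(-1.0, config.peptide_offset_sd, size=n_pep)
    frac_offset = config.fraction_offset_step * np.arange(config.n_fractions) + rng.normal(
        0.0, 0.25, size=(n_pep, config.n_fractions)
    )

    base = prot_base[pep_protein_idx][:, None] + pep_offset[:, None] + frac_offset
    latent = (
        base[:, :, None]
        + (log2fc[pep_protein_idx][:, None, None] * is_case[None, None, :])
        + scale_bias[None, None, :]
    )  # (pep, fraction, sample)
    clean = latent.copy()
    latent = latent + rng.normal(0.0, config.noise_sd, size=latent.shape)

    # quality values: pass probability from the logistic retention curve on
    # the noise-free latent abundance (missingness tracks true abundance)
    z = (clean - config.missingness_midpoint) / config.missingness_scale
    p_pass = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    passed = rng.random(size=latent.shape) < p_pass
    qvalue = np.where(passed, QVALUE_PASS, QVALUE_FAIL)
    # failed identifications carry a noisier peak area
    latent = latent + np.where(passed, 0.0, rng.normal(0.0, 2 * config.noise_sd + 0.2,
                                                       size=latent.shape))

    pep_idx, frac_idx, samp_idx = np.meshgrid(
        np.arange(n_pep), np.arange(config.n_fractions), np.arange(n_samples),
        indexing="ij",
    )
    table = pd.DataFrame(
        {
            "peptide_id": np.asarray(peptides, dtype=object)[pep_idx.ravel()],
            "sample_id": np.asarray(sample_ids, dtype=object)[samp_idx.ravel()],
            "fraction": frac_idx.ravel(),
            "peak_area": np.exp2(latent.ravel()),
            "qvalue": qvalue.ravel(),
        }
    )

    truth = GroundTruth(
        proteins=pd.DataFrame(
            {
                "protein_id": proteins,
                "is_de": is_de,
                "direction": direction,
                "log2fc": log2fc,
                "cell_type": linked,
            }
        ).set_index("protein_id"),
        samples=pd.DataFrame(
            {"sample_id": sample_ids, "group": groups, "scale_bias": scale_bias}
        ).set_index("sample_id"),
        config={k: v for k, v in asdict(config).items() if k != "celltype_link"},
    )
    return table, metadata, pep2prot, truth


def generate_sc_reference(
    n_cells_per_type: int,
    n_genes: int,
    n_marker_per_type: int,
    marker_enrichment: float,
    cell_types: list[str] | None = None,
    n_types: int = 3,
    dispersion: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Simulate a labelled cell x gene count matrix with planted markers.

    Counts follow a negative-binomial model around gene-specific baseline
    means; each cell type owns ``n_marker_per_type`` disjoint marker genes
    whose mean in that type is ``marker_enrichment`` times the mean
    elsewhere, so after specificity computation a marker's own-type
    specificity approaches ``e / (e + n_types - 1)``.
    """
    if cell_types is None:
        defaults = ["astrocyte", "endothelial", "excitatory", "inhibitory",
                    "microglia", "oligodendrocyte", "OPC"]
        cell_types = defaults[:n_types] if n_types <= len(defaults) else [
            f"type{i}" for i in range(n_types)
        ]
    n_types = len(cell_types)
    if n_types < 2:
        raise ValueError("need at least two cell types")
    if n_marker_per_type * n_types > n_genes:
        raise ValueError("marker sets exceed the number of genes")

    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    base_mean = np.exp(rng.normal(1.0, 0.8, size=n_genes))

    marker_type = np.array([None] * n_genes, dtype=object)
    for t, ct in enumerate(cell_types):
        sl = slice(t * n_marker_per_type, (t + 1) * n_marker_per_type)
        marker_type[sl] = ct

    n_cells = n_cells_per_type * n_types
    labels = pd.Series(
        np.repeat(cell_types, n_cells_per_type),
        index=[f"cell{i:05d}" for i in range(n_cells)],
        name="cell_type",
    )
    mean = np.tile(base_mean, (n_cells, 1))
    for t, ct in enumerate(cell_types):
        cols = np.flatnonzero(marker_type == ct)
        rows = slice(t * n_cells_per_type, (t + 1) * n_cells_per_type)
        mean[rows, cols] *= marker_enrichment

    # NB via gamma-Poisson; dispersion = 1/size
    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mean / shape)
    else:
        lam = mean
    counts = rng.poisson(lam)
    matrix = pd.DataFrame(counts, index=labels.index, columns=genes)

    truth = GroundTruth(
        proteins=pd.DataFrame(index=pd.Index([], name="protein_id")),
        markers=pd.DataFrame(
            {"gene": genes, "cell_type": marker_type,
             "enrichment": np.where(marker_type != None, marker_enrichment, 1.0)}  # noqa: E711
        ).set_index("gene"),
        config={"n_cells_per_type": n_cells_per_type, "n_genes": n_genes,
                "n_marker_per_type": n_marker_per_type,
                "marker_enrichment": marker_enrichment, "seed": seed},
    )
    return matrix, labels, truth


def generate_ontology_fixture(
    n_terms: int,
    max_depth: int = 4,
    genes: list[str] | None = None,
    n_genes: int = 200,
    seed: int = 0,
) -> tuple["nx.DiGraph", dict[str, set[str]]]:
    """Build a rooted parent->child term DAG with nested gene sets.

    The root annotates every gene; each further term draws one or two
    parents from shallower levels and annotates a random subset of the
    union of its parents' genes, so the child-subset invariant holds by
    construction. Term sizes span both sides of the usual minimum-size
    threshold of five.
    """
    import networkx as nx

    if n_terms < 3:
        raise ValueError("need at least 3 terms")
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = [f"G{i:05d}" for i in range(n_genes)]
    genes = list(genes)

    dag = nx.DiGraph()
    term_ids = [f"T{i:04d}" for i in range(n_terms)]
    sets: dict[str, set[str]] = {term_ids[0]: set(genes)}
    depth = {term_ids[0]: 0}
    dag.add_node(term_ids[0], name="root", namespace="BP")

    for tid in term_ids[1:]:
        shallow = [t for t in sets if depth[t] < max_depth]
        n_par = int(rng.integers(1, 3)) if len(shallow) > 1 else 1
        parents = list(rng.choice(shallow, size=min(n_par, len(shallow)), replace=False))
        pool = sorted(set().union(*(sets[p] for p in parents)))
        k = int(rng.integers(2, max(3, min(len(pool), 30)) + 1)) if pool else 0
        members = set(rng.choice(pool, size=min(k, len(pool)), replace=False)) if pool else set()
        sets[tid] = members
        depth[tid] = max(depth[p] for p in parents) + 1
        dag.add_node(tid, name=f"term {tid}", namespace="BP")
        for p in parents:
            dag.add_edge(p, tid)
    return dag, sets


def sets_to_gmt(sets: dict[str, set[str]]) -> dict[str, tuple[str, list[str]]]:
    """Adapt a term->members mapping to the GMT-style (name, members) form."""
    return {tid: (tid, sorted(members)) for tid, members in sets.items()}
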