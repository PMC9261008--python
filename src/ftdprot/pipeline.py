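"""End-to-end pipeline: simulate/ingest -> quantify -> test -> interpret.

A single plain-text YAML/JSON config pins every threshold of the analysis
(quality cut 1e-3, presence 0.5, q < 0.05, specificity >= 0.5, 1000
permutations, 20000 bootstraps) so a run is auditable and, given the same
root seed, byte-identical. All randomness flows from one root seed through
per-stage spawned streams, so each stage is independently reproducible.
Every output file is recorded in a manifest with its SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .simulate import SimConfig, generate_dia_cohort, generate_sc_reference
from .quant import (
    filter_peptides, peptide_fraction_matrix, normalize_cyclic_loess,
    rollup_fractions, rollup_proteins, compute_replicate_cov,
)
from .diffexpr import GroupDesign, run_de, de_partition
from .celltype import (
    compute_specificity, ewce_bootstrap, classify_highly_enriched,
    ndc_variation_sd, composition_check,
)
from .enrichment import hypergeometric_enrichment, best_per_parent

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "ConfigError", "DataError"]


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    """Thresholds, seeds and stage toggles for one end-to-end run."""

    seed: int = 0
    qcut: float = 1e-3
    presence: float = 0.5
    filter_mode: str = "pairwise"
    loess_iterations: int = 3
    loess_span: float = 0.7
    normalize_before_rollup: bool = True
    top_fractions: int = 2
    top_peptides: int = 5
    shared_policy: str = "error"
    alpha: float = 0.05
    n_perm: int = 1000
    n_boot: int = 20000
    specificity_threshold: float = 0.5
    merge_neurons: bool = True
    min_term_size: int = 5
    ndc_splits: int = 100
    ndc_group: str = "NDC"
    case_group: str = "FTD"
    run_enrichment: bool = True
    run_celltype: bool = True
    sim: dict = field(default_factory=dict)
    sc: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        checks = [
            (0 <= self.qcut <= 1, "qcut must lie in [0,1]"),
            (0 < self.presence <= 1, "presence must lie in (0,1]"),
            (0 <= self.alpha <= 1, "alpha must lie in [0,1]"),
            (0 < self.specificity_threshold <= 1, "specificity_threshold in (0,1]"),
            (self.n_perm >= 1, "n_perm must be >= 1"),
            (self.n_boot >= 1, "n_boot must be >= 1"),
            (self.top_fractions >= 1 and self.top_peptides >= 1, "top-k must be >= 1"),
            (self.filter_mode in ("global", "pairwise"), "filter_mode unknown"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(root: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(root).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full synthetic analysis and write a result bundle.

    Stages: simulate -> quality filter -> cyclic loess -> fraction and
    peptide rollup -> replicate CoV -> SAM differential expression ->
    specificity + EWCE + highly-enriched classification + control-band
    composition check -> hypergeometric enrichment with best-per-parent.
    Returns the manifest dict (also written to ``manifest.json``).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ["simulate", "sc", "de", "ewce", "ndc"])
    results: dict = {"seeds": seeds, "config": asdict(config)}
    files: list[Path] = []
    stage = "simulate"
    try:
        # --- synthetic single-cell reference and linked cohort ------------
        sc_kwargs = dict(n_cells_per_type=60, n_genes=None, n_marker_per_type=15,
                         marker_enrichment=12.0, n_types=4)
        sc_kwargs.update(config.sc)
        sim_kwargs = dict(config.sim)
        sim_cfg = SimConfig(**{**{"seed": seeds["simulate"]}, **sim_kwargs})
        if sc_kwargs["n_genes"] is None:
            sc_kwargs["n_genes"] = sim_cfg.n_proteins
        stage = "simulate"
        proteins = [f"G{i:05d}" for i in range(sim_cfg.n_proteins)]
        sc_matrix, sc_labels, sc_truth = generate_sc_reference(
            seed=seeds["sc"], **sc_kwargs
        )
        # plant disease effects inside cell-type marker sets so EWCE and the
        # composition check have known structure to recover
        cell_types = sorted(sc_labels.unique())
        marker_idx = {
            ct: [i for i, g in enumerate(proteins)
                 if sc_truth.markers["cell_type"].get(g) == ct]
            for ct in cell_types
        }
        if sim_cfg.celltype_link is None and config.run_celltype:
            link = {}
            for j, ct in enumerate(cell_types[:2]):
                if marker_idx[ct]:
                    link[ct] = (marker_idx[ct], 1 if j == 0 else -1)
            sim_cfg.celltype_link = link
        table, metadata, pep2prot, truth = generate_dia_cohort(sim_cfg, protein_names=proteins)
        fio.write_peptide_table(table, outdir / "peptides.tsv")
        fio.write_metadata(metadata, outdir / "samples.tsv")
        fio.write_map(pep2prot, outdir / "pep2prot.tsv")
        fio.write_ground_truth_json(truth, outdir / "ground_truth.json")
        files += [outdir / f for f in
                  ["peptides.tsv", "samples.tsv", "pep2prot.tsv", "ground_truth.json"]]

        # --- quantification ----------------------------------------------
        stage = "quant"
        base_samples = metadata.index[metadata.index == metadata["replicate_of"]]
        base_meta = metadata.loc[base_samples]
        filtered = filter_peptides(
            table[table["sample_id"].isin(base_samples)], base_meta,
            mode=config.filter_mode, qcut=config.qcut, presence=config.presence,
        )
        mat = peptide_fraction_matrix(filtered, samples=list(base_samples)).to_log2()
        if config.normalize_before_rollup:
            mat = normalize_cyclic_loess(mat, iterations=config.loess_iterations,
                                         span=config.loess_span)
        peptides = rollup_fractions(mat, k=config.top_fractions)
        if not config.normalize_before_rollup:
            peptides = normalize_cyclic_loess(
                peptides.to_log2(), iterations=config.loess_iterations,
                span=config.loess_span,
            ).to_linear()
        protein_mat = rollup_proteins(peptides, pep2prot, k=config.top_peptides,
                                      shared_policy=config.shared_policy)
        fio.write_abundance(protein_mat, outdir / "proteins.tsv")
        files.append(outdir / "proteins.tsv")
        results["n_peptides_retained"] = int(peptides.data.shape[0])
        results["n_proteins_quantified"] = int(protein_mat.data.shape[0])

        # replicate CoV when technical replicates exist
        reps = metadata[metadata.index != metadata["replicate_of"]]
        if len(reps):
            rep_table = filter_peptides(table, metadata, mode=config.filter_mode,
                                        qcut=config.qcut, presence=config.presence)
            rep_mat = peptide_fraction_matrix(rep_table, samples=list(metadata.index)).to_log2()
            rep_prot = rollup_proteins(rollup_fractions(rep_mat, k=config.top_fractions),
                                       pep2prot, k=config.top_peptides,
                                       shared_policy=config.shared_policy)
            groups = {src: [src, *reps.index[reps["replicate_of"] == src]]
                      for src in reps["replicate_of"].unique()}
            _, median_cov = compute_replicate_cov(rep_prot, groups)
            results["median_replicate_cov"] = median_cov

        # --- differential expression --------------------------------------
        stage = "de"
        design = GroupDesign(base_meta["group"], config.ndc_group, config.case_group)
        de = run_de(protein_mat.to_log2(), design, alpha=config.alpha,
                    n_perm=config.n_perm, seed=seeds["de"])
        de.rename_axis("protein_id").to_csv(outdir / "de.tsv", sep="\t", na_rep="NA")
        files.append(outdir / "de.tsv")
        higher, lower = de_partition(de)
        results["n_de"] = len(higher) + len(lower)
        results["n_higher"], results["n_lower"] = len(higher), len(lower)

        # --- cell type enrichment and composition check -------------------
        if config.run_celltype:
            stage = "celltype"
            spec = compute_specificity(sc_matrix, sc_labels)
            fio.write_abundance(
                type(protein_mat)(spec, level="specificity", scale="linear"),
                outdir / "specificity.tsv",
            )
            files.append(outdir / "specificity.tsv")
            background = [p for p in protein_mat.data.index if p in spec.index]
            ewce_tables = {}
            for label, target in [("higher", higher), ("lower", lower)]:
                tgt = [p for p in target if p in spec.index]
                if len(tgt) >= 5:
                    ewce_tables[label] = ewce_bootstrap(
                        tgt, background, spec, n_boot=config.n_boot, seed=seeds["ewce"],
                    )
                    ewce_tables[label].to_csv(outdir / f"ewce_{label}.tsv", sep="\t")
                    files.append(outdir / f"ewce_{label}.tsv")
            assignments = classify_highly_enriched(
                spec, list(protein_mat.data.index),
                threshold=config.specificity_threshold,
                merge_neurons=config.merge_neurons,
            )
            ndc_samples = base_meta.index[base_meta["group"] == config.ndc_group]
            sd = ndc_variation_sd(protein_mat, list(ndc_samples),
                                  n_splits=config.ndc_splits, seed=seeds["ndc"])
            summary, detail = composition_check(de, assignments, sd, alpha=config.alpha)
            summary.to_csv(outdir / "composition_check.tsv", sep="\t")
            detail.rename_axis("protein_id").to_csv(
                outdir / "composition_detail.tsv", sep="\t", na_rep="NA")
            files += [outdir / "composition_check.tsv", outdir / "composition_detail.tsv"]
            results["ndc_fc_sd"] = sd
            results["composition"] = summary.to_dict(orient="index")

        # --- overrepresentation -------------------------------------------
        if config.run_enrichment:
            stage = "enrichment"
            from .simulate import generate_ontology_fixture, sets_to_gmt

            dag, term_sets = generate_ontology_fixture(
                n_terms=40, max_depth=3, genes=list(protein_mat.data.index),
                seed=seeds["simulate"],
            )
            sets = sets_to_gmt(term_sets)
            target = sorted(set(higher) | set(lower))
            bg = list(protein_mat.data.index)
            if target:
                terms = hypergeometric_enrichment(
                    target, bg, sets, min_size=config.min_term_size, alpha=config.alpha)
                bpp = best_per_parent(terms, dag, alpha=config.alpha)
                terms.to_csv(outdir / "terms.tsv", sep="\t")
                bpp.to_csv(outdir / "terms_best_per_parent.tsv", sep="\t")
                files += [outdir / "terms.tsv", outdir / "terms_best_per_parent.tsv"]
                results["n_terms_tested"] = int(len(terms))
                results["n_terms_significant"] = int(terms["significant"].sum())
                results["n_best_per_parent"] = int(len(bpp))
    except (ConfigError, DataError):
        raise
    except Exception as exc:
        raise DataError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seeds": seeds,
        "config": asdict(config),
        "results": {k: v for k, v in results.items() if k not in ("seeds", "config")},
        "files": {f.name: _sha256(f) for f in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
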