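"""End-to-end pipeline: counts → SNPs → scan → candidates → network.

A single :class:`PipelineConfig` holds every input path and threshold; the
pipeline validates inputs, runs the four analysis stages in order with
fail-fast, stage-labelled errors, stamps every output with the tool
version, configuration hash and seed, and writes a machine-readable JSON
manifest of row counts and wall times per stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any

import networkx as nx
import pandas as pd
import yaml

from . import annotation, genome_scan, network, snp_calling
from .io import (config_hash, file_sha256, read_counts, read_design,
                 read_tsv, write_sync, write_tsv, __version__)

__all__ = ["PipelineConfig", "RunManifest", "validate_inputs", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.

    The defaults are the analysis constants the pipeline is built around:
    minimum pool depth 25, dataset-wide MAF 1%, +/-100 kbp candidate
    windows, 0.90 coupling-probability filter, consensus thresholds 1e-5 /
    1e-3 on BH-adjusted p-values, 1000 permutations.
    """

    counts: str
    design: str
    annotation: str
    interactome: str
    out_dir: str
    ortholog_table: str | None = None
    gene2term: str | None = None
    min_depth: int = 25
    maf: float = 0.01
    window: int = 100_000
    prob_threshold: float = 0.90
    q_high: float = 1e-5
    q_sugg: float = 1e-3
    k_max: int = 5
    n_perm: int = 1000
    write_sync_format: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not (0.0 <= self.maf < 0.5):
            raise ValueError("maf must lie in [0, 0.5)")
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if not (0.0 <= self.prob_threshold <= 1.0):
            raise ValueError("prob_threshold must lie in [0, 1]")
        for name in ("q_high", "q_sugg"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.n_perm < 1 or self.k_max < 1:
            raise ValueError("n_perm and k_max must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        # out_dir identifies where results go, not what is computed, so it
        # stays out of the hash: reruns into different directories match
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return config_hash(payload)

    def meta(self) -> dict[str, Any]:
        return {"config": self.hash(), "seed": self.seed}


@dataclasses.dataclass
class RunManifest:
    """Per-stage record counts, parameters and wall time for one run."""
    config: dict[str, Any]
    config_hash: str
    inputs: dict[str, str]
    stages: list[dict[str, Any]] = dataclasses.field(default_factory=list)

    def add_stage(self, name: str, rows_in: int, rows_out: int,
                  wall_s: float, **params) -> None:
        if any(s["stage"] == name for s in self.stages):
            raise ValueError(f"stage {name!r} recorded twice")
        self.stages.append({"stage": name, "rows_in": rows_in,
                            "rows_out": rows_out,
                            "wall_s": round(wall_s, 3), **params})

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {"tool": f"poolscan v{__version__}",
                   "config_hash": self.config_hash,
                   "config": self.config, "inputs": self.inputs,
                   "stages": self.stages}
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


def validate_inputs(config: PipelineConfig) -> dict[str, list[str]]:
    """Schema-check every input file; returns {'errors': [...], 'warnings': [...]}."""
    errors: list[str] = []
    warnings: list[str] = []

    def check(path, label, loader):
        if path is None:
            return None
        if not Path(path).exists():
            errors.append(f"{label}: file not found: {path}")
            return None
        try:
            return loader(path)
        except Exception as err:  # structured validation: collect, don't raise
            errors.append(f"{label}: {err}")
            return None

    counts = check(config.counts, "counts", read_counts)
    design = check(config.design, "design", read_design)
    if counts is not None and design is not None:
        unknown = sorted(set(counts["population"]) - set(design))
        if unknown:
            errors.append(f"counts: populations missing from design: {unknown}")
        if "replicate" not in counts.columns:
            warnings.append("counts: no replicate column; treated as merged")
    check(config.annotation, "annotation", annotation.FeatureCatalog.from_gff3)
    check(config.interactome, "interactome", network.read_interactome)
    if config.ortholog_table:
        check(config.ortholog_table, "ortholog_table",
              lambda p: annotation.map_orthologs([], read_tsv(p)))
    if config.gene2term:
        tab = check(config.gene2term, "gene2term", read_tsv)
        if tab is not None and not {"gene", "term"} <= set(tab.columns):
            errors.append("gene2term: needs 'gene' and 'term' columns")
    return {"errors": errors, "warnings": warnings}


def _stage(manifest: RunManifest, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            return False

        def done(self, rows_in, rows_out, **params):
            wall = time.perf_counter() - self.t0
            manifest.add_stage(name, rows_in, rows_out, wall, **params)
            log.info("stage %s: %d rows in, %d rows out (%.2fs)",
                     name, rows_in, rows_out, wall)
    return _Timer()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run all four analysis stages and write outputs + manifest.

    Outputs under ``config.out_dir``: snps.tsv (and snps.sync when asked),
    scan.tsv, pca.tsv, candidates.tsv, term_enrichment.tsv (when a
    gene→term table is given), enrichment_curve.tsv, permutations.tsv,
    network.sif, network.graphml, topology.tsv, manifest.json.  Fully
    deterministic for a fixed seed.
    """
    report = validate_inputs(config)
    if report["errors"]:
        raise ValueError("invalid inputs:\n  " + "\n  ".join(report["errors"]))
    for warning in report["warnings"]:
        log.warning("%s", warning)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = config.meta()
    inputs = {k: file_sha256(p) for k, p in (
        ("counts", config.counts), ("design", config.design),
        ("annotation", config.annotation),
        ("interactome", config.interactome)) if p}
    manifest = RunManifest(config=config.to_dict(), config_hash=config.hash(),
                           inputs=inputs)

    counts = read_counts(config.counts)
    design = read_design(config.design)
    catalog = annotation.FeatureCatalog.from_gff3(config.annotation)

    with _stage(manifest, "snp_calling") as st:
        merged = snp_calling.merge_replicates(counts) \
            if "replicate" in counts.columns else counts
        deep = snp_calling.filter_depth(merged, min_depth=config.min_depth)
        snps = snp_calling.call_biallelic(deep, maf=config.maf)
        write_tsv(snps, out / "snps.tsv", meta)
        if config.write_sync_format and len(snps):
            write_sync(snps, out / "snps.sync", meta)
        st.done(len(counts), len(snps), min_depth=config.min_depth,
                maf=config.maf)

    with _stage(manifest, "genome_scan") as st:
        if snps.empty:
            scan = pd.DataFrame(columns=["lg", "pos", "ref", "alt",
                                         "mean_fst", "fisher_p", "fisher_q",
                                         "xtx", "xtx_p", "xtx_q",
                                         "snp_class"])
            pca_coords = pd.DataFrame(columns=["population"])
        else:
            scan = genome_scan.scan(snps, design, q_high=config.q_high,
                                    q_sugg=config.q_sugg)
            freqs = genome_scan.allele_freq_matrix(snps)
            coords, ratios = genome_scan.population_pca(freqs)
            pca_coords = coords.reset_index(names="population")
            pca_coords.attrs["explained"] = ratios
            write_tsv(pd.DataFrame(
                {"component": coords.columns,
                 "explained_variance_fraction": ratios}),
                out / "pca_variance.tsv", meta)
        write_tsv(scan, out / "scan.tsv", meta)
        write_tsv(pca_coords, out / "pca.tsv", meta)
        st.done(len(snps), len(scan), q_high=config.q_high,
                q_sugg=config.q_sugg)

    with _stage(manifest, "candidate_annotation") as st:
        candidates = annotation.collate_candidates(scan, catalog,
                                                   window=config.window)
        write_tsv(candidates.to_frame(), out / "candidates.tsv", meta)
        gene_set: tuple[str, ...] = candidates.genes
        if config.ortholog_table:
            ortho = read_tsv(config.ortholog_table)
            gene_set = annotation.map_orthologs(gene_set, ortho)
        if config.gene2term:
            g2t = read_tsv(config.gene2term)
            background = catalog.gene_ids()
            if config.ortholog_table:
                background = list(annotation.map_orthologs(background, ortho))
            enr = annotation.term_enrichment(gene_set, g2t, background)
            write_tsv(enr, out / "term_enrichment.tsv", meta)
        st.done(len(scan), len(candidates.genes) + len(candidates.cpg_islands),
                window=config.window)

    with _stage(manifest, "network_enrichment") as st:
        universe = catalog.gene_ids()
        if config.ortholog_table:
            universe = list(annotation.map_orthologs(universe, ortho))
        net = network.read_interactome(config.interactome, universe=universe)
        filtered = network.filter_by_probability(net, config.prob_threshold)
        n_universe = len(net.graph["universe"])
        if gene_set:
            sub = network.direct_interaction_subgraph(filtered, gene_set)
            sweep = network.degree_sweep(sub, gene_set, n_universe,
                                         k_max=config.k_max)
            curves, null_summary = network.permutation_null(
                filtered, len(gene_set), n_universe, k_max=config.k_max,
                n_perm=config.n_perm, seed=config.seed)
            k_sel, final = network.select_network(sub, gene_set, sweep,
                                                  null_summary)
            topo = network.topology_indices(final)
        else:
            sweep = pd.DataFrame(columns=["k", "n_network", "n_candidates",
                                          "p"])
            null_summary = pd.DataFrame(columns=["k", "median", "q05", "min"])
            k_sel, final = 0, nx.Graph()
            topo = network.topology_indices(final)
        write_tsv(sweep, out / "enrichment_curve.tsv", meta)
        write_tsv(null_summary, out / "permutations.tsv",
                  {**meta, "n_perm": config.n_perm})
        write_tsv(topo, out / "topology.tsv", {**meta, "selected_k": k_sel})
        network.write_sif(final, out / "network.sif")
        network.write_graphml(final, out / "network.graphml")
        st.done(len(gene_set), final.number_of_nodes(),
                n_perm=config.n_perm, selected_k=k_sel,
                prob_threshold=config.prob_threshold)

    manifest.write(out / "manifest.json")
    return manifest
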