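"""Shared fixtures: small synthetic datasets built once per session."""

from __future__ import annotations

import pathlib

import pandas as pd
import pytest

import poolscan as ps
from poolscan import io as pio
from poolscan import network as pnet


@pytest.fixture(scope="session")
def planted_cfg() -> ps.SimConfig:
    """Planted-selection study design: strong domestication shift."""
    return ps.SimConfig(n_sites=1500, n_selected=30, selection_shift=0.6,
                        mean_depth=60.0, seed=11)


@pytest.fixture(scope="session")
def planted_data(planted_cfg):
    counts, truth = ps.simulate_counts(planted_cfg)
    snps = ps.call_biallelic(ps.filter_depth(ps.merge_replicates(counts)))
    return counts, truth, snps


@pytest.fixture(scope="session")
def planted_scan(planted_cfg, planted_data):
    _, truth, snps = planted_data
    res = ps.scan(snps, planted_cfg.design())
    return res.merge(truth, on=["lg", "pos"], suffixes=("", "_truth"))


@pytest.fixture(scope="session")
def toy_catalog() -> ps.FeatureCatalog:
    return ps.FeatureCatalog(pd.DataFrame({
        "id": ["geneA", "geneB", "geneC", "cpg1"],
        "type": ["gene", "gene", "gene", "CpG_island"],
        "lg": ["LG01", "LG01", "LG01", "LG01"],
        "start": [240_000, 40_000, 150_500, 150_900],
        "end": [260_000, 49_999, 150_700, 151_200],
    }))


@pytest.fixture(scope="session")
def pipeline_dataset(tmp_path_factory) -> dict:
    """Complete on-disk synthetic dataset for end-to-end runs.

    The interactome's planted module is anchored on genes neighbouring the
    simulated selected loci, so a successful scan feeds real candidates into
    the network stage.
    """
    d = pathlib.Path(tmp_path_factory.mktemp("dataset"))
    cfg = ps.SimConfig(n_sites=1200, n_selected=25, selection_shift=0.6,
                       n_lg=4, seed=7)
    counts, truth = ps.simulate_counts(cfg)
    catalog = ps.simulate_annotation(cfg, genes_per_lg=25, cpg_per_lg=5)
    sel = truth[truth["selected"]]
    near = sorted({f for r in sel.itertuples()
                   for f in ps.features_in_window(catalog, r.lg,
                                                  int(r.pos))["id"]
                   if f.startswith("gene")})
    module = near[:20]
    net = ps.simulate_interactome(catalog.gene_ids(), module, seed=8)
    pio.write_counts(counts, d / "counts.tsv", {"seed": cfg.seed})
    pio.write_tsv(truth, d / "truth.tsv", {"seed": cfg.seed})
    catalog.to_gff3(d / "annotation.gff3")
    pnet.write_interactome(net, d / "interactome.tsv")
    pio.write_design(cfg.design(), d / "design.tsv")
    g2t = pd.DataFrame({"gene": module, "term": "planted_pathway"})
    pio.write_tsv(g2t, d / "gene2term.tsv")
    return {"dir": d, "cfg": cfg, "truth": truth, "catalog": catalog,
            "module": module}


def make_pipeline_config(dataset: dict, out_dir: pathlib.Path,
                         **overrides) -> ps.PipelineConfig:
    d = dataset["dir"]
    kwargs = dict(counts=str(d / "counts.tsv"),
                  design=str(d / "design.tsv"),
                  annotation=str(d / "annotation.gff3"),
                  interactome=str(d / "interactome.tsv"),
                  gene2term=str(d / "gene2term.tsv"),
                  out_dir=str(out_dir),
                  # toy-scale consensus thresholds so the downstream stages
                  # receive a non-empty candidate set
                  q_high=1e-2, q_sugg=5e-2,
                  n_perm=60, seed=9)
    kwargs.update(overrides)
    return ps.PipelineConfig(**kwargs)
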