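"""Candidate features around outlier SNPs and generic term enrichment.

Every suggestive or highly suggestive SNP is mapped to the genes and CpG
islands whose intervals intersect a +/-100 kbp window around it
(coordinates are GFF3-style: 1-based, closed on both ends), and the union
over SNPs — with per-SNP provenance — forms the candidate set.  A generic
term-enrichment test (one-sided Fisher on candidate x annotated, BH over
terms) runs over any supplied gene→term table; orthology to a
better-annotated reference genome is handled as data, via a two-column
gene→ortholog mapping applied before enrichment.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .genome_scan import bh_adjust

__all__ = ["FeatureCatalog", "CandidateSet", "features_in_window",
           "collate_candidates", "term_enrichment", "map_orthologs"]

log = logging.getLogger(__name__)

FEATURE_TYPES = ("gene", "CpG_island")


class FeatureCatalog:
    """Genes and CpG islands with linkage-group coordinates.

    Wraps a DataFrame with columns ``id, type, lg, start, end`` (1-based,
    inclusive) and provides GFF3 round-tripping plus fast interval lookup.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"id", "type", "lg", "start", "end"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"feature table missing columns {sorted(missing)}")
        df = df[["id", "type", "lg", "start", "end"]].copy()
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] < 1).any():
            bad = df.loc[df["start"] < 1, "id"].iloc[0]
            raise ValueError(f"feature {bad!r}: start < 1")
        if (df["end"] < df["start"]).any():
            bad = df.loc[df["end"] < df["start"], "id"].iloc[0]
            raise ValueError(f"feature {bad!r}: end < start")
        if df["id"].duplicated().any():
            bad = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate feature id {bad!r}")
        self.df = df.sort_values(["lg", "start", "end", "id"],
                                 ignore_index=True)
        self._trees: dict[str, IntervalTree] = {}

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureCatalog) and self.df.equals(other.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def genes(self) -> pd.DataFrame:
        return self.df[self.df["type"] == "gene"]

    @property
    def cpg_islands(self) -> pd.DataFrame:
        return self.df[self.df["type"] == "CpG_island"]

    def gene_ids(self) -> list[str]:
        return sorted(self.genes["id"])

    def tree(self, lg: str) -> IntervalTree:
        if lg not in self._trees:
            sub = self.df[self.df["lg"] == lg]
            # interval tree is half-open; +1 makes the closed GFF3 end inclusive
            self._trees[lg] = IntervalTree.from_tuples(
                (s, e + 1, i) for i, s, e in
                zip(sub["id"], sub["start"], sub["end"]))
        return self._trees[lg]

    def to_gff3(self, path: str | Path,
                meta: Mapping[str, object] | None = None) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for key, value in (meta or {}).items():
                fh.write(f"#!{key} {value}\n")
            for row in self.df.itertuples(index=False):
                fh.write("\t".join([
                    row.lg, "poolscan", row.type, str(row.start),
                    str(row.end), ".", ".", ".", f"ID={row.id}"]) + "\n")

    @classmethod
    def from_gff3(cls, path: str | Path,
                  cpg_type: str = "CpG_island") -> "FeatureCatalog":
        """Parse gene and CpG-island features from a GFF3 file.

        ``cpg_type`` names the feature type used for CpG islands in the
        source annotation.
        """
        db = gffutils.create_db(str(path), dbfn=":memory:",
                                merge_strategy="create_unique",
                                keep_order=True)
        records = []
        for ftype, label in (("gene", "gene"), (cpg_type, "CpG_island")):
            for feat in db.features_of_type(ftype):
                fid = feat.attributes.get("ID", [feat.id])[0]
                records.append((fid, label, feat.seqid, feat.start, feat.end))
        if not records:
            raise ValueError(f"no gene/{cpg_type} features found in {path}")
        return cls(pd.DataFrame(
            records, columns=["id", "type", "lg", "start", "end"]))


@dataclasses.dataclass(frozen=True)
class CandidateSet:
    """De-duplicated features near qualifying SNPs, with provenance."""
    genes: tuple[str, ...]
    cpg_islands: tuple[str, ...]
    #: (lg, pos) -> tuple of feature ids within the window of that SNP
    provenance: dict[tuple[str, int], tuple[str, ...]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (lg, pos), feats in sorted(self.provenance.items()):
            for fid in feats:
                kind = "gene" if fid in set(self.genes) else "CpG_island"
                rows.append((lg, pos, fid, kind))
        return pd.DataFrame(rows, columns=["lg", "pos", "feature_id", "type"])


def features_in_window(catalog: FeatureCatalog, lg: str, pos: int,
                       window: int = 100_000) -> pd.DataFrame:
    """Features intersecting the closed interval [pos-window, pos+window].

    The window is anchored on the SNP position and clipped at coordinate 1;
    an unknown linkage group yields an empty result with a warning.
    """
    if lg not in set(catalog.df["lg"]):
        log.warning("linkage group %r not in annotation", lg)
        return catalog.df.iloc[0:0]
    lo = max(1, pos - window)
    hi = pos + window
    hits = {iv.data for iv in catalog.tree(lg).overlap(lo, hi + 1)}
    return catalog.df[catalog.df["id"].isin(hits)]


def collate_candidates(scan: pd.DataFrame, catalog: FeatureCatalog,
                       window: int = 100_000,
                       classes: Iterable[str] = ("suggestive",
                                                 "highly_suggestive"),
                       ) -> CandidateSet:
    """Union of features within the window of every qualifying SNP."""
    wanted = scan[scan["snp_class"].isin(set(classes))]
    genes: set[str] = set()
    cpgs: set[str] = set()
    provenance: dict[tuple[str, int], tuple[str, ...]] = {}
    for row in wanted.itertuples(index=False):
        feats = features_in_window(catalog, row.lg, int(row.pos), window)
        provenance[(row.lg, int(row.pos))] = tuple(sorted(feats["id"]))
        genes.update(feats.loc[feats["type"] == "gene", "id"])
        cpgs.update(feats.loc[feats["type"] == "CpG_island", "id"])
    return CandidateSet(genes=tuple(sorted(genes)),
                        cpg_islands=tuple(sorted(cpgs)),
                        provenance=provenance)


def map_orthologs(genes: Iterable[str],
                  ortholog_table: pd.DataFrame) -> tuple[str, ...]:
    """Translate gene ids through a two-column gene→ortholog table.

    Genes without a mapping are dropped; the result is de-duplicated and
    sorted.  The table needs columns ``gene`` and ``ortholog``.
    """
    if not {"gene", "ortholog"} <= set(ortholog_table.columns):
        raise ValueError("ortholog table needs 'gene' and 'ortholog' columns")
    mapping = dict(zip(ortholog_table["gene"], ortholog_table["ortholog"]))
    return tuple(sorted({mapping[g] for g in genes if g in mapping}))


def term_enrichment(candidates: Iterable[str], gene2term: pd.DataFrame,
                    background: Iterable[str]) -> pd.DataFrame:
    """One-sided Fisher term enrichment of the candidate set, BH-adjusted.

    ``gene2term`` has columns ``gene`` and ``term``; ``background`` is the
    gene universe the candidates were drawn from.  Terms with no annotated
    background gene are skipped.  Returns one row per term with the
    candidate count, background count, hypergeometric p (enrichment only)
    and BH q across terms.
    """
    cand = set(candidates)
    universe = set(background)
    if not cand <= universe:
        raise ValueError("candidates must be a subset of the background")
    if not cand:
        return pd.DataFrame(
            columns=["term", "n_candidate", "n_background", "p", "q"])
    if not {"gene", "term"} <= set(gene2term.columns):
        raise ValueError("gene2term table needs 'gene' and 'term' columns")
    ann = gene2term[gene2term["gene"].isin(universe)]
    n_universe, n_cand = len(universe), len(cand)
    rows = []
    for term, sub in ann.groupby("term", sort=True):
        term_genes = set(sub["gene"])
        if not term_genes:
            continue
        overlap = len(term_genes & cand)
        p = stats.hypergeom.sf(overlap - 1, n_universe, len(term_genes),
                               n_cand)
        rows.append((term, overlap, len(term_genes), p))
    out = pd.DataFrame(rows, columns=["term", "n_candidate", "n_background",
                                      "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out
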