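"""Interactome-assisted enrichment of candidate genes.

Starting from a probability-weighted gene-gene functional-coupling graph,
the analysis keeps only high-confidence edges (coupling probability >= 0.90),
restricts to edges with at least one candidate endpoint (non-candidate
endpoints become "intermediate partners"), and then sweeps a partner-degree
threshold k: at each k a partner is retained only if it touches at least k
distinct candidate genes, and the enrichment of the surviving network in
candidates is scored with a one-sided Fisher exact test against the
genome-wide gene universe.  A permutation null repeats the sweep for random
gene sets of the same size, giving the envelope against which the observed
curve is judged.  Topology indices (degree, radiality) describe the final
network, Cytoscape-style.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import read_tsv, write_tsv

__all__ = ["read_interactome", "write_interactome", "filter_by_probability",
           "direct_interaction_subgraph", "prune_partners",
           "enrichment_fisher", "degree_sweep", "permutation_null",
           "largest_component", "topology_indices", "select_network",
           "write_sif"]

log = logging.getLogger(__name__)

PROBABILITY_THRESHOLD = 0.90


def _universe(net: nx.Graph, fallback: Iterable[str] | None = None) -> tuple:
    uni = net.graph.get("universe")
    if uni is None:
        uni = tuple(sorted(net.nodes)) if fallback is None \
            else tuple(sorted(fallback))
    return tuple(uni)


def read_interactome(path: str | Path,
                     universe: Iterable[str] | None = None) -> nx.Graph:
    """Read a gene_a/gene_b/probability TSV into an undirected graph.

    Self-loops are rejected; duplicate edges keep the higher probability.
    ``universe`` (e.g. all annotated genes) sets the enrichment background;
    it defaults to the genes present in the file.
    """
    df = read_tsv(path)
    required = {"gene_a", "gene_b", "probability"}
    if not required <= set(df.columns):
        raise ValueError(f"interactome {path} needs columns {sorted(required)}")
    if ((df["probability"] < 0) | (df["probability"] > 1)).any():
        raise ValueError(f"interactome {path}: probabilities outside [0, 1]")
    if (df["gene_a"] == df["gene_b"]).any():
        raise ValueError(f"interactome {path}: self-loop edges")
    g = nx.Graph()
    for a, b, p in df[["gene_a", "gene_b", "probability"]].itertuples(
            index=False):
        if g.has_edge(a, b):
            p = max(p, g[a][b]["probability"])
        g.add_edge(a, b, probability=float(p))
    g.graph["universe"] = _universe(g, universe)
    missing = set(g.nodes) - set(g.graph["universe"])
    if missing:
        raise ValueError(f"interactome genes absent from universe: "
                         f"{sorted(missing)[:5]}")
    return g


def write_interactome(net: nx.Graph, path: str | Path,
                      meta: Mapping[str, object] | None = None) -> None:
    rows = sorted((min(a, b), max(a, b), d["probability"])
                  for a, b, d in net.edges(data=True))
    write_tsv(pd.DataFrame(rows, columns=["gene_a", "gene_b", "probability"]),
              path, meta)


def _copy_graph_attrs(src: nx.Graph, dst: nx.Graph) -> nx.Graph:
    dst.graph.update(src.graph)
    return dst


def filter_by_probability(net: nx.Graph,
                          threshold: float = PROBABILITY_THRESHOLD) -> nx.Graph:
    """Keep edges with coupling probability >= threshold (inclusive)."""
    out = nx.Graph()
    out.add_edges_from((a, b, d) for a, b, d in net.edges(data=True)
                       if d["probability"] >= threshold)
    return _copy_graph_attrs(net, out)


def direct_interaction_subgraph(net: nx.Graph,
                                candidates: Iterable[str]) -> nx.Graph:
    """Edges with at least one candidate endpoint.

    Non-candidate endpoints of retained edges are the network's
    "intermediate partners"; the candidate flag is stored per node.
    """
    cand = set(candidates)
    out = nx.Graph()
    out.add_edges_from((a, b, d) for a, b, d in net.edges(data=True)
                       if a in cand or b in cand)
    nx.set_node_attributes(out, {n: n in cand for n in out.nodes},
                           "candidate")
    out.graph["candidates"] = tuple(sorted(cand))
    return _copy_graph_attrs(net, out)


def prune_partners(subgraph: nx.Graph, k: int,
                   candidates: Iterable[str] | None = None,
                   mode: str = "candidate") -> nx.Graph:
    """Retain intermediate partners connected to >= k candidates.

    ``mode="candidate"`` (default) counts distinct candidate neighbours of
    each partner; ``mode="total"`` counts all neighbours.  Candidate genes
    are retained while they keep at least one edge; k=1 leaves the direct
    subgraph's partners unchanged.
    """
    if k < 1:
        raise ValueError("degree threshold k must be >= 1")
    if mode not in ("candidate", "total"):
        raise ValueError("mode must be 'candidate' or 'total'")
    cand = set(candidates if candidates is not None
               else subgraph.graph.get("candidates", ()))
    keep = set(cand)
    for node in subgraph.nodes:
        if node in cand:
            continue
        if mode == "candidate":
            score = sum(1 for nb in subgraph.neighbors(node) if nb in cand)
        else:
            score = subgraph.degree(node)
        if score >= k:
            keep.add(node)
    out = nx.Graph()
    out.add_edges_from((a, b, d) for a, b, d in subgraph.edges(data=True)
                       if a in keep and b in keep)
    out.remove_nodes_from([n for n in list(out.nodes) if out.degree(n) == 0])
    nx.set_node_attributes(out, {n: n in cand for n in out.nodes},
                           "candidate")
    return _copy_graph_attrs(subgraph, out)


def enrichment_fisher(network_genes: Iterable[str],
                      candidates: Iterable[str], n_universe: int) -> float:
    """One-sided (enrichment) Fisher exact p for candidates in the network.

    2x2 table: network membership x candidacy over a background of
    ``n_universe`` genes; the p-value is the hypergeometric upper tail of
    the observed overlap.
    """
    net = set(network_genes)
    cand = set(candidates)
    if n_universe < len(net | cand):
        raise ValueError("universe smaller than network plus candidates")
    overlap = len(net & cand)
    return float(stats.hypergeom.sf(overlap - 1, n_universe, len(cand),
                                    len(net)))


def degree_sweep(subgraph: nx.Graph, candidates: Iterable[str],
                 n_universe: int, k_max: int = 5,
                 mode: str = "candidate") -> pd.DataFrame:
    """Enrichment curve over the partner-degree threshold k = 1..k_max.

    Stops early once the pruned network is empty.  Returns one row per k
    with the network size, candidate count inside it, and Fisher p.
    """
    cand = set(candidates)
    rows = []
    for k in range(1, k_max + 1):
        pruned = prune_partners(subgraph, k, candidates=cand, mode=mode)
        genes = set(pruned.nodes)
        if not genes:
            break
        rows.append((k, len(genes), len(genes & cand),
                     enrichment_fisher(genes, cand, n_universe)))
    if not rows:
        rows = [(1, 0, 0, 1.0)]
    return pd.DataFrame(rows, columns=["k", "n_network", "n_candidates", "p"])


def permutation_null(net: nx.Graph, candidate_count: int,
                     n_universe: int | None = None, k_max: int = 5,
                     n_perm: int = 1000, seed: int = 0,
                     mode: str = "candidate",
                     ) -> tuple[np.ndarray, pd.DataFrame]:
    """Permutation envelope: the degree sweep on random same-size gene sets.

    Each permutation draws ``candidate_count`` genes uniformly without
    replacement from the interactome's gene universe and repeats the whole
    analysis.  Curves that terminate early (empty network) are padded with
    p = 1.  Returns the (n_perm, k_max) matrix of p-values and a per-k
    summary (median, 5th percentile, minimum).
    """
    universe = _universe(net)
    if n_universe is None:
        n_universe = len(universe)
    if candidate_count > len(universe):
        raise ValueError("candidate_count exceeds universe size")
    rng = np.random.default_rng(seed)
    curves = np.ones((n_perm, k_max))
    uni_arr = np.array(universe)
    for i in range(n_perm):
        random_set = uni_arr[rng.choice(len(uni_arr), size=candidate_count,
                                        replace=False)]
        sub = direct_interaction_subgraph(net, random_set)
        sweep = degree_sweep(sub, random_set, n_universe, k_max=k_max,
                             mode=mode)
        curves[i, sweep["k"].to_numpy() - 1] = sweep["p"].to_numpy()
    summary = pd.DataFrame({
        "k": np.arange(1, k_max + 1),
        "median": np.median(curves, axis=0),
        "q05": np.quantile(curves, 0.05, axis=0),
        "min": curves.min(axis=0),
    })
    return curves, summary


def largest_component(net: nx.Graph) -> nx.Graph:
    """Connected component with the most nodes (ties: smallest node id)."""
    if net.number_of_nodes() == 0:
        return _copy_graph_attrs(net, nx.Graph())
    components = sorted(nx.connected_components(net),
                        key=lambda c: (-len(c), min(c)))
    return _copy_graph_attrs(net, net.subgraph(components[0]).copy())


def topology_indices(net: nx.Graph) -> pd.DataFrame:
    """Degree and radiality per node, computed within connected components.

    Radiality of node v in a component of n nodes and diameter D is
    ``sum_u (D + 1 - d(v, u)) / (n - 1)`` over unweighted shortest-path
    distances; singleton components get radiality 0.
    """
    rows = []
    for comp_id, comp in enumerate(sorted(nx.connected_components(net),
                                          key=lambda c: (-len(c), min(c)))):
        sub = net.subgraph(comp)
        n = len(comp)
        if n == 1:
            node = next(iter(comp))
            rows.append((node, 0, 0.0, comp_id))
            continue
        lengths = dict(nx.all_pairs_shortest_path_length(sub))
        diameter = max(max(d.values()) for d in lengths.values())
        for node in sorted(comp):
            total = sum(diameter + 1 - d
                        for u, d in lengths[node].items() if u != node)
            rows.append((node, net.degree(node), total / (n - 1), comp_id))
    return pd.DataFrame(rows, columns=["node", "degree", "radiality",
                                       "component"])


def select_network(subgraph: nx.Graph, candidates: Iterable[str],
                   sweep: pd.DataFrame, null_summary: pd.DataFrame,
                   alpha: float = 0.05,
                   mode: str = "candidate") -> tuple[int, nx.Graph]:
    """Pick the reported network from the sweep and its permutation null.

    The chosen k is the smallest threshold at which the observed enrichment
    p falls below the null's 5th percentile while the null median is itself
    non-significant (the permutation curves have collapsed); if no k
    qualifies, the k with the smallest observed p is used.  Returns the k
    and the largest connected component of the pruned network at that k.
    """
    merged = sweep.merge(null_summary, on="k", how="left")
    qualifying = merged[(merged["p"] < merged["q05"])
                        & (merged["median"] >= alpha)]
    if len(qualifying):
        k = int(qualifying["k"].iloc[0])
    else:
        k = int(merged.loc[merged["p"].idxmin(), "k"])
    pruned = prune_partners(subgraph, k, candidates=candidates, mode=mode)
    return k, largest_component(pruned)


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    """GraphML export (graph-level tuple attributes are dropped: the format
    only carries scalar data values)."""
    clean = net.copy()
    for key in [k for k, v in clean.graph.items()
                if not isinstance(v, (str, int, float, bool))]:
        del clean.graph[key]
    nx.write_graphml(clean, str(path))


def write_sif(net: nx.Graph, path: str | Path,
              interaction: str = "pp") -> None:
    """Cytoscape SIF export (one ``a pp b`` line per edge, sorted)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for a, b in sorted((min(a, b), max(a, b)) for a, b in net.edges):
            fh.write(f"{a}\t{interaction}\t{b}\n")
        for node in sorted(nx.isolates(net)):
            fh.write(f"{node}\n")
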