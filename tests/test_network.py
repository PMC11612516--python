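"""Interactome filtering, degree sweep, permutation null and topology."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import poolscan as ps
from poolscan import network as net


def graph_from_edges(edges, universe=None):
    g = nx.Graph()
    for a, b, p in edges:
        g.add_edge(a, b, probability=p)
    g.graph["universe"] = tuple(sorted(universe if universe is not None
                                       else g.nodes))
    return g


def test_probability_filter_boundary_and_idempotence():
    g = graph_from_edges([("a", "b", 0.90), ("b", "c", 0.899),
                          ("c", "d", 0.95)])
    kept = net.filter_by_probability(g)
    assert sorted(kept.edges) == [("a", "b"), ("c", "d")]
    again = net.filter_by_probability(kept)
    assert sorted(again.edges) == sorted(kept.edges)


def test_direct_subgraph_partner_set_matches_brute_force():
    rng = np.random.default_rng(2)
    g = nx.gnp_random_graph(40, 0.1, seed=4)
    g = nx.relabel_nodes(g, {i: f"g{i:02d}" for i in g.nodes})
    nx.set_edge_attributes(g, 0.95, "probability")
    g.graph["universe"] = tuple(sorted(g.nodes))
    cand = set(rng.choice(sorted(g.nodes), 8, replace=False))
    sub = net.direct_interaction_subgraph(g, cand)
    # every edge touches a candidate
    assert all(a in cand or b in cand for a, b in sub.edges)
    partners = {n for n in sub.nodes if not sub.nodes[n]["candidate"]}
    brute = set().union(*(set(g.neighbors(c)) for c in cand)) - cand
    assert partners == brute
    # candidate-candidate edges are retained
    for a, b in g.edges:
        if a in cand and b in cand:
            assert sub.has_edge(a, b)


def test_direct_subgraph_no_candidate_contact_is_empty():
    g = graph_from_edges([("a", "b", 0.95)])
    sub = net.direct_interaction_subgraph(g, {"zzz"})
    assert sub.number_of_edges() == 0


def toy_subgraph():
    """3 candidates; partner p1 touches all three, p2 touches one."""
    edges = [("c1", "p1", 0.95), ("c2", "p1", 0.95), ("c3", "p1", 0.95),
             ("c1", "p2", 0.95), ("c1", "c2", 0.95)]
    g = graph_from_edges(edges, universe=[f"u{i}" for i in range(94)]
                         + ["c1", "c2", "c3", "p1", "p2", "x"])
    return net.direct_interaction_subgraph(g, {"c1", "c2", "c3"})


def test_prune_partners_by_candidate_degree():
    sub = toy_subgraph()
    pruned = net.prune_partners(sub, 2)
    assert "p1" in pruned.nodes and "p2" not in pruned.nodes
    k1 = net.prune_partners(sub, 1)
    assert sorted(k1.nodes) == sorted(sub.nodes)  # k=1 keeps all partners
    with pytest.raises(ValueError):
        net.prune_partners(sub, 0)


def test_prune_nested_networks():
    sub = toy_subgraph()
    prev = set(sub.nodes)
    for k in (1, 2, 3, 4):
        cur = set(net.prune_partners(sub, k).nodes)
        assert cur <= prev
        prev = cur


def test_enrichment_fisher_closed_form_and_bounds():
    # N=10, network of 4 genes all candidates: p = 1/C(10,4)
    assert net.enrichment_fisher(list("abcd"), list("abcd"), 10) == \
        pytest.approx(1 / math.comb(10, 4))
    # zero overlap is anti-enrichment
    assert net.enrichment_fisher(list("ab"), list("cd"), 50) >= 0.5
    with pytest.raises(ValueError):
        net.enrichment_fisher(list("abcd"), list("ef"), 5)


def test_enrichment_fisher_matches_enumeration():
    rng = np.random.default_rng(8)
    universe = [f"g{i}" for i in range(15)]
    for _ in range(25):
        network_genes = set(rng.choice(universe, rng.integers(1, 8),
                                       replace=False))
        cand = set(rng.choice(universe, rng.integers(1, 8), replace=False))
        got = net.enrichment_fisher(network_genes, cand, 15)
        kk, nn = len(cand), len(network_genes)
        obs = len(network_genes & cand)
        brute = sum(math.comb(kk, x) * math.comb(15 - kk, nn - x)
                    for x in range(obs, min(kk, nn) + 1)
                    if nn - x <= 15 - kk) / math.comb(15, nn)
        assert got == pytest.approx(brute)


def test_degree_sweep_star_concentrates_enrichment():
    sub = toy_subgraph()
    sweep = net.degree_sweep(sub, {"c1", "c2", "c3"}, 100, k_max=3)
    # pruning the weak partner shrinks the network at constant overlap,
    # so significance improves and sizes never increase
    assert sweep["p"].iloc[1] < sweep["p"].iloc[0]
    assert sweep["n_network"].is_monotonic_decreasing


def test_degree_sweep_empty_candidates():
    g = graph_from_edges([("a", "b", 0.95)])
    sweep = net.degree_sweep(net.direct_interaction_subgraph(g, set()),
                             set(), 10, k_max=3)
    assert (sweep["p"] == 1.0).all()
    assert (sweep["n_network"] == 0).all()


def test_largest_component_ties_and_flood_fill():
    g = graph_from_edges([("b", "c", 0.9), ("x", "y", 0.9), ("p", "q", 0.9),
                          ("q", "r", 0.9)])
    comp = net.largest_component(g)
    assert sorted(comp.nodes) == ["p", "q", "r"]
    two = graph_from_edges([("b", "c", 0.9), ("x", "y", 0.9)])
    assert sorted(net.largest_component(two).nodes) == ["b", "c"]  # tie: min id
    # flood-fill oracle
    seen, stack = set(), ["p"]
    while stack:
        n = stack.pop()
        if n not in seen:
            seen.add(n)
            stack.extend(g.neighbors(n))
    assert seen == set(comp.nodes)


def test_radiality_hand_values():
    path = graph_from_edges([("a", "b", 1.0), ("b", "c", 1.0)])
    topo = net.topology_indices(path).set_index("node")
    assert topo.loc["b", "radiality"] == pytest.approx(2.0)
    assert topo.loc["a", "radiality"] == pytest.approx(1.5)
    assert topo.loc["c", "radiality"] == pytest.approx(1.5)

    k5 = nx.complete_graph(5)
    nx.set_edge_attributes(k5, 1.0, "probability")
    topo = net.topology_indices(k5)
    assert np.allclose(topo["radiality"], 1.0)
    assert (topo["degree"] == 4).all()

    star = nx.star_graph(5)
    topo = net.topology_indices(star).set_index("node")
    assert topo.loc[0, "degree"] == 5


def test_radiality_matches_brute_force_on_random_graphs():
    for seed in range(6):
        g = nx.gnp_random_graph(int(np.random.default_rng(seed)
                                    .integers(5, 30)), 0.15, seed=seed)
        topo = net.topology_indices(g).set_index("node")
        # brute force: BFS shortest paths per component, by hand
        for comp in nx.connected_components(g):
            comp = set(comp)
            dists = {}
            for s in comp:
                d = {s: 0}
                frontier = [s]
                while frontier:
                    nxt = []
                    for u in frontier:
                        for v in g.neighbors(u):
                            if v not in d:
                                d[v] = d[u] + 1
                                nxt.append(v)
                    frontier = nxt
                dists[s] = d
            if len(comp) == 1:
                (s,) = comp
                assert topo.loc[s, "radiality"] == 0.0
                continue
            diam = max(max(d.values()) for d in dists.values())
            for s in comp:
                rad = sum(diam + 1 - d for u, d in dists[s].items()
                          if u != s) / (len(comp) - 1)
                assert topo.loc[s, "radiality"] == pytest.approx(rad)


def test_singleton_component_radiality_zero():
    g = nx.Graph()
    g.add_node("solo")
    topo = net.topology_indices(g).set_index("node")
    assert topo.loc["solo", "radiality"] == 0.0


def test_graph_operations_invariant_to_edge_row_order(tmp_path):
    rng = np.random.default_rng(14)
    edges = [(f"g{a:02d}", f"g{b:02d}", round(float(p), 4))
             for (a, b), p in zip(
                 [(a, b) for a in range(20) for b in range(a + 1, 20)
                  if rng.random() < 0.2],
                 rng.uniform(0.5, 1.0, 400))]
    df = pd.DataFrame(edges, columns=["gene_a", "gene_b", "probability"])
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    df.to_csv(p1, sep="\t", index=False)
    df.sample(frac=1.0, random_state=1).to_csv(p2, sep="\t", index=False)
    g1, g2 = net.read_interactome(p1), net.read_interactome(p2)

    def canon(g):
        return sorted((min(a, b), max(a, b), p)
                      for a, b, p in g.edges(data="probability"))

    assert canon(g1) == canon(g2)
    cand = sorted(g1.nodes)[:5]
    s1 = net.degree_sweep(net.direct_interaction_subgraph(
        net.filter_by_probability(g1), cand), cand, 30, k_max=3)
    s2 = net.degree_sweep(net.direct_interaction_subgraph(
        net.filter_by_probability(g2), cand), cand, 30, k_max=3)
    pd.testing.assert_frame_equal(s1, s2)


def test_read_interactome_validation(tmp_path):
    bad = tmp_path / "bad.tsv"
    bad.write_text("gene_a\tgene_b\tprobability\na\tb\t1.2\n")
    with pytest.raises(ValueError, match="probabilities"):
        net.read_interactome(bad)
    loop = tmp_path / "loop.tsv"
    loop.write_text("gene_a\tgene_b\tprobability\na\ta\t0.9\n")
    with pytest.raises(ValueError, match="self-loop"):
        net.read_interactome(loop)


def planted_fixture(seed=44):
    universe = [f"g{i + 1:05d}" for i in range(250)]
    cand = universe[:18]
    module = cand + universe[18:21]  # 3 intermediate partners
    g = ps.simulate_interactome(universe, module, p_within=0.95,
                                p_background=0.01, seed=seed)
    return g, cand


def test_permutation_null_flags_planted_module():
    g, cand = planted_fixture()
    filtered = net.filter_by_probability(g)
    sub = net.direct_interaction_subgraph(filtered, cand)
    sweep = net.degree_sweep(sub, cand, 250, k_max=3)
    curves, summary = net.permutation_null(filtered, len(cand), 250,
                                           k_max=3, n_perm=100, seed=45)
    assert sweep["p"].iloc[0] < summary["q05"].iloc[0]
    assert sweep["p"].iloc[0] < curves[:, 0].min()


def test_permutation_null_calibrated_on_random_sets():
    """A random candidate set sits inside its own permutation envelope."""
    g, _ = planted_fixture(seed=46)
    filtered = net.filter_by_probability(g)
    universe = np.array(filtered.graph["universe"])
    rng = np.random.default_rng(47)
    inside = 0
    n_trials = 20
    for t in range(n_trials):
        cand = list(rng.choice(universe, 18, replace=False))
        sub = net.direct_interaction_subgraph(filtered, cand)
        sweep = net.degree_sweep(sub, cand, len(universe), k_max=1)
        _, summary = net.permutation_null(filtered, 18, len(universe),
                                          k_max=1, n_perm=60, seed=1000 + t)
        if sweep["p"].iloc[0] >= summary["q05"].iloc[0]:
            inside += 1
    assert inside / n_trials >= 0.9


def test_permutation_single_draw_does_not_crash():
    g, cand = planted_fixture(seed=48)
    curves, summary = net.permutation_null(net.filter_by_probability(g),
                                           5, 250, k_max=2, n_perm=1, seed=0)
    assert curves.shape == (1, 2)
    assert len(summary) == 2


def test_select_network_recovers_planted_module():
    g, cand = planted_fixture(seed=49)
    filtered = net.filter_by_probability(g)
    sub = net.direct_interaction_subgraph(filtered, cand)
    sweep = net.degree_sweep(sub, cand, 250, k_max=3)
    _, summary = net.permutation_null(filtered, len(cand), 250, k_max=3,
                                      n_perm=100, seed=50)
    k, final = net.select_network(sub, cand, sweep, summary)
    got = {n for n in final.nodes if final.nodes[n]["candidate"]}
    jacc = len(got & set(cand)) / len(got | set(cand))
    assert jacc >= 0.8


def test_sif_export(tmp_path):
    g = graph_from_edges([("b", "a", 0.9), ("b", "c", 0.9)])
    path = tmp_path / "n.sif"
    net.write_sif(g, path)
    assert path.read_text() == "a\tpp\tb\nb\tpp\tc\n"
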