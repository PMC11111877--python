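"""Unit tests for kappa agreement, neighbor joining, tree cutting, summaries."""
import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import funcmod as fm
from funcmod.clustering import (
    KappaDistanceMatrix,
    build_kappa_distance_matrix,
    cut_tree,
    kappa_pair,
    nj_tree,
    summarize_modules,
    tree_leaf_distances,
)
from funcmod.datatypes import GeneUniverse, OmicsGeneSet


def kappa_oracle(A, B, universe):
    """Direct 2x2 computation, independent of kappa_pair internals."""
    t = len(universe.genes)
    a = len(set(A) & set(B))
    b = len(set(A) - set(B))
    c = len(set(B) - set(A))
    d = t - a - b - c
    po = (a + d) / t
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / t**2
    return (po - pe) / (1 - pe)


class TestKappa:
    def test_identical_sets(self, universe10):
        assert kappa_pair({"g1", "g2"}, {"g1", "g2"}, universe10) == 1.0

    def test_derived_example(self, universe10):
        # a=2,b=1,c=1,d=6 -> po=0.8, pe=0.58, kappa=0.22/0.42=11/21
        k = kappa_pair({"g1", "g2", "g3"}, {"g2", "g3", "g4"}, universe10)
        assert k == pytest.approx(11 / 21, rel=1e-12)

    def test_complementary_halves(self, universe10):
        A = {f"g{i}" for i in range(5)}
        B = {f"g{i}" for i in range(5, 10)}
        assert kappa_pair(A, B, universe10) == pytest.approx(-1.0, abs=1e-12)

    def test_symmetric(self, universe100, rng):
        for _ in range(20):
            A = set(rng.choice(universe100.genes, 10, replace=False))
            B = set(rng.choice(universe100.genes, 15, replace=False))
            assert kappa_pair(A, B, universe100) == pytest.approx(
                kappa_pair(B, A, universe100), abs=1e-15
            )

    def test_degenerate_pe(self, universe10):
        full = set(universe10.genes)
        assert kappa_pair(full, full, universe10) == 1.0
        assert kappa_pair(set(), set(), universe10) == 1.0

    def test_not_subset_raises(self, universe10):
        with pytest.raises(ValueError):
            kappa_pair({"NOPE"}, {"g1"}, universe10)

    def test_matrix_matches_oracle(self, universe100, rng):
        terms = {f"T{i}": sorted(rng.choice(universe100.genes, int(rng.integers(3, 20)),
                                            replace=False).tolist()) for i in range(25)}
        table = pd.DataFrame({"term": list(terms), "source": "x"})
        dm = build_kappa_distance_matrix([table], terms, universe100)
        for i, j in itertools.combinations(range(len(dm.labels)), 2):
            expect = kappa_oracle(terms[dm.labels[i]], terms[dm.labels[j]], universe100)
            assert dm.kappa[i, j] == pytest.approx(expect, abs=1e-12)

    def test_matrix_symmetric_zero_diag(self, universe100, rng):
        terms = {f"T{i}": sorted(rng.choice(universe100.genes, 8, replace=False).tolist())
                 for i in range(6)}
        dm = build_kappa_distance_matrix(
            [pd.DataFrame({"term": list(terms), "source": "x"})], terms, universe100
        )
        assert np.allclose(dm.distance, dm.distance.T, atol=1e-12)
        assert np.allclose(np.diag(dm.distance), 0.0)
        assert np.allclose(np.diag(dm.kappa), 1.0)

    def test_identical_terms_zero_distance(self, universe10):
        genes = ["g1", "g2", "g3"]
        terms = {"A": genes, "B": genes, "C": genes}
        dm = build_kappa_distance_matrix(
            [pd.DataFrame({"term": list(terms), "source": "x"})], terms, universe10
        )
        assert np.allclose(dm.distance, 0.0, atol=1e-12)

    def test_too_few_terms(self, universe10):
        with pytest.raises(ValueError):
            build_kappa_distance_matrix(
                [pd.DataFrame({"term": ["A", "B"], "source": "x"})],
                {"A": ["g1"], "B": ["g2"]},
                universe10,
            )

    def test_duplicates_across_sources_collapsed(self, universe10):
        terms = {"A": ["g1", "g2"], "B": ["g3", "g4"], "C": ["g5", "g6"]}
        t1 = pd.DataFrame({"term": ["A", "B", "C"], "source": "s1"})
        t2 = pd.DataFrame({"term": ["A", "C"], "source": "s2"})
        dm = build_kappa_distance_matrix([t1, t2], terms, universe10)
        assert dm.labels == ["A", "B", "C"]

    def test_block_design_within_lt_between(self):
        cfg = fm.SimulationConfig(seed=7)
        uni, terms, blocks = fm.gen_universe_and_terms(cfg)
        table = pd.DataFrame({"term": list(terms), "source": "x"})
        dm = build_kappa_distance_matrix([table], terms, uni)
        lab_blocks = np.array([blocks[t] for t in dm.labels])
        same = lab_blocks[:, None] == lab_blocks[None, :]
        off = ~np.eye(len(dm.labels), dtype=bool)
        assert dm.distance[same & off].mean() < dm.distance[~same].mean()


# ---------------------------------------------------------------------------
# neighbor joining

def random_binary_tree(n_leaves: int, rng: np.random.Generator) -> nx.Graph:
    g = nx.Graph()
    active = []
    for i in range(n_leaves):
        g.add_node(f"L{i}", label=f"L{i}")
        active.append(f"L{i}")
    nid = 0
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[j], active[i]
        u = f"I{nid}"
        nid += 1
        g.add_node(u)
        g.add_edge(a, u, length=float(rng.uniform(0.5, 2.0)))
        g.add_edge(b, u, length=float(rng.uniform(0.5, 2.0)))
        active = [x for k, x in enumerate(active) if k not in (i, j)] + [u]
    g.add_edge(active[0], active[1], length=float(rng.uniform(0.5, 2.0)))
    return g


def tree_to_dm(g: nx.Graph) -> KappaDistanceMatrix:
    leaves = sorted(n for n, d in g.degree() if d == 1)
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    n = len(leaves)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = dist[leaves[i]][leaves[j]]
    return KappaDistanceMatrix(labels=leaves, kappa=1.0 - D)


def four_leaf_ls_topology(D: np.ndarray) -> frozenset:
    """Brute-force oracle: best of the 3 unrooted 4-leaf topologies by
    least-squares branch-length fit; returns the winning split as a pair set.
    """
    pairs = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
    best, best_res = None, np.inf
    idx = list(itertools.combinations(range(4), 2))
    y = np.array([D[i, j] for i, j in idx])
    for (a, b), (c, d) in pairs:
        # branch order: leaf a, leaf b, leaf c, leaf d, internal
        rows = []
        for i, j in idx:
            r = [0.0] * 5
            r[i] += 1
            r[j] += 1
            same_side = {i, j} in ({a, b}, {c, d})
            if not same_side:
                r[4] = 1.0
            rows.append(r)
        A = np.array(rows)
        sol, *_ = np.linalg.lstsq(A, y, rcond=None)
        res = float(((A @ sol - y) ** 2).sum())
        if res < best_res:
            best_res, best = res, frozenset({frozenset({a, b}), frozenset({c, d})})
    return best


def tree_splits(tree) -> set[frozenset]:
    g = tree.graph
    leaves = {n for n, d in g.degree() if d == 1}
    splits = set()
    for u, v in g.edges():
        h = g.copy()
        h.remove_edge(u, v)
        side = frozenset(g.nodes[n]["label"] for n in nx.node_connected_component(h, u) & leaves)
        if 1 < len(side) < len(leaves) - 1:
            splits.add(frozenset({side, frozenset(
                g.nodes[n]["label"] for n in leaves) - side}))
    return splits


class TestNJ:
    def test_four_leaf_derived_topology(self):
        D = np.array([[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float)
        dm = KappaDistanceMatrix(labels=["A", "B", "C", "D"], kappa=1 - D)
        tree = nj_tree(dm)
        splits = tree_splits(tree)
        assert frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})}) in splits
        # brute-force oracle agrees
        oracle = four_leaf_ls_topology(D)
        assert oracle == frozenset({frozenset({0, 1}), frozenset({2, 3})})

    def test_three_leaf_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        dm = KappaDistanceMatrix(labels=["A", "B", "C"], kappa=1 - D)
        tree = nj_tree(dm)
        got = tree_leaf_distances(tree)
        for i, a in enumerate("ABC"):
            for j, b in enumerate("ABC"):
                assert got.loc[a, b] == pytest.approx(D[i, j], abs=1e-12)

    def test_additive_recovery_five_leaves(self, rng):
        for _ in range(10):
            g = random_binary_tree(5, rng)
            dm = tree_to_dm(g)
            tree = nj_tree(dm)
            got = tree_leaf_distances(tree)
            want = pd.DataFrame(dm.distance, index=dm.labels, columns=dm.labels)
            assert np.allclose(got.loc[dm.labels, dm.labels].to_numpy(),
                               want.to_numpy(), atol=1e-9)

    def test_negative_branch_clamped(self):
        # non-additive matrix known to produce a negative NJ estimate
        D = np.array(
            [[0, 1, 6, 6], [1, 0, 6, 6], [6, 6, 0, 10], [6, 6, 10, 0]], float
        )
        dm = KappaDistanceMatrix(labels=["A", "B", "C", "D"], kappa=1 - D)
        tree = nj_tree(dm)
        for _, _, data in tree.graph.edges(data=True):
            assert data["length"] >= 0.0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            nj_tree(KappaDistanceMatrix(labels=["A", "B"], kappa=np.eye(2)))

    def test_newick_parses_with_dendropy(self, rng):
        import dendropy

        g = random_binary_tree(6, rng)
        tree = nj_tree(tree_to_dm(g))
        dt = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert {leaf.taxon.label for leaf in dt.leaf_node_iter()} == set(tree.leaves)

    def test_determinism(self, rng):
        g = random_binary_tree(6, rng)
        dm = tree_to_dm(g)
        assert nj_tree(dm).newick() == nj_tree(dm).newick()


class TestCutTree:
    def _toy_tree(self):
        D = np.array([[0, 2, 9, 9], [2, 0, 9, 9], [9, 9, 0, 2], [9, 9, 2, 0]], float)
        return nj_tree(KappaDistanceMatrix(labels=["A", "B", "C", "D"], kappa=1 - D))

    def test_k1_single_module(self):
        p = cut_tree(self._toy_tree(), 1)
        assert p.n_modules == 1
        assert sorted(p.modules[1]) == ["A", "B", "C", "D"]

    def test_k_equals_leaves_singletons(self):
        # NJ of 3 leaves is a star; K=3 must fall back to leaf branches
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_tree(KappaDistanceMatrix(labels=["A", "B", "C"], kappa=1 - D))
        p = cut_tree(tree, 3)
        assert p.n_modules == 3
        assert all(len(m) == 1 for m in p.modules.values())

    def test_partition_is_partition(self):
        p = cut_tree(self._toy_tree(), 2)
        all_terms = [t for m in p.modules.values() for t in m]
        assert sorted(all_terms) == ["A", "B", "C", "D"]
        assert len(set(all_terms)) == len(all_terms)
        assert p.modules == {1: ["A", "B"], 2: ["C", "D"]}

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            cut_tree(self._toy_tree(), 0)
        with pytest.raises(ValueError):
            cut_tree(self._toy_tree(), 5)

    def test_numbering_size_desc_then_lexicographic(self):
        D = np.full((5, 5), 8.0)
        np.fill_diagonal(D, 0.0)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            D[i, j] = D[j, i] = 1.0
        D[3, 4] = D[4, 3] = 1.0
        tree = nj_tree(KappaDistanceMatrix(labels=["a", "b", "c", "y", "z"], kappa=1 - D))
        p = cut_tree(tree, 2)
        assert p.modules[1] == ["a", "b", "c"]
        assert p.modules[2] == ["y", "z"]


class TestSummaries:
    def test_source_covering_all_terms(self, universe10):
        terms = {"A": ["g1", "g2"], "B": ["g3", "g4"], "C": ["g5", "g6"]}
        tab = pd.DataFrame({"term": list(terms), "source": "S"})
        dm = build_kappa_distance_matrix([tab], terms, universe10)
        p = cut_tree(nj_tree(dm), 1)
        src = OmicsGeneSet("S", ["g1", "g2", "g3", "g4", "g5", "g6"])
        summary = summarize_modules(p, [src], terms, [tab])
        assert summary[1]["source_counts"]["S"] == 3

    def test_empty_intersection(self, universe10):
        terms = {"A": ["g1"], "B": ["g2"], "C": ["g3"]}
        tab = pd.DataFrame({"term": list(terms), "source": "S"})
        dm = build_kappa_distance_matrix([tab], terms, universe10)
        p = cut_tree(nj_tree(dm), 1)
        other = OmicsGeneSet("X", ["g9"])
        summary = summarize_modules(p, [other], terms, [])
        assert summary[1]["source_counts"]["X"] == 0
        assert summary[1]["source_genes"]["X"] == []

    def test_gene_ranking_by_logfc(self, universe10):
        terms = {"A": ["g1", "g2", "g3"], "B": ["g1", "g2"], "C": ["g4"]}
        tab = pd.DataFrame({"term": list(terms), "source": "S"})
        dm = build_kappa_distance_matrix([tab], terms, universe10)
        p = cut_tree(nj_tree(dm), 1)
        src = OmicsGeneSet("S", ["g1", "g2", "g3"], {"g1": 0.5, "g2": 3.0, "g3": 1.0})
        summary = summarize_modules(p, [src], terms, [tab])
        assert summary[1]["source_genes"]["S"] == ["g2", "g3", "g1"]

    def test_planted_cnv_block_plurality(self):
        cfg = fm.SimulationConfig(seed=7)
        uni, terms, blocks = fm.gen_universe_and_terms(cfg)
        sources = fm.gen_omics_gene_sets(uni, terms, blocks, cfg)
        tables = [fm.enrich_terms(s, terms, uni) for s in sources]
        dm = build_kappa_distance_matrix(tables, terms, uni)
        p = cut_tree(nj_tree(dm), 6)
        summary = summarize_modules(p, sources, terms, tables)
        # find the module recovering block 6 and check CNV is its plurality source
        for mid, info in summary.items():
            member_blocks = [blocks[t] for t in info["terms"]]
            if max(set(member_blocks), key=member_blocks.count) == 6:
                counts = info["source_counts"]
                assert max(counts, key=counts.get) == "CNV"
                break
        else:
            pytest.fail("no module recovered block 6")
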