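"""Kappa-agreement clustering of enriched terms into function modules.

Enriched terms from all omics sources are pooled, pairwise Cohen's kappa is
computed between their gene-membership vectors over the universe, the
distance 1 - kappa feeds bottom-up neighbor joining, and the resulting
unrooted tree is cut into K modules by removing the longest internal
branches.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import GeneUniverse, OmicsGeneSet


# ---------------------------------------------------------------------------
# kappa

def kappa_pair(term_a, term_b, universe: GeneUniverse) -> float:
    """Cohen's kappa between two terms' binary gene-membership vectors.

    Degenerate case pe = 1 (both sets empty or both equal to the universe):
    returns 1 if the sets are identical, else 0.
    """
    A, B = set(term_a), set(term_b)
    uni = universe.as_set()
    if not A <= uni or not B <= uni:
        raise ValueError("term gene sets must be subsets of the universe")
    t = len(universe)
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = t - a - b - c
    po = (a + d) / t
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / t**2
    if pe >= 1.0:
        return 1.0 if A == B else 0.0
    return (po - pe) / (1 - pe)


@dataclass
class KappaDistanceMatrix:
    """Symmetric term x term kappa agreement and its 1 - kappa distance."""

    labels: list[str]
    kappa: np.ndarray
    distance: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        k = np.asarray(self.kappa, dtype=float)
        if k.shape != (len(self.labels), len(self.labels)):
            raise ValueError("kappa matrix shape does not match labels")
        if not np.allclose(k, k.T, atol=1e-12):
            raise ValueError("kappa matrix must be symmetric")
        self.kappa = (k + k.T) / 2.0
        np.fill_diagonal(self.kappa, 1.0)
        d = 1.0 - self.kappa
        np.fill_diagonal(d, 0.0)
        self.distance = d


def build_kappa_distance_matrix(
    tables: list[pd.DataFrame],
    terms: dict[str, list[str]],
    universe: GeneUniverse,
) -> KappaDistanceMatrix:
    """Pool enriched term ids from all tables and compute the kappa matrix.

    Duplicated terms (enriched in several sources) enter the matrix once.
    """
    pooled = sorted({t for tab in tables for t in tab["term"]})
    if len(pooled) < 3:
        raise ValueError(f"need >= 3 distinct enriched terms, got {len(pooled)}")
    uni_index = {g: i for i, g in enumerate(universe.genes)}
    G = len(universe)
    M = np.zeros((len(pooled), G), dtype=np.int64)
    for i, term_id in enumerate(pooled):
        for g in terms[term_id]:
            if g in uni_index:
                M[i, uni_index[g]] = 1

    a = M @ M.T
    s = M.sum(axis=1)
    b = s[:, None] - a
    c = s[None, :] - a
    d = G - a - b - c
    po = (a + d) / G
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / float(G) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (po - pe) / (1.0 - pe)
    degenerate = pe >= 1.0
    if degenerate.any():
        identical = (s[:, None] == a) & (s[None, :] == a)
        kappa[degenerate] = np.where(identical[degenerate], 1.0, 0.0)
    return KappaDistanceMatrix(labels=pooled, kappa=kappa)


# ---------------------------------------------------------------------------
# neighbor joining

@dataclass
class NJTree:
    """Unrooted binary tree from neighbor joining.

    graph: undirected tree; leaf nodes carry a ``label`` attribute, edges a
    ``length`` attribute (>= 0).
    """

    graph: nx.Graph
    leaves: list[str]

    def leaf_nodes(self) -> list:
        return [n for n, deg in self.graph.degree() if deg == 1]

    def newick(self) -> str:
        g = self.graph
        internal = [n for n, deg in g.degree() if deg > 1]
        root = max(internal) if internal else next(iter(g.nodes))

        def fmt(x: float) -> str:
            return format(float(x), ".10g")

        def rec(node, parent) -> str:
            children = [v for v in sorted(g.neighbors(node), key=_node_sort_key(g)) if v != parent]
            if not children:
                return f"{g.nodes[node]['label']}:{fmt(g.edges[node, parent]['length'])}"
            inner = ",".join(rec(ch, node) for ch in children)
            if parent is None:
                return f"({inner});"
            return f"({inner}):{fmt(g.edges[node, parent]['length'])}"

        return rec(root, None)


def _node_sort_key(g: nx.Graph):
    def key(n):
        lab = g.nodes[n].get("label")
        return (0, lab) if lab is not None else (1, n)

    return key


def nj_tree(dm: KappaDistanceMatrix) -> NJTree:
    """Saitou-Nei neighbor joining on the 1 - kappa distance matrix.

    Q(i,j) = (r-2) d(i,j) - sum_m d(i,m) - sum_m d(j,m); the minimal-Q pair is
    joined each round. Branch lengths follow the standard formulas; negative
    estimates are clamped to 0 with the deficit moved to the sibling branch.
    Exact on additive inputs.
    """
    D0 = np.asarray(dm.distance, dtype=float)
    n = D0.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 labels")
    if not np.allclose(D0, D0.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if (D0 < -1e-12).any():
        raise ValueError("distance matrix must be non-negative")

    g = nx.Graph()
    for i, lab in enumerate(dm.labels):
        g.add_node(i, label=lab)

    active = list(range(n))
    D = {i: {j: float(D0[i, j]) for j in active if j != i} for i in active}
    next_id = n

    while len(active) > 2:
        r = len(active)
        sums = {i: sum(D[i][j] for j in active if j != i) for i in active}
        best = None
        best_q = np.inf
        for ii in range(r):
            i = active[ii]
            for jj in range(ii + 1, r):
                j = active[jj]
                q = (r - 2) * D[i][j] - sums[i] - sums[j]
                if q < best_q - 1e-15 or (abs(q - best_q) <= 1e-15 and best is not None and (i, j) < best):
                    best_q = q
                    best = (i, j)
        i, j = best
        dij = D[i][j]
        li = 0.5 * dij + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        u = next_id
        next_id += 1
        g.add_node(u)
        g.add_edge(i, u, length=li)
        g.add_edge(j, u, length=lj)
        D[u] = {}
        for m in active:
            if m in (i, j):
                continue
            dum = 0.5 * (D[i][m] + D[j][m] - dij)
            dum = max(dum, 0.0)
            D[u][m] = dum
            D[m][u] = dum
            del D[m][i], D[m][j]
        del D[i], D[j]
        active = [m for m in active if m not in (i, j)] + [u]

    i, j = active
    g.add_edge(i, j, length=max(D[i][j], 0.0))
    return NJTree(graph=g, leaves=list(dm.labels))


def tree_leaf_distances(tree: NJTree) -> pd.DataFrame:
    """Pairwise leaf path-length distances implied by the tree."""
    g = tree.graph
    leaves = {n: g.nodes[n]["label"] for n, deg in g.degree() if deg == 1}
    labels = sorted(leaves.values())
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    nodes = {lab: n for n, lab in leaves.items()}
    for a in labels:
        for b in labels:
            if a != b:
                out.loc[a, b] = lengths[nodes[a]][nodes[b]]
    return out


# ---------------------------------------------------------------------------
# tree cutting

@dataclass
class ModulePartition:
    """Assignment of enriched terms to modules 1..K."""

    term_to_module: dict[str, int]
    modules: dict[int, list[str]]

    def __post_init__(self) -> None:
        for mid, members in self.modules.items():
            if not members:
                raise ValueError(f"module {mid} is empty")

    @property
    def n_modules(self) -> int:
        return len(self.modules)


def cut_tree(tree: NJTree, k: int) -> ModulePartition:
    """Cut the NJ tree into K modules by removing the K-1 longest branches.

    Internal branches are preferred over leaf branches; ties are broken by a
    canonical edge ordering. An edge whose removal would strand a leaf-less
    component is skipped. Modules are numbered by size descending, ties by
    the lexicographically smallest member term.
    """
    g = tree.graph
    leaves = {n for n, deg in g.degree() if deg == 1}
    n_leaves = len(leaves)
    if not (1 <= k <= n_leaves):
        raise ValueError(f"K={k} out of range [1, {n_leaves}]")

    def edge_key(e):
        u, v = e
        internal = int(u in leaves) + int(v in leaves)  # 0 = internal edge
        length = g.edges[u, v]["length"]
        labels = sorted(str(g.nodes[x].get("label", f"~{x:09d}")) for x in (u, v))
        return (internal, -length, labels[0], labels[1])

    candidates = sorted(g.edges(), key=edge_key)
    work = g.copy()
    removed = 0
    for u, v in candidates:
        if removed == k - 1:
            break
        work.remove_edge(u, v)
        comp_u = nx.node_connected_component(work, u)
        comp_v = nx.node_connected_component(work, v)
        if not (comp_u & leaves) or not (comp_v & leaves):
            work.add_edge(u, v, **g.edges[u, v])
            continue
        removed += 1
    if removed < k - 1:
        raise ValueError(f"could not cut tree into {k} leaf-bearing components")

    blocks = []
    for comp in nx.connected_components(work):
        members = sorted(g.nodes[n]["label"] for n in comp & leaves)
        if members:
            blocks.append(members)
    blocks.sort(key=lambda m: (-len(m), m[0]))
    modules = {i + 1: members for i, members in enumerate(blocks)}
    term_to_module = {t: mid for mid, members in modules.items() for t in members}
    return ModulePartition(term_to_module=term_to_module, modules=modules)


# ---------------------------------------------------------------------------
# module summaries

def summarize_modules(
    partition: ModulePartition,
    sources: list[OmicsGeneSet],
    terms: dict[str, list[str]],
    tables: list[pd.DataFrame] | None = None,
) -> dict[int, dict]:
    """Per-module source contributions and logFC-ranked gene lists.

    Source term counts come from the enrichment tables when given (a term
    counts for a source iff that source's table retained it); otherwise a
    term counts for a source iff it shares >= 1 gene with the source set.
    Gene lists are the union of member-term genes intersected with each
    source, ordered by that source's logFC descending (ties by gene id).
    """
    term_sources: dict[str, set[str]] = {t: set() for t in partition.term_to_module}
    if tables is not None:
        for tab in tables:
            for _, row in tab.iterrows():
                if row["term"] in term_sources:
                    term_sources[row["term"]].add(row["source"])
    else:
        for t in term_sources:
            tgenes = set(terms[t])
            for src in sources:
                if tgenes & src.as_set():
                    term_sources[t].add(src.name)

    out: dict[int, dict] = {}
    for mid, members in partition.modules.items():
        union_genes: set[str] = set()
        for t in members:
            union_genes |= set(terms[t])
        source_counts = {
            src.name: sum(1 for t in members if src.name in term_sources[t]) for src in sources
        }
        per_source_genes = {}
        best_logfc: dict[str, float] = {}
        for src in sources:
            inter = union_genes & src.as_set()
            ranked = sorted(inter, key=lambda gg: (-src.logfc.get(gg, 0.0), gg))
            per_source_genes[src.name] = ranked
            for gg in inter:
                fc = abs(src.logfc.get(gg, 0.0))
                if fc >= best_logfc.get(gg, -1.0):
                    best_logfc[gg] = fc
        ranked_union = sorted(union_genes, key=lambda gg: (-best_logfc.get(gg, 0.0), gg))
        out[mid] = {
            "terms": list(members),
            "source_counts": source_counts,
            "genes": ranked_union,
            "gene_best_abs_logfc": best_logfc,
            "source_genes": per_source_genes,
        }
    return out
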