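"""Interactome integration of candidate gene lists.

The three genomic feature lists (differentially expressed, alternatively
spliced, and eSNV-bearing genes) are merged into one candidate list and
projected onto a functional-interaction edge list.  Only candidate-to-
candidate edges are kept — linker genes (interactors absent from the
candidate list) are excluded so the model measures direct connectivity.
Integration is quantified against a null of equally sized random gene
draws; modularity-based clustering partitions the network into modules, and
pathway enrichment follows the hypergeometric 2x2 construction: out of G
candidate genes, N were network-incorporated; a pathway of P genes with m
of them satisfying the differential-expression criterion gives the table
[[m, N-m], [P-m, G-N-P+m]] tested one-sided for enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression import dtk_pairwise


@dataclass
class FeatureSet:
    de_genes: set[str]
    as_genes: set[str]
    snv_genes: set[str]

    def __post_init__(self):
        self.de_genes = {g.upper() for g in self.de_genes}
        self.as_genes = {g.upper() for g in self.as_genes}
        self.snv_genes = {g.upper() for g in self.snv_genes}

    @property
    def union(self) -> set[str]:
        return self.de_genes | self.as_genes | self.snv_genes

    def venn_counts(self) -> dict[str, int]:
        """Sizes of the 7 exclusive Venn regions (keys like 'de', 'de_as',
        'de_as_snv')."""
        d, a, s = self.de_genes, self.as_genes, self.snv_genes
        return {
            "de": len(d - a - s),
            "as": len(a - d - s),
            "snv": len(s - d - a),
            "de_as": len((d & a) - s),
            "de_snv": len((d & s) - a),
            "as_snv": len((a & s) - d),
            "de_as_snv": len(d & a & s),
        }


def assemble_candidate_genes(
    de_genes: set[str], as_genes: set[str], snv_genes: set[str]
) -> FeatureSet:
    """Harmonize (upper-case) and merge the three feature lists."""
    fs = FeatureSet(set(de_genes), set(as_genes), set(snv_genes))
    if not fs.union:
        raise ValueError("empty candidate list: all three feature sets are empty")
    return fs


def read_edge_list(path) -> nx.Graph:
    """Undirected simple graph from a 2+-column TSV edge list; symbols
    upper-cased, self-loops dropped, duplicates collapsed."""
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            a, b = line.rstrip("\n").split("\t")[:2]
            a, b = a.upper(), b.upper()
            if a != b:
                g.add_edge(a, b)
    return g


def induced_network(candidates: set[str], interactome: nx.Graph) -> nx.Graph:
    """Subgraph on candidate-candidate edges only, isolates dropped.

    Linker genes never enter; candidates with no edge to another candidate
    are removed, so every remaining node has degree >= 1.
    """
    candidates = {g.upper() for g in candidates}
    sub = interactome.subgraph(candidates).copy()
    sub.remove_nodes_from(list(nx.isolates(sub)))
    return sub


def network_stats(model: nx.Graph) -> pd.DataFrame:
    """Per-node degree and neighborhood connectivity (mean neighbor degree),
    with attrs ``n_degree_ge5`` / ``n_degree_ge10`` on the frame."""
    rows = []
    for node in model.nodes:
        deg = model.degree(node)
        nbr = [model.degree(v) for v in model.neighbors(node)]
        rows.append(
            {
                "gene": node,
                "degree": deg,
                "neighborhood_connectivity": float(np.mean(nbr)) if nbr else 0.0,
            }
        )
    table = pd.DataFrame(rows, columns=["gene", "degree", "neighborhood_connectivity"])
    table.attrs["n_degree_ge5"] = int((table["degree"] >= 5).sum()) if len(table) else 0
    table.attrs["n_degree_ge10"] = int((table["degree"] >= 10).sum()) if len(table) else 0
    return table


@dataclass
class NullDistribution:
    n_draws: int
    nodes: np.ndarray
    edges: np.ndarray
    mean_nodes: float = field(init=False)
    sd_nodes: float = field(init=False)
    mean_edges: float = field(init=False)
    sd_edges: float = field(init=False)

    def __post_init__(self):
        self.mean_nodes = float(np.mean(self.nodes))
        self.mean_edges = float(np.mean(self.edges))
        # sample sd (n-1), matching how a small simulation batch is summarized
        self.sd_nodes = float(np.std(self.nodes, ddof=1)) if self.n_draws > 1 else 0.0
        self.sd_edges = float(np.std(self.edges, ddof=1)) if self.n_draws > 1 else 0.0

    def z_nodes(self, observed: float) -> float:
        return z_score(observed, self.mean_nodes, self.sd_nodes)

    def z_edges(self, observed: float) -> float:
        return z_score(observed, self.mean_edges, self.sd_edges)


def z_score(observed: float, mean: float, sd: float) -> float:
    """(observed - mean)/sd; with sd = 0 the z is +/-inf by sign (0 when
    the observation equals the degenerate mean)."""
    if sd > 0:
        return (observed - mean) / sd
    if observed == mean:
        return 0.0
    return float(np.inf) if observed > mean else float(-np.inf)


def random_network_null(
    universe: list[str],
    draw_size: int,
    interactome: nx.Graph,
    n_draws: int = 20,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> NullDistribution:
    """Induced-subgraph sizes for random candidate draws.

    Each draw samples ``draw_size`` genes uniformly without replacement
    from ``universe`` and records the induced network's node and edge
    counts.  ``exhaustive=True`` enumerates every subset instead (tiny
    universes only) and reports population statistics over all subsets.
    """
    universe = sorted({g.upper() for g in universe})
    if draw_size > len(universe):
        raise ValueError("draw_size exceeds universe size")
    if exhaustive:
        from itertools import combinations

        nodes, edges = [], []
        for subset in combinations(universe, draw_size):
            m = induced_network(set(subset), interactome)
            nodes.append(m.number_of_nodes())
            edges.append(m.number_of_edges())
        return NullDistribution(len(nodes), np.array(nodes), np.array(edges))
    rng = np.random.default_rng(seed)
    nodes, edges = [], []
    for _ in range(n_draws):
        draw = rng.choice(universe, size=draw_size, replace=False)
        m = induced_network(set(draw), interactome)
        nodes.append(m.number_of_nodes())
        edges.append(m.number_of_edges())
    return NullDistribution(n_draws, np.array(nodes), np.array(edges))


def detect_modules(model: nx.Graph, seed: int = 0, resolution: float = 1.0) -> dict[str, int]:
    """Modularity-maximizing (Louvain) community detection; deterministic
    given the seed.  Returns gene -> module index, modules numbered by
    decreasing size."""
    if model.number_of_nodes() == 0:
        return {}
    communities = nx.community.louvain_communities(model, seed=seed, resolution=resolution)
    communities = sorted(communities, key=lambda c: (-len(c), sorted(c)))
    return {g: i for i, comm in enumerate(communities) for g in comm}


@dataclass(frozen=True)
class EnrichmentInput:
    """2x2 contingency inputs: G candidate-universe size, N network-
    incorporated genes, P pathway size, m pathway genes meeting the
    criterion."""

    G: int
    N: int
    P: int
    m: int

    def table(self) -> list[list[int]]:
        cells = [[self.m, self.N - self.m], [self.P - self.m, self.G - self.N - self.P + self.m]]
        for row in cells:
            for c in row:
                if c < 0:
                    raise ValueError(
                        f"negative contingency cell from G={self.G}, N={self.N}, "
                        f"P={self.P}, m={self.m}"
                    )
        return cells


def fisher_enrichment(inp: EnrichmentInput) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test on the pathway table.

    Equals the hypergeometric upper tail P(X >= m) for a population of G
    with P successes and N draws.  Returns (odds_ratio, p); the odds ratio
    is the cross-product ratio (inf when a denominator cell is 0).
    """
    table = inp.table()
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(odds), float(p)


def validation_de_flags(
    counts: pd.DataFrame,
    groups: pd.Series,
    target_group: str,
    alpha: float = 0.05,
    normalize_log: bool = True,
) -> pd.DataFrame:
    """Per-gene pairwise DTK flags in a validation cohort.

    For each gene, every target-vs-other comparison is tested with DTK and
    flagged at ``alpha``; genes missing from the matrix (all-NaN) are left
    unflagged.  The per-comparison flag columns are the ``m`` inputs for
    :func:`fisher_enrichment` per pathway and comparison.
    """
    groups = groups.reindex(counts.columns)
    others = [g for g in pd.unique(groups.dropna()) if g != target_group]
    vals = np.log2(counts + 1) if normalize_log else counts
    rows = {}
    for gene in vals.index:
        row = vals.loc[gene]
        if row.isna().any():
            rows[gene] = {f"flag_vs_{g}": False for g in others}
            continue
        res = dtk_pairwise(
            {g: row[groups == g].to_numpy() for g in pd.unique(groups.dropna())},
            alpha=alpha,
            compute_ci=False,
        )
        rows[gene] = {
            f"flag_vs_{g}": res.p_value(target_group, g) < alpha for g in others
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    return out


def pathway_enrichment_table(
    pathways: dict[str, set[str]],
    flags: pd.DataFrame,
    G: int,
    N: int,
    network_genes: set[str],
) -> pd.DataFrame:
    """Per-pathway, per-comparison enrichment mirroring the published
    layout (pathway, P, m, odds ratio, p for each flag column)."""
    network_genes = {g.upper() for g in network_genes}
    rows = []
    for name, members in pathways.items():
        members = {g.upper() for g in members} & network_genes
        P = len(members)
        rec: dict[str, object] = {"pathway": name, "P": P}
        for col in flags.columns:
            flagged = {g for g in members if g in flags.index and bool(flags.loc[g, col])}
            m = len(flagged)
            if P == 0:
                rec[f"m_{col}"], rec[f"p_{col}"] = 0, 1.0
                continue
            odds, p = fisher_enrichment(EnrichmentInput(G=G, N=N, P=P, m=m))
            rec[f"m_{col}"] = m
            rec[f"odds_{col}"] = odds
            rec[f"p_{col}"] = p
        rows.append(rec)
    return pd.DataFrame(rows)
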