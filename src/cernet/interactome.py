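"""Bipartite miRNA-mRNA interactome: reading, filtering and graph statistics.

Reads CLASH-style tab-separated interaction tables (miRNA id, transcript id,
gene id, read count, binding free energy in kcal/mol), aggregates transcript
records to genes, applies confidence filters, builds the bipartite graph and
its two unipartite projections, and computes the statistics used to
characterize the interactome: shortest-path distribution and ASPL, average
clustering, small-world coefficient against an Erdos-Renyi null ensemble,
and a power-law fit to the degree distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .kinetics import BipartiteTopology

__all__ = [
    "DIALECT_HELWAK",
    "NetworkStats",
    "read_interaction_table",
    "write_interaction_table",
    "filter_high_confidence",
    "build_bipartite",
    "to_graph",
    "project",
    "path_statistics",
    "clustering",
    "small_world_sigma",
    "degree_powerlaw_fit",
]

#: canonical column names of an in-memory interaction table
CANONICAL = ["mirna", "gene", "reads", "energy"]

#: column mapping matching the layout of the Helwak et al. supplementary table
DIALECT_HELWAK = {
    "mirna": "microRNA_name",
    "transcript": "mRNA_name",
    "gene": "gene_name",
    "reads": "experiments_count",
    "energy": "folding_energy",
}

#: plain dialect used by the synthetic generator and the bundled writers
DIALECT_PLAIN = {
    "mirna": "mirna",
    "transcript": "transcript",
    "gene": "gene",
    "reads": "reads",
    "energy": "energy",
}


def read_interaction_table(path, dialect: dict | None = None,
                           aggregate: bool = True) -> pd.DataFrame:
    """Read a tab-separated interaction table into canonical form.

    ``dialect`` maps the canonical keys (mirna, gene, reads, energy and
    optionally transcript) to the file's column names.  Transcript-level
    records of the same gene are aggregated by summing reads and keeping
    the minimum (most stable) binding free energy per miRNA-gene pair.
    """
    dialect = dict(DIALECT_PLAIN if dialect is None else dialect)
    df = pd.read_csv(path, sep="\t")
    for key in ("mirna", "gene", "reads", "energy"):
        col = dialect.get(key)
        if col is None or col not in df.columns:
            raise ValueError(f"required column for {key!r} ({col!r}) missing from table")
    out = pd.DataFrame({
        "mirna": df[dialect["mirna"]].astype(str),
        "gene": df[dialect["gene"]].astype(str),
        "reads": df[dialect["reads"]],
        "energy": df[dialect["energy"]],
    })
    for col in ("reads", "energy"):
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            raise ValueError(  # header line + 1-based data rows
                f"non-numeric {col} value at line {int(bad.idxmax()) + 2}")
        out[col] = coerced
    out["reads"] = out["reads"].astype(int)
    out["energy"] = out["energy"].astype(float)
    if (out["reads"] < 0).any():
        raise ValueError("negative read counts")
    if (out["mirna"].str.len() == 0).any() or (out["gene"].str.len() == 0).any():
        raise ValueError("empty identifiers")
    if aggregate:
        out = (out.groupby(["mirna", "gene"], as_index=False)
               .agg(reads=("reads", "sum"), energy=("energy", "min")))
    return out.sort_values(["mirna", "gene"], ignore_index=True)


def write_interaction_table(records: pd.DataFrame, path) -> None:
    """Write a canonical interaction table as TSV (round-trips with the reader)."""
    records[CANONICAL].to_csv(path, sep="\t", index=False)


def filter_high_confidence(records: pd.DataFrame,
                           energy_threshold: float = -13.4,
                           min_reads: int | None = None) -> pd.DataFrame:
    """High-confidence subset: binding free energy strictly below the
    threshold (default -13.4 kcal/mol), optionally read count > min_reads."""
    keep = records["energy"] < energy_threshold
    if min_reads is not None:
        keep &= records["reads"] > min_reads
    return records[keep].reset_index(drop=True)


def build_bipartite(records: pd.DataFrame) -> BipartiteTopology:
    """One undirected edge per distinct (miRNA, gene) pair.

    Gene ids colliding with miRNA ids are suffixed with ':g' to keep the
    two sides disjoint (never triggered by real nomenclature).
    """
    pairs = records[["mirna", "gene"]].drop_duplicates()
    mirnas = tuple(sorted(pairs["mirna"].unique()))
    mi_set = set(mirnas)
    rename = {g: (f"{g}:g" if g in mi_set else g) for g in pairs["gene"].unique()}
    genes = tuple(sorted(rename.values()))
    edges = tuple(sorted((r, rename[g]) for r, g in pairs.itertuples(index=False)))
    return BipartiteTopology(mirnas, genes, edges)


def to_graph(topology: BipartiteTopology) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(topology.mirnas, side="mirna")
    G.add_nodes_from(topology.mrnas, side="mrna")
    G.add_edges_from(topology.edges)
    return G


def project(topology: BipartiteTopology, side: str) -> nx.Graph:
    """Unipartite projection: two same-side nodes are linked if they share
    a neighbour on the other side; edge weight = number of shared neighbours."""
    if side not in ("mirna", "mrna"):
        raise ValueError(f"side must be 'mirna' or 'mrna', got {side!r}")
    keep = set(topology.mirnas if side == "mirna" else topology.mrnas)
    G = to_graph(topology)
    P = nx.Graph()
    P.add_nodes_from(sorted(keep))  # deterministic node (and edge) order
    for hub in (topology.mrnas if side == "mirna" else topology.mirnas):
        neigh = sorted(G.neighbors(hub))
        for i in range(len(neigh)):
            for j in range(i + 1, len(neigh)):
                u, v = neigh[i], neigh[j]
                if P.has_edge(u, v):
                    P[u][v]["weight"] += 1
                else:
                    P.add_edge(u, v, weight=1)
    return P


# ---------------------------------------------------------------------------
# statistics

@dataclass
class NetworkStats:
    """Summary statistics of an (unweighted) graph."""

    n_nodes: int
    n_edges: int
    aspl: float = float("nan")
    path_length_histogram: dict = field(default_factory=dict)
    cc: float = float("nan")
    sigma: float = float("nan")
    powerlaw_exponent: float = float("nan")
    powerlaw_r: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes, "n_edges": self.n_edges,
            "aspl": self.aspl, "cc": self.cc, "sigma": self.sigma,
            "powerlaw_exponent": self.powerlaw_exponent,
            "powerlaw_r": self.powerlaw_r,
            "path_length_histogram": {int(k): int(v) for k, v in
                                      sorted(self.path_length_histogram.items())},
        }


def path_statistics(graph: nx.Graph) -> tuple[float, dict]:
    """ASPL and shortest-path-length histogram on the largest component.

    ASPL is the mean over connected ordered node pairs (self-pairs
    excluded); the histogram counts unordered pairs per length.
    """
    if graph.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    comp = max(nx.connected_components(graph), key=len)
    H = graph.subgraph(comp)
    hist: dict[int, int] = {}
    total, n_pairs = 0, 0
    for node, dists in nx.all_pairs_shortest_path_length(H):
        for other, d in dists.items():
            if other == node:
                continue
            total += d
            n_pairs += 1
            if node < other:  # count unordered pairs once in the histogram
                hist[d] = hist.get(d, 0) + 1
    return total / n_pairs, hist


def clustering(graph: nx.Graph) -> float:
    """Average (unweighted) local clustering; degree-<2 nodes contribute 0."""
    return nx.average_clustering(graph)


def small_world_sigma(graph: nx.Graph, n_random: int = 100,
                      seed: int | None = None) -> tuple[float, dict]:
    """Small-world coefficient sigma = (CC/CC_rand) / (ASPL/ASPL_rand).

    The null is an ensemble of ``n_random`` Erdos-Renyi graphs with the
    same node count and edge probability p = |E|/C(|V|, 2); their CC and
    (largest-component) ASPL are averaged.  sigma > 1 flags a small-world
    graph.  Degenerate null draws (largest component < 2 nodes) are
    resampled and counted in the diagnostics.
    """
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    p = graph.number_of_edges() / (n * (n - 1) / 2)
    aspl, _ = path_statistics(graph)
    cc = clustering(graph)
    rng = np.random.default_rng(seed)
    cc_rand, aspl_rand, resampled = [], [], 0
    while len(cc_rand) < n_random:
        G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
        comp = max(nx.connected_components(G), key=len)
        if len(comp) < 2:
            resampled += 1
            continue
        cc_rand.append(clustering(G))
        aspl_rand.append(path_statistics(G)[0])
    cc_r, aspl_r = float(np.mean(cc_rand)), float(np.mean(aspl_rand))
    sigma = (cc / cc_r) / (aspl / aspl_r) if cc_r > 0 else float("inf")
    diag = {"cc": cc, "aspl": aspl, "cc_rand": cc_r, "aspl_rand": aspl_r,
            "n_random": n_random, "resampled": resampled}
    return sigma, diag


def degree_powerlaw_fit(graph_or_degrees, method: str = "loglog",
                        kmin: int = 1) -> tuple[float, float]:
    """Power-law fit to the degree distribution.

    ``method='loglog'``: least-squares fit of log frequency vs log degree
    over the positive-frequency support; returns (|slope|, |Pearson r| of
    the log-log relation).  ``method='ml'``: discrete maximum likelihood
    with the zeta-normalized model P(k) ~ k^-alpha for k >= ``kmin``
    (degrees below kmin are ignored); r is then NaN, as no regression is
    performed.
    """
    if isinstance(graph_or_degrees, nx.Graph):
        degrees = np.array([d for _, d in graph_or_degrees.degree()])
    else:
        degrees = np.asarray(graph_or_degrees)
    degrees = degrees[degrees > 0]
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) < 10:
        raise ValueError(f"need >= 10 distinct positive degrees, have {len(ks)}")
    if method == "ml":
        from scipy.optimize import minimize_scalar
        from scipy.special import zeta

        tail = degrees[degrees >= kmin]
        log_sum = np.sum(np.log(tail))

        def nll(alpha: float) -> float:
            return len(tail) * np.log(zeta(alpha, kmin)) + alpha * log_sum

        res = minimize_scalar(nll, bounds=(1.05, 8.0), method="bounded")
        return float(res.x), float("nan")
    if method != "loglog":
        raise ValueError(f"unknown method {method!r}")
    x, y = np.log(ks.astype(float)), np.log(counts.astype(float))
    slope, _ = np.polyfit(x, y, 1)
    r = float(abs(np.corrcoef(x, y)[0, 1]))
    if r < 0.3:
        raise ValueError(f"degree distribution is not power-law-like (|r| = {r:.2f})")
    return float(abs(slope)), r


def write_graph(graph: nx.Graph, path, fmt: str = "edgelist") -> None:
    """Export a (weighted) graph as edge-list TSV or GraphML."""
    if fmt == "edgelist":
        rows = sorted(tuple(sorted((str(u), str(v)))) + (data.get("weight", 1),)
                      for u, v, data in graph.edges(data=True))
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, w in rows:
                fh.write(f"{u}\t{v}\t{w}\n")
    elif fmt == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def network_stats(graph: nx.Graph, n_random: int = 100,
                  seed: int | None = None, with_sigma: bool = True) -> NetworkStats:
    """Convenience bundle of all statistics for one graph."""
    aspl, hist = path_statistics(graph)
    stats = NetworkStats(n_nodes=graph.number_of_nodes(),
                         n_edges=graph.number_of_edges(),
                         aspl=aspl, path_length_histogram=hist,
                         cc=clustering(graph))
    if with_sigma:
        stats.sigma, _ = small_world_sigma(graph, n_random=n_random, seed=seed)
    try:
        stats.powerlaw_exponent, stats.powerlaw_r = degree_powerlaw_fit(graph)
    except ValueError:
        pass
    return stats
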