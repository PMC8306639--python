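"""Permutation-calibrated Pearson co-occurrence network over OTUs.

Pipeline
--------
1. Pearson correlation ``r_ij`` between every OTU pair across samples
   (:func:`pearson_matrix`); zero-variance OTUs are flagged and excluded.
2. A permutation null: each OTU row's sample order is shuffled
   independently ``B`` times (default 100), destroying exactly the
   inter-OTU dependence being tested while preserving every marginal.
   ``p_raw = #{b : |r_b| >= |r_obs|} / B`` (:func:`permutation_pvalues`).
   The count is taken without a pseudo-count, so p = 0 is attainable —
   with B = 100 a pseudo-counted minimum of ~0.0099 would leave almost no
   edge under a Benjamini–Hochberg threshold of 0.01 over ~10^6 pairs.
   ``pseudocount=True`` switches to the conservative (count+1)/(B+1).
3. Benjamini–Hochberg adjustment over all testable pairs (:func:`bh_adjust`).
4. Edges where ``p_adj <= alpha`` (default 0.01) and ``|r| >= r_min``;
   nodes are the OTUs incident to at least one retained edge
   (:func:`build_network`).
5. Kleinberg hub scores — for an undirected graph, the principal
   eigenvector of the adjacency matrix normalized to max 1 — rank candidate
   keystone OTUs (:func:`hub_scores`); global metrics summarize topology
   (:func:`network_metrics`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .tables import OtuTable, TaxonomyMap, RhizonetError

__all__ = [
    "CorrelationResult",
    "CoocNetwork",
    "NetworkMetrics",
    "pearson_matrix",
    "permutation_pvalues",
    "bh_adjust",
    "build_network",
    "hub_scores",
    "network_metrics",
    "node_composition",
]

logger = logging.getLogger(__name__)

DEFAULT_B = 100
DEFAULT_ALPHA = 0.01
MIN_SAMPLES_WARN = 5


def pearson_matrix(table: OtuTable) -> np.ndarray:
    """Pairwise Pearson correlation between OTU rows across samples.

    Rows with zero variance get NaN in their row/column (undefined, excluded
    from downstream testing). Requires at least 3 samples.
    """
    if table.n_samples < 3:
        raise RhizonetError("Pearson correlation needs at least 3 samples")
    X = table.counts.astype(float)
    sd = X.std(axis=1)
    valid = sd > 0
    r = np.full((table.n_otus, table.n_otus), np.nan)
    if valid.sum() >= 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            sub = np.corrcoef(X[valid])
        sub = np.atleast_2d(sub)
        r[np.ix_(valid, valid)] = np.clip(sub, -1.0, 1.0)
    return r


def _row_shuffled(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each row's sample order."""
    idx = rng.random(X.shape).argsort(axis=1)
    return np.take_along_axis(X, idx, axis=1)


@dataclass
class CorrelationResult:
    """Correlation matrix with permutation and BH-adjusted p-values.

    All three matrices are symmetric with shape (n_otus, n_otus); entries
    involving zero-variance OTUs are NaN (flagged undefined). Diagonals: r=1,
    p undefined.
    """

    otu_ids: list
    r: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    n_permutations: int
    seed: int | None = None
    pseudocount: bool = False

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def testable_pairs(self) -> np.ndarray:
        """Boolean upper-triangle mask of pairs with a defined p-value."""
        iu = np.triu(np.ones_like(self.p_raw, dtype=bool), k=1)
        return iu & ~np.isnan(self.p_raw)


def permutation_pvalues(
    table: OtuTable,
    n_permutations: int = DEFAULT_B,
    seed: int | None = None,
    pseudocount: bool = False,
) -> CorrelationResult:
    """Permutation p-values for every OTU pair's Pearson correlation.

    For each of ``n_permutations`` replicates, every OTU row is shuffled
    independently across samples and the full correlation matrix recomputed;
    the p-value is the fraction of replicates whose ``|r|`` meets or exceeds
    the observed one. Deterministic given ``seed``. BH adjustment over all
    testable (finite-p) pairs is included in the result.
    """
    B = int(n_permutations)
    if B < 1:
        raise ValueError("n_permutations must be >= 1")
    if table.n_samples < MIN_SAMPLES_WARN:
        logger.warning(
            "only %d samples: Pearson co-occurrence estimates will be unstable",
            table.n_samples,
        )
    r_obs = pearson_matrix(table)
    n = table.n_otus
    X = table.counts.astype(float)
    valid = X.std(axis=1) > 0
    abs_obs = np.abs(r_obs)
    exceed = np.zeros((n, n), dtype=np.int64)
    rng = np.random.default_rng(seed)
    Xv = X[valid]
    vidx = np.flatnonzero(valid)
    with np.errstate(invalid="ignore", divide="ignore"):
        for _ in range(B):
            rb = np.corrcoef(_row_shuffled(Xv, rng))
            rb = np.atleast_2d(rb)
            exceed[np.ix_(vidx, vidx)] += (
                np.abs(rb) >= abs_obs[np.ix_(vidx, vidx)]
            )
    if pseudocount:
        p_raw = (exceed + 1.0) / (B + 1.0)
    else:
        p_raw = exceed / float(B)
    p_raw[np.isnan(r_obs)] = np.nan
    np.fill_diagonal(p_raw, np.nan)

    p_adj = np.full_like(p_raw, np.nan)
    iu = np.triu(np.ones((n, n), dtype=bool), k=1)
    mask = iu & ~np.isnan(p_raw)
    if mask.any():
        p_adj[mask] = bh_adjust(p_raw[mask])
        # mirror the adjusted upper triangle onto the lower one
        p_adj = np.where(np.isnan(p_adj) & ~np.isnan(p_adj.T), p_adj.T, p_adj)
    return CorrelationResult(
        otu_ids=list(table.otu_ids),
        r=r_obs,
        p_raw=p_raw,
        p_adj=p_adj,
        n_permutations=B,
        seed=seed,
        pseudocount=pseudocount,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CoocNetwork:
    """Undirected co-occurrence graph with build parameters.

    ``graph`` carries per-edge attributes ``r`` and ``p_adj``; nodes are the
    OTUs incident to at least one retained edge (unless built with
    ``include_isolates=True``).
    """

    graph: nx.Graph
    alpha: float
    r_min: float = 0.0
    n_permutations: int = DEFAULT_B
    seed: int | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        """Deterministically ordered edge list with r and adjusted p."""
        rows = [
            {"otu_a": min(u, v), "otu_b": max(u, v), "r": d["r"], "p_adj": d["p_adj"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["otu_a", "otu_b", "r", "p_adj"])
        return df.sort_values(["otu_a", "otu_b"]).reset_index(drop=True)

    def edge_set(self) -> set:
        return {frozenset((u, v)) for u, v in self.graph.edges()}


def build_network(
    corr: CorrelationResult,
    alpha: float = DEFAULT_ALPHA,
    r_min: float = 0.0,
    include_isolates: bool = False,
) -> CoocNetwork:
    """Threshold the adjusted p-value matrix into a co-occurrence graph.

    An edge joins OTUs i and j iff ``p_adj[i,j] <= alpha`` and
    ``|r[i,j]| >= r_min``. Isolated OTUs (no significant partner) are
    excluded from the node set unless ``include_isolates`` is set.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if r_min < 0:
        raise ValueError("r_min must be non-negative")
    g = nx.Graph()
    if include_isolates:
        g.add_nodes_from(corr.otu_ids)
    mask = corr.testable_pairs()
    sig = mask & (corr.p_adj <= alpha) & (np.abs(corr.r) >= r_min)
    for i, j in zip(*np.nonzero(sig)):
        u, v = corr.otu_ids[i], corr.otu_ids[j]
        g.add_edge(u, v, r=float(corr.r[i, j]), p_adj=float(corr.p_adj[i, j]))
    return CoocNetwork(
        graph=g,
        alpha=alpha,
        r_min=r_min,
        n_permutations=corr.n_permutations,
        seed=corr.seed,
    )


def hub_scores(net: CoocNetwork, k: int = 20) -> tuple[dict, list]:
    """Kleinberg hub scores and the top-k candidate keystone OTUs.

    For an undirected graph the hub score is the principal eigenvector of
    the adjacency matrix, normalized so the maximum score is 1. Ties in the
    top-k ranking are broken by node id (deterministic output).
    """
    if net.n_nodes == 0:
        raise RhizonetError("hub scores undefined for an empty network")
    nodes = sorted(net.graph.nodes, key=str)
    A = nx.to_numpy_array(net.graph, nodelist=nodes)
    if net.n_nodes == 1:
        scores = {nodes[0]: 1.0}
        return scores, nodes[:1]
    w, V = np.linalg.eigh(A)
    v = np.abs(V[:, -1])  # Perron eigenvector of the dominant component
    top = v.max()
    if top <= 0:  # pragma: no cover - requires an edgeless graph
        v = np.ones_like(v)
        top = 1.0
    v = v / top
    scores = {node: float(s) for node, s in zip(nodes, v)}
    # round the sort key so numerically tied scores fall through to the id
    ranked = sorted(nodes, key=lambda nd: (-round(scores[nd], 10), str(nd)))
    return scores, ranked[: int(k)]


@dataclass
class NetworkMetrics:
    """Global topology summary; NaN marks undefined (e.g. single node)."""

    n_nodes: int
    n_edges: int
    density: float
    transitivity: float
    diameter: float
    average_path_length: float
    n_components: int = 0

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "transitivity": self.transitivity,
            "diameter": self.diameter,
            "average_path_length": self.average_path_length,
            "n_components": self.n_components,
        }


def network_metrics(net: CoocNetwork) -> NetworkMetrics:
    """Density, transitivity, diameter, and average path length.

    For disconnected graphs the diameter is the largest finite shortest-path
    length and the average path length is taken over connected (reachable)
    pairs only; both conventions are logged with the result.
    """
    g = net.graph
    n = g.number_of_nodes()
    m = g.number_of_edges()
    if n == 0:
        raise RhizonetError("metrics undefined for an empty network")
    if n == 1:
        return NetworkMetrics(1, m, np.nan, 0.0, np.nan, np.nan, 1)
    density = 2.0 * m / (n * (n - 1))
    transitivity = nx.transitivity(g)
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        logger.info(
            "network has %d components; diameter/APL computed within components",
            len(comps),
        )
    diameter = 0.0
    total_dist = 0.0
    n_pairs = 0
    for comp in comps:
        sub = g.subgraph(comp)
        for src, dists in nx.all_pairs_shortest_path_length(sub):
            for dst, d in dists.items():
                if d > 0:
                    total_dist += d
                    n_pairs += 1
                    if d > diameter:
                        diameter = float(d)
    apl = total_dist / n_pairs if n_pairs else np.nan
    return NetworkMetrics(n, m, density, transitivity, diameter, apl, len(comps))


def node_composition(
    net: CoocNetwork, tax: TaxonomyMap, rank: str = "phylum"
) -> pd.Series:
    """Fraction of network nodes per taxonomic rank value (sums to 1).

    Nodes without taxonomy are tallied as ``"unclassified"``.
    """
    if net.n_nodes == 0:
        raise RhizonetError("composition undefined for an empty network")
    labels = [tax.get_rank(node, rank) for node in net.graph.nodes]
    counts = pd.Series(labels).value_counts()
    return (counts / counts.sum()).sort_values(ascending=False)
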