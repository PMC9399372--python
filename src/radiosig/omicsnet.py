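"""The 4-layer multi-omics network and hub screening.

Layers
------
mutation / cna : the reference interaction graph carrying per-gene "heat"
    (mutation frequency, absolute copy-number deviation).  Heat is spread by
    an insulated random walk with restart and pairs exchanging heat above a
    threshold become "hot" edges (HotNet2-style diffusion).
coexpression : weighted co-expression modules from the bulk matrix via the
    topological overlap measure (TOM), average-linkage clustering and module
    eigengenes.
protein : a confidence-filtered interaction edge list.

Hub rule: on the union graph, a gene is a hub when its degree, betweenness
and closeness are each strictly greater than the network-wide median.
Harmonic closeness is the default because union graphs may be disconnected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .exceptions import InsufficientDataError
from .radioscreen import ClusterEigengene

__all__ = [
    "NetworkLayer",
    "DiffusionResult",
    "CoexpressionModules",
    "HubReport",
    "diffuse_heat",
    "tom_matrix",
    "coexpression_layer",
    "union_graph",
    "hub_screen",
]

LAYER_KINDS = ("mutation", "cna", "coexpression", "protein")


@dataclass
class NetworkLayer:
    """One omics layer: an undirected weighted graph plus optional node heat."""

    kind: str
    graph: nx.Graph
    heat: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"kind must be one of {LAYER_KINDS}")
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:5]}")
        if self.heat is not None:
            self.heat = pd.Series(self.heat, dtype=float)
            if (self.heat < 0).any():
                bad = self.heat[self.heat < 0]
                raise ValueError(f"negative heats: {bad.head().to_dict()}")

    def nodes(self) -> list:
        nodes = set(self.graph.nodes)
        if self.heat is not None:
            nodes |= set(self.heat.index)
        return sorted(nodes)


@dataclass
class DiffusionResult:
    """Insulated-diffusion output: exchanged heat, hot edges, hot subnetworks."""

    exchanged: pd.DataFrame  # E[i, j] = heat of source j observed at i
    delta: float
    hot_graph: nx.Graph
    subnetworks: list  # connected hot components with >= k_min nodes

    @property
    def hot_edges(self) -> list:
        return sorted(tuple(sorted(e)) for e in self.hot_graph.edges)


def diffuse_heat(
    layer: NetworkLayer,
    restart_beta: float = 0.4,
    delta: float | None = None,
    delta_quantile: float | None = None,
    k_min: int = 3,
) -> DiffusionResult:
    """Random-walk-with-restart heat diffusion over one heated layer.

    Per connected component, with W the column-degree-normalized walk matrix
    of the (unweighted) adjacency, the insulated diffusion operator is

        F = restart_beta * (I - (1 - restart_beta) * W)^-1

    and the exchanged heat is E[i, j] = F[i, j] * h[j].  Column sums of F are
    exactly 1, so each source's heat is conserved.  An undirected edge (i, j)
    is "hot" when min(E[i, j], E[j, i]) >= delta; connected components of the
    hot graph with at least ``k_min`` nodes are reported as subnetworks.

    ``delta`` may be given directly or derived as a quantile
    (``delta_quantile``) of the off-diagonal min-exchange values; with
    restart_beta = 1 the walk never leaves its source and E is diagonal.
    """
    if not 0 < restart_beta <= 1:
        raise ValueError("restart_beta must lie in (0, 1]")
    if layer.heat is None:
        raise ValueError(f"layer {layer.kind!r} carries no heat")
    nodes = layer.nodes()
    h = layer.heat.reindex(nodes).fillna(0.0)
    n = len(nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    F = np.zeros((n, n))
    G = layer.graph
    seen = set()
    for comp in nx.connected_components(G):
        comp = sorted(comp)
        seen.update(comp)
        idx = np.array([pos[v] for v in comp])
        if len(comp) == 1:
            F[idx[0], idx[0]] = 1.0  # isolated node keeps its heat
            continue
        A = nx.to_numpy_array(G, nodelist=comp, weight=None)
        W = A / A.sum(axis=0, keepdims=True)
        Fc = restart_beta * np.linalg.inv(
            np.eye(len(comp)) - (1.0 - restart_beta) * W
        )
        F[np.ix_(idx, idx)] = Fc
    for v in nodes:  # heat-only nodes absent from the graph
        if v not in seen:
            F[pos[v], pos[v]] = 1.0
    E = F * h.to_numpy()[None, :]
    M = np.minimum(E, E.T)
    if delta is None:
        if delta_quantile is not None:
            off = M[~np.eye(n, dtype=bool)]
            delta = float(np.quantile(off, delta_quantile)) if off.size else 0.0
        else:
            delta = 0.0
    hot = nx.Graph()
    hot.add_nodes_from(nodes)
    # zero-exchange pairs (different components, zero heat) are never hot
    iu, ju = np.where(np.triu((M >= delta) & (M > 0), k=1))
    hot.add_edges_from((nodes[i], nodes[j]) for i, j in zip(iu, ju))
    subnets = [
        sorted(c) for c in nx.connected_components(hot) if len(c) >= k_min
    ]
    exchanged = pd.DataFrame(E, index=nodes, columns=nodes)
    return DiffusionResult(
        exchanged=exchanged, delta=float(delta), hot_graph=hot, subnetworks=subnets
    )


def tom_matrix(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap from a symmetric adjacency in [0, 1].

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    connectivities k_i = sum_u a_iu (self-adjacency excluded), TOM_ii = 1.
    """
    A = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    num = A @ A + A
    den = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / den
    tom = np.clip(np.nan_to_num(tom, nan=0.0), 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return tom


@dataclass
class CoexpressionModules:
    """Weighted co-expression modules, eigengenes and trait correlations."""

    power: float
    tom: pd.DataFrame
    labels: pd.Series  # gene -> module id (0 = unassigned)
    eigengenes: pd.DataFrame  # samples x modules
    trait_correlations: pd.Series | None
    dropped: list  # constant genes removed before correlation

    def module_members(self, module_id: int) -> pd.Index:
        return self.labels.index[self.labels == module_id]


def coexpression_layer(
    expr: pd.DataFrame,
    trait: pd.Series | None = None,
    power: float = 6.0,
    min_module_size: int = 30,
    cut_height: float = 0.99,
    merge_corr: float = 0.75,
    edge_quantile: float = 0.9,
) -> tuple[CoexpressionModules, NetworkLayer]:
    """Co-expression modules and the derived network layer from a bulk matrix.

    ``expr`` is genes x samples.  Adjacency is |Pearson r|^power, similarity
    is the topological overlap, genes are clustered by average linkage on
    1 - TOM and the tree is cut at ``cut_height``; clusters below
    ``min_module_size`` stay unassigned (module 0).  Modules whose eigengenes
    correlate above ``merge_corr`` are merged.  The emitted layer connects
    within-module pairs whose TOM reaches the ``edge_quantile`` quantile of
    within-module TOM values.
    """
    if expr.shape[1] < 20:
        warnings.warn(
            f"only {expr.shape[1]} samples; co-expression estimates are noisy",
            UserWarning,
            stacklevel=2,
        )
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1)
    dropped = list(expr.index[sd <= 1e-12])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant gene(s) before correlation",
            UserWarning,
            stacklevel=2,
        )
    keep = expr.index[sd > 1e-12]
    X = expr.loc[keep].to_numpy(dtype=float)
    A = np.abs(np.corrcoef(X)) ** power
    tom = tom_matrix(A)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=keep, name="module")
    sizes = labels.value_counts()
    small = sizes.index[sizes < min_module_size]
    labels[labels.isin(small)] = 0
    labels = _relabel(labels)
    eigengenes = _module_eigengenes(expr.loc[keep], labels)
    labels, eigengenes = _merge_modules(
        expr.loc[keep], labels, eigengenes, merge_corr
    )
    trait_corr = None
    if trait is not None and not eigengenes.empty:
        t = pd.Series(trait).reindex(eigengenes.index)
        trait_corr = eigengenes.apply(lambda col: col.corr(t))
        trait_corr.name = "trait_correlation"
    tom_df = pd.DataFrame(tom, index=keep, columns=keep)
    G = nx.Graph()
    G.add_nodes_from(expr.index)
    for mod in sorted(set(labels) - {0}):
        members = list(labels.index[labels == mod])
        sub = tom_df.loc[members, members].to_numpy()
        vals = sub[np.triu_indices(len(members), k=1)]
        if vals.size == 0:
            continue
        thr = np.quantile(vals, edge_quantile)
        iu, ju = np.where(np.triu(sub >= thr, k=1))
        G.add_edges_from(
            (members[i], members[j], {"weight": float(sub[i, j])})
            for i, j in zip(iu, ju)
        )
    modules = CoexpressionModules(
        power=power,
        tom=tom_df,
        labels=labels,
        eigengenes=eigengenes,
        trait_correlations=trait_corr,
        dropped=dropped,
    )
    return modules, NetworkLayer(kind="coexpression", graph=G)


def _relabel(labels: pd.Series) -> pd.Series:
    """Renumber modules 1..K by decreasing size, keeping 0 for unassigned."""
    sizes = labels[labels != 0].value_counts()
    mapping = {old: new for new, old in enumerate(sizes.index, start=1)}
    mapping[0] = 0
    return labels.map(mapping)


def _module_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    cols = {}
    for mod in sorted(set(labels) - {0}):
        members = labels.index[labels == mod]
        eg = ClusterEigengene()
        scores = eg.fit_transform(expr.loc[members].T.to_numpy())[:, 0]
        cols[mod] = scores
    return pd.DataFrame(cols, index=expr.columns)


def _merge_modules(expr, labels, eigengenes, merge_corr):
    """Iteratively merge module pairs whose eigengenes correlate > merge_corr."""
    labels = labels.copy()
    while eigengenes.shape[1] > 1:
        C = eigengenes.corr().to_numpy()
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if C[i, j] <= merge_corr:
            break
        keep_mod, drop_mod = sorted([eigengenes.columns[i], eigengenes.columns[j]])
        labels[labels == drop_mod] = keep_mod
        labels = _relabel(labels)
        eigengenes = _module_eigengenes(expr, labels)
    return labels, eigengenes


def union_graph(layers, candidates=None) -> nx.Graph:
    """Unweighted union of the layers' edge sets, optionally induced.

    ``layers`` may mix NetworkLayer, DiffusionResult (its hot graph is used)
    and plain graphs.  With ``candidates`` given, the union is induced on that
    gene set and isolated candidates are retained as degree-0 nodes.
    """
    graphs = []
    for layer in layers:
        if isinstance(layer, NetworkLayer):
            graphs.append(layer.graph)
        elif isinstance(layer, DiffusionResult):
            graphs.append(layer.hot_graph)
        elif isinstance(layer, nx.Graph):
            graphs.append(layer)
        else:
            raise TypeError(f"unsupported layer type: {type(layer)!r}")
    if not any(g.number_of_edges() or g.number_of_nodes() for g in graphs):
        raise ValueError("all layers are empty")
    if candidates is not None:
        candidates = set(candidates)
        if not candidates:
            raise ValueError("empty candidate set")
    U = nx.Graph()
    for g in graphs:
        nodes = g.nodes if candidates is None else (set(g.nodes) & candidates)
        U.add_nodes_from(nodes)
        for a, b in g.edges:
            if candidates is None or (a in candidates and b in candidates):
                U.add_edge(a, b)
    if candidates is not None:
        U.add_nodes_from(candidates)
    return U


@dataclass
class HubReport:
    """Per-node centralities, their medians, and the strict-median hub flags."""

    centralities: pd.DataFrame  # columns degree, betweenness, closeness, is_hub
    medians: dict

    @property
    def hubs(self) -> list:
        flags = self.centralities["is_hub"]
        return sorted(flags.index[flags])


def hub_screen(graph: nx.Graph, closeness: str = "harmonic") -> HubReport:
    """Call hub genes: every centrality strictly above its median.

    Degree, shortest-path betweenness (unnormalized) and closeness (harmonic
    by default, 'classic' optional) are computed per node; a node is a hub iff
    all three exceed the corresponding median over all nodes.  Regular graphs
    (every node identical) therefore yield an empty hub set.
    """
    if graph.number_of_nodes() < 1:
        raise ValueError("graph must have at least one node")
    if closeness not in ("harmonic", "classic"):
        raise ValueError("closeness must be 'harmonic' or 'classic'")
    nodes = sorted(graph.nodes)
    deg = pd.Series(dict(graph.degree), dtype=float)
    btw = pd.Series(nx.betweenness_centrality(graph, normalized=False), dtype=float)
    if closeness == "harmonic":
        clo = pd.Series(nx.harmonic_centrality(graph), dtype=float)
    else:
        clo = pd.Series(nx.closeness_centrality(graph), dtype=float)
    df = pd.DataFrame(
        {"degree": deg, "betweenness": btw, "closeness": clo}
    ).loc[nodes]
    medians = {c: float(df[c].median()) for c in df.columns}
    df["is_hub"] = (
        (df["degree"] > medians["degree"])
        & (df["betweenness"] > medians["betweenness"])
        & (df["closeness"] > medians["closeness"])
    )
    return HubReport(centralities=df, medians=medians)
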