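"""Centralities, efficiencies, folding degree, paths and partitions on residue networks.

Weight semantics follow the network construction: the edge *weight* acts as a
distance (shortest-path based measures), and the edge *importance* = 1/weight
acts as a connection strength / conductance (current flow, modularity,
spectral clustering).  With PIE-PRN weights w = 1/|E| this means strongly
interacting residues are topologically close and conduct well — the physically
sensible convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.linalg import expm

from .residue_io import StructureModel

__all__ = [
    "CentralityResult",
    "Partition",
    "NoPathError",
    "node_centrality",
    "total_energy_centrality",
    "global_efficiency",
    "local_efficiency",
    "efficiency_centrality",
    "folding_degree",
    "shortest_path",
    "louvain_communities",
    "spectral_partition",
]

CENTRALITY_KINDS = (
    "degree",
    "closeness",
    "betweenness",
    "current_flow_betweenness",
    "etot",
    "efficiency",
)


class NoPathError(ValueError):
    """No path exists between the requested nodes."""


@dataclass
class CentralityResult:
    """Per-node centrality scores.

    ``etot`` scores are in kcal/mol; all other kinds are dimensionless.
    """

    kind: str
    values: dict[str, float]
    graph_id: str = ""

    def top(self, n: int = 10, reverse: bool = True) -> list[tuple[str, float]]:
        return sorted(self.values.items(), key=lambda kv: kv[1], reverse=reverse)[:n]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            sorted(self.values.items()), columns=["node", self.kind]
        )


@dataclass
class Partition:
    """Node → community assignment with (for Louvain) the achieved modularity."""

    method: str
    assignment: dict[str, int]
    modularity: float | None = None
    seed: int | None = None

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values())) if self.assignment else 0

    def communities(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for node, c in self.assignment.items():
            out.setdefault(c, set()).add(node)
        return [out[k] for k in sorted(out)]


def node_centrality(g: nx.Graph, kind: str) -> CentralityResult:
    """Standard node centralities with the network's weight semantics.

    degree — unweighted degree / (n−1).  closeness and betweenness — edge
    weight as distance, Wasserman–Faust scaling on disconnected graphs
    ((component size − 1)/(n − 1)).  current_flow_betweenness — edge
    importance as conductance, computed per connected component.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if kind == "degree":
        values = nx.degree_centrality(g)
    elif kind == "closeness":
        values = nx.closeness_centrality(g, distance="weight", wf_improved=True)
    elif kind == "betweenness":
        values = nx.betweenness_centrality(g, weight="weight", normalized=True)
    elif kind == "current_flow_betweenness":
        values = {}
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp)
            if sub.number_of_nodes() < 3:
                # no possible intermediary in a 1- or 2-node component
                values.update({n: 0.0 for n in sub})
                continue
            values.update(
                nx.current_flow_betweenness_centrality(sub, weight="importance")
            )
    else:
        raise ValueError(f"unknown centrality kind {kind!r}")
    return CentralityResult(kind=kind, values={n: float(v) for n, v in values.items()})


def total_energy_centrality(g: nx.Graph) -> CentralityResult:
    """Total energy centrality: C_k^Etot = Σ E_tot over edges incident to k.

    A node with a more negative score is more strongly bound in the network.
    Only defined for PIE-PRNs, whose edges carry an e_tot attribute.
    """
    if g.number_of_edges() > 0 and not all(
        "e_tot" in d for _, _, d in g.edges(data=True)
    ):
        raise ValueError("total energy centrality needs e_tot on every edge (PIE-PRN)")
    if g.graph.get("kind") == "dprn":
        raise ValueError("total energy centrality is undefined for a D-PRN")
    values = {
        n: float(sum(d["e_tot"] for _, _, d in g.edges(n, data=True))) for n in g.nodes
    }
    return CentralityResult(kind="etot", values=values)


def _pairwise_efficiency_sum(g: nx.Graph) -> float:
    total = 0.0
    for _, dists in nx.all_pairs_dijkstra_path_length(g, weight="weight"):
        for t, d in dists.items():
            if d > 0:
                total += 1.0 / d
    return total


def global_efficiency(g: nx.Graph) -> float:
    """Weighted global efficiency: mean of 1/d(i,j) over ordered node pairs.

    d is the weighted shortest-path length; disconnected pairs contribute 0.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("global efficiency undefined for fewer than 2 nodes")
    return _pairwise_efficiency_sum(g) / (n * (n - 1))


def local_efficiency(g: nx.Graph, node: str) -> float:
    """Global efficiency of the subgraph induced by the node's neighbours."""
    neigh = list(g.neighbors(node))
    if len(neigh) < 2:
        return 0.0
    return global_efficiency(g.subgraph(neigh))


def efficiency_centrality(g: nx.Graph) -> CentralityResult:
    """Relative drop of global efficiency when the node is removed.

    C_k^eff = (E_glob(G) − E_glob(G − k)) / E_glob(G).  Scores can be
    negative: removing a peripheral node can *raise* the mean efficiency of
    the remainder.
    """
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError("efficiency centrality needs at least 3 nodes")
    e_full = global_efficiency(g)
    if e_full == 0:
        raise ValueError("global efficiency of the graph is zero")
    values = {}
    for k in g.nodes:
        rest = g.subgraph(n_ for n_ in g.nodes if n_ != k)
        values[k] = (e_full - global_efficiency(rest)) / e_full
    return CentralityResult(kind="efficiency", values=values)


# --------------------------------------------------------------------------
# Folding degree
# --------------------------------------------------------------------------

_BACKBONE = ("N", "CA", "C")


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return float(np.arctan2(y, x))


def folding_degree(structure: StructureModel) -> dict[str, float]:
    """Per-residue backbone-dihedral spectral folding index.

    For each chain the backbone atoms (N, CA, C in residue order) define a
    sequence of consecutive dihedral angles θ_i.  These are assembled into
    the tridiagonal matrix B with B_ii = cos θ_i and B_{i,i±1} = 1 (adjacent
    dihedrals share a bond), and the spectral index is the diagonal of
    exp(B).  Each residue's score is the mean over the dihedrals its atoms
    take part in.  Folded (helical) backbones, whose dihedrals are closer to
    0°, score higher than extended strands.  The score depends only on
    dihedral angles, hence is invariant under rigid-body motion.
    """
    scores: dict[str, list[float]] = {}
    for chain_id in structure.chain_ids:
        atoms: list[tuple[str, np.ndarray]] = []  # (residue label, coord)
        for rid, res_atoms in structure.residues:
            if rid.chain != chain_id:
                continue
            by_name = {a.name: a for a in res_atoms}
            for name in _BACKBONE:
                if name in by_name:
                    atoms.append((rid.label, by_name[name].coord))
        if len(atoms) < 4:
            raise ValueError(
                f"chain {chain_id}: needs ≥4 consecutive backbone atoms for folding degree"
            )
        coords = np.array([c for _, c in atoms])
        n_dih = len(atoms) - 3
        theta = np.array(
            [_dihedral(coords[i], coords[i + 1], coords[i + 2], coords[i + 3]) for i in range(n_dih)]
        )
        B = np.diag(np.cos(theta))
        for i in range(n_dih - 1):
            B[i, i + 1] = B[i + 1, i] = 1.0
        diag = np.diag(expm(B))
        for i in range(n_dih):
            for lbl in {atoms[i + k][0] for k in range(4)}:
                scores.setdefault(lbl, []).append(float(diag[i]))
    return {lbl: float(np.mean(v)) for lbl, v in scores.items()}


# --------------------------------------------------------------------------
# Paths and partitions
# --------------------------------------------------------------------------


def shortest_path(g: nx.Graph, s: str, t: str) -> tuple[list[str], float]:
    """Minimal-total-weight path from s to t; ties broken lexicographically."""
    if s not in g or t not in g:
        raise KeyError(f"node not in graph: {s if s not in g else t}")
    try:
        paths = list(nx.all_shortest_paths(g, s, t, weight="weight"))
    except nx.NetworkXNoPath:
        raise NoPathError(f"no path between {s!r} and {t!r}") from None
    best = min(paths)
    length = sum(g[u][v]["weight"] for u, v in zip(best, best[1:]))
    return best, float(length)


def louvain_communities(
    g: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> Partition:
    """Louvain modularity communities; edge importance as connection strength."""
    if g.number_of_edges() == 0:
        assignment = {n: i for i, n in enumerate(sorted(g.nodes))}
        return Partition(method="louvain", assignment=assignment, modularity=None, seed=seed)
    comms = nx.community.louvain_communities(
        g, weight="importance", resolution=resolution, seed=seed
    )
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    assignment = {n: i for i, c in enumerate(comms) for n in c}
    q = nx.community.modularity(
        g, [set(c) for c in comms], weight="importance", resolution=resolution
    )
    return Partition(method="louvain", assignment=assignment, modularity=float(q), seed=seed)


def spectral_partition(g: nx.Graph, k: int, seed: int = 0) -> Partition:
    """Spectral clustering from the k leading eigenvectors of the normalized Laplacian.

    The Laplacian is weighted by edge importance.  Rows of the eigenvector
    matrix are normalized and grouped by seeded k-means, so repeated runs
    with the same seed give the same partition.
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == 1:
        return Partition(method="spectral", assignment={m: 0 for m in nodes}, seed=seed)
    if k == n:
        return Partition(
            method="spectral", assignment={m: i for i, m in enumerate(nodes)}, seed=seed
        )

    A = nx.to_numpy_array(g, nodelist=nodes, weight="importance")
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    L = np.eye(n) - d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :]
    evals, evecs = np.linalg.eigh(L)
    X = evecs[:, :k]  # k smallest eigenvalues = leading spectral coordinates
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    X = X / np.where(norms > 0, norms, 1.0)

    from sklearn.cluster import KMeans

    labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(X)
    # renumber communities deterministically by first node occurrence
    remap: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for node, lab in zip(nodes, labels):
        if lab not in remap:
            remap[lab] = len(remap)
        assignment[node] = remap[lab]
    return Partition(method="spectral", assignment=assignment, seed=seed)
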