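"""Supramolecular (protein–protein interface) analyses.

Given a supersystem network split into monomers A and B this module provides:

* **Network differential analysis (NDA)** — ΔC_k = C_k(G) − C_k(G_{A∪B}),
  the part of each node's centrality attributable to the interface edges.
  G_{A∪B} has all nodes of G with the interface edges removed, so both
  evaluations run on graphs of the same size and the differences are
  directly comparable.
* **SVD motif analysis** — the interface energy matrix M (either the
  N_A′ × N_B′ block of the adjacency matrix, or the full symmetric
  N_PPI × N_PPI matrix of G_PPI) is decomposed as M = U Σ V*; the leading
  rank-1 terms σ_i u_i ⊗ v_i* are the interaction motifs, and the
  convergence factor f^(r) = Σ_{i≤r} σ_i / Σ_i σ_i measures how much of the
  interface the first r motifs capture.
* **3D-SPIE** — the long-format table of all cross-monomer pair energies
  (attractive and repulsive), the data behind the scattered-PIE plot.
* **Binding-energy partitioning** — assignment of the total inter-monomer
  interaction energy to individual fragments, symmetrically or to one side.

SPIE and binding energies read from the raw pair-energy table rather than
the thresholded network, because repulsive interactions that the edge
criterion E ≤ E_lim excludes are part of both analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .energy_sources import PieTable
from .network_metrics import (
    CentralityResult,
    efficiency_centrality,
    node_centrality,
    total_energy_centrality,
)
from .prn_build import SystemSplit

__all__ = [
    "NdaResult",
    "PpiMatrix",
    "SvdResult",
    "BindingResult",
    "nda",
    "ppi_matrix",
    "svd_motifs",
    "reconstruct_rank_r",
    "dominant_motif_nodes",
    "spie_data",
    "binding_energies",
]


@dataclass
class NdaResult:
    centrality_kind: str
    delta: dict[str, float]
    baseline: str = "g_aub"  # or "monomer" (size-inconsistent; see docstring of nda)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.delta.items()),
            columns=["node", f"delta_{self.centrality_kind}"],
        )


@dataclass
class PpiMatrix:
    """Interface energy matrix fed to the SVD.

    block mode: rows are the A-side interface nodes, columns the B-side ones
    (n_a′ × n_b′).  full mode: the symmetric N_PPI × N_PPI adjacency-style
    matrix of G_PPI.  The sign filter keeps only attractive (≤ 0) or
    repulsive (≥ 0) entries, zeroing the rest.
    """

    mode: str
    entries: np.ndarray
    row_index: list[str]
    col_index: list[str]
    sign_filter: str = "both"
    term: str = "e_tot"


@dataclass
class SvdResult:
    """M = U Σ V* with the sign convention that the largest-|entry| of each
    left singular vector is positive, plus the convergence series f^(r)."""

    sigma: np.ndarray
    u_vectors: np.ndarray  # shape (n, k), columns are u_i
    v_vectors: np.ndarray  # shape (k, m), rows are v_i*
    f_series: np.ndarray
    row_index: list[str]
    col_index: list[str]
    matrix: np.ndarray = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return len(self.sigma)


@dataclass
class BindingResult:
    mode: str
    contributions: dict[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.contributions.values()))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.contributions.items()), columns=["node", "binding_energy"]
        )


def _centrality(g: nx.Graph, kind: str) -> CentralityResult:
    if kind == "etot":
        return total_energy_centrality(g)
    if kind == "efficiency":
        return efficiency_centrality(g)
    return node_centrality(g, kind)


def nda(g: nx.Graph, split: SystemSplit, kind: str, baseline: str = "g_aub") -> NdaResult:
    """Network differential analysis: ΔC_k = C_k(G) − C_k(G_{A∪B}).

    Both centralities are evaluated with identical weighting on graphs with
    identical node sets, so ΔC_k isolates the effect of the interface edges.
    ``baseline="monomer"`` instead subtracts the centrality computed in the
    node's own monomer graph G_A or G_B; since those graphs are smaller than
    G, centralities are not strictly comparable across them and the ranking
    may be unreliable — the option exists for completeness.
    """
    if kind == "etot" and baseline == "g_aub":
        # The difference reduces in closed form to the sum of the node's
        # cross-monomer edge energies (the intra-monomer terms cancel), so it
        # is evaluated directly — this keeps the identity exact in floats.
        delta = {}
        for n in g.nodes:
            if n in split.g_ppi:
                nbrs = sorted(split.g_ppi.neighbors(n))
                delta[n] = float(sum(split.g_ppi[n][v]["e_tot"] for v in nbrs))
            else:
                delta[n] = 0.0
        return NdaResult(centrality_kind=kind, delta=delta, baseline=baseline)

    full = _centrality(g, kind).values
    if baseline == "g_aub":
        base = _centrality(split.g_aub, kind).values
        delta = {n: full[n] - base.get(n, 0.0) for n in full}
    elif baseline == "monomer":
        base = {}
        for sub in (split.g_a, split.g_b):
            if sub.number_of_nodes():
                base.update(_centrality(sub, kind).values)
        delta = {n: full[n] - base.get(n, 0.0) for n in full}
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    return NdaResult(centrality_kind=kind, delta=delta, baseline=baseline)


def ppi_matrix(
    split: SystemSplit,
    term: str = "e_tot",
    mode: str = "block",
    sign_filter: str = "both",
) -> PpiMatrix:
    """Interface energy matrix of the chosen term over cross-monomer edges."""
    g_ppi = split.g_ppi
    if g_ppi.number_of_edges() == 0:
        raise ValueError("empty interface: no cross-monomer edges")
    if sign_filter not in ("attractive", "repulsive", "both"):
        raise ValueError(f"unknown sign filter {sign_filter!r}")

    a_nodes = sorted(n for n, d in g_ppi.nodes(data=True) if d.get("monomer") == "A")
    b_nodes = sorted(n for n, d in g_ppi.nodes(data=True) if d.get("monomer") == "B")

    def value(u: str, v: str) -> float:
        if not g_ppi.has_edge(u, v):
            return 0.0
        e = g_ppi[u][v].get(term)
        if e is None:
            raise ValueError(f"edge ({u},{v}) lacks term {term!r}")
        if sign_filter == "attractive" and e > 0:
            return 0.0
        if sign_filter == "repulsive" and e < 0:
            return 0.0
        return float(e)

    if mode == "block":
        m = np.array([[value(a, b) for b in b_nodes] for a in a_nodes])
        return PpiMatrix(mode, m, a_nodes, b_nodes, sign_filter, term)
    if mode == "full":
        nodes = a_nodes + b_nodes
        m = np.array([[value(u, v) for v in nodes] for u in nodes])
        return PpiMatrix(mode, m, nodes, nodes, sign_filter, term)
    raise ValueError(f"unknown mode {mode!r}")


def svd_motifs(m: PpiMatrix | np.ndarray) -> SvdResult:
    """Singular value decomposition of the interface matrix.

    Returns σ sorted descending, the singular vector families with a fixed
    sign convention (largest-|entry| of each u_i made positive), and the
    convergence factors f^(r) = Σ_{i≤r} σ_i / Σ_i σ_i (f^(k) = 1).
    """
    if isinstance(m, PpiMatrix):
        entries, rows, cols = m.entries, m.row_index, m.col_index
    else:
        entries = np.asarray(m, dtype=float)
        rows = [str(i) for i in range(entries.shape[0])]
        cols = [str(j) for j in range(entries.shape[1])]
    if not np.any(entries):
        raise ValueError("all-zero matrix: nothing to decompose")

    u, s, vt = np.linalg.svd(entries, full_matrices=False)
    for i in range(len(s)):
        j = int(np.argmax(np.abs(u[:, i])))
        if u[j, i] < 0:
            u[:, i] = -u[:, i]
            vt[i, :] = -vt[i, :]
    total = s.sum()
    f = np.cumsum(s) / total
    return SvdResult(
        sigma=s, u_vectors=u, v_vectors=vt, f_series=f,
        row_index=rows, col_index=cols, matrix=entries,
    )


def reconstruct_rank_r(res: SvdResult, r: int) -> np.ndarray:
    """Rank-r approximation M̃(r) = Σ_{i≤r} σ_i u_i ⊗ v_i*."""
    if not 1 <= r <= res.k:
        raise ValueError(f"rank r must be in [1, {res.k}], got {r}")
    return (res.u_vectors[:, :r] * res.sigma[:r]) @ res.v_vectors[:r, :]


def dominant_motif_nodes(
    res: SvdResult,
    i: int,
    side: str = "A",
    alpha: float = 0.5,
    g_ppi: nx.Graph | None = None,
    term: str = "e_tot",
) -> list[dict]:
    """Dominant nodes of the i-th motif and their strongest interface partners.

    A node is dominant when its |component| in u_i (side A / rows) or v_i
    (side B / columns) reaches at least ``alpha`` times the largest
    |component|.  When the interface graph is supplied, each dominant node
    comes with its partner nodes from the other monomer ordered by the
    |term| of the shared edge.  ``i`` is 1-based (motif 1 = largest σ).
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if not 1 <= i <= res.k:
        raise ValueError(f"motif index must be in [1, {res.k}]")
    if side == "A":
        comps = res.u_vectors[:, i - 1]
        labels = res.row_index
    elif side == "B":
        comps = res.v_vectors[i - 1, :]
        labels = res.col_index
    else:
        raise ValueError("side must be 'A' or 'B'")

    threshold = alpha * float(np.max(np.abs(comps)))
    picked = [
        (labels[j], float(comps[j]))
        for j in np.argsort(-np.abs(comps))
        if abs(comps[j]) >= threshold
    ]
    out = []
    for lbl, comp in picked:
        partners: list[tuple[str, float]] = []
        if g_ppi is not None and lbl in g_ppi:
            partners = sorted(
                ((nbr, float(g_ppi[lbl][nbr].get(term, 0.0))) for nbr in g_ppi.neighbors(lbl)),
                key=lambda kv: -abs(kv[1]),
            )
        out.append({"node": lbl, "component": comp, "partners": partners})
    return out


def spie_data(
    split: SystemSplit,
    pie: PieTable,
    term: str = "e_tot",
    min_abs: float = 0.0,
) -> pd.DataFrame:
    """Long-format scattered-PIE table over *all* cross-monomer pairs.

    Every cross-monomer pair present in the pair-energy table with
    |term| ≥ min_abs gets a row (node_A, node_B, energy, sign label) —
    including repulsive pairs that the network's edge criterion would drop.
    """
    membership = split.membership
    rows = []
    for i, j, comp in pie.iter_pairs():
        mi, mj = membership.get(i), membership.get(j)
        if mi is None or mj is None or mi == mj:
            continue
        e = getattr(comp, term)
        if e is None:
            raise ValueError(f"term {term!r} absent from pair ({i},{j})")
        if abs(e) < min_abs:
            continue
        a, b = (i, j) if mi == "A" else (j, i)
        rows.append(
            {"node_A": a, "node_B": b, "energy": float(e),
             "sign": "attractive" if e < 0 else "repulsive"}
        )
    df = pd.DataFrame(rows, columns=["node_A", "node_B", "energy", "sign"])
    return df.sort_values(["node_A", "node_B"]).reset_index(drop=True)


def binding_energies(
    pie: PieTable,
    membership: Mapping[str, str],
    mode: str = "symmetric",
) -> BindingResult:
    """Assign the total inter-monomer interaction energy to fragments.

    symmetric — each cross pair's E_tot is split half/half between its two
    endpoints.  asymmetric_A — fragment i ∈ A accumulates Σ_{j∈B} E_tot(i,j)
    and B fragments get 0 (asymmetric_B mirrored).  All cross pairs of the
    raw table are used, regardless of any edge criterion; every mode
    conserves the total cross-monomer energy.
    """
    if mode not in ("symmetric", "asymmetric_A", "asymmetric_B"):
        raise ValueError(f"unknown mode {mode!r}")
    missing = [l for l in pie.node_labels if l not in membership]
    if missing:
        raise ValueError(f"labels without membership: {missing[:5]}")

    contributions = {l: 0.0 for l in pie.node_labels}
    n_cross = 0
    for i, j, comp in pie.iter_pairs():
        if membership[i] == membership[j]:
            continue
        n_cross += 1
        e = comp.e_tot
        if mode == "symmetric":
            contributions[i] += e / 2.0
            contributions[j] += e / 2.0
        else:
            side = "A" if mode == "asymmetric_A" else "B"
            target = i if membership[i] == side else j
            contributions[target] += e
    if n_cross == 0:
        import warnings

        warnings.warn("no cross-monomer pairs: binding energies are all zero")
    return BindingResult(mode=mode, contributions=contributions)
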