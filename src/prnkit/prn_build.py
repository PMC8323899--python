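"""Construct residue networks (D-PRN, PIE-PRN) and split supersystems.

A residue network is an undirected weighted graph whose nodes are residues
(or FMO fragments) and whose edges are interactions accepted by the build
criteria:

* **D-PRN** — edge iff the centre-of-mass distance R_ij ≤ R_lim; the edge
  weight is the distance itself (w_ij = R_ij).
* **PIE-PRN** — edge iff the chosen energy term satisfies E ≤ E_lim
  (E_lim < 0 selects attractive interactions), optionally gated by a
  secondary distance criterion; the weight is the inverse energy magnitude
  (w_ij = 1/|E|), so strong interactions are "short".

Either way the edge *importance* is defined as the inverse of the weight.
For dimeric supersystems the network G splits into the monomer graphs G_A,
G_B, the bipartite interface graph G_PPI (cross-monomer edges only, and only
nodes touching at least one such edge) and G_{A∪B} = G minus the interface
edges, which is the baseline of the network differential analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .energy_sources import PieTable
from .residue_io import ResidueId, StructureModel, center_of_mass

__all__ = [
    "BuildCriteria",
    "SystemSplit",
    "CriteriaError",
    "build_dprn",
    "build_pieprn",
    "split_supersystem",
    "edge_table",
    "residue_com_map",
]

ENERGY_TERMS = ("e_tot", "es", "ex", "ct", "di", "solv", "elec_ff", "vdw_ff")


class CriteriaError(ValueError):
    """Build criteria are inconsistent with the requested network kind."""


@dataclass
class BuildCriteria:
    """Edge-acceptance criteria.

    e_lim : float, kcal/mol
        PIE cutoff; a pair becomes an edge when the chosen term ≤ e_lim.
        Mandatory (and the only mandatory criterion) for PIE-PRNs.
    r_lim : float, Å
        Centre-of-mass distance cutoff.  Mandatory for D-PRNs; optional
        secondary criterion for PIE-PRNs.
    energy_term : str
        Which component drives acceptance and weighting (default e_tot).
    include_covalent : bool
        When set, sequence-adjacent (peptide-bonded) pairs are ordinary edge
        candidates; when unset they are skipped.
    weight_scheme : str
        "inverse_abs_energy" (PIE-PRN default) or "distance" (D-PRN).
    """

    e_lim: float | None = None
    r_lim: float | None = None
    energy_term: str = "e_tot"
    include_covalent: bool = True
    weight_scheme: str = "inverse_abs_energy"

    def __post_init__(self):
        if self.energy_term not in ENERGY_TERMS:
            raise CriteriaError(f"unknown energy term {self.energy_term!r}")


@dataclass
class SystemSplit:
    """The four graphs of a dimeric supersystem (plus G_{A∪B})."""

    g: nx.Graph
    g_a: nx.Graph
    g_b: nx.Graph
    g_ppi: nx.Graph
    g_aub: nx.Graph
    n_a: int
    n_b: int
    n_ppi: int
    membership: dict[str, str]


def _new_graph(kind: str) -> nx.Graph:
    g = nx.Graph()
    g.graph["kind"] = kind
    return g


def residue_com_map(structure: StructureModel) -> dict[str, np.ndarray]:
    """Centre of mass per residue, keyed by canonical node label."""
    return {rid.label: center_of_mass((rid, atoms)) for rid, atoms in structure.residues}


def _sequence_adjacent(a: ResidueId, b: ResidueId) -> bool:
    return a.chain == b.chain and abs(a.number - b.number) == 1 and not (
        a.insertion_code or b.insertion_code
    )


def _character(es: float | None, di: float | None) -> float | None:
    """Electrostatic share es/(es+di) over attractive magnitudes, in [0, 1].

    1 = purely electrostatic, 0 = purely dispersive; only the attractive
    (negative) parts of the two terms are compared.
    """
    if es is None or di is None:
        return None
    a_es = max(-es, 0.0)
    a_di = max(-di, 0.0)
    tot = a_es + a_di
    if tot == 0:
        return None
    return a_es / tot


def build_dprn(structure: StructureModel, criteria: BuildCriteria) -> nx.Graph:
    """Distance-based residue network: edge iff COM distance ≤ r_lim.

    Edge weight is the distance R_ij (Å); importance is 1/R_ij.
    """
    if criteria.r_lim is None or criteria.r_lim <= 0:
        raise CriteriaError("D-PRN requires r_lim > 0")
    g = _new_graph("dprn")
    rids = structure.residue_ids()
    coms = residue_com_map(structure)
    for rid in rids:
        g.add_node(rid.label, chain=rid.chain, number=rid.number, resname=rid.name)
    for i in range(len(rids)):
        for j in range(i + 1, len(rids)):
            a, b = rids[i], rids[j]
            if not criteria.include_covalent and _sequence_adjacent(a, b):
                continue
            r = float(np.linalg.norm(coms[a.label] - coms[b.label]))
            if r <= criteria.r_lim:
                g.add_edge(a.label, b.label, weight=r, importance=1.0 / r, r_ij=r)
    return g


def build_pieprn(
    pie: PieTable,
    criteria: BuildCriteria,
    structure: StructureModel | None = None,
) -> nx.Graph:
    """Energy-based residue network: edge iff chosen term ≤ e_lim.

    Weight is 1/|E_term| and importance |E_term| under the default scheme.
    When a secondary r_lim is given (and a structure supplies coordinates),
    pairs farther than r_lim between centres of mass are rejected too.
    Pairs whose accepted term is exactly zero cannot be weighted and are
    rejected with a warning.
    """
    if criteria.e_lim is None:
        raise CriteriaError("PIE-PRN requires e_lim")
    term = criteria.energy_term

    if criteria.r_lim is not None and structure is None:
        raise CriteriaError("secondary r_lim criterion needs a structure")
    # distances are recorded whenever coordinates are available
    coms = residue_com_map(structure) if structure is not None else None

    kind = "pieprn_ff" if pie.source == "forcefield" else "pieprn_fmo"
    g = _new_graph(kind)
    rid_by_label: dict[str, ResidueId] = {}
    if structure is not None:
        rid_by_label = {rid.label: rid for rid in structure.residue_ids()}
    for lbl in pie.node_labels:
        rid = rid_by_label.get(lbl)
        if rid is not None:
            g.add_node(lbl, chain=rid.chain, number=rid.number, resname=rid.name)
        else:
            g.add_node(lbl)

    for i_lbl, j_lbl, comp in pie.iter_pairs():
        value = getattr(comp, term)
        if value is None:
            raise CriteriaError(f"energy term {term!r} not present in PIE table")
        if value > criteria.e_lim:
            continue
        if not criteria.include_covalent:
            a, b = rid_by_label.get(i_lbl), rid_by_label.get(j_lbl)
            if a is not None and b is not None and _sequence_adjacent(a, b):
                continue
        r_ij = None
        if coms is not None and i_lbl in coms and j_lbl in coms:
            r_ij = float(np.linalg.norm(coms[i_lbl] - coms[j_lbl]))
            if criteria.r_lim is not None and r_ij > criteria.r_lim:
                continue
        elif criteria.r_lim is not None:
            continue  # secondary criterion cannot be checked without coordinates
        if value == 0.0:
            import warnings

            warnings.warn(f"pair ({i_lbl},{j_lbl}): zero-valued accepted energy, skipped")
            continue
        if criteria.weight_scheme == "distance":
            if r_ij is None:
                raise CriteriaError("distance weight scheme needs coordinates")
            w = r_ij
        else:
            w = 1.0 / abs(value)
        attrs: dict = {"weight": w, "importance": 1.0 / w}
        attrs.update(comp.as_dict())
        if r_ij is not None:
            attrs["r_ij"] = r_ij
        ch = _character(comp.es, comp.di)
        if ch is not None:
            attrs["character"] = ch
        g.add_edge(i_lbl, j_lbl, **attrs)
    return g


def split_supersystem(g: nx.Graph, membership: Mapping[str, str]) -> SystemSplit:
    """Split the supersystem network into G_A, G_B, G_PPI and G_{A∪B}.

    ``membership`` maps every node to "A" or "B".  The edge sets of G_A, G_B
    and G_PPI partition the edges of G; G_PPI keeps only nodes with at least
    one cross-monomer edge and only cross edges (a bipartite graph);
    G_{A∪B} keeps all nodes of G but drops exactly the interface edges.
    """
    missing = [n for n in g.nodes if n not in membership]
    if missing:
        raise ValueError(f"nodes without monomer membership: {missing[:5]}")
    bad = {m for m in membership.values()} - {"A", "B"}
    if bad:
        raise ValueError(f"membership values must be 'A' or 'B', got {sorted(bad)}")

    kind = g.graph.get("kind", "prn")
    g_a, g_b, g_ppi, g_aub = (_new_graph(kind) for _ in range(4))
    for n, data in g.nodes(data=True):
        side = membership[n]
        attrs = {**data, "monomer": side}
        (g_a if side == "A" else g_b).add_node(n, **attrs)
        g_aub.add_node(n, **attrs)

    for u, v, data in g.edges(data=True):
        su, sv = membership[u], membership[v]
        cross = su != sv
        data = {**data, "cross_monomer": cross}
        if cross:
            g_ppi.add_node(u, **{**g.nodes[u], "monomer": su})
            g_ppi.add_node(v, **{**g.nodes[v], "monomer": sv})
            g_ppi.add_edge(u, v, **data)
        else:
            (g_a if su == "A" else g_b).add_edge(u, v, **data)
            g_aub.add_edge(u, v, **data)

    g_full = _new_graph(g.graph.get("kind", "prn"))
    g_full.add_nodes_from(g_aub.nodes(data=True))
    for h in (g_a, g_b, g_ppi):
        g_full.add_edges_from(h.edges(data=True))

    return SystemSplit(
        g=g_full,
        g_a=g_a,
        g_b=g_b,
        g_ppi=g_ppi,
        g_aub=g_aub,
        n_a=g_a.number_of_nodes(),
        n_b=g_b.number_of_nodes(),
        n_ppi=g_ppi.number_of_nodes(),
        membership=dict(membership),
    )


_EDGE_COLUMNS = [
    "node_i", "node_j", "weight", "importance", "e_tot", "es", "ex", "ct",
    "di", "solv", "elec_ff", "vdw_ff", "r_ij", "character", "cross_monomer",
]


def edge_table(g: nx.Graph) -> pd.DataFrame:
    """All edges with their attributes, deterministically ordered by labels."""
    rows = []
    for u, v, data in g.edges(data=True):
        i, j = sorted((str(u), str(v)))
        row = {"node_i": i, "node_j": j}
        row.update({k: data.get(k) for k in _EDGE_COLUMNS[2:]})
        rows.append(row)
    df = pd.DataFrame(rows, columns=_EDGE_COLUMNS)
    df = df.dropna(axis=1, how="all") if len(df) else df[["node_i", "node_j", "weight", "importance"]]
    return df.sort_values(["node_i", "node_j"]).reset_index(drop=True)
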