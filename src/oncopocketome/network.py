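"""Residue-level validation (MCC) and per-cancer PPI hub networks.

Validation compares the residues lining a detected pocket against the
residues observed in contact with a binder (partner chain, inhibitor or
degrader) using the Matthews correlation coefficient over a binary
confusion matrix on a residue universe (by default, all residues of the
evaluated chain).

Networks: one undirected graph per cancer type; nodes are proteins carrying
their pocket counts, edges are the oncogenic interactions.  A protein is a
*hub* when it has two or more interaction partners; a homodimer counts as a
single partner (the protein itself).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import ResidueId, Structure

CANCER_TYPES = (
    "BRCA", "COAD", "HNSC", "KIRC", "KIRP", "LIHC",
    "LUAD", "LUSC", "PRAD", "STAD", "THCA", "UCEC",
)
HUB_MIN_PARTNERS = 2
DEFAULT_CONTACT_CUTOFF = 5.0  # Å, heavy-atom


@dataclass
class ResidueComparison:
    predicted: frozenset
    observed: frozenset
    universe: frozenset
    tp: int
    fp: int
    fn: int
    tn: int
    mcc: float
    degenerate: bool = False  # a confusion-matrix margin was zero


def observed_contact_residues(
    structure: Structure,
    binder: Structure,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> frozenset:
    """Residues of ``structure`` with a heavy atom within ``cutoff`` of the
    binder's heavy atoms."""
    binder_pts = binder.coords(heavy_only=True)
    if len(binder_pts) == 0:
        raise ValueError("binder has no heavy atoms")
    heavy = structure.heavy_atoms()
    tree = cKDTree(binder_pts)
    found: set[ResidueId] = set()
    d, _ = tree.query(np.asarray([a.coord for a in heavy]))
    for atom, dist in zip(heavy, d):
        if dist <= cutoff:
            found.add(atom.residue_id)
    return frozenset(found)


def compute_mcc(predicted, observed, universe) -> ResidueComparison:
    """Matthews correlation coefficient of a residue-set prediction.

    +1 is an ideal prediction, 0 no better than random, −1 complete
    disagreement.  A zero margin in the confusion matrix makes the usual
    formula undefined; such cases are reported as 0 with a flag.
    """
    predicted, observed, universe = (
        frozenset(predicted), frozenset(observed), frozenset(universe))
    if not universe:
        raise ValueError("residue universe is empty")
    if not predicted <= universe or not observed <= universe:
        raise ValueError("predicted and observed must be subsets of the universe")
    tp = len(predicted & observed)
    fp = len(predicted - observed)
    fn = len(observed - predicted)
    tn = len(universe) - tp - fp - fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    degenerate = denom == 0
    mcc = 0.0 if degenerate else (tp * tn - fp * fn) / np.sqrt(denom)
    return ResidueComparison(
        predicted=predicted, observed=observed, universe=universe,
        tp=tp, fp=fp, fn=fn, tn=tn, mcc=float(mcc), degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def _partners(graph: nx.Graph, node: str) -> set:
    """Interaction partners; a self-loop contributes the node itself once."""
    out = set(graph.neighbors(node))
    return out


def build_network(
    interactions: pd.DataFrame,
    pocket_summary: pd.DataFrame | None,
    cancer_type: str,
) -> nx.Graph:
    """Per-cancer graph with pocket-count node attributes and hub flags.

    ``interactions`` needs columns (protein_a, protein_b, cancer_types)
    where cancer_types is a semicolon-separated label list;
    ``pocket_summary`` needs (protein, n_interface_pockets,
    n_allosteric_pockets) — proteins absent from it are zero-filled.
    Duplicate edges are collapsed with a warning.
    """
    g = nx.Graph()
    g.graph["cancer_type"] = cancer_type
    counts: dict[str, tuple[int, int]] = {}
    if pocket_summary is not None and len(pocket_summary):
        for row in pocket_summary.itertuples(index=False):
            counts[row.protein] = (
                int(row.n_interface_pockets), int(row.n_allosteric_pockets))

    seen = set()
    for row in interactions.itertuples(index=False):
        cancers = {c.strip() for c in str(row.cancer_types).split(";") if c.strip()}
        if cancer_type not in cancers:
            continue
        a, b = str(row.protein_a), str(row.protein_b)
        key = tuple(sorted((a, b)))
        if key in seen:
            warnings.warn(f"duplicate interaction row {key} collapsed", stacklevel=2)
            continue
        seen.add(key)
        g.add_edge(a, b)

    for node in g.nodes:
        ni, na = counts.get(node, (0, 0))
        g.nodes[node]["n_interface_pockets"] = ni
        g.nodes[node]["n_allosteric_pockets"] = na
        g.nodes[node]["n_total_pockets"] = ni + na
    for node in g.nodes:
        g.nodes[node]["degree"] = len(_partners(g, node))
        g.nodes[node]["hub"] = g.nodes[node]["degree"] >= HUB_MIN_PARTNERS
    return g


def hub_table(networks: dict[str, nx.Graph]) -> pd.DataFrame:
    """One row per (protein, cancer) with degree, hub flag, pocket counts,
    plus a cross-cancer degree from the union of partners over all cancers."""
    union_partners: dict[str, set] = {}
    for g in networks.values():
        for node in g.nodes:
            union_partners.setdefault(node, set()).update(_partners(g, node))
    rows = []
    for cancer, g in networks.items():
        for node in sorted(g.nodes):
            nd = g.nodes[node]
            rows.append(
                {
                    "protein": node,
                    "cancer": cancer,
                    "degree": nd["degree"],
                    "hub": nd["hub"],
                    "n_interface_pockets": nd["n_interface_pockets"],
                    "n_allosteric_pockets": nd["n_allosteric_pockets"],
                    "n_total_pockets": nd["n_total_pockets"],
                    "cross_cancer_degree": len(union_partners[node]),
                }
            )
    return pd.DataFrame(rows)


def export_graphml(graph: nx.Graph, path: str) -> None:
    nx.write_graphml(graph, path)


def export_cytoscape_csv(graph: nx.Graph, edge_path: str, node_path: str) -> None:
    """Edge list + node attribute table importable into Cytoscape."""
    edges = pd.DataFrame(
        sorted((min(a, b), max(a, b)) for a, b in graph.edges),
        columns=["source", "target"],
    )
    nodes = pd.DataFrame(
        [
            {
                "protein": n,
                "n_total_pockets": graph.nodes[n]["n_total_pockets"],
                "n_interface_pockets": graph.nodes[n]["n_interface_pockets"],
                "hub": graph.nodes[n]["hub"],
            }
            for n in sorted(graph.nodes)
        ]
    )
    edges.to_csv(edge_path, index=False)
    nodes.to_csv(node_path, index=False)
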