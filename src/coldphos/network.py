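"""Kinase-substrate network assembly and cold-responsive subnetwork mapping.

The curated interaction table becomes a directed graph (kinase -> substrate)
with kinase-family annotations; phosphoproteins identified in the study and
the differentially phosphorylated subset are flagged on the nodes, and the
responsive subnetwork is the set of edges touching a differentially
phosphorylated protein (so a responsive substrate keeps its upstream kinases
even when those kinases were not themselves identified).
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .io_formats import InteractionTable

logger = logging.getLogger(__name__)


def build_network(interactions: InteractionTable) -> nx.DiGraph:
    """Deduplicated directed kinase -> substrate graph with node roles.

    A node appearing as both kinase and substrate gets role "both".
    """
    g = nx.DiGraph()
    kinases, substrates = set(), set()
    for row in interactions.table.itertuples(index=False):
        g.add_edge(row.kinase_id, row.substrate_id, source=row.source)
        kinases.add(row.kinase_id)
        substrates.add(row.substrate_id)
        fam = row.kinase_family if pd.notna(row.kinase_family) else "other"
        g.nodes[row.kinase_id]["family"] = fam
    for node in g.nodes:
        if node in kinases and node in substrates:
            role = "both"
        elif node in kinases:
            role = "kinase"
        else:
            role = "substrate"
        g.nodes[node]["role"] = role
        g.nodes[node].setdefault("family", "")
        g.nodes[node].setdefault("identified_here", False)
        g.nodes[node].setdefault("phosphorylated_here", False)
    logger.info("built kinase-substrate network: %d nodes, %d edges",
                g.number_of_nodes(), g.number_of_edges())
    return g


def map_subnetwork(network: nx.DiGraph, study_proteins, dep_proteins,
                   mode: str = "any") -> nx.DiGraph:
    """Extract the subnetwork of differentially phosphorylated proteins.

    ``mode="any"`` keeps edges with at least one endpoint in ``dep_proteins``
    (a responsive substrate retains its upstream kinases); ``mode="both"``
    requires both endpoints. Node flags ``identified_here`` (in the study) and
    ``phosphorylated_here`` (differentially phosphorylated) are set.
    """
    if mode not in ("any", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    study = set(study_proteins)
    deps = set(dep_proteins)
    if mode == "any":
        edges = [(u, v) for u, v in network.edges if u in deps or v in deps]
    else:
        edges = [(u, v) for u, v in network.edges if u in deps and v in deps]
    sub = network.edge_subgraph(edges).copy() if edges else nx.DiGraph()
    if not edges:
        logger.warning("no interactions touch the differentially "
                       "phosphorylated set; subnetwork is empty")
    for node in sub.nodes:
        sub.nodes[node]["identified_here"] = node in study
        sub.nodes[node]["phosphorylated_here"] = node in deps
    logger.info("responsive subnetwork: %d nodes, %d edges (mode=%s)",
                sub.number_of_nodes(), sub.number_of_edges(), mode)
    return sub


def family_interaction_counts(subnetwork: nx.DiGraph) -> pd.Series:
    """Edge counts grouped by the kinase endpoint's family.

    Kinases without a family annotation count under "other"; the counts sum
    to the subnetwork's edge total.
    """
    counts: dict[str, int] = {}
    for u, _ in subnetwork.edges:
        fam = subnetwork.nodes[u].get("family") or ""
        if not fam:
            logger.warning("kinase %s has no family annotation; counted as other", u)
            fam = "other"
        counts[fam] = counts.get(fam, 0) + 1
    return pd.Series(counts, dtype=int).sort_values(ascending=False)
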