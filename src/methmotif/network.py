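"""TF-level aggregation of motif enrichment and first-neighbor subnetworks.

Motif databases often carry several matrices per transcription factor, so
enrichment is aggregated to the TF level: motifs passing the significance
threshold (adjusted p < alpha, enriched only — depletion excluded) are
grouped by TF and their p-values averaged. The significant TFs plus their
first-order partners in a TF-TF physical-interaction network form the
reported subnetwork (induced subgraph, so neighbor-neighbor edges are
kept), with per-node attributes mean_p, degree and category: protective /
hazardous / both (significant in both analyses) / neighbor.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd


def aggregate_tf_pvalues(
    enrichment: pd.DataFrame,
    alpha: float = 0.01,
    enriched_only: bool = True,
) -> pd.DataFrame:
    """Average significant motif p-values per TF; tag which analyses contributed.

    ``enrichment`` may concatenate several analyses (column ``analysis``,
    e.g. "protective"/"hazardous"). Only motifs with adjusted_p < alpha (and
    relative enrichment > 1 when ``enriched_only``) contribute; mean_p is
    the arithmetic mean of their raw p-values (mean_adjusted_p also given).
    """
    sig = enrichment[enrichment["adjusted_p"] < alpha]
    if enriched_only:
        sig = sig[sig["relative_enrichment"] > 1.0]
    if sig.empty:
        return pd.DataFrame(columns=["tf_name", "mean_p", "mean_adjusted_p", "n_motifs", "category"])
    rows = []
    for tf, grp in sig.groupby("tf_name", sort=True):
        analyses = set(grp["analysis"])
        if {"protective", "hazardous"} <= analyses:
            category = "both"
        elif "protective" in analyses:
            category = "protective"
        elif "hazardous" in analyses:
            category = "hazardous"
        else:
            category = ",".join(sorted(analyses))
        rows.append(
            {
                "tf_name": tf,
                "mean_p": float(grp["raw_p"].mean()),
                "mean_adjusted_p": float(grp["adjusted_p"].mean()),
                "n_motifs": len(grp),
                "category": category,
            }
        )
    return pd.DataFrame(rows)


def validate_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Undirected simple TF-TF edge list: no self-loops, no duplicate pairs."""
    if not {"tf1", "tf2"} <= set(edges.columns):
        raise ValueError("edge list needs columns tf1, tf2")
    if (edges["tf1"] == edges["tf2"]).any():
        raise ValueError("self-loop in TF edge list")
    keys = edges.apply(lambda r: tuple(sorted((r["tf1"], r["tf2"]))), axis=1)
    if keys.duplicated().any():
        raise ValueError("duplicate undirected edge in TF edge list")
    return edges


def build_subnetwork(tf_table: pd.DataFrame, edges: pd.DataFrame) -> nx.Graph:
    """Induced subgraph on significant TFs and their first-order partners.

    Significant TFs absent from the interaction network appear as isolated
    nodes. Node attributes: category, degree (within the subnetwork), and
    mean_p / mean_adjusted_p for significant TFs.
    """
    validate_edges(edges)
    full = nx.Graph()
    full.add_edges_from(edges[["tf1", "tf2"]].itertuples(index=False, name=None))
    significant = list(tf_table["tf_name"])
    nodes = set(significant)
    for tf in significant:
        if tf in full:
            nodes.update(full.neighbors(tf))
    sub = nx.Graph()
    sub.add_nodes_from(sorted(nodes))
    sub.add_edges_from(full.subgraph(nodes).edges())
    info = tf_table.set_index("tf_name")
    for node in sub.nodes:
        if node in info.index:
            sub.nodes[node]["category"] = info.loc[node, "category"]
            sub.nodes[node]["mean_p"] = float(info.loc[node, "mean_p"])
            sub.nodes[node]["mean_adjusted_p"] = float(info.loc[node, "mean_adjusted_p"])
        else:
            sub.nodes[node]["category"] = "neighbor"
        sub.nodes[node]["degree"] = sub.degree(node)
    return sub


def network_tables(graph: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plain node / edge tables mirroring the GraphML attributes."""
    node_rows = [
        {
            "tf_name": n,
            "category": data.get("category"),
            "mean_p": data.get("mean_p", np.nan),
            "degree": data["degree"],
        }
        for n, data in sorted(graph.nodes(data=True))
    ]
    edge_rows = [{"tf1": u, "tf2": v} for u, v in sorted(map(sorted, graph.edges()))]
    return (
        pd.DataFrame(node_rows, columns=["tf_name", "category", "mean_p", "degree"]),
        pd.DataFrame(edge_rows, columns=["tf1", "tf2"]),
    )
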