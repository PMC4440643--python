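"""CpG beta-value clustering (k-means, WCSS curve) and the TF subnetwork.

Writes the WCSS elbow table, cluster assignments, and the TF network node
and edge tables aggregated from the protective/hazardous enrichment.
"""

import os

import pandas as pd

from common import get_bundle, results_dir
from methmotif.cluster import cluster_assignments_table
from methmotif.network import network_tables

bundle = get_bundle()
out = results_dir()

wcss = pd.DataFrame(bundle["wcss_curve"], columns=["k", "wcss_total"])
wcss.to_csv(os.path.join(out, "06_wcss_curve.tsv"), sep="\t", index=False)
cluster_assignments_table(bundle["cluster"]).to_csv(
    os.path.join(out, "06_cluster_assignments.tsv"), sep="\t", index=False
)
print("WCSS by k:")
print(wcss.to_string(index=False))
sizes = bundle["cluster"].assignments.value_counts().sort_index()
print(f"\ncluster sizes at k={bundle['cluster'].k}: {sizes.to_dict()}")

if bundle["network"] is not None:
    nodes, edges = network_tables(bundle["network"])
    nodes.to_csv(os.path.join(out, "06_tf_network_nodes.tsv"), sep="\t", index=False)
    edges.to_csv(os.path.join(out, "06_tf_network_edges.tsv"), sep="\t", index=False)
    print(f"\nTF subnetwork: {len(nodes)} nodes, {len(edges)} edges")
    print(nodes.to_string(index=False))
else:
    print("\nno significant TFs: network skipped")
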