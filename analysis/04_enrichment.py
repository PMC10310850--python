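#!/usr/bin/env python
"""Preranked enrichment, similarity network and over-representation.

Scores truth-derived response sets and random sets against the Pb
Level-I ranking, builds the enrichment-map network over significant
sets, reports its global metrics, and runs hypergeometric
over-representation of the Pb DEGs against curated-style target lists,
with the background restricted to expressed genes (base mean > 20).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ffed import enrich
from ffed.io import read_rnk, write_gmt, write_graphml

DATA = Path("results/data")
DGE = Path("results/dge")
OUT = Path("results/enrichment")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 17

truth = pd.read_csv(DATA / "truth_gene_effects.tsv", sep="\t", index_col=0)
ranked = read_rnk(DGE / "levelI_Pb.rnk")
gene_universe = [g for g, _ in ranked]

rng = np.random.default_rng(SEED)
collection = {
    f"{f} response targets": set(truth.index[truth[f] != 0])
    for f in truth.columns
}
for i in range(6):
    collection[f"random set {i + 1}"] = set(
        rng.choice(gene_universe, 50, replace=False)
    )
write_gmt(collection, OUT / "genesets.gmt")

res = enrich.gsea_significance(ranked, collection, n_perm=1000, seed=SEED)
res.to_csv(OUT / "gsea.tsv", sep="\t")
sig = res[res["q"] < 0.05]
print(f"GSEA: {len(sig)}/{len(res)} sets at q < 0.05:",
      ", ".join(sig.index))

net = enrich.build_similarity_network(res, collection)
write_graphml(net, OUT / "network.graphml")
m = enrich.network_metrics(net)
print(f"Similarity network: {m.total_nodes} nodes, {m.total_edges} edges, "
      f"diameter {m.diameter}, density {m.density:.3f}, "
      f"clustering {m.clustering_coefficient:.3f}, "
      f"average degree {m.average_degree:.2f}")
if net.number_of_nodes() == 0:
    print("No network could be generated at the selected thresholds.")
for cluster in enrich.summarize_clusters(net):
    print(f"  cluster '{cluster['label']}': {len(cluster['members'])} sets")

# over-representation of Pb DEGs against curated-style lists
pb = pd.read_csv(DGE / "levelI_Pb.tsv", sep="\t", index_col=0)
background = set(pb.index[pb["baseMean"] > 20])
hits = set(pb.index[(pb["padj"] < 0.05)]) & background
targets = {
    "Pb truth": set(truth.index[truth["Pb"] != 0]) & background,
    "FH truth": set(truth.index[truth["FH"] != 0]) & background,
    "random": set(rng.choice(sorted(background), 60, replace=False)),
}
ora = enrich.hypergeom_enrichment_multi(hits, targets, background)
ora.to_csv(OUT / "ora.tsv", sep="\t")
print("Over-representation of Pb DEGs (base-mean > 20 background):")
for name, row in ora.iterrows():
    print(f"  {name}: k={row['k']}/{row['n']} hits in K={row['K']}, "
          f"adj. p = {row['padj']:.2e}")
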