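"""Relative splice-site usage and differential splice clusters.

Builds the planted intron-excision count tables and measures how usage of
the cryptic 3' splice site shifts when hnRNPC is lost.
"""

import pandas as pd

from ecrscan.splicing import (
    SpliceClusterCounts,
    differential_splice_clusters,
    relative_splice_site_use,
)
from ecrscan.simulate import SimSpec, generate_annotation, generate_counts, sample_table

spec = SimSpec(seed=1)
sim = generate_annotation(spec)
counts = generate_counts(spec, sim)
design = sample_table()
groups = {
    c: design.loc[design["condition"] == c, "sample_id"].tolist()
    for c in ("CTRL", "hnRNPC")
}

clusters = [
    SpliceClusterCounts(clu, chrom, grp.drop(columns=["chrom", "cluster_id"]).reset_index(drop=True))
    for (chrom, clu), grp in counts.splice_counts.groupby(["chrom", "cluster_id"])
]
res = differential_splice_clusters(clusters, groups).set_index("cluster_id")
truth = counts.truth_splice.set_index("cluster_id")
n_sig = int((res["p_adj"] <= 0.001).sum())
print(f"clusters tested: {len(res)}; differential at adjusted p<=0.001: {n_sig} "
      f"(planted: {int(truth['shifted'].sum())})")

shifted_id = truth.index[truth["shifted"]][0]
cl = next(c for c in clusters if c.cluster_id == shifted_id)
usage = relative_splice_site_use(cl, groups)
cryptic = usage[usage["side"] == "end"].sort_values("fold_change").iloc[-1]
print(f"cluster {shifted_id}: cryptic 3' site {int(cryptic['site'])} relative use "
      f"{cryptic['CTRL']:.2f} (CTRL) -> {cryptic['hnRNPC']:.2f} (hnRNPC KO), "
      f"fold change {cryptic['fold_change']:.2f}")

print(
    "\nIn hnRNPC-deficient samples the normally repressed (cryptic, often "
    "Alu-derived) splice site gains relative use, pulling intronic dsRNA "
    "into mature transcripts."
)
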