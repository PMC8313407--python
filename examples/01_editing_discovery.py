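"""Discover A-to-I editing clusters and ECRs on a synthetic study.

Generates pileups for the 36-sample design (4 genotypes x 3 days x 3
replicates), runs the full post-caller filter cascade, and reports pooled
editing per genotype.
"""

from ecrscan import PipelineParams, SiteTable
from ecrscan.editing import (
    build_ecrs,
    finalize_clusters,
    pooled_site_editing,
    primary_site_filter,
    secondary_site_filter,
)
from ecrscan.simulate import SimSpec, generate_annotation, generate_pileups, sample_table

spec = SimSpec(seed=1)
params = PipelineParams()
sim = generate_annotation(spec)
pileups = generate_pileups(spec, sim)
design = sample_table()

table = SiteTable.from_pileups(pileups, sim.snps)
print(f"candidate sites: {len(table.sites)} (incl. planted decoys)")

wt = design.loc[design["ADAR"] == "WT", "sample_id"].tolist()
table = primary_site_filter(table, wt, params)
print(f"after primary filter (caller pass, coverage, 0.05<=f<=0.95): {len(table.sites)}")

treatments = {t: g["sample_id"].tolist() for t, g in design.groupby("treatment")}
table = secondary_site_filter(table, treatments, params)
print(f"after secondary per-triplet filter: {len(table.sites)}")

table, clusters = finalize_clusters(table, params)
ecrs = build_ecrs(clusters, params)
print(f"final sites: {len(table.sites)} in {len(clusters)} clusters "
      f"(>=5 sites, gaps <=50 nt) -> {len(ecrs)} ECRs (pad 1 kb, merge)")

conds = {c: g["sample_id"].tolist() for c, g in design.groupby("condition")}
pooled = pooled_site_editing(table, conds)
for cond in ("CTRL", "hnRNPC", "ADAR", "DKO"):
    print(f"mean pooled editing, {cond}: {pooled[cond].mean():.3f}")

print(
    "\nEditing collapses in the ADAR-deficient arms (ADAR, DKO) while the "
    "cluster/ECR geometry is genotype-independent: these unedited dsRNA "
    "regions are the candidate MDA5 ligands."
)
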