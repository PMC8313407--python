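"""Rank repeat families by eCLIP enrichment to nominate Alu-binding proteins.

Simulates per-family eCLIP/input read counts with a planted 4-fold Alu
antisense enrichment and ranks families by relative information content.
"""

from ecrscan.eclip import family_enrichment
from ecrscan.simulate import SimSpec, generate_family_counts

counts, truth = generate_family_counts(SimSpec(seed=1))
res = family_enrichment(counts)

for strand in ("sense", "antisense"):
    top = res[res["strand"] == strand].nsmallest(3, "rank")
    print(f"top families, {strand}:")
    for _, r in top.iterrows():
        print(f"  {r['family']:<8} FE={r['fold_enrichment']:.2f} "
              f"RIC={r['ric']:.4f}")

print(
    "\nRelative information content (eCLIP read fraction x log2 fold "
    "enrichment) rewards families that are both abundant in the eCLIP "
    "library and enriched over input - the screen statistic that surfaced "
    "hnRNPC as an antisense-Alu binder."
)
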