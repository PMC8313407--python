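"""Moderated differential expression with TMM normalization.

Simulates a two-group study with 200 features carrying a planted log2FC of
2 and reports recovery and the realized false-discovery behaviour.
"""

from ecrscan import PipelineParams
from ecrscan.diffexp import differential_expression, normalization_factors
from ecrscan.simulate import simulate_de_counts

params = PipelineParams()
counts, design, planted = simulate_de_counts(
    seed=1, n_features=2000, n_planted=200, log2fc=2.0
)
nf = normalization_factors(counts)
print("TMM factors:", ", ".join(f"{s}={v:.3f}" for s, v in nf.items()))

res = differential_expression(counts, design, ("A", "B"), params, norm_factor=nf)
sub = res.loc[planted]
false = res.drop(planted)["regulated"].sum()
print(f"planted features flagged: {sub['regulated'].mean():.1%}")
print(f"mean estimated log2FC: {sub['log2fc'].mean():.3f} (truth 2.0)")
print(f"false 'regulated' calls among {len(res) - len(planted)} nulls: {false}")

print(
    "\nThe moderated t on log2-cpm recovers the planted effect with small "
    "bias; TMM factors absorb the composition shift the planted features "
    "induce in group B's library size."
)
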