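"""2x2 factorial test for hnRNPC x ADAR synergy on interferon-stimulated genes.

Simulates a single-day factorial design in which 100 of 500 ISGs carry a
synergistic interaction of log2FC 2 in the double knockout only, and tests
each ISG for a statistical interaction.
"""

from ecrscan import PipelineParams
from ecrscan.diffexp import interaction_test, normalization_factors
from ecrscan.simulate import simulate_factorial_counts

params = PipelineParams()
counts, design, isgs, synergistic = simulate_factorial_counts(
    seed=1, n_isg=500, n_synergistic=100, interaction=2.0
)
nf = normalization_factors(counts)
res = interaction_test(counts, design, list(isgs), params, norm_factor=nf)

syn = res.loc[synergistic]
additive = res.drop(synergistic)
print(f"ISGs tested: {len(res)}")
print(f"synergistic ISGs significant (BH p<=0.05): {int(syn['significant'].sum())}"
      f"/{len(syn)}")
print(f"mean interaction estimate, synergistic set: {syn['interaction'].mean():.3f} "
      f"(truth 2.0)")
print(f"mean interaction estimate, additive set: {additive['interaction'].mean():+.3f} "
      f"(truth 0)")

print(
    "\nThe interaction coefficient (DKO-ADAR)-(hnRNPC-CTRL) isolates "
    "super-additive ISG induction: the signature of two cooperating dsRNA "
    "checkpoints failing together."
)
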