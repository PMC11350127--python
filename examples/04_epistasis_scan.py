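"""Decompose a trait into chromosome main effects and epistasis.

The staged backward elimination first prunes three-way interactions at
alpha = 5e-5, then unprotected two-way terms, then main effects, always
keeping terms nested under surviving interactions (marginality).  Here the
generative truth for main stem length contains a large three-way
interaction among chromosomes 1, 2 and 5.
"""

import numpy as np

from cslmap import EffectModel, run_selection, simulate_csl_trait

rng = np.random.default_rng(4)
model = EffectModel.stem_length_default()
y, genotypes = simulate_csl_trait(model, reps=12, rng=rng)

result = run_selection(y, genotypes)

print("selected model: ", " + ".join(result.terms()))
print(f"R^2 (selected model)    = {result.r2_full:.3f}")
print(f"R^2 (main effects only) = {result.r2_main_only:.3f}")
print("\ncoefficients (mm):")
print(result.coef.round(2).to_string())
print("\npredicted class means for Chr1:Chr2:Chr5 (mm):")
print(result.class_means["Chr1:Chr2:Chr5"].round(1).to_string(index=False))
# The truth (a three-way c_125 plus two-way epistasis) is recovered exactly;
# the R^2 gap quantifies how much variation main effects alone would miss.
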