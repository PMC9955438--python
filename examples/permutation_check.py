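"""Validate an OPLS-DA model with a 100-label-permutation test.

The class labels are shuffled 100 times and the model refitted each
time; R2Y and Q2 are regressed against the correlation between permuted
and original responses.  Intercepts near or below zero at correlation 0
mean the real model's fit cannot be explained by overfitting.
"""

import sersdx
from sersdx import CohortConfig, ModelSpec, generate_cohort, permutation_test, preprocess_pipeline

ORDER = [sersdx.HEALTHY, sersdx.STONE, sersdx.POLYP]

sset, _ = generate_cohort(CohortConfig(seed=1))
pset = preprocess_pipeline(sset)

result = permutation_test(pset.intensities, pset.labels,
                          ModelSpec("opls", {"n_orthogonal": 1}),
                          n_perm=100, seed=1, cv_folds=10, class_order=ORDER)

print(f"original model: R2Y = {result.original_r2y:.3f}, Q2 = {result.original_q2:.3f}")
print(f"permuted Q2 range: [{result.q2_values.min():.3f}, {result.q2_values.max():.3f}]")
print(f"R2 intercept = {result.r2_intercept:.3f}  (well-constructed if < 0.4)")
print(f"Q2 intercept = {result.q2_intercept:.3f}  (well-constructed if < 0.05)")
print("verdict: model", "is" if result.well_constructed else "is NOT", "well-constructed")
# A real class structure gives an original Q2 far above every permuted
# Q2, and a negative Q2 intercept.
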