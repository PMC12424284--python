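"""Varimax PCA of resting-state breathing dynamics.

Simulates a rest-only cohort, computes the 16-feature table, and runs a
PCA of the feature correlation matrix with eigenvalue > 1 retention and
varimax rotation. Rotated components group features that covary across
subjects (e.g. entropy/complexity of one series loading together).
"""

import numpy as np

from breathdyn import extract_feature_table, gen_cohort, pca_varimax, prepare_features
from breathdyn.synthetic import SyntheticCohortSpec

bundle = gen_cohort(SyntheticCohortSpec(n_subjects=60, include_task=False, seed=3))
table = extract_feature_table(bundle.recordings)
prepared = prepare_features(table).drop_incomplete()

res = pca_varimax(prepared.select("rest"))
print(f"eigenvalues > 1: {res.n_retained} components retained")
print("explained variance (%):",
      np.round(res.explained_variance_pct, 1))
for pc in res.loadings.columns[:3]:
    top = res.loadings[pc].abs().sort_values(ascending=False).head(3)
    pairs = ", ".join(f"{f}={res.loadings.loc[f, pc]:+.2f}" for f in top.index)
    print(f"{pc}: {pairs}")
# Loadings are correlations between features and rotated components;
# communalities (row sums of squared loadings) are rotation-invariant.
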