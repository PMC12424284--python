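"""Paired rest-vs-task comparison of breathing dynamics.

Simulates a 30-subject cohort whose task state breathes faster,
shallower, more variably and more irregularly than rest, extracts the
16-feature dynamics vector per recording, log-transforms and site-
harmonizes the table, and runs paired t-tests with Benjamini-Hochberg
FDR across features. Negative t means the feature increased under task
(diff = rest - task).
"""

import numpy as np

from breathdyn import extract_feature_table, gen_cohort, paired_compare, prepare_features
from breathdyn.io import FeatureTable
from breathdyn.synthetic import SyntheticCohortSpec

bundle = gen_cohort(SyntheticCohortSpec(n_subjects=30, seed=1))
table = extract_feature_table(bundle.recordings)
prepared = prepare_features(table).drop_incomplete()

rest, task = prepared.select("rest"), prepared.select("task")
common = sorted(set(rest.df["subject"]) & set(task.df["subject"]))
rest = FeatureTable(rest.df[rest.df["subject"].isin(common)], prepared.transform_state)
task = FeatureTable(task.df[task.df["subject"].isin(common)], prepared.transform_state)

print(f"{len(common)} paired subjects")
print(f"{'feature':16s} {'t':>8s} {'p_adj':>10s} {'d':>7s}  planted")
for r in paired_compare(rest, task):
    planted = bundle.truth.expected_signs.get(r.feature)
    mark = {1: "rest>task", -1: "task>rest", None: "-"}[planted]
    star = "*" if r.p_adjusted < 0.05 else " "
    print(f"{r.feature:16s} {r.t:8.2f} {r.p_adjusted:10.2e}{star} {r.cohens_d:7.2f}  {mark}")
# Every feature with a planted direction should come out significant
# with the matching sign; Cohen's d = t/sqrt(n) for paired designs.
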