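"""Per-marker diagnostic rows: ROC AUC, cutoff sensitivity/specificity
with exact binomial CIs, and the positive likelihood ratio.

Runs on a synthetic cohort at the published group structure and renders
one row per STOP variable at its canonical cutoff, in the style of a
clinical diagnostic-accuracy table.
"""

import pandas as pd

from stopscore import canonical_stop_definition, default_cohort_spec, generate_cohort, records_to_frame
from stopscore.diagnostics import table_row

frame = records_to_frame(generate_cohort(default_cohort_spec(), seed=5, n_scale=10))
labels = (frame["outcome"] == "sepsis").astype(int).tolist()

rows = []
for rule in canonical_stop_definition().rules:
    values = frame[rule.variable].tolist()
    rows.append(table_row(values, labels, rule))

print(pd.DataFrame(rows).to_string(index=False))
# 'sensitivity_pct' is the share of septic patients meeting the cutoff,
# 'specificity_pct' the share of non-septic patients not meeting it
# (Clopper-Pearson 95% CIs in parentheses-columns); 'likelihood_ratio'
# is sensitivity / (1 - specificity) -- values near 2 roughly double the
# pre-test odds of sepsis.
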