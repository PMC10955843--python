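"""Semantic measures of depression/anxiety and their age correlations with
the rating scales as covariates.

A semantic measure is the cross-validated prediction of PHQ-9 (or GAD-7)
from the All-texts representation.  If the words carry age-related
mental-health information beyond the scale, the measure still correlates
with age after partialling out the scale.
"""

import qcla

cohort, truth = qcla.generate_cohort(seed=51)
kept = qcla.apply_control_filter(cohort)
tokens = qcla.generate_reference_corpus(truth.config, seed=52)
space = qcla.build_space(tokens, d=512)

measures = [
    qcla.build_semantic_measure(kept, space, construct, seed=53)
    for construct in ("depression", "anxiety")
]
table = qcla.age_correlation_table(kept, measures)
cols = ["measure", "r_scale_age", "r_semantic_age", "r_partial", "p_partial", "sig_partial"]
print(table[cols].round(4).to_string(index=False))
print(
    "\nnegative r: mental-health burden declines with age in this cohort.  "
    "r_partial < 0 with a\nsmall p means the language carries incremental "
    "age-related signal beyond the rating scale."
)
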