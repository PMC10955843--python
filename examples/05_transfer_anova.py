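"""Do younger and older adults need different prediction models?

Median-splits the cohort by age, trains 68 models (17 text variables x 4
rating scales) within each half and across halves, and analyses the
2 (test group) x 2 (same vs opposite training data) grid of per-model
correlations with a repeated-measures ANOVA.  A significant interaction
means the same-group advantage differs between the age groups, i.e. the
groups need distinct models.
"""

import qcla

cohort, truth = qcla.generate_cohort(seed=41)
kept = qcla.apply_control_filter(cohort)
tokens = qcla.generate_reference_corpus(truth.config, seed=42)
space = qcla.build_space(tokens, d=512)
split = qcla.median_split(kept, "median")

result = qcla.run_transfer(kept, space, split, seed=43)
print(qcla.summarize_fig3(result).round(3).to_string(index=False))

anova = qcla.repeated_anova_2x2(result, response="r")
print("\nrepeated-measures ANOVA on r (68 models as subjects):")
print(anova.effects.round(4).to_string())
print(
    "\nage: are the older group's scales easier to predict overall; "
    "age:condition: does the\nsame-group advantage depend on the group "
    "(the generator plants old-specific vocabulary)."
)
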