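"""Find words indicative of younger vs older participants.

Every word used by at least five participants gets a Welch t-test
comparing the ages of its users and non-users; Bonferroni-significant
words form the two cloud datasets (size weight = frequency, colour
weight = p).  With the synthetic generator, the planted young/old marker
words should dominate the clouds.
"""

import qcla

cohort, truth = qcla.generate_cohort(seed=21)
kept = qcla.apply_control_filter(cohort)

clouds = qcla.indicative_cloud(kept)
for group in ("young", "old"):
    cloud = clouds[group]
    top = cloud.entries.head(10)
    print(f"\n{group} cloud ({len(cloud.entries)} significant words, m={cloud.m} tested):")
    print(top[["word", "size_weight", "p"]].to_string(index=False))
    markers = set(truth.marker_words[group])
    hit = len(markers & set(cloud.words())) / len(markers)
    print(f"planted {group} markers recovered: {hit:.0%}")
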