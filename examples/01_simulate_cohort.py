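"""Generate the default synthetic cohort and inspect its structure.

The default cohort emulates a baseline MCI study: 177 non-converters and
142 converters, 285 features across six modalities, with 15 planted
discriminative features (8 cognitive scores, 6 MRI-like volumes inside a
correlated block, and the APOE allele count) whose standardized group
differences follow published effect sizes.
"""

import numpy as np

from biosig import default_cohort_spec, generate_cohort

table, truth = generate_cohort(default_cohort_spec(seed=0))

print(f"subjects: {table.n_subjects} "
      f"({(table.labels == -1).sum()} non-converters, "
      f"{(table.labels == 1).sum()} converters)")
print(f"features: {table.n_features}")
for tag in dict.fromkeys(table.modality_tags):
    feats = table.modality_features(tag)
    n_missing = int(np.isnan(table.columns(feats)).any(axis=1).sum())
    print(f"  {tag:12s} {len(feats):4d} features, "
          f"{table.n_subjects - n_missing} subjects observed")

print(f"\nplanted support ({len(truth.support)} features):")
for name in sorted(truth.support, key=lambda n: -abs(truth.effect_sizes[n])):
    print(f"  {name:28s} d = {truth.effect_sizes[name]:+.2f}")
# d is the converter-minus-nonconverter mean difference in SD units; the
# CSF panel, lab tests, age and education are deliberately null.
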