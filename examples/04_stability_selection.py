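"""Bootstrap stability selection: from selection frequencies to a panel.

Repeatedly refitting the sparse model on bootstrap resamples across a
penalty grid gives each feature a selection frequency per penalty; the
stability score is the maximum frequency over the grid, and features with
score >= tau form the stable set.  A modest bootstrap count is used here so
the example runs in under a minute; the reference configuration is N=1000.
"""

from biosig import (StabilityConfig, default_cohort_spec, generate_cohort,
                    selection_profile, stable_set)

table, truth = generate_cohort(default_cohort_spec(seed=0))
sub = table.subset_features(
    table.modality_features("cognitive", "mri", "demographic", "apoe", "lab"))

cfg = StabilityConfig(n_bootstrap=100, tau=0.5, seed=0)
profile = selection_profile(sub, cfg)
panel = stable_set(profile)

print(f"stable set at tau={cfg.tau}: {len(panel)} features "
      f"(true planted support: {len(truth.support)})")
print(f"{'feature':28s} {'score':>6s}  planted?")
for name in sorted(panel, key=lambda n: -profile.score_of(n)):
    print(f"{name:28s} {profile.score_of(name):6.2f}  "
          f"{'yes' if name in truth.support else 'NO (false positive)'}")
# The score is the fraction of bootstrap fits that selected the feature at
# its best penalty; planted features should dominate the top of the list.
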