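"""Preprocess one small cohort into labelled, standardized 1-Hz features.

Chain: 20-Hz high-pass -> adaptive noise cancellation against the frontalis
reference -> 1-s RMS/waveform-length windows -> Hampel outlier filter ->
period labelling (P0 baseline, P1-P4 pain strata) -> per-test z-scoring.
"""

import painemg

config = painemg.CohortConfig(n_subjects=4, n_excluded_tests=0, seed=7)
cohort = painemg.generate_cohort(config)

features = painemg.preprocess_cohort(cohort)
labelled = painemg.label_table(features, cohort.manifest)
standardized, scale = painemg.standardize_labelled(labelled)

print(f"tests: {len(cohort.tests)}, labelled 1-Hz rows: {len(standardized)}")
print("rows per period:")
print(standardized["period"].value_counts().sort_index().to_string())

# Median standardized corrugator features should climb from P1 to P4 —
# the corrugator envelope grows with the pain stimulus.
profile = painemg.median_profiles(standardized, ["corrms", "corwl", "levwl"])
print(profile.round(2).to_string(index=False))
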