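"""Nonparametric statistics on the full default cohort (~1 min).

Computes subject-level period medians, the pairwise Wilcoxon signed-rank
grid across pain periods, and Spearman correlations of each feature with
the ordinal period index — the evidence base for feature screening.
"""

import painemg

cohort = painemg.generate_cohort(painemg.CohortConfig(seed=1))
features = painemg.preprocess_cohort(cohort)
labelled = painemg.label_table(features, cohort.manifest)
standardized, _ = painemg.standardize_labelled(labelled)

medians = painemg.subject_period_medians(standardized)
grid = painemg.pairwise_period_tests(medians)
print("Wilcoxon signed-rank p-values (n = 31 subjects):")
print(grid.round(4).to_string())
# Expect the corrugator rows significant nearly everywhere and the P2-vs-P3
# column (the pain-threshold transition) strongest overall.

corr = painemg.correlation_matrix(standardized)
rho = corr.loc[list(painemg.FEATURES), "period_index"].sort_values(ascending=False)
print("\nSpearman rho vs period index:")
print(rho.round(3).to_string())
print("\nscreened candidates:", painemg.feature_screening(mode="fixed"))
print("automatic screening:", painemg.feature_screening(standardized, mode="auto"))
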