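"""Meta-learning and final evaluation of the ordinal kNN model (~1 min).

Nested leave-subject-out CV selects a feature subset and k per outer fold;
the modal choice becomes the final model, scored by plain LOSO per subject.
"""

import painemg
from painemg.model import (final_loso_evaluation, nested_loso_cv,
                           select_final_model)

cohort = painemg.generate_cohort(painemg.CohortConfig(seed=1))
features = painemg.preprocess_cohort(cohort)
labelled = painemg.label_table(features, cohort.manifest)
standardized, _ = painemg.standardize_labelled(labelled)

config = painemg.ModelConfig()  # candidates {corrms, corwl, levwl, orbwl}, k in 1..31
cv = nested_loso_cv(standardized, config)
print(f"nested LOSO aggregate c-index: {cv.aggregate:.3f}")
print("fold selections (first 5):")
print(cv.folds.head().to_string(index=False))

subset, k = select_final_model(cv)
per_subject, mean = final_loso_evaluation(standardized, subset, k, config)
print(f"\nfinal model: features={subset}, k={k}")
print(f"final plain-LOSO mean c-index: {mean:.3f} "
      f"(subjects range {per_subject['c_index'].min():.2f}"
      f"-{per_subject['c_index'].max():.2f})")
# c-index 0.5 is chance; ~0.64 is the moderate-but-significant level this
# calibrated cohort is built to reproduce.
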