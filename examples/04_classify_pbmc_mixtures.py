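"""Classifying heterogeneous PBMC mixtures with a derived signature.

Derives the common IFN signature from a sorted-cell cohort, then mixes
cell-type profiles into 20 PBMC samples (Dirichlet-varying composition)
and classifies them by average-linkage clustering on correlation distance.
"""

from ifnsig import (
    classify_samples,
    derive_partition,
    simulate_cohort,
    simulate_pbmc_cohort,
)

cohort = simulate_cohort(seed=5)
part, *_ = derive_partition(cohort)
print(f"common signature: {len(part.common)} probe-sets")

matrix, labels = simulate_pbmc_cohort(cohort, n_case=10, n_control=10, seed=5)
report = classify_samples(matrix, labels, part.common)
print(f"classification: {report.n_correct}/{report.n_total} correct")

# one vaccinee without an interferon response
m2, l2 = simulate_pbmc_cohort(cohort, seed=5, zero_effect_cases={"PBMC_SLE_03"})
r2 = classify_samples(m2, l2, part.common)
print(f"non-responder scenario: misclassified = {r2.misclassified(l2)}")
print(r2.dendrogram.to_newick()[:120] + "...")

print("\nThe k=2 dendrogram cut separates samples with an active IFN\n"
      "signature from baseline samples despite per-sample differences in\n"
      "cell-type composition; the configured non-responder clusters with\n"
      "the controls and is the only misclassified sample.")
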