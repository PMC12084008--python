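"""Classify responders in a simulated two-condition proteomics experiment.

Simulates a 3-vs-3 replicated log2 intensity matrix with planted
positive and negative effects and abundance-dependent missing values,
then runs the standard workflow: 70% valid-value filter, down-shifted
normal imputation, moderated t-test with permutation q-values, and
classification by sign of the fold change and raw p < 0.05.
"""

import ribosig as r

matrix, truth = r.generate_quant_matrix(r.SimQuantParams(
    n_proteins=2000, effect_log2=1.0, noise_sd_log2=0.3, seed=1))
print(f"simulated {matrix.n_proteins} proteins, "
      f"{float(matrix.values.isna().mean().mean()):.1%} missing cells")

matrix = r.filter_valid(matrix, r.FilterParams(min_valid_frac=0.70))
print(f"{matrix.n_proteins} proteins pass the 70% valid-value filter")

matrix = r.impute_downshifted_normal(matrix, r.ImputeParams(width=0.3, shift=1.8, seed=2))
result = r.classify_responders(
    r.differential_test(matrix, r.TestParams(seed=3)), r.TestParams())
counts = result.class_counts
print(f"responders at p<0.05: {counts['positive']} positive, "
      f"{counts['negative']} negative, {counts['non_responder']} unchanged")

# how well did the classes recover the planted truth?
merged = result.table.join(truth.proteins.set_index("protein_id"))
planted = merged["true_class"] != "null"
hit = (merged["class"] == merged["true_class"]) & planted
print(f"recovered {int(hit.sum())} of {int(planted.sum())} planted responders "
      f"that survived filtering")
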