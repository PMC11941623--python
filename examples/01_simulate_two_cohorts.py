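"""Simulate a two-cohort RNA-seq experiment with planted ground truth.

Builds the default synthetic world scaled down (500 genes, 47 early- and
174 late-onset samples split at age 70), then prints what was planted:
modules, differentially expressed genes and perturbed gene sets.
"""

import coexdiff as cd

params = cd.SimParams(n_genes=500, n_modules=5, module_size=30, seed=7)
truth = cd.simulate_truth(params)
design = cd.simulate_design(params)
counts = cd.simulate_counts(truth, design, params)

print(f"samples: {len(design.samples_in('early'))} early / {len(design.samples_in('late'))} late "
      f"(age-at-diagnosis cutoff {design.cutoff:.0f} years)")
print(f"counts matrix: {counts.shape[0]} genes x {counts.shape[1]} samples, "
      f"median library {counts.sum(axis=0).median():.2e} reads")
members = truth.module_members()
print(f"planted: {len(members)} co-expression modules of {params.module_size} genes, "
      f"{len(truth.de_genes)} DE genes at |log2FC| = {params.de_log2fc}, "
      f"{len(truth.perturbed_sets)} coherently up-shifted gene set(s)")
print(f"annotation: {len(truth.annotation)} terms "
      f"({params.n_true_terms} module copies + {params.n_decoy_terms} decoys)")
# The same seed always regenerates this exact dataset, so every downstream
# example can recover the structure printed above.
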