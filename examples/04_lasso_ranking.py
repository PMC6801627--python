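"""Rank marker importance with repeated cross-validated LASSO logistic fits.

Concentrations are log10-transformed and standardized to unit variance, an
L1-penalized logistic model is tuned by 10-fold CV (lambda minimizing the
held-out binomial deviance), and the fit is repeated under re-randomized
folds.  Markers are ranked by the mean absolute standardized coefficient;
the selection frequency says how often each coefficient was nonzero.
"""

from uropanel import apply_exclusions, generate_cohort, paperlike_scenario, rank_by_lasso

cohort, truth = generate_cohort(paperlike_scenario(seed=1))
analyzed = apply_exclusions(cohort)

importance = rank_by_lasso(analyzed, n_iter=50, seed=1)  # 2000 at full scale
print(importance.table.head(8).round(3).to_string(index=False))
print("\nplanted informative markers:", truth.informative)
print("Large mean |coefficient| with selection frequency near 1 marks a "
      "stable contributor; null markers hover near zero.")
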