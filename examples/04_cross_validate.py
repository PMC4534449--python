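"""Score predictive skill with RSF-plot-index cross-validation.

Four folds (Huberty's rule), each predicted by an all-subsets averaged model
fitted on the other three; withheld predictions are pooled, binned by both
quantile and equal-interval rules, and the Pearson correlation between bin
midpoints and observed presence proportions is averaged over iterations.
"""

import pigsdm as pg

X, y = pg.simulate_discrimination_data(n_presence=800, seed=5)
report = pg.cross_validate(X, y, k=4, iterations=5, n_bins=10, seed=11)

print(report.summary().to_string(index=False))
print("\none iteration's quantile bin table:")
tab = report.bin_tables.query("iteration == 0 and method == 'quantile'")
print(tab[["bin", "midpoint", "n", "presence_proportion"]]
      .round(3).to_string(index=False))
print("\nr near 1 means the predicted relative occurrence probability is "
      "proportional to the observed frequency of presence.")
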