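"""Presence-only cross-validation via the RSF plot index.

Discrimination metrics that need true absences (AUC, kappa) are off the table
in a presence-background design, so predictive skill is scored by
proportionality: withheld records are binned by predicted score and the
Pearson correlation between bin prediction midpoints and the observed
fraction of presence records per bin is the index. Records are split into
k = 4 folds (Huberty's rule for this covariate count); each set of three
folds fits the full all-subsets averaged model and predicts the withheld
fold; withheld predictions are pooled within an iteration, binned by both
quantile and equal-interval rules, and the whole procedure is repeated over
fresh random fold allocations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateBinningError
from .model import fit_all_subsets, model_average

BINNING_METHODS = ("quantile", "equal_interval")


def kfold_split(ids, k: int = 4,
                seed: int | np.random.Generator = 0) -> np.ndarray:
    """Seeded random partition into k folds whose sizes differ by at most 1.

    Returns an array of fold labels (0..k−1) aligned with ``ids``.
    """
    ids = np.asarray(ids)
    if k < 2:
        raise ConfigError("k must be at least 2")
    if ids.size < k:
        raise ConfigError(f"cannot split {ids.size} records into {k} folds")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    folds = np.empty(ids.size, dtype=np.int64)
    perm = rng.permutation(ids.size)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


def rsf_plot_index(pred, labels, n_bins: int = 10,
                   method: str = "quantile") -> tuple:
    """Pearson correlation between binned prediction midpoints and observed
    presence proportions.

    ``quantile`` bins hold near-equal record counts and use the median
    predicted value in each bin as its midpoint; ``equal_interval`` bins
    split the score range evenly and use the interval centre. Empty bins are
    dropped. Returns ``(r, bin_table)``.
    """
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels)
    if method not in BINNING_METHODS:
        raise ConfigError(f"unknown binning method {method!r}")
    if n_bins < 2:
        raise ConfigError("n_bins must be at least 2")
    if pred.size != labels.size:
        raise ConfigError("pred and labels must be aligned")
    if np.ptp(pred) == 0:
        raise DegenerateBinningError("all predictions identical")

    if method == "quantile":
        edges = np.unique(np.quantile(pred, np.linspace(0, 1, n_bins + 1)))
    else:
        edges = np.linspace(pred.min(), pred.max(), n_bins + 1)
    # right-closed last edge so the maximum lands in the top bin
    idx = np.clip(np.searchsorted(edges, pred, side="right") - 1,
                  0, len(edges) - 2)

    rows = []
    for b in range(len(edges) - 1):
        in_bin = idx == b
        if not in_bin.any():
            continue
        mid = (float(np.median(pred[in_bin])) if method == "quantile"
               else float((edges[b] + edges[b + 1]) / 2.0))
        rows.append((b, mid, int(in_bin.sum()),
                     float(labels[in_bin].mean())))
    if len(rows) < 2:
        raise DegenerateBinningError(
            f"fewer than 2 non-empty bins (got {len(rows)})")
    table = pd.DataFrame(rows, columns=["bin", "midpoint", "n",
                                        "presence_proportion"])
    if table["midpoint"].nunique() < 2 or table["presence_proportion"].nunique() < 2:
        raise DegenerateBinningError("degenerate bin table: constant axis")
    r = float(stats.pearsonr(table["midpoint"],
                             table["presence_proportion"]).statistic)
    return r, table


@dataclass
class ValidationReport:
    """Per-iteration correlations and their per-method summaries."""

    per_iteration: pd.DataFrame   # iteration, method, r
    bin_tables: pd.DataFrame      # iteration, method, bin rows (long)
    k: int
    iterations: int
    n_bins: int

    def summary(self) -> pd.DataFrame:
        return (self.per_iteration.groupby("method")["r"]
                .agg(["mean", "std", "count"]).reset_index())


def plot_rsf_bins(bin_table: pd.DataFrame, ax=None):
    """RSF plot: bin prediction midpoints against observed presence
    proportions, with a 1:1 reference line. Returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(bin_table["midpoint"], bin_table["presence_proportion"],
               color="k", zorder=3)
    lim = [0, max(bin_table["midpoint"].max(),
                  bin_table["presence_proportion"].max()) * 1.05]
    ax.plot(lim, lim, ls="--", color="grey", lw=1)
    ax.set_xlabel("predicted bin midpoint")
    ax.set_ylabel("observed proportion present")
    return ax


def cross_validate(X: pd.DataFrame, y, k: int = 4, iterations: int = 100,
                   n_bins: int = 10, methods=BINNING_METHODS,
                   marginality: bool = True, form: str = "logistic",
                   seed: int | np.random.SeedSequence = 0) -> ValidationReport:
    """k-fold RSF-plot cross-validation of the averaged model.

    Per iteration: a fresh random fold allocation; each fold is predicted by
    the all-subsets averaged model fitted on the remaining folds; withheld
    predictions are pooled and scored per binning method.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    iter_rows, bin_rows = [], []
    for it in range(iterations):
        folds = kfold_split(np.arange(len(y)), k=k, seed=rng)
        pooled = np.empty(len(y), dtype=float)
        for f in range(k):
            test = folds == f
            fits = fit_all_subsets(X.loc[~test], y[~test],
                                   marginality=marginality)
            avg = model_average(fits)
            pooled[test] = avg.predict(X.loc[test], form=form).to_numpy()
        for method in methods:
            r, table = rsf_plot_index(pooled, y, n_bins=n_bins, method=method)
            iter_rows.append((it, method, r))
            table.insert(0, "method", method)
            table.insert(0, "iteration", it)
            bin_rows.append(table)
    return ValidationReport(
        per_iteration=pd.DataFrame(iter_rows,
                                   columns=["iteration", "method", "r"]),
        bin_tables=pd.concat(bin_rows, ignore_index=True),
        k=k, iterations=iterations, n_bins=n_bins)
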