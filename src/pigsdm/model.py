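"""Logistic discrimination function with all-subsets AICc model averaging.

The global model holds the seven standardized habitat covariates plus a
quadratic term for hot days (suitability rises with hot days up to an
optimum). Every additive subset is fitted by maximum-likelihood logistic
regression of presence (1) versus background (0) records; subsets are ranked
by AICc and combined by Akaike-weight model averaging with shrinkage (a term
absent from a subset contributes a zero coefficient), yielding unconditional
standard errors, 95 % confidence intervals, and cumulative-weight variable
importances. The exponential form exp(eta) of the averaged model, without
intercept, maps relative occurrence probability in the resource-selection
convention; the logistic form includes the intercept.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError, ScaleError
from .synthetic import ALL_TERMS, LINEAR_TERMS, QUAD_TERM

Z_95 = 1.959964  # two-sided 95 % normal quantile

INTERCEPT = "intercept"


# ---------------------------------------------------------------------------
# design construction

def build_design(covariates, sample) -> tuple[pd.DataFrame, np.ndarray]:
    """Record-level design matrix (8 model terms) and 0/1 labels.

    ``covariates`` must be a standardized CovariateTable; the quadratic term
    is the square of the standardized hot-day covariate. ``sample`` is a
    SampleDesign; a watershed drawn into both samples contributes one row per
    membership.
    """
    from .covariates import CovariateTable

    if isinstance(covariates, CovariateTable):
        if not covariates.standardized:
            raise ScaleError("design requires standardized covariates")
        z = covariates.data
    else:
        raise ScaleError("expected a CovariateTable")
    X = z.loc[sample.record_ids, list(LINEAR_TERMS)].reset_index(drop=True)
    X[QUAD_TERM] = X["days_above_35"] ** 2
    return X, sample.labels


# ---------------------------------------------------------------------------
# collinearity screen

@dataclass
class CollinearityReport:
    pairwise_r: pd.DataFrame
    vif: pd.Series
    flagged: list
    r_cut: float
    vif_cut: float


def collinearity_screen(X: pd.DataFrame, r_cut: float = 0.7,
                        vif_cut: float = 10.0) -> CollinearityReport:
    """Pairwise Pearson correlations and variance inflation factors.

    Terms exceeding either cutoff are flagged, never dropped — exclusion is
    the caller's decision. A singular design yields infinite VIF.
    """
    if X.shape[1] < 2:
        raise ConfigError("collinearity screen needs at least two columns")
    if (X.std(ddof=0) == 0).any():
        raise ConfigError("constant column in design")
    r = X.corr()
    cols = list(X.columns)
    A = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    vifs = {}
    for j, c in enumerate(cols):
        yj = A[:, 1 + j]
        others = np.delete(A, 1 + j, axis=1)
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        sst = ((yj - yj.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / sst
        vifs[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    vif = pd.Series(vifs, name="vif")
    flagged = sorted(
        set(vif.index[vif > vif_cut])
        | {c for i, c in enumerate(cols) for d in cols[i + 1:]
           if abs(r.loc[c, d]) > r_cut}
        | {d for i, c in enumerate(cols) for d in cols[i + 1:]
           if abs(r.loc[c, d]) > r_cut})
    return CollinearityReport(pairwise_r=r, vif=vif, flagged=flagged,
                              r_cut=r_cut, vif_cut=vif_cut)


# ---------------------------------------------------------------------------
# maximum-likelihood logistic fit

@dataclass
class LogisticFit:
    """One converged (or warning-carrying) ML logistic regression."""

    terms: tuple
    params: pd.Series          # indexed intercept + terms
    bse: pd.Series
    llf: float
    n: int
    converged: bool
    warnings: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.params)


def fit_logistic(X, y, terms: tuple | None = None, max_iter: int = 60,
                 tol: float = 1e-8) -> LogisticFit:
    """Newton–Raphson ML logistic regression with an always-on intercept.

    Converged when the score (gradient) norm falls below ``tol``. Standard
    errors come from the inverse observed information. Quasi-separation is
    detected (diverging coefficients / vanishing curvature) and recorded as a
    warning on the returned fit rather than raised.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ConfigError("labels must be 0/1")
    if y.min() == y.max():
        raise ConfigError("both classes must be present")
    if terms is None:
        terms = tuple(X.columns)
    A = np.column_stack([np.ones(len(X))] + [X[t].to_numpy(float) for t in terms])
    names = [INTERCEPT, *terms]
    beta = np.zeros(A.shape[1])
    beta[0] = np.log(y.mean() / (1 - y.mean()))
    warnings_: list = []
    converged = False
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = A @ beta
        mu = expit(eta)
        g = A.T @ (y - mu)
        w = mu * (1 - mu)
        H = (A * w[:, None]).T @ A
        if np.linalg.norm(g) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
            warnings_.append("singular information matrix")
        # step-halving on the log-likelihood
        ll = _loglik(A, beta, y)
        lam = 1.0
        for _h in range(30):
            cand = beta + lam * step
            if _loglik(A, cand, y) >= ll - 1e-12:
                break
            lam *= 0.5
        beta = beta + lam * step
        ll_new = _loglik(A, beta, y)
        if abs(ll_new - ll_old) < 1e-12 and np.linalg.norm(g) < 1e-4:
            converged = True
            break
        ll_old = ll_new
    if np.abs(beta).max() > 25:
        warnings_.append("possible separation: diverging coefficients")
    if not converged and not warnings_:
        warnings_.append("did not converge")
    eta = A @ beta
    mu = expit(eta)
    w = mu * (1 - mu)
    H = (A * w[:, None]).T @ A
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        warnings_.append("singular information matrix")
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return LogisticFit(
        terms=tuple(terms),
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        llf=_loglik(A, beta, y),
        n=len(y),
        converged=converged,
        warnings=warnings_,
    )


def _loglik(A: np.ndarray, beta: np.ndarray, y: np.ndarray) -> float:
    eta = A @ beta
    # log(1+e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


# ---------------------------------------------------------------------------
# information criteria and subset enumeration

def aicc(llf: float, k: int, n: int) -> float:
    """AICc = −2·logLik + 2k + 2k(k+1)/(n−k−1)."""
    if n <= k + 1:
        raise ConfigError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def enumerate_subsets(terms: tuple = ALL_TERMS,
                      marginality: bool = True) -> list:
    """All additive subsets of the global model, null model included.

    With marginality on, the hot-day quadratic enters only alongside its
    linear term.
    """
    terms = tuple(terms)
    subsets = []
    for r in range(len(terms) + 1):
        for comb in itertools.combinations(terms, r):
            if marginality and QUAD_TERM in comb and "days_above_35" not in comb:
                continue
            subsets.append(comb)
    return subsets


# ---------------------------------------------------------------------------
# ledger and averaging

@dataclass
class SubsetFit:
    """One row of the all-subsets ledger."""

    terms: tuple
    fit: LogisticFit
    k: int
    aicc: float
    delta: float = np.nan
    weight: float = np.nan


def fit_all_subsets(X: pd.DataFrame, y: np.ndarray,
                    marginality: bool = True,
                    terms: tuple | None = None) -> list:
    """Fit every additive subset and compute AICc deltas and Akaike weights."""
    if terms is None:
        terms = tuple(X.columns)
    fits = []
    for sub in enumerate_subsets(terms, marginality=marginality):
        f = fit_logistic(X, y, terms=sub)
        fits.append(SubsetFit(terms=sub, fit=f, k=f.k,
                              aicc=aicc(f.llf, f.k, f.n)))
    best = min(f.aicc for f in fits)
    raw = np.array([np.exp(-(f.aicc - best) / 2.0) for f in fits])
    w = raw / raw.sum()
    for f, d, wi in zip(fits, (f.aicc - best for f in fits), w):
        f.delta = float(d)
        f.weight = float(wi)
    return fits


def ledger_frame(fits: list) -> pd.DataFrame:
    return pd.DataFrame({
        "terms": ["+".join(f.terms) if f.terms else "(null)" for f in fits],
        "k": [f.k for f in fits],
        "logLik": [f.fit.llf for f in fits],
        "AICc": [f.aicc for f in fits],
        "delta_AICc": [f.delta for f in fits],
        "weight": [f.weight for f in fits],
        "warnings": [";".join(f.fit.warnings) for f in fits],
    }).sort_values("delta_AICc", kind="stable").reset_index(drop=True)


@dataclass
class AveragedModel:
    """Model-averaged coefficients with unconditional errors.

    ``table`` is indexed by term with columns estimate, se, ci_low, ci_high,
    importance; the intercept appears in every subset so its importance is 1.
    ``meta`` carries the standardization used to build the design, so the
    hot-day optimum can be reported on the natural (days/yr) scale.
    """

    table: pd.DataFrame
    meta: object | None = None

    @property
    def coef(self) -> pd.Series:
        return self.table["estimate"]

    def linear_predictor(self, covariates, include_intercept: bool) -> pd.Series:
        from .covariates import CovariateTable

        if isinstance(covariates, CovariateTable):
            if not covariates.standardized:
                raise ScaleError("prediction requires standardized covariates")
            z = covariates.data
        elif isinstance(covariates, pd.DataFrame):
            z = covariates
        else:
            raise ScaleError("expected a CovariateTable or term DataFrame")
        eta = pd.Series(0.0, index=z.index)
        for term, b in self.coef.items():
            if term == INTERCEPT:
                continue
            if term in z.columns:
                col = z[term]
            elif term == QUAD_TERM:
                col = z["days_above_35"] ** 2
            else:
                raise ConfigError(f"term {term!r} missing from covariates")
            eta = eta + b * col
        if include_intercept:
            eta = eta + self.coef.get(INTERCEPT, 0.0)
        return eta

    def predict(self, covariates, form: str = "exponential") -> pd.Series:
        """Relative occurrence score per watershed.

        ``exponential``: exp(eta) without intercept (RSF convention — only
        relative values are meaningful); ``logistic``: inverse-logit with the
        intercept included.
        """
        if form == "exponential":
            return np.exp(self.linear_predictor(covariates, include_intercept=False))
        if form == "logistic":
            eta = self.linear_predictor(covariates, include_intercept=True)
            return pd.Series(expit(eta), index=eta.index)
        raise ConfigError(f"unknown prediction form {form!r}")

    def quadratic_optimum(self) -> dict:
        """Hot-day count maximizing suitability, from −b1/(2·b2).

        Returns the optimum on the standardized scale and, when
        standardization metadata is attached, on the natural days/yr scale.
        """
        b1 = self.coef["days_above_35"]
        b2 = self.coef[QUAD_TERM]
        if b2 == 0:
            raise ConfigError("no curvature: quadratic coefficient is zero")
        z_star = -b1 / (2.0 * b2)
        out = {"z_star": float(z_star), "natural": None}
        if self.meta is not None:
            out["natural"] = float(self.meta.mean["days_above_35"]
                                   + self.meta.sd["days_above_35"] * z_star)
        return out


def model_average(fits: list, meta=None) -> AveragedModel:
    """Akaike-weight averaging with shrinkage over a complete subset ledger.

    estimate_j = sum_i w_i b_ij with b_ij = 0 when term j is absent from
    subset i; unconditional SE_j = sum_i w_i sqrt(se_ij² + (b_ij − estimate_j)²)
    (se_ij = 0 for absent terms); importance_j = sum of w_i over subsets
    containing j; 95 % CI = estimate ± 1.959964·SE.
    """
    if not fits:
        raise ConfigError("empty subset ledger")
    w = np.array([f.weight for f in fits])
    if not np.isfinite(w).all() or abs(w.sum() - 1.0) > 1e-8:
        raise ConfigError("ledger weights must be computed and sum to 1")
    terms = [INTERCEPT] + [t for t in ALL_TERMS
                           if any(t in f.terms for f in fits)]
    # keep ledger term order for non-canonical term sets
    extra = [t for f in fits for t in f.terms if t not in terms]
    terms += list(dict.fromkeys(extra))

    est, se, imp = {}, {}, {}
    for t in terms:
        b = np.array([f.fit.params.get(t, 0.0) for f in fits])
        s = np.array([f.fit.bse.get(t, 0.0) for f in fits])
        est[t] = float(w @ b)
        se[t] = float(w @ np.sqrt(s**2 + (b - est[t]) ** 2))
        imp[t] = float(w[[t == INTERCEPT or t in f.terms
                          for f in fits]].sum())
    table = pd.DataFrame({
        "estimate": pd.Series(est),
        "se": pd.Series(se),
        "importance": pd.Series(imp),
    }).loc[terms]
    table["ci_low"] = table["estimate"] - Z_95 * table["se"]
    table["ci_high"] = table["estimate"] + Z_95 * table["se"]
    table = table[["estimate", "se", "ci_low", "ci_high", "importance"]]
    return AveragedModel(table=table, meta=meta)
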