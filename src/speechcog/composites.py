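"""Composite cognitive domain scores from individual test scores.

Pipeline: (1) flag outliers per test by demographic regression (|z| > 4 on
the residual scale) and set them missing, (2) impute missing cells with a
round-robin Bayesian-ridge regression strategy over the remaining test
scores, (3) fit a confirmatory factor analysis (CFA) with four correlated
factors — language, executive function, memory, speed — under a fixed
sparse loading pattern (Trail Making Test A cross-loads on executive
function and speed), (4) extract regression-method factor scores and
standardize them to mean 0, SD 1.

The CFA is a maximum-likelihood fit of the model-implied covariance
``Sigma = L Phi L' + Psi`` (unit factor variances, free correlations,
diagonal residuals) minimised with L-BFGS-B.  Fit indices (CFI, TLI, RMSEA)
are the standard ML versions computed from the model and independence
chi-squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "DEFAULT_TESTS", "DOMAINS", "FactorModelSpec", "FactorModelFit",
    "default_factor_spec", "flag_outliers_by_demographic_regression",
    "impute_round_robin", "fit_factor_model", "standardize_columns",
]

DOMAINS = ("language", "executive_function", "memory", "speed")

#: Test battery outcome measures, sign-harmonised so higher = better
#: (completion times and reaction times enter negated upstream).
DEFAULT_TESTS = (
    "trail_making_a", "trail_making_b", "ravlt_learning", "ravlt_recall",
    "reaction_time", "tol_extra_moves", "corsi", "pegboard", "digit_span",
    "clicking_speed", "mouse_drag", "phonemic_fluency", "semantic_fluency",
    "boston_naming",
)


@dataclass
class FactorModelSpec:
    """Sparse test -> factor loading pattern for the four-domain CFA."""

    factors: tuple[str, ...]
    pattern: dict[str, list[str]]  # test name -> factors it loads on

    def __post_init__(self):
        for test, facs in self.pattern.items():
            if not facs:
                raise ValueError(f"test {test!r} loads on no factor")
            unknown = set(facs) - set(self.factors)
            if unknown:
                raise ValueError(f"unknown factors {unknown} for {test!r}")

    @property
    def tests(self) -> list[str]:
        return list(self.pattern)

    def loading_entries(self) -> list[tuple[int, int]]:
        """(row=test index, col=factor index) of free loadings."""
        fidx = {f: j for j, f in enumerate(self.factors)}
        out = []
        for i, t in enumerate(self.tests):
            for f in self.pattern[t]:
                out.append((i, fidx[f]))
        return out


def default_factor_spec() -> FactorModelSpec:
    """The study's four-domain assignment.  Each test loads on one domain;
    Trail Making Test A cross-loads on executive function and speed."""
    return FactorModelSpec(
        factors=DOMAINS,
        pattern={
            "phonemic_fluency": ["language"],
            "semantic_fluency": ["language"],
            "boston_naming": ["language"],
            "trail_making_b": ["executive_function"],
            "tol_extra_moves": ["executive_function"],
            "corsi": ["executive_function"],
            "digit_span": ["executive_function"],
            "ravlt_learning": ["memory"],
            "ravlt_recall": ["memory"],
            "reaction_time": ["speed"],
            "pegboard": ["speed"],
            "clicking_speed": ["speed"],
            "mouse_drag": ["speed"],
            "trail_making_a": ["executive_function", "speed"],
        },
    )


# ---------------------------------------------------------------------------
# Outlier flagging
# ---------------------------------------------------------------------------

def _demographic_design(demographics: pd.DataFrame) -> np.ndarray:
    """Intercept + age + female + high education + UK indicator columns."""
    cols = [np.ones(len(demographics)), demographics["age"].to_numpy(float)]
    for name in ("gender", "education", "country"):
        col = demographics[name]
        if col.dtype == object:
            ref = sorted(col.unique())[0]
            cols.append((col != ref).to_numpy(float))
        else:
            cols.append(col.to_numpy(float))
    return np.column_stack(cols)


def flag_outliers_by_demographic_regression(
        scores: pd.DataFrame, demographics: pd.DataFrame,
        z_cap: float = 4.0, min_observed: int = 10,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per test: OLS on demographic predictors; observations whose residual
    z exceeds ``z_cap`` in absolute value are set missing.

    Columns with fewer than ``min_observed`` observed values are skipped
    with a warning, as are zero-residual-variance columns (z undefined,
    no flags).  Returns (table with outliers set missing, per-test counts).
    """
    if demographics.isna().any().any():
        raise ValueError("demographics must be complete for outlier "
                         "regression")
    X_full = _demographic_design(demographics)
    out = scores.copy()
    report: dict[str, int] = {}
    for col in scores.columns:
        y = scores[col].to_numpy(float)
        obs = np.isfinite(y)
        if obs.sum() < min_observed:
            warnings.warn(f"column {col!r} has <{min_observed} observed "
                          "values; outlier flagging skipped")
            report[col] = 0
            continue
        X = X_full[obs]
        beta, *_ = np.linalg.lstsq(X, y[obs], rcond=None)
        resid = y[obs] - X @ beta
        sd = resid.std(ddof=X.shape[1])
        if sd <= 1e-12:
            report[col] = 0
            continue
        z = resid / sd
        flags = np.abs(z) > z_cap
        idx = np.flatnonzero(obs)[flags]
        out.iloc[idx, out.columns.get_loc(col)] = np.nan
        report[col] = int(flags.sum())
    return out, report


# ---------------------------------------------------------------------------
# Round-robin imputation
# ---------------------------------------------------------------------------

def impute_round_robin(table: pd.DataFrame, max_iter: int = 20,
                       tol: float = 1e-3, seed: int = 0) -> pd.DataFrame:
    """Iterative column-by-column regression imputation (Bayesian ridge)
    over the remaining score columns, visiting columns left-to-right,
    initialised with column means.  Deterministic given ``seed``.

    Observed cells are never altered.  Requires >= 1 observed value per row
    and >= 2 per column; an all-missing column raises.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer
    from sklearn.linear_model import BayesianRidge

    vals = table.to_numpy(float)
    if np.any((~np.isfinite(vals)).all(axis=0)):
        raise ValueError("a column is entirely missing; cannot impute")
    if np.any((~np.isfinite(vals)).all(axis=1)):
        raise ValueError("a row is entirely missing; cannot impute")
    col_obs = np.isfinite(vals).sum(axis=0)
    if np.any(col_obs < 2):
        raise ValueError("every column needs at least 2 observed values")
    if not np.isnan(vals).any():
        return table.copy()
    imp = IterativeImputer(estimator=BayesianRidge(), max_iter=max_iter,
                           tol=tol, imputation_order="roman",
                           initial_strategy="mean", sample_posterior=False,
                           random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter
        filled = imp.fit_transform(vals)
    out = table.copy()
    out.iloc[:, :] = filled
    return out


# ---------------------------------------------------------------------------
# Confirmatory factor analysis
# ---------------------------------------------------------------------------

@dataclass
class FactorModelFit:
    spec: FactorModelSpec
    loadings: pd.DataFrame          # tests x factors
    factor_corr: pd.DataFrame       # factors x factors
    residual_var: pd.Series         # per test
    chi2: float
    df: int
    cfi: float
    tli: float
    rmsea: float
    factor_scores: pd.DataFrame     # participants x factors
    converged: bool
    heywood: list[str] = field(default_factory=list)
    n_obs: int = 0


def _build_sigma(lam: np.ndarray, phi: np.ndarray,
                 psi: np.ndarray) -> np.ndarray:
    return lam @ phi @ lam.T + np.diag(psi)


def fit_factor_model(table: pd.DataFrame,
                     spec: FactorModelSpec | None = None,
                     max_iter: int = 500) -> FactorModelFit:
    """Maximum-likelihood CFA under the fixed loading pattern.

    Factor variances are fixed at 1 (correlations free), residual variances
    diagonal.  Raises on non-convergence; Heywood cases (residual variances
    at the lower bound) are reported, not silently accepted.  Factor scores
    use the regression method ``f = Phi L' Sigma^{-1} (x - mu)``.
    """
    spec = spec or default_factor_spec()
    tests = spec.tests
    missing = set(tests) - set(table.columns)
    if missing:
        raise ValueError(f"table lacks test columns {missing}")
    data = table[tests].to_numpy(float)
    if np.isnan(data).any():
        raise ValueError("table must be complete (impute first)")
    n, p = data.shape
    k = len(spec.factors)
    entries = spec.loading_entries()
    n_lam = len(entries)
    n_phi = k * (k - 1) // 2
    n_free = n_lam + n_phi + p
    if n <= n_free:
        raise ValueError("not enough observations for the free parameters")
    S = np.cov(data, rowvar=False, ddof=1)
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance is singular")
    tri = np.tril_indices(k, -1)
    diag_S = np.diag(S)

    def unpack(theta):
        lam = np.zeros((p, k))
        for val, (i, j) in zip(theta[:n_lam], entries):
            lam[i, j] = val
        phi = np.eye(k)
        phi[tri] = theta[n_lam:n_lam + n_phi]
        phi.T[tri] = phi[tri]
        psi = theta[n_lam + n_phi:]
        return lam, phi, psi

    def objective(theta):
        lam, phi, psi = unpack(theta)
        sigma = _build_sigma(lam, phi, psi)
        sign_m, logdet = np.linalg.slogdet(sigma)
        if sign_m <= 0:
            return 1e6
        try:
            inv = np.linalg.inv(sigma)
        except np.linalg.LinAlgError:
            return 1e6
        return logdet + np.trace(S @ inv) - logdet_S - p

    x0 = np.concatenate([
        np.full(n_lam, 0.7) * np.sqrt([diag_S[i] for i, _ in entries]),
        np.full(n_phi, 0.3),
        0.5 * diag_S,
    ])
    bounds = ([(None, None)] * n_lam + [(-0.95, 0.95)] * n_phi
              + [(1e-6, None)] * p)
    res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": max_iter, "maxfun": 10 * max_iter * len(x0)})
    if not res.success and res.fun > 1e5:
        raise RuntimeError(f"CFA did not converge: {res.message}")
    lam, phi, psi = unpack(res.x)
    heywood = [tests[i] for i in range(p) if psi[i] <= 2e-6]

    chi2 = (n - 1) * max(res.fun, 0.0)
    df = p * (p + 1) // 2 - n_free
    # independence baseline
    f_base = logdet_S_diag = float(np.sum(np.log(diag_S)))
    f_base = logdet_S_diag - logdet_S
    chi2_b = (n - 1) * max(f_base, 0.0)
    df_b = p * (p - 1) // 2
    if df > 0:
        num = max(chi2 - df, 0.0)
        den = max(chi2_b - df_b, num, 1e-12)
        cfi = 1.0 - num / den
        rb = chi2_b / df_b
        rm = chi2 / df
        tli = (rb - rm) / (rb - 1.0) if rb > 1 else 1.0
        tli = min(tli, 1.0)
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    else:
        cfi, tli, rmsea = 1.0, 1.0, 0.0

    sigma = _build_sigma(lam, phi, psi)
    inv = np.linalg.inv(sigma)
    centered = data - data.mean(axis=0)
    scores = centered @ inv @ lam @ phi

    return FactorModelFit(
        spec=spec,
        loadings=pd.DataFrame(lam, index=tests, columns=list(spec.factors)),
        factor_corr=pd.DataFrame(phi, index=list(spec.factors),
                                 columns=list(spec.factors)),
        residual_var=pd.Series(psi, index=tests),
        chi2=float(chi2), df=int(df), cfi=float(cfi), tli=float(tli),
        rmsea=float(rmsea),
        factor_scores=pd.DataFrame(scores, index=table.index,
                                   columns=list(spec.factors)),
        converged=bool(res.success), heywood=heywood, n_obs=n,
    )


def standardize_columns(scores: pd.DataFrame) -> pd.DataFrame:
    """Subtract the column mean and divide by the column SD (ddof=1).
    Constant columns raise."""
    sd = scores.std(ddof=1)
    if (sd <= 1e-12).any():
        bad = list(sd.index[sd <= 1e-12])
        raise ValueError(f"constant columns cannot be standardized: {bad}")
    return (scores - scores.mean()) / sd
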