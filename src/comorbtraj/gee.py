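"""Logistic GEE for yearly comorbidity-trajectory models.

Per comorbidity, binary presence indicators over the five yearly pre-index
intervals are modelled marginally as

    logit Pr(Y_it = 1) = eta + alpha * AD_i + beta * (t - t_bar)
                         + gamma * AD_i * (t - t_bar)

where t increases toward the index date (t = 6 - k for interval k), AD_i is
the case indicator, and t_bar is the mean follow-up time (3 for complete
panels).  With centered time the fitted alpha is directly the case-vs-control
log-odds difference at the mean follow-up time.  Estimation is Fisher scoring
on the generalized estimating equations with an unstructured, exchangeable or
independence working correlation across the five yearly outcomes;
uncertainty comes from the Huber-White sandwich (robust) covariance
clustered on person.

The solver exploits the balanced panel layout (every member contributes the
same number of intervals) and is fully vectorized over members, which is what
makes whole-cohort refits and bootstrap/simulation suites cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

PARAM_NAMES = ("eta", "alpha", "beta", "gamma")
CORRELATION_FALLBACK = ("unstructured", "exchangeable", "independence")


class ConvergenceError(RuntimeError):
    """GEE iteration diverged or produced a singular solve."""


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of the per-comorbidity trajectory model.

    ``time_coding`` maps interval k (years prior, 1..K) to the time covariate
    t; the default t = K + 1 - k makes t increase toward the index date so a
    positive gamma means the comorbidity rises toward diagnosis in cases.
    ``t_bar`` centers time (default: mean of the observed t, i.e. 3 for
    complete 5-interval panels); set ``t_bar=0`` for the uncentered
    parameterization.
    """

    time_coding: Mapping[int, float] | None = None
    t_bar: float | None = None
    working_correlation: str = "unstructured"
    max_iter: int = 200
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.working_correlation not in CORRELATION_FALLBACK:
            raise ValueError(f"unknown working correlation {self.working_correlation!r}")

    def t_values(self, n_intervals: int) -> np.ndarray:
        if self.time_coding is None:
            t = np.array([n_intervals + 1 - k for k in range(1, n_intervals + 1)], float)
        else:
            t = np.array([self.time_coding[k] for k in range(1, n_intervals + 1)], float)
        if n_intervals > 1 and not (np.diff(t) < 0).all():
            # k counts years prior, so t must decrease in k to increase in calendar time
            raise ValueError("time coding must increase toward the index date")
        return t

    def centering(self, t: np.ndarray) -> float:
        t_bar = float(np.mean(t)) if self.t_bar is None else float(self.t_bar)
        if self.t_bar is not None and len(t) > 1 and not (min(t) <= t_bar <= max(t)) and t_bar != 0.0:
            raise ValueError("t_bar must lie within the observed time range (or be 0)")
        return t_bar


@dataclass
class GeeFit:
    """Estimates and robust inference for one comorbidity."""

    label: str
    params: np.ndarray                   # (eta, alpha, beta, gamma)
    cov: np.ndarray                      # 4x4 robust (sandwich) covariance
    converged: bool
    correlation: str                     # working correlation actually used
    working_R: np.ndarray | None
    t_bar: float
    n_members: int
    n_obs: int
    n_iter: int = 0
    p_alpha_centered: float = np.nan
    p_gamma: float = np.nan
    q_alpha_centered: float | None = None
    q_gamma: float | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def __getattr__(self, name: str):
        if name in PARAM_NAMES:
            return float(self.params[PARAM_NAMES.index(name)])
        raise AttributeError(name)


def _estimate_correlation(E: np.ndarray, n_params: int, structure: str) -> np.ndarray:
    """Working correlation from Pearson residuals E (n_members x T)."""
    n, T = E.shape
    phi = (E**2).sum() / max(n * T - n_params, 1)
    if structure == "unstructured":
        R = (E.T @ E) / (max(n - n_params, 1) * phi)
        d = np.sqrt(np.clip(np.diag(R), 1e-12, None))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        off = ~np.eye(T, dtype=bool)
        R[off] = np.clip(R[off], -0.99, 0.99)
        return R
    if structure == "exchangeable":
        cross = (E.sum(axis=1) ** 2 - (E**2).sum(axis=1)).sum() / 2.0
        denom = max(n * T * (T - 1) / 2 - n_params, 1) * phi
        rho = float(np.clip(cross / denom, -1.0 / (T - 1) + 1e-6, 0.99))
        return (1 - rho) * np.eye(T) + rho * np.ones((T, T))
    return np.eye(T)


def gee_logistic(
    y: np.ndarray,
    X: np.ndarray,
    working_correlation: str = "independence",
    max_iter: int = 200,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool, int]:
    """Solve the logistic GEE on a balanced panel.

    Parameters
    ----------
    y : (n_members, T) binary outcomes.
    X : (n_members, T, p) covariate array.

    Returns ``(params, robust_cov, working_R, converged, n_iter)``.  The
    sandwich covariance is clustered on the member (first axis).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, T = y.shape
    p = X.shape[2]
    structure = working_correlation if T > 1 else "independence"

    beta = np.zeros(p)
    R = np.eye(T)
    Rinv = np.eye(T)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lin = X @ beta
        if not np.isfinite(lin).all() or np.abs(beta).max() > 50:
            raise ConvergenceError("diverging linear predictor")
        mu = expit(np.clip(lin, -30, 30))
        v = mu * (1 - mu)
        sv = np.sqrt(v)
        E = (y - mu) / sv
        if structure != "independence" and it > 1:
            R = _estimate_correlation(E, p, structure)
            try:
                Rinv = np.linalg.inv(R)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError("singular working correlation") from exc
        W = sv[:, :, None] * X
        B = np.einsum("nti,ts,nsj->ij", W, Rinv, W, optimize=True)
        U = np.einsum("nti,ts,ns->i", W, Rinv, E, optimize=True)
        try:
            step = np.linalg.solve(B, U)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular estimating-equation solve") from exc
        if not np.isfinite(step).all():
            raise ConvergenceError("non-finite update step")
        beta = beta + step
        if np.abs(step).max() < tol * (1 + np.abs(beta).max()):
            converged = True
            break

    # sandwich at the final estimate (phi cancels between bread and meat)
    mu = expit(np.clip(X @ beta, -30, 30))
    sv = np.sqrt(mu * (1 - mu))
    E = (y - mu) / sv
    if structure != "independence":
        R = _estimate_correlation(E, p, structure)
        Rinv = np.linalg.inv(R)
    W = sv[:, :, None] * X
    B = np.einsum("nti,ts,nsj->ij", W, Rinv, W, optimize=True)
    S = np.einsum("nti,ts,ns->ni", W, Rinv, E, optimize=True)
    M = S.T @ S
    try:
        Binv = np.linalg.inv(B)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError("singular bread matrix") from exc
    cov = Binv @ M @ Binv
    cov = (cov + cov.T) / 2
    return beta, cov, R, converged, it


def trajectory_design(
    is_case: np.ndarray, t: np.ndarray, t_bar: float
) -> np.ndarray:
    """(n, T, 4) design: intercept, AD, centered time, AD x centered time."""
    n, T = len(is_case), len(t)
    tc = t - t_bar
    X = np.empty((n, T, 4))
    X[:, :, 0] = 1.0
    X[:, :, 1] = np.asarray(is_case, float)[:, None]
    X[:, :, 2] = tc[None, :]
    X[:, :, 3] = X[:, :, 1] * tc[None, :]
    return X


def fit_trajectory_gee(
    y: np.ndarray,
    is_case: np.ndarray,
    spec: ModelSpec | None = None,
    label: str = "",
    fallback: bool = True,
) -> GeeFit:
    """Fit the trajectory model for one comorbidity.

    On non-convergence of the requested working correlation the fit falls
    back along unstructured -> exchangeable -> independence (when ``fallback``
    is true); a degenerate outcome (all-0/all-1, or a singular solve at every
    structure) yields ``converged=False`` with NaN estimates, to be excluded
    downstream.
    """
    spec = spec or ModelSpec()
    y = np.asarray(y, float)
    is_case = np.asarray(is_case)
    n, T = y.shape
    t = spec.t_values(T)
    t_bar = spec.centering(t)
    X = trajectory_design(is_case, t, t_bar)

    def failed(corr: str) -> GeeFit:
        return GeeFit(
            label=label, params=np.full(4, np.nan), cov=np.full((4, 4), np.nan),
            converged=False, correlation=corr, working_R=None, t_bar=t_bar,
            n_members=n, n_obs=n * T,
        )

    if y.min() == y.max():
        return failed(spec.working_correlation)

    start = CORRELATION_FALLBACK.index(spec.working_correlation)
    chain = CORRELATION_FALLBACK[start:] if fallback else (spec.working_correlation,)
    for corr in chain:
        try:
            params, cov, R, converged, n_iter = gee_logistic(
                y, X, corr, spec.max_iter, spec.tol
            )
        except ConvergenceError:
            continue
        if not converged:
            continue
        se = np.sqrt(np.diag(cov))
        return GeeFit(
            label=label, params=params, cov=cov, converged=True, correlation=corr,
            working_R=R, t_bar=t_bar, n_members=n, n_obs=n * T, n_iter=n_iter,
            p_alpha_centered=wald_p(params[1], se[1]),
            p_gamma=wald_p(params[3], se[3]),
        )
    return failed(chain[-1])


def centered_alpha(fit: GeeFit, t_bar: float) -> tuple[float, float]:
    """Case-vs-control effect at the mean follow-up time from an uncentered fit.

    estimate = alpha + gamma * t_bar; the standard error comes from the delta
    method: var = var(alpha) + t_bar^2 var(gamma) + 2 t_bar cov(alpha, gamma).
    Equals the alpha of a centered-time refit.
    """
    if fit.cov is None or not np.isfinite(fit.cov).all():
        raise ValueError("fit has no covariance; cannot compute centered alpha")
    est = fit.params[1] + fit.params[3] * t_bar
    var = fit.cov[1, 1] + t_bar**2 * fit.cov[3, 3] + 2 * t_bar * fit.cov[1, 3]
    return float(est), float(np.sqrt(var))


def wald_p(estimate: float, se: float) -> float:
    """Two-sided Wald p-value against the standard normal reference."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return float(2 * stats.norm.sf(abs(estimate / se)))


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def odds_ratio_table(fits: Sequence[GeeFit]) -> pd.DataFrame:
    """OR = exp(estimate) with 95% Wald CIs for the centered alpha and gamma."""
    z = stats.norm.ppf(0.975)
    rows = []
    for f in fits:
        se = f.se
        rows.append(
            {
                "comorbidity": f.label,
                "or_alpha": np.exp(f.params[1]),
                "or_alpha_lo": np.exp(f.params[1] - z * se[1]),
                "or_alpha_hi": np.exp(f.params[1] + z * se[1]),
                "or_gamma": np.exp(f.params[3]),
                "or_gamma_lo": np.exp(f.params[3] - z * se[3]),
                "or_gamma_hi": np.exp(f.params[3] + z * se[3]),
            }
        )
    return pd.DataFrame(rows)
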