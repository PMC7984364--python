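"""Per-outcome complete-case analyses.

Continuous outcomes are analysed by linear regression of the outcome on the
arm indicator; binary outcomes by probit regression (which matches the
latent-threshold data-generating model).  Each outcome is analysed on its own
complete cases, so participants are dropped independently per outcome.
Inference is Wald-z by default; t-based inference for the linear model is
available via ``use_t`` (the difference is immaterial at trial sizes of a few
hundred).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datagen import BINARY, CONTINUOUS, TrialData
from .results import FitResult, wald_result

_GRAD_TOL = 1e-8


def _complete_cases(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    x = np.asarray(x)
    keep = ~np.isnan(y)
    return y[keep], x[keep]


def fit_linear(y: np.ndarray, x: np.ndarray, use_t: bool = False) -> FitResult:
    """OLS of a single outcome on the arm indicator, complete cases only.

    The two-group design admits a closed-form solve: the effect estimate is
    the difference in arm means and its variance is the pooled residual
    variance times (1/n0 + 1/n1).
    """
    y, x = _complete_cases(y, x)
    n = y.shape[0]
    if n == 0:
        raise ValueError("outcome is entirely missing")
    n1 = int(np.sum(x == 1))
    n0 = n - n1
    if n0 < 2 or n1 < 2:
        raise ValueError("need at least two observed values in each arm")
    y0 = y[x == 0]
    y1 = y[x == 1]
    m0, m1 = y0.mean(), y1.mean()
    beta1 = m1 - m0
    rss = np.sum((y0 - m0) ** 2) + np.sum((y1 - m1) ** 2)
    sigma2 = rss / (n - 2)
    se = float(np.sqrt(sigma2 * (1.0 / n0 + 1.0 / n1)))
    if use_t:
        tq = stats.t.ppf(0.975, n - 2)
        tval = beta1 / se if se > 0 else np.inf * np.sign(beta1)
        p = 2 * stats.t.sf(abs(tval), n - 2) if se > 0 else float(beta1 == 0.0)
        return FitResult(
            method="linear",
            estimates=beta1,
            se=se,
            p_values=p,
            ci_lower=beta1 - tq * se,
            ci_upper=beta1 + tq * se,
            n_used=n,
            nuisance={"sigma2": sigma2, "intercept": m0, "df": n - 2},
        )
    return wald_result(
        "linear", beta1, se, n, nuisance={"sigma2": sigma2, "intercept": m0}
    )


def _probit_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    s = 2.0 * y - 1.0
    return float(np.sum(np.log(np.clip(stats.norm.cdf(s * eta), 1e-300, None))))


def fit_probit(y: np.ndarray, x: np.ndarray) -> FitResult:
    """Maximum-likelihood probit regression of a binary outcome on arm.

    Newton iterations on the exact log-likelihood from a closed-form start
    (the arm-only design is saturated, so the start is already the MLE up to
    floating point; Newton polishes to gradient norm < 1e-8).  Complete
    separation (an arm with all events or all non-events) is flagged as
    nonconvergence.
    """
    y, x = _complete_cases(y, x)
    n = y.shape[0]
    if n == 0:
        raise ValueError("outcome is entirely missing")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("both outcome classes must be present")
    p0 = y[x == 0].mean() if np.any(x == 0) else np.nan
    p1 = y[x == 1].mean() if np.any(x == 1) else np.nan
    if np.isnan(p0) or np.isnan(p1):
        raise ValueError("need observed values in both arms")
    if p0 in (0.0, 1.0) or p1 in (0.0, 1.0):
        return wald_result(
            "probit",
            np.nan,
            np.nan,
            n,
            converged=False,
            message="complete separation: one arm has all events or all non-events",
        )

    X = np.column_stack([np.ones(n), x.astype(float)])
    beta = np.array([stats.norm.ppf(p0), stats.norm.ppf(p1) - stats.norm.ppf(p0)])
    converged = False
    for _ in range(50):
        eta = X @ beta
        s = 2.0 * y - 1.0
        pdf = stats.norm.pdf(eta)
        cdf = np.clip(stats.norm.cdf(s * eta), 1e-12, None)
        score_w = s * pdf / cdf  # d loglik / d eta
        grad = X.T @ score_w
        # observed information weights: lambda * (lambda + eta) with lambda = s*phi/Phi(s eta)
        w = score_w * (score_w + eta)
        H = X.T @ (X * w[:, None])
        if np.max(np.abs(grad)) < _GRAD_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(beta)) > 15:
            break
    if not converged:
        return wald_result(
            "probit", np.nan, np.nan, n, converged=False, message="Newton iterations failed"
        )
    cov = np.linalg.inv(H)
    return wald_result(
        "probit",
        beta[1],
        float(np.sqrt(cov[1, 1])),
        n,
        nuisance={"intercept": beta[0], "loglik": _probit_loglik(beta, X, y)},
    )


def fit_uv(data: TrialData, use_t: bool = False) -> list[FitResult]:
    """Analyse each outcome separately (complete cases per outcome)."""
    out: list[FitResult] = []
    for j, t in enumerate(data.outcome_types):
        y = np.where(data.observed[:, j], data.outcomes[:, j], np.nan)
        if t == CONTINUOUS:
            out.append(fit_linear(y, data.arm, use_t=use_t))
        elif t == BINARY:
            out.append(fit_probit(y, data.arm))
        else:  # pragma: no cover - TrialData validates types
            raise ValueError(f"unknown outcome type {t!r}")
    return out
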