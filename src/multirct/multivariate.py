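"""Likelihood-based joint estimators for multiple correlated outcomes.

Three families of models are implemented, all fitted by direct maximisation
of the observed-data log-likelihood so that partially missing outcome
vectors contribute their marginal density (valid under MAR):

* :func:`fit_mm_continuous` — the multivariate (multilevel) normal model
  ``Y_i ~ N(beta0 + beta1 x_i, Omega)`` with unstructured covariance
  ``Omega``, parameterised by its log-Cholesky factor so positive
  definiteness is automatic.  Each participant contributes the marginal
  normal density of their observed outcome subvector.
* :func:`fit_mm_binary_pair` / :func:`fit_mm_mixed_pair` — the latent-normal
  analogues for two binary outcomes (bivariate probit) and for one
  continuous plus one binary outcome.  Because the only covariate is the arm
  indicator, the bivariate-probit likelihood depends on the data only
  through per-arm cell counts, which makes each evaluation O(1).
* :func:`fit_lv` — a shared-latent-variable model: one normal random effect
  ``l ~ N(0, sigma_l^2)`` (variance fixed, loading 1 on the first outcome)
  induces all cross-outcome correlation; the marginal likelihood integrates
  over ``l`` by Gauss-Hermite quadrature (10 nodes by default, optional
  mean/curvature-adaptive recentring).  Binary effects are additionally
  reported rescaled by 1/sqrt(lambda^2 sigma_l^2 + 1) to place them on the
  marginal probit scale.
* :func:`fit_factorisation` — the two-step factorisation of a mixed
  continuous-binary joint density: a marginal probit for the binary outcome
  followed by a linear model for the continuous outcome given the centred
  binary outcome.

Standard errors come from the inverse observed information (numerical
Hessian at the optimum); Wald-z inference throughout.  Nonconvergence —
optimizer failure, a gradient norm above tolerance, a latent correlation at
its boundary or an indefinite Hessian — is flagged on the result so that
simulation summaries can exclude and count such replicates.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtr

from ._bvn import bvn_cdf
from .datagen import BINARY, CONTINUOUS, TrialData
from .results import FitResult, wald_result

_LOG2PI = np.log(2.0 * np.pi)
_GRAD_TOL = 1e-6
_RHO_MAX = 0.99


# ---------------------------------------------------------------------------
# multivariate normal model with unstructured covariance (MM, continuous)


def _group_stats(data: TrialData):
    """Sufficient statistics per (arm, missingness-pattern) group.

    Returns a list of (arm, observed-index array, n, sum-vector, sum-of-outer-
    products) tuples; the observed-data likelihood and its gradient are O(1)
    in n given these.
    """
    groups = []
    for a in (0, 1):
        sel = data.arm == a
        obs = data.observed[sel]
        y = data.outcomes[sel]
        patterns, inverse = np.unique(obs, axis=0, return_inverse=True)
        for p_idx in range(patterns.shape[0]):
            idx = np.flatnonzero(patterns[p_idx])
            if idx.size == 0:
                continue
            rows = y[inverse == p_idx][:, idx]
            groups.append((a, idx, rows.shape[0], rows.sum(axis=0), rows.T @ rows))
    return groups


def _chol_unpack(theta_cov: np.ndarray, m: int) -> np.ndarray:
    L = np.zeros((m, m))
    pos = 0
    for i in range(m):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(theta_cov[pos])
            else:
                L[i, j] = theta_cov[pos]
            pos += 1
    return L


def _chol_pack(Omega: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(Omega)
    out = []
    for i in range(L.shape[0]):
        for j in range(i + 1):
            out.append(np.log(L[i, j]) if i == j else L[i, j])
    return np.array(out)


def _mm_nll_grad(theta: np.ndarray, groups, m: int, common_effect: bool):
    if common_effect:
        beta0 = theta[:m]
        beta1 = np.full(m, theta[m])
        theta_cov = theta[m + 1:]
    else:
        beta0 = theta[:m]
        beta1 = theta[m: 2 * m]
        theta_cov = theta[2 * m:]
    L = _chol_unpack(theta_cov, m)
    Omega = L @ L.T
    nll = 0.0
    g_b0 = np.zeros(m)
    g_b1 = np.zeros(m)
    G = np.zeros((m, m))  # d nll / d Omega (full symmetric)
    for a, idx, n_g, S1, S2 in groups:
        mu = beta0[idx] + beta1[idx] * a
        Sig = Omega[np.ix_(idx, idx)]
        try:
            C = np.linalg.cholesky(Sig)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros_like(theta)
        Sig_inv = np.linalg.inv(Sig)
        logdet = 2.0 * np.log(np.diag(C)).sum()
        M = S2 - np.outer(S1, mu) - np.outer(mu, S1) + n_g * np.outer(mu, mu)
        nll += 0.5 * (n_g * idx.size * _LOG2PI + n_g * logdet + np.trace(Sig_inv @ M))
        gmu = Sig_inv @ (n_g * mu - S1)
        g_b0[idx] += gmu
        g_b1[idx] += a * gmu
        G[np.ix_(idx, idx)] += 0.5 * (n_g * Sig_inv - Sig_inv @ M @ Sig_inv)
    gL = 2.0 * G @ L
    g_cov = []
    for i in range(m):
        for j in range(i + 1):
            g_cov.append(gL[i, j] * (L[i, i] if i == j else 1.0))
    if common_effect:
        grad = np.concatenate([g_b0, [g_b1.sum()], g_cov])
    else:
        grad = np.concatenate([g_b0, g_b1, g_cov])
    return nll, grad


def mm_continuous_loglik(
    data: TrialData, beta0: np.ndarray, beta1: np.ndarray, Omega: np.ndarray
) -> float:
    """Observed-data log-likelihood of the multivariate normal model."""
    m = data.n_outcomes
    theta = np.concatenate([np.asarray(beta0, float), np.asarray(beta1, float), _chol_pack(np.asarray(Omega, float))])
    nll, _ = _mm_nll_grad(theta, _group_stats(data), m, common_effect=False)
    return -nll


def _numeric_hessian(fun, theta: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function with gradient output."""
    p = theta.shape[0]
    H = np.zeros((p, p))
    for i in range(p):
        step = np.zeros(p)
        step[i] = eps
        _, gp = fun(theta + step)
        _, gm = fun(theta - step)
        H[i] = (gp - gm) / (2 * eps)
    return 0.5 * (H + H.T)


def _start_values(data: TrialData):
    """Complete-case per-outcome means and pairwise covariance (PD-repaired)."""
    m = data.n_outcomes
    beta0 = np.zeros(m)
    beta1 = np.zeros(m)
    for j in range(m):
        yj = data.outcomes[:, j]
        obs = data.observed[:, j]
        m0 = yj[obs & (data.arm == 0)].mean()
        m1 = yj[obs & (data.arm == 1)].mean()
        beta0[j], beta1[j] = m0, m1 - m0
    resid = data.outcomes - (beta0 + np.outer(data.arm, beta1))
    resid = np.where(data.observed, resid, np.nan)
    with np.errstate(invalid="ignore"):
        pc = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1):
                both = data.observed[:, i] & data.observed[:, j]
                if both.sum() > 2:
                    pc[i, j] = pc[j, i] = np.nanmean(resid[both, i] * resid[both, j])
                elif i == j:
                    pc[i, j] = 1.0
    w, V = np.linalg.eigh(0.5 * (pc + pc.T))
    Omega = V @ np.diag(np.clip(w, 1e-3, None)) @ V.T
    return beta0, beta1, Omega


def fit_mm_continuous(
    data: TrialData, common_effect: bool = False, max_iter: int = 500,
    use_t: bool = True,
) -> FitResult:
    """Fit the multivariate normal model by observed-data maximum likelihood.

    With ``common_effect=True`` a single intervention effect shared across
    all outcomes is estimated (equality constraint on the effect vector).
    By default the per-outcome Wald statistics are referred to a t
    distribution with (cases observed for that outcome - 2) degrees of
    freedom, mirroring the small-sample convention of the univariate linear
    comparator; ``use_t=False`` gives plain Wald-z inference.
    """
    if any(t != CONTINUOUS for t in data.outcome_types):
        raise ValueError("fit_mm_continuous requires all outcomes continuous")
    m = data.n_outcomes
    for j in range(m):
        for a in (0, 1):
            if (data.observed[:, j] & (data.arm == a)).sum() < 2:
                raise ValueError(f"outcome {j} needs >=2 observed values per arm")
    groups = _group_stats(data)
    b0, b1, Om = _start_values(data)
    if common_effect:
        theta0 = np.concatenate([b0, [b1.mean()], _chol_pack(Om)])
    else:
        theta0 = np.concatenate([b0, b1, _chol_pack(Om)])
    fun = lambda th: _mm_nll_grad(th, groups, m, common_effect)
    res = optimize.minimize(
        fun, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-9},
    )
    theta = res.x
    # Newton polish to drive the gradient norm below tolerance
    nll, grad = fun(theta)
    for _ in range(10):
        if np.max(np.abs(grad)) < 1e-9:
            break
        H_p = _numeric_hessian(fun, theta)
        try:
            step = np.linalg.solve(H_p, grad)
        except np.linalg.LinAlgError:
            break
        nll_new, grad_new = fun(theta - step)
        if not np.isfinite(nll_new) or nll_new > nll + 1e-9:
            break
        theta, nll, grad = theta - step, nll_new, grad_new
    gnorm = float(np.max(np.abs(grad)))
    converged = bool(res.success or gnorm < _GRAD_TOL) and gnorm < 1e-3
    if common_effect:
        beta0, beta1 = theta[:m], np.full(m, theta[m])
        eff_idx = [m]
        Omega = _chol_unpack(theta[m + 1:], m) @ _chol_unpack(theta[m + 1:], m).T
    else:
        beta0, beta1 = theta[:m], theta[m: 2 * m]
        eff_idx = list(range(m, 2 * m))
        Omega = _chol_unpack(theta[2 * m:], m) @ _chol_unpack(theta[2 * m:], m).T
    H = _numeric_hessian(fun, theta)
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        converged = False
        se_all = np.full(theta.shape[0], np.nan)
    if common_effect:
        se = np.full(m, se_all[m])
    else:
        se = se_all[eff_idx]
    if not np.isfinite(se).all() or (se <= 0).any():
        converged = False
    n_used = data.observed.sum(axis=0)
    sd = np.sqrt(np.diag(Omega))
    corr = Omega / np.outer(sd, sd)
    nuisance = {
        "intercepts": beta0,
        "Omega": Omega,
        "correlation": corr,
        "loglik": -nll,
        "grad_norm": gnorm,
        "common_effect": common_effect,
    }
    message = "" if converged else f"gradient norm {gnorm:.2e}"
    if not use_t:
        return wald_result(
            "mm", beta1, se, n_used, converged=converged, message=message,
            nuisance=nuisance,
        )
    df = np.maximum(n_used - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta1 / np.where(se > 0, se, 1.0), np.inf)
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    q = stats.t.ppf(0.975, df)
    return FitResult(
        method="mm",
        estimates=beta1,
        se=se,
        p_values=p,
        ci_lower=beta1 - q * se,
        ci_upper=beta1 + q * se,
        n_used=n_used,
        converged=converged,
        message=message,
        nuisance=nuisance,
    )


def em_mm_continuous(
    data: TrialData, max_iter: int = 2000, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """EM fit of the same multivariate normal model (fallback / cross-check).

    Returns (beta0, beta1, Omega, loglik).  Used as an algorithmically
    independent route to the observed-data MLE.
    """
    m = data.n_outcomes
    beta0, beta1, Omega = _start_values(data)
    n = data.n
    arm = data.arm
    prev = -np.inf
    for _ in range(max_iter):
        mu = beta0 + np.outer(arm, beta1)
        Ey = np.where(data.observed, data.outcomes, 0.0)
        C_acc = np.zeros((m, m))
        for i in range(n):
            mis = np.flatnonzero(~data.observed[i])
            if mis.size == 0:
                continue
            obs = np.flatnonzero(data.observed[i])
            if obs.size:
                Soo_inv = np.linalg.inv(Omega[np.ix_(obs, obs)])
                B = Omega[np.ix_(mis, obs)] @ Soo_inv
                Ey[i, mis] = mu[i, mis] + B @ (data.outcomes[i, obs] - mu[i, obs])
                C = Omega[np.ix_(mis, mis)] - B @ Omega[np.ix_(obs, mis)]
            else:
                Ey[i, mis] = mu[i, mis]
                C = Omega[np.ix_(mis, mis)]
            C_acc[np.ix_(mis, mis)] += C
        nu0 = Ey[arm == 0].mean(axis=0)
        nu1 = Ey[arm == 1].mean(axis=0)
        beta0, beta1 = nu0, nu1 - nu0
        resid = Ey - (beta0 + np.outer(arm, beta1))
        Omega = (resid.T @ resid + C_acc) / n
        ll = mm_continuous_loglik(data, beta0, beta1, Omega)
        if abs(ll - prev) < tol:
            break
        prev = ll
    return beta0, beta1, Omega, ll


# ---------------------------------------------------------------------------
# bivariate probit (MM for two binary outcomes)


def _binary_pair_counts(data: TrialData):
    counts = []
    for a in (0, 1):
        sel = data.arm == a
        o1, o2 = data.observed[sel, 0], data.observed[sel, 1]
        y1, y2 = data.outcomes[sel, 0], data.outcomes[sel, 1]
        both = o1 & o2
        cell = np.zeros((2, 2))
        for v1 in (0, 1):
            for v2 in (0, 1):
                cell[v1, v2] = np.sum(both & (y1 == v1) & (y2 == v2))
        only1 = o1 & ~o2
        only2 = o2 & ~o1
        counts.append(
            {
                "cell": cell,
                "only1": (np.sum(only1 & (y1 == 1)), np.sum(only1)),
                "only2": (np.sum(only2 & (y2 == 1)), np.sum(only2)),
            }
        )
    return counts


def binary_pair_loglik(data: TrialData, beta0, beta1, rho: float) -> float:
    """Observed-data log-likelihood of the bivariate probit model."""
    theta = np.array([beta0[0], beta0[1], beta1[0], beta1[1], np.arctanh(rho)])
    return -_binary_pair_nll(theta, _binary_pair_counts(data), fix_rho=None)


def _binary_pair_nll(theta: np.ndarray, counts, fix_rho: float | None) -> float:
    b01, b02, b11, b12 = theta[:4]
    rho = fix_rho if fix_rho is not None else float(np.tanh(theta[4]))
    nll = 0.0
    for a, cnt in enumerate(counts):
        e1 = b01 + b11 * a
        e2 = b02 + b12 * a
        p1 = ndtr(e1)
        p2 = ndtr(e2)
        p11 = bvn_cdf(e1, e2, rho)
        probs = np.array(
            [
                [1.0 - p1 - p2 + p11, p2 - p11],  # (y1=0,y2=0), (0,1)
                [p1 - p11, p11],  # (1,0), (1,1)
            ]
        )
        probs = np.clip(probs, 1e-300, None)
        nll -= float(np.sum(cnt["cell"] * np.log(probs)))
        for (k, t), p in (
            (cnt["only1"], p1),
            (cnt["only2"], p2),
        ):
            if t:
                nll -= k * np.log(max(p, 1e-300)) + (t - k) * np.log(max(1 - p, 1e-300))
    return nll


def fit_mm_binary_pair(data: TrialData, constrain_rho_zero: bool = False) -> FitResult:
    """Bivariate probit by ML with latent correlation; handles per-outcome missingness.

    Singly observed participants contribute univariate probit terms.  A fit
    whose latent correlation reaches the admissible boundary (|rho| = 0.99)
    is flagged as nonconverged.
    """
    if data.n_outcomes != 2 or any(t != BINARY for t in data.outcome_types):
        raise ValueError("fit_mm_binary_pair requires exactly two binary outcomes")
    counts = _binary_pair_counts(data)
    # univariate probit starts from observed marginal rates, clipped off 0/1
    start = []
    for j, key in ((0, "only1"), (1, "only2")):
        rates = []
        for a in (0, 1):
            cell = counts[a]["cell"]
            k_b = cell[1].sum() if j == 0 else cell[:, 1].sum()
            n_b = cell.sum()
            k_s, n_s = counts[a][key]
            tot = n_b + n_s
            rates.append(np.clip((k_b + k_s) / max(tot, 1), 0.02, 0.98))
        start.append((stats.norm.ppf(rates[0]), stats.norm.ppf(rates[1]) - stats.norm.ppf(rates[0])))
    (b01, b11), (b02, b12) = start
    fix_rho = 0.0 if constrain_rho_zero else None
    if constrain_rho_zero:
        theta0 = np.array([b01, b02, b11, b12])
        bounds = [(-8, 8)] * 4
    else:
        theta0 = np.array([b01, b02, b11, b12, 0.0])
        bounds = [(-8, 8)] * 4 + [(-np.arctanh(_RHO_MAX), np.arctanh(_RHO_MAX))]
    fun = lambda th: _binary_pair_nll(th, counts, fix_rho)
    res = optimize.minimize(fun, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-13})
    theta = res.x
    rho_hat = fix_rho if constrain_rho_zero else float(np.tanh(theta[4]))
    at_boundary = (not constrain_rho_zero) and abs(rho_hat) >= _RHO_MAX - 1e-6
    H = optimize.approx_fprime(theta, lambda th: optimize.approx_fprime(th, fun, 1e-6), 1e-6)
    H = 0.5 * (H + H.T)
    converged = bool(res.success) and not at_boundary
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[2:4], 0.0, None))
        if not np.isfinite(se).all() or (se <= 0).any():
            converged = False
    except np.linalg.LinAlgError:
        converged = False
        se = np.array([np.nan, np.nan])
    n_used = data.observed.sum(axis=0)
    return wald_result(
        "mm",
        theta[2:4],
        se,
        n_used,
        converged=converged,
        message="" if converged else ("latent correlation at boundary" if at_boundary else res.message),
        nuisance={"intercepts": theta[:2], "rho": rho_hat, "loglik": -res.fun},
    )


# ---------------------------------------------------------------------------
# mixed continuous-binary pair


def mixed_pair_conditional_logprob(y1, y2, x, params) -> np.ndarray:
    """log f(y1, y2 | x) under the joint latent-normal mixed model.

    ``params`` = (b01, b11, sigma1, b02, b12, rho).  The binary outcome's
    conditional probability given the continuous one is
    Phi(+-(eta2 + (rho/sigma1)(y1 - mu1)) / sqrt(1 - rho^2)).
    """
    b01, b11, sigma1, b02, b12, rho = params
    mu1 = b01 + b11 * x
    eta2 = b02 + b12 * x
    r = (np.asarray(y1) - mu1) / sigma1
    s = 2.0 * np.asarray(y2) - 1.0
    log_norm = -np.log(sigma1) - 0.5 * _LOG2PI - 0.5 * r**2
    z = s * (eta2 + rho * r) / np.sqrt(1.0 - rho**2)
    return log_norm + np.log(np.clip(ndtr(z), 1e-300, None))


def _mixed_nll(theta: np.ndarray, parts) -> float:
    b01, b11, log_s1, b02, b12, zr = theta
    sigma1 = np.exp(log_s1)
    rho = float(np.tanh(zr))
    params = (b01, b11, sigma1, b02, b12, rho)
    nll = 0.0
    y1b, y2b, xb, y1o, xo1, y2o, xo2 = parts
    if y1b.size:
        nll -= float(np.sum(mixed_pair_conditional_logprob(y1b, y2b, xb, params)))
    if y1o.size:
        r = (y1o - (b01 + b11 * xo1)) / sigma1
        nll -= float(np.sum(-np.log(sigma1) - 0.5 * _LOG2PI - 0.5 * r**2))
    if y2o.size:
        s = 2.0 * y2o - 1.0
        nll -= float(np.sum(np.log(np.clip(ndtr(s * (b02 + b12 * xo2)), 1e-300, None))))
    return nll


def fit_mm_mixed_pair(data: TrialData) -> FitResult:
    """Joint latent-normal ML for one continuous and one binary outcome.

    Effect estimates are returned in the original column order (linear scale
    for the continuous outcome, probit latent scale for the binary one).
    """
    types = data.outcome_types
    if data.n_outcomes != 2 or set(types) != {CONTINUOUS, BINARY}:
        raise ValueError("fit_mm_mixed_pair requires one continuous and one binary outcome")
    c = types.index(CONTINUOUS)
    b = types.index(BINARY)
    oc, ob = data.observed[:, c], data.observed[:, b]
    yc, yb, x = data.outcomes[:, c], data.outcomes[:, b], data.arm
    both = oc & ob
    parts = (
        yc[both], yb[both], x[both].astype(float),
        yc[oc & ~ob], x[oc & ~ob].astype(float),
        yb[ob & ~oc], x[ob & ~oc].astype(float),
    )
    # starts from the decoupled fits
    m0 = yc[oc & (x == 0)].mean()
    m1 = yc[oc & (x == 1)].mean()
    s1 = np.std(np.concatenate([yc[oc & (x == 0)] - m0, yc[oc & (x == 1)] - m1]))
    p0 = np.clip(yb[ob & (x == 0)].mean(), 0.02, 0.98)
    p1 = np.clip(yb[ob & (x == 1)].mean(), 0.02, 0.98)
    theta0 = np.array([
        m0, m1 - m0, np.log(max(s1, 1e-3)),
        stats.norm.ppf(p0), stats.norm.ppf(p1) - stats.norm.ppf(p0), 0.0,
    ])
    zmax = np.arctanh(_RHO_MAX)
    bounds = [(None, None)] * 2 + [(-10, 10)] + [(-8, 8)] * 2 + [(-zmax, zmax)]
    fun = lambda th: _mixed_nll(th, parts)
    res = optimize.minimize(fun, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-13})
    theta = res.x
    rho_hat = float(np.tanh(theta[5]))
    at_boundary = abs(rho_hat) >= _RHO_MAX - 1e-6
    H = optimize.approx_fprime(theta, lambda th: optimize.approx_fprime(th, fun, 1e-6), 1e-6)
    H = 0.5 * (H + H.T)
    converged = bool(res.success) and not at_boundary
    try:
        cov = np.linalg.inv(H)
        diag = np.clip(np.diag(cov), 0.0, None)
        se_c, se_b = np.sqrt(diag[1]), np.sqrt(diag[4])
        if not (np.isfinite(se_c) and np.isfinite(se_b) and se_c > 0 and se_b > 0):
            converged = False
    except np.linalg.LinAlgError:
        converged = False
        se_c = se_b = np.nan
    est = np.empty(2)
    se = np.empty(2)
    est[c], est[b] = theta[1], theta[4]
    se[c], se[b] = se_c, se_b
    return wald_result(
        "mm",
        est,
        se,
        data.observed.sum(axis=0),
        converged=converged,
        message="" if converged else ("latent correlation at boundary" if at_boundary else res.message),
        nuisance={
            "rho": rho_hat,
            "sigma1": float(np.exp(theta[2])),
            "intercepts": {"continuous": theta[0], "binary": theta[3]},
            "loglik": -res.fun,
        },
    )


# ---------------------------------------------------------------------------
# shared-latent-variable model


def _lv_unpack(theta: np.ndarray, m: int, cont_idx: np.ndarray):
    beta0 = theta[:m]
    beta1 = theta[m: 2 * m]
    lam = np.ones(m)
    lam[1:] = theta[2 * m: 3 * m - 1]
    sigma = np.ones(m)
    sigma[cont_idx] = np.exp(theta[3 * m - 1:])
    return beta0, beta1, lam, sigma


def lv_loglik(
    data: TrialData,
    beta0,
    beta1,
    loadings,
    resid_sd,
    sigma_l2: float,
    n_quad: int = 10,
    adaptive: bool = True,
) -> float:
    """Marginal log-likelihood of the shared-latent-variable model."""
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    parts = _lv_parts(data)
    theta_like = (np.asarray(beta0, float), np.asarray(beta1, float),
                  np.asarray(loadings, float), np.asarray(resid_sd, float))
    return -_lv_nll_eval(theta_like, parts, data, sigma_l2, nodes, weights, adaptive)


def _lv_parts(data: TrialData):
    return [
        (j, t, data.observed[:, j], data.outcomes[:, j])
        for j, t in enumerate(data.outcome_types)
    ]


def _lv_nll_eval(unpacked, parts, data, sigma_l2, nodes, weights, adaptive) -> float:
    beta0, beta1, lam, sigma = unpacked
    x = data.arm
    n = data.n
    sl = np.sqrt(sigma_l2)
    if not adaptive:
        l_nodes = np.sqrt(2.0) * sl * nodes  # (K,)
        logw = np.log(weights) - 0.5 * np.log(np.pi)
        A = np.zeros((n, l_nodes.shape[0]))
        for j, t, obs, y in parts:
            eta = beta0[j] + beta1[j] * x
            if t == CONTINUOUS:
                r = (y[obs, None] - eta[obs, None] - lam[j] * l_nodes) / sigma[j]
                A[obs] += -np.log(sigma[j]) - 0.5 * _LOG2PI - 0.5 * r**2
            else:
                s = (2.0 * y[obs] - 1.0)[:, None]
                z = s * (eta[obs, None] + lam[j] * l_nodes)
                A[obs] += np.log(np.clip(ndtr(z), 1e-300, None))
        has_obs = data.observed.any(axis=1)
        Ao = A[has_obs] + logw
        amax = Ao.max(axis=1, keepdims=True)
        ll = float(np.sum(amax[:, 0] + np.log(np.exp(Ao - amax).sum(axis=1))))
        return -ll
    return -_lv_adaptive_ll(unpacked, parts, data, sigma_l2, nodes, weights)


def _lv_integrand_derivs(l, unpacked, parts, data, sigma_l2):
    """First/second derivative in l of log[ prior * prod f_j ] per participant."""
    beta0, beta1, lam, sigma = unpacked
    x = data.arm
    g1 = -l / sigma_l2
    g2 = np.full_like(l, -1.0 / sigma_l2)
    for j, t, obs, y in parts:
        eta = beta0[j] + beta1[j] * x
        if t == CONTINUOUS:
            r = y[obs] - eta[obs] - lam[j] * l[obs]
            g1[obs] += lam[j] * r / sigma[j] ** 2
            g2[obs] += -lam[j] ** 2 / sigma[j] ** 2
        else:
            s = 2.0 * y[obs] - 1.0
            z = s * (eta[obs] + lam[j] * l[obs])
            ratio = stats.norm.pdf(z) / np.clip(ndtr(z), 1e-300, None)
            g1[obs] += s * lam[j] * ratio
            g2[obs] += -(lam[j] ** 2) * ratio * (ratio + z)
    return g1, g2


def _lv_adaptive_ll(unpacked, parts, data, sigma_l2, nodes, weights) -> float:
    """Mean/curvature-adaptive Gauss-Hermite: recentre nodes at the per-
    participant posterior mode of the latent variable."""
    beta0, beta1, lam, sigma = unpacked
    x = data.arm
    n = data.n
    mode = np.zeros(n)
    for _ in range(15):
        g1, g2 = _lv_integrand_derivs(mode, unpacked, parts, data, sigma_l2)
        step = g1 / np.minimum(g2, -1e-8)
        mode -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    _, g2 = _lv_integrand_derivs(mode, unpacked, parts, data, sigma_l2)
    scale = 1.0 / np.sqrt(-g2)
    l_nodes = mode[:, None] + np.sqrt(2.0) * scale[:, None] * nodes  # (n, K)
    A = np.zeros_like(l_nodes)
    for j, t, obs, y in parts:
        eta = beta0[j] + beta1[j] * x
        if t == CONTINUOUS:
            r = (y[obs, None] - eta[obs, None] - lam[j] * l_nodes[obs]) / sigma[j]
            A[obs] += -np.log(sigma[j]) - 0.5 * _LOG2PI - 0.5 * r**2
        else:
            s = (2.0 * y[obs] - 1.0)[:, None]
            z = s * (eta[obs, None] + lam[j] * l_nodes[obs])
            A[obs] += np.log(np.clip(ndtr(z), 1e-300, None))
    A += stats.norm.logpdf(l_nodes, scale=np.sqrt(sigma_l2))
    A += np.log(weights) + nodes**2 + 0.5 * np.log(2.0) + np.log(scale)[:, None]
    has_obs = data.observed.any(axis=1)
    Ao = A[has_obs]
    amax = Ao.max(axis=1, keepdims=True)
    return float(np.sum(amax[:, 0] + np.log(np.exp(Ao - amax).sum(axis=1))))


def fit_lv(
    data: TrialData,
    n_quad: int = 10,
    sigma_l2: float | None = None,
    adaptive: bool = True,
) -> FitResult:
    """Fit the shared-latent-variable model by Gauss-Hermite marginal ML.

    The latent variance is fixed for identifiability: 1.0 when all outcomes
    are binary, 0.8 otherwise; the first outcome's loading is fixed at 1.
    By default the quadrature recentres its nodes at each participant's
    posterior mode of the latent variable (adaptive), which makes 10 nodes
    accurate to ~1e-7; ``adaptive=False`` uses fixed prior-scaled nodes.
    Binary effects are reported rescaled to the marginal probit scale
    (raw conditional estimates are kept in ``nuisance['effects_raw']``).
    """
    m = data.n_outcomes
    if m < 2:
        raise ValueError("the latent-variable model needs at least two outcomes")
    if sigma_l2 is None:
        sigma_l2 = 1.0 if all(t == BINARY for t in data.outcome_types) else 0.8
    cont_idx = np.array([j for j, t in enumerate(data.outcome_types) if t == CONTINUOUS], dtype=int)
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    parts = _lv_parts(data)

    b0 = np.zeros(m)
    b1 = np.zeros(m)
    sig = np.ones(m)
    for j, t in enumerate(data.outcome_types):
        obs = data.observed[:, j]
        y = data.outcomes[:, j]
        if t == CONTINUOUS:
            m0 = y[obs & (data.arm == 0)].mean()
            m1 = y[obs & (data.arm == 1)].mean()
            b0[j], b1[j] = m0, m1 - m0
            resid_var = np.var(np.concatenate([
                y[obs & (data.arm == 0)] - m0, y[obs & (data.arm == 1)] - m1]))
            sig[j] = np.sqrt(max(resid_var - (sigma_l2 if j == 0 else 0.2), 0.05))
        else:
            p0 = np.clip(y[obs & (data.arm == 0)].mean(), 0.02, 0.98)
            p1 = np.clip(y[obs & (data.arm == 1)].mean(), 0.02, 0.98)
            b0[j] = stats.norm.ppf(p0)
            b1[j] = stats.norm.ppf(p1) - b0[j]
    theta0 = np.concatenate([b0, b1, np.full(m - 1, 0.5), np.log(sig[cont_idx])])

    def fun(th):
        return _lv_nll_eval(_lv_unpack(th, m, cont_idx), parts, data, sigma_l2, nodes, weights, adaptive)

    res = optimize.minimize(fun, theta0, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-12})
    theta = res.x
    beta0, beta1, lam, sigma = _lv_unpack(theta, m, cont_idx)
    H = optimize.approx_fprime(theta, lambda th: optimize.approx_fprime(th, fun, 1e-5), 1e-5)
    H = 0.5 * (H + H.T)
    converged = bool(res.success)
    try:
        cov = np.linalg.inv(H)
        se_raw = np.sqrt(np.clip(np.diag(cov)[m: 2 * m], 0.0, None))
        if not np.isfinite(se_raw).all() or (se_raw <= 0).any():
            converged = False
    except np.linalg.LinAlgError:
        converged = False
        se_raw = np.full(m, np.nan)
    # rescale binary effects to the marginal probit scale: / sqrt(lam^2 sl2 + 1)
    scale = np.ones(m)
    for j, t in enumerate(data.outcome_types):
        if t == BINARY:
            scale[j] = np.sqrt(lam[j] ** 2 * sigma_l2 + 1.0)
    est = beta1 / scale
    se = se_raw / scale
    return wald_result(
        "lv",
        est,
        se,
        data.observed.sum(axis=0),
        converged=converged,
        message="" if converged else str(res.message),
        nuisance={
            "effects_raw": beta1.copy(),
            "intercepts": beta0,
            "loadings": lam,
            "resid_sd": sigma,
            "sigma_l2": sigma_l2,
            "rescale": scale,
            "loglik": -res.fun,
            "n_quad": n_quad,
        },
    )


def rescale_binary_effect(raw_effect: float, loading: float, sigma_l2: float) -> float:
    """Conditional-to-marginal probit rescaling: divide by sqrt(lam^2 sl2 + 1)."""
    return raw_effect / np.sqrt(loading**2 * sigma_l2 + 1.0)


# ---------------------------------------------------------------------------
# factorisation model (marginal probit x conditional linear)


def fit_factorisation(data: TrialData) -> FitResult:
    """Two-step factorisation fit for a continuous + binary outcome pair.

    Step 1: marginal probit of the binary outcome on arm (all its observed
    cases).  Step 2: OLS of the continuous outcome on arm and the centred
    binary outcome (complete cases of the pair); the coefficient on the
    centred term is the association tau.
    """
    types = data.outcome_types
    if data.n_outcomes != 2 or set(types) != {CONTINUOUS, BINARY}:
        raise ValueError("fit_factorisation requires one continuous and one binary outcome")
    c = types.index(CONTINUOUS)
    b = types.index(BINARY)
    from .univariate import fit_probit

    yb = np.where(data.observed[:, b], data.outcomes[:, b], np.nan)
    probit_fit = fit_probit(yb, data.arm)
    if not probit_fit.converged:
        return probit_fit
    b02 = probit_fit.nuisance["intercept"]
    b12 = probit_fit.estimates[0]
    mu2 = ndtr(b02 + b12 * data.arm)

    both = data.observed[:, c] & data.observed[:, b]
    X = np.column_stack([
        np.ones(both.sum()),
        data.arm[both].astype(float),
        data.outcomes[both, b] - mu2[both],
    ])
    y = data.outcomes[both, c]
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ (X.T @ y)
    resid = y - X @ coef
    sigma_c2 = resid @ resid / (both.sum() - 3)
    cov = sigma_c2 * XtX_inv
    se_lin = np.sqrt(np.diag(cov))
    est = np.empty(2)
    se = np.empty(2)
    est[c], est[b] = coef[1], b12
    se[c], se[b] = se_lin[1], probit_fit.se[0]
    n_used = np.empty(2, dtype=int)
    n_used[c], n_used[b] = both.sum(), probit_fit.n_used[0]
    return wald_result(
        "factorisation",
        est,
        se,
        n_used,
        nuisance={
            "tau": coef[2],
            "tau_se": se_lin[2],
            "sigma_c2": float(sigma_c2),
            "probit_intercept": b02,
            "linear_intercept": coef[0],
        },
    )
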