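"""Shared result containers for all estimators.

Every fitter in the package returns a :class:`FitResult`: per-outcome
intervention-effect estimates on the analysis scale, Wald standard errors,
95% confidence intervals and two-sided p-values, together with a convergence
flag, the number of cases actually used per outcome and a free-form block of
nuisance-parameter estimates (residual variances, the outcome covariance
matrix, the latent correlation, factor loadings, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

Z975 = float(stats.norm.ppf(0.975))


@dataclass
class FitResult:
    """Per-outcome intervention-effect estimates from one model fit.

    All array fields have length ``m`` (the number of outcomes covered by the
    fit; univariate fits have ``m = 1``).  ``converged`` refers to the whole
    fit: joint models either converge for all outcomes or none.
    """

    method: str
    estimates: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_used: np.ndarray
    converged: bool = True
    message: str = ""
    nuisance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.estimates = np.atleast_1d(np.asarray(self.estimates, dtype=float))
        self.se = np.atleast_1d(np.asarray(self.se, dtype=float))
        self.p_values = np.atleast_1d(np.asarray(self.p_values, dtype=float))
        self.ci_lower = np.atleast_1d(np.asarray(self.ci_lower, dtype=float))
        self.ci_upper = np.atleast_1d(np.asarray(self.ci_upper, dtype=float))
        self.n_used = np.atleast_1d(np.asarray(self.n_used, dtype=int))

    @property
    def n_outcomes(self) -> int:
        return self.estimates.shape[0]

    def nuisance_frame(self) -> pd.DataFrame:
        """Nuisance-parameter estimates flattened to one (name, value) row each."""
        rows = []

        def emit(prefix, value):
            arr = np.asarray(value)
            if arr.ndim == 0:
                rows.append((prefix, float(arr) if arr.dtype.kind == "f" else arr.item()))
            elif arr.ndim == 1:
                for i, v in enumerate(arr):
                    rows.append((f"{prefix}[{i + 1}]", float(v)))
            else:
                for i in range(arr.shape[0]):
                    for j in range(arr.shape[1]):
                        rows.append((f"{prefix}[{i + 1},{j + 1}]", float(arr[i, j])))

        for key, value in self.nuisance.items():
            if isinstance(value, dict):
                for sub, v in value.items():
                    emit(f"{key}.{sub}", v)
            elif isinstance(value, (int, float, np.ndarray, np.floating, np.integer, bool)):
                emit(key, value)
            else:
                rows.append((key, value))
        return pd.DataFrame(rows, columns=["parameter", "value"]).assign(method=self.method)

    def to_frame(self) -> pd.DataFrame:
        """One row per outcome, suitable for appending to a results CSV."""
        return pd.DataFrame(
            {
                "method": self.method,
                "outcome": np.arange(1, self.n_outcomes + 1),
                "estimate": self.estimates,
                "se": self.se,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p_value": self.p_values,
                "converged": self.converged,
                "n_used": self.n_used,
            }
        )


def wald_result(
    method: str,
    estimates: np.ndarray,
    se: np.ndarray,
    n_used: np.ndarray,
    converged: bool = True,
    message: str = "",
    nuisance: dict[str, Any] | None = None,
) -> FitResult:
    """Build a FitResult with Wald-z two-sided p-values and 95% CIs.

    A zero standard error (an exact fit) yields p = 0 for a nonzero estimate
    and p = 1 for a zero estimate.
    """
    estimates = np.atleast_1d(np.asarray(estimates, dtype=float))
    se = np.atleast_1d(np.asarray(se, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, estimates / np.where(se > 0, se, 1.0), np.inf * np.sign(estimates))
    z = np.where((se == 0) & (estimates == 0), 0.0, z)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return FitResult(
        method=method,
        estimates=estimates,
        se=se,
        p_values=p,
        ci_lower=estimates - Z975 * se,
        ci_upper=estimates + Z975 * se,
        n_used=np.asarray(n_used),
        converged=converged,
        message=message,
        nuisance=nuisance or {},
    )


def collect_univariate(results: list[FitResult]) -> tuple[np.ndarray, np.ndarray, bool]:
    """Stack a list of single-outcome fits into (estimates, p-values, converged)."""
    est = np.concatenate([r.estimates for r in results])
    p = np.concatenate([r.p_values for r in results])
    converged = all(r.converged for r in results)
    return est, p, converged
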