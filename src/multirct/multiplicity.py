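"""Holm adjustment, FWER / disjunctive power estimation and design formulas.

The familywise error rate (FWER) is the probability of at least one false
positive across the outcomes under the global null; disjunctive power is the
probability of at least one true positive when effects are present.  Both are
estimated as rejection proportions across simulation replicates after Holm
step-down adjustment of the per-outcome p-values, with binomial Monte Carlo
standard errors.  Nonconverged replicates are excluded from the denominator
and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datagen import OutcomeModel
from .results import FitResult, collect_univariate


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the original order.

    The k-th smallest p-value is multiplied by (m - k + 1) with running-max
    monotonicity enforcement and capping at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.shape[0]
    order = np.argsort(p, kind="stable")
    mult = m - np.arange(m)
    adj = np.minimum(1.0, np.maximum.accumulate(p[order] * mult))
    out = np.empty(m)
    out[order] = adj
    return out


def disjunctive_reject(adjusted_p, alpha: float = 0.05) -> bool:
    """True iff at least one adjusted p-value falls below alpha."""
    adjusted_p = np.asarray(adjusted_p, dtype=float)
    if adjusted_p.size == 0:
        raise ValueError("no p-values available for the disjunctive test")
    return bool(np.min(adjusted_p) < alpha)


def mcse_proportion(p_hat: float, n: int) -> float:
    """Binomial Monte Carlo standard error of an estimated proportion."""
    return float(np.sqrt(p_hat * (1.0 - p_hat) / n))


@dataclass
class SimulationSummary:
    """Per-method Monte Carlo summary of one simulation scenario."""

    method: str
    scenario: str
    proportion: float  # FWER under the null, disjunctive power otherwise
    is_power: bool
    mcse: float
    bias: np.ndarray
    empirical_se: np.ndarray
    mean_estimates: np.ndarray
    alpha: float
    n_replicates: int
    n_converged: int
    n_excluded: int

    @property
    def fwer(self) -> float | None:
        return None if self.is_power else self.proportion

    @property
    def power(self) -> float | None:
        return self.proportion if self.is_power else None


def _replicate_arrays(rep) -> tuple[np.ndarray, np.ndarray, bool]:
    if isinstance(rep, FitResult):
        return rep.estimates, rep.p_values, rep.converged
    return collect_univariate(list(rep))


def summarize(
    replicate_results,
    truth: OutcomeModel,
    alpha: float = 0.05,
    method: str | None = None,
    scenario: str = "",
) -> SimulationSummary:
    """Aggregate per-replicate fits into FWER-or-power, bias, empirical SE, MCSE.

    ``replicate_results`` is a list over replicates; each element is a single
    joint-model :class:`FitResult` or a list of per-outcome univariate fits.
    Replicates with any nonconverged fit are excluded from every summary and
    counted in ``n_excluded``.
    """
    est_rows = []
    rejections = []
    n_excluded = 0
    label = method
    for rep in replicate_results:
        est, p, conv = _replicate_arrays(rep)
        if label is None:
            label = rep.method if isinstance(rep, FitResult) else rep[0].method
        if not conv or np.isnan(p).any():
            n_excluded += 1
            continue
        est_rows.append(est)
        rejections.append(disjunctive_reject(holm_adjust(p), alpha))
    n_total = len(replicate_results)
    n_conv = len(est_rows)
    if n_conv < 2:
        raise ValueError("fewer than two converged replicates")
    E = np.vstack(est_rows)
    prop = float(np.mean(rejections))
    is_power = bool(np.any(truth.effects != 0))
    return SimulationSummary(
        method=label or "unknown",
        scenario=scenario,
        proportion=prop,
        is_power=is_power,
        mcse=mcse_proportion(prop, n_conv),
        bias=E.mean(axis=0) - truth.effects,
        empirical_se=E.std(axis=0, ddof=1),
        mean_estimates=E.mean(axis=0),
        alpha=alpha,
        n_replicates=n_total,
        n_converged=n_conv,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# design-stage sample size formulas


def sample_size_binary(
    p_control: float, p_intervention: float, alpha: float = 0.05, power: float = 0.80
) -> tuple[int, int]:
    """Classical two-proportion sample size; returns (per-arm, total).

    n/arm = (z_{1-a/2} sqrt(2 pbar qbar) + z_{1-b} sqrt(p1 q1 + p2 q2))^2
            / (p2 - p1)^2, rounded up.
    """
    for p in (p_control, p_intervention):
        if not 0 < p < 1:
            raise ValueError("event rates must lie strictly in (0, 1)")
    if p_control == p_intervention:
        raise ValueError("event rates must differ")
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    pbar = (p_control + p_intervention) / 2
    num = za * np.sqrt(2 * pbar * (1 - pbar)) + zb * np.sqrt(
        p_control * (1 - p_control) + p_intervention * (1 - p_intervention)
    )
    n_arm = int(np.ceil(num**2 / (p_intervention - p_control) ** 2))
    return n_arm, 2 * n_arm


def sample_size_continuous(
    effect_size: float, alpha: float = 0.05, power: float = 0.80
) -> tuple[int, int]:
    """Normal-approximation sample size for a standardised mean difference.

    n/arm = 2 (z_{1-a/2} + z_{1-b})^2 / ES^2, rounded up.
    """
    if effect_size <= 0:
        raise ValueError("effect size must be positive")
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    n_arm = int(np.ceil(2 * (za + zb) ** 2 / effect_size**2))
    return n_arm, 2 * n_arm
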