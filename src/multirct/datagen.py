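"""Synthetic two-arm trial generator with controlled missingness.

Complete data follow the latent-normal outcome model

    Y_i = beta0 + beta1 * x_i + eps_i,     eps_i ~ N(0, R(rho)),

where ``x_i`` is the arm indicator (1 = intervention, 0 = control), the error
covariance ``R(rho)`` is equicorrelated with unit variances, and binary
outcomes are obtained by dichotomising the latent normal at zero (probit
threshold model).  Effect sizes for continuous outcomes are therefore
standardised mean differences; for binary outcomes they are shifts on the
latent probit scale (a shift of ``Phi^{-1}(0.65) ~= 0.385`` turns a 50%
control event rate into a 65% intervention event rate).

Missingness is imposed after the fact:

* **MCAR** — each outcome is missing independently with its target
  probability.
* **MAR** — missingness depends on arm only: the control arm is
  ``mar_ratio`` (default 1.5) times more likely to be missing, with the two
  per-arm probabilities averaging to the target proportion.
* **MNAR** — participants are sorted in ascending order of the (complete)
  value of the targeted outcome, split into quartile groups, and made
  missing at quartile-specific rates whose mean equals the target
  proportion (rates rise steeply with the outcome value, e.g. 50% overall =
  (0, 25, 75, 100)% by quartile).

The complete outcome matrix is retained on the returned object
(``complete_outcomes``) so that simulation oracles can measure bias; the
estimators in this package only ever read the masked ``outcomes``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
BINARY = "binary"

#: Per-quartile missingness rates (fractions, quartiles in ascending order of
#: the outcome value) keyed by the overall missingness proportion.
MNAR_QUARTILE_SCHEDULE: dict[float, tuple[float, float, float, float]] = {
    0.00: (0.0, 0.000, 0.000, 0.00),
    0.15: (0.0, 0.075, 0.225, 0.30),
    0.20: (0.0, 0.100, 0.300, 0.40),
    0.30: (0.0, 0.150, 0.450, 0.60),
    0.40: (0.0, 0.200, 0.600, 0.80),
    0.50: (0.0, 0.250, 0.750, 1.00),
}


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class TrialData:
    """One two-arm trial: arm indicator, outcome matrix and observation mask.

    ``outcomes`` holds NaN wherever ``observed`` is False.  When produced by
    :func:`apply_missingness`, ``complete_outcomes`` retains the pre-deletion
    values for bias oracles; estimators must not read it.
    """

    arm: np.ndarray
    outcomes: np.ndarray
    observed: np.ndarray
    outcome_types: tuple[str, ...]
    complete_outcomes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.arm = np.asarray(self.arm, dtype=int)
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        self.outcome_types = tuple(self.outcome_types)
        if self.outcomes.shape != self.observed.shape:
            raise ValueError("outcomes and observed mask must have identical shapes")
        if self.outcomes.shape[1] != len(self.outcome_types):
            raise ValueError("outcome_types length must match the number of outcome columns")
        for j, t in enumerate(self.outcome_types):
            if t not in (CONTINUOUS, BINARY):
                raise ValueError(f"unknown outcome type {t!r}")
            if t == BINARY:
                vals = self.outcomes[self.observed[:, j], j]
                if vals.size and not np.isin(vals, (0.0, 1.0)).all():
                    raise ValueError(f"binary outcome {j} contains values outside {{0, 1}}")

    @property
    def n(self) -> int:
        return self.arm.shape[0]

    @property
    def n_outcomes(self) -> int:
        return self.outcomes.shape[1]


@dataclass
class OutcomeModel:
    """Data-generating parameters: intercepts, effects, equicorrelation, types.

    ``effects`` are standardised mean differences for continuous outcomes and
    latent probit shifts for binary outcomes.  The implied error covariance
    (unit variances, all off-diagonals ``rho``) must be positive definite,
    which requires ``rho > -1/(m-1)``.
    """

    effects: np.ndarray
    intercepts: np.ndarray | None = None
    rho: float = 0.0
    outcome_types: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.effects = np.atleast_1d(np.asarray(self.effects, dtype=float))
        m = self.effects.shape[0]
        if self.intercepts is None:
            self.intercepts = np.zeros(m)
        self.intercepts = np.atleast_1d(np.asarray(self.intercepts, dtype=float))
        if self.intercepts.shape[0] != m:
            raise ValueError("intercepts and effects must have equal length")
        if not self.outcome_types:
            self.outcome_types = (CONTINUOUS,) * m
        self.outcome_types = tuple(self.outcome_types)
        if len(self.outcome_types) != m:
            raise ValueError("outcome_types length must match effects")
        lower = -1.0 / (m - 1) if m > 1 else -1.0
        if not (lower < self.rho < 1.0):
            raise ValueError(
                f"equicorrelation rho={self.rho} is not positive definite for m={m} "
                f"outcomes; require rho > {lower:.4f} (= -1/(m-1)) and rho < 1"
            )

    @property
    def n_outcomes(self) -> int:
        return self.effects.shape[0]

    def correlation_matrix(self) -> np.ndarray:
        m = self.n_outcomes
        return np.full((m, m), self.rho) + (1.0 - self.rho) * np.eye(m)


@dataclass
class MissingnessPlan:
    """Specification of the missingness mechanism for one trial.

    ``target_props`` gives the overall proportion missing per outcome.  For
    MAR the two per-arm probabilities satisfy
    ``p_control = mar_ratio * p_intervention`` with mean equal to the target
    ("1.5 times more likely" read as a probability ratio).  For MNAR the
    target must be a key of ``mnar_quartile_schedule``.
    ``cross_outcome_dependence`` is the correlation of the latent Gaussian
    copula driving the per-outcome missingness indicators (0 = independent).
    """

    mechanism: str = "none"
    target_props: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mar_ratio: float = 1.5
    mnar_quartile_schedule: dict[float, tuple[float, ...]] = field(
        default_factory=lambda: dict(MNAR_QUARTILE_SCHEDULE)
    )
    cross_outcome_dependence: float = 0.0

    def __post_init__(self) -> None:
        if self.mechanism not in ("none", "MCAR", "MAR", "MNAR"):
            raise ValueError(f"unknown missingness mechanism {self.mechanism!r}")
        self.target_props = np.atleast_1d(np.asarray(self.target_props, dtype=float))
        if ((self.target_props < 0) | (self.target_props > 1)).any():
            raise ValueError("target proportions must lie in [0, 1]")
        for key, rates in self.mnar_quartile_schedule.items():
            if abs(float(np.mean(rates)) - key) > 1e-9:
                raise ValueError(
                    f"MNAR schedule row {key}: quartile rates {rates} do not average "
                    f"to the overall proportion"
                )


def _simulate_latent(model: OutcomeModel, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if n % 2:
        raise ValueError("n must be even for equal allocation to the two arms")
    arm = np.repeat([0, 1], n // 2)
    chol = np.linalg.cholesky(model.correlation_matrix())
    eps = rng.standard_normal((n, model.n_outcomes)) @ chol.T
    latent = model.intercepts + np.outer(arm, model.effects) + eps
    return arm, latent


def _finish(model: OutcomeModel, arm: np.ndarray, latent: np.ndarray) -> TrialData:
    outcomes = latent.copy()
    for j, t in enumerate(model.outcome_types):
        if t == BINARY:
            outcomes[:, j] = (latent[:, j] > 0.0).astype(float)
    mask = np.ones_like(outcomes, dtype=bool)
    return TrialData(arm, outcomes, mask, model.outcome_types)


def simulate_continuous(model: OutcomeModel, n: int, seed=None) -> TrialData:
    """Simulate a complete trial with all-continuous outcomes."""
    if any(t != CONTINUOUS for t in model.outcome_types):
        raise ValueError("simulate_continuous requires all outcome types continuous")
    arm, latent = _simulate_latent(model, n, _as_rng(seed))
    return _finish(model, arm, latent)


def simulate_binary(model: OutcomeModel, n: int, seed=None) -> TrialData:
    """Simulate a complete trial with all-binary outcomes (latent threshold at 0)."""
    if any(t != BINARY for t in model.outcome_types):
        raise ValueError("simulate_binary requires all outcome types binary")
    arm, latent = _simulate_latent(model, n, _as_rng(seed))
    return _finish(model, arm, latent)


def simulate_mixed(model: OutcomeModel, n: int, seed=None) -> TrialData:
    """Simulate a complete trial with a mix of continuous and binary outcomes.

    Continuous columns are returned on the latent scale; binary columns are
    dichotomised at zero.
    """
    types = set(model.outcome_types)
    if types != {CONTINUOUS, BINARY}:
        raise ValueError("simulate_mixed requires both continuous and binary outcome types")
    arm, latent = _simulate_latent(model, n, _as_rng(seed))
    return _finish(model, arm, latent)


def simulate(model: OutcomeModel, n: int, seed=None) -> TrialData:
    """Dispatch to the appropriate simulator based on the model's outcome types."""
    types = set(model.outcome_types)
    if types == {CONTINUOUS}:
        return simulate_continuous(model, n, seed)
    if types == {BINARY}:
        return simulate_binary(model, n, seed)
    return simulate_mixed(model, n, seed)


def _quartile_groups(order: np.ndarray) -> list[np.ndarray]:
    # group sizes differ by at most 1 when n % 4 != 0, larger groups first
    n = order.shape[0]
    base, extra = divmod(n, 4)
    sizes = [base + (1 if g < extra else 0) for g in range(4)]
    bounds = np.cumsum([0] + sizes)
    return [order[bounds[g]: bounds[g + 1]] for g in range(4)]


def apply_missingness(data: TrialData, plan: MissingnessPlan, seed=None) -> TrialData:
    """Impose the plan's missingness mechanism on a complete trial.

    Returns a new :class:`TrialData` with the mask updated and masked values
    replaced by NaN; the complete values are kept on ``complete_outcomes``.
    """
    if plan.mechanism == "none":
        return replace(data)
    rng = _as_rng(seed)
    n, m = data.outcomes.shape
    props = plan.target_props
    if props.shape[0] != m:
        raise ValueError("target_props length must match the number of outcomes")
    complete = data.complete_outcomes if data.complete_outcomes is not None else data.outcomes
    missing = np.zeros((n, m), dtype=bool)

    if plan.mechanism in ("MCAR", "MAR"):
        c = plan.cross_outcome_dependence
        if c != 0.0:
            corr = np.full((m, m), c) + (1 - c) * np.eye(m)
            z = rng.standard_normal((n, m)) @ np.linalg.cholesky(corr).T
            u = _norm_cdf(z)
        else:
            u = rng.random((n, m))
        for j in range(m):
            if plan.mechanism == "MCAR":
                p = np.full(n, props[j])
            else:
                p_int = 2.0 * props[j] / (1.0 + plan.mar_ratio)
                p_ctrl = plan.mar_ratio * p_int
                if p_ctrl > 1.0:
                    raise ValueError(
                        f"MAR control-arm missingness probability {p_ctrl:.3f} exceeds 1 "
                        f"for target {props[j]} and ratio {plan.mar_ratio}"
                    )
                p = np.where(data.arm == 1, p_int, p_ctrl)
            missing[:, j] = u[:, j] < p
    else:  # MNAR
        keys = np.array(sorted(plan.mnar_quartile_schedule))
        for j in range(m):
            if props[j] == 0.0:
                continue
            match = np.isclose(keys, props[j], atol=1e-9)
            if not match.any():
                raise ValueError(
                    f"MNAR proportion {props[j]} is not a key of the quartile schedule "
                    f"{sorted(plan.mnar_quartile_schedule)}"
                )
            rates = plan.mnar_quartile_schedule[float(keys[match][0])]
            order = np.argsort(complete[:, j], kind="stable")
            for rate, idx in zip(rates, _quartile_groups(order)):
                if rate <= 0.0:
                    continue
                missing[idx, j] = rng.random(idx.shape[0]) < rate

    observed = data.observed & ~missing
    outcomes = np.where(observed, complete, np.nan)
    return TrialData(
        arm=data.arm,
        outcomes=outcomes,
        observed=observed,
        outcome_types=data.outcome_types,
        complete_outcomes=complete.copy(),
    )


def _norm_cdf(z: np.ndarray) -> np.ndarray:
    from scipy.special import ndtr

    return ndtr(z)


# ---------------------------------------------------------------------------
# wide-format CSV interface


def write_trial_csv(data: TrialData, path) -> None:
    """Write a trial as wide-format CSV: one row per participant, blank = missing."""
    cols = {"arm": data.arm}
    for j in range(data.n_outcomes):
        col = data.outcomes[:, j].astype(object)
        col[~data.observed[:, j]] = np.nan
        cols[f"y{j + 1}"] = col
    pd.DataFrame(cols).to_csv(path, index=False)


def read_trial_csv(path, outcome_types: tuple[str, ...] | None = None) -> TrialData:
    """Read a wide-format trial CSV (column ``arm`` plus outcome columns).

    Outcome types are inferred (a column whose observed values are all 0/1 is
    treated as binary) unless supplied explicitly.
    """
    df = pd.read_csv(path)
    if "arm" not in df.columns:
        raise ValueError("trial CSV must contain an 'arm' column")
    arm = df["arm"].to_numpy(dtype=int)
    ycols = [c for c in df.columns if c != "arm"]
    outcomes = df[ycols].to_numpy(dtype=float)
    observed = ~np.isnan(outcomes)
    if outcome_types is None:
        outcome_types = tuple(
            BINARY if np.isin(outcomes[observed[:, j], j], (0.0, 1.0)).all() else CONTINUOUS
            for j in range(outcomes.shape[1])
        )
    return TrialData(arm, outcomes, observed, outcome_types)
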