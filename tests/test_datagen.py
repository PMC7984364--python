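"""Generator checks: latent-normal outcome model and missingness mechanisms."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

from multirct import (
    MissingnessPlan,
    OutcomeModel,
    TrialData,
    apply_missingness,
    read_trial_csv,
    simulate,
    simulate_binary,
    simulate_continuous,
    simulate_mixed,
    write_trial_csv,
)
from multirct._bvn import bvn_cdf


class TestOutcomeModel:
    def test_rejects_non_positive_definite_equicorrelation(self):
        with pytest.raises(ValueError, match=r"-1/\(m-1\)"):
            OutcomeModel(effects=[0, 0, 0], rho=-0.6)

    @pytest.mark.parametrize("m,rho", [(2, -0.9), (4, -0.3), (2, 0.8)])
    def test_admissible_correlations_accepted(self, m, rho):
        OutcomeModel(effects=np.zeros(m), rho=rho)


class TestSimulateContinuous:
    def test_equal_allocation_and_complete_mask(self):
        data = simulate_continuous(OutcomeModel(effects=[0.35, 0.35]), 260, seed=1)
        assert data.arm.sum() == 130
        assert data.observed.all()
        assert data.outcomes.shape == (260, 2)

    def test_null_model_mean_difference_centred_on_zero(self):
        model = OutcomeModel(effects=[0.0, 0.0])
        diffs = []
        for s in range(1000):
            d = simulate_continuous(model, 260, seed=s)
            diffs.append(
                d.outcomes[d.arm == 1].mean(axis=0) - d.outcomes[d.arm == 0].mean(axis=0)
            )
        diffs = np.asarray(diffs)
        tol = 3 * diffs.std(axis=0, ddof=1) / np.sqrt(len(diffs))
        assert (np.abs(diffs.mean(axis=0)) < tol).all()

    def test_within_arm_correlation_matches_rho(self):
        model = OutcomeModel(effects=[0.35, 0.35], rho=0.8)
        d = simulate_continuous(model, 100_000, seed=2)
        r = np.corrcoef(d.outcomes[d.arm == 0].T)[0, 1]
        assert abs(r - 0.8) < 0.01

    def test_varying_effect_sizes_recovered(self):
        model = OutcomeModel(effects=[0.2, 0.4])
        d = simulate_continuous(model, 100_000, seed=3)
        diff = d.outcomes[d.arm == 1].mean(axis=0) - d.outcomes[d.arm == 0].mean(axis=0)
        assert np.allclose(diff, [0.2, 0.4], atol=0.01)


class TestSimulateBinary:
    def test_event_rates_50_control_65_intervention(self):
        shift = stats.norm.ppf(0.65)
        model = OutcomeModel(effects=[shift, shift], outcome_types=("binary", "binary"))
        d = simulate_binary(model, 100_000, seed=4)
        p_ctrl = d.outcomes[d.arm == 0].mean(axis=0)
        p_int = d.outcomes[d.arm == 1].mean(axis=0)
        assert np.allclose(p_ctrl, 0.50, atol=0.01)
        assert np.allclose(p_int, 0.65, atol=0.01)

    def test_null_rate_is_half_in_both_arms(self):
        model = OutcomeModel(effects=[0.0, 0.0], outcome_types=("binary", "binary"))
        d = simulate_binary(model, 40_000, seed=5)
        assert np.allclose(d.outcomes.mean(axis=0), 0.5, atol=0.015)

    def test_tetrachoric_correlation_preserves_latent_rho(self):
        # dichotomisation preserves rho as the tetrachoric, not phi, correlation
        model = OutcomeModel(effects=[0.0, 0.0], rho=0.8, outcome_types=("binary", "binary"))
        d = simulate_binary(model, 100_000, seed=6)
        y = d.outcomes[d.arm == 0]
        p11 = np.mean((y[:, 0] == 1) & (y[:, 1] == 1))
        h = stats.norm.ppf(1 - y[:, 0].mean())
        k = stats.norm.ppf(1 - y[:, 1].mean())
        tetra = brentq(lambda r: bvn_cdf(-h, -k, r) - p11, -0.99, 0.99)
        phi = np.corrcoef(y.T)[0, 1]
        assert abs(tetra - 0.8) < 0.02
        assert phi < 0.7  # the phi coefficient is attenuated


class TestSimulateMixed:
    def test_structure_and_binary_column(self):
        model = OutcomeModel(
            effects=[0.35, 0.35], outcome_types=("continuous", "binary")
        )
        d = simulate_mixed(model, 260, seed=7)
        assert d.outcomes.shape == (260, 2)
        assert set(np.unique(d.outcomes[:, 1])) <= {0.0, 1.0}

    def test_binary_intervention_rate_is_probit_of_effect(self):
        model = OutcomeModel(
            effects=[0.35, 0.35], outcome_types=("continuous", "binary")
        )
        d = simulate_mixed(model, 100_000, seed=8)
        assert abs(d.outcomes[d.arm == 1, 1].mean() - stats.norm.cdf(0.35)) < 0.01

    def test_independent_columns_uncorrelated(self):
        model = OutcomeModel(
            effects=[0.35, 0.35], rho=0.0, outcome_types=("continuous", "binary")
        )
        d = simulate_mixed(model, 100_000, seed=9)
        r = np.corrcoef(d.outcomes[d.arm == 0].T)[0, 1]
        assert abs(r) < 0.01


class TestApplyMissingness:
    def test_none_mechanism_is_identity(self, bivariate_trial):
        out = apply_missingness(bivariate_trial, MissingnessPlan("none", [0, 0]), seed=1)
        np.testing.assert_array_equal(out.outcomes, bivariate_trial.outcomes)
        assert out.observed.all()

    def test_mcar_hits_target_proportions(self):
        model = OutcomeModel(effects=[0, 0])
        d = simulate(model, 40_000, seed=10)
        out = apply_missingness(d, MissingnessPlan("MCAR", [0.3, 0.5]), seed=11)
        frac = 1 - out.observed.mean(axis=0)
        assert np.allclose(frac, [0.3, 0.5], atol=3 * np.sqrt(0.25 / 40_000) * 3)

    def test_mar_arm_probabilities_are_30_and_20_percent(self):
        # target 25%, ratio 1.5  =>  control 30%, intervention 20%
        model = OutcomeModel(effects=[0, 0])
        d = simulate(model, 100_000, seed=12)
        out = apply_missingness(d, MissingnessPlan("MAR", [0.25, 0.25]), seed=13)
        miss = ~out.observed
        p_ctrl = miss[out.arm == 0].mean(axis=0)
        p_int = miss[out.arm == 1].mean(axis=0)
        assert np.allclose(p_ctrl, 0.30, atol=0.01)
        assert np.allclose(p_int, 0.20, atol=0.01)

    def test_mar_probability_exceeding_one_rejected(self, bivariate_trial):
        with pytest.raises(ValueError, match="exceeds 1"):
            apply_missingness(bivariate_trial, MissingnessPlan("MAR", [0.9, 0.9]), seed=1)

    def test_mnar_quartile_expected_count_at_50_percent(self):
        # n=260: quartile groups of 65, rates (0,25,75,100)% -> expected 130 missing
        model = OutcomeModel(effects=[0, 0])
        counts = []
        for s in range(300):
            d = simulate(model, 260, seed=s)
            out = apply_missingness(d, MissingnessPlan("MNAR", [0.5, 0.0]), seed=s + 1000)
            counts.append((~out.observed[:, 0]).sum())
        mean = np.mean(counts)
        # expected 0 + 65*0.25 + 65*0.75 + 65 = 130; MC error of the mean
        assert abs(mean - 130.0) < 3 * np.std(counts, ddof=1) / np.sqrt(len(counts))

    def test_mnar_highest_quartile_always_missing_at_50(self):
        model = OutcomeModel(effects=[0, 0])
        d = simulate(model, 260, seed=20)
        out = apply_missingness(d, MissingnessPlan("MNAR", [0.5, 0.0]), seed=21)
        order = np.argsort(d.outcomes[:, 0])
        top = order[-65:]
        bottom = order[:65]
        assert (~out.observed[top, 0]).all()
        assert out.observed[bottom, 0].all()

    def test_mnar_proportion_not_in_schedule_rejected(self, bivariate_trial):
        with pytest.raises(ValueError, match="schedule"):
            apply_missingness(bivariate_trial, MissingnessPlan("MNAR", [0.33, 0.0]), seed=1)

    def test_schedule_rows_must_average_to_overall_rate(self):
        with pytest.raises(ValueError, match="average"):
            MissingnessPlan(
                "MNAR", [0.5, 0.0], mnar_quartile_schedule={0.5: (0, 0.5, 0.5, 0.9)}
            )

    def test_mcar_missingness_independent_of_value_mnar_is_not(self):
        model = OutcomeModel(effects=[0, 0])
        d = simulate(model, 50_000, seed=22)
        slopes = {}
        for mech, props in [("MCAR", [0.3, 0.0]), ("MNAR", [0.3, 0.0])]:
            out = apply_missingness(d, MissingnessPlan(mech, props), seed=23)
            miss = (~out.observed[:, 0]).astype(float)
            y = out.complete_outcomes[:, 0]
            slopes[mech] = np.cov(miss, y)[0, 1] / np.var(y)
        se = np.sqrt(0.3 * 0.7 / 50_000)  # rough MC scale for the MCAR slope
        assert abs(slopes["MCAR"]) < 4 * se
        assert slopes["MNAR"] > 0.1

    def test_complete_values_retained_but_masked(self, mcar_trial):
        assert np.isnan(mcar_trial.outcomes[~mcar_trial.observed]).all()
        assert not np.isnan(mcar_trial.complete_outcomes).any()


class TestCsvRoundTrip:
    def test_round_trip_preserves_values_mask_and_types(self, tmp_path, mcar_trial):
        path = tmp_path / "trial.csv"
        write_trial_csv(mcar_trial, path)
        back = read_trial_csv(path)
        np.testing.assert_array_equal(back.arm, mcar_trial.arm)
        np.testing.assert_array_equal(back.observed, mcar_trial.observed)
        obs = mcar_trial.observed
        np.testing.assert_allclose(back.outcomes[obs], mcar_trial.outcomes[obs])
        assert back.outcome_types == mcar_trial.outcome_types

    def test_binary_columns_inferred(self, tmp_path, mixed_trial):
        path = tmp_path / "mixed.csv"
        write_trial_csv(mixed_trial, path)
        assert read_trial_csv(path).outcome_types == ("continuous", "binary")

    def test_binary_values_validated(self):
        with pytest.raises(ValueError, match="outside"):
            TrialData(
                arm=[0, 1],
                outcomes=[[0.5], [1.0]],
                observed=[[True], [True]],
                outcome_types=("binary",),
            )
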