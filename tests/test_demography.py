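"""Composite likelihood, AIC bookkeeping, model selection, and the
parametric bootstrap (at reduced scale)."""

import math

import numpy as np
import pytest

from popdiv import (
    DemographicModel,
    FitSettings,
    JointSFS,
    aic,
    composite_log10_likelihood,
    fit_model,
    fold_joint_sfs,
    max_obs_log10_likelihood,
    model_selection,
    parametric_bootstrap,
    simulate_expected_sfs,
)
from popdiv.demography import FitResult
from popdiv.models import MODEL_N_PARAMS


def counts_sfs(values):
    """Counts on a 1 x C strip embedded in a grid with masked corners."""
    c = len(values)
    grid = np.zeros((2, c + 1))
    grid[1, :c] = values  # row 1 avoids both masked corners for c cells
    return JointSFS(grid)


class TestCompositeLikelihood:
    def test_two_cell_direct_evaluation(self):
        obs = counts_sfs([3, 1])
        exp = counts_sfs([0.5, 0.5])
        got = composite_log10_likelihood(obs, exp)
        assert got == pytest.approx(4 * math.log10(0.5), abs=1e-6)
        assert got == pytest.approx(-1.204120, abs=1e-6)

    def test_saturated_expected_attains_max_obs(self):
        obs = counts_sfs([3, 1, 6, 2])
        exp = counts_sfs([0.25, 1 / 12, 0.5, 1 / 6])
        assert composite_log10_likelihood(obs, exp) == pytest.approx(
            max_obs_log10_likelihood(obs)
        )

    def test_gibbs_inequality_fuzz(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            c = rng.integers(2, 12)
            obs = counts_sfs(rng.integers(0, 50, size=c))
            if obs.total() == 0:
                continue
            exp = counts_sfs(rng.random(c) + 1e-12)
            assert (
                composite_log10_likelihood(obs, exp)
                <= max_obs_log10_likelihood(obs) + 1e-9
            )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            composite_log10_likelihood(counts_sfs([1, 2]), counts_sfs([1, 2, 3]))


class TestMaxObsLikelihood:
    def test_direct_evaluation(self):
        # counts (3,1): 3*log10(0.75) + log10(0.25)
        assert max_obs_log10_likelihood(counts_sfs([3, 1])) == pytest.approx(
            -0.976876, abs=1e-6
        )

    def test_point_mass_is_zero(self):
        assert max_obs_log10_likelihood(counts_sfs([7, 0, 0])) == 0.0

    def test_uniform_counts_closed_form(self):
        m, c = 5, 4
        got = max_obs_log10_likelihood(counts_sfs([m] * c))
        assert got == pytest.approx(m * c * math.log10(1 / c))


class TestAic:
    def test_zero_parameters_zero_likelihood(self):
        assert aic(0, 0.0) == 0.0

    def test_natural_log_scale_conversion(self):
        # AIC = 2k - 2 ln(10) L10; for k=1, L10=-1: 2 + 2 ln 10
        assert aic(1, -1.0) == pytest.approx(2 + 2 * math.log(10))

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            aic(-1, 0.0)


def fake_fit(model_id, ll, max_obs=-100.0):
    model = DemographicModel(
        model_id=model_id, N_anc=1e4, N1=1e4, N2=1e4, T_div=1e4,
        T_change=1e3 if model_id != 1 else 0.0,
    )
    return FitResult(
        model=model, n_params=MODEL_N_PARAMS[model_id],
        log10_lhood=ll, max_obs_log10=max_obs,
        delta_likelihood=max_obs - ll, n_starts=1, n_genealogies=1,
    )


class TestModelSelection:
    def test_single_model_gets_weight_one(self):
        table = model_selection([fake_fit(1, -120.0)])
        assert table["weight"][0] == 1.0
        assert table["delta_AIC"][0] == 0.0

    def test_delta_aic_two_gives_logistic_weights(self):
        # contrive lhoods so AIC differs by exactly 2
        l1 = -120.0
        l2 = l1 - (2 * (MODEL_N_PARAMS[2] - MODEL_N_PARAMS[3]) + 2) / (
            2 * math.log(10)
        )
        table = model_selection([fake_fit(2, l1), fake_fit(3, l2)])
        assert table["delta_AIC"].max() == pytest.approx(2.0)
        assert sorted(table["weight"]) == pytest.approx(
            sorted([0.731059, 0.268941]), abs=1e-6
        )

    def test_weights_sum_to_one_and_rank_ascending(self):
        fits = [fake_fit(i, ll) for i, ll in zip((1, 2, 3, 4), (-150, -120, -130, -118))]
        table = model_selection(fits)
        assert table["weight"].sum() == pytest.approx(1.0)
        assert (table["AIC"].diff().dropna() >= 0).all()

    def test_mismatched_observed_sfs_rejected(self):
        with pytest.raises(ValueError):
            model_selection([fake_fit(1, -120, -100), fake_fit(2, -110, -90)])


@pytest.fixture(scope="module")
def small_model4_obs():
    """Reduced-scale observed SFS from a two-epoch migration model."""
    truth = DemographicModel(
        model_id=4, N_anc=2e4, N1=2e4, N2=2e4, T_div=4e4, T_change=4e3,
        m12_early=5e-4, m21_early=3e-4, m12_recent=5e-5, m21_recent=1e-4,
    )
    expected = fold_joint_sfs(simulate_expected_sfs(truth, 10, 8, 300_000, seed=61))
    return truth, JointSFS(expected.data * 50_000, folded=True)


class TestFitModel:
    def test_likelihood_prefers_truth_over_perturbed(self, small_model4_obs):
        truth, obs = small_model4_obs
        ll_truth = composite_log10_likelihood(
            obs, fold_joint_sfs(simulate_expected_sfs(truth, 10, 8, 50_000, seed=3)),
            50_000,
        )
        worse = truth.with_params(T_div=truth.T_div * 4)
        ll_worse = composite_log10_likelihood(
            obs, fold_joint_sfs(simulate_expected_sfs(worse, 10, 8, 50_000, seed=3)),
            50_000,
        )
        assert ll_truth > ll_worse

    def test_nested_model_never_beats_fuller_model(self, small_model4_obs):
        truth, obs = small_model4_obs
        fixed = {"N_anc": truth.N_anc, "N1": truth.N1, "N2": truth.N2}
        settings = FitSettings(n_starts=3, n_genealogies=3_000, max_iter=12, seed=71)
        f1 = fit_model(obs, 1, settings, fixed=fixed)
        f4 = fit_model(obs, 4, settings, fixed=fixed, init=truth)
        assert f4.log10_lhood >= f1.log10_lhood - 1.0
        assert f4.delta_likelihood >= 0
        assert f1.delta_likelihood >= 0

    def test_recovers_divergence_time_from_model1_data(self):
        truth = DemographicModel(
            model_id=1, N_anc=2e4, N1=2e4, N2=2e4, T_div=4e4
        )
        expected = fold_joint_sfs(
            simulate_expected_sfs(truth, 10, 8, 400_000, seed=81)
        )
        obs = JointSFS(expected.data * 200_000, folded=True)
        settings = FitSettings(n_starts=4, n_genealogies=5_000, max_iter=25, seed=82)
        fit = fit_model(
            obs, 1, settings,
            fixed={"N_anc": 2e4, "N1": 2e4, "N2": 2e4},
        )
        assert fit.model.T_div == pytest.approx(4e4, rel=0.2)


class TestParametricBootstrap:
    def test_intervals_ordered_and_deterministic(self, small_model4_obs):
        truth, obs = small_model4_obs
        fixed = {
            "N_anc": truth.N_anc, "N1": truth.N1, "N2": truth.N2,
            "T_change": truth.T_change,
            "m21_early": truth.m21_early,
            "m12_recent": truth.m12_recent, "m21_recent": truth.m21_recent,
        }
        settings = FitSettings(n_starts=1, n_genealogies=2_000, max_iter=15, seed=91)
        best = fit_model(obs, 4, settings, fixed=fixed, init=truth)
        ci1 = parametric_bootstrap(best, 20_000, n_reps=3, settings=settings,
                                   fixed=fixed)
        ci2 = parametric_bootstrap(best, 20_000, n_reps=3, settings=settings,
                                   fixed=fixed)
        assert (ci1["ci_low"] <= ci1["ci_high"]).all()
        assert np.allclose(ci1.values, ci2.values)

    def test_coverage_at_reduced_scale(self):
        # bootstrap intervals from the true model should cover the truth
        # for most parameters (free: T_div and m12_early); migration is
        # kept moderate (2Nm of order 1) so both are identifiable and the
        # check exercises the interval machinery rather than a likelihood
        # ridge
        truth = DemographicModel(
            model_id=4, N_anc=2e4, N1=2e4, N2=2e4, T_div=4e4, T_change=4e3,
            m12_early=6e-5, m21_early=3e-5, m12_recent=2e-5, m21_recent=4e-5,
        )
        fixed = {
            "N_anc": truth.N_anc, "N1": truth.N1, "N2": truth.N2,
            "T_change": truth.T_change,
            "m21_early": truth.m21_early,
            "m12_recent": truth.m12_recent, "m21_recent": truth.m21_recent,
        }
        settings = FitSettings(n_starts=1, n_genealogies=3_000, max_iter=24, seed=93)
        best = FitResult(
            model=truth, n_params=11, log10_lhood=0.0, max_obs_log10=0.0,
            delta_likelihood=0.0, n_starts=0, n_genealogies=0, n1h=10, n2h=8,
        )
        ci = parametric_bootstrap(best, 50_000, n_reps=20, settings=settings,
                                  fixed=fixed)
        covered = sum(
            ci.loc[p, "ci_low"] <= getattr(truth, p) <= ci.loc[p, "ci_high"]
            for p in ci.index
        )
        assert covered >= math.ceil(0.8 * len(ci.index))

    def test_zero_reps_rejected(self, small_model4_obs):
        truth, obs = small_model4_obs
        best = FitResult(
            model=truth, n_params=11, log10_lhood=0.0, max_obs_log10=0.0,
            delta_likelihood=0.0, n_starts=0, n_genealogies=0, n1h=10, n2h=8,
        )
        with pytest.raises(ValueError):
            parametric_bootstrap(best, 1000, n_reps=0)
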