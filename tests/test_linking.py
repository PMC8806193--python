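import numpy as np
import pytest

from driftbandit._mcmc import SamplerSettings
from driftbandit.ddm import choice_prob_closed_form
from driftbandit.linking import (
    MODELS,
    LinkingParams,
    dic,
    dic_table,
    fit_ddm_mcmc,
    linked_params,
    peri_cp_trialwise_fit,
    posterior_overlap,
    relative_position,
    simulate_linked_subject,
)
from driftbandit.observer import ObserverConfig
from driftbandit.task_env import TaskConfig


class TestLinkedParams:
    def test_null_coefficients_give_baselines(self):
        link = LinkingParams(v0=1.0, a0=0.8, beta_v=0.0, beta_a=0.0)
        v, a, clamped = linked_params(np.linspace(-2, 2, 9), np.linspace(0, 1, 9), link)
        assert np.all(v == 1.0) and np.all(a == 0.8) and not clamped.any()

    def test_regression_arithmetic(self):
        link = LinkingParams(v0=1.0, a0=0.8, beta_v=0.576, beta_a=0.05)
        v, a, _ = linked_params(np.array([0.5]), np.array([1.0]), link)
        assert v[0] == pytest.approx(1.288)
        assert a[0] == pytest.approx(0.85)

    def test_boundary_clamped_with_flag(self):
        link = LinkingParams(v0=1.0, a0=0.05, beta_v=0.0, beta_a=-1.0)
        _, a, clamped = linked_params(np.zeros(1), np.ones(1), link)
        assert a[0] == 0.01 and clamped[0]

    def test_cumulative_drift_variant(self):
        link = LinkingParams(v0=1.0, beta_v=0.5, cumulative_v=True)
        v, _, _ = linked_params(np.array([1.0, 1.0, 1.0]), np.zeros(3), link)
        np.testing.assert_allclose(v, [1.0, 1.5, 2.0])


class TestSimulateLinkedSubject:
    def test_null_linking_matches_closed_form_accuracy(self):
        # beta_v = beta_a = 0: constant policy, accuracy is the analytic
        # upper-boundary probability at (v0, a0)
        task = TaskConfig(lambda_mean=50, n_trials=2000, rt_bounds=(0.05, 5.0))
        obs = ObserverConfig.from_task(task)
        link = LinkingParams(v0=0.8, a0=1.0, beta_v=0.0, beta_a=0.0, t_r=0.26)
        data = simulate_linked_subject(task, obs, link, np.random.default_rng(0))
        p_true = choice_prob_closed_form(0.8, 1.0, 0.5, 1.0)
        se = np.sqrt(p_true * (1 - p_true) / len(data))
        assert abs(data["correct"].mean() - p_true) < 4 * se

    def test_rts_respect_bounds(self, linked_session):
        _, _, _, data = linked_session
        assert data["rt"].between(0.1, 2.5).all()

    def test_accuracy_dips_then_recovers_at_change_points(self, linked_session):
        _, _, _, data = linked_session
        cps = np.flatnonzero(data["is_change_point"].to_numpy())
        cps = cps[(cps > 6) & (cps < len(data) - 6)]
        acc = data["correct"].to_numpy()
        pre = np.mean([acc[c - 3 : c].mean() for c in cps])
        at = np.mean([acc[c : c + 2].mean() for c in cps])
        late = np.mean([acc[c + 4 : c + 7].mean() for c in cps])
        assert at < pre
        assert late > at


class TestPosteriorOverlap:
    def test_identical_samples_overlap_fully(self):
        x = np.random.default_rng(0).normal(size=2000)
        assert posterior_overlap(x, x) > 0.95

    def test_distant_distributions_do_not_overlap(self):
        rng = np.random.default_rng(1)
        assert posterior_overlap(rng.normal(0, 1, 2000), rng.normal(10, 1, 2000)) < 0.01

    def test_unit_normals_two_apart(self):
        # analytic overlap of N(0,1) and N(2,1): 2 Phi(-1) = 0.3173
        rng = np.random.default_rng(2)
        ov = posterior_overlap(rng.normal(0, 1, 20000), rng.normal(2, 1, 20000))
        assert ov == pytest.approx(0.3173, abs=0.03)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            posterior_overlap(np.zeros(100), np.zeros(100))


@pytest.fixture(scope="module")
def small_fit(linked_session):
    _, _, _, data = linked_session
    settings = SamplerSettings(n_samples=1500, burn=800, thin=1)
    fit = fit_ddm_mcmc(data, MODELS["I"], settings, np.random.default_rng(3))
    return data, fit


class TestFitAndDic:

    def test_parameter_recovery_in_wide_interval(self, small_fit):
        _, fit = small_fit
        m = fit.mean()
        # generating values: v0=1.2, a0=0.8, t_r=0.26, beta_v=0.5, beta_a=0.1
        assert abs(m["a0"] - 0.8) < 0.1
        assert abs(m["t_r"] - 0.26) < 0.02
        lo, hi = fit.ci("beta_v")
        assert lo > 0  # sign of the belief->drift coupling recovered

    def test_posterior_set_consistency(self, small_fit):
        _, fit = small_fit
        assert fit.draws.shape == (fit.settings.n_kept, len(fit.param_names))
        assert np.all(np.isfinite(fit.loglik))

    def test_dic_identical_fits_tie(self, small_fit):
        _, fit = small_fit
        assert dic(fit).dic == dic(fit).dic

    def test_dic_table_deltas(self, linked_session):
        _, _, _, data = linked_session
        settings = SamplerSettings(n_samples=900, burn=500, thin=1)
        fits = {
            name: fit_ddm_mcmc(data, MODELS[name], settings, np.random.default_rng(4))
            for name in ("IV", "VII")
        }
        table = dic_table(fits)
        assert table.loc["VII", "delta_dic_null"] == 0.0
        # data carry a real belief->drift effect: model IV must win clearly
        assert table.loc["IV", "delta_dic_null"] < -10

    def test_nonpositive_rt_rejected(self, linked_session):
        _, _, _, data = linked_session
        broken = data.copy()
        broken.loc[0, "rt"] = -0.1
        with pytest.raises(ValueError):
            fit_ddm_mcmc(broken, MODELS["VII"], SamplerSettings(n_samples=20, burn=10, thin=1))


class TestPeriChangePoint:
    def test_relative_positions_windowed(self):
        import pandas as pd

        cp = np.zeros(30, bool)
        cp[[10, 20]] = True
        df = pd.DataFrame({"is_change_point": cp})
        pos = relative_position(df, (-1, 3))
        assert pos[9] == -1 and pos[10] == 0 and pos[13] == 3
        assert pos[15] > 100  # outside the window

    def test_insufficient_trials_error_names_bin(self):
        import pandas as pd

        cp = np.zeros(40, bool)
        cp[20] = True
        df = pd.DataFrame(
            {
                "is_change_point": cp,
                "rt": np.full(40, 0.5),
                "correct": np.ones(40, int),
                "choice": np.ones(40, int),
            }
        )
        with pytest.raises(ValueError, match="relative position"):
            peri_cp_trialwise_fit(df, vary="v", min_epochs=20)

    def test_recovers_injected_drift_dip(self):
        # generative truth: v collapses at the change point, recovers after
        rng = np.random.default_rng(5)
        from driftbandit.ddm import DDMParams, simulate_trials_batch
        import pandas as pd

        n_epochs, epoch_len = 60, 10
        n = n_epochs * epoch_len
        cp = np.zeros(n, bool)
        cp[np.arange(1, n_epochs) * epoch_len] = True
        pos = relative_position(pd.DataFrame({"is_change_point": cp}), (-1, 3))
        v = np.where(pos == 0, 0.2, 1.5)  # deep dip at the switch
        params = DDMParams(v=0.0, a=0.9, z_rel=0.5, t_r=0.26, sigma=1.0)
        choices, rts, cens = simulate_trials_batch(
            params, n, rng=rng, v=v, a=np.full(n, 0.9)
        )
        data = pd.DataFrame(
            {
                "is_change_point": cp,
                "rt": rts,
                "correct": choices,
                "choice": choices,
            }
        ).loc[~cens]
        fit = peri_cp_trialwise_fit(
            data,
            vary="v",
            settings=SamplerSettings(n_samples=2600, burn=1400, thin=1),
            rng=rng,
            min_epochs=20,
        )
        ov = fit.adjacent_overlaps()
        assert ov[(-1, 0)] < 0.05  # change-point sensitivity detected
        assert ov[(1, 2)] > 0.05  # stable positions stay indistinct
        assert fit.positions == [-1, 0, 1, 2, 3]
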