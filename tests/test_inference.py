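import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from orligt import (
    ORLParams,
    SamplerConfig,
    StudyConfig,
    SubjectTrials,
    constrain,
    fit_hierarchical,
    fit_subject_map,
    generate_study,
    make_classic_schedule,
    recovery_report,
    save_fit,
    simulate_agent,
    truth_manifest,
    unconstrain,
)


class TestTransforms:
    @given(
        st.floats(0.001, 0.999), st.floats(0.001, 0.999),
        st.floats(0.01, 4.99), st.floats(-5, 5), st.floats(-5, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_across_support(self, a, b, k, f, p):
        theta = np.array([a, b, k, f, p])
        assert np.allclose(constrain(unconstrain(theta)), theta, atol=1e-12)

    def test_constrain_maps_into_support(self):
        z = np.array([[-50.0, 50.0, -50.0, -3.0, 3.0]])
        theta = constrain(z)[0]
        assert 0 <= theta[0] <= 1 and 0 <= theta[1] <= 1 and 0 <= theta[2] <= 5
        assert theta[3] == -3.0 and theta[4] == 3.0


class TestSubjectMAP:
    def test_long_series_recovers_learning_rates(self, classic_schedule):
        # averaged over independent 500-trial series: single realizations
        # of a softmax policy still carry noticeable estimator noise
        truth = ORLParams(a_rew=0.6, a_pun=0.05, k_prime=0.5, beta_f=1.0, beta_p=0.5)
        estimates = []
        for seed in range(3):
            trials = simulate_agent(truth, classic_schedule, 500, seed=seed)
            fit = fit_subject_map(trials, seed=0)
            assert fit.diagnostics["converged"]
            estimates.append(fit.estimates.iloc[0])
        mean_est = sum(estimates) / len(estimates)
        assert mean_est["a_rew"] == pytest.approx(0.6, abs=0.1)
        assert mean_est["a_pun"] == pytest.approx(0.05, abs=0.1)

    def test_flat_likelihood_returns_prior_mode(self):
        # all-zero outcomes never move EV or EF, so beta_F is unidentified
        # and the MAP falls back to its prior mode at 0
        rng = np.random.default_rng(1)
        trials = SubjectTrials("s", rng.integers(1, 5, 100), np.zeros(100), np.zeros(100))
        fit = fit_subject_map(trials, n_starts=4, seed=0)
        assert abs(fit.estimates.iloc[0]["beta_f"]) < 0.05
        assert abs(fit.estimates.iloc[0]["beta_p"]) < 1.0  # weak perseveration info only

    def test_short_series_warns_and_empty_errors(self, classic_schedule):
        trials = simulate_agent(ORLParams(0.3, 0.1, 0.5, 1.0, 0.5), classic_schedule, 10, seed=0)
        with pytest.warns(UserWarning):
            fit_subject_map(trials, n_starts=2, seed=0)
        with pytest.raises(ValueError):
            fit_subject_map(SubjectTrials("s", [], [], []))

    def test_pointwise_loglik_shape(self, classic_schedule):
        trials = simulate_agent(ORLParams(0.3, 0.1, 0.5, 1.0, 0.5), classic_schedule, 60, seed=0)
        fit = fit_subject_map(trials, n_starts=2, seed=0)
        assert fit.pointwise.shape == (1, 60)
        assert np.all(fit.pointwise <= 0)


@pytest.fixture(scope="module")
def hier_fit_20():
    """Default-sampler hierarchical fit of a 20-subject synthetic study."""
    study = generate_study(StudyConfig(n_per_cell=5, seed=3))
    return study, fit_hierarchical(study, sampler=SamplerConfig(seed=0))


class TestHierarchicalFit:
    def test_diagnostics_converge_on_small_study(self, hier_fit_20):
        _, fit = hier_fit_20
        assert fit.diagnostics["max_rhat"] <= 1.05
        assert fit.diagnostics["warnings"] == []

    def test_estimates_respect_supports(self, hier_fit_20):
        _, fit = hier_fit_20
        est = fit.estimates
        assert ((est["a_rew"] >= 0) & (est["a_rew"] <= 1)).all()
        assert ((est["a_pun"] >= 0) & (est["a_pun"] <= 1)).all()
        assert ((est["k_prime"] >= 0) & (est["k_prime"] <= 5)).all()

    def test_pointwise_draws_cover_all_subjects_and_trials(self, hier_fit_20):
        study, fit = hier_fit_20
        assert fit.pointwise_draws.shape[1:] == (study.n_subjects, 100)
        assert np.all(fit.pointwise_draws <= 0)

    def test_likelihood_path_matches_sequence_loglik(self, hier_fit_20):
        # the sampler's stored pointwise log-lik must agree with the public
        # scalar path at the same parameter values
        from orligt import sequence_loglik

        study, fit = hier_fit_20
        theta = fit.draws["theta"][0, -1]  # one arbitrary retained draw
        subject0 = study.subjects[0].trials
        _, pw = sequence_loglik(subject0, ORLParams(*theta[0]))
        # recompute draw 0's pointwise for subject 0 from scratch
        from orligt import pointwise_loglik_matrix

        direct = pointwise_loglik_matrix(
            subject0.choices[None, :], subject0.net[None, :],
            theta[0:1, 0], theta[0:1, 1], theta[0:1, 2], theta[0:1, 3], theta[0:1, 4],
        )[0]
        assert np.allclose(pw, direct, atol=1e-10)

    def test_zero_heterogeneity_shrinks_group_sd(self):
        # all subjects share one a_rew: its group SD posterior should sit
        # well below that of a heterogeneous study fitted identically
        schedule = make_classic_schedule()
        cfg = SamplerConfig(chains=2, warmup=300, draws=300, thin=1, seed=0)

        def build(sd, seed):
            rng = np.random.default_rng(seed)
            subs = []
            for i in range(12):
                a = 0.3 if sd == 0 else float(np.clip(rng.normal(0.3, sd), 0.02, 0.98))
                p = ORLParams(a, 0.1, 0.3, 1.5, 1.0)
                subs.append(simulate_agent(p, schedule, 100, seed=1000 + i, subject=f"s{i}"))
            return subs

        fit_same = fit_hierarchical(build(0.0, 1), sampler=cfg)
        fit_varied = fit_hierarchical(build(0.25, 2), sampler=cfg)
        tau_same = fit_same.draws["tau"][:, :, 0].mean()
        tau_varied = fit_varied.draws["tau"][:, :, 0].mean()
        assert tau_same < tau_varied

    def test_single_subject_rejected(self, classic_schedule):
        trials = [simulate_agent(ORLParams(0.3, 0.1, 0.5, 1, 1), classic_schedule, 100, seed=0)]
        with pytest.raises(ValueError):
            fit_hierarchical(trials)

    def test_unequal_lengths_rejected(self, classic_schedule):
        p = ORLParams(0.3, 0.1, 0.5, 1, 1)
        trials = [
            simulate_agent(p, classic_schedule, 100, seed=0, subject="a"),
            simulate_agent(p, classic_schedule, 50, seed=1, subject="b"),
        ]
        with pytest.raises(ValueError):
            fit_hierarchical(trials)


class TestRecoveryReport:
    def _truth(self, estimates):
        truth = estimates.copy()
        truth.insert(0, "subject", truth.index)
        return truth.reset_index(drop=True)

    def test_perfect_estimates(self, hier_fit_20):
        _, fit = hier_fit_20
        report = recovery_report(fit, self._truth(fit.estimates))
        assert np.allclose(report["correlation"], 1.0)
        assert np.allclose(report["bias"], 0.0, atol=1e-12)
        assert np.allclose(report["rmse"], 0.0, atol=1e-12)

    def test_constant_offset_shows_as_bias(self, hier_fit_20):
        _, fit = hier_fit_20
        truth = self._truth(fit.estimates - 0.1)
        report = recovery_report(fit, truth)
        assert np.allclose(report["correlation"], 1.0)
        assert np.allclose(report["bias"], 0.1, atol=1e-12)

    def test_subject_mismatch_rejected(self, hier_fit_20):
        _, fit = hier_fit_20
        truth = self._truth(fit.estimates).iloc[:3]
        with pytest.raises(ValueError):
            recovery_report(fit, truth)

    def test_default_study_recovery_meets_gates(self, hier_fit_20):
        study, fit = hier_fit_20
        report = recovery_report(fit, truth_manifest(study))
        # learning rates are the well-identified parameters
        assert report.loc["a_rew", "correlation"] > 0.5
        assert report.loc["a_pun", "correlation"] > 0.3


def test_save_fit_round_trips_files(hier_fit_20, tmp_path):
    _, fit = hier_fit_20
    paths = save_fit(fit, tmp_path)
    assert paths["estimates"].exists() and paths["draws"].exists()
    loaded = pd.read_csv(paths["estimates"]).set_index("subject")
    assert np.allclose(loaded.to_numpy(), fit.estimates.to_numpy())
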