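"""Staged WLS estimation: objective, uncertainty, recovery, error handling."""

import numpy as np
import pytest

import tgicomb as tg
from tgicomb.estimation import STAGE1_NAMES, _scaled_residuals
from tgicomb.exceptions import ConfigurationError, NonIdentifiableError

TRUE = {"w0": 0.05, "lambda0": 0.15, "lambda1": 0.25,
        "k1a": 0.9, "k2a": 0.08, "k1b": 1.4, "k2b": 0.06}


def toy_arm(arm_id, arm_type, times, weights, ses=None):
    ses = np.zeros_like(np.asarray(weights, float)) if ses is None else ses
    return tg.TumorArm(arm_id=arm_id, arm_type=arm_type, regimens={},
                       times=np.asarray(times, float),
                       weights=np.asarray(weights, float), ses=ses)


@pytest.fixture(scope="module")
def noise_free_dataset():
    fx = tg.experiment_fixture("c1")
    pk = tg.example_pk_library(fx.drug_a, fx.drug_b)
    spec = tg.example_model_spec(gamma=2.0)
    ds, truth = tg.generate_experiment(spec, fx.regimen_a, fx.regimen_b, pk,
                                       noise=tg.NoiseModel(cv=0.0))
    return ds, truth


class TestObjective:
    def test_matches_brute_force_double_loop(self):
        arms = [
            toy_arm("a", "control", [1, 2, 3], [0.2, 0.4, 0.8]),
            toy_arm("b", "single_a", [1, 2], [0.2, 0.3]),
            toy_arm("c", "single_b", [1, 2, 3, 4], [0.1, 0.2, 0.3, 0.5]),
        ]
        ds = tg.TumorDataset(tuple(arms))
        preds = {"a": np.array([0.25, 0.35, 0.9]),
                 "b": np.array([0.18, 0.33]),
                 "c": np.array([0.09, 0.22, 0.28, 0.55])}
        got = tg.wls_objective(ds, lambda arm, p: preds[arm.arm_id], None)
        brute = 0.0
        for arm in arms:
            ssr = 0.0
            for y, yhat in zip(arm.weights, preds[arm.arm_id]):
                ssr += (y - yhat) ** 2 / y ** 2
            brute += ssr / arm.n_obs
        assert got == pytest.approx(brute, abs=1e-14)
        # the residual vector squares to the same number
        r = _scaled_residuals(arms, [preds[a.arm_id] for a in arms])
        assert float(r @ r) == pytest.approx(brute, abs=1e-14)

    def test_equal_relative_misfit_arms_contribute_equally(self):
        dense = toy_arm("dense", "control", np.arange(1, 13), np.full(12, 1.0))
        sparse = toy_arm("sparse", "single_a", [1, 2, 3], np.full(3, 2.0))
        ds = tg.TumorDataset((dense, sparse))
        # both arms off by +10% everywhere
        got = tg.wls_objective(ds, lambda arm, p: arm.weights * 1.1, None)
        assert got == pytest.approx(2 * 0.1 ** 2, rel=1e-12)

    def test_perfect_fit_is_zero(self):
        ds = tg.TumorDataset((toy_arm("a", "control", [1, 2], [0.5, 0.9]),))
        assert tg.wls_objective(ds, lambda arm, p: arm.weights, None) == 0.0


class TestRMSE:
    def test_values(self):
        y = np.array([0.5, 1.0, 1.5])
        assert tg.rmse(y, y) == 0.0
        assert tg.rmse(y, y + 0.1) == pytest.approx(0.1, rel=1e-12)
        pred = np.array([0.4, 1.1, 1.8])
        assert tg.rmse(y, pred) == pytest.approx(
            np.sqrt(((y - pred) ** 2).mean()), rel=1e-14)


class TestParameterCV:
    def test_linear_model_closed_form(self):
        """y = theta*x: cov = s^2 / sum(x^2) with s^2 = SSR/(n-1)."""
        rng = np.random.default_rng(7)
        x = np.linspace(1.0, 5.0, 40)
        theta = 2.0
        y = theta * x + rng.normal(0, 0.1, x.size)
        theta_hat = float(x @ y / (x @ x))
        resid = y - theta_hat * x
        J = (-x)[:, None]
        cv, se, cov, ok = tg.parameter_cv(J, resid, np.array([theta_hat]))
        s2 = resid @ resid / (x.size - 1)
        assert ok
        assert cov[0, 0] == pytest.approx(s2 / (x @ x), rel=1e-10)
        assert cv[0] == pytest.approx(100 * np.sqrt(s2 / (x @ x)) / theta_hat, rel=1e-10)

    def test_cv_shrinks_with_sample_size(self):
        rng = np.random.default_rng(11)
        def cv_for(n):
            x = np.tile(np.linspace(1.0, 5.0, 10), n // 10)
            y = 2.0 * x + rng.normal(0, 0.1, x.size)
            th = float(x @ y / (x @ x))
            cv, *_ = tg.parameter_cv((-x)[:, None], y - th * x, np.array([th]))
            return cv[0]
        assert cv_for(160) < 0.6 * cv_for(10)

    def test_rank_deficient_jacobian_flagged(self):
        x = np.linspace(1, 5, 20)
        J = np.column_stack([x, x])  # duplicated column
        cv, se, cov, ok = tg.parameter_cv(J, np.ones(20), np.array([1.0, 1.0]))
        assert not ok
        assert np.all(np.isnan(cv))


class TestStagedFit:
    def test_noise_free_recovery(self, noise_free_dataset):
        """All 7 single-agent parameters and gamma recovered within 1 percent
        from noise-free synthetic data."""
        ds, truth = noise_free_dataset
        model = tg.CombinationTGIModel(ds)
        staged = model.fit(seed=1, n_starts=2)
        for name in STAGE1_NAMES:
            assert staged.params[name] == pytest.approx(TRUE[name], rel=0.01), name
        assert staged.gamma == pytest.approx(2.0, rel=0.01)
        assert staged.interaction.rmse < 1e-4
        # spec round-trips into a simulatable model specification
        assert staged.spec.gamma == staged.gamma

    def test_staged_determinism(self, noise_free_dataset):
        ds, _ = noise_free_dataset
        r1 = tg.CombinationTGIModel(ds).fit(seed=3, n_starts=1)
        r2 = tg.CombinationTGIModel(ds).fit(seed=3, n_starts=1)
        assert (r1.params == r2.params).all()
        assert r1.interaction.objective == r2.interaction.objective

    def test_antagonistic_gamma_sign_recovered(self):
        """True gamma = -1 with 10 percent noise: the staged estimate keeps the
        antagonistic sign in every sampled replicate."""
        fx = tg.experiment_fixture("c1")
        pk = tg.example_pk_library(fx.drug_a, fx.drug_b)
        spec = tg.example_model_spec(gamma=-1.0)
        for r in range(4):
            ds, _ = tg.generate_experiment(spec, fx.regimen_a, fx.regimen_b, pk,
                                           noise=tg.NoiseModel(cv=0.10, seed=800 + r))
            staged = tg.CombinationTGIModel(ds).fit(seed=1, n_starts=1)
            assert staged.gamma < 0

    def test_summary_contains_estimates(self, noise_free_dataset):
        ds, _ = noise_free_dataset
        staged = tg.CombinationTGIModel(ds).fit(seed=1, n_starts=1)
        text = staged.summary()
        assert "gamma" in text and "CV%" in text and "RMSE" in text


class TestJointFit:
    def test_noise_free_joint_recovery_and_stage_agreement(self, noise_free_dataset):
        ds, _ = noise_free_dataset
        model = tg.CombinationTGIModel(ds)
        joint = model.fit_joint(seed=1, n_starts=1)
        for name in STAGE1_NAMES:
            assert joint.params[name] == pytest.approx(TRUE[name], rel=0.01), name
        assert joint.params["gamma"] == pytest.approx(2.0, rel=0.01)
        staged = model.fit(seed=1, n_starts=1)
        # staged and joint gamma agree within their joint confidence radii
        radius = 1.96 * (joint.bse["gamma"] + staged.gamma_se) + 1e-6
        assert abs(joint.params["gamma"] - staged.gamma) <= radius


class TestErrorCases:
    def test_missing_control_arm(self, noise_free_dataset):
        ds, _ = noise_free_dataset
        arms = tuple(a for a in ds.arms if a.arm_type is not tg.ArmType.control)
        with pytest.raises(NonIdentifiableError):
            tg.CombinationTGIModel(tg.TumorDataset(arms, ds.pk_library)).fit_single_agents()

    def test_control_only_dataset_cannot_identify_potency(self, noise_free_dataset):
        ds, _ = noise_free_dataset
        control = tuple(a for a in ds.arms if a.arm_type is tg.ArmType.control)
        model = tg.CombinationTGIModel(tg.TumorDataset(control, ds.pk_library),
                                       drug_a="Drug C2", drug_b="CPT-11")
        with pytest.raises(NonIdentifiableError):
            model.fit_single_agents()

    def test_combination_only_dataset_rejected_by_joint(self, noise_free_dataset):
        ds, _ = noise_free_dataset
        combo = tuple(a for a in ds.arms if a.arm_type is tg.ArmType.combination)
        with pytest.raises(NonIdentifiableError):
            tg.CombinationTGIModel(tg.TumorDataset(combo, ds.pk_library)).fit_joint()

    def test_incomplete_fixed_set_rejected(self, noise_free_dataset):
        ds, _ = noise_free_dataset
        with pytest.raises(ConfigurationError):
            tg.CombinationTGIModel(ds).fit_interaction({"w0": 0.05})

    def test_unresolved_drug_in_regimens_rejected(self):
        arm = tg.TumorArm(arm_id="x", arm_type="single_a",
                          regimens={"mystery": tg.DosingRegimen("mystery")},
                          times=np.array([1.0]), weights=np.array([0.1]),
                          ses=np.array([0.0]))
        with pytest.raises(ConfigurationError):
            tg.TumorDataset((arm,), pk_library={})


class TestPrediction:
    def test_identical_regimen_reproduces_training_curve(self, noise_free_dataset):
        ds, _ = noise_free_dataset
        staged = tg.CombinationTGIModel(ds).fit(seed=1, n_starts=1)
        combo = ds.by_type(tg.ArmType.combination)[0]
        traj, idx = staged.predict(combo.regimens, combo.times)
        fitted = staged.interaction.fitted_curves[combo.arm_id]
        # the stored fitted curve lives on a 241-point reporting grid, so
        # agreement is limited by its linear interpolation (~1e-3 relative)
        np.testing.assert_allclose(traj.total_at(combo.times),
                                   fitted.total_at(combo.times), rtol=2e-3)
        assert idx.classification == "synergistic"

    def test_dose_increase_raises_predicted_sc_for_positive_gamma(self, noise_free_dataset):
        ds, _ = noise_free_dataset
        staged = tg.CombinationTGIModel(ds).fit(seed=1, n_starts=1)
        combo = ds.by_type(tg.ArmType.combination)[0]
        base_idx = staged.predict(combo.regimens, combo.times)[1]
        boosted = {d: (reg.scaled(2.0) if d == "Drug C2" else reg)
                   for d, reg in combo.regimens.items()}
        boosted_idx = staged.predict(boosted, combo.times)[1]
        assert boosted_idx.sc > base_idx.sc
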