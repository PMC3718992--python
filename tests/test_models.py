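"""TGI ODE systems: growth regimes, reductions, monotonicity, mass balance."""

import dataclasses

import numpy as np
import pytest

import tgicomb as tg
from tgicomb.exceptions import ModelValidityWarning, ValidationError
from tgicomb.models import FirstAttemptSpec, proliferation_rate

GROWTH = tg.TumorGrowthParameters(w0=0.1, lambda0=0.1, lambda1=0.2, psi=20.0)


def zero_profile():
    return tg.ConcentrationProfile.zero()


def switched_closed_form(g, t):
    """Hard-switch (psi -> inf) growth law: exponential to weight lambda1/lambda0,
    then linear at slope lambda1."""
    w_th = g.lambda1 / g.lambda0
    t_sw = np.log(w_th / g.w0) / g.lambda0
    t = np.asarray(t, dtype=float)
    return np.where(t < t_sw, g.w0 * np.exp(g.lambda0 * t),
                    w_th + g.lambda1 * (t - t_sw))


class TestUnperturbedGrowth:
    def test_exponential_regime(self):
        t = np.linspace(0.0, 10.0, 21)
        w = tg.unperturbed_growth(GROWTH, t).total
        np.testing.assert_allclose(w, 0.1 * np.exp(0.1 * t), rtol=5e-3)

    def test_linear_regime_slope(self):
        t = np.linspace(0.0, 120.0, 241)
        w = tg.unperturbed_growth(GROWTH, t).total
        late = (w[-1] - w[-5]) / (t[-1] - t[-5])
        assert late == pytest.approx(GROWTH.lambda1, rel=1e-3)

    def test_psi_limit_closed_form_within_2pct(self):
        t = np.linspace(0.0, 80.0, 161)
        w = tg.unperturbed_growth(GROWTH, t).total
        ref = switched_closed_form(GROWTH, t)
        assert np.max(np.abs(w - ref) / ref) < 0.02

    def test_monotonically_increasing(self):
        t = np.linspace(0.0, 60.0, 200)
        w = tg.unperturbed_growth(GROWTH, t).total
        assert np.all(np.diff(w) > 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            tg.TumorGrowthParameters(w0=-0.1, lambda0=0.1, lambda1=0.2)
        with pytest.raises(ValidationError):
            tg.TumorGrowthParameters(w0=0.1, lambda0=0.0, lambda1=0.2)


class TestSingleAgent:
    DRUG = tg.DrugEffectParameters(k1=1.0, k2=0.1)

    def test_no_drug_equals_control(self):
        t = np.linspace(0.0, 40.0, 81)
        control = tg.unperturbed_growth(GROWTH, t).total
        treated = tg.simulate_single_agent(GROWTH, self.DRUG, zero_profile(), t).total
        np.testing.assert_allclose(treated, control, rtol=1e-8)

    def test_zero_potency_equals_control(self, c1_setup):
        # tight solver tolerance so restart noise at dose times stays below
        # the 1e-8 comparison level
        t = np.linspace(0.0, 40.0, 81)
        control = tg.unperturbed_growth(GROWTH, t, rtol=1e-10, atol=1e-12).total
        inert = tg.DrugEffectParameters(k1=1.0, k2=0.0)
        treated = tg.simulate_single_agent(GROWTH, inert, c1_setup["conc_b"], t,
                                           rtol=1e-10, atol=1e-12).total
        np.testing.assert_allclose(treated, control, rtol=1e-8)

    def test_treated_below_control_under_constant_exposure(self):
        t = np.linspace(0.0, 40.0, 161)
        control = tg.unperturbed_growth(GROWTH, t).total
        treated = tg.simulate_single_agent(GROWTH, self.DRUG, lambda t: 1.0, t).total
        assert np.all(treated <= control + 1e-12)
        assert np.all(treated[1:] < control[1:])


class TestCombination:
    def test_no_drug_matches_control_and_states_stay_empty(self, example_spec):
        t = np.linspace(0.0, 40.0, 81)
        comb = tg.simulate_combination(example_spec, zero_profile(), zero_profile(), t)
        control = tg.unperturbed_growth(example_spec.growth, t)
        np.testing.assert_allclose(comb.total, control.total, rtol=1e-8)
        assert np.all(comb.states[:, 1:] == 0.0)

    @pytest.mark.parametrize("n_draws", [5])
    def test_reduces_to_single_agent_when_one_drug_absent(self, c1_setup, rng, n_draws):
        """With c_b = 0, the drug-A margin of the 16-state system reproduces the
        independently coded 4-state single-agent chain."""
        t = np.linspace(0.0, 45.0, 91)
        for _ in range(n_draws):
            growth = tg.TumorGrowthParameters(
                w0=rng.uniform(0.02, 0.2), lambda0=rng.uniform(0.08, 0.3),
                lambda1=rng.uniform(0.1, 0.5))
            da = tg.DrugEffectParameters(k1=rng.uniform(0.3, 3.0), k2=rng.uniform(0.01, 0.2))
            db = tg.DrugEffectParameters(k1=rng.uniform(0.3, 3.0), k2=rng.uniform(0.01, 0.2))
            spec = tg.CombinationModelSpec(growth, da, db, gamma=rng.uniform(-1.0, 2.0))
            comb = tg.simulate_combination(spec, c1_setup["conc_a"], zero_profile(), t)
            single = tg.simulate_single_agent(growth, da, c1_setup["conc_a"], t)
            np.testing.assert_allclose(comb.total, single.total, rtol=1e-8, atol=1e-10)
            np.testing.assert_allclose(comb.margin_a(), single.margin_a(),
                                       rtol=1e-7, atol=1e-10)

    def test_ptgc_is_gamma_zero(self, example_spec, c1_setup):
        t = np.linspace(0.0, 45.0, 91)
        ca, cb = c1_setup["conc_a"], c1_setup["conc_b"]
        ptgc = tg.simulate_zero_interaction(example_spec, ca, cb, t)
        explicit = tg.simulate_combination(dataclasses.replace(example_spec, gamma=0.0),
                                           ca, cb, t)
        np.testing.assert_array_equal(ptgc.states, explicit.states)

    @pytest.mark.parametrize("gamma,side", [(1.5, "below"), (-0.5, "above")])
    def test_combination_sits_on_correct_side_of_ptgc(self, example_spec, c1_setup,
                                                      gamma, side):
        t = np.linspace(0.0, 45.0, 91)
        ca, cb = c1_setup["conc_a"], c1_setup["conc_b"]
        spec = dataclasses.replace(example_spec, gamma=gamma)
        ptgc = tg.simulate_zero_interaction(spec, ca, cb, t).total
        comb = tg.simulate_combination(spec, ca, cb, t).total
        if side == "below":
            assert np.all(comb <= ptgc + 1e-9)
        else:
            assert np.all(comb >= ptgc - 1e-9)

    def test_gamma_monotonicity(self, c1_setup, rng):
        """w(t; gamma1) <= w(t; gamma2) whenever gamma1 >= gamma2."""
        t = np.linspace(0.0, 45.0, 91)
        ca, cb = c1_setup["conc_a"], c1_setup["conc_b"]
        for _ in range(3):
            growth = tg.TumorGrowthParameters(
                w0=rng.uniform(0.03, 0.1), lambda0=rng.uniform(0.1, 0.25),
                lambda1=rng.uniform(0.15, 0.4))
            da = tg.DrugEffectParameters(k1=rng.uniform(0.5, 2.0), k2=rng.uniform(0.02, 0.1))
            db = tg.DrugEffectParameters(k1=rng.uniform(0.5, 2.0), k2=rng.uniform(0.02, 0.1))
            gammas = [-0.3, 0.0, 0.5, 2.0]
            curves = [tg.simulate_combination(
                tg.CombinationModelSpec(growth, da, db, g), ca, cb, t).total
                for g in gammas]
            for lo_curve, hi_curve in zip(curves, curves[1:]):
                assert np.all(hi_curve <= lo_curve + 1e-9)

    def test_k2a_monotonicity(self, example_spec, c1_setup):
        t = np.linspace(0.0, 45.0, 91)
        ca, cb = c1_setup["conc_a"], c1_setup["conc_b"]
        w_ref = tg.simulate_combination(example_spec, ca, cb, t).total
        stronger = dataclasses.replace(
            example_spec, drug_a=tg.DrugEffectParameters(example_spec.drug_a.k1,
                                                         2 * example_spec.drug_a.k2))
        w_strong = tg.simulate_combination(stronger, ca, cb, t).total
        assert np.all(w_strong <= w_ref + 1e-9)

    def test_mass_balance(self, example_spec, c1_setup):
        """Finite-difference dw/dt equals f_p - k1a*sum_j x_3j - k1b*sum_i x_i3."""
        ca, cb = c1_setup["conc_a"], c1_setup["conc_b"]
        dt = 0.01
        t = np.arange(0.0, 40.0 + dt, dt)
        tr = tg.simulate_combination(example_spec, ca, cb, t)
        w = tr.total
        fd = (w[2:] - w[:-2]) / (2 * dt)
        fp = np.array([proliferation_rate(x00, wt, example_spec.growth)
                       for x00, wt in zip(tr.states[1:-1, 0], w[1:-1])])
        rhs = (fp - example_spec.drug_a.k1 * tr.margin_a()[1:-1, 3]
               - example_spec.drug_b.k1 * tr.margin_b()[1:-1, 3])
        bps = np.union1d(ca.breakpoints, cb.breakpoints)
        interior = np.all(np.abs(t[1:-1][:, None] - bps[None, :]) > 2 * dt, axis=1)
        scale = np.max(np.abs(fd))
        assert np.max(np.abs(fd - rhs)[interior]) / scale < 1e-3

    def test_states_nonnegative(self, example_spec, c1_setup):
        t = np.linspace(0.0, 45.0, 181)
        tr = tg.simulate_combination(example_spec, c1_setup["conc_a"],
                                     c1_setup["conc_b"], t)
        assert np.all(tr.states >= 0.0)
        assert tr.max_clip < 1e-9

    def test_negative_gamma_validity_warning(self, example_spec, c1_setup):
        spec = dataclasses.replace(example_spec, gamma=-5.0)
        t = np.linspace(0.0, 45.0, 91)
        with pytest.warns(ModelValidityWarning):
            tg.simulate_combination(spec, c1_setup["conc_a"], c1_setup["conc_b"], t)

    def test_trajectory_frame_round_trip(self, example_spec, c1_setup):
        t = np.linspace(0.0, 20.0, 11)
        tr = tg.simulate_combination(example_spec, c1_setup["conc_a"],
                                     c1_setup["conc_b"], t)
        df = tr.to_frame()
        assert list(df.columns[:2]) == ["time_days", "x_00"]
        assert df.shape == (11, 18)
        np.testing.assert_array_equal(df["w_total_g"].to_numpy(), tr.total)


class TestFirstAttempt:
    def make_spec(self, example_spec, k2a_b=None, k2b_a=None):
        return FirstAttemptSpec(
            example_spec.growth, example_spec.drug_a, example_spec.drug_b,
            k2a_b=example_spec.drug_a.k2 if k2a_b is None else k2a_b,
            k2b_a=example_spec.drug_b.k2 if k2b_a is None else k2b_a)

    def test_equal_cross_potencies_match_gamma_zero(self, example_spec, c1_setup):
        t = np.linspace(0.0, 45.0, 91)
        ca, cb = c1_setup["conc_a"], c1_setup["conc_b"]
        fa = tg.simulate_first_attempt(self.make_spec(example_spec), ca, cb, t)
        ptgc = tg.simulate_zero_interaction(example_spec, ca, cb, t)
        np.testing.assert_allclose(fa.total, ptgc.total, rtol=1e-8)

    def test_single_drug_reduction(self, example_spec, c1_setup):
        t = np.linspace(0.0, 45.0, 91)
        fa = tg.simulate_first_attempt(self.make_spec(example_spec, k2a_b=1.0, k2b_a=1.0),
                                       c1_setup["conc_a"], zero_profile(), t)
        single = tg.simulate_single_agent(example_spec.growth, example_spec.drug_a,
                                          c1_setup["conc_a"], t)
        np.testing.assert_allclose(fa.total, single.total, rtol=1e-8)

    def test_sensitivity_study_properties(self, example_spec, c1_setup):
        t = np.linspace(0.0, 45.0, 91)
        tab = tg.potency_sensitivity_study(self.make_spec(example_spec),
                                           c1_setup["conc_a"], c1_setup["conc_b"], t,
                                           fold_range=(0.2, 0.5, 1.0, 2.0, 5.0))
        at1 = tab.loc[tab["fold"] == 1.0]
        assert float(at1["cross_potency_dev"].iloc[0]) == 0.0
        # deviations grow away from fold = 1 on either side
        up = tab[tab["fold"] >= 1.0].sort_values("fold")["cross_potency_dev"].to_numpy()
        down = tab[tab["fold"] <= 1.0].sort_values("fold", ascending=False)[
            "cross_potency_dev"].to_numpy()
        assert np.all(np.diff(up) >= -1e-12)
        assert np.all(np.diff(down) >= -1e-12)
        # cross-potency perturbations matter far less than direct-potency ones
        off = tab[tab["fold"] != 1.0]
        assert np.all(off["cross_potency_dev"].to_numpy()
                      < off["direct_potency_dev"].to_numpy())
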