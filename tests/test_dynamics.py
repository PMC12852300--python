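"""ODE assembly, integration against closed forms, events and outcome classes."""

import numpy as np
import pytest

from conftest import make_morphology, single_component_toy
from ironcell.core import (Component, IronCenterProfile, Reaction,
                           ReactionNetwork, ValidationError)
from ironcell.dynamics import (PerturbationSpec, assemble_system,
                               classify_outcome, integrate,
                               perturbation_experiment, verify_steady_state)
from ironcell.kinetics import RateLaw
from ironcell.model import CellModel
from ironcell.stoichiometry import build_smatrix


def toy_model(alpha=0.05, x_star=10.0):
    net = single_component_toy(alpha=alpha, x_star=x_star)
    return CellModel(net).fit(regulate=False)


class TestAssembly:
    def test_rhs_vanishes_at_reference(self, fitted):
        rhs = fitted.kinetic.rhs(0.0, fitted.kinetic.U_ss)
        scale = np.abs(fitted.kinetic.rates(fitted.kinetic.U_ss)).max()
        assert np.abs(rhs).max() < 1e-8 * scale

    def test_toy_rhs_closed_form(self):
        res = toy_model()
        model = res.kinetic
        x_star = model.U_ss[0]
        alpha = 0.05
        for x in (0.0, 0.5 * x_star, x_star, 2 * x_star):
            rhs = model.rhs(0.0, np.array([x]))
            assert rhs[0] == pytest.approx(alpha * x_star - alpha * x, rel=1e-9,
                                           abs=1e-12)

    def test_zero_state_has_only_imports_active(self):
        res = toy_model()
        rates = res.kinetic.rates(np.zeros(1))
        by_id = dict(zip(res.S.reaction_index, rates))
        assert by_id["TIN"] > 0          # nutrient import still runs
        assert by_id["DX"] == 0          # dilution proportional to [X]

    def test_missing_law_rejected(self, fitted):
        with pytest.raises(ValidationError, match="laws"):
            assemble_system(fitted.network, fitted.S, list(fitted.laws)[:-1],
                            {n: 1.0 for n in fitted.S.component_index})


class TestIntegration:
    def test_unperturbed_stays_at_reference(self, fitted):
        traj = fitted.simulate(500.0)
        assert traj.success
        assert np.abs(traj.normalized() - 1).max() < 1e-3
        assert traj.outcome.cls == "at_reference_steady_state"

    def test_single_component_matches_exponential_return(self):
        """After a step to 1.5 x*, the linear toy relaxes as
        x(t) = x* + 0.5 x* e^(-alpha t)."""
        alpha = 0.05
        res = toy_model(alpha=alpha)
        model = res.kinetic
        x_star = model.U_ss[0]
        traj = integrate(model, np.array([1.5 * x_star]), 200.0,
                         rtol=1e-10, atol=1e-12)
        expected = x_star + 0.5 * x_star * np.exp(-alpha * traj.times)
        np.testing.assert_allclose(traj.states[:, 0], expected, rtol=1e-6)

    def test_event_changes_only_target_at_event_time(self, fitted):
        step = PerturbationSpec("concentration_step", "FC", 1.5, 50.0)
        traj = fitted.simulate(100.0, events=[step], classify=False)
        i_fc = traj.component_index.index("FC")
        before = traj.times < 50.0
        at = np.argmin(np.abs(traj.times - 50.0))
        # target jumps by the factor; every other component is continuous
        pre_state = traj.states[before][-1]
        post_state = traj.states[at]
        assert post_state[i_fc] == pytest.approx(1.5 * pre_state[i_fc], rel=1e-3)
        others = np.arange(len(pre_state)) != i_fc
        np.testing.assert_allclose(post_state[others], pre_state[others],
                                   rtol=1e-3)

    def test_times_strictly_increasing(self, fitted):
        traj = fitted.simulate(200.0, events=[
            PerturbationSpec("concentration_step", "FC", 1.2, 50.0),
            PerturbationSpec("nutrient_step", "IRON", 0.9, 100.0)])
        assert (np.diff(traj.times) > 0).all()

    def test_event_after_horizon_rejected(self, fitted):
        with pytest.raises(ValidationError):
            fitted.simulate(10.0, events=[
                PerturbationSpec("concentration_step", "FC", 1.5, 50.0)])


class TestConservation:
    def test_closed_subnetwork_conserves_iron(self):
        """With dilution disabled, total Fe atoms (summed over compartments
        with volume weights) stay constant along trajectories."""
        morph = make_morphology({"c": 0.7, "m": 0.3}, alpha=0.01)
        fe1 = IronCenterProfile(FO=1.0)
        comps = (Component("A", "c", fe1), Component("B", "m", fe1))
        rxn = Reaction("RAB", reactants=(("A", 1.0),), products=(("B", 1.0),),
                       kinetics_kind="mass_action")
        net = ReactionNetwork(comps, (rxn,), morph)
        S = build_smatrix(net)
        law = RateLaw("RAB", "mass_action", k=0.3,
                      substrates=(("A", 1.0, 5.0),))
        model = assemble_system(net, S, [law], {"A": 8.0, "B": 1.0},
                                nutrient_levels={})
        traj = integrate(model, np.array([8.0, 1.0]), 50.0)
        total = traj.states[:, 0] * 0.7 + traj.states[:, 1] * 0.3
        np.testing.assert_allclose(total, total[0], rtol=1e-8)
        assert traj.states[0, 0] != pytest.approx(traj.states[-1, 0], rel=1e-3)


class TestOutcomes:
    def test_constant_trajectory_is_at_reference(self, fitted):
        traj = fitted.simulate(100.0)
        out = classify_outcome(traj, fitted.kinetic)
        assert out.cls == "at_reference_steady_state"

    def test_mutual_autocatalysis_blows_up(self):
        """Two components catalyzing each other's synthesis quadratically;
        without regulation the positive feedback diverges."""
        morph = make_morphology({"c": 1 - 1e-9, "m": 1e-9}, alpha=0.2)
        comps = (
            Component("N", "c", role="nutrient", ss_cellular_concentration=10),
            Component("A", "c", ss_cellular_concentration=1.0),
            Component("B", "c", ss_cellular_concentration=1.0),
        )
        rxns = (
            Reaction("BA", reactants=(("N", 1.0),), products=(("A", 1.0),),
                     catalysts=("B", "B")),
            Reaction("BB", reactants=(("N", 1.0),), products=(("B", 1.0),),
                     catalysts=("A", "A")),
        )
        net = ReactionNetwork(comps, rxns, morph).with_dilutions()
        res = CellModel(net).fit(regulate=False)
        traj = res.simulate(400.0, events=[
            PerturbationSpec("concentration_step", "A", 1.3, 5.0)],
            classify=False)
        out = classify_outcome(traj, res.kinetic)
        assert out.cls == "blowup"

    def test_damped_return_reports_convergence_time(self):
        res = toy_model(alpha=0.05)
        traj = res.simulate(400.0, events=[
            PerturbationSpec("concentration_step", "X", 1.5, 10.0)])
        out = traj.outcome
        assert out.cls == "at_reference_steady_state"
        assert 10.0 < out.convergence_time < 400.0

    def test_new_steady_state_after_nutrient_shift(self, fitted):
        traj, table = fitted.perturb("IRON", 0.8, t_end=60000.0)
        assert traj.outcome.cls == "new_steady_state"
        ratios = table["ratio_new_over_old"]
        assert np.isfinite(ratios).all() and (ratios > 0).all()
        # less iron in the medium lowers the labile cytosolic pool
        assert traj.outcome.ratios["FC"] < 1.0

    def test_null_perturbation_keeps_reference_and_unit_ratios(self, fitted):
        traj, table = fitted.perturb("FC", 1.0, t_end=2000.0)
        assert traj.outcome.cls == "at_reference_steady_state"
        np.testing.assert_allclose(table["ratio_new_over_old"], 1.0, atol=1e-6)


class TestVerify:
    def test_reference_passes(self, fitted):
        rep = verify_steady_state(fitted.kinetic, fitted.kinetic.U_ss)
        assert rep.attrs["ok"]

    def test_doubled_component_dominates_residual(self, fitted):
        U = fitted.kinetic.U_ss.copy()
        i = fitted.kinetic.component_index.index("FC")
        U[i] *= 2
        rep = verify_steady_state(fitted.kinetic, U)
        assert not rep.attrs["ok"]
        assert rep["scaled_residual"]["FC"] > 1e-8

    def test_zero_state_flags_imports(self):
        res = toy_model()
        rep = verify_steady_state(res.kinetic, np.zeros(1))
        assert not rep.attrs["ok"]
        assert rep.loc["X", "dominant_reaction"] == "TIN"
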