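"""Nonnegative null-space bases: construction, singleton structure, weight
solving, and equivalence with a brute-force flux-cone oracle on small systems.
"""

import itertools

import numpy as np
import pytest
from scipy.optimize import nnls

from ironcell.basic_pathways import (RateAssignment, build_null_basis_G,
                                     build_steady_state, classify_pathway,
                                     compose_rates, decompose_rates,
                                     dilution_rate_assignment, extreme_rays,
                                     make_nonnegative_basis,
                                     select_independent_set, singleton_stats,
                                     solve_weights)
from ironcell.core import (CellMorphology, Component, Reaction,
                           ReactionNetwork, ValidationError)
from ironcell.stoichiometry import build_smatrix
from ironcell.synthetic import SyntheticSpec, synthetic_network


# ---------------------------------------------------------------------------
# independent oracle: vertices of {S x = 0, x >= 0, sum x = 1} by enumerating
# basic feasible solutions over column subsets
# ---------------------------------------------------------------------------

def flux_cone_vertices(S, tol=1e-9):
    m, n = S.shape
    A = np.vstack([S, np.ones(n)])
    b = np.zeros(m + 1)
    b[-1] = 1.0
    rank = np.linalg.matrix_rank(A)
    vertices = []
    for cols in itertools.combinations(range(n), rank):
        sub = A[:, cols]
        if np.linalg.matrix_rank(sub) < rank:
            continue
        x_sub, *_ = np.linalg.lstsq(sub, b, rcond=None)
        x = np.zeros(n)
        x[list(cols)] = x_sub
        if np.all(x >= -tol) and np.linalg.norm(A @ x - b) < 1e-8:
            x = np.clip(x, 0, None)
            if not any(np.allclose(x, v, atol=1e-7) for v in vertices):
                vertices.append(x)
    return vertices


def cone_equal(generators_a, generators_b, tol=1e-7):
    """Each generator of one set must be a nonnegative combination of the
    other's (both directions)."""
    A = np.column_stack(generators_a)
    B = np.column_stack(generators_b)
    for x in generators_a:
        _, resid = nnls(B, x)
        if resid > tol * max(1.0, np.linalg.norm(x)):
            return False
    for x in generators_b:
        _, resid = nnls(A, x)
        if resid > tol * max(1.0, np.linalg.norm(x)):
            return False
    return True


# ---------------------------------------------------------------------------
# G construction
# ---------------------------------------------------------------------------

class TestNullBasisG:
    def test_single_component_toy(self):
        morph = CellMorphology.from_fractions(1e-15, 0.01, {"c": 0.8, "m": 0.2})
        comps = (Component("N", "c", role="nutrient",
                           ss_cellular_concentration=1.0),
                 Component("X", "m"))
        rxn = Reaction("TIN", reactants=(("N", 1.0),), products=(("X", 1.0),))
        net = ReactionNetwork(comps, (rxn,), morph).with_dilutions()
        S = build_smatrix(net)
        G = build_null_basis_G(S)
        d = -S.matrix[0, 1]
        np.testing.assert_allclose(G[:, 0], [1.0, S.matrix[0, 0] / d])
        assert np.abs(S.matrix @ G).max() < 1e-12

    def test_fixture_G_is_null_basis(self, fitted):
        G = build_null_basis_G(fitted.S)
        assert G.shape == (fitted.S.n, fitted.S.n - fitted.S.m)
        assert np.abs(fitted.S.matrix @ G).max() < 1e-10


# ---------------------------------------------------------------------------
# W construction
# ---------------------------------------------------------------------------

class TestNonnegativeBasis:
    def test_already_nonnegative_G_kept(self):
        morph = CellMorphology.from_fractions(1e-15, 0.01, {"c": 0.9, "m": 0.1})
        comps = (Component("N", "c", role="nutrient",
                           ss_cellular_concentration=1.0),
                 Component("X", "c"))
        rxn = Reaction("TIN", reactants=(("N", 1.0),), products=(("X", 1.0),),
                       kinetics_kind="mass_action")
        net = ReactionNetwork(comps, (rxn,), morph).with_dilutions()
        S = build_smatrix(net)
        G = build_null_basis_G(S)
        basis = make_nonnegative_basis(G, S)
        assert basis.W.min() >= 0
        # identical up to column scaling
        ratio = basis.W[:, 0] / G[:, 0]
        np.testing.assert_allclose(ratio, ratio[0])

    def test_two_component_chain_matches_brute_force(self, toy_chain_network):
        S = build_smatrix(toy_chain_network)
        G = build_null_basis_G(S)
        assert G.min() < 0  # the chain column mixes signs
        basis = make_nonnegative_basis(G, S)
        assert basis.W.min() >= 0
        assert np.abs(S.matrix @ basis.W).max() < 1e-8
        verts = flux_cone_vertices(S.matrix)
        assert cone_equal([basis.W[:, j] for j in range(basis.r)], verts)

    def test_fixture_basis_contract(self, fitted):
        basis, S = fitted.basis, fitted.S
        assert basis.W.shape == (S.n, S.r)
        assert basis.W.min() >= 0
        assert np.abs(S.matrix @ basis.W).max() < 1e-8 * max(
            1, np.abs(basis.W).max())
        assert np.linalg.matrix_rank(basis.W, tol=1e-9) == basis.r
        # every row and column carries at least one nonzero
        assert (basis.W.max(axis=1) > 0).all()
        assert (basis.W.max(axis=0) > 0).all()

    def test_null_space_preserved_both_ways(self, fitted):
        G = build_null_basis_G(fitted.S)
        W = fitted.basis.W
        for j in range(G.shape[1]):
            c, *_ = np.linalg.lstsq(W, G[:, j], rcond=None)
            assert np.linalg.norm(W @ c - G[:, j]) < 1e-8 * max(
                1, np.linalg.norm(G[:, j]))
        for j in range(W.shape[1]):
            c, *_ = np.linalg.lstsq(G, W[:, j], rcond=None)
            assert np.linalg.norm(G @ c - W[:, j]) < 1e-8 * max(
                1, np.linalg.norm(W[:, j]))

    def test_extreme_rays_of_orthant_are_axes(self):
        rays = extreme_rays(np.zeros((0, 3)).reshape(0, 3))
        assert rays.shape == (3, 3)
        # columns are the coordinate axes, in some order
        assert np.allclose(rays @ rays.T, np.eye(3))
        assert rays.min() >= 0


class TestSingletonStats:
    def test_identity(self):
        sparsity, n_single, srank, n_def = singleton_stats(np.eye(4))
        assert n_single == 4 and srank == 1.0 and n_def == 0
        assert sparsity == pytest.approx(0.75)

    def test_all_ones(self):
        _, n_single, _, n_def = singleton_stats(np.ones((3, 3)))
        assert n_single == 0 and n_def == 3

    def test_fixture_stats_consistent(self, fitted):
        sparsity, n_single, srank, n_def = singleton_stats(fitted.basis.W)
        assert sparsity == pytest.approx(fitted.basis.sparsity)
        assert n_single == len(fitted.basis.singleton_rows)
        assert n_def == len(fitted.basis.deficient_columns)
        assert 0 < sparsity < 1


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

class TestWeights:
    def test_singleton_rows_read_off_weights(self):
        from ironcell.basic_pathways import BasicPathwayBasis

        # hand-built 2-column basis: row 0 is a singleton of column 0 with
        # entry 2, so an assigned rate R_0 = 6 pins c_0 = 3 directly
        W = np.array([[2.0, 0.0], [1.0, 1.0], [0.0, 4.0]])
        basis = BasicPathwayBasis(
            W=W, reaction_index=["R1", "R2", "R3"],
            singleton_rows={0: 0, 2: 1}, deficient_columns=[],
            sparsity=1 / 3)
        c = solve_weights(basis, RateAssignment(
            independent={"R1": 6.0, "R3": 8.0}))
        np.testing.assert_allclose(c, [3.0, 2.0])

    def test_identity_basis_returns_assignment(self):
        from ironcell.basic_pathways import BasicPathwayBasis

        basis = BasicPathwayBasis(
            W=np.eye(3), reaction_index=["A", "B", "C"],
            singleton_rows={0: 0, 1: 1, 2: 2}, deficient_columns=[],
            sparsity=2 / 3)
        c = solve_weights(basis, RateAssignment(
            independent={"A": 1.5, "B": 0.0, "C": 7.0}))
        np.testing.assert_allclose(c, [1.5, 0.0, 7.0])

    def test_fixture_roundtrip_and_zero_set(self, fitted, fixture_model):
        rates = fixture_model.steady_rates
        R_true = np.array([rates[rid] for rid in fitted.S.reaction_index])
        assert np.abs(fitted.steady.R_cell - R_true).max() < 1e-8 * max(
            1, R_true.max())
        assert fitted.steady.C_BP.min() >= 0
        for rid in fixture_model.zero_set:
            assert fitted.steady.rate(rid) == 0.0

    def test_compose_decompose_roundtrip(self, fitted, rng):
        basis = fitted.basis
        c = rng.uniform(0, 5, basis.r)
        R = compose_rates(basis, c)
        assert R.min() >= 0
        assert np.abs(fitted.S.matrix @ R).max() < 1e-8 * max(1, R.max())
        c2, resid = decompose_rates(basis, R)
        assert resid < 1e-8 * max(1, np.linalg.norm(R))
        np.testing.assert_allclose(c2, c, atol=1e-7 * max(1, c.max()))

    def test_decompose_zero(self, fitted):
        c, resid = decompose_rates(fitted.basis, np.zeros(fitted.S.n))
        assert np.all(c == 0) and resid == 0

    def test_scale_covariance(self, fitted, fixture_model):
        lam = 3.7
        assign = dilution_rate_assignment(
            fixture_model.network,
            extra={k: lam * v for k, v in fixture_model.steady_rates.items()},
            zero_set=set(fixture_model.zero_set), basis=fitted.basis)
        scaled_net = fixture_model.network.with_concentrations(
            {c.name: lam * c.ss_cellular_concentration
             for c in fixture_model.network.dynamic_components})
        assign = dilution_rate_assignment(
            scaled_net, extra={k: lam * v
                               for k, v in fixture_model.steady_rates.items()},
            zero_set=set(fixture_model.zero_set), basis=fitted.basis)
        c = solve_weights(fitted.basis, assign)
        np.testing.assert_allclose(c, lam * fitted.steady.C_BP,
                                   atol=1e-8 * max(1, c.max()))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            RateAssignment(independent={"R1": -1.0})

    def test_wrong_count_rejected(self, fitted):
        with pytest.raises(ValidationError, match="exactly r"):
            solve_weights(fitted.basis, RateAssignment(independent={"DFC": 1.0}))

    def test_all_zero_assignment_gives_zero_state(self, fitted, fixture_model):
        chosen = select_independent_set(fitted.basis, fixture_model.network)
        ss = build_steady_state(
            fixture_model.network, fitted.basis,
            RateAssignment(independent={rid: 0.0 for rid in chosen}),
            {c.name: 0.0 for c in fixture_model.network.dynamic_components})
        assert np.all(ss.R_cell == 0)


# ---------------------------------------------------------------------------
# interpretation
# ---------------------------------------------------------------------------

class TestClassifyPathway:
    def test_import_to_destination_chain(self, toy_chain_network):
        S = build_smatrix(toy_chain_network)
        basis = make_nonnegative_basis(build_null_basis_G(S), S)
        reports = [classify_pathway(basis.W[:, j], toy_chain_network,
                                    list(S.reaction_index), column=j)
                   for j in range(basis.r)]
        # every pathway consumes the nutrient; at least one ends in B, the
        # terminal destination
        assert all(r.nutrients_consumed == ["N"] for r in reports)
        assert any("B" in r.destinations for r in reports)
        assert not any(r.cyclic for r in reports)

    def test_futile_loop_is_cyclic(self):
        morph = CellMorphology.from_fractions(1e-15, 0.01, {"c": 0.9, "m": 0.1})
        comps = (Component("A", "c"), Component("B", "c"))
        rxns = (
            Reaction("RAB", reactants=(("A", 1.0),), products=(("B", 1.0),)),
            Reaction("RBA", reactants=(("B", 1.0),), products=(("A", 1.0),)),
        )
        net = ReactionNetwork(comps, rxns, morph).with_dilutions()
        S = build_smatrix(net)
        w = np.array([1.0, 1.0, 0.0, 0.0])  # loop flux, no dilution
        assert np.abs(S.matrix @ w).max() < 1e-12
        report = classify_pathway(w, net, list(S.reaction_index))
        assert report.cyclic
        assert not report.destinations and not report.nutrients_consumed

    def test_fixture_pathways_have_interpretations(self, fitted):
        reports = fitted.pathway_reports()
        with_flux = [r for j, r in enumerate(reports)
                     if fitted.steady.C_BP[j] > 1e-9]
        # active pathways in a growing cell consume nutrients
        assert all(r.nutrients_consumed or r.cyclic for r in with_flux)
        assert any("IRON" in r.nutrients_consumed for r in reports)


# ---------------------------------------------------------------------------
# oracle equivalence and parameter recovery on synthetic networks
# ---------------------------------------------------------------------------

class TestSyntheticOracles:
    @pytest.mark.parametrize("seed", range(6))
    def test_small_network_cone_oracle(self, seed):
        """Brute-force oracle on <= 8 reaction systems: every basis column is
        a nonnegative null vector of the enumerated flux cone, the basis spans
        the same null space, and when the cone is simplicial (as many extreme
        rays as null-space dimensions) the generator sets coincide exactly."""
        spec = SyntheticSpec(n_components=3, n_nutrients=1, n_destinations=1,
                             n_compartments=2, seed=seed)
        sm = synthetic_network(spec)
        S = build_smatrix(sm.network)
        if S.n > 8:
            pytest.skip("oracle reserved for <= 8 reaction systems")
        basis = make_nonnegative_basis(build_null_basis_G(S), S)
        verts = flux_cone_vertices(S.matrix)
        assert verts, "flux cone should be nontrivial"
        # containment: each pathway is a nonnegative combination of the
        # brute-force extreme rays
        B = np.column_stack(verts)
        for j in range(basis.r):
            _, resid = nnls(B, basis.W[:, j])
            assert resid < 1e-7 * max(1, np.linalg.norm(basis.W[:, j]))
        # span: each extreme ray is reproduced by the (signed) basis
        for v in verts:
            c, *_ = np.linalg.lstsq(basis.W, v, rcond=None)
            assert np.linalg.norm(basis.W @ c - v) < 1e-7
        if len(verts) == basis.r:  # simplicial cone: exact equivalence
            assert cone_equal([basis.W[:, j] for j in range(basis.r)], verts)

    @pytest.mark.parametrize("seed", range(5))
    def test_parameter_recovery(self, seed, rng):
        spec = SyntheticSpec(n_components=8, n_nutrients=2, n_destinations=2,
                             n_compartments=3, seed=seed)
        sm = synthetic_network(spec)
        S = build_smatrix(sm.network)
        basis = make_nonnegative_basis(build_null_basis_G(S), S)
        c_star = rng.uniform(0.1, 4.0, basis.r)
        R_star = compose_rates(basis, c_star)
        chosen = select_independent_set(basis, sm.network)
        row_of = {rid: i for i, rid in enumerate(basis.reaction_index)}
        assign = RateAssignment(
            independent={rid: float(R_star[row_of[rid]]) for rid in chosen})
        c_hat = solve_weights(basis, assign)
        np.testing.assert_allclose(c_hat, c_star, rtol=1e-6, atol=1e-9)
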