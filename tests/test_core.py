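"""Element bookkeeping, group-coefficient arithmetic and morphology math."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ironcell.core import (CellMorphology, Component, GroupMember,
                           IronCenterProfile, ProteinGroupSpec, Reaction,
                           ValidationError, carbon_coefficient_from_aa,
                           copies_to_concentration, element_balance,
                           group_aa_coefficient, group_center_total,
                           group_coefficients, group_concentration,
                           iron_per_molecule, mean_gene_length,
                           member_center_contribution, membrane_volumes,
                           metallation_coefficient, pl_count,
                           respiring_concentration, total_iron)

profiles = st.builds(
    IronCenterProfile,
    **{k: st.floats(0, 5, allow_nan=False) for k in
       ("FH", "FO", "FF", "F2", "F3", "F4")})


class TestIronArithmetic:
    @pytest.mark.parametrize("profile,expected", [
        (IronCenterProfile(F2=0.85334), 1.70668),          # 2 Fe per [Fe2S2]
        (IronCenterProfile(), 0.0),
        (IronCenterProfile(FH=1, FO=1, FF=1, F2=1, F3=1, F4=1), 13.0),
    ])
    def test_iron_per_molecule(self, profile, expected):
        assert iron_per_molecule(profile) == pytest.approx(expected, abs=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            IronCenterProfile(F2=-0.1)

    @given(a=profiles, b=profiles)
    @settings(max_examples=50, deadline=None)
    def test_linearity(self, a, b):
        assert iron_per_molecule(a) + iron_per_molecule(b) == pytest.approx(
            iron_per_molecule(a + b), rel=1e-12)


class TestGroupCoefficients:
    def test_member_contribution_matches_printed_aft_value(self):
        # half an [Fe2S2] per monomer at concentration weight 1.54866
        assert member_center_contribution(0.5, 1.54866) == pytest.approx(0.77433)
        assert member_center_contribution(0.0, 2.0) == 0.0
        assert member_center_contribution(3.5, 1.0) == 3.5

    def test_group_total_is_plain_sum(self):
        assert group_center_total([0.77433, 0.07901, 0, 0]) == pytest.approx(0.85334)
        assert group_center_total([]) == 0.0

    def test_group_concentration_is_mean_with_weights(self):
        conc, weights = group_concentration([4.0, 0.0])
        assert conc == 2.0 and weights == [2.0, 0.0]
        conc, weights = group_concentration([2, 2, 2])
        assert conc == 2.0 and weights == [1, 1, 1]
        with pytest.raises(ValidationError):
            group_concentration([])

    @given(st.lists(st.floats(0, 1e3), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_weights_average_to_one(self, concs):
        conc, weights = group_concentration(concs)
        if conc > 0:
            assert sum(weights) / len(weights) == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("mult,expected", [(1, 1.0), (3, 3.0), (9, 9.0)])
    def test_respiring_multipliers(self, mult, expected):
        assert respiring_concentration(1.0, mult) == expected

    def test_respiring_multiplier_validated(self):
        with pytest.raises(ValidationError):
            respiring_concentration(1.0, 2)

    def test_aa_coefficient_sums_member_contributions(self):
        # the four printed member contributions of the iron-regulon group sum
        # to 2094.60 (their printed group total is 2197.75; see methods note)
        contributions = [(1223.35, 1.0), (75.25, 1.0), (388.05, 1.0),
                         (407.95, 1.0)]
        assert group_aa_coefficient(contributions) == pytest.approx(2094.60)
        assert group_aa_coefficient([(100, 1.0)]) == 100
        assert group_aa_coefficient([(123, 0.0)]) == 0

    def test_carbon_from_aa_at_five_carbons_each(self):
        assert carbon_coefficient_from_aa(2197.75) == pytest.approx(10988.75)
        assert carbon_coefficient_from_aa(0) == 0
        assert carbon_coefficient_from_aa(1) == 5

    def test_group_coefficients_composition(self):
        spec = ProteinGroupSpec("G", (
            GroupMember("p1", 2.0, 1, {"F2": 0.5}, residue_count=100),
            GroupMember("p2", 0.0, 3, {"F2": 1.0}, residue_count=300),
        ))
        out = group_coefficients(spec)
        # weights (2, 0) around mean 1.0
        assert out["concentration"] == pytest.approx(1.0)
        assert out["profile"].F2 == pytest.approx(1.0)
        assert out["iron"] == pytest.approx(2.0)
        assert out["aa"] == pytest.approx(200.0)
        assert out["carbon"] == pytest.approx(1000.0)


class TestMetallation:
    def test_isu_coefficient_from_cluster_bookkeeping(self):
        # 1.787040 [Fe4S4] built per acceptor, 3.795715 [Fe2S2] per donor,
        # two [Fe2S2] consumed per [Fe4S4]
        assert metallation_coefficient(1.787040, 3.795715, 2) == pytest.approx(
            0.9416092, rel=1e-6)

    def test_labile_pool_coefficient(self):
        # 3.795715 clusters x 2 Fe, one Fe per pool molecule
        assert metallation_coefficient(3.795715 * 2, 1, 1) == pytest.approx(
            7.59143, rel=1e-5)

    def test_identity_and_errors(self):
        assert metallation_coefficient(1, 1, 1) == 1
        with pytest.raises(ValidationError):
            metallation_coefficient(1, 0, 1)


class TestElementBalance:
    COMPS = {
        "ACAC": Component("ACAC", "c", carbon_count=5),
        "ATP": Component("ATP", "c", carbon_count=10),
        "NAH": Component("NAH", "c", carbon_count=10),
        "O2": Component("O2", "c", carbon_count=0),
        "PL": Component("PL", "c", carbon_count=50),
        "ADP": Component("ADP", "c", carbon_count=10),
        "NAD": Component("NAD", "c", carbon_count=10),
        "CARBON": Component("CARBON", "c", carbon_count=1, role="nutrient"),
        "MEM": Component("MEM", "c", carbon_count=0),
    }

    def test_phospholipid_synthesis_balances(self):
        rxn = Reaction("ACMEM",
                       reactants=(("ACAC", 10), ("ATP", 28), ("NAH", 36),
                                  ("O2", 4)),
                       products=(("PL", 1), ("ADP", 28), ("NAD", 36)),
                       catalysts=("MEM",))
        fe, c = element_balance(rxn, self.COMPS)
        assert fe == 0 and c == pytest.approx(0, abs=1e-12)

    @pytest.mark.parametrize("coeff,c_resid", [(0.2, 0.0), (0.3, 0.5)])
    def test_carbon_import(self, coeff, c_resid):
        rxn = Reaction("BACAC", reactants=(("CARBON", 1),),
                       products=(("ACAC", coeff),), kinetics_kind="mass_action")
        _, c = element_balance(rxn, self.COMPS)
        assert c == pytest.approx(c_resid, abs=1e-12)

    def test_unknown_component_raises(self):
        rxn = Reaction("X", reactants=(("NOPE", 1),), products=())
        with pytest.raises(ValidationError, match="NOPE"):
            element_balance(rxn, self.COMPS)

    def test_fixture_reactions_all_balance(self, fixture_model):
        net = fixture_model.network
        cmap = net.component_map
        for rxn in net.non_dilution_reactions:
            fe, c = element_balance(rxn, cmap)
            assert abs(fe) < 1e-4 and abs(c) < 1e-4, rxn.id


class TestMorphology:
    def test_fractional_volumes_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            CellMorphology.from_fractions(42e-15, 0.003,
                                          {"c": 0.6, "m": 0.3})

    def test_plasma_membrane_of_42fL_sphere(self):
        morph = CellMorphology.from_fractions(
            42e-15, 0.003333,
            {"c": 0.643, "m": 0.1, "v": 0.181, "n": 0.0495, "e": 0.0265})
        vols = membrane_volumes(morph)
        # r = (3V/4pi)^(1/3) = 2.154 µm, A = 58.3 µm^2, x 0.006 µm
        assert vols["plasma"] == pytest.approx(0.35e-15, rel=0.01)
        assert vols["total"] == pytest.approx(sum(
            v for k, v in vols.items() if k != "total"), rel=1e-12)

    def test_zero_thickness_zeroes_membranes(self):
        morph = CellMorphology.from_fractions(
            42e-15, 0.003333,
            {"c": 0.643, "m": 0.1, "v": 0.181, "n": 0.0495, "e": 0.0265},
            bilayer_thickness=1e-300)
        vols = membrane_volumes(morph)
        assert vols["plasma"] < 1e-250
        assert vols["mitochondria"] < 1e-250

    def test_pl_count(self):
        assert pl_count(1.51e-15, 3e-24) == pytest.approx(5.03e8, rel=5e-3)
        assert pl_count(3e-24, 3e-24) == 1
        assert pl_count(0, 3e-24) == 0
        with pytest.raises(ValidationError):
            pl_count(1.0, 0.0)

    def test_copies_to_concentration(self):
        assert copies_to_concentration(6275, 42e-15) == pytest.approx(
            0.248, rel=5e-3)
        assert copies_to_concentration(5.03e8, 42e-15) == pytest.approx(
            19900, rel=0.01)
        assert copies_to_concentration(0, 42e-15) == 0

    def test_mean_gene_length(self):
        assert round(mean_gene_length(12_156_677, 6275)) == 1937


class TestTotalIron:
    def test_scalar_and_partitions(self):
        conc = {"A": 2.0, "B": 1.0, "C": 0.0}
        prof = {"A": IronCenterProfile(F2=1.0),      # 2 Fe
                "B": IronCenterProfile(FH=3.0)}      # 3 Fe
        comps = {"A": "c", "B": "m", "C": "c"}
        assert total_iron(conc, prof) == pytest.approx(7.0)
        by_comp = total_iron(conc, prof, "compartment", comps)
        assert by_comp == {"c": pytest.approx(4.0), "m": pytest.approx(3.0)}
        by_name = total_iron(conc, prof, "component")
        assert sum(by_name.values()) == pytest.approx(total_iron(conc, prof))

    def test_missing_profile_flagged(self):
        with pytest.raises(ValidationError, match="no iron profile"):
            total_iron({"A": 1.0}, {})

    def test_empty_model(self):
        assert total_iron({}, {}) == 0.0

    def test_fixture_partition_is_exact(self, fitted):
        scalar = fitted.total_iron()
        by_comp = fitted.total_iron(group_by="compartment")
        assert sum(by_comp.values()) == pytest.approx(scalar, rel=1e-12)
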