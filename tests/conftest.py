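"""Shared fixtures: the reduced iron-metabolism model (fitted once per
session) and small hand-built toy networks."""

import numpy as np
import pytest
from hypothesis import settings

from ironcell import CellModel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from ironcell.core import (CellMorphology, Component, IronCenterProfile,
                           Reaction, ReactionNetwork)


@pytest.fixture(scope="session")
def fixture_model():
    return CellModel.fixture()


@pytest.fixture(scope="session")
def fitted(fixture_model):
    return fixture_model.fit()


@pytest.fixture(scope="session")
def fitted_unregulated(fixture_model):
    return fixture_model.fit(regulate=False)


def make_morphology(fractions=None, alpha=0.003333, V=42e-15, **geometry):
    fractions = fractions or {"c": 0.6, "m": 0.4}
    return CellMorphology.from_fractions(V, alpha, fractions, **geometry)


def single_component_toy(alpha=0.05, x_star=10.0):
    """Nutrient import feeding one diluted component: X' = k - alpha*X."""
    morph = make_morphology({"c": 1.0 - 1e-12, "m": 1e-12}, alpha=alpha)
    comps = (
        Component("N", "c", IronCenterProfile(), 1.0, 100.0, "nutrient"),
        Component("X", "c", IronCenterProfile(), 1.0, x_star),
    )
    rxns = (
        Reaction("TIN", reactants=(("N", 1.0),), products=(("X", 1.0),),
                 kinetics_kind="mass_action"),
    )
    return ReactionNetwork(comps, rxns, morph).with_dilutions()


@pytest.fixture
def toy_chain_network():
    """Nutrient -> A -> B with both intermediates diluted (the smallest
    network whose algebraic null basis mixes signs)."""
    morph = make_morphology({"c": 0.7, "m": 0.3})
    comps = (
        Component("N", "c", IronCenterProfile(), 1.0, 50.0, "nutrient"),
        Component("A", "c", IronCenterProfile(), 1.0, 5.0),
        Component("B", "m", IronCenterProfile(), 1.0, 2.0),
    )
    rxns = (
        Reaction("TIN", reactants=(("N", 1.0),), products=(("A", 1.0),),
                 kinetics_kind="mass_action"),
        Reaction("ACAB", reactants=(("A", 1.0),), products=(("B", 1.0),)),
    )
    return ReactionNetwork(comps, rxns, morph).with_dilutions()


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
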