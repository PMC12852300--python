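"""Seeded generator of element-balanced growth-dilution networks.

Generated networks emulate the structural features of compartmentalized
whole-cell models: boundary nutrients feeding branched conversion chains that
end in diluted destination components, components spread over several
compartments (so volume-ratio scaling is exercised), a full (S0 | -D) dilution
block, and — by construction — a strictly positive steady-state rate vector
with concentrations consistent with growth dilution.  Every reaction conserves
its chain's element (a carbon-like or iron-like label), with stoichiometric
coefficients set by content ratios, so fractional coefficients appear
naturally.  The same seed always yields the identical network, rates and
concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (CellMorphology, Component, IronCenterProfile, Reaction,
                   ReactionNetwork, ValidationError)

__all__ = ["SyntheticSpec", "SyntheticModel", "synthetic_network"]

_COMPARTMENT_POOL = ("c", "m", "v", "n", "e")


@dataclass(frozen=True)
class SyntheticSpec:
    """Sampling parameters for one synthetic network.

    ``n_components`` counts non-nutrient species; each nutrient roots one
    backbone chain and extra destinations become side branches ending in new
    terminal components.  ``alpha_cell`` is the growth rate in 1/min.
    """

    n_components: int = 10
    n_nutrients: int = 2
    n_destinations: int = 2
    n_compartments: int = 3
    seed: int = 0
    alpha_cell: float = 0.003333
    branch_probability: float = 0.3

    def __post_init__(self):
        if min(self.n_components, self.n_nutrients, self.n_destinations,
               self.n_compartments) < 1:
            raise ValidationError("all counts must be positive")
        if self.n_compartments > len(_COMPARTMENT_POOL):
            raise ValidationError(
                f"at most {len(_COMPARTMENT_POOL)} compartments supported")
        if self.n_destinations < self.n_nutrients:
            raise ValidationError(
                "need at least one destination per nutrient chain")
        extra = self.n_destinations - self.n_nutrients
        if self.n_components < self.n_nutrients + extra:
            raise ValidationError(
                "more destinations than components available for chains")


@dataclass
class SyntheticModel:
    """A generated network with its known steady state."""

    network: ReactionNetwork
    steady_rates: dict[str, float]       # cytosol-referenced µM/min, all > 0
    U_ss: dict[str, float]               # cellular µM, all > 0
    spec: SyntheticSpec = field(repr=False, default=None)


def synthetic_network(spec: SyntheticSpec) -> SyntheticModel:
    """Generate one network plus a consistent strictly positive steady state.

    Construction: nutrient chains are laid down with per-component element
    contents; conversion coefficients are content ratios (exact balance).
    Fluxes are propagated from sampled import rates, each component passing a
    sampled fraction of its inflow onward and shedding the remainder to
    dilution, which fixes U_local = net-production/alpha > 0 everywhere.
    """
    rng = np.random.default_rng(spec.seed)

    comp_ids = list(_COMPARTMENT_POOL[:spec.n_compartments])
    fracs = rng.dirichlet(np.full(spec.n_compartments, 4.0))
    fracs = 0.05 + 0.95 * fracs / fracs.sum()
    fracs = fracs / fracs.sum()
    fractions = dict(zip(comp_ids, fracs.round(6)))
    fractions[comp_ids[0]] += 1.0 - sum(fractions.values())  # exact unit sum
    morphology = CellMorphology.from_fractions(42e-15, spec.alpha_cell, fractions)

    extra_tails = spec.n_destinations - spec.n_nutrients
    backbone_total = spec.n_components - extra_tails
    # split backbone components across chains, each at least one long
    cuts = np.sort(rng.choice(np.arange(1, backbone_total),
                              size=spec.n_nutrients - 1, replace=False)) \
        if spec.n_nutrients > 1 else np.array([], dtype=int)
    chain_lengths = np.diff([0, *cuts.tolist(), backbone_total])

    components: list[Component] = []
    reactions: list[Reaction] = []
    element_of: dict[str, str] = {}
    content: dict[str, float] = {}
    chains: list[list[str]] = []

    def add_component(name, element, role="metabolite"):
        compartment = str(rng.choice(comp_ids))
        amount = float(rng.integers(1, 12))
        if element == "iron":
            profile = IronCenterProfile(FO=amount)
            carbon = 0.0
        else:
            profile = IronCenterProfile()
            carbon = amount
        components.append(Component(
            name=name, compartment=compartment, iron_profile=profile,
            carbon_count=carbon, role=role))
        element_of[name] = element
        content[name] = amount

    idx = 0
    for ci, length in enumerate(chain_lengths):
        element = "iron" if ci % 2 == 1 else "carbon"
        nutrient = f"N{ci}"
        if element == "iron":
            components.append(Component(nutrient, comp_ids[0],
                                        IronCenterProfile(FO=1.0), 0.0,
                                        float(rng.uniform(10, 100)), "nutrient"))
        else:
            components.append(Component(nutrient, comp_ids[0],
                                        IronCenterProfile(), 1.0,
                                        float(rng.uniform(100, 5000)), "nutrient"))
        element_of[nutrient] = element
        content[nutrient] = 1.0
        chain = []
        for k in range(length):
            name = f"X{idx}"
            idx += 1
            add_component(name, element)
            chain.append(name)
        chains.append(chain)
        # import reaction and the conversion backbone
        reactions.append(Reaction(
            id=f"T{nutrient}", reactants=((nutrient, 1.0),),
            products=((chain[0], content[nutrient] / content[chain[0]]),),
            kinetics_kind="mass_action"))
        for a, b in zip(chain, chain[1:]):
            reactions.append(Reaction(
                id=f"AC{a}{b}", reactants=((a, 1.0),),
                products=((b, content[a] / content[b]),)))

    # extra destinations: side branches from random backbone nodes
    for t in range(extra_tails):
        donors = [n for ch in chains for n in ch]
        donor = str(rng.choice(donors))
        name = f"X{idx}"
        idx += 1
        add_component(name, element_of[donor])
        reactions.append(Reaction(
            id=f"AC{donor}{name}", reactants=((donor, 1.0),),
            products=((name, content[donor] / content[name]),)))

    # optional shortcut branches between same-element components (forward only,
    # keeping the conversion graph acyclic)
    ordered = [c.name for c in components if c.role != "nutrient"]
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            if element_of[a] == element_of[b] and rng.random() < \
                    spec.branch_probability / max(1, len(ordered)):
                rid = f"AB{a}{b}"
                if any(r.id == rid for r in reactions):
                    continue
                reactions.append(Reaction(
                    id=rid, reactants=((a, 1.0),),
                    products=((b, content[a] / content[b]),)))

    # sprinkle catalysts on a few conversions (never on their own reaction)
    for r_i, rxn in enumerate(reactions):
        if rxn.kinetics_kind != "michaelis_menten" or rng.random() > 0.3:
            continue
        names = {n for n, _ in (*rxn.reactants, *rxn.products)}
        candidates = [n for n in ordered if n not in names]
        if candidates:
            reactions[r_i] = Reaction(
                id=rxn.id, reactants=rxn.reactants, products=rxn.products,
                catalysts=(str(rng.choice(candidates)),),
                kinetics_kind=rxn.kinetics_kind, location=rxn.location)

    # flux propagation: each component passes a sampled fraction of its molar
    # inflow to each outgoing conversion and dilutes the remainder
    inflow = {name: 0.0 for name in ordered}
    rate: dict[str, float] = {}
    outgoing: dict[str, list[Reaction]] = {name: [] for name in ordered}
    for rxn in reactions:
        src = rxn.reactants[0][0]
        if src in outgoing:
            outgoing[src].append(rxn)
        else:  # import: nutrient source, rate sampled directly
            rate[rxn.id] = float(rng.uniform(1.0, 10.0))
            prod, coeff = rxn.products[0]
            inflow[prod] += coeff * rate[rxn.id]
    for name in ordered:  # creation order is topological
        I = inflow[name]
        outs = outgoing[name]
        if outs:
            shares = rng.dirichlet(np.ones(len(outs))) * rng.uniform(0.3, 0.8)
            for rxn, q in zip(outs, shares):
                rate[rxn.id] = float(q * I)
                for prod, coeff in rxn.products:
                    inflow[prod] += coeff * rate[rxn.id]
    dilution_molar = {}
    for name in ordered:
        consumed = sum(r_out.reactants[0][1] * rate[r_out.id]
                       for r_out in outgoing[name])
        d = inflow[name] - consumed
        if d <= 0:  # cannot happen with shares < 1, but guard the invariant
            raise ValidationError(f"non-positive dilution for {name}")
        dilution_molar[name] = d

    f_c = morphology.fraction(comp_ids[0])
    U_cellular = {}
    for c in components:
        if c.role == "nutrient":
            continue
        U_cellular[c.name] = dilution_molar[c.name] * f_c / spec.alpha_cell
    network = ReactionNetwork(tuple(components), tuple(reactions), morphology)
    network = network.with_dilutions().with_concentrations(U_cellular)

    rates = dict(rate)
    for name in ordered:
        rates[f"D{name}"] = dilution_molar[name]
    return SyntheticModel(network=network, steady_rates=rates,
                          U_ss=U_cellular, spec=spec)
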