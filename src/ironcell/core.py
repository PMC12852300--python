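"""Domain types and element bookkeeping for compartmentalized cell models.

The model universe is a growing yeast-like cell subdivided into homogeneous
compartments (cytosol ``c``, mitochondria ``m``, nucleus ``n``, vacuoles ``v``,
endoplasmic reticulum ``e``).  Cellular *components* — protein groups, labile
iron pools, housekeeping metabolites, nutrients and wastes — carry an explicit
elemental composition in iron and carbon.  Iron is bookkept per *center kind*
(heme ``FH``, non-heme mononuclear ``FO``, di-iron ``FF``, [Fe2S2] ``F2``,
[Fe3S4] ``F3``, [Fe4S4] ``F4``, holding 1, 1, 2, 2, 3 and 4 Fe atoms
respectively).  Reactions are irreversible, stoichiometrically balanced in Fe
and C, and may name catalysts that influence rates without entering the
stoichiometry.  Exponential growth at rate ``alpha_cell`` is represented by one
dilution pseudo-reaction per non-nutrient component.

Units: concentrations in µM, time in minutes, volumes in liters, throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "AVOGADRO",
    "CENTER_IRON",
    "CENTER_KINDS",
    "Compartment",
    "CellMorphology",
    "IronCenterProfile",
    "Component",
    "GroupMember",
    "ProteinGroupSpec",
    "Reaction",
    "ReactionNetwork",
    "ValidationError",
    "iron_per_molecule",
    "member_center_contribution",
    "group_center_total",
    "group_concentration",
    "respiring_concentration",
    "group_aa_coefficient",
    "group_coefficients",
    "carbon_coefficient_from_aa",
    "element_balance",
    "metallation_coefficient",
    "membrane_volumes",
    "pl_count",
    "copies_to_concentration",
    "mean_gene_length",
    "total_iron",
]

AVOGADRO = 6.02214076e23

#: iron atoms per center, by center kind
CENTER_KINDS = ("FH", "FO", "FF", "F2", "F3", "F4")
CENTER_IRON = {"FH": 1.0, "FO": 1.0, "FF": 2.0, "F2": 2.0, "F3": 3.0, "F4": 4.0}

#: component roles
ROLES = ("nutrient", "waste", "protein_group", "metabolite", "iron_pool")

#: reaction kinetics kinds
KINETICS_KINDS = ("mass_action", "michaelis_menten", "transport_ratio", "dilution")

BALANCE_TOL = 1e-4  # atoms per reaction event; printed coefficients are 6-7 sig figs


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Compartment:
    """A homogeneous cellular sub-volume with fractional volume f = V_i/V_cell."""

    id: str
    fractional_volume: float

    def __post_init__(self):
        if not (0.0 < self.fractional_volume < 1.0):
            raise ValidationError(
                f"compartment {self.id!r}: fractional volume must lie in (0, 1), "
                f"got {self.fractional_volume}"
            )


@dataclass(frozen=True)
class CellMorphology:
    """Cell size, growth rate and membrane geometry.

    Parameters
    ----------
    V_cell : float
        Whole-cell volume in liters.
    alpha_cell : float
        Exponential growth rate in 1/min; every non-nutrient component is
        diluted at ``alpha_cell * [C]_local``.
    compartments : tuple of Compartment
        Fractional volumes must sum to 1 (within 1e-9).
    bilayer_thickness : float
        Phospholipid bilayer thickness in µm.
    mito_inner_to_outer_area_ratio : float
        Inner membrane area relative to the outer membrane.
    nuclear_membrane_layers : float
        The nuclear envelope is a double membrane by default.
    er_membrane_fraction_of_compartment : float
        Fraction of the ER compartment volume that is membrane.
    pl_molecule_volume : float
        Volume of one phospholipid molecule in liters (1 x 1 x 3 nm cuboid).
    mito_cylinder_radius : float
        Radius in µm of the long thin cylinders used to approximate the
        mitochondrial outer membrane area when none is supplied explicitly.
    """

    V_cell: float
    alpha_cell: float
    compartments: tuple[Compartment, ...]
    bilayer_thickness: float = 0.006
    mito_inner_to_outer_area_ratio: float = 3.0
    nuclear_membrane_layers: float = 2.0
    er_membrane_fraction_of_compartment: float = 0.5
    pl_molecule_volume: float = 3e-24
    mito_cylinder_radius: float = 0.3

    def __post_init__(self):
        if self.V_cell <= 0:
            raise ValidationError("V_cell must be positive")
        if self.alpha_cell < 0:
            raise ValidationError("alpha_cell must be nonnegative")
        for name in ("bilayer_thickness", "mito_inner_to_outer_area_ratio",
                     "nuclear_membrane_layers", "er_membrane_fraction_of_compartment",
                     "pl_molecule_volume", "mito_cylinder_radius"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        ids = [c.id for c in self.compartments]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate compartment ids")
        total = sum(c.fractional_volume for c in self.compartments)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"fractional volumes must sum to 1, got {total!r}"
            )

    @property
    def fractions(self) -> dict[str, float]:
        return {c.id: c.fractional_volume for c in self.compartments}

    def fraction(self, cid: str) -> float:
        try:
            return self.fractions[cid]
        except KeyError:
            raise ValidationError(f"unknown compartment {cid!r}") from None

    def volume(self, cid: str) -> float:
        """Compartment volume in liters."""
        return self.fraction(cid) * self.V_cell

    def volume_ratio(self, cid: str) -> float:
        """V_cyt / V_i — the scaling that refers compartment-i quantities to cytosol."""
        return self.fraction("c") / self.fraction(cid)

    @classmethod
    def from_fractions(cls, V_cell: float, alpha_cell: float,
                       fractions: dict[str, float], **geometry) -> "CellMorphology":
        comps = tuple(Compartment(k, v) for k, v in fractions.items())
        return cls(V_cell=V_cell, alpha_cell=alpha_cell, compartments=comps, **geometry)


# ---------------------------------------------------------------------------
# iron profiles and components
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IronCenterProfile:
    """Molar iron-center coefficients per molecule (fractional counts allowed,
    since they arise from weighted averages over protein-group members)."""

    FH: float = 0.0
    FO: float = 0.0
    FF: float = 0.0
    F2: float = 0.0
    F3: float = 0.0
    F4: float = 0.0

    def __post_init__(self):
        for k in CENTER_KINDS:
            if getattr(self, k) < 0:
                raise ValidationError(f"iron-center count {k} must be nonnegative")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in CENTER_KINDS}

    @property
    def iron(self) -> float:
        return iron_per_molecule(self)

    def __add__(self, other: "IronCenterProfile") -> "IronCenterProfile":
        return IronCenterProfile(**{k: getattr(self, k) + getattr(other, k)
                                    for k in CENTER_KINDS})

    def scaled(self, factor: float) -> "IronCenterProfile":
        return IronCenterProfile(**{k: getattr(self, k) * factor for k in CENTER_KINDS})


EMPTY_PROFILE = IronCenterProfile()


def iron_per_molecule(profile: IronCenterProfile) -> float:
    """Fe atoms per molecule: sum of center counts weighted by irons per center."""
    return sum(getattr(profile, k) * CENTER_IRON[k] for k in CENTER_KINDS)


@dataclass(frozen=True)
class Component:
    """A chemically defined cellular species housed in one compartment."""

    name: str
    compartment: str
    iron_profile: IronCenterProfile = EMPTY_PROFILE
    carbon_count: float = 0.0
    ss_cellular_concentration: float = 0.0  # µM, wild-type steady state
    role: str = "metabolite"

    def __post_init__(self):
        if self.carbon_count < 0:
            raise ValidationError(f"{self.name}: carbon count must be nonnegative")
        if self.ss_cellular_concentration < 0:
            raise ValidationError(f"{self.name}: concentration must be nonnegative")
        if self.role not in ROLES:
            raise ValidationError(f"{self.name}: unknown role {self.role!r}")

    @property
    def iron_count(self) -> float:
        return iron_per_molecule(self.iron_profile)


# ---------------------------------------------------------------------------
# protein-group coefficient arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupMember:
    """One member protein of a group.

    ``fermenting_concentration`` is the proteomics-derived cellular
    concentration under fermentation; the respiring concentration multiplies it
    by 1, 3 or 9 (mitochondrial proteins are scaled up for the larger organelle
    and higher expression under respiration).
    """

    name: str
    fermenting_concentration: float
    respiring_multiplier: int = 1
    center_counts: dict[str, float] = field(default_factory=dict)
    residue_count: float = 0.0

    def __post_init__(self):
        if self.fermenting_concentration < 0:
            raise ValidationError(f"{self.name}: concentration must be nonnegative")
        if self.respiring_multiplier not in (1, 3, 9):
            raise ValidationError(
                f"{self.name}: respiring multiplier must be 1, 3 or 9")
        if self.residue_count < 0:
            raise ValidationError(f"{self.name}: residue count must be nonnegative")
        for k, v in self.center_counts.items():
            if k not in CENTER_KINDS:
                raise ValidationError(f"{self.name}: unknown center kind {k!r}")
            if v < 0:
                raise ValidationError(f"{self.name}: center count must be nonnegative")


@dataclass(frozen=True)
class ProteinGroupSpec:
    group_name: str
    members: tuple[GroupMember, ...]

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"group {self.group_name}: no members")


def respiring_concentration(fermenting_conc: float, multiplier: int) -> float:
    """Concentration under respiration: fermenting value times 1, 3 or 9."""
    if multiplier not in (1, 3, 9):
        raise ValidationError(f"respiring multiplier must be 1, 3 or 9, got {multiplier}")
    if fermenting_conc < 0:
        raise ValidationError("concentration must be nonnegative")
    return fermenting_conc * multiplier


def group_concentration(member_respiring_concentrations: list[float]
                        ) -> tuple[float, list[float]]:
    """Group concentration = mean of member concentrations; also returns the
    per-member weights [P_i]/[P_g] used for all coefficient averaging.

    Weights average to exactly 1 over the members.
    """
    concs = list(member_respiring_concentrations)
    if not concs:
        raise ValidationError("group has no members")
    if any(c < 0 for c in concs):
        raise ValidationError("member concentrations must be nonnegative")
    mean = sum(concs) / len(concs)
    if mean == 0:
        weights = [0.0 for _ in concs]
    else:
        weights = [c / mean for c in concs]
    return mean, weights


def member_center_contribution(member_count: float, member_weight: float) -> float:
    """Centers contributed to the group coefficient by one member:
    member's centers-per-molecule times its concentration weight."""
    if member_count < 0 or member_weight < 0:
        raise ValidationError("center count and weight must be nonnegative")
    return member_count * member_weight


def group_center_total(contributions: list[float]) -> float:
    """Group molar center coefficient: sum of member contributions."""
    if any(c < 0 for c in contributions):
        raise ValidationError("contributions must be nonnegative")
    return float(sum(contributions))


def group_aa_coefficient(members: list[tuple[float, float]]) -> float:
    """Amino acids per group molecule: sum of member residue counts times weights."""
    total = 0.0
    for aa, w in members:
        if aa < 0 or w < 0:
            raise ValidationError("residue counts and weights must be nonnegative")
        total += aa * w
    return total


def carbon_coefficient_from_aa(aa_total: float, carbons_per_aa: float = 5.0) -> float:
    """Carbons per group molecule, at 5 carbons per generic amino acid."""
    if aa_total < 0 or carbons_per_aa < 0:
        raise ValidationError("inputs must be nonnegative")
    return aa_total * carbons_per_aa


def group_coefficients(spec: ProteinGroupSpec) -> dict:
    """Full coefficient table for a protein group.

    Returns group concentration (µM, respiring), member weights, the molar
    coefficient for each iron-center kind, total iron per group molecule, the
    amino-acid coefficient and the derived carbon coefficient.
    """
    concs = [respiring_concentration(m.fermenting_concentration, m.respiring_multiplier)
             for m in spec.members]
    conc, weights = group_concentration(concs)
    centers = {}
    for kind in CENTER_KINDS:
        centers[kind] = group_center_total(
            [member_center_contribution(m.center_counts.get(kind, 0.0), w)
             for m, w in zip(spec.members, weights)])
    profile = IronCenterProfile(**centers)
    aa = group_aa_coefficient([(m.residue_count, w)
                               for m, w in zip(spec.members, weights)])
    return {
        "concentration": conc,
        "weights": weights,
        "profile": profile,
        "iron": iron_per_molecule(profile),
        "aa": aa,
        "carbon": carbon_coefficient_from_aa(aa),
    }


# ---------------------------------------------------------------------------
# reactions and networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """An irreversible reaction with positive stoichiometric coefficients.

    Catalysts influence the rate law only; they are never consumed or produced.
    A dilution reaction has exactly one reactant, no products and no catalysts.
    ``invented`` marks closure reactions added to make a reduced model
    self-consistent (as opposed to reactions with literature-derived
    stoichiometry).
    """

    id: str
    reactants: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...] = ()
    catalysts: tuple[str, ...] = ()
    kinetics_kind: str = "michaelis_menten"
    location: str = "c"
    invented: bool = False

    def __post_init__(self):
        if self.kinetics_kind not in KINETICS_KINDS:
            raise ValidationError(
                f"{self.id}: unknown kinetics kind {self.kinetics_kind!r}")
        for name, coeff in (*self.reactants, *self.products):
            if coeff <= 0:
                raise ValidationError(
                    f"{self.id}: stoichiometric coefficient for {name} must be "
                    f"strictly positive, got {coeff}")
        participants = {n for n, _ in (*self.reactants, *self.products)}
        overlap = participants & set(self.catalysts)
        if overlap:
            raise ValidationError(
                f"{self.id}: catalysts {sorted(overlap)} also appear in the "
                "stoichiometry; catalysts must not be consumed or produced")
        if self.is_dilution:
            if len(self.reactants) != 1 or self.products or self.catalysts:
                raise ValidationError(
                    f"{self.id}: a dilution reaction has exactly one reactant, "
                    "no products and no catalysts")

    @property
    def is_dilution(self) -> bool:
        return self.kinetics_kind == "dilution"

    @property
    def substrate_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.reactants)


def element_balance(reaction: Reaction,
                    components: dict[str, Component]) -> tuple[float, float]:
    """Per-event conservation residual (Fe, C): products minus reactants.

    Catalysts are excluded.  A balanced reaction returns (0, 0) within
    ``BALANCE_TOL`` atoms.  Dilution pseudo-reactions deliberately violate
    conservation (matter simply leaves) and are rejected here.
    """
    if reaction.is_dilution:
        raise ValidationError(
            f"{reaction.id}: element balance is undefined for dilution reactions")

    def content(side):
        fe = c = 0.0
        for name, coeff in side:
            try:
                comp = components[name]
            except KeyError:
                raise ValidationError(
                    f"{reaction.id}: unknown component {name!r}") from None
            fe += coeff * comp.iron_count
            c += coeff * comp.carbon_count
        return fe, c

    fe_in, c_in = content(reaction.reactants)
    fe_out, c_out = content(reaction.products)
    return fe_out - fe_in, c_out - c_in


def metallation_coefficient(centers_built: float, donor_capacity: float,
                            centers_per_built_unit: float = 1.0) -> float:
    """Stoichiometric coefficient on a metallation donor.

    ``centers_built`` centers are installed per acceptor molecule, each
    consuming ``centers_per_built_unit`` donor centers; the donor carries
    ``donor_capacity`` centers per molecule.  E.g. building 1.787040 [Fe4S4]
    per acceptor from an [Fe2S2] donor holding 3.795715 clusters, at 2 [Fe2S2]
    per [Fe4S4], requires 1.787040*2/3.795715 = 0.9416092 donor molecules.
    """
    if donor_capacity <= 0:
        raise ValidationError("donor capacity must be strictly positive")
    if centers_built < 0 or centers_per_built_unit < 0:
        raise ValidationError("center counts must be nonnegative")
    return centers_built * centers_per_built_unit / donor_capacity


@dataclass(frozen=True)
class ReactionNetwork:
    """A complete model definition: components, reactions and morphology.

    Reactions are ordered with all non-dilution reactions first, then all
    dilution reactions — the order in which the stoichiometric matrix columns
    are laid out so the (S0 | -D) block structure holds without permutation.
    """

    components: tuple[Component, ...]
    reactions: tuple[Reaction, ...]
    morphology: CellMorphology

    def __post_init__(self):
        self.validate()

    # -- derived views -----------------------------------------------------

    @property
    def component_map(self) -> dict[str, Component]:
        return {c.name: c for c in self.components}

    @property
    def dynamic_components(self) -> tuple[Component, ...]:
        """Components that are state variables (everything but nutrients)."""
        return tuple(c for c in self.components if c.role != "nutrient")

    @property
    def nutrients(self) -> tuple[Component, ...]:
        return tuple(c for c in self.components if c.role == "nutrient")

    @property
    def non_dilution_reactions(self) -> tuple[Reaction, ...]:
        return tuple(r for r in self.reactions if not r.is_dilution)

    @property
    def dilution_reactions(self) -> tuple[Reaction, ...]:
        return tuple(r for r in self.reactions if r.is_dilution)

    @property
    def r(self) -> int:
        return len(self.non_dilution_reactions)

    @property
    def m(self) -> int:
        return len(self.dynamic_components)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate component names: {dupes}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dupes = sorted({i for i in rids if rids.count(i) > 1})
            raise ValidationError(f"duplicate reaction ids: {dupes}")

        known = self.morphology.fractions
        for c in self.components:
            if c.compartment not in known:
                raise ValidationError(
                    f"component {c.name}: unknown compartment {c.compartment!r}")

        cmap = self.component_map
        seen_dilution = False
        for rxn in self.reactions:
            if rxn.is_dilution:
                seen_dilution = True
            elif seen_dilution:
                raise ValidationError(
                    f"reaction {rxn.id}: non-dilution reactions must precede "
                    "dilution reactions")
            for name, _ in (*rxn.reactants, *rxn.products):
                if name not in cmap:
                    raise ValidationError(
                        f"reaction {rxn.id}: unknown component {name!r}")
            for name in rxn.catalysts:
                if name not in cmap:
                    raise ValidationError(
                        f"reaction {rxn.id}: unknown catalyst {name!r}")
            if not rxn.is_dilution:
                fe, cb = element_balance(rxn, cmap)
                if abs(fe) > BALANCE_TOL or abs(cb) > BALANCE_TOL:
                    raise ValidationError(
                        f"reaction {rxn.id}: element balance violated "
                        f"(Fe residual {fe:+.3e}, C residual {cb:+.3e})")

        # dilution coverage: once any dilution reaction exists the network is a
        # closed growth model, so every non-nutrient, non-waste component needs
        # exactly one; nutrients never have one.  A network with no dilutions
        # at all is an open skeleton (complete it with `with_dilutions`).
        diluted: dict[str, int] = {}
        for rxn in self.dilution_reactions:
            target = rxn.reactants[0][0]
            diluted[target] = diluted.get(target, 0) + 1
        for c in self.components:
            n = diluted.get(c.name, 0)
            if c.role == "nutrient":
                if n:
                    raise ValidationError(
                        f"nutrient {c.name} must not have a dilution reaction")
            elif diluted and c.role != "waste" and n != 1:
                raise ValidationError(
                    f"component {c.name} must appear in exactly one dilution "
                    f"reaction, found {n}")

    # -- construction helpers ---------------------------------------------

    def with_dilutions(self) -> "ReactionNetwork":
        """Return a network with a dilution reaction auto-generated (named
        ``D<component>``) for every non-nutrient component lacking one."""
        have = {r.reactants[0][0] for r in self.dilution_reactions}
        extra = []
        for c in self.components:
            if c.role != "nutrient" and c.name not in have:
                extra.append(Reaction(
                    id=f"D{c.name}", reactants=((c.name, 1.0),),
                    kinetics_kind="dilution", location=c.compartment))
        reactions = (*self.non_dilution_reactions,
                     *sorted((*self.dilution_reactions, *extra),
                             key=lambda r: [c.name for c in self.components
                                            ].index(r.reactants[0][0])))
        return ReactionNetwork(self.components, reactions, self.morphology)

    def with_concentrations(self, cellular: dict[str, float]) -> "ReactionNetwork":
        comps = tuple(
            replace(c, ss_cellular_concentration=cellular.get(c.name,
                                                              c.ss_cellular_concentration))
            for c in self.components)
        return ReactionNetwork(comps, self.reactions, self.morphology)


# ---------------------------------------------------------------------------
# morphology-derived quantities
# ---------------------------------------------------------------------------

def _sphere_area_um2(volume_liters: float) -> float:
    v_um3 = volume_liters * 1e15  # 1 L = 1e15 µm^3
    r = (3.0 * v_um3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return 4.0 * math.pi * r * r


def membrane_volumes(morphology: CellMorphology,
                     mito_outer_area_um2: float | None = None) -> dict[str, float]:
    """Per-compartment membrane volumes in liters, and their total.

    The cell, nucleus and vacuole are spheres whose surface area times the
    bilayer thickness gives the membrane volume (the nuclear envelope counts
    twice).  Mitochondria are long thin cylinders: the outer-membrane area is
    either supplied or approximated as 2V/r for the default cylinder radius,
    and the inner membrane multiplies it by the configured area ratio.  The ER
    membrane is a fixed fraction of the compartment volume.
    """
    t = morphology.bilayer_thickness
    out: dict[str, float] = {}
    out["plasma"] = _sphere_area_um2(morphology.V_cell) * t * 1e-15
    out["nucleus"] = (_sphere_area_um2(morphology.volume("n")) * t
                      * morphology.nuclear_membrane_layers * 1e-15)
    out["vacuole"] = _sphere_area_um2(morphology.volume("v")) * t * 1e-15
    if mito_outer_area_um2 is None:
        v_um3 = morphology.volume("m") * 1e15
        mito_outer_area_um2 = 2.0 * v_um3 / morphology.mito_cylinder_radius
    out["mitochondria"] = (mito_outer_area_um2 * t * 1e-15
                           * (1.0 + morphology.mito_inner_to_outer_area_ratio))
    out["er"] = morphology.er_membrane_fraction_of_compartment * morphology.volume("e")
    out["total"] = sum(out.values())
    return out


def pl_count(total_membrane_volume: float, pl_molecule_volume: float) -> float:
    """Phospholipid molecules per cell: membrane volume over per-molecule volume."""
    if pl_molecule_volume <= 0:
        raise ValidationError("phospholipid molecule volume must be positive")
    if total_membrane_volume < 0:
        raise ValidationError("membrane volume must be nonnegative")
    return total_membrane_volume / pl_molecule_volume


def copies_to_concentration(copies_per_cell: float, volume: float) -> float:
    """Cellular concentration in µM of a species at a given copy number."""
    if volume <= 0:
        raise ValidationError("volume must be positive")
    return copies_per_cell / (AVOGADRO * volume) * 1e6


def mean_gene_length(genome_basepairs: float, gene_count: float) -> float:
    """Average gene length in base pairs."""
    if gene_count <= 0:
        raise ValidationError("gene count must be positive")
    return genome_basepairs / gene_count


def total_iron(concentrations: dict[str, float],
               profiles: dict[str, IronCenterProfile],
               group_by: str = "none",
               compartments: dict[str, str] | None = None):
    """Total cellular iron in µM: sum of cellular concentration times Fe atoms
    per molecule over components.

    ``group_by='compartment'`` needs a component→compartment map and returns a
    per-compartment breakdown; ``group_by='component'`` returns per-component
    contributions.  Grouped sums partition the scalar total exactly.
    """
    contributions: dict[str, float] = {}
    for name, conc in concentrations.items():
        if conc == 0:
            continue
        if name not in profiles:
            raise ValidationError(f"component {name} has nonzero concentration "
                                  "but no iron profile")
        contributions[name] = conc * iron_per_molecule(profiles[name])
    if group_by == "none":
        return float(sum(contributions.values()))
    if group_by == "component":
        return contributions
    if group_by == "compartment":
        if compartments is None:
            raise ValidationError("compartment map required for group_by='compartment'")
        out: dict[str, float] = {}
        for name, fe in contributions.items():
            out[compartments[name]] = out.get(compartments[name], 0.0) + fe
        return out
    raise ValidationError(f"unknown group_by {group_by!r}")
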