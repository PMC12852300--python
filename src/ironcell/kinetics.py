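"""Rule-generated rate laws, steady-state calibration and logistic regulation.

Rate-law expressions are not measured; they are generated from each reaction's
declared kind:

* ``michaelis_menten`` — a saturating term [S]/(K_M + [S]) per substrate, with
  every K_M equated to the substrate's wild-type local concentration, times a
  normalized first-order factor [E]/[E]_w per catalyst, times k.  At the
  wild-type state each substrate term is exactly 1/2 and each catalyst term 1.
* ``mass_action`` — k times a normalized first-order factor [S]/[S]_w per
  substrate (for the few uncatalyzed reactions).
* ``transport_ratio`` — k·([donor]/[receiver] − 1): transfer is driven by the
  concentration ratio across the interface and may run backwards dynamically.
* ``dilution`` — alpha_cell·[C]_local, referred to the cytosol frame
  (multiplied by f_k/f_c so the −f_c/f_k matrix entry reproduces
  d[C]_local/dt = −alpha·[C]_local).

Calibration inverts the law at the wild-type state: k = R_ss / law(U_ss; k=1),
so every calibrated law returns its steady-state rate exactly at U_ss.
Regulation multiplies a law by logistic factors lf(2 − [C]/[C]_ss) that are
exactly 1 at the reference state, leaving calibration untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .core import CellMorphology, Reaction, ValidationError

__all__ = [
    "RateLaw",
    "RegulationRule",
    "CalibrationError",
    "logistic",
    "build_rate_law",
    "calibrate_rate_constant",
    "evaluate_rate",
    "apply_regulation",
]


class CalibrationError(ValidationError):
    pass


def logistic(x: float, steepness: float = 5.0) -> float:
    """lf(x) = 2 / (1 + e^(−steepness·(x−1))): 1 at x = 1, limits 0 and 2."""
    arg = min(max(-steepness * (x - 1.0), -700.0), 700.0)  # avoid overflow
    return 2.0 / (1.0 + math.exp(arg))


@dataclass(frozen=True)
class RegulationRule:
    """Multiply a reaction's rate by lf(2 − [C](t)/[C]_ss) for a sensed
    component; neutral (factor 1) when the component sits at its reference."""

    reaction_id: str
    sensed: str
    reference: float
    steepness: float = 5.0

    def __post_init__(self):
        if self.reference <= 0:
            raise ValidationError(
                f"regulation of {self.reaction_id}: reference concentration "
                "must be positive")

    def factor(self, concentration: float) -> float:
        return logistic(2.0 - concentration / self.reference, self.steepness)


@dataclass(frozen=True)
class RateLaw:
    """A calibrated rate-law expression for one reaction.

    ``substrates`` holds (component, K_M, reference) triples in local µM;
    ``catalysts`` holds (component, reference) pairs; ``transport`` names the
    (donor, receiver) pair for ratio-driven transfer; ``dilution_factor`` is
    alpha·f_k/f_c for dilution pseudo-reactions.
    """

    reaction_id: str
    kind: str
    k: float = 1.0
    substrates: tuple[tuple[str, float, float], ...] = ()
    catalysts: tuple[tuple[str, float], ...] = ()
    transport: tuple[str, str] | None = None
    dilution_component: str | None = None
    dilution_factor: float = 0.0
    regulation: tuple[RegulationRule, ...] = ()

    def __post_init__(self):
        if self.k < 0:
            raise ValidationError(f"{self.reaction_id}: k must be nonnegative")
        for name, km, ref in self.substrates:
            if km <= 0 or ref <= 0:
                raise ValidationError(
                    f"{self.reaction_id}: K_M and reference concentration for "
                    f"{name} must be positive")
        for name, ref in self.catalysts:
            if ref <= 0:
                raise ValidationError(
                    f"{self.reaction_id}: reference concentration for catalyst "
                    f"{name} must be positive")

    def with_k(self, k: float) -> "RateLaw":
        return replace(self, k=k)


def build_rate_law(reaction: Reaction, kinetics_kind: str,
                   U_ss_local: dict[str, float],
                   morphology: CellMorphology | None = None,
                   component_compartment: dict[str, str] | None = None,
                   ) -> RateLaw:
    """Generate the (uncalibrated, k = 1) rate law for a reaction.

    Needs wild-type local concentrations for every substrate and catalyst.
    Dilution laws additionally need the morphology and the component's home
    compartment to form the cytosol-referencing factor.
    """
    def ref(name: str) -> float:
        try:
            val = U_ss_local[name]
        except KeyError:
            raise ValidationError(
                f"{reaction.id}: no steady-state concentration for {name}"
            ) from None
        if val <= 0:
            raise ValidationError(
                f"{reaction.id}: zero reference concentration for {name}")
        return val

    if kinetics_kind == "dilution":
        comp = reaction.reactants[0][0]
        if morphology is None or component_compartment is None:
            raise ValidationError("dilution law needs morphology and compartments")
        f_k = morphology.fraction(component_compartment[comp])
        f_c = morphology.fraction("c")
        return RateLaw(reaction_id=reaction.id, kind="dilution",
                       dilution_component=comp,
                       dilution_factor=morphology.alpha_cell * f_k / f_c)

    if kinetics_kind == "transport_ratio":
        if len(reaction.reactants) != 1 or len(reaction.products) != 1:
            raise ValidationError(
                f"{reaction.id}: transport law needs one donor and one receiver")
        donor = reaction.reactants[0][0]
        receiver = reaction.products[0][0]
        ref(donor), ref(receiver)  # existence/positivity check
        return RateLaw(reaction_id=reaction.id, kind="transport_ratio",
                       transport=(donor, receiver))

    substrates = tuple((name, ref(name), ref(name))
                       for name, _ in reaction.reactants)
    catalysts = tuple((name, ref(name)) for name in reaction.catalysts)
    if kinetics_kind == "michaelis_menten":
        return RateLaw(reaction_id=reaction.id, kind="michaelis_menten",
                       substrates=substrates, catalysts=catalysts)
    if kinetics_kind == "mass_action":
        return RateLaw(reaction_id=reaction.id, kind="mass_action",
                       substrates=substrates, catalysts=catalysts)
    raise ValidationError(f"{reaction.id}: unknown kinetics kind {kinetics_kind!r}")


def _core_rate(law: RateLaw, conc: dict[str, float]) -> float:
    """Rate with k = 1 and without regulation factors."""
    def get(name: str) -> float:
        try:
            return conc[name]
        except KeyError:
            raise ValidationError(
                f"{law.reaction_id}: missing concentration for {name}") from None

    if law.kind == "dilution":
        return law.dilution_factor * get(law.dilution_component)
    if law.kind == "transport_ratio":
        donor, receiver = law.transport
        recv = get(receiver)
        if recv <= 0:
            raise ValidationError(
                f"{law.reaction_id}: receiver concentration must be positive")
        return get(donor) / recv - 1.0
    rate = 1.0
    if law.kind == "michaelis_menten":
        for name, km, _ in law.substrates:
            s = get(name)
            rate *= s / (km + s)
    else:  # mass_action
        for name, _, ref in law.substrates:
            rate *= get(name) / ref
    for name, ref in law.catalysts:
        rate *= get(name) / ref
    return rate


def evaluate_rate(law: RateLaw, conc: dict[str, float], t: float = 0.0) -> float:
    """Rate at the given local concentrations, regulation factors included.

    Nonnegative for all kinds except transport_ratio, whose negative values
    (net reverse flow down a reversed gradient) are passed through."""
    rate = law.k * _core_rate(law, conc)
    for rule in law.regulation:
        rate *= rule.factor(conc[rule.sensed])
    return rate


def calibrate_rate_constant(law: RateLaw, R_ss: float,
                            U_ss_local: dict[str, float]) -> float:
    """k such that the law evaluated at the wild-type state returns R_ss.

    For a Michaelis–Menten law with s substrates (each term 1/2 at U_ss) this
    gives k = R_ss·2^s; for transport, k = R_ss/(ratio_w − 1).  A zero
    steady-state rate calibrates to k = 0 (the law is inert)."""
    if R_ss < 0:
        raise CalibrationError(f"{law.reaction_id}: negative steady-state rate")
    if R_ss == 0:
        return 0.0
    core = _core_rate(law, U_ss_local)
    if core == 0:
        raise CalibrationError(
            f"{law.reaction_id}: law evaluates to zero at the wild-type state "
            f"but R_ss = {R_ss}; cannot calibrate (e.g. a transport reaction "
            "with unit wild-type concentration ratio)")
    if core < 0:
        raise CalibrationError(
            f"{law.reaction_id}: law is negative at the wild-type state "
            "(transport against its gradient); cannot calibrate a nonnegative k")
    return R_ss / core


def apply_regulation(law: RateLaw, rules: list[RegulationRule]) -> RateLaw:
    """Attach logistic regulation factors; neutrality at the reference state
    means calibration is unchanged."""
    mine = tuple(r for r in rules if r.reaction_id == law.reaction_id)
    if not mine:
        return law
    return replace(law, regulation=(*law.regulation, *mine))
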