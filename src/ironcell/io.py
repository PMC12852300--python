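"""Model bundle formats: component/reaction TSV, morphology and kinetics JSON.

A model bundle is a directory holding ``components.tsv``, ``reactions.tsv``,
``morphology.json`` and optionally ``kinetics.json``.  Stoichiometry strings
use the ``"2·AA + 3·ATP -> NUCM"`` dialect; ``*`` and the UTF-8 arrow are
accepted on read and normalized on write.  Numeric columns are written at full
repr precision so a write/read cycle is bit-exact.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (CENTER_KINDS, CellMorphology, Component, IronCenterProfile,
                   Reaction, ReactionNetwork, ValidationError)
from .kinetics import RegulationRule
from .stoichiometry import StoichiometricMatrix

__all__ = [
    "read_model",
    "write_model",
    "parse_reaction_equation",
    "format_reaction_equation",
    "read_kinetics_config",
    "write_kinetics_config",
    "load_si_matrix",
]

_TERM_RE = re.compile(r"^\s*(?:([0-9.eE+-]+)\s*[·*]\s*)?(\S+)\s*$")


def parse_reaction_equation(text: str) -> tuple[list, list]:
    """Parse ``"aISU + 7.59143·FM -> ISU"`` into reactant/product lists."""
    text = text.replace("→", "->")
    if "->" not in text:
        raise ValidationError(f"no '->' arrow in reaction equation {text!r}")
    lhs, rhs = text.split("->", 1)

    def side(chunk):
        out = []
        chunk = chunk.strip()
        if not chunk:
            return out
        for term in chunk.split("+"):
            m = _TERM_RE.match(term)
            if not m:
                raise ValidationError(f"cannot parse term {term!r}")
            coeff = float(m.group(1)) if m.group(1) else 1.0
            out.append((m.group(2), coeff))
        return out

    return side(lhs), side(rhs)


def format_reaction_equation(reaction: Reaction) -> str:
    def side(entries):
        parts = []
        for name, coeff in entries:
            parts.append(name if coeff == 1 else f"{float(coeff)!r}·{name}")
        return " + ".join(parts)

    return f"{side(reaction.reactants)} -> {side(reaction.products)}"


# ---------------------------------------------------------------------------
# bundle read/write
# ---------------------------------------------------------------------------

_COMPONENT_COLUMNS = ["name", "compartment", "role", "conc_uM", "carbon",
                      *[f"fe_{k}" for k in CENTER_KINDS]]


def write_model(network: ReactionNetwork, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    rows = []
    for c in network.components:
        row = {"name": c.name, "compartment": c.compartment, "role": c.role,
               "conc_uM": repr(float(c.ss_cellular_concentration)),
               "carbon": repr(float(c.carbon_count))}
        for k in CENTER_KINDS:
            row[f"fe_{k}"] = repr(float(getattr(c.iron_profile, k)))
        rows.append(row)
    pd.DataFrame(rows, columns=_COMPONENT_COLUMNS).to_csv(
        directory / "components.tsv", sep="\t", index=False)

    rows = []
    for rxn in network.reactions:
        rows.append({
            "id": rxn.id, "kind": rxn.kinetics_kind, "location": rxn.location,
            "equation": format_reaction_equation(rxn),
            "catalysts": ",".join(rxn.catalysts),
            "invented": str(rxn.invented).lower(),
        })
    pd.DataFrame(rows, columns=["id", "kind", "location", "equation",
                                "catalysts", "invented"]).to_csv(
        directory / "reactions.tsv", sep="\t", index=False)

    morph = network.morphology
    payload = {
        "V_cell": morph.V_cell,
        "alpha_cell": morph.alpha_cell,
        "fractions": morph.fractions,
        "bilayer_thickness": morph.bilayer_thickness,
        "mito_inner_to_outer_area_ratio": morph.mito_inner_to_outer_area_ratio,
        "nuclear_membrane_layers": morph.nuclear_membrane_layers,
        "er_membrane_fraction_of_compartment":
            morph.er_membrane_fraction_of_compartment,
        "pl_molecule_volume": morph.pl_molecule_volume,
        "mito_cylinder_radius": morph.mito_cylinder_radius,
    }
    (directory / "morphology.json").write_text(json.dumps(payload, indent=1))
    return directory


def read_model(directory) -> ReactionNetwork:
    """Read and validate a model bundle; errors name the offending row."""
    directory = Path(directory)
    morph_payload = json.loads((directory / "morphology.json").read_text())
    fractions = morph_payload.pop("fractions")
    morphology = CellMorphology.from_fractions(
        morph_payload.pop("V_cell"), morph_payload.pop("alpha_cell"),
        fractions, **morph_payload)

    cdf = pd.read_csv(directory / "components.tsv", sep="\t",
                      float_precision="round_trip")
    components = []
    for i, row in cdf.iterrows():
        try:
            profile = IronCenterProfile(
                **{k: float(row[f"fe_{k}"]) for k in CENTER_KINDS})
            components.append(Component(
                name=str(row["name"]), compartment=str(row["compartment"]),
                iron_profile=profile, carbon_count=float(row["carbon"]),
                ss_cellular_concentration=float(row["conc_uM"]),
                role=str(row["role"])))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(
                f"components.tsv line {i + 2}: {exc}") from exc

    rdf = pd.read_csv(directory / "reactions.tsv", sep="\t",
                      float_precision="round_trip")
    reactions = []
    for i, row in rdf.iterrows():
        try:
            reactants, products = parse_reaction_equation(str(row["equation"]))
            catalysts = tuple(x for x in str(row.get("catalysts", "") or "")
                              .split(",") if x and x != "nan")
            reactions.append(Reaction(
                id=str(row["id"]), reactants=tuple(reactants),
                products=tuple(products), catalysts=catalysts,
                kinetics_kind=str(row["kind"]), location=str(row["location"]),
                invented=str(row.get("invented", "false")).lower() == "true"))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"reactions.tsv line {i + 2}: {exc}") from exc

    return ReactionNetwork(tuple(components), tuple(reactions), morphology)


def read_protein_groups(path) -> list:
    """Read a protein-group TSV (columns: group, member, conc_fer_uM,
    multiplier, aa, and one column per iron-center kind) into
    :class:`ProteinGroupSpec` objects."""
    from .core import GroupMember, ProteinGroupSpec

    df = pd.read_csv(path, sep="\t")
    groups = []
    for gname, sub in df.groupby("group", sort=False):
        members = tuple(GroupMember(
            name=str(row["member"]),
            fermenting_concentration=float(row["conc_fer_uM"]),
            respiring_multiplier=int(row["multiplier"]),
            residue_count=float(row["aa"]),
            center_counts={k: float(row[k]) for k in CENTER_KINDS
                           if k in row and pd.notna(row[k])})
            for _, row in sub.iterrows())
        groups.append(ProteinGroupSpec(group_name=str(gname), members=members))
    return groups


# ---------------------------------------------------------------------------
# kinetics configuration
# ---------------------------------------------------------------------------

def write_kinetics_config(path, regulation: list[RegulationRule] = (),
                          zero_set=(), k_overrides: dict | None = None,
                          kind_overrides: dict | None = None,
                          steady_rates: dict | None = None) -> None:
    payload = {
        "regulation": [{"reaction": r.reaction_id, "sensed": r.sensed,
                        "reference": r.reference, "steepness": r.steepness}
                       for r in regulation],
        "zero_set": sorted(zero_set),
        "k_overrides": k_overrides or {},
        "kind_overrides": kind_overrides or {},
        "steady_rates": steady_rates or {},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_kinetics_config(path) -> dict:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        payload = yaml.safe_load(path.read_text())
    else:
        payload = json.loads(path.read_text())
    rules = [RegulationRule(reaction_id=r["reaction"], sensed=r["sensed"],
                            reference=float(r["reference"]),
                            steepness=float(r.get("steepness", 5.0)))
             for r in payload.get("regulation", [])]
    return {
        "regulation": rules,
        "zero_set": frozenset(payload.get("zero_set", [])),
        "k_overrides": dict(payload.get("k_overrides", {})),
        "kind_overrides": dict(payload.get("kind_overrides", {})),
        "steady_rates": {k: float(v)
                         for k, v in payload.get("steady_rates", {}).items()},
    }


# ---------------------------------------------------------------------------
# external matrix documents
# ---------------------------------------------------------------------------

_SI_SHAPES = {"S": (80, 169), "W": (169, 89)}


def load_si_matrix(path, kind: str) -> StoichiometricMatrix | np.ndarray:
    """Load a plain-CSV export of an externally published S or W matrix.

    ``kind='S'`` expects the 80-component x 169-reaction stoichiometric matrix
    (returned as a StoichiometricMatrix with its trailing 80-column dilution
    block validated); ``kind='W'`` expects the 169 x 89 nonnegative
    basic-pathway matrix (returned as an array).  Dimension or structure
    mismatches raise ValidationError.
    """
    if kind not in _SI_SHAPES:
        raise ValidationError(f"kind must be 'S' or 'W', got {kind!r}")
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    M = df.to_numpy(dtype=float)
    expected = _SI_SHAPES[kind]
    if M.shape != expected:
        raise ValidationError(
            f"{kind} matrix has shape {M.shape}, expected {expected}")
    if kind == "W":
        if M.min() < 0:
            raise ValidationError("W matrix must be nonnegative")
        return M
    m, n = M.shape
    block = M[:, n - m:]
    if np.any(block - np.diag(np.diag(block)) != 0) or np.any(np.diag(block) >= 0):
        raise ValidationError(
            "trailing block of the S matrix is not a negative diagonal "
            "dilution block")
    return StoichiometricMatrix(matrix=M,
                                component_index=[str(i) for i in df.index],
                                reaction_index=[str(c) for c in df.columns],
                                r=n - m)
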