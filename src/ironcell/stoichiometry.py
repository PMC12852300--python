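"""Volume-scaled stoichiometric matrix with the (S0 | -D) dilution block.

Every reaction rate in the model is *cytosol-referenced*: the extent of
reaction per cytosolic volume, regardless of where the reaction occurs.  The
local concentration ODE for a component housed in compartment k then picks up
the volume ratio V_cyt/V_k = f_c/f_k on every stoichiometric coefficient, so
that a single matrix relates one shared rate frame to all local-concentration
derivatives.  Dilution pseudo-reactions occupy the trailing columns, one per
non-nutrient component, forming a strictly negative diagonal block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ReactionNetwork, ValidationError

__all__ = [
    "StoichiometricMatrix",
    "StructureReport",
    "build_smatrix",
    "local_concentration",
    "cellular_concentration",
    "validate_structure",
    "write_matrix_csv",
    "read_matrix_csv",
]


@dataclass
class StoichiometricMatrix:
    """m-component by n-reaction matrix of volume-scaled coefficients.

    Columns are ordered with the r non-dilution reactions first (input order),
    then the m dilution reactions in component order, so the matrix has the
    block structure (S0 | -D) with D diagonal and positive.
    """

    matrix: np.ndarray
    component_index: list[str]
    reaction_index: list[str]
    r: int

    @property
    def m(self) -> int:
        return len(self.component_index)

    @property
    def n(self) -> int:
        return len(self.reaction_index)

    @property
    def S0(self) -> np.ndarray:
        return self.matrix[:, :self.r]

    @property
    def dilution_block(self) -> np.ndarray:
        return self.matrix[:, self.r:]

    @property
    def D(self) -> np.ndarray:
        """Positive diagonal of the dilution block (the block itself is -D)."""
        return -np.diag(self.dilution_block.copy())

    def row(self, component: str) -> np.ndarray:
        return self.matrix[self.component_index.index(component)]

    def entry(self, component: str, reaction: str) -> float:
        return float(self.matrix[self.component_index.index(component),
                                 self.reaction_index.index(reaction)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.component_index,
                            columns=self.reaction_index)


def build_smatrix(network: ReactionNetwork) -> StoichiometricMatrix:
    """Assemble S_cell from a validated network.

    For component i in compartment k and reaction j with molar coefficient s
    (negative for reactants, positive for products) the entry is
    ``s * f_c/f_k``.  Nutrients are boundary species and have no row.  The
    dilution column for component i carries the single entry ``-f_c/f_k`` at
    row i.  Duplicate (component, reaction) contributions are summed with a
    warning.
    """
    comps = network.dynamic_components
    comp_names = [c.name for c in comps]
    comp_pos = {n: i for i, n in enumerate(comp_names)}
    ratio = {c.name: network.morphology.volume_ratio(c.compartment) for c in comps}

    non_dil = network.non_dilution_reactions
    dil = network.dilution_reactions
    # dilution columns in component order
    dil_by_target = {rxn.reactants[0][0]: rxn for rxn in dil}
    if len(dil_by_target) != len(dil):
        raise ValidationError("multiple dilution reactions for one component")
    dil_ordered = [dil_by_target[n] for n in comp_names if n in dil_by_target]
    if len(dil_ordered) != len(dil):
        raise ValidationError("dilution reaction targets a nutrient or unknown component")

    reactions = [*non_dil, *dil_ordered]
    r = len(non_dil)
    S = np.zeros((len(comps), len(reactions)))

    for j, rxn in enumerate(reactions):
        seen: set[str] = set()
        for side, sign in ((rxn.reactants, -1.0), (rxn.products, +1.0)):
            for name, coeff in side:
                if name not in comp_pos:  # nutrient / boundary species
                    continue
                if name in seen:
                    warnings.warn(
                        f"reaction {rxn.id}: duplicate entry for {name}; "
                        "contributions summed", stacklevel=2)
                seen.add(name)
                S[comp_pos[name], j] += sign * coeff * ratio[name]

    return StoichiometricMatrix(matrix=S, component_index=comp_names,
                                reaction_index=[x.id for x in reactions], r=r)


def local_concentration(cellular: float, f_i: float) -> float:
    """Concentration inside a compartment: cellular value over fractional volume."""
    if not (0.0 < f_i <= 1.0):
        raise ValidationError(f"fractional volume must lie in (0, 1], got {f_i}")
    return cellular / f_i


def cellular_concentration(local: float, f_i: float) -> float:
    """Inverse of :func:`local_concentration`; round-trips exactly."""
    if not (0.0 < f_i <= 1.0):
        raise ValidationError(f"fractional volume must lie in (0, 1], got {f_i}")
    return local * f_i


@dataclass
class StructureReport:
    rank: int
    m: int
    nullity: int
    dilution_block_ok: bool
    full_row_rank: bool
    problems: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.dilution_block_ok and self.full_row_rank and not self.problems


def validate_structure(S: StoichiometricMatrix) -> StructureReport:
    """Check the (S0 | -D) structure and report numerical rank and nullity.

    Structural violations are enumerated in the report, not thrown."""
    problems: list[str] = []
    block = S.dilution_block
    dil_ok = True
    if block.shape != (S.m, S.m):
        dil_ok = False
        problems.append(f"dilution block is {block.shape}, expected square of size {S.m}")
    else:
        off = block - np.diag(np.diag(block))
        if np.any(off != 0):
            dil_ok = False
            problems.append("dilution block has off-diagonal entries")
        if np.any(np.diag(block) >= 0):
            bad = [S.component_index[i] for i in np.where(np.diag(block) >= 0)[0]]
            dil_ok = False
            problems.append(f"non-negative dilution diagonal for {bad}")
    rank = int(np.linalg.matrix_rank(S.matrix))
    full = rank == S.m
    if not full:
        problems.append(f"rank {rank} < component count {S.m}")
    return StructureReport(rank=rank, m=S.m, nullity=S.n - rank,
                           dilution_block_ok=dil_ok, full_row_rank=full,
                           problems=problems)


# ---------------------------------------------------------------------------
# CSV round trip (also reads plain matrix exports of external S/W documents)
# ---------------------------------------------------------------------------

def write_matrix_csv(S: StoichiometricMatrix, path) -> None:
    """First row = reaction ids, first column = component ids; entries written
    at 17 significant digits so a read-back is bit-exact."""
    df = S.to_frame()
    df.to_csv(path, float_format="%.17g")


def read_matrix_csv(path, r: int | None = None) -> StoichiometricMatrix:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    matrix = df.to_numpy(dtype=float)
    m, n = matrix.shape
    if r is None:
        r = n - m
    if not (0 <= r <= n):
        raise ValidationError(f"invalid non-dilution reaction count r={r}")
    return StoichiometricMatrix(matrix=matrix,
                                component_index=[str(i) for i in df.index],
                                reaction_index=[str(c) for c in df.columns], r=r)
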