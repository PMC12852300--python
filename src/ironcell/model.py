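"""High-level modeling objects: build a :class:`CellModel`, ``fit()`` it, work
with the resulting :class:`CellResults`.

``fit`` performs the full steady-state construction: assemble the
volume-scaled stoichiometric matrix, derive the nonnegative basic-pathway
basis, assign the independent rates (growth-dilution rates from the measured
concentrations, plus any supplied non-dilution rates), solve for the pathway
weights and the complete rate vector, and calibrate one rate law per reaction
so the wild-type state is an exact equilibrium.  The results object carries
the estimates and diagnostics and exposes simulation and perturbation
experiments.

Example
-------
>>> from ironcell import CellModel
>>> res = CellModel.fixture().fit()
>>> print(res.summary())            # doctest: +SKIP
>>> traj, table = res.perturb("FC", 1.5, t_end=20000)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import basic_pathways as bp
from .core import ReactionNetwork, ValidationError, total_iron
from .dynamics import (KineticModel, PerturbationSpec, Trajectory,
                       assemble_system, classify_outcome, integrate,
                       perturbation_experiment, verify_steady_state)
from .kinetics import (RateLaw, RegulationRule, apply_regulation,
                       build_rate_law, calibrate_rate_constant, evaluate_rate)
from .stoichiometry import StoichiometricMatrix, build_smatrix, validate_structure

__all__ = ["CellModel", "CellResults"]


class CellModel:
    """A compartmentalized growth-dilution cell model awaiting calibration.

    Parameters
    ----------
    network : ReactionNetwork
        Validated components, reactions and morphology; steady-state cellular
        concentrations must be present on the components.
    steady_rates : dict, optional
        Known non-dilution steady rates (cytosol-referenced µM/min), used for
        any non-dilution reactions selected into the independent set and as
        the preferred vector when constructing the pathway basis.
    regulation : list of RegulationRule, optional
    zero_set : set of reaction ids pinned to zero rate (their laws go inert).
    k_overrides : dict, optional
        Explicit rate constants overriding calibration (e.g. to reactivate a
        zero-rate reaction).
    """

    def __init__(self, network: ReactionNetwork, *,
                 steady_rates: dict[str, float] | None = None,
                 regulation: list[RegulationRule] | None = None,
                 zero_set=frozenset(),
                 kind_overrides: dict[str, str] | None = None,
                 k_overrides: dict[str, float] | None = None):
        self.network = network
        self.steady_rates = dict(steady_rates or {})
        self.regulation = list(regulation or [])
        self.zero_set = frozenset(zero_set)
        self.kind_overrides = dict(kind_overrides or {})
        self.k_overrides = dict(k_overrides or {})

    # -- constructors ------------------------------------------------------

    @classmethod
    def fixture(cls) -> "CellModel":
        """The built-in reduced iron-metabolism model, fully configured."""
        from .fixture import (fixture_core_model, fixture_regulation,
                              fixture_steady_rates, fixture_zero_set)

        return cls(fixture_core_model(), steady_rates=fixture_steady_rates(),
                   regulation=fixture_regulation(), zero_set=fixture_zero_set())

    @classmethod
    def from_bundle(cls, directory) -> "CellModel":
        """Load a model bundle directory (components/reactions/morphology,
        plus kinetics.json when present)."""
        from .io import read_kinetics_config, read_model

        directory = Path(directory)
        network = read_model(directory)
        kwargs = {}
        kin = directory / "kinetics.json"
        if kin.exists():
            cfg = read_kinetics_config(kin)
            kwargs = dict(steady_rates=cfg["steady_rates"],
                          regulation=cfg["regulation"],
                          zero_set=cfg["zero_set"],
                          kind_overrides=cfg["kind_overrides"],
                          k_overrides=cfg["k_overrides"])
        return cls(network, **kwargs)

    @classmethod
    def from_synthetic(cls, spec) -> "CellModel":
        from .synthetic import synthetic_network

        sm = synthetic_network(spec)
        return cls(sm.network, steady_rates=sm.steady_rates)

    # -- fitting -----------------------------------------------------------

    def fit(self, regulate: bool = True) -> "CellResults":
        network = self.network
        S = build_smatrix(network)
        structure = validate_structure(S)
        if not structure.ok:
            raise ValidationError(
                f"stoichiometric structure invalid: {structure.problems}")

        G = bp.build_null_basis_G(S)
        prefer = self._preferred_vector(S)
        basis = bp.make_nonnegative_basis(G, S, prefer_vector=prefer)

        assignment = bp.dilution_rate_assignment(
            network, extra=self.steady_rates, zero_set=set(self.zero_set),
            basis=basis)
        U_cellular = {c.name: c.ss_cellular_concentration
                      for c in network.dynamic_components}
        steady = bp.build_steady_state(network, basis, assignment, U_cellular)

        fractions = network.morphology.fractions
        U_local = {name: conc / fractions[network.component_map[name].compartment]
                   for name, conc in U_cellular.items()}
        refs = dict(U_local)
        for c in network.nutrients:
            refs[c.name] = c.ss_cellular_concentration

        cc = {c.name: c.compartment for c in network.components}
        laws: list[RateLaw] = []
        for j, rid in enumerate(S.reaction_index):
            rxn = network.reaction(rid)
            kind = self.kind_overrides.get(rid, rxn.kinetics_kind)
            law = build_rate_law(rxn, kind, refs, network.morphology, cc)
            if rid in self.k_overrides:
                law = law.with_k(float(self.k_overrides[rid]))
            else:
                law = law.with_k(calibrate_rate_constant(
                    law, float(steady.R_cell[j]), refs))
            if regulate:
                law = apply_regulation(law, self.regulation)
            laws.append(law)

        kinetic = assemble_system(network, S, laws, U_local)
        return CellResults(model=self, S=S, structure=structure, basis=basis,
                           steady=steady, laws=tuple(laws), kinetic=kinetic,
                           regulated=regulate)

    def _preferred_vector(self, S: StoichiometricMatrix) -> np.ndarray | None:
        """Full steady rate vector from the known rates, when complete."""
        needed = S.reaction_index[:S.r]
        alpha = self.network.morphology.alpha_cell
        f_c = self.network.morphology.fraction("c")
        if any(rid not in self.steady_rates and rid not in self.zero_set
               for rid in needed):
            return None
        R = np.empty(S.n)
        for j, rid in enumerate(S.reaction_index):
            if j < S.r:
                R[j] = self.steady_rates.get(rid, 0.0)
            else:
                comp = self.network.reaction(rid).reactants[0][0]
                conc = self.network.component_map[comp].ss_cellular_concentration
                R[j] = alpha * conc / f_c
        return R


@dataclass
class CellResults:
    """Results of fitting a :class:`CellModel`: the steady state, the pathway
    basis, calibrated rate laws and the assembled dynamical system."""

    model: CellModel
    S: StoichiometricMatrix
    structure: object
    basis: bp.BasicPathwayBasis
    steady: bp.SteadyState
    laws: tuple[RateLaw, ...]
    kinetic: KineticModel
    regulated: bool = True
    _law_by_id: dict = field(default=None, repr=False)

    # -- accessors ---------------------------------------------------------

    @property
    def network(self) -> ReactionNetwork:
        return self.model.network

    @property
    def R_cell(self) -> np.ndarray:
        return self.steady.R_cell

    @property
    def C_BP(self) -> np.ndarray:
        return self.steady.C_BP

    @property
    def U_ss_local(self) -> np.ndarray:
        return self.kinetic.U_ss

    def law(self, rid: str) -> RateLaw:
        if self._law_by_id is None:
            object.__setattr__(self, "_law_by_id",
                               {law.reaction_id: law for law in self.laws})
        return self._law_by_id[rid]

    # -- diagnostics -------------------------------------------------------

    def steady_state_residual(self) -> float:
        return float(np.abs(self.S.matrix @ self.steady.R_cell).max())

    def calibration_table(self) -> pd.DataFrame:
        rows = []
        refs = {name: self.kinetic.U_ss[i]
                for i, name in enumerate(self.S.component_index)}
        refs.update(self.kinetic.nutrient_levels)
        for j, rid in enumerate(self.S.reaction_index):
            law = self.law(rid)
            rows.append({"reaction": rid, "kind": law.kind, "k": law.k,
                         "R_ss": float(self.steady.R_cell[j]),
                         "rate_at_Uss": evaluate_rate(law, refs)})
        return pd.DataFrame(rows).set_index("reaction")

    def verify(self) -> pd.DataFrame:
        return verify_steady_state(self.kinetic, self.kinetic.U_ss)

    def total_iron(self, group_by: str = "none"):
        """Total iron (µM of Fe) held by the steady-state cell, optionally
        broken down by compartment or component."""
        comps = self.network.dynamic_components
        conc = {c.name: c.ss_cellular_concentration for c in comps}
        profiles = {c.name: c.iron_profile for c in comps}
        compartments = {c.name: c.compartment for c in comps}
        return total_iron(conc, profiles, group_by=group_by,
                          compartments=compartments)

    def pathway_report(self, j: int) -> bp.PathwayReport:
        return bp.classify_pathway(self.basis.W[:, j], self.network,
                                   list(self.S.reaction_index), column=j)

    def pathway_reports(self) -> list[bp.PathwayReport]:
        return [self.pathway_report(j) for j in range(self.basis.r)]

    def pathway_reports_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            [r.to_dict() for r in self.pathway_reports()], indent=1))

    # -- simulation --------------------------------------------------------

    def simulate(self, t_end: float, events: list[PerturbationSpec] | None = None,
                 U0: np.ndarray | None = None, classify: bool = True,
                 **kwargs) -> Trajectory:
        U0 = self.kinetic.U_ss.copy() if U0 is None else U0
        traj = integrate(self.kinetic, U0, t_end, events=events, **kwargs)
        if classify:
            traj.outcome = classify_outcome(traj, self.kinetic)
        return traj

    def perturb(self, target: str, factor: float, kind: str | None = None,
                time: float = 50.0, t_end: float = 20000.0, **kwargs):
        """Run a single perturbation experiment and return (trajectory, ratio
        table).  The kind is inferred from the target when not given."""
        if kind is None:
            if target in self.kinetic.nutrient_levels:
                kind = "nutrient_step"
            elif target in self.S.component_index:
                kind = "concentration_step"
            elif target in self.S.reaction_index:
                kind = "rate_constant_step"
            else:
                raise ValidationError(f"unknown perturbation target {target!r}")
        spec = PerturbationSpec(kind=kind, target=target, factor=factor,
                                time=time)
        return perturbation_experiment(self.kinetic, spec, t_end=t_end, **kwargs)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        net = self.network
        morph = net.morphology
        sparsity, n_single, srank, n_def = (
            self.basis.sparsity, len(self.basis.singleton_rows),
            len(self.basis.singleton_rows) / self.basis.n,
            len(self.basis.deficient_columns))
        fe = self.total_iron()
        fe_comp = self.total_iron(group_by="compartment")
        active = int((self.steady.C_BP > 1e-9).sum())
        lines = [
            "Compartmentalized kinetic cell model",
            "=" * 60,
            f"Components (state variables)      {self.S.m:>10d}",
            f"Reactions (incl. dilutions)       {self.S.n:>10d}",
            f"Non-dilution reactions (r)        {self.S.r:>10d}",
            f"Compartments                      {len(morph.compartments):>10d}",
            f"Growth rate alpha (1/min)         {morph.alpha_cell:>10.6f}",
            f"Cell volume (L)                   {morph.V_cell:>10.2e}",
            "-" * 60,
            f"Stoichiometric rank               {self.structure.rank:>10d}",
            f"Null-space dimension              {self.structure.nullity:>10d}",
            f"Basis sparsity                    {sparsity:>10.3f}",
            f"Singleton rows                    {n_single:>10d}"
            f"  (rank {srank:.2f})",
            f"Singleton-deficient columns       {n_def:>10d}",
            f"Active basic pathways             {active:>10d}",
            f"Steady-state residual |S·R|_max   "
            f"{self.steady_state_residual():>10.2e}",
            "-" * 60,
            f"Total cellular iron (µM)          {fe:>10.1f}",
            "  by compartment: "
            + ", ".join(f"{k}: {v:.1f}" for k, v in sorted(fe_comp.items())),
            f"Regulated reactions               "
            f"{len({r.reaction_id for r in self.model.regulation}):>10d}",
            f"Zero-rate reactions               {len(self.model.zero_set):>10d}",
            "=" * 60,
        ]
        return "\n".join(lines)
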