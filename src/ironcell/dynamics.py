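"""Nonlinear ODE dynamics U' = S·R(U), perturbations and outcome classing.

The state is the vector of *local* concentrations (µM) of every non-nutrient
component; nutrient levels are fixed parameters that perturbations may step.
The stoichiometric matrix is already volume-scaled, so composing it with the
cytosol-referenced rate vector yields local-concentration derivatives
directly.  Integration is stiff and adaptive (LSODA, rtol 1e-8 / atol 1e-10 by
default — tight enough to study roundoff-induced departure from unstable
steady states, which is expected behavior for the unregulated system, not a
bug).

Rate evaluation is compiled to padded index arrays over an extended state
vector (states + nutrients + a constant-1 sentinel), so one right-hand-side
call is a handful of vectorized numpy operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import ReactionNetwork, ValidationError
from .kinetics import RateLaw
from .stoichiometry import StoichiometricMatrix

__all__ = [
    "KineticModel",
    "PerturbationSpec",
    "Trajectory",
    "Outcome",
    "assemble_system",
    "integrate",
    "classify_outcome",
    "perturbation_experiment",
    "verify_steady_state",
]

OUTCOME_CLASSES = ("at_reference_steady_state", "new_steady_state", "blowup",
                   "oscillation", "undetermined")


@dataclass(frozen=True)
class PerturbationSpec:
    """A step perturbation applied during integration.

    ``concentration_step`` multiplies one component's concentration,
    ``nutrient_step`` multiplies a nutrient level, ``rate_constant_step``
    multiplies one reaction's rate constant; all at the given time."""

    kind: str
    target: str
    factor: float
    time: float = 50.0

    def __post_init__(self):
        if self.kind not in ("concentration_step", "nutrient_step",
                             "rate_constant_step"):
            raise ValidationError(f"unknown perturbation kind {self.kind!r}")
        if self.factor <= 0:
            raise ValidationError("perturbation factor must be positive")
        if self.time < 0:
            raise ValidationError("perturbation time must be nonnegative")


@dataclass
class Outcome:
    cls: str
    final_state: np.ndarray | None = None
    ratios: dict[str, float] | None = None
    convergence_time: float | None = None
    period: float | None = None
    diagnostics: str = ""

    def __post_init__(self):
        if self.cls not in OUTCOME_CLASSES:
            raise ValidationError(f"unknown outcome class {self.cls!r}")


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray                      # len(times) x m, local µM
    component_index: list[str]
    U_ss: np.ndarray                        # reference local concentrations
    events: tuple[PerturbationSpec, ...] = ()
    outcome: Outcome | None = None
    success: bool = True
    message: str = ""
    negative_clamps: int = 0

    def normalized(self) -> np.ndarray:
        """Component-wise U(t)/U_ss."""
        return self.states / self.U_ss[None, :]

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        data = self.normalized() if normalized else self.states
        df = pd.DataFrame(data, columns=self.component_index)
        df.insert(0, "time_min", self.times)
        return df

    def to_tsv(self, path, normalized: bool = False) -> None:
        self.to_frame(normalized=normalized).to_csv(path, sep="\t", index=False)

    def plot(self, components: list[str] | None = None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        norm = self.normalized()
        names = components or self.component_index
        for name in names:
            ax.plot(self.times, norm[:, self.component_index.index(name)],
                    label=name, lw=1)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("U(t)/U_ss")
        if len(names) <= 12:
            ax.legend(fontsize=7, ncol=2)
        return ax


# ---------------------------------------------------------------------------
# compiled model
# ---------------------------------------------------------------------------

class _Compiled:
    """Padded index arrays over the extended state [x, nutrients, 1]."""

    def __init__(self, laws: list[RateLaw], name_to_idx: dict[str, int],
                 sentinel: int, n: int):
        self.n = n
        self.k = np.array([law.k for law in laws])

        def idx(name):
            return name_to_idx[name]

        mm, ma, tr, dil = [], [], [], []
        for pos, law in enumerate(laws):
            if law.kind == "michaelis_menten":
                mm.append(pos)
            elif law.kind == "mass_action":
                ma.append(pos)
            elif law.kind == "transport_ratio":
                tr.append(pos)
            elif law.kind == "dilution":
                dil.append(pos)
            else:  # pragma: no cover
                raise ValidationError(f"unknown law kind {law.kind}")

        def pad_terms(positions, kind):
            """substrate (idx, denom) and catalyst (idx, ref) matrices."""
            max_s = max((len(laws[p].substrates) for p in positions), default=0)
            max_c = max((len(laws[p].catalysts) for p in positions), default=0)
            s_idx = np.full((len(positions), max(max_s, 1)), sentinel, dtype=int)
            s_par = np.zeros((len(positions), max(max_s, 1)))
            s_par[:] = 0.0 if kind == "mm" else 1.0
            c_idx = np.full((len(positions), max(max_c, 1)), sentinel, dtype=int)
            c_ref = np.ones((len(positions), max(max_c, 1)))
            for row, p in enumerate(positions):
                for col, (name, km, ref) in enumerate(laws[p].substrates):
                    s_idx[row, col] = idx(name)
                    s_par[row, col] = km if kind == "mm" else ref
                for col, (name, ref) in enumerate(laws[p].catalysts):
                    c_idx[row, col] = idx(name)
                    c_ref[row, col] = ref
            return np.array(positions, dtype=int), s_idx, s_par, c_idx, c_ref

        self.mm = pad_terms(mm, "mm")
        self.ma = pad_terms(ma, "ma")
        self.tr_pos = np.array(tr, dtype=int)
        self.tr_donor = np.array([idx(laws[p].transport[0]) for p in tr], dtype=int)
        self.tr_recv = np.array([idx(laws[p].transport[1]) for p in tr], dtype=int)
        self.dil_pos = np.array(dil, dtype=int)
        self.dil_idx = np.array([idx(laws[p].dilution_component) for p in dil],
                                dtype=int)
        self.dil_factor = np.array([laws[p].dilution_factor for p in dil])

        # regulation: flattened (law position, sensed idx, ref, steepness)
        reg = [(pos, idx(rule.sensed), rule.reference, rule.steepness)
               for pos, law in enumerate(laws) for rule in law.regulation]
        self.reg_pos = np.array([t[0] for t in reg], dtype=int)
        self.reg_idx = np.array([t[1] for t in reg], dtype=int)
        self.reg_ref = np.array([t[2] for t in reg])
        self.reg_steep = np.array([t[3] for t in reg])

    def rates(self, xe: np.ndarray) -> np.ndarray:
        R = np.zeros(self.n)
        pos, s_idx, s_par, c_idx, c_ref = self.mm
        if pos.size:
            s = xe[s_idx]
            R[pos] = (s / (s_par + s)).prod(axis=1) * (xe[c_idx] / c_ref).prod(axis=1)
        pos, s_idx, s_par, c_idx, c_ref = self.ma
        if pos.size:
            R[pos] = (xe[s_idx] / s_par).prod(axis=1) * (xe[c_idx] / c_ref).prod(axis=1)
        if self.tr_pos.size:
            # floor the receiver to keep the ratio finite if a concentration
            # collapses; the trajectory is already failing in that regime
            R[self.tr_pos] = xe[self.tr_donor] / np.maximum(xe[self.tr_recv],
                                                            1e-12) - 1.0
        if self.dil_pos.size:
            R[self.dil_pos] = self.dil_factor * xe[self.dil_idx]
        R *= self.k
        if self.reg_pos.size:
            f = 2.0 / (1.0 + np.exp(-self.reg_steep *
                                    (1.0 - xe[self.reg_idx] / self.reg_ref)))
            np.multiply.at(R, self.reg_pos, f)
        return R


@dataclass
class KineticModel:
    """The assembled dynamical system: network, matrix, one law per reaction,
    the reference steady state (local µM) and the nutrient levels."""

    network: ReactionNetwork
    S: StoichiometricMatrix
    laws: tuple[RateLaw, ...]
    U_ss: np.ndarray
    nutrient_levels: dict[str, float]
    _compiled: _Compiled | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.laws) != self.S.n:
            raise ValidationError(
                f"{len(self.laws)} laws for {self.S.n} reactions; every "
                "reaction needs a law")
        by_id = {law.reaction_id for law in self.laws}
        missing = [rid for rid in self.S.reaction_index if rid not in by_id]
        if missing:
            raise ValidationError(f"missing rate laws for {missing}")

    # -- compiled evaluation ----------------------------------------------

    @property
    def component_index(self) -> list[str]:
        return self.S.component_index

    def _extended_names(self) -> dict[str, int]:
        names = {n: i for i, n in enumerate(self.S.component_index)}
        base = len(names)
        for j, n in enumerate(self.nutrient_levels):
            names[n] = base + j
        return names

    def compiled(self) -> _Compiled:
        if self._compiled is None:
            order = {rid: i for i, rid in enumerate(self.S.reaction_index)}
            laws = sorted(self.laws, key=lambda law: order[law.reaction_id])
            names = self._extended_names()
            sentinel = len(names)
            object.__setattr__(self, "_compiled",
                               _Compiled(laws, names, sentinel, self.S.n))
        return self._compiled

    def _extend(self, x: np.ndarray) -> np.ndarray:
        return np.concatenate([x, list(self.nutrient_levels.values()), [1.0]])

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Cytosol-referenced rate vector at local-concentration state x."""
        return self.compiled().rates(self._extend(np.asarray(x, dtype=float)))

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        # overflow in a diverging trajectory is expected and handled by the
        # outcome classifier; don't warn mid-integration
        with np.errstate(over="ignore", invalid="ignore"):
            return self.S.matrix @ self.rates(np.maximum(x, 0.0))

    # -- perturbed copies --------------------------------------------------

    def with_nutrient(self, name: str, factor: float) -> "KineticModel":
        if name not in self.nutrient_levels:
            raise ValidationError(f"unknown nutrient {name!r}")
        levels = dict(self.nutrient_levels)
        levels[name] *= factor
        return replace(self, nutrient_levels=levels, _compiled=None)

    def with_rate_constant(self, reaction_id: str, factor: float) -> "KineticModel":
        if reaction_id not in {law.reaction_id for law in self.laws}:
            raise ValidationError(f"unknown reaction {reaction_id!r}")
        laws = tuple(law.with_k(law.k * factor) if law.reaction_id == reaction_id
                     else law for law in self.laws)
        return replace(self, laws=laws, _compiled=None)


def assemble_system(network: ReactionNetwork, S: StoichiometricMatrix,
                    laws: list[RateLaw], U_ss_local: dict[str, float],
                    nutrient_levels: dict[str, float] | None = None
                    ) -> KineticModel:
    """Build the right-hand-side system from calibrated laws.

    ``U_ss_local`` maps every state component to its wild-type local
    concentration; nutrient levels default to the concentrations stored on
    nutrient components."""
    if nutrient_levels is None:
        nutrient_levels = {c.name: c.ss_cellular_concentration
                           for c in network.nutrients}
    U = np.array([U_ss_local[name] for name in S.component_index])
    return KineticModel(network=network, S=S, laws=tuple(laws), U_ss=U,
                        nutrient_levels=dict(nutrient_levels))


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate(model: KineticModel, U0: np.ndarray, t_end: float,
              events: list[PerturbationSpec] | None = None,
              rtol: float = 1e-8, atol: float = 1e-10,
              n_points: int = 400, method: str = "LSODA") -> Trajectory:
    """Integrate the system with step perturbations applied as discontinuities.

    Events split the horizon into segments; concentration steps modify the
    state, nutrient and rate-constant steps swap in a modified model for the
    remaining segments.  Small negative excursions (|value| < atol) are
    clamped to zero and counted; larger ones abort as a solver failure."""
    events = sorted(events or [], key=lambda e: e.time)
    if any(e.time > t_end for e in events):
        raise ValidationError("perturbation scheduled after t_end")
    U0 = np.asarray(U0, dtype=float)
    if np.any(U0 < 0):
        raise ValidationError("initial state must be nonnegative")
    if t_end <= 0:
        raise ValidationError("t_end must be positive")

    boundaries = [0.0] + [e.time for e in events] + [t_end]
    cur = model
    state = U0.copy()
    clamps = 0
    all_t: list[np.ndarray] = []
    all_x: list[np.ndarray] = []
    pending = list(events)
    ok, msg = True, ""

    for seg in range(len(boundaries) - 1):
        t0, t1 = boundaries[seg], boundaries[seg + 1]
        if seg > 0:
            ev = pending.pop(0)
            if ev.kind == "concentration_step":
                idx = cur.component_index.index(ev.target)
                state[idx] *= ev.factor
            elif ev.kind == "nutrient_step":
                cur = cur.with_nutrient(ev.target, ev.factor)
            else:
                cur = cur.with_rate_constant(ev.target, ev.factor)
        if t1 <= t0:
            continue
        frac = (t1 - t0) / t_end
        t_eval = np.linspace(t0, t1, max(int(n_points * frac), 8))
        # an explicit first step sidesteps a pathological automatic initial
        # step when resuming from a near-equilibrium state
        sol = solve_ivp(cur.rhs, (t0, t1), state, method=method,
                        rtol=rtol, atol=atol, t_eval=t_eval,
                        first_step=min(1.0, (t1 - t0) / 1000))
        if not sol.success:
            ok, msg = False, sol.message
            if sol.t.size:
                all_t.append(sol.t)
                all_x.append(sol.y.T)
            break
        y = sol.y.T
        if not np.isfinite(y).all():
            ok, msg = False, "state became non-finite (overflow)"
            finite_rows = np.isfinite(y).all(axis=1)
            all_t.append(sol.t[finite_rows])
            all_x.append(y[finite_rows])
            break
        neg = y < 0
        big_neg = y < -100 * atol
        if big_neg.any():
            ok, msg = False, "state went significantly negative"
            y = np.clip(y, 0.0, None)
        elif neg.any():
            clamps += int(neg.sum())
            y = np.clip(y, 0.0, None)
        all_t.append(sol.t)
        all_x.append(y)
        state = y[-1].copy()

    times = np.concatenate(all_t) if all_t else np.array([0.0])
    states = np.vstack(all_x) if all_x else U0[None, :]
    keep = np.concatenate([[True], np.diff(times) > 0])
    # at event boundaries prefer the post-event sample
    for i in np.where(~keep)[0]:
        states[i - 1] = states[i]
    return Trajectory(times=times[keep], states=states[keep],
                      component_index=list(model.component_index),
                      U_ss=model.U_ss.copy(), events=tuple(events),
                      success=ok, message=msg, negative_clamps=clamps)


# ---------------------------------------------------------------------------
# outcome classification
# ---------------------------------------------------------------------------

def classify_outcome(traj: Trajectory, model: KineticModel,
                     tail_window: float = 0.2, at_tol: float = 1e-3,
                     blowup_threshold: float = 1e3,
                     deriv_tol: float = 1e-6, osc_tol: float = 1e-3) -> Outcome:
    """Classify the asymptotic behavior of a trajectory.

    Order of tests: blowup (any normalized concentration beyond the threshold,
    or solver collapse), return to the reference state (tail within
    ``at_tol``), sustained oscillation (alternating derivative with stable
    autocorrelation period in the tail), new steady state (tail derivative
    below ``deriv_tol`` of the dilution scale), else undetermined."""
    norm = traj.normalized()
    if np.nanmax(norm) > blowup_threshold or not traj.success:
        t_cross = traj.times[-1]
        over = np.where(np.nanmax(norm, axis=1) > blowup_threshold)[0]
        if over.size:
            t_cross = float(traj.times[over[0]])
        return Outcome(cls="blowup", final_state=traj.states[-1],
                       convergence_time=None,
                       diagnostics=(traj.message or
                                    f"normalized state exceeded "
                                    f"{blowup_threshold:g} at t={t_cross:g}"))

    tail_start = traj.times[-1] - tail_window * (traj.times[-1] - traj.times[0])
    tail = traj.times >= tail_start
    dev = np.abs(norm[tail] - 1.0)
    if dev.max() < at_tol:
        path = np.abs(norm - 1.0).max(axis=1)
        inside = path < at_tol
        conv = traj.times[-1]
        for i in range(len(inside) - 1, -1, -1):
            if not inside[i]:
                conv = float(traj.times[min(i + 1, len(inside) - 1)])
                break
        else:
            conv = float(traj.times[0])
        return Outcome(cls="at_reference_steady_state",
                       final_state=traj.states[-1], convergence_time=conv)

    # oscillation: strongest tail component, detrended
    tail_t = traj.times[tail]
    tail_x = norm[tail]
    amp = tail_x.max(axis=0) - tail_x.min(axis=0)
    j = int(np.argmax(amp))
    sig = tail_x[:, j] - tail_x[:, j].mean()
    rel_amp = amp[j] / max(abs(tail_x[:, j].mean()), 1e-12)
    if rel_amp > osc_tol and sig.size > 16:
        d = np.diff(sig)
        flips = int(np.sum(np.sign(d[:-1]) * np.sign(d[1:]) < 0))
        ac = np.correlate(sig, sig, mode="full")[sig.size - 1:]
        ac /= max(ac[0], 1e-300)
        peaks = [i for i in range(2, len(ac) - 1)
                 if ac[i] > ac[i - 1] and ac[i] > ac[i + 1] and ac[i] > 0.5]
        if flips >= 4 and peaks:
            period = float(np.interp(peaks[0], np.arange(len(tail_t)),
                                     tail_t - tail_t[0]))
            return Outcome(cls="oscillation", final_state=traj.states[-1],
                           period=period,
                           diagnostics=f"dominant component {traj.component_index[j]}")

    # derivative from the sampled tail (finite differences): an instantaneous
    # right-hand side at an interpolated state is polluted by fast stiff modes
    scale = max(float(np.abs(model.rhs(0.0, model.U_ss)).max()),
                float((model.U_ss * model.network.morphology.alpha_cell).max()))
    tail_states = traj.states[tail]
    final_deriv = float(np.abs(np.gradient(tail_states, tail_t, axis=0)).max())
    if final_deriv < deriv_tol * max(scale, 1e-12):
        ratios = {name: float(traj.states[-1, i] / model.U_ss[i])
                  for i, name in enumerate(traj.component_index)}
        return Outcome(cls="new_steady_state", final_state=traj.states[-1],
                       ratios=ratios, convergence_time=float(traj.times[-1]))
    return Outcome(cls="undetermined", final_state=traj.states[-1],
                   diagnostics=f"tail derivative {final_deriv:.3e}")


def perturbation_experiment(model: KineticModel, spec: PerturbationSpec,
                            t_end: float = 5000.0, U0: np.ndarray | None = None,
                            **kwargs) -> tuple[Trajectory, pd.DataFrame]:
    """Run one perturbation from the reference state and report steady-state
    concentration ratios new/old per component."""
    U0 = model.U_ss.copy() if U0 is None else np.asarray(U0, dtype=float)
    traj = integrate(model, U0, t_end, events=[spec], **kwargs)
    traj.outcome = classify_outcome(traj, model)
    ratios = traj.states[-1] / model.U_ss
    table = pd.DataFrame({"component": model.component_index,
                          "ratio_new_over_old": ratios}).set_index("component")
    return traj, table


def verify_steady_state(model: KineticModel, U: np.ndarray,
                        tol: float = 1e-8) -> pd.DataFrame:
    """Per-component |dU/dt| with a scaled residual; pass when every scaled
    residual is below ``tol``.  The scale for each component is the largest
    individual flux contribution |S_ij·R_j| feeding it, so a zero state
    immediately flags its import reactions."""
    U = np.asarray(U, dtype=float)
    R = model.rates(U)
    contrib = np.abs(model.S.matrix) * np.abs(R)[None, :]
    scale = np.maximum(contrib.max(axis=1), 1e-300)
    dU = model.S.matrix @ R
    df = pd.DataFrame({
        "component": model.component_index,
        "dUdt": dU,
        "scaled_residual": np.abs(dU) / scale,
        "dominant_reaction": [model.S.reaction_index[j]
                              for j in np.argmax(contrib, axis=1)],
    }).set_index("component")
    df.attrs["ok"] = bool((df["scaled_residual"] < tol).all())
    return df
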