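"""Nonnegative null-space bases ("basic pathways") for (S0 | -D) systems.

A steady-state rate vector R satisfies S_cell·R = 0 with R >= 0.  Because the
dilution block -D is diagonal and nonsingular, the null space of
S_cell = (S0 | -D) has dimension r (the non-dilution reaction count) and the
algebraic basis G = [I_r ; D^{-1} S0].  Columns of G can carry negative
dilution entries and are then not chemically feasible.  This module transforms
G into a basis W whose r columns are nonnegative rate vectors — basic pathways,
typically stoichiometric flows from nutrients to diluted destination
components — and solves the overdetermined system R = W·C for the pathway
weights C from an assigned set of r independent rates, exploiting singleton
rows of W (rows with a single nonzero, which expose one weight directly as
c_j = R_i/w_ij).

The null space is parameterized by the non-dilution sub-vector u (the top
block): a null vector [u ; D^{-1}S0 u] is nonnegative exactly when u >= 0 and
S0·u >= 0, i.e. when u lies in the flux cone of the growth-diluted network.
Basis construction therefore works in this reduced r-dimensional cone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .core import ReactionNetwork, ValidationError
from .stoichiometry import StoichiometricMatrix

__all__ = [
    "BasicPathwayBasis",
    "RateAssignment",
    "SteadyState",
    "PathwayReport",
    "InfeasibleBasisError",
    "build_null_basis_G",
    "extreme_rays",
    "make_nonnegative_basis",
    "singleton_stats",
    "solve_weights",
    "compose_rates",
    "decompose_rates",
    "classify_pathway",
    "build_steady_state",
    "select_independent_set",
]

NULLSPACE_TOL = 1e-8
WEIGHT_CLAMP = 1e-10


class InfeasibleBasisError(ValidationError):
    """No nonnegative basis could be constructed; carries a structured report."""

    def __init__(self, message: str, offending: list[int] | None = None):
        super().__init__(message)
        self.offending = offending or []


# ---------------------------------------------------------------------------
# basis types
# ---------------------------------------------------------------------------

@dataclass
class BasicPathwayBasis:
    """Nonnegative n x r basis W of the null space of an (S0 | -D) matrix.

    ``singleton_rows`` maps each singleton row index to the column index of its
    sole nonzero; ``deficient_columns`` lists columns with no singleton
    element (their weights need a small linear solve).
    """

    W: np.ndarray
    reaction_index: list[str]
    singleton_rows: dict[int, int]
    deficient_columns: list[int]
    sparsity: float
    provenance: str = "constructed"

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def r(self) -> int:
        return self.W.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.W[:, j]


@dataclass(frozen=True)
class RateAssignment:
    """r independent rates (µM/min, cytosol-referenced), plus reactions pinned
    to zero.  Zero-set reactions count toward the independent total."""

    independent: dict[str, float]
    zero_set: frozenset[str] = frozenset()

    def __post_init__(self):
        bad = [k for k, v in self.independent.items() if v < 0]
        if bad:
            raise ValidationError(f"negative assigned rates for {bad}")

    @property
    def rates(self) -> dict[str, float]:
        out = dict(self.independent)
        for rid in self.zero_set:
            out.setdefault(rid, 0.0)
        return out


@dataclass
class SteadyState:
    """A complete chemically feasible steady state."""

    R_cell: np.ndarray
    C_BP: np.ndarray
    U_ss: dict[str, float]          # cellular µM per component
    reaction_index: list[str]
    residual: float = 0.0

    def rate(self, rid: str) -> float:
        return float(self.R_cell[self.reaction_index.index(rid)])


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _split_blocks(S: StoichiometricMatrix) -> tuple[np.ndarray, np.ndarray]:
    block = S.dilution_block
    if block.shape[0] != block.shape[1]:
        raise ValidationError("dilution block is not square")
    off = block - np.diag(np.diag(block))
    if np.any(off != 0) or np.any(np.diag(block) >= 0):
        raise ValidationError("dilution block must be diagonal with strictly "
                              "negative diagonal")
    d = -np.diag(block)
    return S.S0, d


def build_null_basis_G(S: StoichiometricMatrix) -> np.ndarray:
    """Algebraic null basis G = [I_r ; D^{-1} S0]; S·G = 0 exactly (up to FP)."""
    S0, d = _split_blocks(S)
    r = S.r
    bottom = S0 / d[:, None]
    return np.vstack([np.eye(r), bottom])


def extreme_rays(A: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Extreme rays of the pointed cone {u >= 0, A·u >= 0} by double
    description: start from the positive orthant and add the inequalities of A
    one at a time, combining adjacent positive/negative rays.

    Returns rays as columns, each scaled to unit maximum entry.  Intended for
    the small systems where basis construction needs a combinatorial fallback.
    """
    r = A.shape[1]
    rays = [np.eye(r)[:, i] for i in range(r)]
    halfspaces = [A[i] for i in range(A.shape[0])]
    processed: list[np.ndarray] = []

    def zero_set(u):
        z = {("x", i) for i in range(r) if u[i] <= tol}
        for k, h in enumerate(processed):
            if abs(h @ u) <= tol * (1 + np.abs(h) @ u):
                z.add(("h", k))
        return z

    for h in halfspaces:
        vals = [float(h @ u) for u in rays]
        scale = [tol * (1 + np.abs(h) @ u) for u in rays]
        pos = [i for i, v in enumerate(vals) if v > scale[i]]
        neg = [i for i, v in enumerate(vals) if v < -scale[i]]
        zer = [i for i in range(len(rays)) if i not in pos and i not in neg]
        new_rays = [rays[i] for i in pos + zer]
        zsets = {i: zero_set(rays[i]) for i in pos + neg}
        for ip in pos:
            for im in neg:
                # adjacency: no third ray's zero set contains the common one
                common = zsets[ip] & zsets[im]
                adjacent = True
                for k in pos + neg:
                    if k in (ip, im):
                        continue
                    if common <= zsets[k]:
                        adjacent = False
                        break
                if not adjacent:
                    continue
                u = vals[ip] * rays[im] - vals[im] * rays[ip]
                mx = u.max()
                if mx > tol:
                    new_rays.append(u / mx)
        processed.append(h)
        # deduplicate
        uniq: list[np.ndarray] = []
        for u in new_rays:
            mx = u.max()
            if mx <= tol:
                continue
            u = u / mx
            if not any(np.allclose(u, v, atol=1e-9) for v in uniq):
                uniq.append(u)
        rays = uniq
    return np.array(rays).T if rays else np.zeros((r, 0))


def _minimal_pathway_lp(S0: np.ndarray, j: int) -> np.ndarray | None:
    """Smallest-total-flux nonnegative pathway through reaction j:
    min 1'u  s.t.  S0 u >= 0, u >= 0, u_j = 1."""
    r = S0.shape[1]
    res = linprog(c=np.ones(r), A_ub=-S0, b_ub=np.zeros(S0.shape[0]),
                  bounds=[(1.0, 1.0) if i == j else (0.0, None) for i in range(r)],
                  method="highs")
    if not res.success:
        return None
    u = np.asarray(res.x)
    u[np.abs(u) < 1e-12] = 0.0
    return u


def _interior_point(S0: np.ndarray) -> tuple[np.ndarray, float]:
    """Chebyshev-style interior point of {u >= 0, S0 u >= 0, sum u = 1}:
    maximize the margin t with u >= t and S0 u >= t."""
    m, r = S0.shape
    # variables (u_1..u_r, t); maximize t
    A_ub = np.block([[-S0, np.ones((m, 1))],
                     [-np.eye(r), np.ones((r, 1))]])
    b_ub = np.zeros(m + r)
    A_eq = np.concatenate([np.ones(r), [0.0]])[None, :]
    res = linprog(c=np.concatenate([np.zeros(r), [-1.0]]),
                  A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
                  bounds=[(0.0, None)] * r + [(0.0, None)], method="highs")
    if not res.success or res.x[-1] <= 0:
        raise InfeasibleBasisError(
            "flux cone has empty interior: no strictly positive steady-state "
            "rate vector exists")
    return res.x[:r], float(res.x[-1])


def _rank(M: np.ndarray) -> int:
    return int(np.linalg.matrix_rank(M, tol=1e-9))


def _cone_decompose(S0: np.ndarray, u_star: np.ndarray, tol: float = 1e-9
                    ) -> tuple[list[np.ndarray], np.ndarray]:
    """Exact nonnegative pathway decomposition of a flux-cone point.

    Iterative peeling: at each step a minimal-total-flux pathway is found whose
    support (in both reaction coordinates and net dilution rows) is restricted
    to the coordinates still active in the remainder; subtracting the largest
    feasible multiple zeroes at least one active coordinate, so the loop
    terminates in at most n + m steps with u* written exactly (to roundoff) as
    a nonnegative combination.  The support is then pruned to a linearly
    independent set (Carathéodory reduction for cones)."""
    m, r = S0.shape
    scale = float(u_star.max())
    if scale <= 0:
        return [], np.zeros(0)
    eps = tol * scale
    u_rem = u_star.astype(float).copy()
    cols: list[np.ndarray] = []
    coeffs: list[float] = []

    for _ in range(r + m + 5):
        if u_rem.max() <= eps:
            break
        du = S0 @ u_rem
        d_scale = max(float(np.abs(du).max()), eps)
        active_u = u_rem > eps
        active_d = du > tol * d_scale
        j = int(np.argmax(u_rem))
        bounds = [(1.0, 1.0) if i == j else
                  ((0.0, None) if active_u[i] else (0.0, 0.0))
                  for i in range(r)]
        inactive_rows = S0[~active_d]
        res = linprog(c=np.ones(r), A_ub=-S0, b_ub=np.zeros(m),
                      A_eq=inactive_rows if inactive_rows.size else None,
                      b_eq=np.zeros(inactive_rows.shape[0])
                      if inactive_rows.size else None,
                      bounds=bounds, method="highs")
        if not res.success:
            break
        p = np.asarray(res.x)
        p[np.abs(p) < 1e-12] = 0.0
        dp = S0 @ p
        ratios = [u_rem[i] / p[i] for i in range(r) if p[i] > tol]
        ratios += [du[k] / dp[k] for k in range(m)
                   if active_d[k] and dp[k] > tol * max(1.0, np.abs(dp).max())]
        if not ratios:
            break
        lam = min(ratios)
        if lam <= 0:
            break
        cols.append(p)
        coeffs.append(lam)
        u_rem = np.clip(u_rem - lam * p, 0.0, None)

    if u_rem.max() > 1e-7 * scale:
        raise InfeasibleBasisError(
            "preferred rate vector could not be decomposed over the flux cone "
            f"(remainder {u_rem.max():.3e} of scale {scale:.3e})")

    # Carathéodory pruning: shrink the support to independent columns
    c = np.array(coeffs)
    supp = [i for i in range(len(c)) if c[i] > tol]
    while supp:
        A_s = np.column_stack([cols[i] for i in supp])
        if _rank(A_s) == len(supp):
            break
        ns = _null_vector(A_s)
        steps = [(c[i] / ns[k], i) for k, i in enumerate(supp) if ns[k] > tol]
        alt = [(c[i] / -ns[k], i) for k, i in enumerate(supp) if ns[k] < -tol]
        if not steps or (alt and min(alt)[0] < min(steps)[0] and not steps):
            ns, steps = -ns, alt
        if not steps:
            break
        t, _ = min(steps)
        for k, i in enumerate(supp):
            c[i] -= t * ns[k]
        supp = [i for i in supp if c[i] > tol]
    return [cols[i] for i in supp], np.array([c[i] for i in supp])


def _null_vector(A: np.ndarray) -> np.ndarray:
    _, s, vt = np.linalg.svd(A)
    return vt[-1]


def make_nonnegative_basis(G: np.ndarray, S: StoichiometricMatrix,
                           prefer_vector: np.ndarray | None = None,
                           tol: float = NULLSPACE_TOL) -> BasicPathwayBasis:
    """Transform an algebraic null basis into a nonnegative basic-pathway basis.

    Columns of G whose dilution entries are already nonnegative are kept as
    candidates.  Each remaining reaction contributes the minimal-support
    pathway through it (a feasibility LP over the reduced flux cone — this
    adds positive multiples of other generators until every negative entry is
    cancelled).  Candidates are admitted greedily by rank; if coupled
    reactions leave the set rank deficient it is completed with perturbed
    interior-point columns u* + eps·e_j, which are always feasible and restore
    independence.

    When ``prefer_vector`` (a nonnegative steady-state rate vector, e.g. the
    wild-type one) is supplied, a nonnegative Carathéodory decomposition of it
    is computed first and its support columns are locked into the basis, so
    that the preferred vector's unique weight representation is nonnegative.

    Raises :class:`InfeasibleBasisError`, naming the offending reactions, when
    some reaction admits no nonnegative pathway or the cone has empty interior.
    """
    S0, d = _split_blocks(S)
    r = S.r
    if G.shape != (S.n, r):
        raise ValidationError(f"G has shape {G.shape}, expected {(S.n, r)}")
    scaled = S0 / d[:, None]  # bottom-block map u -> dilution rates

    # per-reaction minimal pathways (sparse, chemically interpretable)
    pool: list[np.ndarray] = []
    offending: list[int] = []
    for j in range(r):
        u = G[:r, j]
        if np.all(u >= 0) and np.all(scaled @ u >= -tol):
            pool.append(u)
            continue
        lp = _minimal_pathway_lp(S0, j)
        if lp is None:
            offending.append(j)
        else:
            pool.append(lp)
    if offending:
        names = [S.reaction_index[j] for j in offending]
        raise InfeasibleBasisError(
            "no nonnegative pathway exists through reactions "
            f"{names}: the flux cone does not span these coordinates",
            offending=offending)

    chosen: list[np.ndarray] = []
    if prefer_vector is not None:
        R_pref = np.asarray(prefer_vector, dtype=float)
        if R_pref.shape[0] == S.n:
            u_pref = R_pref[:r]
        elif R_pref.shape[0] == r:
            u_pref = R_pref
        else:
            raise ValidationError("prefer_vector must have length n or r")
        if np.any(u_pref < -tol):
            raise ValidationError("prefer_vector must be nonnegative")
        support, _ = _cone_decompose(S0, np.clip(u_pref, 0.0, None))
        chosen.extend(support)

    # greedy rank-building over the sparse candidates
    rank = _rank(np.column_stack(chosen)) if chosen else 0
    for cand in pool:
        if rank == r:
            break
        trial = np.column_stack(chosen + [cand])
        if _rank(trial) > rank:
            chosen.append(cand)
            rank += 1

    # completion from the cone interior: u* + eps·e_j stays feasible and the
    # family spans R^r, so the greedy pass always reaches full rank
    if rank < r:
        u_star, margin = _interior_point(S0)
        col_scale = np.abs(S0).max(axis=0)
        for j in range(r):
            if rank == r:
                break
            eps = 0.5 * margin / max(1.0, col_scale[j])
            cand = u_star + eps * np.eye(r)[:, j]
            trial = np.column_stack(chosen + [cand])
            if _rank(trial) > rank:
                chosen.append(cand)
                rank += 1
    if rank < r:
        raise InfeasibleBasisError(
            f"could not assemble {r} independent nonnegative pathways "
            f"(reached rank {rank})")

    T = np.column_stack(chosen)
    W = np.vstack([T, scaled @ T])
    W[np.abs(W) < 1e-12] = 0.0
    if W.min() < -tol:
        rows, cols = np.where(W < -tol)
        raise InfeasibleBasisError(
            f"negative entries remain in W at rows {sorted(set(rows.tolist()))}, "
            f"columns {sorted(set(cols.tolist()))}",
            offending=sorted(set(cols.tolist())))
    W = np.clip(W, 0.0, None)

    W = _normalize_columns(W)
    basis = _finalize(W, S, provenance="constructed")

    # contract checks
    resid = np.abs(S.matrix @ basis.W).max()
    scale = max(1.0, np.abs(basis.W).max())
    if resid > tol * scale * 10:
        raise InfeasibleBasisError(f"null-space residual {resid:.2e} too large")
    for g_col in range(r):
        proj, *_ = np.linalg.lstsq(basis.W, G[:, g_col], rcond=None)
        if np.linalg.norm(basis.W @ proj - G[:, g_col]) > 1e-6 * max(
                1.0, np.linalg.norm(G[:, g_col])):
            raise InfeasibleBasisError(
                "constructed basis does not span the null space")
    return basis


def _normalize_columns(W: np.ndarray) -> np.ndarray:
    """Scale each column by its first singleton-row entry (so c_j = R_i reads
    directly) or, for deficient columns, to unit maximum."""
    n, r = W.shape
    nz_per_row = (W > 0).sum(axis=1)
    W = W.copy()
    for j in range(r):
        rows = np.where((W[:, j] > 0) & (nz_per_row == 1))[0]
        scale = W[rows[0], j] if rows.size else W[:, j].max()
        if scale > 0:
            W[:, j] /= scale
    return W


def _finalize(W: np.ndarray, S: StoichiometricMatrix, provenance: str
              ) -> BasicPathwayBasis:
    sparsity, singles, _, deficient = _stats(W)
    return BasicPathwayBasis(W=W, reaction_index=list(S.reaction_index),
                             singleton_rows=singles, deficient_columns=deficient,
                             sparsity=sparsity, provenance=provenance)


# ---------------------------------------------------------------------------
# singleton structure
# ---------------------------------------------------------------------------

def _stats(W: np.ndarray):
    n, r = W.shape
    nz = W != 0
    sparsity = 1.0 - nz.sum() / W.size
    singles: dict[int, int] = {}
    for i in range(n):
        cols = np.where(nz[i])[0]
        if cols.size == 1:
            singles[i] = int(cols[0])
    covered = set(singles.values())
    deficient = [j for j in range(r) if j not in covered]
    return sparsity, singles, len(singles) / n if n else 0.0, deficient


def singleton_stats(W: np.ndarray) -> tuple[float, int, float, int]:
    """(sparsity, singleton row count, singleton row rank, deficient column count).

    A singleton row has exactly one nonzero; the singleton row rank is the
    fraction of rows that are singletons; a deficient column has no singleton
    element."""
    sparsity, singles, rank, deficient = _stats(np.asarray(W))
    return sparsity, len(singles), rank, len(deficient)


# ---------------------------------------------------------------------------
# weights and rates
# ---------------------------------------------------------------------------

def solve_weights(basis: BasicPathwayBasis, assignment: RateAssignment,
                  tol: float = NULLSPACE_TOL) -> np.ndarray:
    """Pathway weights C from r assigned independent rates.

    Columns with a singleton element in an independent row are read off
    directly (c_j = R_i / w_ij, using the lowest singleton row when several
    map to the same column); remaining weights come from the reduced linear
    system over the independent rows.  The residual of the full system
    restricted to the independent rows must stay below ``tol`` (relative), and
    all weights must be nonnegative (tiny negatives are clamped to zero).
    """
    rates = assignment.rates
    row_of = {rid: i for i, rid in enumerate(basis.reaction_index)}
    missing = [rid for rid in rates if rid not in row_of]
    if missing:
        raise ValidationError(f"assigned rates for unknown reactions {missing}")
    if len(rates) != basis.r:
        raise ValidationError(
            f"independent assignment must cover exactly r={basis.r} reactions, "
            f"got {len(rates)}")

    ind_rows = np.array([row_of[rid] for rid in rates])
    R_ind = np.array([rates[rid] for rid in rates])

    W = basis.W
    c = np.full(basis.r, np.nan)
    ind_set = set(ind_rows.tolist())
    for i in sorted(basis.singleton_rows):
        j = basis.singleton_rows[i]
        if i in ind_set and np.isnan(c[j]):
            c[j] = rates[basis.reaction_index[i]] / W[i, j]

    unknown = np.where(np.isnan(c))[0]
    known = np.where(~np.isnan(c))[0]
    if unknown.size:
        rhs = R_ind - W[np.ix_(ind_rows, known)] @ c[known]
        A = W[np.ix_(ind_rows, unknown)]
        if np.linalg.matrix_rank(A, tol=1e-9) < unknown.size:
            names = [f"BP{j + 1:02d}" for j in unknown]
            raise ValidationError(
                "independent set is insufficient to resolve columns "
                f"{names}: reduced system is under-determined")
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        c[unknown] = sol

    neg = np.where(c < -WEIGHT_CLAMP)[0]
    if neg.size:
        worst = neg[np.argmin(c[neg])]
        raise ValidationError(
            f"assignment is chemically infeasible: pathway column {worst} "
            f"requires negative weight {c[worst]:.3e}")
    c = np.clip(c, 0.0, None)

    resid = np.linalg.norm(W[ind_rows] @ c - R_ind)
    scale = max(1.0, np.linalg.norm(R_ind))
    if resid > tol * scale:
        raise ValidationError(
            f"assigned independent rates are inconsistent with the null space "
            f"(residual {resid:.3e})")
    return c


def compose_rates(basis: BasicPathwayBasis, C_BP: np.ndarray) -> np.ndarray:
    """R_cell = W·C; nonnegative by construction."""
    C_BP = np.asarray(C_BP, dtype=float)
    if C_BP.shape != (basis.r,):
        raise ValidationError(f"C_BP must have length r={basis.r}")
    if np.any(C_BP < 0):
        raise ValidationError("pathway weights must be nonnegative")
    return basis.W @ C_BP


def decompose_rates(basis: BasicPathwayBasis, R: np.ndarray
                    ) -> tuple[np.ndarray, float]:
    """Least-squares weights for a rate vector, with the residual norm.

    Exact (residual < tol) when R lies in span(W); the residual conveys
    infeasibility otherwise."""
    R = np.asarray(R, dtype=float)
    # equilibrate columns: pathway norms span orders of magnitude and would
    # otherwise dominate the least-squares conditioning
    norms = np.linalg.norm(basis.W, axis=0)
    norms[norms == 0] = 1.0
    Ws = basis.W / norms
    y, *_ = np.linalg.lstsq(Ws, R, rcond=None)
    # one step of iterative refinement sharpens consistent systems
    dy, *_ = np.linalg.lstsq(Ws, R - Ws @ y, rcond=None)
    c = (y + dy) / norms
    c[np.abs(c) < WEIGHT_CLAMP] = 0.0
    resid = float(np.linalg.norm(basis.W @ c - R))
    return c, resid


# ---------------------------------------------------------------------------
# interpretation
# ---------------------------------------------------------------------------

@dataclass
class PathwayReport:
    column: int
    nutrients_consumed: list[str]
    destinations: list[str]
    intermediates_diluted: list[str]
    active_reactions: list[str]
    cyclic: bool

    def to_dict(self) -> dict:
        return {
            "column": self.column,
            "nutrients_consumed": self.nutrients_consumed,
            "destinations": self.destinations,
            "intermediates_diluted": self.intermediates_diluted,
            "active_reactions": self.active_reactions,
            "cyclic": self.cyclic,
        }


def classify_pathway(w: np.ndarray, network: ReactionNetwork,
                     reaction_index: list[str], column: int = -1,
                     tol: float = 1e-9) -> PathwayReport:
    """Interpret one basic pathway chemically.

    Destinations are components whose dilution reaction carries flux and that
    no active non-dilution reaction consumes (wastes count as co-diluted
    intermediates instead); nutrients consumed are the boundary reactants of
    active import reactions.  A pathway with neither nutrient consumption nor
    dilution is cyclic."""
    cmap = network.component_map
    active = {reaction_index[i] for i in np.where(np.abs(w) > tol)[0]}
    consumed: set[str] = set()
    nutrients: set[str] = set()
    diluted: set[str] = set()
    for rxn in network.reactions:
        if rxn.id not in active:
            continue
        if rxn.is_dilution:
            diluted.add(rxn.reactants[0][0])
            continue
        for name, _ in rxn.reactants:
            if cmap[name].role == "nutrient":
                nutrients.add(name)
            else:
                consumed.add(name)
    destinations = sorted(d for d in diluted
                          if d not in consumed and cmap[d].role != "waste")
    co_diluted = sorted(d for d in diluted if d not in destinations)
    return PathwayReport(
        column=column,
        nutrients_consumed=sorted(nutrients),
        destinations=destinations,
        intermediates_diluted=co_diluted,
        active_reactions=sorted(active),
        cyclic=not nutrients and not diluted,
    )


# ---------------------------------------------------------------------------
# independent-set selection and steady-state assembly
# ---------------------------------------------------------------------------

def select_independent_set(basis: BasicPathwayBasis, network: ReactionNetwork,
                           zero_set: set[str] = frozenset(),
                           preferred_extra: list[str] | None = None) -> list[str]:
    """Choose r reactions whose rates determine all weights.

    Mirrors the modeling convention of preferring dilution reactions (their
    rates follow from the growth rate and measured concentrations), skipping
    any rendered dependent by the null-space structure, then zero-set
    reactions, then any caller-preferred reactions, then the rest — greedily
    keeping the restricted rows of W full rank."""
    dil_ids = [rxn.id for rxn in network.dilution_reactions]
    rest = [rid for rid in basis.reaction_index if rid not in set(dil_ids)]
    preferred_extra = preferred_extra or []
    order = (dil_ids
             + [rid for rid in rest if rid in zero_set]
             + [rid for rid in preferred_extra
                if rid in rest and rid not in zero_set]
             + [rid for rid in rest
                if rid not in zero_set and rid not in set(preferred_extra)])
    row_of = {rid: i for i, rid in enumerate(basis.reaction_index)}
    chosen: list[str] = []
    rows: list[np.ndarray] = []
    rank = 0
    for rid in order:
        if len(chosen) == basis.r:
            break
        trial = rows + [basis.W[row_of[rid]]]
        new_rank = np.linalg.matrix_rank(np.array(trial), tol=1e-9)
        if new_rank > rank:
            chosen.append(rid)
            rows = trial
            rank = new_rank
    if len(chosen) < basis.r:
        raise ValidationError(
            f"could not find {basis.r} independent reactions (got {len(chosen)})")
    return chosen


def build_steady_state(network: ReactionNetwork, basis: BasicPathwayBasis,
                       assignment: RateAssignment,
                       U_ss_input: dict[str, float]) -> SteadyState:
    """Solve weights, compose the full rate vector and attach concentrations.

    For consistency, dilution rates in the assignment must equal
    alpha_cell * cellular concentration / f_c (the cytosol-referenced dilution
    rate) for the concentrations in ``U_ss_input``."""
    from .stoichiometry import build_smatrix

    C = solve_weights(basis, assignment)
    R = compose_rates(basis, C)
    if np.any(R < -WEIGHT_CLAMP):
        raise ValidationError("composed rates contain negative entries")
    R = np.clip(R, 0.0, None)
    S = build_smatrix(network)
    resid = float(np.abs(S.matrix @ R).max())
    scale = max(1.0, float(np.abs(R).max()))
    if resid > NULLSPACE_TOL * scale * 10:
        raise ValidationError(
            f"composed steady state violates S·R = 0 (residual {resid:.3e})")
    return SteadyState(R_cell=R, C_BP=C, U_ss=dict(U_ss_input),
                       reaction_index=list(basis.reaction_index),
                       residual=resid)


def dilution_rate_assignment(network: ReactionNetwork,
                             extra: dict[str, float] | None = None,
                             zero_set: set[str] = frozenset(),
                             basis: BasicPathwayBasis | None = None
                             ) -> RateAssignment:
    """Assignment built from steady-state concentrations: each selected
    dilution reaction gets alpha_cell * [C]_cellular / f_c; non-dilution
    independents come from ``extra`` (or zero for the zero set)."""
    if basis is None:
        raise ValidationError("basis required to select the independent set")
    extra = extra or {}
    chosen = select_independent_set(basis, network, zero_set=set(zero_set),
                                    preferred_extra=sorted(extra))
    alpha = network.morphology.alpha_cell
    f_c = network.morphology.fraction("c")
    dil_rate = {}
    for rxn in network.dilution_reactions:
        comp = network.component_map[rxn.reactants[0][0]]
        dil_rate[rxn.id] = alpha * comp.ss_cellular_concentration / f_c
    independent: dict[str, float] = {}
    for rid in chosen:
        if rid in dil_rate:
            independent[rid] = dil_rate[rid]
        elif rid in zero_set:
            independent[rid] = 0.0
        elif rid in extra:
            independent[rid] = extra[rid]
        else:
            raise ValidationError(
                f"independent reaction {rid} has no assigned rate; supply it "
                "via the steady-rate table")
    return RateAssignment(independent=independent, zero_set=frozenset(zero_set))
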