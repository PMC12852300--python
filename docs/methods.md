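# Methods

This note records the model conventions, numerical choices and design
decisions behind `ironcell`, and what the shipped reduced model and the
synthetic-network generator do and do not capture.

## Units and frames

Concentrations are µM, time is minutes, volumes are liters, throughout;
conversions happen only at I/O boundaries. Two concentration frames exist:
*cellular* (moles per cell volume) and *local* (moles per compartment volume),
related by `[local] = [cellular]/f_i` for fractional compartment volume
`f_i`. The ODE state is the vector of local concentrations; the paper-style
single rate frame is obtained by referencing every reaction rate to the
cytosol, so the stoichiometric entry for a component in compartment *k* is
the molar coefficient times `f_c/f_k`. Only volume *ratios* enter the matrix;
scaling the whole cell leaves it unchanged.

## Element bookkeeping

Components are chemically defined in iron and carbon only. Iron is carried by
six center kinds (heme `FH`, mononuclear `FO`, di-iron `FF`, `[Fe2S2]` `F2`,
`[Fe3S4]` `F3`, `[Fe4S4]` `F4`, holding 1, 1, 2, 2, 3, 4 Fe). Center counts
are fractional because protein-group coefficients are concentration-weighted
averages over members. Every non-dilution reaction must balance Fe and C to
within 1e-4 atoms per event — loose enough for coefficients printed to 6–7
significant figures, tight enough to catch real bookkeeping errors. Catalysts
never enter stoichiometry or balance; they only appear in rate laws.
Dilution pseudo-reactions (`C → ∅` at `α·[C]_local`) deliberately break
conservation: matter leaves the ledger as the population grows.

## Growth dilution and the (S₀ | −D) structure

Each non-nutrient component gets exactly one dilution reaction
(auto-generated as `D<name>` when absent). Dilution columns sit after all
chemical reactions, in component order, so the matrix is `(S₀ | −D)` with
`D = diag(f_c/f_k) > 0` without any permutation bookkeeping. The dilution
*rate* is cytosol-referenced (`α·[C]_local·f_k/f_c`), so the matrix entry
`−f_c/f_k` reproduces `d[C]_local/dt = −α·[C]_local` exactly; this is the
self-consistent reading of the cytosol-referencing convention and reproduces
volume-scaled ODE coefficients such as −6.43 on a mitochondrial component's
dilution term when `f_c/f_m = 6.43`.

## Nonnegative basis construction

The null space of `(S₀ | −D)` is parameterized by the non-dilution
coordinates `u`: the null vector is `[u ; D⁻¹S₀u]` and it is chemically
feasible iff `u ≥ 0` and `S₀u ≥ 0` — the reduced flux cone. Construction of
the nonnegative basis `W` proceeds in that r-dimensional cone:

1. Columns of the algebraic basis `G = [I_r ; D⁻¹S₀]` that are already
   nonnegative are kept as candidates.
2. For every other reaction *j*, a minimal-total-flux pathway through *j*
   (`min Σu` s.t. `u ≥ 0`, `S₀u ≥ 0`, `u_j = 1`) is found by LP. This is the
   "cancel negative entries by adding positive multiples of other columns"
   operation in closed form, and it lands on sparse, chemically readable
   pathways (LP vertices are extreme-ray-like).
3. Candidates are admitted greedily by rank. Rigidly coupled reactions can
   produce duplicate minimal pathways; any rank deficit is repaired with
   perturbed interior-point columns `u* + ε·e_j`, where `u*` is a
   Chebyshev-style interior point of the cone (`max t` s.t. `u ≥ t`,
   `S₀u ≥ t`, `Σu = 1`). These columns are always feasible and the family
   spans `R^r`, so completion cannot fail while the cone has interior — and
   an empty interior means no strictly positive steady state exists, which is
   reported as such.
4. When a reference rate vector is supplied (the wild-type state), it is
   first decomposed *exactly* over the cone by iterative peeling: repeatedly
   subtract the largest feasible multiple of a support-restricted minimal
   pathway, which zeroes at least one active coordinate per step and
   terminates in at most `n + m` steps; the support is then pruned to linear
   independence (Carathéodory reduction) and locked into the basis. Because a
   basis gives unique coordinates, this guarantees the reference vector's
   weights are nonnegative — a property that does *not* follow from `W ≥ 0`
   alone.

Columns are scaled so the first singleton-row entry is 1 (weights then read
directly off rates); singleton-deficient columns are scaled to unit maximum.
A small double-description enumerator of extreme rays is provided for
analysis of small systems and is cross-checked in the tests against an
independent brute-force vertex enumeration.

One structural fact worth stating: a nonnegative *basis* has exactly `r`
columns, while the flux cone may have more than `r` extreme rays. `cone(W)`
therefore equals the full feasible cone only when the cone is simplicial;
in general some feasible rate vectors have negative coordinates in any basis.
The oracle tests assert exactly this: containment always, equality when
simplicial.

## Independent rates and weights

The weight solver consumes exactly `r` independent rates. The default
selection mirrors experimental practice: dilution reactions first (their
rates are `α` times a measurable concentration), skipping any made dependent
by the null-space structure (e.g. a waste product whose only consumer is its
own dilution), then reactions pinned to zero, then caller-supplied rates —
greedily keeping the corresponding rows of `W` full rank. Weights for
singleton-covered columns are read off directly; the rest come from the
reduced linear system. Weights in `[−1e-10, 0)` are clamped to zero; anything
more negative is reported as chemical infeasibility, naming the column.
Null-space residual tolerances are 1e-8 (relative).

## Rate-law rules and calibration

Per-reaction kinds: `michaelis_menten` (saturating term per substrate with
`K_M` equal to the wild-type *local* concentration — rate laws operate in the
local frame — times normalized first-order catalyst factors),
`mass_action` (normalized first order per substrate), `transport_ratio`
(`k([donor]/[receiver] − 1)`; may run backwards dynamically, there is no
clamp), and `dilution`. Calibration inverts the law at the wild-type state:
`k = R_ss / law(U_ss; k=1)`; with `s` substrates each MM term is 1/2 there,
so `k = R_ss·2^s`. Reactions with `R_ss = 0` calibrate to `k = 0` and are
inert; reactivating one requires an explicit `k` override. Transport with a
unit wild-type concentration ratio cannot be calibrated against a nonzero
rate and raises a named error; the fixture's steady-state construction
enforces a ≥1.1 donor/receiver gradient to avoid the degenerate regime.

Regulation multiplies a law by `lf(2 − [C](t)/[C]_ss)` per sensed component,
with `lf(x) = 2/(1+e^{−5(x−1)})` (steepness 5 by default; the exponent is
clipped at ±700 to avoid overflow). The factor is exactly 1 at the reference
state, so regulated and unregulated systems have identical right-hand sides
there and calibration is unaffected. Regulation multiplies the evaluated rate
only; it never enters the calibration step (the conventions coincide at the
reference and the multiplicative-on-rate reading is used mid-trajectory).

## Integration and outcome classification

LSODA with `rtol = 1e-8`, `atol = 1e-10` µM by default — tight because
roundoff-induced departure from unstable steady states is a phenomenon of
interest, not a bug. An explicit initial step is passed when (re)starting a
segment: LSODA's automatic initial-step heuristic can collapse to micro-steps
when resuming from a near-equilibrium state. Step perturbations split the
horizon into segments (concentration steps edit the state; nutrient and
rate-constant steps swap in a modified model). Negative excursions smaller
than 100×atol are clamped to zero and counted; larger ones, and non-finite
states, abort as solver failure.

Outcomes: *blowup* when any normalized concentration exceeds 1e3 (config) or
integration collapses; *at reference* when the tail (last 20% of the
horizon) stays within 1e-3 of `U_ss`; *oscillation* when the dominant tail
component shows relative amplitude > 1e-3 with alternating derivative and a
stable autocorrelation period; *new steady state* when the finite-difference
tail derivative falls below 1e-6 of the dilution scale. Finite differences
on the sampled tail are used rather than the instantaneous right-hand side,
which is polluted by fast stiff modes at interpolated states.

## The reduced iron-metabolism model

The fixture is a scaled-down, self-consistent cell, not a reproduction of
the full published 80-component model. Fractional volumes are
`c 0.643, m 0.100, v 0.181, n 0.0495, e 0.0265` (chosen so `f_c/f_m = 6.43`),
`V_cell = 42 fL`, `α = 0.003333 /min`. The iron-trafficking core uses
literature-derived fractional stoichiometries (e.g. 7.59143 labile Fe per
loaded scaffold, 0.9416092 donors per `[Fe4S4]` coupling); holo-protein iron
profiles are *derived* from the transferred payloads so cluster-transfer
reactions balance exactly by construction. Closure reactions needed to make
the reduced network autotrophic from three nutrients (IRON, CARBON, OXYGEN)
— e.g. NAD/ADP biosynthesis, ROS degradation, CO₂ venting to a boundary
pool, cofactor transports — are marked `invented: true`, and tests never
assert on their coefficients. Apo scaffolds are iron-free in this reduced
model (permanent-center installation chains are omitted); single-form
catalytic groups (ETC, MEM, MRS, CCC, FT3, FT5, LEU, NUC, TCA, RIB) are
iron-free for the same reason. Two reactions are pinned to zero rate under
healthy iron-replete growth: vacuolar iron export (ACFT5) and the
iron-regulon unmetallation back-reaction (UAFT).

The wild-type steady state is constructed once, deterministically, by linear
programming: minimize total flux subject to `S₀R ≥ 0` componentwise within
concentration bands (net production equals `α·U_local`, so bands on local
concentrations are linear constraints on fluxes), a ≥1.1 wild-type gradient
for every ratio transport, a 1e-6 µM/min floor on every non-zero-set
reaction (strict positivity), and zero bounds on the zero set. Concentrations
then follow from `U_local = (S₀R)/α`. The bands are design choices (pools
and metabolites at µM-to-mM scale, proteins at 0.02–5 µM local) made once
for plausibility; they are inputs to the construction, not fitted values.

Regulation of the fixture follows the published strategy of damping
biosynthesis reactions with logistic factors: the electron-transport chain,
the vacuolar exporter and the glutaredoxin pool are autoregulated, and the
mitochondrial iron importer's biosynthesis is doubly regulated by the
mitochondrial labile pool and free cytosolic heme. A transcriptional rule on
the iron-regulon biosynthesis (sensing the cytosolic labile pool) is
deliberately omitted: the regulon has no catalytic clients in this reduced
network, so the rule would add feedback with no stabilizing function — and
measurably destabilizes the state (the leading Jacobian eigenvalue crosses
zero). With the chosen set the reference state is locally stable (leading
eigenvalue ≈ −9e-4 /min) and ±50% steps in the cytosolic labile pool recover
to the reference in about 1000 min. Recovery timescales are governed by the
slow growth-dilution modes (~1/α) and are biologically long, because the
model has no degradation channels faster than dilution.

## Synthetic networks

The generator emulates the structural features the engine relies on —
boundary nutrients, branched conversion chains over several compartments,
full `(S₀ | −D)` structure, exact single-element balance with fractional
coefficients, and a strictly positive steady state — by sampling chain
topologies and propagating fluxes so that every component sheds a positive
remainder to dilution (`U_local = net/α > 0`). The same seed reproduces the
network byte-for-byte. It does not emulate: shared cofactor pools, catalytic
feedback loops between chains, multi-substrate reactions, or regulation.
Passing tests on synthetic networks therefore demonstrate the linear-algebra
and calibration machinery at scale, not dynamical stability phenomena —
those are exercised on the fixture and hand-built toys.

## Known limitations

* Reversible reactions are out of scope; the flux cone lives in the
  nonnegative orthant.
* The basis-construction LP route needs the cone to have nonempty interior
  (equivalently, a strictly positive steady state); networks with dead
  reactions are reported, not silently truncated.
* Iron totals of the reduced model (~32 µM) are an order of magnitude below
  a real iron-replete cell, since the reduced model carries far fewer
  iron-protein groups at lower concentration bands.
* The full published 80×169 model is supported as *input* (plain-CSV exports
  of its S/W documents are loaded and validated structurally) but is not
  re-derived; its printed summary statistics are not reproducible from this
  package alone.
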