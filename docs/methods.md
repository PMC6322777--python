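# Methods

This note documents the models implemented in `stoichnet`, the defaults and
units, the numerical choices, and what the synthetic-data generator does and
does not emulate.

## Networks, units and conventions

A web is a set of compartments (producers, consumers, detritus pools, one
dissolved-inorganic nutrient pool) with, per chemical element *k* ∈ {C, N, P},
biomass stocks `B_ik` (g element m⁻² ), an internodal flow matrix `T_ijk`
(g element m⁻² y⁻¹, donor row → recipient column, diagonal allowed for
cannibalism) and boundary imports `z`, exports `e` and respirations `r`.
Networks are annualised steady states; there is no spatial or temporal
structure.

All user-facing stoichiometric ratios are **molar** C:N and C:P; they are
converted once, at the module boundary, to mass ratios via the atomic masses
12.011, 14.007 and 30.974 g mol⁻¹. Everything internal runs on a single mass
basis, so "C:N" below always means the mass ratio unless stated otherwise.

Respiration is a carbon-specific loss. Non-carbon networks carry `r = 0`; the
N and P analogues of respiration (excretion of surplus nutrient) are
represented as boundary exports. Consequently, when the N/P networks are
derived from carbon, the carbon `e + r` of a node maps to a derived export
`(e + r)/ρ` with ρ the node's own mass ratio — this preserves the identity
that a uniformly-ratioed web stays balanced under derivation.

A node is *balanced* when `|inflow − outflow| / max(inflow, outflow)` is below
tolerance; the default tolerance is 1e-3 because the layered balancing
procedure converges approximately, not exactly. Convergence is judged on this
relative measure because the three element networks differ by orders of
magnitude.

## Ecopath-style mass balance

For each living group the master equation
`B·PB·EE = predation + catches + accumulation` holds with at most one unknown
among {B, PB, QB, EE}. EE and PB unknowns are local once predator biomasses
are known; unknown biomasses are coupled through predation and are solved as
one linear system (the master equation is linear in B with PB, QB, EE fixed).
QB cannot be recovered from the master equation alone; an optional gross
efficiency GE = P/Q (the EwE convention) supplies `QB = PB/GE`, otherwise a
missing QB is an error. The unassimilated fraction defaults to U = 0.2 for
consumers; biomass accumulation defaults to zero (steady state).

Flows are constructed so every living node closes *exactly*: consumption
`T_ij = B_j·QB_j·DC_ij`, diet-import fractions as boundary imports,
respiration as the consumption residual (negative residuals are an error
naming the group), and detritus flows as egesta plus the *residual*
non-utilised production `max(0, P − predation − Y − BA)` apportioned by the
detritus-fate fractions. The residual form equals `(1 − EE)·P` whenever the
given EE is consistent with realised predation, and keeps the network closed
when it is not; realised EE > 1 is reported per group rather than raised, so
diagnosing an over-grazed web remains possible. Detritus pools close at the
boundary (surplus → export, deficit → import). Primary production enters
producers as a boundary-import placeholder that the inorganic-pool step
replaces.

## Inorganic pool and N/P derivation

Ecopath-style models do not represent dissolved inorganic uptake, so a DIC
pool is appended afterwards: each producer receives a pool→producer flow equal
to its outflow deficit (clipped at zero with a warning), and the pool itself
closes at the boundary. The pool stock is conventionally inferred from a DIN
stock at a molar DIC:DIN ratio of 8.2; the pool's molar C:P defaults to
131.2 (= 8.2 × a Redfield N:P of 16). An option reroutes a fraction of system
respiration into the pool as remineralisation; the default keeps respiration
at the boundary.

Derived networks follow donor stoichiometry exactly at derivation time:
`T_ijk = T_ijC / ρ_ik` with ρ the *donor's* ratio; boundary imports use the
recipient's ratio (the recipient pool is the donor of record for everything
downstream). The derived network is flagged unbalanced whenever consumer diet
stoichiometry differs from consumer body stoichiometry — that imbalance *is*
the stoichiometric signal the rest of the analysis reads.

## Layered balancing

Flows are grouped in layers by order of magnitude (`layer = floor(log10 f)`,
exact powers open a new layer; zero flows are never adjusted) and repaired
iteratively, nodes in fixed index order, damped by 0.5 per sweep, until the
worst relative imbalance is below tolerance. The literature on layered
balancing leaves the per-layer operator open, so it is isolated behind
`BalancerConfig`:

* **export-only** (default): a node's element surplus becomes a boundary
  export (the excretion analogue of carbon respiration); a deficit shrinks the
  node's outflows proportionally — a node limited in an element passes less of
  it on, letting scarcity propagate downstream. Measured imports stay intact.
  This is the configuration under which the ascendency-based limitation
  classification coincides with the classical Liebig test.
* **import-export**: both signs absorb at the boundary (deficit → import).
  Internodal flows are never touched, so the donor-stoichiometry identity
  survives balancing exactly (zero drift). The cost: importing the deficit
  erases the distinction between a well-supplied and a limited node, so this
  mode is for users who must preserve flow stoichiometry, not for limitation
  analysis.
* **frozen boundary** (`adjustable_boundary=False`): for webs whose measured
  boundary flows may not move; the over-supplied side of a node is
  scaled down (or the starved side up, when the large side is frozen) within
  the current layer only, sweeping layers from largest magnitude to smallest.
  Flows that cross a layer boundary are re-assigned at the next outer
  iteration, keeping "other layers constant" literal within a sweep.

Every mode is deterministic, preserves non-negativity, and records a
convergence trace (worst node and imbalance per outer iteration, monotone
non-increasing: a sweep that would overshoot is reverted and replayed at half
the step). Non-convergence within `max_outer_iterations` (default 500) and an
imbalanced node without adjustable flows are errors naming the node. On
derived N/P webs of the default generator the export-only mode converges in
30–40 outer iterations to tolerance 1e-6.

## System indices

* **TSTf** — sum of all nodal inflows including boundary flows; computed in
  both the import form (ΣT + Σz) and export form (ΣT + Σe + Σr) and compared;
  conservation makes them equal on a balanced network.
* **FCI** — fractional inflow matrix `g_ij = T_ij/T_j` with `T_j` the nodal
  throughflow, integral matrix `N = (I − G)⁻¹`, cycled throughflow
  `Σ T_i (N_ii − 1)/N_ii`, divided by TSTf. The published compact formula for
  this index omits the TSTf divisor its surrounding text requires ("fraction
  of throughput recycled"); the normalised form is implemented, so FCI ∈ [0, 1)
  and is exactly 0 on acyclic webs.
* **Trophic levels** — producers, detritus and nutrient pools sit at TL 1;
  consumers at 1 + the consumption-weighted mean TL of their diet, solved as a
  linear system. Diet imports enter at TL 1 (an outside producer-equivalent
  source); entering them at consumer-specific levels would require data that
  do not exist at this stage.
* **Transfer efficiencies** — canonical trophic aggregation: each node's
  activity is apportioned to integer levels by path-length expansion of its
  diet (cannibalistic loops decay geometrically; expansion stops at an
  unassigned residual < 1e-12 and the sub-1e-9 remainder is renormalised).
  `TE_m` is the predatory flow passed from level *m* to *m+1* over the total
  input to level *m*; detrital returns route back to level 1 and do not count
  as passed on. Efficiencies above 1 are possible only for degenerate webs and
  are flagged, not raised.

## Biomass-inclusive ascendency and limitation

`A_B = Σ T_ijk log₂(T_ijk B..²/(T… B_ik B_jk))` over internodal flows, with
`B..` the all-element biomass total and `T…` the total internodal flow of all
elements. Defining `T…` over internodal flows (rather than including boundary
flows) is what makes the published sensitivity expressions the *exact*
gradients of A_B — with boundary flows inside `T…`, the flow gradient picks up
a spurious constant and the finite-difference identity fails. Logarithms are
base 2 (bits); the limiting-element argmax is base-invariant. Summing grams of
C, N and P is dimensionally heterogeneous but is what the biomass-inclusive
formulation prescribes; the per-element decomposition of A_B is also reported.

Node sensitivities `∂A_B/∂B_pk = 2[T…/B.. − (T_.pk + T_p.k)/(2B_pk)]` (per
ln 2 in bits) are computed in two modes. With internodal flow sums they are
the exact gradient, and the test suite and acceptance script verify them — and
the flow gradients — against central finite differences of A_B to < 1e-6
relative on dozens of random webs. (The finite differences are evaluated by
exact regrouping of the summand differences via `log1p` in extended precision;
a naive difference of two ~1e5-magnitude sums loses ten digits to cancellation
and would test the arithmetic, not the gradient.) With boundary flows included
(the default for classification) the sensitivity reads as the contrast between
the system's turnover rate and the node's element turnover rate — negative for
fast-turnover nodes — and at mass balance (inflow = outflow per node) its
argmax over elements coincides *exactly* with the classical Liebig test
`argmin_k supply_k/B_pk`. That identity is the reason the two limitation
routes agree; it holds in the limit of exact balance, so the
equivalence-asserting tests balance at tolerance 1e-6 to keep residual
imbalance far below the classification's resolution.

Co-limitation: elements whose turnover rate lies within 5% (relative) of the
minimum are reported as co-limiting. The published account notes only
"similar sensitivity values"; 5% is this package's threshold, applied to
turnover rates rather than to the sensitivities themselves because the latter
cross zero (relative closeness is ill-defined there) while their order is the
exact reverse of the turnover order. Ties are labelled deterministically in
the order C < N < P. Nutrient pools are excluded (they have no nutrient
demand), as are nodes lacking positive biomass in any element.

Flow sensitivities are ranked over positive internodal flows only (zero flows
have no defined gradient; boundary flows are not ranked). The element of the
top-ranked flow is the network's limiting element of flows.

## The synthetic-data generator

`SyntheticWebConfig` emulates a ~25-node subtropical shelf web: 2 producers, a
consumer ladder split evenly across microbial, zooplankton, zoobenthos and
fish guilds (20 consumers by default), 3 detritus pools (suspended POM,
sediment POM, DOM), and the DIC pool appended downstream. Trophic ordering is
enforced by guild with limited omnivory; within the fish guild predation runs
from higher to lower index, so all cycles run through detritus (detritivory by
the microbial, zooplankton and zoobenthos guilds; switching it off yields
provably acyclic webs for the FCI = 0 fixtures). Link realisation follows a
connectance of 0.35 over permitted prey, with Dirichlet diet proportions.

Defaults: biomass log-uniform on 0.05–10 gC m⁻² (detritus ×5); P/B gradients
per guild (producers 80–400 y⁻¹ down to fish 0.3–3 y⁻¹, following the
turnover-declines-with-size rule); QB = PB/GE with GE uniform on 0.15–0.30;
U = 0.2; molar C:N 5–12 and C:P 40–250 for living nodes (bracketing Redfield),
wider for detritus (C:N 8–20, C:P 80–500); DIN stock 0.1–2 gN m⁻² for the DIC
pool. Feasibility is guaranteed by construction: processing predators before
prey, any prey whose predation demand exceeds a capped fraction (≤ 0.85) of
its production has its biomass raised to meet it, so the Ecopath solve always
succeeds with EE < 0.9 for every group. Seconds per year are fixed at
3.1536e7 for flow-rate conversion.

**Planted limitation** is causal, not labelled: the target consumer's upstream
closure is set stoichiometrically neutral (all ratios anchored to the
inorganic pool's 8.2 / 131.2, so balancing leaves upstream flow stoichiometry
alone), then the direct diet is made three-fold poor — and the target's body
three-fold rich — in the planted element only. The resulting supply-turnover
margin is ≥ ~3× against the co-limiting 5% band, and the classifier must
recover the element from the balanced flows. Planting several nodes whose
upstream closures overlap lets the later assignment win; recovery is
guaranteed per planted node only when direct diets do not overlap.

**River forcing**: a `RiverScenario` (flow as m³ s⁻¹ or L y⁻¹; sediment as
concentration or annual yield; DOC, DIN, DIP concentrations; POC fraction of
TSS, default 8.4%; plume area) yields per-element POM/DOM/DIM import fluxes in
g m⁻² y⁻¹ — a pure function, linear in flow and concentrations. In a forced
web the POM and DOM pools take these as boundary imports and inherit the river
material's stoichiometry. Note the published import table this module's
defaults echo prints values ~10³ above what its own inputs reproduce
(4.28 g L⁻¹ × 429 m³ s⁻¹ over 561 km² gives ≈ 8.7e3, not 8.7e6 g m⁻² y⁻¹);
the closed-form arithmetic is used throughout and the analysis script reports
the factor instead of absorbing it. The DIC:DIN ratio of 8.2 is treated as
molar and mass-converted like every other ratio, although the printed DIM
rows suggest the original table multiplied mass values directly; one
convention is applied uniformly.

**What passing tests do and do not show.** The generator produces balanced,
guild-ordered, stoichiometrically plausible webs — it does not emulate
seasonal forcing, ontogenetic diet shifts, isotope-constrained diets, or the
specific biomass structure of any real shelf system. Tests passing on these
webs demonstrate the *mathematical* properties of the pipeline (conservation,
gradient exactness, Liebig equivalence, recovery of causally planted signals);
they do not certify that any particular real ecosystem is P-limited.

## Problem sizes and runtimes

The test suite runs ~130 tests in under 15 s; the acceptance script uses 50
random 8–30-node webs for the gradient identity, 100 webs for the Liebig
equivalence, 100 planted webs for recovery, and one 26-node reference web for
the index block — about 10 s in total. These sizes match the study scale (a
~28-compartment shelf web) rather than stress-testing scalability; all
operations are dense-matrix and comfortably handle a few hundred nodes.

## Known limitations

* The balancer's repair operators are this package's constructions; published
  accounts of layered balancing do not specify the adjustment rule, and
  alternatives (e.g. linear inverse modelling) are deliberately out of scope.
* Diet imports contribute at TL 1, a convention, not a measurement.
* EE > 1 diagnostics are reported but diets are never auto-edited; iterative
  rebalancing of diet compositions is a modeller's loop, not an algorithm here.
* Limitation analysis reads boundary-inclusive turnover; on *unbalanced*
  networks the sensitivity route and the classical supply route legitimately
  diverge (one sees drains, the other does not), and the package exposes both
  rather than hiding the difference.
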