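# Methods

This note documents the models and procedures implemented in `mtow`, the
choices made where the design was genuinely open, and what the synthetic
fixtures do and do not demonstrate.

## Model and conventions

A network is a stoichiometric matrix S (n metabolites × m reactions) with
per-reaction reversibility, flux bounds, and — for the subset R_G — a
standard reaction Gibbs energy ΔG′⁰ with a standard error.  Exchange
reactions carry stoichiometry on a single boundary metabolite; they open
the system and are exempt from thermodynamic constraints (R_G contains only
internal reactions: transport energetics are not modelled, and which
transporters should be constrained in a genome-scale model is genuinely
ambiguous — the exemption is therefore a configuration-level convention,
not a claim).

Units: concentrations are mM throughout; log-concentration variables are
natural logs of the value in mM, so ΔG′⁰ is referenced to a 1 mM standard
state and ΔG′ = ΔG′⁰ + RT·(S′ⱼ·ln c).  All energies are kJ/mol.  The gas
constant is configurable so that the rounded convention RT = 2.5 kJ/mol can
be reproduced exactly (the default is R = 8.314×10⁻³ kJ/mol/K, RT ≈ 2.479
at 298.15 K).

Key parameters, defaults and meaning:

| parameter | default | meaning |
|---|---|---|
| c_L | 10⁻⁵ mM | global concentration floor (≈ one molecule per bacterial cell) |
| c_U | 100 mM | global ceiling (above any measured bacterial metabolite) |
| α | 4 | dimensionless driving force beyond which extra force saves no enzyme (≈ 10 kJ/mol) |
| β | 0.02 | minimal driving force for a flux-carrying reaction (≈ 0.05 kJ/mol) |
| w⁺ | 1000 mmol/(gDW·h) | kinetic capacity bound per unit enzyme mass fraction |
| δ | swept | weight of enzyme cost against metabolite load |

Currency metabolites (ATP, ADP, AMP, NADH, NAD⁺, Pi) and medium-determined
extracellular species are pinned to given concentrations rather than
optimised; pins are equality constraints in log space and medium-level pins
take precedence over per-metabolite fixed values.

## Stage 1: feasibility MILP

The joint problem (fluxes and concentrations minimising load plus enzyme
cost under the second law) is non-convex, so it is approximated in two
stages.  Stage 1 finds, on the split-irreversible network, fluxes v ≥ 0
with S·v = 0 and medium constraints satisfied, such that shared log
concentrations within the box give every active reaction in R_G a driving
force of at least β after bounded corrections ε to the standard energies.
The objective is Σ|ε| (positive/negative splitting), so corrections are
spent only when the uncorrected energies admit no feasible pattern.

Encoding choices:

* **Correction bounds.**  |εⱼ| ≤ max(2·stderrⱼ, 2.9) kJ/mol by default —
  twice the estimate's standard error, floored at the typical accuracy of
  component-contribution estimates on measured reaction sets.  The bound is
  a single override parameter.
* **Indicators and big-M.**  A binary aⱼ per reaction (for R_G members and
  both halves of every split pair) with ubⱼ·aⱼ ≥ vⱼ ≥ 2·10⁻⁶·aⱼ, so aⱼ = 1
  exactly when the reaction carries non-negligible flux; the second-law row
  is relaxed by Mⱼ(1 − aⱼ) with Mⱼ computed per reaction as the exact
  worst case of the left-hand side over the concentration box (plus 1), the
  tightest valid constant.  Forward/reverse pairs satisfy a_f + a_r ≤ 1,
  which structurally excludes futile two-cycles.
* **Activity threshold.**  Fluxes below 10⁻⁶ mmol/(gDW·h) count as
  inactive and are thermodynamically unconstrained (a strict v > 0 is not
  representable in a MILP).
* **Determinism.**  A tie-break term 10⁻⁶·Σv steers the solver to sparse
  minimal-flux optima among correction-equivalent solutions; reported
  objectives exclude it.  The backend is HiGHS (`scipy.optimize.milp`),
  which is deterministic for a fixed build.
* **Measured fluxes and growth** enter as box constraints value ± tolerance
  on net fluxes (net = forward − reverse across split pairs).

Alternative optima are enumerated by integer cuts on the binary activity
pattern (Hamming distance ≥ 1 from all previous patterns) with the
correction objective capped near the optimum.  Every returned solution is
re-checked by an independent validator: mass-balance residual < 10⁻⁶, no
co-active split pair, and a feasibility LP certifying a concentration
witness for the active set.

## Stage 2: concentration QP

With fluxes fixed and the corrected energies from stage 1, minimise

  Σᵢ (ln(cᵢ/c_L))² + δ·Σⱼ∈active∩R_G Ẽⱼ,

where the piecewise enzyme surrogate Ẽⱼ — infinite below β, vⱼ(α − fⱼ)² on
[β, α], zero above α — is convexified exactly: the infinite branch becomes
the hard constraint fⱼ ≥ β, and the finite part is encoded with a slack
sⱼ ≥ max(0, α − fⱼ) contributing vⱼ·sⱼ².  At the boundary f = β the finite
branch applies (the floor is a closed constraint, so the boundary value
must be finite).  The load sum runs over all intracellular metabolites;
pinned ones contribute constants.  Metabolites untouched by any active
constrained reaction collapse to c_L and are flagged in the output.

The program is a diagonal convex QP with affine constraints.  It is solved
with `trust-constr` (interior point) started from a maximum-margin point
(Chebyshev-style LP), then **polished by an active-set refinement**: the
active set guessed at the interior-point solution is iterated with KKT
solves, adding violated constraints and dropping negative multipliers.
The polish removes the barrier bias (objectives accurate to ~10⁻¹² rather
than ~10⁻⁶), which is what makes the δ-monotonicity of the sweep hold to
tight tolerances.  A polished point is accepted only if it is feasible and
does not worsen the objective; otherwise the interior-point solution
stands.  Boundary round-off when re-evaluating driving forces is clamped
within 10⁻⁶ of the floor so solutions sitting exactly on f = β do not read
as infinite.

If the pinned concentrations contradict the stage-1 witness (no feasible
log concentrations for the active set), the solution is reported
infeasible rather than silently relaxed.

## Pareto sweep, selection, robustness

The δ grid is 25 geometric points on [10⁻⁴, 10⁴] plus the anchors δ = 0
(pure load) and δ = 10⁸ (pure-enzyme limit).  Dominated points are removed
(≤ on both axes, < on one, 10⁻⁹ tolerance; coincident points deduplicated)
and the front is ordered by load.  Fold-change normalisation to the
per-axis minimum (1 = the minimum) is reported for plotting; a zero
minimum is handled by an additive floor.

The compromise solution minimises the sum of min–max-normalised objectives
((x − min)/(max − min) per axis; a degenerate axis contributes 0).  Ties
break first towards the more balanced point (smaller worst-axis score),
then towards smaller load — on a symmetric three-point front this selects
the middle point, which is the intended "good in both" behaviour; a pure
load tie-break would arbitrarily favour one extreme.  Normalising by the
per-axis maximum instead is available as an option
(`normalization="max"`); min–max was chosen as the default because it is
invariant to rescaling either objective.

The robustness scan collects front points whose objectives both lie within
a fractional tolerance of the selected point and reports the mean log-log
Pearson correlation against reference concentrations (log₁₀,
pairwise-complete) and its drop relative to the selected point.

## Component-contribution Gibbs estimation

Reactions (signed vectors on a compound index) are decomposed orthogonally
against the span of the measured training reactions.  The in-span half is
priced by the least-squares formation-energy fit to the measured energies;
the orthogonal remainder by group contributions (fit to the same training
energies unless group energies are supplied).  Both halves collapse into a
single per-compound formation-energy vector h = P·g_rc + (I − P)·G·a, so
every estimate is the inner product r·h — linear in r — and first-law
consistency, additivity and antisymmetry hold by construction.  Categories:
I (in span, estimate independent of the group model), II (no span
component), III (both halves), undetermined (remainder touches a compound
with no group decomposition — such reactions simply drop out of R_G
downstream).  Span membership uses a relative residual tolerance of 10⁻⁸
with an SVD rank cutoff; standard errors propagate the residual variance of
each fit through the corresponding pseudoinverse (the training data carry
no replicate information, so this is a leverage-based approximation, not a
calibrated uncertainty).

The Legendre transform conditions species-level formation energies on pH
and ionic strength: each species gets +n_H·RT·ln(10)·pH and an extended
Debye–Hückel screening term on z² − n_H (2.91482·√I/(1 + 1.6√I) kJ/mol at
25 °C), and the compound value is −RT·ln Σ exp(−ΔfG′/RT) over its
pseudoisomers.  When every participant has species data the reaction energy
is recomposed from the transformed per-compound values; if any table is
missing the raw value passes through unchanged with a warning — no partial
transforms, since mixing transformed and untransformed formation energies
in one reaction would be inconsistent.  pKa-derived species tables are
inputs; the package does not compute pKa values.

Leave-one-out cross-validation re-estimates each training reaction from
the remainder, once with the full estimator and once with the group fit
alone; held-out reactions that become undetermined are flagged and
excluded from the reported medians.

## Distributed thermodynamic bottlenecks

Given adjusted Gibbs energies along an ordered pathway (cofactors at
measured concentrations, all other participants at a reference, default
1 mM), a distributed bottleneck is reported for every window of
consecutive reactions whose summed adjusted ΔG′ exceeds a threshold and
that is not contained in a larger qualifying window.  This
contiguous-window formulation is one reasonable reading of "distributed
bottleneck"; the per-reaction marking threshold of 5.7 kJ/mol used in
reports is a display convention, and window sums are computed by direct
summation so results agree exactly with naive enumeration.

## Synthetic fixtures and what they show

The toy generator builds linear chains, diamonds (two parallel two-step
routes) and cycles with prescribed step energies, unit-demand media and
optional pinned boundary concentrations.  A standard battery of 21 such
fixtures (`benchmark_specs`) spans the three topologies, favourable and
uphill steps, and pinned/free boundaries; each keeps at most two free
metabolites so that the exhaustive grid oracle at step 0.01 in ln-space
(~1600 points per axis, ≤ ~2.6×10⁶ points) remains tractable — with three
or more free metabolites the full-box grid would exceed the 10⁸-point cap.
The oracle evaluates the exact objective on the grid under the same hard
floor f ≥ β as the QP; agreement is asserted within a Lipschitz bound on
one grid step's objective change (2·step·(2·Σspanᵢ + 2αδ·Σvⱼ‖Sⱼ‖₁), the
factor 2 covering constraint snapping).

The synthetic training-set generator for the Gibbs estimator draws integer
group-incidence matrices, Gaussian group energies (σ = 50 kJ/mol) and
sparse training reactions of 2–5 compounds; a quarter of the training
reactions are sums/differences of earlier ones, mimicking the linear
dependencies (pathway sums) present in real measured-reaction collections —
without them no held-out reaction could ever be recovered from the span
alone.  With zero noise the data are exactly first-law consistent and
group-explainable, so recovery tests have a sharp truth; noise is added
i.i.d. Gaussian on reaction energies only.

None of these fixtures emulate genome-scale structure: no biomass
composition, no cofactor coupling across pathways, no correlated estimation
errors, and concentrations in toys have no measurement counterpart.
Passing the battery therefore demonstrates correctness of the encodings
and optimisers on the identical feasible sets, not predictive accuracy on
real metabolomes.

## Numerical choices and degenerate inputs

* Span/rank decisions: relative tolerance 10⁻⁸ everywhere a rank cutoff is
  needed (SVD and pseudoinverses), so categorisation is deterministic.
* The MILP reports `infeasible` rather than raising; the QP raises only on
  solver failure (not on infeasibility, which is a modelling outcome).
* Empty pathways, empty fronts and zero-flux reactions are legal inputs
  with defined results (empty list, error, zero cost respectively).
* Degenerate correction windows: when stage-1 corrections are exhausted to
  exactly meet feasibility, the concentration window for some metabolite
  can shrink to a point; the QP handles this (equality-like constraint) but
  a grid oracle can miss it, so benchmark fixtures avoid zero-width
  windows.
* Problem sizes: the shipped battery and tests use networks of 2–6
  metabolites and up to ~10 reactions, where the MILP solves in
  milliseconds and the exhaustive oracle in seconds; the encodings
  themselves are sparse and scale to larger models, with the MILP expected
  to dominate runtime.

## Known limitations

* Enzyme cost is the three-factor driving-force approximation: no
  saturation kinetics, no allosteric regulation, no per-enzyme k_cat/K_m —
  w⁺ is a single physiological bound, so absolute enzyme levels from
  `enzyme_level` are a crude diagnostic.
* The two-stage scheme approximates a non-convex joint problem; the flux
  pattern is not re-optimised against the concentration objective
  (robustness across alternative flux optima can be checked via
  enumeration).
* pH/ionic-strength corrections must already be folded into the supplied
  ΔG′⁰ values at the network layer; compartments carry no correction of
  their own.
* The total-concentration cap (≈ 300 mM in bacteria) motivates the load
  term but is not enforced by default; `solve_concentrations` accepts an
  optional `total_conc_cap` (Σ exp(ln c) ≤ C is convex, so the program
  stays convex, at the cost of skipping the affine polish).
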