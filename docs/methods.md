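# Methods

## Model and optimization

A metabolic network is a set of compartment-localized metabolites and
reactions with exact rational stoichiometry.  External species (prefix
`x_`) are boundary pools with no mass-balance row; every other metabolite
must be balanced at steady state, `N·v = 0`.  The flux distribution at
each scan point is the solution of a linear program: minimize the sum of
split (non-negative) fluxes subject to steady state, fixed export fluxes,
fixed photon uptake, a fixed maintenance-ATPase flux, the cyclic ≤
non-cyclic photophosphorylation inequality, and the rubisco
carboxylase + oxygenase cap.  Minimal total flux is a parsimony
objective: among all flux distributions able to meet the imposed
exchange, it selects the one using the least enzymatic machinery.

Two formulation choices matter for the phenomenology:

* **Photon uptake is an equality.**  If light were only an upper bound,
  every response would be flat beyond saturation.  Fixing uptake forces
  the network to absorb surplus photons, which is what produces the
  high-light regimes (photorespiration, substrate cycles).  The
  *bisection search* for the feasibility threshold is the one place where
  the photon constraint is relaxed to an upper bound: "feasible with at
  most p photons" is monotone in p (so bisection is valid even for
  networks with no dissipation route) and has the same threshold.
* **The output is a set of fixed transporter fluxes, not a biomass
  equation.**  Each measured constituent gets its own export transporter
  fixed in proportion to composition; every export transporter *not* in
  the composition table is closed, otherwise the LP would quietly dump
  surplus carbon through an unconstrained sink (this matters: a free
  starch exporter turns the starch pathway into a photon sink and
  corrupts the transition axis).

The transition axis mixes the two scenarios componentwise,
`(1−r)·biomass + r·phloem`, after rescaling phloem to equal net carbon;
carbon fixation is then invariant in `r` to rounding error, making light
the only energetic variable along the axis.

## Numerical choices

* Solver: scipy `linprog` with the HiGHS backend; deterministic, so
  identical configurations give byte-identical artifacts.
* Steady-state acceptance: `‖N·v‖∞ ≤ 1e-9 × max(1, max|v|)` (observed
  residuals are ~1e-16 on the core-leaf model).
* Activity threshold (shared by active-reaction counts and region
  detection): `|v| > 1e-7 × photon_flux`, floored at 1e-9 — scale-aware
  because fluxes grow linearly with the imposed light.
* Flux capability: per-reaction maximization on the split problem with
  variable bound 1e3 and cutoff 1e-6 × bound; reactions seen active in
  any earlier optimum are harvested without their own solve.
* Degenerate optima: the objective value is unique; individual fluxes
  need not be.  Tests on degenerate fixtures assert the objective, and
  active-reaction counts are reported under this caveat.
* Relative differences with an inactive reference flux are undefined
  markers (NaN), never ±∞, so surface summaries stay finite.
* Bisection tolerance defaults to 1e-6 in photon-flux units; region
  breakpoints are placed midway between adjacent grid points whose
  active sets differ by at least `min_change` members (default 1; a
  coarse "major rearrangement" summary uses 5, since the boundary
  between major and minor rearrangements is a judgment call we expose
  rather than hard-code).

## The core-leaf generator

The synthetic model lumps each pathway into one pseudo-reaction
(Calvin cycle, photorespiratory cycle, glycolysis, pyruvate oxidation,
oxidative phosphorylation, …) so that exact oracles stay tractable while
the energy/redox trade-offs that drive the phenotypes survive.  Carbon
travels in single-carbon carbohydrate units (CH2O); ATP, NADPH and NADH
are element-free bookkeeping species confined to their compartments
(reductant crosses membranes only via the malate–oxaloacetate shuttle);
every reaction balances C, N and O (hydrogen and phosphate are not
tracked, so redox bookkeeping lives in the explicit cofactor terms).

Default energetics follow textbook stoichiometry, in model units:

| parameter | default | meaning |
|---|---|---|
| photons_per_nadph_noncyclic | 4 | 8 photons → 2 NADPH + 3 ATP + O₂ |
| atp_per_nadph_noncyclic | 1.5 | ATP:NADPH ratio of linear electron flow |
| photons_per_atp_cyclic | 2 | cyclic photophosphorylation cost |
| nadph_per_co2_calvin / atp_per_co2_calvin | 2 / 3 | Calvin-cycle demand |
| oxygenase_atp_cost | 1 | salvage ATP per oxygenation (lumped) |
| nadph_per_no3 | 4 | 8 electrons to reduce NO₃⁻ to NH₃ |
| atp_per_mito_nadh | 2.5 | P/O-equivalent of complex V |
| maintenance_atp | 20 | fixed cytosolic ATPase flux |
| rubisco_cap | 12 | carboxylase + oxygenase rate bound |

The biomass table (cell wall 0.4, starch 0.3, sucrose 0.1, amino acid
0.3; N:C ≈ 0.048) and phloem table (sucrose 1.0, amino acid 0.9;
N:C ≈ 0.061) keep the phloem mix nitrogen-richer, which the builder
asserts.  With these defaults the whole regime ladder — mitochondrial
ATP support, cyclic-cap binding with a transient TCA contribution,
the nitrate switch, photorespiration onset, and substrate-cycle
dissipation at the rubisco cap — unfolds between the feasibility
threshold (~71.7 photons) and about 2× that value; the defaults were
chosen once so all regimes appear inside a 100-fold light range.

Why the qualitative results come out as they do:

* Non-cyclic ATP exactly covers Calvin-cycle ATP (1.5 × 2 = 3), so all
  *extra* ATP comes from either cyclic photophosphorylation (2
  photons/ATP) or the "shuttle bundle": diverting one NADPH through the
  malate valve to mitochondrial oxidation yields 2.5 + 1.5 = 4 ATP per 4
  photons, i.e. 1 photon/ATP.  At minimal light the photon-cheaper
  bundle wins — mitochondrial ATP synthesis is obligatory at low light.
  The closed-form threshold in the manifest is exactly this accounting:
  `photons = 8 × (carbon exported) + 1 × (extra ATP demand)`.
* As imposed light rises past the minimum, the LP sheds the flux-heavy
  shuttle in favor of cyclic ATP until the cyclic ≤ non-cyclic cap
  binds; surplus then flows through progressively costlier sinks —
  nitrate substitution (bounded by nitrogen demand), photorespiration
  (bounded by the rubisco cap), and finally the unbounded pair of
  alternative oxidase (reductant) and the starch cycle (ATP).
* Every route is O₂-neutral net of the non-cyclic O₂ it consumes, so AQ
  is exactly 1 for carbohydrate output on ammonia and stays constant
  while photorespiration rises; nitrate reduction adds reductant-only
  demand and is the one lever that moves AQ (downward, more for the
  nitrogen-richer phloem mix).

Removing the cyclic ≤ non-cyclic constraint lets surplus photons drain
trivially through cyclic photophosphorylation (the ATP ending in the
photorespiratory salvage cost and, at extreme excess, the starch
cycle) — the toy reproduces why the constraint exists.

## What the generator does and does not emulate

It reproduces the *mechanistic skeleton*: compartmentation, the
energy/redox couplings, and the ordered light regimes.  It does not
attempt a genome-scale reconstruction's realism: no individual enzymes
or isozymes, no phosphate/sulfate nutrition, no hydrogen balance, no
thermodynamics or kinetics, and composition tables are round numbers
rather than measured rice data.  Passing tests therefore demonstrate
that the pipeline's mathematics and the qualitative physiology are
right; absolute flux magnitudes, genome-scale network dimensions and
flux-capability counts, experimentally comparable AQ values and
genome-scale active-reaction counts are properties of a real
reconstruction, which is an external download and outside the
desk-scale suite's reach.  The pipeline accepts such a reconstruction
unchanged (reaction-list or SBML input plus composition and element
tables).

## Oracles and cross-checks

Three independent routes guard the LP core: (1) exact rational vertex
enumeration (`brute_force_min_flux`) — the split problem in standard
form, every basic solution enumerated with `fractions.Fraction`, capped
at 24 columns; (2) cobra's parsimonious FBA (GLPK backend) on the same
random networks, used in tests only; (3) closed-form arithmetic for the
core-leaf thresholds and the 4-reaction energy-chain fixture.  One
hundred seeded random branched networks are compared against route (1)
in the acceptance run.

## Problem sizes

The shipped analyses use a 43-reaction model, 48-point light scans, a
24 × 11 (tests) or 16 × 11 (acceptance) transition grid, and 100 oracle
networks of ≤ 8 reactions — sizes chosen so the full suite and the
acceptance script each complete in well under a minute while every
regime of interest is still resolved by several grid points.

## Known limitations

* Counts of "active" reactions inherit LP degeneracy; the optional
  variability pass (fix the objective, extremize one flux) bounds but
  does not remove the ambiguity.
* Region detection is grid-based; a breakpoint is located to one grid
  step.  Refining the grid tightens but never relocates breakpoints
  beyond one coarse step (tested).
* The closed-form threshold covers the default parameter regime (shuttle
  bundle cheaper than cyclic ATP, chloroplast ATP demand within the
  bundle's chloroplast share) and raises a clear error outside it.
* SBML input honors stoichiometry, reversibility and boundary species
  only; flux-bound annotations are deliberately ignored (bounds belong
  to the analysis, not the file).
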