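# Methods

## Circuit model

Both circuits are small feedforward networks of rate-coded elements.  An
element is an external input (US, CS, and in Model 2 IL), an internal unit,
or the output gate (PAG).  Internal activity is

    a_j = max(0, b_j + Σ_i s_ij · w_ij · a_i)

with bias `b_j`, connection sign `s_ij ∈ {+1, −1}` and integer weight
magnitude `w_ij ∈ {0, 1, 2}` (signed weight = sign × magnitude).  The floor
at zero treats activities as firing rates; a purely linear variant is
available (`rectify=False`).  The published baseline configuration counts
discriminate the two semantics — Model 2's baseline count is reproduced only
with the floor, and Model 1's counts are identical either way — so the floor
is the calibrated default.  PAG is a binary gate: active iff its summed input
(CEm drive) is strictly positive, so a CEm activity of exactly 0 is "off".

Evaluation is one feedforward pass in topological order (both circuits are
acyclic; there is no settling dynamics, no time course, and no learning-rule
mechanism — plasticity steps are simply assumed to occur).  With integer
biases and magnitudes every activity is an integer, so enumeration is exact;
only the directed-search module uses real arithmetic.

Biases and initial weights are the published ones.  Model 1: biases
LA1 = LA2 = 2, LAi1 = LAi2 = 1, BA/ITCm/CEm = 0; all initial magnitudes 1
except the two CS inputs at 0; wUStoLA2 and wCEmtoPAG are fixed.  Model 2:
biases CEm = 1, ITCl = −1, ITCm = 2, LA1 = 2, LA2 = 1, LAi = 1; initial
magnitudes 1 except the three CS and three IL inputs at 0; the three US
inputs, wITCltoITCm, wITCmtoCEm and wCEmtoPAG are fixed.  Both models then
show spontaneous rates of 1 on all amygdaloid elements (CEm 0) and a fear
response to US alone.

## Two-phase rewriting semantics

Learning is modeled as nondeterministic rewriting over the weight
magnitudes.  A *move* is a unit magnitude step on one modifiable connection
(or on a whole tie group jointly), restricted to [0, 2]:

* **Conditioning.**  Allowed moves are the schedule's LTP directions.  After
  each move the circuit is probed with the cue alone (CS = 1, US = 0,
  IL = 0); the moment PAG activates, the record-tracked weights (the
  interneuron weights wLAi1toLA1/wLAi2toLA2 in Model 1, wLAitoLA1 in
  Model 2) are snapshotted and the state enters extinction.  Conditioning
  states in which no move remains and PAG never activated (e.g. the fully
  saturated Model 1 configuration) are dead ends, reported but not counted.
* **Extinction.**  Allowed moves are the extinction directions (LTD for the
  pathway weights; LTP for Model 2's IL weights).  The probe context is
  CS = 1, IL = 1 (IL is active only during extinction training; Model 1 has
  no IL).  The moment PAG goes inactive the state is DONE.  At the phase
  boundary the two probe contexts agree because the IL weights are still 0,
  so the convention is benign there.

State identity is the triple (phase, magnitudes, records); the same final
magnitudes reached with different conditioning histories are distinct
configurations, which is what makes the record parameters multiply the
configuration space (×2² for Model 1, ×2 for Model 2: each tracked weight
ends conditioning at its initial or potentiated magnitude).
`enumerate_terminals` runs a memoized breadth-first traversal and returns
the set of distinct DONE states plus diagnostics (maximum traversal depth,
dead-end count).  `enumerate_terminals_naive` walks every rule-execution
sequence without memoization and serves as the brute-force oracle on small
experiments; the two agree exactly wherever the oracle is tractable.

Counts are always of distinct (magnitudes, records) configurations, never of
paths.

## Constraint queries

Terminal-state predicates are pure functions of a DONE state:

* `ltd_of(w)` — final magnitude strictly below the post-conditioning record;
  `no_ltd_of` is its negation.
* `finals_equal` / `records_equal` — magnitude (record) equality across the
  named weights.
* `excited_by_cs(e)` — CS response strictly positive; `not_inhibited_by_cs`
  — CS response ≥ 0; `any_excited` — disjunction.  The CS response of an
  element is its activity difference between CS = 1 and CS = 0 at the final
  weights, evaluated in the extinction context (US = 0, IL = 1).  A response
  of exactly zero is neither excitation nor inhibition, which lets "either
  excited" and "neither inhibited" coexist.

Equality conditions on Model 2's CS/LA/IL weight families (registry rows
8–12) are encoded as *tied joint updates* — one move changes every group
member, keeping them equal in every reachable state — matching the
"modified by the same amount" reading; a terminal-equality-filter reading is
available behind `equality_as_filter`.  "No LTD of the LA→ITCl weights"
(row 5) is a schedule restriction by default, with an outcome-filter reading
behind `q5_outcome_filter`.

## Reproduction status and a known discrepancy

Under the default semantics the package reproduces exactly: all Model 1
rows except row 11 (12 of 13, including the 19,273 / 11,310 / 11,761 /
6,914 / 3,833 / 2,315 / 777 / 773 / 619 / 6 / 0 / 0 counts), Model 2 rows
1, 2 and 6 (8,394 / 4,659 / 0), every configuration-space size (78,732;
39,366; 26,244; 324; 108), and the ~59% / ~56% interneuron-LTD shares.

The remaining published counts — Model 1 row 11 and the Model 2 rows whose
conditions involve cue-response predicates or tied weights — do not
reproduce, and the failure is not a tolerance issue.  The analysis that
supports this conclusion:

1. The Model 2 baseline terminal set is pinned down by two independent
   exact matches (8,394 terminals; 4,659 with interneuron LTD).
2. On that set, LA2's CS response is identically wCStoLA2 (its only
   CS-dependent input), and only 1,924 of the 4,659 LTD configurations have
   wCStoLA2 = 0 — fewer than the ≥ 2,324 CS-unresponsive configurations the
   published row-3 count implies.  No activity-based reading of "responding
   to CS" can bridge that gap on this set.
3. Exhaustive mechanical searches — per-element predicates over rectified
   and linear responses in every stimulus-context combination, thresholds,
   activity-versus-baseline variants, record-substituted and
   pathway-transmitted responses, heterogeneous per-element predicate pairs,
   and all subsets of the joint response table tested simultaneously against
   every constrained row — found no predicate consistent with the published
   numbers; a parallel scan over enumeration-semantics variants (per-element
   flooring, probe contexts, gate thresholds, record timing, rule gating,
   phase-overshoot, tie readings) found no variant that preserves the two
   verified baseline counts with a different set composition.

The package therefore implements the literal reading stated above, reports
observed versus published per row (`amygsearch tables`), and leaves the
discrepant rows visible rather than fitting them.  The depth diagnostic
points the same way: the longest shortest path in the memoized graph is 20
for Model 1 (19 for Model 2), at the boundary of the published "all series
ended before depth 20".

## Directed search

The cross-check parameterizes each schedule-active connection by a real
conditioning change and extinction change in magnitude space, constrained so
the weight stays in [0, 2] after conditioning and after extinction.  By
default the changes are free in sign (bounds-only), because the
schedule-mirrored alternative makes the extinction change of the interneuron
weight negative in essentially every feasible point, collapsing the LTD
classification to 100%; the sign-constrained mode remains available
(`constrain_directions=True`).  The objective is Σ|desired − actual| PAG
response over three cases: unconditioned (initial weights, cue on, desired
0), conditioned (initial + conditioning changes, desired 1), extinguished
(initial + both changes, extinction context, desired 0); PAG response is the
binary activation indicator (a continuous clamped-CEm variant is available).
Starts are uniform over the feasible box (conditioning change first, then
the extinction change on its conditional interval).  The search probes each
free parameter by ±Δ (Δ₀ = 0.5, a quarter of the weight range; unspecified
in the original procedure, hence configurable), clips probes to the box,
accepts the best strictly-improving probe (ties broken by parameter order)
doubling Δ, otherwise halves Δ, and stops when Δ < 10⁻⁶.

A batch is `restarts` independent seeded searches (default 1000, a few
seconds per model).  A zero-error run counts as "with LTD" when the
extinction change of the designated interneuron weight is below −10⁻⁹.
For seed 1: Model 1, 626/1000 zero error, 50.5% with LTD; Model 2, 553/1000,
37.4% — in both models well below the exhaustive-search shares (58.7%,
55.5%), the qualitative relation the integer-restriction argument needs.
Exact stochastic fractions are not a target: the original procedure's start
distribution and probe details are under-specified, and the batch fractions
are sensitive to them.

## Problem sizes and determinism

The full 26-row table reproduction explores at most ~40,000 memoized states
per row and finishes in well under a minute; the naive oracle is used only
on the sub-1000-state experiments.  Move offering follows connection
declaration order, making enumeration byte-reproducible; all stochastic
components (start sampling) flow from a single seeded NumPy generator.

## Limitations

* The models are conceptual: two or three neurons per region, no dynamics,
  no learning mechanism — conclusions are about configuration counting, not
  physiology.
* The cue-response-constrained published counts are not reproduced (see
  above); the corresponding predicates follow the literal stated semantics.
* Likelihood interpretations of the counts (more configurations ⇒ more
  probable outcome) are reported in prose only; no statistics are computed
  over counts.
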