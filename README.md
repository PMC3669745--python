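# amygsearch

Exhaustive state-space search over the synaptic-weight configurations of two
rate-coded amygdala circuit models of fear conditioning and extinction.

## The scientific problem

Extinction of conditioned fear requires endocannabinoid (CB1) signalling,
which depresses the GABAergic synapses that inhibitory interneurons make onto
amygdala projection neurons.  That is a paradox: depressing inhibition should
*enhance* the cue responses that drive fear, not extinguish them.  This
package asks the question combinatorially: of all the ways a circuit can
rewire during conditioning and extinction, how many are compatible with both
extinction *and* GABAergic LTD?

Two circuits are built in:

* **Model 1** — parallel *Fear* (CS→LA2→BA2→CEm) and *No Fear*
  (CS→LA1→BA1→ITCm⊣CEm) pathways, each with its own inhibitory interneuron
  (LAi1, LAi2).
* **Model 2** — a single pathway CS→{LAi, LA1, LA2}→ITCl⊣ITCm⊣CEm with
  infralimbic cortex (IL) input to LAi, ITCl and ITCm; IL is active only
  during extinction.

Each element's activity is the sum of its weighted inputs plus a bias
(firing rates floored at zero); CEm drives the fear response (PAG) whenever
its activity is strictly positive.  Weight magnitudes are integers in
{0, 1, 2}.  Learning is nondeterministic unit-step rewriting: during
conditioning any allowed weight may take an LTP step (one at a time, in any
order) until the cue alone activates PAG; the tracked interneuron weights are
then recorded, and extinction LTD/LTP steps follow until the cue no longer
activates PAG.  A **terminal configuration** is the pair (final weights,
post-conditioning records) at that moment.  The package enumerates *all*
distinct terminal configurations by memoized breadth-first search and counts
those satisfying constraint queries — LTD of a tracked weight (final
magnitude strictly below its record), weight equalities, and cue-response
predicates (excited ⇔ CS response > 0, inhibited ⇔ < 0).

A real-valued cross-check replaces the integer steps with continuous
conditioning/extinction weight-change vectors and minimizes the summed
|desired − actual| PAG response over the unconditioned, conditioned and
extinguished cases by derivative-free pattern search (probe each parameter
by ±Δ, double Δ on improvement, halve on failure, stop at Δ < 10⁻⁶).

## Worked example

```python
>>> from amygsearch import experiment, enumerate_terminals, apply_filters
>>> exp = experiment(1, 1)                 # Model 1, baseline schedule
>>> terminals = enumerate_terminals(exp)
>>> len(terminals)
19273
>>> apply_filters(terminals, [("ltd_of", "wLAi1toLA1")])[0]
11310
```

Of the 78,732 possible (weight, weight-record) configurations of Model 1,
19,273 complete extinction after conditioning, and 11,310 of those (59%) do
so in conjunction with LTD of the interneuron weight wLAi1toLA1 — the
CB1-paradox resolution in numbers: GABAergic LTD accompanies a majority of
the ways extinction can occur.

The same from the shell, with the published value checked:

```sh
$ amygsearch enumerate --model 1 --row 1 --check
model 1 row 1: 19273 configurations (|terminals|=19273, max depth 20)  [pass]
$ amygsearch tables            # all 26 registered search conditions
$ amygsearch directed --model 1 --n 1000 --seed 1
```

The directed cross-check prints, for seed 1, 626/1000 searches reaching zero
error of which 316 (50.5%) show real-valued LTD of wLAi1toLA1 — a smaller
share than the exhaustive search's 59%, the qualitative comparison the
integer/real consistency argument rests on.

Some published counts for the cue-response-constrained search conditions are
not reproduced by the documented semantics; `amygsearch tables` reports
observed vs expected per row, and docs/methods.md analyses the discrepancy.

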