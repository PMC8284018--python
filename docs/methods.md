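# Methods

This note records the models, parameter choices and numerical conventions
behind `combilogic`, including the points where the design was genuinely
open and what the synthetic benchmarks do and do not demonstrate.

## Prior knowledge network and preprocessing

A PKN is a signed directed graph (activation +1 / inhibition −1) with
optional AND-gate hyperedges for protein-complex requirements, read from
SIF plus two CSV sidecars (node roles/pathways; gate membership — SIF
cannot express hyperedges, and keeping the main file plain SIF preserves
interoperability).  Duplicate identical interactions are dropped with a
warning; the same ordered pair with both signs is kept as two parallel
edges, since dual-sign regulation occurs in curated networks.

Identifiability preprocessing iterates to a fixed point: (a) intermediates
with no directed path from any stimulus are removed (non-controllable),
(b) intermediates with no path to any readout are removed (non-observable),
(c) unmeasured, unperturbed pass-through nodes (in-degree = out-degree = 1,
not part of an AND gate) are compressed, rewiring source → target with the
product of the signs.  Designated nodes (stimulus, drug, readout) are never
removed; a readout unreachable from every stimulus is kept, flagged and
warned about rather than silently dropped.  The procedure is idempotent,
never grows the network, and preserves stimulus→readout reachability
(property-tested).

Closeness centrality uses the harmonic formulation on *outgoing* distances,
normalized by n−1, so disconnected graphs and isolated nodes (score 0) are
well defined.

## Boolean semantics

Node update is synchronous: value = OR over selected incoming hyperedges,
where a single-input edge contributes the input (sign +1) or its negation
(sign −1) and an AND gate the conjunction of its signed inputs; stimuli are
clamped on, drug inhibitions clamp their target to 0.  Iteration stops at a
fixpoint or after 2·|nodes| steps; entries still changing afterwards
(oscillations, e.g. mutual negation loops) are *unresolved* and enter the
objective through the NA penalty instead of being compared to data.  Note a
consequence of pure-OR semantics: a bare inhibitory edge contributes NOT
input, so it activates its target whenever its source is at rest.  Negative
feedback loops of the form S→A→B, B⊣A therefore settle at a fixpoint
(the OR term keeps A on) rather than oscillating; oscillation requires the
negations to dominate, as in a mutual-negation pair without stimulus drive.

## Normalization

1. Fold change: log(MFI_stim,t / MFI_control,t) per donor, stimulus,
   readout and post-baseline timepoint; MFI must be positive.
2. Timepoint collapse: of the 5- and 25-min values, the one with maximal
   absolute magnitude, sign preserved.  "Maximum" is read as maximal
   *magnitude* because the motivation — capturing late effects of negative
   feedback — concerns the size of the response, not its sign.
3. Three-state filter: robust z = fc / (1.4826 × MAD of control fold
   changes for that readout), two-sided normal p, Benjamini–Hochberg within
   each donor at q < 0.05.  Control fold changes (log control_t /
   control_0) are pooled across donors per readout because a single donor
   contributes only two such values, below any reasonable floor for a
   spread estimate; the BH correction itself stays per-donor (recorded in
   output metadata; configurable).  A zero MAD with nonzero fold change is
   flagged significant with a warning — the degenerate case of noise-free
   data.
4. Hill transform: phosphorylated → |fc|^k / (ec50^k + |fc|^k) with k = 2;
   dephosphorylated → target value 0 (kept in the objective so inhibitory
   edges are fittable); non-significant → missing (excluded).  The default
   half-effect point is **half** the donor's median positive |fc|: with the
   median itself, the donor's typical significant response would map to
   exactly 0.5 — equidistant from both Boolean states and uninformative —
   whereas half maps it to ≈ 0.8 while remaining adaptive to each donor's
   dynamic range and penalizing outliers.

The whole pipeline is invariant to rescaling all MFI by a positive
constant (property-tested).

## Model training

Objective = MSE between simulated readout states and normalized values
over defined pairs + na_penalty × (fraction unresolved among defined
pairs) + size_factor × (selected / total hyperedges).  Defaults:
size_factor 1e-4 (small enough never to trade a data mismatch for size,
large enough to prune non-contributing edges), na_penalty 1.0.

The GA is a bit-vector algorithm: population 50, tournament selection
(size 3), uniform crossover, one uniformly chosen bit flipped per child
with probability 0.5, elitism of one, early stop after 100 stall
generations, cap 500 generations — ecosystem-typical defaults, all
configurable.  Ten independent seeded runs per donor; the donor model is
the per-hyperedge **median** of the selections scoring within rel_tol = 0.1
of the best (band closed at its border).  An even ensemble's median is the
mean of the central values, so fractional weights such as 0.5 occur — which
is what makes group-mean edge activities continuous.  Simulations are
memoized by genome across runs *and donors* (the simulation depends only on
the genome and condition panel), which is what keeps cohort fitting fast.

On networks of ≤ 10 hyperedges the GA's best score equals the exhaustive
2^H optimum on every tested instance.

## Synthetic cohorts

The generator emulates the structure of a multi-center stimulation study:
default panel 20 stimuli + media control, 17 readouts, timepoints 0/5/25
min, donor groups healthy / untreated / five treatments.  The PKN generator
builds a layered DAG (stimuli → intermediates → readouts) with activating
edges; inhibition enters through AND gates (activator AND NOT inhibitor),
because under OR semantics a bare inhibitory edge would fire at rest,
activate the unstimulated control, and be unconstrainable by
stimulus-vs-control fold changes.  Two further construction rules keep the
fitting problem well posed: a gate replaces its plain activator edge
(otherwise the two are observationally equivalent under single-stimulus
conditions), and a readout's second driver must not share stimulus
ancestry with the first (otherwise two equal-cost routes explain the same
response).

The healthy ground truth is a random sub-model minimized to a locally
minimal, identifiable core: every selected edge changes some simulated
readout when removed, and no output-neutral single-edge addition permits a
strictly smaller model.  The untreated group differs from healthy in
exactly `n_deregulated` output-changing flips, gain-of-function preferred
(constitutive over-activation, the motif treatment is expected to miss);
each treatment keeps `n_unreverted` of them (default half, rounded up) and
replaces the rest with fresh off-target flips, so every non-healthy group
differs from healthy in exactly the same number of edges.  Flips are chosen
sequentially in context and avoid making other selected edges redundant.

Measurements: readout state 1 → baseline × effect_size, state 0 → baseline,
baseline timepoint always at baseline, optional "slow" edges acting only at
the last timepoint; everything multiplied by log-normal noise with
sigma² = ln(1 + cv²).  Defaults: baseline 500 MFI (typical bead-assay
mid-range), effect_size 4 (log fold change ≈ 1.4, a clear but not extreme
response), cv 0.15 (replicate-level variation of multiplex immunoassays),
donor edge-flip probability 0.05.  Same seed ⇒ byte-identical MIDAS.

What the synthetic data does *not* emulate: plate/batch and center effects,
missing-well patterns, readout cross-talk, non-binary partial responses,
or dose dependence.  Passing recovery benchmarks therefore demonstrates
correctness of the inference machinery under the generative assumptions,
not performance on clinical data.

## Subgroup analysis and co-druggability

Subgroup networks are per-edge arithmetic means of donor weights; the
active mask is activity ≥ the 75th percentile (linear interpolation) of the
group's *nonzero* activities, ties included.  Jaccard distances binarize
weights at 0.5 (the natural midpoint; configurable); the background
distribution is all unordered donor pairs of the whole cohort, and group
distances are compared to it with the two-sample Wilcoxon rank-sum test.
The rank-sum p uses the exact null distribution for tie-free pooled
samples up to 50 values, else the continuity-corrected normal
approximation — the classical convention, and the choice that keeps the
test's type-I error at its nominal level in calibration.

Co-druggability per treatment: score = |S_H − S_MS| − |S_H − S_T|;
|score| below its own lower-quartile threshold collapses to 0; candidates
(collapsed score ≤ 0) are retained when the healthy-vs-treated difference
is in its upper quartile *and* rank-sum significant across donor weights
(p < 0.05; the test for this step is a package choice, recorded in output
metadata) *and* the interaction is active in the treated network.
Quantile thresholds are computed within one treatment comparison
(per-treatment; configurable), following the per-drug framing of the
selection.  On binary inputs the score-and-filter cascade reproduces the
8-row truth table exactly.

Prediction is sign-agnostic reachability over the treated network's active
edges (AND gates expanded to their member arcs): for each flagged u → v,
every stimulus s with s ⇝ u and every readout m with v ⇝ m yields one
prediction, with shortest-path lengths recorded so stricter upstream
filters can be applied downstream; the desired modulation is *inhibit* when
treated activity exceeds healthy and *activate* otherwise.

## Statistical confirmation

Stage 1: two-sided one-sample Wilcoxon signed-rank per (group, stimulus,
readout) on collapsed fold changes (≥ 5 donors; all-zero vectors get p = 1
by convention), BH within group, significance on adjusted q at 0.05 — the
stringent reading of "BH then p < 0.05 cutoff"; thresholding raw p instead
is a flag.  Two-sidedness follows from testing deviation from zero in
either direction.  Stage 2: support = readout reachable from stimulus over
the group's active edges.  Stage 3: one-sided Fisher exact test (enrichment
of significant pairs among supported ones); degenerate margins give p = 1
with a warning.  Group sizes matter: with fewer than ~8 donors the exact
signed-rank minimum p (2/2^n) cannot survive BH correction across a
30-pair panel, so the desk-scale study uses 8 donors per group and the
calibration benchmark 20 — representative of real treatment arms.

## Benchmark sizes

The evaluation studies (shared by the test suite and
`scripts/acceptance.py`) use: truth table — all 8 binary patterns; dataset
cardinality — the full 180 × 20 × 17 × 3 design; GA oracle — 20 random
networks of ≤ 10 hyperedges; recovery — 16-node networks (6 stimuli, 6
readouts, preprocessed), 3 groups × 10 donors, noise-free, 3 deregulated
edges of which 2 unreverted; calibration — 1000 null replicates at 20
donors per group.  These sizes complete in seconds to a couple of minutes
on one CPU while leaving each benchmark statistically meaningful.

## Known limitations

- Boolean steady-state semantics: no kinetics, no partial activation; the
  two post-baseline timepoints are collapsed rather than fitted
  dynamically.
- Equal-cost alternative explanations can survive in hand-supplied PKNs
  (the generator avoids constructing them, but cannot be enforced on user
  networks); ensemble weights near 0.5 are the symptom.
- The deregulation model is single-edge flips; coordinated multi-edge
  rewiring is not planted, though nothing in the inference assumes
  single-edge effects.
- Quality-control of raw plates (control wells, reproducibility filters)
  is out of scope; inputs are assumed already QC'd.
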