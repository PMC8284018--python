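# combilogic

Donor-specific Boolean logic models of immune signaling from perturbation
phosphoproteomics, with subgroup network comparison, co-druggability scoring
and topology-based prediction of combination therapies.

## The problem

In complex immune-mediated diseases such as multiple sclerosis, approved
drugs modulate signaling but rarely restore it to a healthy-like state:
some interactions stay deregulated, and the drug itself can push others
off-target.  Given ex vivo phosphoproteomic responses of donor immune cells
to a panel of stimuli — healthy controls, untreated patients, and patients
under different single-drug therapies — this package answers two questions:

1. **Which signaling interactions are active in each donor and donor
   group?**  A literature-derived prior knowledge network (PKN) is fitted
   per donor as a Boolean logic model; donor models are merged per group
   into subgroup networks.
2. **Which interactions should a second drug target?**  Interactions whose
   activity under treatment remains (or becomes) un-healthy-like are
   *co-druggable*; a graph search maps each one to experimental stimuli and
   readouts that can engage and report it.

## The method

For each donor, the preprocessed PKN (identifiability: removal of
non-controllable / non-observable nodes and compression of pass-through
nodes) defines candidate hyperedges: signed single-input edges and AND
gates.  Measurements are normalized per donor — log fold change vs the
media control, collapse of the 5/25-min timepoints to the value of maximal
magnitude, a robust-z + Benjamini-Hochberg three-state filter
(phosphorylated / dephosphorylated / non-significant), and a Hill transform
to [0, 1].  A genetic algorithm then selects the hyperedge subset whose
synchronous Boolean fixpoint best matches the data while penalizing model
size; the donor model is the per-edge median over all solutions within a
relative tolerance of the best across 10 independent runs.

Subgroup networks are per-edge means of donor weights, with an active mask
at the upper quartile of nonzero activities.  For each treatment T, with
S<sub>g</sub> the activity of an interaction in subgroup g, the
co-druggability score is

&nbsp;&nbsp;&nbsp;&nbsp;|S<sub>Healthy</sub> − S<sub>MS</sub>| − |S<sub>Healthy</sub> − S<sub>T</sub>|

Near-zero scores are collapsed to zero (lower-quartile threshold on
|score|); interactions with a non-positive collapsed score, an
upper-quartile and rank-sum-significant healthy-vs-treated difference, and
active signaling are flagged co-druggable.  For every flagged interaction
u → v, each stimulus with a directed active path to u and each readout
reachable from v yields a testable combination prediction.

A synthetic-data module generates cohorts with known ground truth —
subgroup-specific Boolean networks with planted unreverted deregulation,
multiplicative log-normal MFI noise, MIDAS-format output — so the whole
pipeline is exercisable and testable at desk scale without clinical data.

## Worked example

The numbered scripts under `analysis/` run a complete desk-scale study
(shared config in `analysis/study_config.py`: 4 groups × 8 donors, 6
stimuli + media control, 5 readouts, 3 planted deregulated edges per
diseased group of which 2 are unreverted by each treatment):

```sh
python analysis/01_simulate_cohort.py   # network + ground truth + MIDAS
python analysis/02_normalize.py         # fold changes -> 3-state -> [0,1]
python analysis/03_fit_models.py        # GA logic model per donor
python analysis/04_subgroup_networks.py # merge, Jaccard distances
python analysis/05_codruggability.py    # scores, filters, predictions
python analysis/06_statistical_confirmation.py
```

`05_codruggability.py` prints, for this cohort:

```
co-druggable interactions (per treatment):
treatment interaction  s_healthy  s_ms  s_treatment  score  p_value
      FTY     S02=I00      0.000 0.875          1.0 -0.125    0.000
      FTY     I01=M04      0.125 1.000          1.0  0.000    0.001
     IFNB     S02=I00      0.000 0.875          1.0 -0.125    0.000
FTY: planted unreverted ['I01=M04', 'S02=I00'] -> 2/2 flagged
IFNB: planted unreverted ['I01=M04', 'S02=I00'] -> 1/2 flagged

2 combination predictions (stimulus x co-druggable interaction x readout):
treatment interaction stimulus readout direction  path_length_up  path_length_down
      FTY     I01=M04      S00     M04   inhibit               1                 0
     IFNB     S02=I00      S02     M03   inhibit               0                 1
```

Reading: interaction `S02=I00` is inactive in healthy donors (S = 0.000),
constitutively active in untreated patients (0.875) and still active under
both treatments (1.0) — deregulation the drugs failed to revert — so a
second drug should *inhibit* it; stimulating `S02` while measuring readout
`M03` would probe exactly that interaction.  The statistical confirmation
script reports that donor-level responses are enriched among
model-supported stimulus–readout pairs (one-sided Fisher exact, e.g.
p = 4.7e-5 for the healthy subgroup on this cohort).

The same pipeline runs on user data from files (SIF network + node
annotations + MIDAS CSV) through a YAML config:

```sh
combilogic run-all --config my_study.yml
```

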