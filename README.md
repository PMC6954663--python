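# foldevents

Automated detection of structural transition events in cotranscriptional
RNA chemical probing (SHAPE-Seq style) reactivity matrices.

A cotranscriptional probing experiment yields a matrix of per-nucleotide
reactivities, one row per intermediate transcript length. `foldevents`
scans each nucleotide column for two classes of transitions:

* **swing events** — rapid reactivity changes over a few transcript
  lengths, detected with a proportional/integral/relative thresholding
  scheme inspired by feedback control (seven tunable thresholds:
  `p_up/p_down`, `i_up/i_down`, `r_up/r_down`, `m_floor`);
* **ramp events** — gradual changes spanning many lengths, detected with
  sliding-window linear regression (window length, minimum slope, minimum
  R², minimum net change).

On top of the detectors it provides:

* automated swing-threshold selection (scale the thresholds over a grid,
  count consensus flagged cells, pick the elbow point closest to the
  origin after min–max normalization);
* replicate **consensus** calling (an event must be present, within a
  length tolerance, in *every* replicate), concurrency grouping across
  nucleotides, and mining of upswing→downswing lagged pairs;
* **sensitivity analysis**: stringent (×2) / lenient (×0.5) global
  perturbations, single-parameter perturbations, and the pairwise cohort
  (all C(7,2)·4 = 84 pair perturbations) with per-cell agreement maps;
* a **simulator** that generates matrices from a known pairing-state
  trajectory (ternary gamma reactivity model, a 14-nt polymerase
  footprint forced to the paired state, per-cell averaging over many
  draws, per-length renormalization to mean 1) plus precision/recall
  benchmarking against the ground truth.

## File formats

Matrices are TSV/CSV with a `length` first column, nucleotide positions
in the header, `NA` for undefined cells, and `#`-prefixed provenance
comments. Event tables are TSVs with columns
`nucleotide, class, direction, start_length, end_length, magnitude,
n_replicates_supporting, group_id`.

## CLI

```sh
# detection on three replicates (thresholds auto-selected when omitted)
foldevents detect rep1.tsv rep2.tsv rep3.tsv --out-dir results/

# automated swing-threshold selection only
foldevents autotune rep1.tsv rep2.tsv rep3.tsv --out thresholds.yaml

# simulate a hairpin-formation benchmark and score a detection run
foldevents simulate --scenario hairpin_formation --seed 1 --out-prefix sim
foldevents benchmark detected.tsv sim.truth.tsv --tol 3

# 84-run pairwise threshold-sensitivity cohort
foldevents sensitivity rep1.tsv rep2.tsv rep3.tsv --out-dir sens/

# grayscale matrix rendering with event annotations
foldevents plot sim.matrix.tsv --events results/events_grouped.tsv --out fig.png
```

Threshold values can also come from a YAML config (`--config`) with
`swing:` and `ramp:` sections; command-line flags override file values,
and the fully resolved configuration is written next to the outputs.

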