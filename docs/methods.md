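# Methods

## Signal model and scope

The package operates on amplitude-integrated EEG (aEEG) *trend* traces:
non-negative amplitude series in µV, nominally 3 hours long, sampled slowly
(1 Hz default — the cerebral function monitor's display is heavily
time-compressed, so nothing in the feature set depends on sub-second
structure). The raw-EEG processing chain that produces aEEG (2–15 Hz
asymmetric band-pass, rectification, semi-logarithmic compression) is out of
scope; inputs are assumed to be aEEG amplitude already. Sample interval is a
configuration field throughout, never hard-coded in feature code. Recordings
shorter than the nominal 3 hours are accepted with a warning so that test
fixtures can stay small; feature extraction only requires enough duration
for 15 segments (24 minutes at the defaults).

## Feature extraction

**Segmentation.** Windows of `window_s` = 180 s stepped by `step_s` = 90 s
give `floor((L − window)/step) + 1` segments — 119 for a full 3-hour trace.
Window and step (and the selection counts below) are configurable.

**Second-order envelope.** One envelope pass marks local extrema (plateau
points and both endpoints qualify) and linearly interpolates through them;
the second-order envelope iterates this twice, which smooths over individual
oscillations and tracks the edge of the aEEG band. A segment's *upper/lower
boundary* is the mean of its second-order upper/lower envelope. The same
construction at recording level defines the *lower margin* series used by
the fourth basic feature (percentage of lower-envelope samples strictly
below 5 µV). The construction was a genuinely open choice; iterated
extremum interpolation was picked because it is parameter-free, exact on
constant series, and reproduces the smooth band edges expected of an aEEG
envelope.

**Approximate entropy.** Standard Pincus conventions: embedding dimension
`m = 2`, tolerance `r = 0.2 × SD` of the segment, Chebyshev distance,
self-matches included, natural logarithm. With self-matches every match
count is ≥ 1, `Φ` is finite, and ApEn ≥ 0. A constant segment has SD 0 and
no meaningful tolerance; it is defined to have ApEn 0 (perfect regularity),
which is also the limit of the formula for any r > 0. `N ≥ m + 2` is
required so both `Φ_m` and `Φ_{m+1}` exist.

**Segment selection.** Segments are ranked by ApEn (ties broken toward the
lower segment index, a stable choice); the 10 highest and 5 lowest survive.
Output order is fixed — top block in descending ApEn, then bottom block in
ascending ApEn — so feature k always means "k-th most / least irregular
segment", giving the forest a stable column semantics. Extreme ApEn in
either direction is the informative signal: bursts raise it, suppression
and flat traces lower it.

**Histogram.** Bins `[0,1), …, [49,50), [50,60), …, [90, ∞)`. The last bin
is open-ended so no sample is dropped; an amplitude of exactly 50 µV falls
in the first wide bin. Proportions rather than counts keep recordings of
different lengths comparable.

Total: 4 + 55 + 60 = 119 features with stable names
(`basic_*`, `hist_000..054`, `seg_00_upper..seg_14_apen`).

## Synthetic data

Real clinical recordings are not distributable, so the generator emulates
exactly the properties the features read out, with per-pattern defaults:

| pattern | model | key defaults |
|---|---|---|
| normal | baseline + slow sinusoid (3600 s period, sleep–wake-like cycling) + Gaussian noise, clipped at 0 | baseline 25 µV, band 10 µV, noise SD 2.5 µV |
| burst_suppression | suppressed floor + Poisson bursts (2–8 s) | floor 3 µV, 6 bursts/min, burst ≈ 40 µV |
| low_voltage | as normal but low | baseline 3 µV, band 2 µV, noise SD 1 µV |
| flat | near-constant | 1 µV, noise SD 0.15 µV |

These values were chosen once so that the normal lower margin sits well
above 5 µV, the low-voltage margin below it, and the burst-suppression
amplitude histogram is bimodal — i.e. the classes are genuinely separable
through the published feature set, which is what end-to-end tests need to
exercise. The generator does **not** model electrode artifacts, seizures,
sleep-state scoring or inter-patient variability; consequently the
near-perfect OOB rates on synthetic data demonstrate that the pipeline
wires signal → features → classifier correctly, not that those rates would
be attained on clinical traces. Datasets are pure functions of
`(counts, config, seed)`; per-recording seeds derive from the master seed
and are recorded in each recording's metadata and the dataset manifest.

## Classifier

A two-class random forest written from first principles:

* **Bootstrap + random subspace.** Each of `n_tree` (default 1000) trees is
  grown on a size-n bootstrap; at every node a fresh `m_try` features
  (default `round(√p)`, = 11 at p = 119) are drawn without replacement.
* **Weighted Gini.** Node proportions are weight-scaled,
  `p_k = w_k n_k / Σ w_j n_j`; splits maximise the decrease in
  weighted-mass-averaged impurity over all midpoints between consecutive
  distinct feature values. Ties go to the lowest feature index, then the
  lowest threshold (deterministic). A split must improve impurity by more
  than 1e-12 — nodes whose candidates are all constant become leaves.
* **Fully grown.** Recursion stops only at purity, fewer than 2 samples, or
  no improving split; no depth cap, no pruning.
* **Weighted vote.** Leaves store weighted class probabilities; prediction
  averages leaf probability vectors across trees (`vote="soft"`, the
  default) or counts one vote per tree (`vote="hard"`); the two differ only
  on near-ties. Exact probability ties resolve to the abnormal class, the
  costlier miss. Class weights default to abnormal:normal = 3:1 and apply
  only in the Gini criterion and the vote — the bootstrap itself is uniform.
* **Determinism.** Per-tree generators derive from
  `SeedSequence(master_seed, spawn_key=(tree_index,))`, so fits are
  bit-reproducible and independent of execution order. Setting
  `class_weights=None` and `{1, 1}` produce identical forests.

**OOB estimation.** Each tree's bootstrap misses on average
`(1 − 1/n)^n → e⁻¹ ≈ 37%` of samples. OOB predictions aggregate, per
sample, only the trees that missed it; the error denominator counts samples
with at least one OOB tree.

**Permutation significance.** Per tree: the correct-vote rate on its OOB
cases minus the rate after shuffling feature i among those cases; the
feature's raw significance is the mean over trees. Permutations come from a
single stream seeded explicitly, iterated tree-major then feature-major —
part of the documented contract so results are reproducible.

**Serialization.** Forests round-trip through a versioned JSON schema
(config, classes, feature names, recursive node records, per-tree bootstrap
indices); reloaded models predict identically.

## Evaluation and tuning

Sensitivity, specificity, F1 and the G-mean
`g = √(sensitivity × specificity)` are computed from explicit confusion
counts with the positive class stated (default `abnormal`; the CLI flag
`--positive-class` switches it, since the convention materially changes F1
under class imbalance). Undefined ratios are reported as NaN with a flag,
never silently 0. Cross-validation uses seeded stratified folds (class
proportions within one sample, fold sizes within one of each other).

Three sweeps mirror the tuning procedure: OOB error vs `n_tree`, OOB error
vs `m_try` at fixed `n_tree`, and OOB metrics vs the abnormal:normal weight
ratio, recommending the ratio with the highest mean G-mean (ties to the
smaller ratio). Sweeps average over 5 seeded repeats by default to tame OOB
noise at small forest sizes.

## Numerical choices and problem sizes

* Split-gain and ApEn comparisons are plain float64; the ApEn
  implementation agrees with a nested-loop evaluation to 1e-12.
* Histogram proportions sum to 1 within 1e-9 (accumulated float error).
* The test suite and acceptance script use 100/35 and 150/30 recording
  datasets at the full 3-hour duration for statistical checks, 200–1000
  trees where OOB calibration matters, and 30-minute recordings for
  smoke-level checks — sizes chosen to give stable statistics on a single
  CPU.

## Known limitations

* Two classes only (the formulas generalise; multi-class is untested).
* The synthesizer's abnormal subtypes are conventions, not fitted to
  clinical data; absolute performance numbers on synthetic data do not
  transfer to real aEEG.
* No artifact rejection, impedance handling, seizure detection or ROC
  analysis. EDF support reads a single channel and assumes physical units
  convert to µV.
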