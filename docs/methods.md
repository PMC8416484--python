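# Methods

## Problem and model

Given a pre-delimited prion-like domain (PrLD) sequence over the 20
canonical amino acids, the package predicts whether the domain is
recruited into stress granules (SG) upon heat stress. Recruitment is
treated as a binary classification driven by three sequence-derived
biophysical features, combined by a small feed-forward neural network.
The approach assumes the decision is a (possibly non-linear) function of
these three quantities alone; positional sequence information beyond the
window-averaged aggregation profile is not used.

## Features

**Aggregation propensity (Na4vSS).** Each residue has an intrinsic
aggregation-propensity value a3v from a 20-entry scale (packaged in
`src/sgnn/data/a3v_scale.txt`, transcribed from the published AGGRESCAN
scale; every operation accepts the scale as a parameter, so tests run on
toy scales and are independent of the transcription). A window centered on
each residue averages a3v into a per-position value a4v. Window size
follows a length-dependent band rule (window 5 for sequences of ≤ 75
residues, 7 up to 175, 9 up to 300, 11 beyond), configurable as a list of
(max-length, window) bands. At the sequence ends the window is truncated
(shrunk one-sided) rather than dropping flanking positions — this keeps one
a4v per residue so the summary is defined for short PrLDs. The sequence
summary is `Na4vSS = mean(a4v) × 100`, i.e. a length-normalized total.
Because Na4vSS mixes positive and negative values, it is min–max
normalized to [0, 1] between the least and most aggregation-prone
reference PrLDs; out-of-range inputs are clamped. The anchors are derived
from the training data at fit time (min and max Na4vSS over training
sequences) and frozen inside the trained model bundle, so prediction is
self-consistent.

**Net charge per residue (NCPR).** Fractional charges from the
Henderson–Hasselbalch equation: a basic group contributes
`+1/(1+10^(pH−pKa))`, an acidic group `−1/(1+10^(pKa−pH))`. The default
pKa set (D 3.65, E 4.25, C 8.30, Y 10.07, H 6.00, K 10.53, R 12.48;
N-terminus 8.0, C-terminus 3.1) is a conventional biochemistry table
packaged as an editable config file. Default pH is 7.0 (cytosolic-like).
Terminal charges are excluded by default because PrLDs are internal
domains of larger proteins, making free termini artifactual; a flag
enables them. NCPR is the summed charge divided by sequence length and is
a pure composition property (invariant under sequence permutation).

**Cysteine percentage.** `100 × count(C) / length`, a proxy for
disulfide-bonding potential under the oxidative conditions of heat
stress.

## Classifier

A multilayer perceptron with layer sizes 3 → 9 → 6 → 1 and
hyperbolic-tangent activations in every layer. The two hidden widths (9
and 6) are fixed; alternative architectures, regularization and
early stopping are deliberately out of scope. Class targets are encoded
−1 (not recruited) / +1 (recruited) and the decision threshold is 0 on the
output activation, with ties classified positive.

Raw features live on very different scales (normalized aggregation in
[0, 1], NCPR around ±0.1, Cys% in [0, 100]), so a per-feature affine input
scaling `(x − offset) × gain`, fitted as min–max → [−1, 1] on the training
features, is stored inside the model; a feature constant across training
maps to 0. Weights and biases are initialized from a seeded uniform
distribution on [−0.5, 0.5] — simple and reproducible, adequate for a
network of this size.

**Training (gdx).** Batch backpropagation on the sum of squared errors
with momentum and an adaptive learning rate. Per epoch the candidate
update is `Δw(t) = momentum·Δw(t−1) − (1−momentum)·lr·∇E`. If the new
error exceeds the previous one by more than the factor `max_perf_inc`,
the step is rejected: weights are restored, the momentum memory is
cleared, and `lr ← lr·lr_dec`. Otherwise the step is accepted and, when
the error strictly decreased, `lr ← lr·lr_inc`. Training stops when the
error reaches `goal` or the epoch budget is exhausted. Defaults (epochs
500, goal 0.01 SSE, lr0 0.01, lr_inc 1.05, lr_dec 0.7, max_perf_inc 1.04,
momentum 0.9) are the canonical settings of this scheme; all are
overridable. With momentum 0 and both lr factors at 1 the update reduces
to plain batch gradient descent, which the tests exploit as an oracle
(one-epoch update equals −lr·∇E; the analytic gradient is checked against
central finite differences to < 1e−6 relative error).

Divergence (non-finite error) aborts with an error naming the epoch.
Training is deterministic given (seed, data, config).

## Evaluation machinery

Confusion counts use "recruited to SG" as the positive class. The six
statistics follow their defining formulas — sensitivity TP/(TP+FN),
specificity TN/(TN+FP), precision TP/(TP+FP), accuracy (TP+TN)/n,
F1 TP/(TP+½(FP+FN)), MCC (TP·TN−FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) —
computed verbatim; a metric with a zero denominator is reported as an
explicit undefined marker (`null` in JSON), never silently as 0.

ROC curves sweep the decision threshold over the unique scores in
descending order; tied scores move the curve in a single step; the curve
is anchored at (0,0) and (1,1) and AUC is trapezoidal. By construction
this AUC equals U/(n1·n2) of the Mann–Whitney statistic, which the tests
verify on random small instances including ties.

The two-tailed Mann–Whitney test computes U from midrank sums. For a
combined sample size of at most 12 the p-value is exact: all
C(n1+n2, n1) assignments of the pooled observations are enumerated and
the p-value is the fraction whose U deviates from n1·n2/2 at least as
much as the observed value (midranks make the enumeration valid under
ties). Larger samples use the normal approximation with tie correction
and a 0.5 continuity correction. The cutoff at 12 balances fidelity
against cost; enumeration at n=12 is 924 assignments.

The stratified split draws, per class, `round_half_up(fraction · n)`
members into the training half (seeded permutation); the halves are
disjoint and exhaustive, and a class that cannot yield two non-empty
halves is an error. The package's standard protocol splits a 32+32
dataset into 16+16 training and 16+16 testing halves.

## Synthetic data generator

The generator emulates the compositional contrast between recruited and
non-recruited PrLDs with two residue-frequency profiles:

- *positive*: enriched in hydrophobic residues (W 3%, F 5%, I 7%, L 9%,
  V 8%) and charged residues with cationic mass (K+R+H = 14%) exceeding
  anionic (D+E = 8%), plus 1.5% cysteine → expected NCPR > 0, high
  aggregation propensity, measurable Cys%;
- *negative*: Q/N-rich and polar (Q 14%, N 14%, G 10%, S 12%, Y 6%) with
  D+E (7%) slightly above K+R+H (5.5%) and 0.15% cysteine → expected
  NCPR < 0, low aggregation propensity, near-zero Cys%.

Both expected class orderings (aggregation, NCPR, Cys%: positives >
negatives) hold in closed form as profile-weighted expectations, and
empirically in generated data. Sequences are drawn i.i.d. per residue
from the class profile — justified because every feature the classifier
consumes is composition- or window-average-based, so positional structure
would not change the learning problem. Lengths are uniform on [60, 250],
a typical PrLD span. Default dataset size is 32 positives + 32 negatives,
matching the standard training condition of the protocol.

**What passing tests show and do not show.** The synthetic classes are
cleanly separated in feature space by construction, so near-perfect
held-out accuracy on generated data demonstrates that the pipeline
(featurization → scaling → training → thresholding) is implemented
correctly and is stable across randomizations — not that real PrLDs are
classified with that accuracy. Real recruited/non-recruited domains
overlap in all three features, and the generator does not emulate that
overlap, nor positional effects such as localized aggregation hot spots.

## Numerical and design choices

- Non-canonical residues (X, B, Z, U, \*) are rejected at parse time with
  record and position named, because no downstream feature is defined for
  them; `--skip-invalid` drops offending records with a warning instead.
- Sequences shorter than the scoring window are rejected with a clear
  length error.
- Labels travel in a separate two-column TSV (`id<TAB>label`) rather than
  being encoded in FASTA headers, keeping the FASTA standard-compliant.
- NCPR is fed to the network as a raw fraction; the model's input-scaling
  layer makes the choice of ×100 vs raw immaterial to the decision
  function.
- Model bundles serialize to a single versioned JSON document (layer
  sizes, row-major weights, biases, input scaling, normalization bounds,
  feature configuration, training-config echo); loading validates the
  version and structure and round-trips byte-identically.
- All randomness flows through seeded NumPy generators; duplicate runs
  with one seed produce byte-identical artifacts.

## Problem sizes

The test suite and the acceptance script work at the protocol's native
scale: datasets of 64 sequences (32+32), five replicate train/evaluate
cycles, gradient checks on a 3-5-3-1 network (42 parameters), and
exact Mann–Whitney enumeration up to a combined n of 12. The full suite
runs in a few seconds.

## Known limitations

- The a3v scale transcription and the pKa table are configuration data;
  other published tables will shift Na4vSS and NCPR values (though the
  trained bundle pins the values it was fitted with).
- The normalization anchors are data-derived; a model trained on a
  narrow Na4vSS range will clamp extreme query sequences to 0 or 1.
- No confidence intervals on AUC and no cross-validation: the protocol
  uses a single stratified split, repeated only via seeds.
- Predictions for organisms with divergent PrLD composition inherit the
  generator's and the training data's compositional assumptions.
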