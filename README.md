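# sgnn

Prediction of whether a prion-like domain (PrLD) is recruited into stress
granules (SG) upon heat stress, from three sequence-derived biophysical
features feeding a small feed-forward neural network.

PrLDs are low-complexity, intrinsically disordered protein regions
compositionally similar to yeast prion domains. Under heat stress some of
them coalesce into stress granules — membraneless condensates of proteins
and stalled mRNAs. Recruitment correlates with three simple properties of
the domain sequence:

1. **Aggregation propensity.** Each residue carries an intrinsic
   aggregation-propensity value *a3v*; a sliding window averages these into
   per-position values *a4v*, and the length-normalized summary
   `Na4vSS = mean(a4v) × 100` condenses the profile into one number, which
   is min–max normalized between the least and most aggregation-prone
   reference PrLDs.
2. **Net charge per residue (NCPR).** Summed Henderson–Hasselbalch
   fractional charges at a given pH (default 7.0) divided by sequence
   length: basic groups contribute `+1/(1+10^(pH−pKa))`, acidic groups
   `−1/(1+10^(pKa−pH))`.
3. **Cysteine percentage**, `100 × count(C) / length`, a proxy for
   disulfide-bonding potential under oxidative stress.

The classifier is a multilayer perceptron (3 inputs → 9 → 6 → 1, tanh
activations) trained by batch gradient descent with momentum and an
adaptive learning rate ("gdx"): the learning rate grows when the
sum-of-squared-errors falls and shrinks — with the step rejected — when the
error grows beyond a tolerance ratio. Targets are encoded −1/+1 and the
decision threshold is 0 on the output activation.

The package also ships the full evaluation machinery (confusion counts,
sensitivity/specificity/precision/accuracy/F1/MCC, ROC with trapezoidal
AUC, a two-tailed Mann–Whitney U test, stratified 50/50 splitting) and a
seeded synthetic PrLD generator, so training and evaluation are fully
exercisable without external data.

Input sequences must already be delimited PrLDs; the tool does not extract
PrLDs from full-length proteins (use PLAAC, PAPA, PrionScan or PrionW for
that).

## Worked example

Generate a synthetic labeled dataset (32 recruited + 32 non-recruited
PrLDs), train with a stratified 50/50 held-out split, and predict:

```sh
sgnn simulate -o demo/data --seed 7
sgnn train demo/data/sequences.fasta demo/data/labels.tsv -o demo/run --seed 7
sgnn predict demo/data/sequences.fasta demo/run/model.json -o demo/pred
```

The training run logs

```
INFO sgnn: split: train 32 (16+/16-), test 32 (16+/16-)
INFO sgnn: training stopped after 20 epochs (goal reached), final SSE 0.008852
```

and writes `demo/run/metrics.json` with the held-out test performance:

```json
{
  "auc": 1.0,
  "counts": {"fn": 0, "fp": 0, "tn": 16, "tp": 16},
  "metrics": {"accuracy": 1.0, "f1": 1.0, "mcc": 1.0,
              "precision": 1.0, "sensitivity": 1.0, "specificity": 1.0}
}
```

On this synthetic dataset the two compositional classes are cleanly
separable, so the network classifies the 16 positive and 16 negative
held-out PrLDs perfectly (all 32 on the diagonal of the confusion matrix,
AUC 1.0). `demo/pred/results.tsv` holds one row per input sequence:

```
id        agg_raw  agg_norm  ncpr       cys_pct   score     label
pos_0001  17.0766  0.85086   0.0136815  0.833333  0.998539  positive
pos_0002  1.3492   0.688423  0.0236773  1.67598   0.997864  positive
```

`agg_raw` is the Na4vSS score, `agg_norm` its normalized value in [0, 1],
`score` the raw network output in (−1, 1); `label` is positive when the
score reaches the decision threshold. A JSON mirror of the table
(`results.json`) is written alongside, matching the original web server's
download contract. Every command is seed-reproducible: rerunning with the
same inputs and `--seed` produces byte-identical outputs.

The same pipeline is available as a library:

```python
from sgnn import (GeneratorConfig, TrainConfig, default_feature_config,
                  evaluate_predictor, fit_pipeline, generate_dataset,
                  stratified_split)

ds = generate_dataset(GeneratorConfig(seed=7))
train, test = stratified_split(ds, 0.5, seed=7)
bundle, report = fit_pipeline(train, default_feature_config(), TrainConfig(seed=7))
counts, metrics, roc = evaluate_predictor(bundle, test)
```

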