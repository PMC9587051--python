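# estrocycle

Automated estrous-stage classification from rodent vaginal cytology.

The rodent estrous cycle (~4–5 days; diestrus → proestrus → estrus →
metestrus) is usually staged by inspecting the proportions of leukocytes,
cornified epithelial and nucleated epithelial cells in a vaginal smear — a
manual procedure that is slow and varies between examiners. `estrocycle`
is a toolkit for researchers who want that staging automated and
reproducible: a preprocessing and augmentation pipeline for cytology
images, a pluggable softmax stage classifier with the transfer-learning
training schedule, a Confidence Index on every prediction, an
archetypal-cycle fitter that exploits the temporal structure of sequential
samples, detectors for pseudopregnancy/anestrus, and the standard
evaluation machinery (confusion matrices, one-vs-rest ROC, bootstrap,
Fisher's exact comparisons, grouped k-fold out-of-sample testing). A
seeded synthetic cytology generator makes the whole pipeline testable
end-to-end with no data download.

Core quantities:

- **Confidence Index** over the softmax output
  `CI = (P_max − P_max−1) / (P_max + P_max−1)` — 1 when all probability
  mass is on one stage, 0 when the top two stages tie. Predictions with
  CI < 0.30 that also disagree with the fitted cycle trigger a
  transition-stage suggestion.
- **Archetypal cycle**: a periodic waveform with period T = 4.8 days
  through the stage midpoints of the numeric encoding D = 0.5, P = 1.5,
  E = 2.5, M = 3.5 (0.0 ≡ 4.0 = metestrus/diestrus boundary). A sequence
  of classifications (t_i, s_i) is fitted by maximizing the Pearson
  correlation r(φ) between s_i and the waveform at t_i + φT over the
  phase grid φ ∈ {0.0, 0.1, …, 0.9}; samples deviating from the fitted
  waveform by more than 1.0 stage units (circular distance) are flagged
  as outliers.
- **Step-decay schedule**:
  `lr(epoch) = max(lr_floor, lr0 · drop^⌊epoch/epochs_drop⌋)` with
  RMSprop (ρ = 0.99), minibatches and per-epoch shuffling.

## Worked example

```python
import numpy as np
from estrocycle import (
    classifier, fit_cycle_phase, generate_dataset, simulate_stage_sequence,
    SequenceSpec, split_dataset,
)

# 1. a balanced synthetic dataset: 200 images per stage, seeded
manifest = generate_dataset(200, out_dir="scratch/demo", seed=0)
split = split_dataset(manifest, seed=0)          # stratified 80/10/10

# 2. train the bundled CNN with the step-decay schedule
cfg = classifier.smallcnn_config(seed=0)
trained = classifier.train(classifier.build_model(cfg), split, cfg)
print([round(h["val_accuracy"], 3) for h in trained.history])

# 3. classify held-out images
results = classifier.classify_manifest(trained, split.test.subset(range(3)))
for r in results:
    print(r.stage, round(r.confidence_index, 3))

# 4. fit the archetypal cycle to a 10-day sequence of labels
times, _, labels = simulate_stage_sequence(SequenceSpec(n_days=10, true_phase=0.3, seed=1))
fit = fit_cycle_phase(times, labels)
print(round(fit.best_phase, 1), round(fit.pearson_r, 3))
```

Output:

```
[0.875, 0.925, 0.9]
diestrus 0.983
diestrus 0.861
diestrus 0.917
0.3 1.0
```

The history line shows validation accuracy over the three epochs as the
learning rate steps down. Each classification carries its stage and
Confidence Index (high CI = an unambiguous smear). The cycle fit
recovers the true phase (0.3 cycles) exactly on this noiseless sequence
(r = 1.0); on real sequential data the same call flags samples that
contradict the animal's cycle position.

A thin CLI mirrors the library for shell use:

```bash
estrocycle generate --n-per-stage 50 --seed 0 --out data/
estrocycle split --manifest data/manifest.csv --seed 0 --out splits/
estrocycle train --train-manifest splits/train.csv --val-manifest splits/validation.csv --out model/
estrocycle classify --model model/ --manifest splits/test.csv --out results.json
estrocycle cyclefit --results results.json --times splits/test.csv --out fit.json
estrocycle evaluate --results results.json --truth splits/test.csv --out report.json
```

See `examples/` for one short narrative script per capability and
`docs/methods.md` for the model, its assumptions and the design
decisions.

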