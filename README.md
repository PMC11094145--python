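# dabis

Audit **data-acquisition-bias-induced shortcut learning (DABIS)** in
classifiers of unstructured clinical data — images, physiological
signals, small volumes, free text — and report a **bias-corrected
estimate of external-site performance without any external data**.

## The problem

Large clinical datasets are mostly assembled *passively*, from routine
care across many acquisition pathways. Scanner settings, hardware and
protocols then correlate with disease labels through the care pathway,
and deep models readily exploit these acquisition fingerprints —
typically first-order histogram shifts in brightness, contrast or noise
— as shortcuts. The model looks accurate on its own held-out split and
loses a large fraction of that accuracy at any other site, where the
fingerprints differ.

## The method

Randomly permuting all elements of each sample along its structured
axes (pixels of an image, timesteps of each ECG lead, words of a note
and letters within each word) destroys structural and semantic features
while leaving every per-channel value histogram exactly intact.
Channels are never mixed, since each lead or channel carries its own
acquisition bias. A model trained **and** evaluated on shuffled data can
therefore only have learned histogram-level signal — exactly the
feature family acquisition bias lives in.

The audit trains the same architecture twice on one dataset:

* `P_Source` — test AUROC after normal training;
* `P_DABIS` — test AUROC after training on per-epoch-reshuffled data
  (evaluation splits are shuffled once, with a fixed seed);

and reports the calibrated external estimate

```
P_Est = P_Source − P_DABIS + Ō
```

where `Ō` is the performance of a purely random model (0.5 for AUROC).
The same pointwise correction applied to the ROC curves yields a
calibrated ROC curve. All AUROCs are one-vs-rest averages for
multi-class problems, with 95% percentile intervals from 1000
sample-level bootstrap resamples. Splits are always made at the patient
level.

Because no external data exists to validate against in the intended use
case, the package ships a two-site simulator whose ground truth is
known by construction: a structural class signal (constant-area bar
orientation in images, constant-width pulse position in signals) that
is exactly invisible to histogram features, plus per-(site, class)
histogram offsets and noise-scale factors. A pure offset bias `β` over
`N` elements with noise `σ` has a closed-form best histogram AUROC,
`Φ(β√N/(σ√2))`, which the generator records and a histogram-only
logistic baseline verifies.

## Worked example

Audit a simulated source hospital whose images carry a subtle
structural disease signal plus a class-correlated brightness offset of
0.057 (≈ 6% of the pixel noise — invisible to the eye), then check the
estimate against a second, unbiased site:

```python
from dabis import (ShuffleSpec, TrainConfig, estimate_external_accuracy,
                   external_validate, generate, model_factory)
from dabis.synthetic import mixed_two_site_config

source, external, truth = generate(mixed_two_site_config(seed=0))

train = TrainConfig(max_epochs=20, patience=5, seed=0)
factory = model_factory("small_cnn2d", (1, 32, 32), n_classes=2, seed=0)
audit = estimate_external_accuracy(source, factory, train,
                                   ShuffleSpec(base_seed=0))
p_ext = external_validate(audit, external)
shuf = external_validate(audit, external, shuffled=True)

fmt = lambda e: f"{e.value:.2f} [{e.ci_low:.2f}-{e.ci_high:.2f}]"
print(f"P_Source      = {fmt(audit.p_source)}")
print(f"P_DABIS       = {fmt(audit.p_dabis)}")
print(f"P_Est         = {fmt(audit.p_est)}")
print(f"P_Ext         = {fmt(p_ext)}")
print(f"Shuffled Ext. = {fmt(shuf)}")
```

which prints (formatted as `value [95% CI]`):

```
P_Source      = 0.85 [0.79-0.91]
P_DABIS       = 0.86 [0.79-0.92]
P_Est         = 0.49 [0.40-0.58]
P_Ext         = 0.63 [0.58-0.67]
Shuffled Ext. = 0.49 [0.45-0.54]
```

Reading: the source model's held-out AUROC (0.85) is almost entirely
reproduced after shuffling (0.86) — it leaned on the brightness
shortcut, not the anatomy. At the unbiased external site it actually
scores 0.63: conventional reporting overestimates by 22 points, while
the calibrated estimate (0.49) is 14 points low — closer, and on the
conservative side. The shuffled-source model scores at chance on
shuffled external data, confirming the learned shortcut does not
transfer.

## Command line

```sh
dabis simulate  --config sim.yaml --out data/
dabis shuffle   --in data/source_manifest.csv --modality image2d --out shuffled/ --seed 1
dabis audit     --manifest data/source_manifest.csv --modality image2d \
                --model small_cnn2d --out audit.json
dabis external  --audit audit.json --manifest data/external_manifest.csv [--shuffled]
dabis calibrate --results table.csv --out calibrated.csv
dabis report    --results calibrated.csv
```

Audit reports are JSON and embed configuration, seeds and per-epoch
validation traces, so every number is reproducible.

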