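# bgaudit

**Does the background of your microscopy dataset leak the class label?**

`bgaudit` audits the informativeness of the *surroundings* of annotated
cells in leukocyte microscopy (e.g. acute lymphoblastic leukemia blood-smear
benchmarks).  Every annotated lymphocyte is covered with a black rectangle,
each image is reduced to the 30-bin density distribution of a single color
channel (obfuscated pixels excluded), and the distributions are classified
healthy-vs-sick.  If background-only features classify well above chance,
the dataset's backgrounds carry label information — a warning sign that
models trained on it (deep networks included) may be exploiting
dataset-specific background artifacts rather than cell morphology.

## Method

For an image with pixel values of one channel binned into a density vector
*P* (30 equal-width bins over the channel's full range; hue is kept on the
half-degree scale [0, 180)), three families of classifiers are applied:

1. **Divergence to class representatives.**  Training images are averaged
   per class into representatives *M₀* (healthy) and *M₁* (sick).  For a
   divergence *d* — cross-entropy `H(P,Q) = −Σᵢ Pᵢ log Qᵢ` or summed
   squared error `MSE(P,Q) = Σᵢ (Pᵢ−Qᵢ)²` — the divergences of all training
   samples to each representative are summarized by means and standard
   deviations (m₀, s₀, m₁, s₁), and a test sample is labeled sick iff

   `(d(P, M₁) − m₁)/s₁ < (d(P, M₀) − m₀)/s₀`.

2. **Shannon entropy alone.**  `H(P) = −Σᵢ Pᵢ log Pᵢ` (reported normalized
   by log 30) is used as the single feature of a logistic regression —
   a test of whether mere color dispersion separates the classes.

3. **ML baselines.**  XGBoost and logistic regression on the raw 30-bin
   vector.

Each configuration — channel (R, G, B, H, S, V) × obfuscation state ×
optional augmentation (Gaussian blur, median blur, multiplicative Gaussian
noise, applied *before* obfuscation) — is scored by accuracy and per-class
F1 averaged over 30 random 2/3-train / 1/3-test splits.

A built-in synthetic generator renders balanced blood-smear-like datasets
(central annotated lymphocyte blob, unannotated erythrocyte-like
distractors, background hue drawn from class-conditional von Mises
distributions), so the whole pipeline is testable without access to a
restricted clinical benchmark.  Real datasets load from an image directory
with a bounding-box CSV sidecar (the ALL-IDB2 `ImXXX_Y` file-name label
convention is also understood).

## Worked example

```python
from bgaudit import ExperimentConfig, SyntheticSpec, generate_dataset, run_experiment

images = generate_dataset(SyntheticSpec(seed=0))   # 260 images, 130 per class
cfg = ExperimentConfig(channels=["H"], obfuscate=[True],
                       classifiers=["mse", "shannon_logreg"], n_repeats=30)
res = run_experiment(images, cfg)
print(res.summary[["channel", "classifier", "accuracy", "accuracy_std"]])
```

```
  channel      classifier  accuracy  accuracy_std
0       H             mse       1.0           0.0
1       H  shannon_logreg       1.0           0.0
```

Both background-only classifiers are perfect on this synthetic contrast
(hue means 60° apart, sick backgrounds more dispersed): the background
alone fully determines the class, which is exactly the pathology the audit
is designed to expose.  The entropy table (`analysis/03_…`) shows why the
single-feature classifier works — obfuscated background hue entropy is
0.602 ± 0.007 for healthy vs 0.756 ± 0.014 for sick images.

The numbered scripts under `analysis/` run the full study on synthetic
data and write their tables to `results/`:

```sh
python analysis/01_generate_dataset.py      # render + save the dataset
python analysis/02_background_divergence.py # divergence grid (channels × obfuscation)
python analysis/03_entropy_informativeness.py
python analysis/04_ml_baselines.py
python analysis/05_augmentation_influence.py
```

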