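# gaborvessel

Detection and segmentation of vessel-like structures in angiogram-style
grayscale images, built around three ideas:

1. a **single-scale Gabor filter bank** — a Gaussian envelope modulated by a
   cosine, `g(x, y) = 1/(2π σx σy) · exp(−(x²/σx² + y²/σy²)/2) · cos(2π f0 x)`,
   rotated into κ evenly spaced orientations on [−π/2, π/2); each pixel keeps
   the maximum response over orientations.  The bank has two free
   parameters: the average vessel thickness τ (pixels, with
   σx = τ/(2√(2 ln 2)) so τ is the cross-sectional FWHM) and the elongation
   l (σy = l·σx);
2. the **Boltzmann univariate marginal distribution algorithm (BUMDA)**, an
   estimation-of-distribution optimizer that tunes (τ, l) by maximizing the
   area A_z under the ROC curve of the training responses.  Each generation
   it selects the elite set S above a nondecreasing threshold φ, fits one
   Gaussian per parameter with Boltzmann weights ḡ(xᵢ) = g(xᵢ) − g(worst) + 1,

       μ = Σ ḡ(xᵢ) xᵢ / Σ ḡ(xᵢ),   v = Σ ḡ(xᵢ)(xᵢ − μ)² / (1 + Σ ḡ(xᵢ)),

   samples the next population from N(μ, v) and stops when v ≤ v_min —
   typically an order of magnitude fewer fitness evaluations than the
   16 × 43 = 688-cell exhaustive grid over τ ∈ {1,…,16},
   l ∈ {1.3, 1.7, …, 18.1};
3. **interclass-variance (Otsu) thresholding** of the 8-bit-quantized
   response to classify vessel vs. background pixels, scored by pixel
   accuracy (TP+TN)/(TP+FP+TN+FN).

Clinical angiograms are rarely shareable, so the package ships a seeded
**phantom generator**: dark tubular structures of controlled width and
contrast on nonuniformly illuminated noisy backgrounds, with exact
ground-truth masks.  It is first-class, tested code — the whole pipeline is
developed and benchmarked against it.

## Worked example

Generate two disjoint 6-image phantom sets and run the full pipeline
(train with BUMDA, enhance and segment the test set, score it):

```sh
$ printf 'width: 96\nheight: 96\n' > phantom.yaml
$ gaborvessel simulate --out train --n-images 6 --seed 101 --config phantom.yaml
$ gaborvessel simulate --out test  --n-images 6 --seed 202 --config phantom.yaml
$ gaborvessel run train test --out results --kappa 36 --seed 0
{
  "accuracy_per_image": {
    "img_000": 0.981879,
    "img_001": 0.984592,
    "img_002": 0.970595,
    "img_003": 0.990017,
    "img_004": 0.976562,
    "img_005": 0.979058
  },
  "ell": 1.829517,
  "kappa": 36,
  "mean_accuracy": 0.980451,
  "method": "bumda",
  "n_evaluations": 265,
  "seed": 0,
  "tau": 6,
  "test_az": 0.99548,
  "train_az": 0.997059
}
```

Reading the report: BUMDA spent 265 distinct fitness evaluations (the
exhaustive grid would need 688) and selected a bank matched to τ = 6 px —
within one pixel of the phantoms' true 7-px vessel width — with elongation
l ≈ 1.83.  That bank separates vessel from background pixels on the unseen
test set with A_z = 0.995 (area under the ROC curve of the concatenated
responses), and Otsu thresholding of the responses classifies 98.0 % of
test pixels correctly.  `results/` also holds the response maps and
predicted masks (PNG), the test ROC curve (CSV), the per-generation
optimizer trace (CSV) and this report (JSON).

The same workflow is available as a library, statsmodels-style:

```python
from gaborvessel import GaborVesselModel, load_dataset

model = GaborVesselModel(load_dataset("train"), kappa=36)
results = model.fit(method="bumda", seed=0)   # or method="grid"
print(results.summary())
report = results.evaluate(load_dataset("test"))
```

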