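# fastrbf

Fast training of radial-basis-function (RBF) network classifiers for
pixel-wise organ identification in abdominal Dixon MR images, using a
core-set (minimum enclosing ball) reformulation of the training QP.

## The problem

Pixel-wise tissue classification of abdominal MR slices — liver vs.
kidney vs. everything else — is a supervised learning problem with a
very large sample count: every labelled pixel of every slice is a
training sample, so realistic studies reach tens of thousands of points.
A classical RBF network handles the nonlinearity well, but training its
output weights on the full kernel matrix stops being feasible somewhere
around 3 × 10⁴ samples. This package implements a trainer whose
per-iteration cost depends on a small *core set* of samples rather than
on n, together with the full image pipeline around it.

Each pixel is described by six features: the four Dixon channel
intensities (fat, water, in-phase, opposed-phase) after a fixed 3×3
smoothing kernel, plus the physical pixel coordinates (x, y) in mm.

## The model

An RBF network with M Gaussian hidden units maps a feature vector x to
x̃ᵢ = exp(−‖x − cᵢ‖²/δᵢ). Centers cᵢ and widths δᵢ come from fuzzy
C-means: cᵢ is the membership-weighted mean and δᵢ the
membership-weighted mean squared distance of the data to it. The output
weights are trained by an ε-insensitive, structural-risk-regularized
program

    min ‖p‖² + 2λε + (λ/μn) Σᵢ (ξᵢ² + ξᵢ*²)
    s.t. |yᵢ − pᵀφ(x̃ᵢ)| < ε + slack,

whose dual is a QP over the probability simplex in α̃ = [α; α*]:

    max 2λ[y; −y]ᵀα̃ − α̃ᵀK̃α̃ ,   α̃ ≥ 0, 1ᵀα̃ = 1,

with the augmented kernel K̃ = [[K + (μn/λ)I, −K], [−K, K + (μn/λ)I]]
and K the Gaussian base kernel on hidden representations. Adding
per-point augmentation distances Δᵢ = −K̃ᵢᵢ + η + 2λỹᵢ turns this dual
into a center-constrained minimum enclosing ball (MEB) over 2n points,
which is solved approximately by growing a core set: solve the ball on
the current subset, add the farthest point outside the (1 + ε_tol)-
inflated ball, repeat until one exhaustive scan certifies the cover.
The certified core set is typically two orders of magnitude smaller
than n. Three binary classifiers (liver–kidney, liver–other,
kidney–other) are combined by one-vs-one voting.

Because the clinical MRI used to develop this method is not publicly
available, the package ships a synthetic abdominal phantom generator
(elliptical organs, tissue-dependent channel means, Gaussian noise)
that reproduces the statistical structure of the task, so every result
can be regenerated from a seed.

## Worked example

```python
import numpy as np
from fastrbf import default_benchmark, train_ovo, predict_ovo, accuracy, TrainConfig

train, test = default_benchmark(10_000, seed=0)
model = train_ovo(train, TrainConfig(seed=0))

sizes = [clf.diagnostics["coreset_size"] for clf in model.classifiers]
acc = accuracy(predict_ovo(model, test.X), test.labels)
print(f"training pixels : {train.n}")
print(f"test pixels     : {test.n}")
print(f"core-set sizes  : {sizes} (mean {np.mean(sizes):.1f})")
print(f"test accuracy   : {acc:.4f}")
```

prints

```
training pixels : 10000
test pixels     : 16896
core-set sizes  : [41, 114, 93] (mean 82.7)
test accuracy   : 0.9559
```

Of the 10,000 training pixels, each pairwise classifier ends up
retaining only 41–114 core-set samples, yet classifies 95.6% of the
16,896 held-out pixels correctly — the regime a practitioner should
expect for moderately overlapping tissue intensities.

The same pipeline is available from the shell:

```bash
fastrbf simulate --out run_sim --seed 0
fastrbf train    --case-dir run_sim --out run_train --seed 0
fastrbf predict  --case-dir run_sim --model run_train/model.npz --out run_pred
fastrbf evaluate --pred-mask run_pred/pred_mask.png --truth-mask run_sim/truth_mask.png --out run_eval
```

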