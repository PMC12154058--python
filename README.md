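# fritqc

Chemometrics for handheld near-infrared (NIR) quality control of
*Fritillaria* bulb powder — a high-value herb whose four common species
(*F. cirrhosa*, *F. ussuriensis*, *F. pallidiflora*, *F. thunbergii*) are
morphologically similar, frequently substituted, and priced very
differently.  The package answers the two questions a market inspector with
a handheld spectrometer actually asks:

1. **Which origin is this powder?**  Four-way classification of absorbance
   spectra (900–1700 nm, 1 nm grid) with PLS-DA, SVM, decision-tree and a
   1-D CNN, compared over Monte Carlo resampling, with Grad-CAM attribution
   of the wavelengths each origin's decision relies on.
2. **How much cheap *F. ussuriensis* was blended into *F. cirrhosa*?**
   Regression of the adulteration mass fraction (0.1%–50%) with PLSR, a
   full-spectrum CNN and a PCA-reduced CNN.

Because the instrument spectra behind the workflow are not public, the
package includes a first-class synthetic generator
(`fritqc.simulate`) producing spectra with the same structure: shared
overtone bands (dominant 1450 nm water band), one class-specific marker
band per species (1575 / 1460 / 1100 / 1200 nm), batch effects,
multiplicative scatter, baseline drift and noise, plus Beer–Lambert
two-component mixtures.  Every model in the package is tested as parameter
*recovery* against this generator's known truth.

## Core methods

* **Preprocessing** — Savitzky–Golay smoothing/derivatives (window 51,
  cubic), standard normal variate (SNV), and airPLS baseline removal
  (adaptive iteratively reweighted penalized least squares on a Whittaker
  smoother).
* **Chemometrics** — mean-centred SVD PCA; NIPALS PLS for regression and
  one-hot discriminant analysis; 10-fold CV component selection with a
  one-SE rule: `ŷ = X·b + b₀`, `R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²`, RMSECV/RMSEP in
  percent.
* **CNN** — five conv blocks (16/32/64/128/256 filters, kernel 3, each
  conv→batch-norm→ReLU), max-pool ×2 after the first four blocks, global
  average pooling, dense-64 head; Adam with lr(e) = lr₀·0.8^⌊e/50⌋,
  mini-batch 10.  Implemented from scratch in NumPy (`fritqc.nn`),
  single-precision, deterministic under one seed.
* **Grad-CAM** — class-logit gradients w.r.t. the last conv block, channel
  weights = position-averaged gradients, rectified weighted sum upsampled
  to the wavelength grid; class-average-spectrum protocol with a
  consistency check (mispredicted class means are refused).

See `docs/methods.md` for assumptions, parameter tables and limitations.

## Worked example

```python
import numpy as np
from fritqc import (GeneratorConfig, simulate_adulteration_dataset,
                    split_adulteration, r_squared, rmse)
from fritqc.chemometrics import PLSModel, select_components_cv

mix = simulate_adulteration_dataset(GeneratorConfig(seed=1))   # 580 spectra
tr, te = split_adulteration(mix, seed=1)                       # 377 / 203
y = mix.labels                                                 # fractions
k = select_components_cv(mix.X[tr], y[tr], seed=1)
model = PLSModel(mix.X[tr], y[tr]).fit(k)
pred = model.predict(mix.X[te])
print(f"components={k}  R2={r_squared(y[te], pred):.4f}  "
      f"RMSEP={100 * rmse(y[te], pred):.3f}%")
```

```
components=5  R2=0.9928  RMSEP=1.182%
```

Five latent variables recover the blended mass fraction on held-out
spectra with ~1.2 percentage-point error across the 0.1–50% range — the
multiplicative scatter and baseline drift injected by the generator cost
the linear model less than one point of R².

The same experiment from the shell, including the CNN arms and the
Table-style summary (`regression_summary.csv`, residuals, PC1 loading):

```bash
fritqc adulteration --seed 1 --out runs/adult        # add --no-cnn for speed
fritqc origin --seed 1 --out runs/origin             # Monte Carlo + Grad-CAM
fritqc simulate --experiment origin --seed 1 --out origin.csv
```

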