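# chlorospec

Chlorophyll-content inversion from leaf reflectance spectra (350–2500 nm),
built for hyperspectral phenotyping of drought-stressed seedlings.

Leaf chlorophyll (mg/g fresh mass) is a standard stress indicator, but wet
assays are destructive and slow. A leaf-clip spectrometer measures
reflectance R(λ) in seconds; the green reflectance peak near 550 nm falls
as pigment rises, and the water-absorption troughs near 1440 and 1920 nm
deepen with leaf water status. This package implements the full
chemometric pipeline that turns such spectra into chlorophyll estimates
and decides *which* model to trust:

- **Preprocessing** — a registry of 21 named spectral transforms
  (derivatives R′ and R″, √R, logR, 1/R, log(1/R) and their compositions,
  SNV, MSC, FD-SNV, FD-MSC), with training-set fit contexts so MSC never
  peeks at held-out spectra.
- **Predictor construction** — all bands (AB), principal components with
  the eigenvalue > 1 rule (PCA), the ten bands most correlated with
  chlorophyll (CA), or six whole-grid bands plus two from each
  water-absorption window 1390–1490 / 1870–1970 nm (CA(W)); alternatively
  14 vegetation/water indices (GNDVI, CIgreen, …, WI, MSI) or a single
  index.
- **Regression** — PLS1 (NIPALS) in the linear form
  y = a₀ + a₁x₁ + … + aₙxₙ, with the latent-variable count chosen by
  inner cross-validation under the one-standard-error rule; ordinary least
  squares for the index models.
- **Evaluation** — 5-fold cross-validation grouped by seedling (twin
  leaves never straddle a fold) reporting R²_CV/RMSE_CV, an 80/20
  seedling-stratified hold-out reporting R²_P/RMSE_P, and per-leaf-position
  accuracy. Model ranking uses a bottleneck criterion: hold-out accuracy
  on the first pair of top leaves first, uniformity across positions
  second.
- **Synthetic study generator** — the measured study data are not public,
  so a seeded generator emulates the design (4 drought treatments × 25
  seedlings, 1–4 leaf pairs, ≈478 leaves) and the spectral physics that
  the analysis relies on. See `docs/methods.md`.

## Worked example

```python
import chlorospec as cs

spectra, truth = cs.make_fixture("study")   # 473 leaves x 2151 bands
model = cs.ChlorophyllPLS(spectra, strategy="caw",
                          transform="log(1/R)", seed=7)
res = model.fit()
print(res.summary())
```

```
Chlorophyll inversion results
==============================================
strategy:        CA(W)-PLS
transform:       log(1/R)
latent variables: 1
train/test leaves: 377/96
R2_CV  = 0.6084   RMSE_CV = 2.6430 mg/g
R2_P   = 0.6114   RMSE_P  = 2.6522 mg/g
per leaf position (hold-out):
  position 1: R2_P = 0.5440, RMSE_P = 3.3466, n = 40
  position 2: R2_P = 0.7145, RMSE_P = 1.9370, n = 29
  position 3: R2_P = 0.7075, RMSE_P = 2.0482, n = 19
  position 4: R2_P = 0.5879, RMSE_P = 2.2017, n = 8
R2_P range across positions: 0.1705
selected bands (nm): 553, 549, 556, 551, 548, 541, 1435, 1445, 1931, 1940
```

Reading it: the two-round screening picked six green-peak bands (541–556
nm, where reflectance is most correlated with pigment) plus two bands in
each water window; cross-validated and hold-out accuracy agree (no
leakage); the first pair of top leaves — the only position present in
every drought treatment, hence the most heterogeneous — is predicted
worst, which is exactly why the ranking in
`chlorospec.select_optimal` prioritizes it.

The same pipeline is scriptable:

```bash
chlorospec generate --seed 1 --out spectra.csv --truth truth.csv
chlorospec fit --strategy caw --transform "log(1/R)" --in spectra.csv \
               --report report.json
chlorospec compare --in spectra.csv --out matrix.json
```

## The published ten-band model

The reported optimal CA(W)-PLS equation is available as a frozen object:

```python
from chlorospec import PublishedModel
import numpy as np
PublishedModel().predict_values(np.zeros(10))   # -> array([2.1754])
```

Whether its band symbols denote raw reflectance or log(1/R)-transformed
values is ambiguous in the source; both interpretations are supported via
`input_transform`.

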