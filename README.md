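# nanoform

A design-of-experiments toolkit for nanoparticle formulation development:
Box–Behnken designs, quadratic response-surface models with full ANOVA,
Derringer–Suich desirability optimization with prediction-interval
validation, drug-release kinetic model fitting and selection, and the
standard formulation (encapsulation efficiency / drug loading) and
plate-assay (percent inhibition, fold potency) arithmetic.

It is written for formulation scientists who optimize lipid or polymer
nanoparticle preparations with response surface methodology (RSM) and want
the whole workflow — design generation, model fitting and reduction,
multi-response optimization, confirmation-batch validation, and release
kinetics — scripted, testable and reproducible instead of locked inside
point-and-click DoE software.

## The model

A three-factor Box–Behnken design (BBD) probes the factor cube at the 12
edge midpoints plus replicated center points.  Factor settings are coded so
low = −1, center = 0, high = +1, and each response *y* is modelled by the
second-order polynomial

```
y = b0 + bA·A + bB·B + bC·C + bAB·AB + bAC·AC + bBC·BC + bAA·A² + bBB·B² + bCC·C²
```

fit by ordinary least squares.  The ANOVA uses partial sums of squares, and
the replicated center points split the residual into lack-of-fit and pure
error.  Non-significant terms are removed by backward elimination (keeping
the model hierarchical).  Each fitted response is then mapped to a
desirability d ∈ [0, 1] (Derringer–Suich ramps: minimize / maximize /
target, with optional hard bounds such as size ≤ 200 nm), and the overall
desirability D — the importance-weighted geometric mean of the d's — is
maximized over the coded cube to find the compromise optimum.  A
confirmation batch is judged by 95 % prediction intervals
`ŷ ± t·s·√(1 + x'(X'X)⁻¹x)` and the percent error
`(observed − predicted)/predicted × 100`.

Release time courses are corrected for aliquot sampling
(`CRₙ = (Ve·Σᵢ<ₙCᵢ + Vo·Cₙ)/m × 100`), fit to five empirical kinetic models
(zero-order, first-order, Higuchi, Korsmeyer–Peppas, Hixson–Crowell) by
nonlinear least squares, and ranked by the model selection criterion
`MSC = ln(SST/SSR) − 2p/n` (equivalently AIC = n·ln(SSR) + 2p); the
Korsmeyer–Peppas exponent *n* classifies the transport mechanism
(n < 0.45 quasi-Fickian, 0.45 < n < 0.89 anomalous, n > 0.89 super case II).

## Worked example

The package ships the 15-run BBD study of a cannabidiol solid-lipid-
nanoparticle (CBD-SLN) formulation — factors glyceryl monostearate (GMS,
1.5–2.5 g), polysorbate 80 (P80, 0.6–1.0 g) and CBD (10–20 mg); responses
particle size Y1 (nm), polydispersity index Y2, encapsulation efficiency
Y3 (%) and drug loading Y4 (%):

```python
import nanoform as nf
from nanoform.datasets import load_cbd_sln_design, cbd_sln_goals

design = load_cbd_sln_design()
fit = nf.reduce_model(design, "Y4", alpha=0.05)   # drug loading
print(fit.summary())
```

```
Response surface fit: Y4
  Y4 = 1.3571 - 0.34A - 0.0312B + 0.5162C - 0.125AC - 0.0175BC + 0.0954A²

                    SS  df       MS          F        p
source
Model           3.1624   6   0.5271  2922.3472  <0.0001
A               0.9248   1   0.9248  5127.6040  <0.0001
B               0.0078   1   0.0078    43.3168   0.0002
C               2.1321   1   2.1321 11821.6139  <0.0001
AC              0.0625   1   0.0625   346.5347  <0.0001
BC              0.0012   1   0.0012     6.7921   0.0313
A^2             0.0339   1   0.0339   188.2218  <0.0001
Residual        0.0014   8   0.0002        NaN      NaN
Lack of fit     0.0010   6   0.0002     0.6973   0.6903
Pure error      0.0005   2   0.0002        NaN      NaN
Total (corr.)   3.1638  14      NaN        NaN      NaN

R-squared              0.9995
Adjusted R-squared     0.9992
Predicted R-squared    0.9978
Adequate precision     186.66
Backward elimination dropped: AB, B^2, C^2
```

Drug amount (C, +0.5162 % DL per coded unit) and lipid amount (A, −0.34)
dominate drug loading; the insignificant lack of fit (p = 0.69) says the
reduced polynomial is adequate relative to center-point noise.  Optimizing
all four responses at once:

```python
goals = cbd_sln_goals(design)   # size min (≤200 nm), PDI min, EE max, DL max
fits = [nf.reduce_model(design, g.response) for g in goals]
opt = nf.optimize_desirability(fits, goals, seed=0)
print(opt.actual, opt.predicted, opt.overall)
```

```
optimum (actual): {'GMS': 1.57, 'P80': 0.62, 'CBD': 20.0}
predicted: {'Y1': 119.552, 'Y2': 0.192, 'Y3': 94.983, 'Y4': 2.386}
overall desirability: 0.9567
```

The optimizer lands at low lipid, low surfactant and the drug amount pinned
at its +1 bound (20 mg) — small particles (≈120 nm), PDI ≈ 0.19, EE ≈ 95 %
and DL ≈ 2.4 % — with overall desirability 0.96.  A confirmation batch is
validated with prediction intervals and percent errors:

```python
pi = nf.predict_interval(fits[3], opt.coded)          # drug loading
print(pi.point, pi.lower, pi.upper)                   # 2.386 [2.345, 2.427]
print(nf.percent_error(2.36, pi.point))               # -1.08 %
```

The same workflow is available from the shell:

```
nanoform fit --factors factors.yaml --design design.csv --response Y4
nanoform run --config config.yaml --design design.csv --out report.json
nanoform release-fit --release curve.csv --select
```

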