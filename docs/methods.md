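# Methods

This note records the statistical machinery behind `nanoform`, the choices
made where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## Design generation and coding

The three-factor Box–Behnken design is generated deterministically: the 12
edge-midpoint runs grouped by factor pair in the order (1,2), (1,3), (2,3)
— each block enumerated (−,−), (+,−), (−,+), (+,+) with the remaining
factor at its center — followed by the replicated center points.  This is
the order such matrices are conventionally printed, so generated designs
diff cleanly against published tables; a randomized run order is available
from the CLI (`design --randomize --seed`) but is never the default.

Coding uses the midpoint convention: `coded = (actual − center)/half_range`
with `center = (low + high)/2` and `half_range = (high − low)/2`.  Nothing
else is defensible for symmetric low/high level pairs, and it makes all
linear and pairwise-interaction columns mutually orthogonal over the
design, which in turn makes coefficient estimates invariant to the presence
of other linear/interaction terms.  Extrapolated actual values code to
|coded| > 1 and are returned as-is rather than clamped.

## Response-surface fitting

Fitting is OLS in coded units (statsmodels provides the base solve; the
surrounding ANOVA and diagnostics are computed here).  Per-term ANOVA uses
partial (type-III) sums of squares — the increase in residual SS when the
term alone is deleted — which on the orthogonal BBD columns coincides with
sequential SS.  Replicate groups (identical coded settings) supply pure
error, `SS_pe = Σ_groups Σ(y − ȳ_group)²` with `df = Σ(n_g − 1)`, and the
residual splits into lack-of-fit and pure error; the lack-of-fit F-test is
reported whenever both partitions have positive df.

Diagnostics: R², adjusted R², PRESS-based predicted R²
(`PRESS = Σ(eᵢ/(1−hᵢᵢ))²`, which may be negative for poor models), and
adequate precision `(max ŷ − min ŷ)/√(p·MSE/n)` over the design points —
the signal-to-noise definition used by mainstream DoE software; values
above ~4 indicate a surface worth navigating.

Model reduction is backward elimination from the full quadratic: at each
step the non-significant removable term with the largest partial-F p-value
is dropped and the model refit, until everything remaining is significant
at `alpha` (default 0.05) or protected.  Hierarchy enforcement is on by
default — a retained interaction or square keeps its parent main effects —
because hierarchical polynomials remain meaningful under re-coding of the
factors.  The elimination trace is kept on the results object.

Numerical edge cases: a rank-deficient model matrix raises a singular-fit
error naming the collinear terms (greedy scan of columns against the span
of their predecessors); a constant response fits with all non-intercept
coefficients at zero, ANOVA F reported as NaN and a warning; a saturated
model (n = p) fits exactly but leaves predicted R² undefined (all hat
diagonals equal 1) and no residual df for intervals.  p-values below 1e−4
are printed as `<0.0001` in text reports; full precision is kept internally
and in JSON.

On the packaged study the refit equations agree with the published
coded-unit coefficients to well under 1 % for the size, PDI and
drug-loading models (the two-interaction drug-loading coefficients
reproduce exactly), and backward elimination at alpha = 0.05 recovers all
four published term sets.  The encapsulation-efficiency response is the
known exception: its published linear coefficients for surfactant (−2.47)
and drug (+3.10) are not recoverable from the printed (rounded, replicate-
averaged) response table, which yields −2.10 and +3.45.  The published fit
was evidently computed from unrounded raw replicates; the package reports
what the printed data imply and does not force agreement.  Printed
F-statistics from the original analysis are similarly treated as
order-of-magnitude context only.

## Desirability optimization

Individual desirabilities follow Derringer–Suich ramps with a weight
exponent (default 1, linear); hard constraint bounds (e.g. size ≤ 200 nm)
zero the desirability outright at and beyond the bound.  Ramp anchors
default to each response's observed range — the conventional default when
no explicit anchors are specified — and are fully configurable.  All
responses carry equal importance unless stated otherwise.  The overall
desirability is the importance-weighted geometric mean, so any infeasible
response vetoes the point.

The search maximizes D over the coded cube [−1, 1]³ with a full 21³
evaluation grid seeding 10 bounded Nelder–Mead polishes; the best polished
point wins, ties broken by larger D then smaller predicted first response.
The procedure is deterministic (the `seed` argument exists for interface
symmetry).  A desirability surface that is zero everywhere raises a
no-feasible-point error rather than returning an arbitrary corner.  On the
packaged study the optimum reproduces the published conditions to the
rounding the study reports for the drug amount (pinned at the 20 mg
boundary — the robust feature, since every response improves toward C = +1)
and to within ~0.03 g on the two mass factors, whose exact published
coordinates depend on anchor defaults of the original software and on the
rounding of the printed response table.

Prediction intervals for a single future observation use
`ŷ ± t_{df,(1+level)/2}·s·√(1 + x'(X'X)⁻¹x)` with `s²` the residual mean
square.  The interval is for a new measurement, not the mean response,
which is what a confirmation batch actually is.

## Release kinetics

Cumulative release applies the aliquot-replacement correction
`CRₙ = (Ve·Σᵢ<ₙCᵢ + Vo·Cₙ)/m × 100`; the first timepoint has no
correction.  Default vessel geometry (Ve = 1 mL aliquot, Vo = 200 mL
vessel) mirrors a standard dialysis-bag setup and is configurable.

All five models are fit on untransformed cumulative percents by damped
(Levenberg–Marquardt) nonlinear least squares, with starting values from
the classical linearizations (log–log regression for Korsmeyer–Peppas,
log-fraction for first-order, cube-root for Hixson–Crowell); the
linearized estimates are starting values only, never the reported fit,
because log-scale fitting reweights the residuals.  First-order and
Hixson–Crowell are anchored at 100 % release at infinite time, keeping
them single-parameter models.  t = 0 points are excluded (CR(0) = 0 by
construction); points may arrive in any order.  A non-convergent fit
returns the linearized estimate flagged as not converged rather than
raising.

Comparison statistics are the unit-weight forms `AIC = n·ln(SSR) + 2p` and
`MSC = ln(SST/SSR) − 2p/n` (so `MSC = −ln(1−R²) − 2p/n` identically);
selection ranks by MSC descending with ties (ΔMSC < 1e−9, including two
perfect fits) going to the model with fewer parameters.  The
Korsmeyer–Peppas fit uses all supplied points by default; restricting to
the early portion of the curve (CR ≤ 60 %) is a documented option left
off, matching practice when the full 24 h profile is modelled.  Exponent
classification applies the standard thresholds with a 1e−9 equality
tolerance.

## Formulation and bioassay arithmetic

`EE = (Wt − Ws)/Wt × 100` and `DL = (Wt − Ws)/Wnp × 100`, so
`EE·Wt = DL·Wnp` identically and both are invariant to the shared mass
unit.  Colloidal thresholds (PDI ≤ 0.3 acceptable, PDI > 0.7 aggregation-
prone per ISO guidance, |ζ| ≥ 30 mV for electrostatic stability) are
stored in a configurable `Thresholds` object with inclusive comparisons at
the stated bounds.

Plate signals are normalized to the stimulated-control mean
(percent-of-control level), inhibition is `100 − level`, and fold potency
is the ratio of residual levels (reference/test) — the definition under
which a 77 % vs 62 % pair reads as 1.2-fold, consistent with how such
figures are quoted; the inhibition-ratio alternative (which would give
1.65 here) is deliberately not used.  Replicates aggregate as mean ± SD
with n; a Welch t-test is provided as a convenience for two-group
comparisons, with full ANOVA/post-hoc machinery out of scope.

## Synthetic data

Generators exist so every stage is testable without any instrument data,
and each is a pure function of (parameters, seed) via
`numpy.random.default_rng` — no global state.  Surfaces add Gaussian noise
to a known coded-unit polynomial; release curves evaluate a kinetic model,
clip at the physical 100 % bound, optionally back-convert to the
concentrations an experimenter would record under aliquot replacement
(making `cumulative_release` an exact inverse at σ = 0), then add Gaussian
noise; plates draw unit-mean lognormal replicate noise at a given CV.
Default noise scales imitate replicate scatter typical of DLS/UV readouts
(a few nm on size, a few tenths of a percent on EE); they are modelling
defaults, not measurements.

What the generators do **not** emulate: heteroscedastic noise across the
design (real size SDs grow with size), run-order drift, correlated
responses from shared preparations, plate edge effects, or any nanoparticle
physics (nucleation, ripening).  Passing tests therefore demonstrate
correctness of the estimators under their stated assumptions, not
robustness to every pathology of real instrument data.

## Problem sizes in the tests

The seeded simulation studies use sizes chosen to make Monte-Carlo error
comfortably smaller than the tolerances they check: 500 replicates for
coefficient-bias checks (bias bound 3 SE of the mean), 1000 replicates for
95 % prediction-interval coverage (binomial SE ≈ 0.7 %, asserted within
±2 %), 200 noisy curves for Korsmeyer–Peppas exponent recovery (median
|n̂ − n| < 0.02 at σ = 1 %), and 1000 plates for assay-level unbiasedness
(within 1 %).  The whole suite runs in a few minutes on a single core.

## Known limitations

- Only the 3-factor BBD is generated (central-composite, Plackett–Burman
  and larger designs are out of scope); the RSM fitter itself accepts any
  3-factor coded design table.
- No response transformations (Box–Cox) or GLMs; responses are modelled on
  their measured scale.
- Desirability search is local-polish-over-grid, adequate for smooth
  quadratics on a cube; no global or Pareto multi-objective machinery.
- Weibull, Gompertz and Peppas–Sahlin release models are not included.
- Standard-curve quantitation (4PL) and EC50 estimation are out of scope
  for the assay module.
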