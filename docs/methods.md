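# Methods

`socmap` implements a digital-soil-mapping (DSM) workflow for predicting
soil-organic-carbon (SOC) stocks of the organic layer in a data-poor,
topographically complex landscape: predictors are derived from a 30 m
DEM and a multispectral scene, five machine-learning regressors are
compared under repeated tenfold cross-validation, predictor subsets are
chosen by wrapper selection, and the final model is mapped with a
cellwise uncertainty surface.  This note records the models, the
defaults and the design choices made where the design was genuinely
open.

## Predictors

### Spectral chain

Digital numbers are calibrated per band by affine transforms
(`spectral.LANDSAT8_TRANSFORMS` carries the coefficients of the Landsat
8 OLI/TIRS scene the workflow was designed around; the TIRS rows are
plain linear transforms — no Planck brightness-temperature inversion is
applied).  Four indices are computed from reflectance:

* NDVI = (NIR − R)/(NIR + R) and NDMI = (NIR − SWIR1)/(NIR + SWIR1);
* PVI = (NIR − β₁R − β₀)/√(β₁² + 1) and
  TSAVI = β₁(NIR − β₁R − β₀)/(β₁NIR + R − β₁β₀ + X(1 + β₁²)),
  both built on the *soil line* NIR = β₁·R + β₀ of bare soil, with the
  soil-adjustment constant X = 0.08 by convention.

The soil line is estimated automatically as a lower-envelope
regression: the red range is split into equal-width bins (default 20),
the minimum NIR per bin is taken as a bare-soil candidate, and an
ordinary least-squares line through the bin minima gives (β₁, β₀).
Vegetated pixels lie above the envelope and drop out by construction.
Both PVI and TSAVI are exactly zero on the soil line for any (β₁, β₀),
which is the invariant the tests enforce.

### Terrain chain

Every terrain attribute derives from a local bivariate quadratic
z = au² + bv² + cuv + du + ev + f fitted by least squares over a
circular neighborhood of *search radius* r (u east, v north, meters).
Slope, aspect and six curvatures follow the Evans/Wood quadratic-fit
family; the exact formulas, including the slope-normalized plan and
profile forms, are stated in `terrain.py`'s module docstring and are
validated against closed forms on polynomial surfaces (a global
quadratic is scale-invariant, so every radius must reproduce the same
derivatives — a strong test of the window algebra).  Sign conventions:
aspect is the downslope azimuth clockwise from north, flat cells are
masked (gradient below 1e-10, which only ever captures numerical
noise); a bowl has positive minimum curvature.

The convergence index averages, over all cells within the radius, the
absolute angular difference between each cell's aspect and the azimuth
from that cell toward the center, minus 90: −90 at a symmetric pit, 0
on a plane, +90 at a peak.  The ±90 scaling is fixed here (GIS
implementations vary).  The terrain ruggedness index is the RMS
elevation difference to the neighborhood.

Radii default to 45–615 m in 30 m steps (20 scales), mapping to
3×3…41×41 windows at 30 m cells via window = 2·floor(r/cs)+1; windows
are circular (all cells whose center lies within r).  Layers are named
`param@radius`; border cells within floor(r/cs) cells of the edge are
masked.  No parity with any particular GIS package is targeted — the
formulas are fixed and tested against analytic surfaces instead.

## Learners

All learners see minmax-normalized predictors and response (z-score
available; the choice is configurable because reported normalized
errors are most naturally read as fractions of the response range).
Family defaults:

| family | fixed settings | tuned |
|---|---|---|
| rf | 1000 trees, mtry = max(1, ⌊p/3⌋), node size 5, bootstrap n with replacement | — |
| ann | 1 hidden layer, tanh, L2 weight 1e-3, L-BFGS (deterministic under seed) | neurons 1–20 |
| mars | forward pass only, degree 2 | terms 1–50 |
| brt | shrinkage 0.001, bag fraction 0.90, depth 2, node size 5 | iterations ≤ cap (500; 10,000 for final fits) |
| svr | RBF kernel, ε = 3σ(y)√(ln n/n) from each training response | C 0.1–1.0 step 0.1, γ 0.2–0.5 step 0.05; extended 1e-3–1e4 log grid available |

Additional diagnostic baselines: `ridge` (deterministic linear model,
small fixed L2) and `constant` (training mean — the analytic null whose
CV RMSE equals the held-out response sd in expectation).  They anchor
the validation machinery and serve as fast stand-in learners in
selection experiments; they are not part of the five-way comparison.

The ANN is trained by L-BFGS with a fixed L2 penalty rather than a
Bayesian-evidence procedure: the contract is "single hidden layer +
L2 regularization, deterministic under seed", which is what the
downstream machinery relies on.  In untuned (screening) mode the
defaults are neurons = 5, MARS terms = 21, BRT iterations = 500 (its
base cap), SVR C = 1.0 / γ = 0.35 (grid midpoints).

MARS is implemented natively (`MarsForward`) because the forward-only
variant is compact and exactly testable: starting from the intercept,
hinge terms (x−t)₊ / (t−x)₊ (or degree-2 products with an existing
term; no variable twice in one term) are added greedily by largest RSS
reduction under full least-squares refit, with knots at training
values.  Candidates are scored against an incrementally maintained
orthonormal basis (one projection per candidate, no per-candidate
solve); the final basis is refitted exactly.  Because the greedy path
is nested, one fit at the term cap scores every smaller term count —
the "staged" tuner exploits this, as does the equivalent
`staged_predict` path for BRT iteration counts.  Exactness guarantees
(frozen in tests): y = max(x−0.5, 0) with the knot in the data is
reproduced to RSS < 1e-20; a 1-term model predicts the response mean.

The SVR ε heuristic's σ is best read as a noise-scale estimate; on
noiseless data it overestimates the tube width and caps attainable
accuracy near ε/√3, so interpolation tests pin ε explicitly.
Likewise BRT at shrinkage 0.001 leaves roughly (1−0.001)^500 ≈ 61% of
the signal unlearned after 500 iterations and needs the 10,000 cap to
converge — the motivation for widening tuning ranges after a first
screening pass, and a property the tests assert rather than hide.

## Cross-validation and tuning

The model criterion is the arithmetic mean of held-out RMSEs over five
repetitions of a tenfold cross-validation (50 fold RMSEs), computed on
the normalized response scale (the denormalized value is also exposed —
both scales are emitted because either reading of a normalized error is
defensible).  Folds are balanced (sizes differ by ≤1), drawn uniformly
at random, with an independent child seed per repeat so repeats can be
evaluated concurrently with results identical to serial execution.
Failed folds are excluded from the mean and counted; a result with
>20% failures is marked invalid.

Tuning modes:

* **none** — fit the fixed defaults (candidate screening);
* **flat** — grid-tune on the same fold plan and score the tuned
  settings (the budget-matching reading of tuning-by-external-CV);
* **nested** — re-tune inside every outer training split on an inner
  repeated-CV plan (2 inner repeats by default for runtime); the inner
  plan never contains the outer held-out fold, an invariant the tests
  assert directly.

Ties in a tuning grid resolve toward the simpler model (fewer
neurons/terms/iterations, smaller C).

## Predictor selection

Three wrapper strategies share the machinery:

1. **Ranking / 10bestPR** — every predictor is scored by its
   one-predictor model's mean repeated-CV RMSE; the 10bestPR model uses
   the ten best-ranked predictors.
2. **sFS** — greedy forward selection from the best-ranked predictor;
   at each step the best-scoring addition is accepted if it improves
   the mean RMSE by more than δ.
3. **3stepFS** — sFS alternated with a greedy backward subset step
   (repeatedly drop the member whose removal most improves the RMSE)
   until a full forward+backward cycle accepts nothing.  The backward
   step may eject the starting predictor.  By construction the final
   RMSE is never above the plain sFS result.

Open-design choices, fixed here: all candidate evaluations in one run
share a single fold plan (so RMSE differences reflect predictors, not
fold luck); the ranking is computed once, not re-ranked between cycles;
the backward step is greedy elimination to a fixed point, not
exhaustive subset search (exhaustive search over hundreds of predictors
is exactly what wrapper forward selection exists to avoid); ties break
lexicographically on predictor id; δ defaults to 0 (strict improvement)
and is configurable.

δ deserves a number: evaluating ~50 candidates per step on a shared
plan and keeping the best is a maximum over correlated noisy estimates,
so at n = 60 the best *noise* candidate typically "improves" the mean
RMSE by a few 1e-3 even when genuinely uninformative.  The shipped
recovery experiments use δ = 2e-3, which damps most of that selection
noise while passing genuine signal of the size the weak-signal regime
produces; at δ = 0 the trace is still monotone but longer and noisier.

## Synthetic landscape

The generator stands in for undeposited field data and defines the
study conditions:

* **DEM** — ridge/valley sinusoids plus smoothed Gaussian noise, scaled
  to a relief amplitude (default 600 m over a 80×80 grid of 30 m
  cells), seeded and reproducible.
* **Bands** — red reflectance decreases monotonically with elevation;
  NIR is the planted soil line (β₁ = 0.71, β₀ = 0.11) applied to red
  plus a vegetation uplift damped above the tree line, so bare-soil
  cells sit on the line and the soil-line fitter can recover it to
  ±0.02; SWIR1 decreases with vegetation moisture.  With band noise
  zero the bands collapse to pure functions of elevation.
* **Stand-in predictors** — smoothed random fields with a controllable
  correlation to the DEM play the statistical role of the many
  additional GIS terrain variables (wetness, openness, insolation...)
  without reimplementing them, and let the predictor count grow toward
  the ~236 of a full study.
* **Sampling** — 20 transects × 3 slope positions = 60 points; each
  transect runs from a high-elevation cell toward a low one with one
  random position per third, emulating a ridge-to-valley design.
* **Response** — a weighted sum of the informative predictors'
  sample-standardized values (optionally plus pairwise products) with
  additive Gaussian noise, affinely mapped so the sampled stocks span
  0.2–17.7 kg m⁻².  Standardizing over the *sample* (not the grid)
  makes each weight contribute its nominal share of signal variance
  under the realized design.  The noise sd defaults to the value that
  sets the population R² to 0.5 — the weak-signal regime the workflow
  is aimed at — and the closed form R² = s²/(s² + σ²) is recorded in
  the truth record and checked against the empirical value.

What the generator does *not* emulate: hydrological realism, spatially
structured response noise, measurement error in the predictors, and
land-use heterogeneity.  Passing recovery tests therefore show that the
selection machinery behaves correctly under known weak linear signal —
not that any particular real landscape is predictable.  One lesson from
building the test bed is worth recording: with heavily smoothed noise
fields and 60 spatially clustered samples, "noise" predictors carry
genuine within-landscape information (the effective sample size is far
below 60) and *no* selector can reliably separate 3 planted predictors
from 47 confounders; the shipped recovery fixture therefore uses
near-white stand-in fields (smoothing 0.5 cells, zero DEM correlation).
Real predictor stacks behave like the smooth case — a reason to expect,
and tolerate, correlated surrogates in selected sets on real data.

## Ensemble mapping

The final model is not refitted once: one member is trained per
(repeat, fold) training split of the CV plan — 50 members under the
default 5×10 plan — and the map reports the cellwise median (the
SOC-stock estimate, kg m⁻² after denormalization) and the
interquartile range Q3−Q1 (linear interpolation between order
statistics) as the uncertainty surface.  This defines the per-cell
predictive distribution as the spread of CV-trained models, a
reproducible choice among several defensible ones (a bootstrap ensemble
would be the obvious alternative and is not implemented).  Cells masked
in any input predictor are masked in the map.

## Numerical and I/O details

* GeoTIFF I/O is built on tifffile with the ModelPixelScale,
  ModelTiepoint and GDAL-nodata tags: single band, square cells,
  projected meters, upper-left origin, no reprojection or CRS handling.
* Cell convention: row-major from the north-west corner, half-open cell
  intervals, points sampled by the cell containing them.
* Normalization records permit exact inversion (round-trip identity to
  1e-12 is a tested property); constant predictor columns are dropped
  with a warning, a constant response is an error.
* Quadratic-surface fitting is a linear filter (one kernel per
  coefficient from the pseudo-inverse of the window design matrix);
  windows touching nodata are refitted per cell on their unmasked
  subset, requiring ≥6 cells.
* Tests and the bundled experiments run at reduced problem sizes
  (51×51–80×80 grids, radii subsets, 2–5 CV repeats for screening);
  sizes are stated next to each experiment.

## Known limitations

* The ANN is an L2-regularized MLP, not a Bayesian-regularized network;
  absolute ANN RMSEs are not comparable to evidence-trained ones.
* Terrain formulas are validated against analytic surfaces, not against
  any specific GIS implementation; convergence-index scaling is fixed
  at ±90.
* The backward step is greedy; on adversarial predictor sets it can
  stop above the exhaustive-subset optimum (the tests assert only the
  oracle ordering exhaustive ≤ 3stepFS ≤ sFS ≤ best single).
* Flat tuning reuses the selection fold plan and therefore carries the
  usual optimism of tuning-on-the-criterion; nested mode exists for
  honest final error estimates.
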