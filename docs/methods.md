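# Methods

This note records the models, defaults and numerical conventions behind
`nirpls`, and what the synthetic study design does and does not establish.

## Spectral axis

The canonical wavenumber grid has 1550 points descending from 9974.2 cm⁻¹
in steps of 3.8571 cm⁻¹ (≈ 9974–4000 cm⁻¹). These values were chosen so
that 31 sub-intervals of 50 points reproduce the published band↔wavenumber
map of this problem family to within ±1 cm⁻¹; the published endpoints are
not mutually consistent with any single uniform grid, so band-range
agreement is always asserted at ±1 cm⁻¹, never exactly. Grid parameters
are overridable (`canonical_grid(n_points, start, spacing)`).

Spectra CSVs store the wavenumber header to two decimals. Reading such a
header back perturbs each step by up to 0.01 cm⁻¹, so the grid-uniformity
check accepts step deviations up to max(10⁻⁶·spacing, 0.0105 cm⁻¹).
Ascending headers are accepted and reversed internally (descending is the
canonical orientation).

## Synthetic tablet model

The generator is a Beer–Lambert additive mixture, which is exactly the
linearity assumption multivariate calibration relies on:

    a(ν) = g · Σₖ cₖ sₖ(ν) + b(ν) + o + ε(ν)

with cₖ the component mass fractions (w/w%), sₖ Gaussian-band component
signatures (AU per w/w%), g ~ N(1, gain_sd) a per-replicate scatter gain,
b a random degree-2 polynomial baseline, o ~ N(0, offset_sd) an offset and
ε white noise.

* **Components.** Anhydrate, hemihydrate (host API), monohydrate,
  excipient. The hydrates share the crystal-water combination band at
  5099 cm⁻¹ (monohydrate strongest, hemihydrate weaker) and the
  hydroxyl/H-bond overtones at 6913/6811 cm⁻¹; the anhydrate has no band
  within 5099 ± 50 cm⁻¹; the excipient dominates 9010–7471 cm⁻¹,
  including the carbonyl overtone at 8621 cm⁻¹. Widths are 34–60 cm⁻¹
  (broad NIR bands); amplitudes (~0.002–0.006 AU per w/w%) put the
  impurity signal near 50:1 against the default additive noise.
* **Design.** 41 calibration tablets: five anchor impurity pairs
  ((10,0), (5,2.5), (1.5,3.5), (2.5,5), (0,10)), the blank, the six
  matched validation levels, and seeded space-filling points over the
  triangle an + mono ≤ 10 w/w%. 6 validation tablets at matched
  anhydrate/monohydrate levels 0.5, 1.5, 2.5, 3.5, 4.5, 5.0 w/w%.
  Triplicate scans per tablet.
* **Mass balance.** Tablets are 1:2 API:excipient by mass (the commercial
  ratio is proprietary; this is a configurable stand-in), so the
  hemihydrate fraction is 100/3 − an − mono and only two concentration
  directions vary independently. A noiseless dataset therefore has
  centered rank 2 and is fitted exactly by two latent variables.
* **Noise defaults.** additive_sd 5·10⁻⁴ AU, gain_sd 0.01,
  offset_sd 2·10⁻³ AU, baseline degree 2 at scale 5·10⁻³ AU. All
  randomness flows from one `numpy` generator seeded by `NoiseModel.seed`;
  identical seeds give bit-identical datasets.

What the generator does **not** emulate: instrument line shape, detector
nonlinearity, wavelength-axis drift, Kubelka–Munk/radiative-transfer
scattering physics, or chemically realistic full NIR signatures (each
component carries a handful of Gaussian bands, not hundreds). Passing
recovery tests on this generator demonstrates that the pipeline's
machinery is correct under its own modelling assumptions, not that any
particular accuracy is attainable on real tablets.

## Pretreatment

* Savitzky–Golay: default window 11 points, polynomial order 2 (supports
  the second derivative). Derivatives are taken with respect to the point
  index; division by spacing^deriv is an option (off by default) and is
  irrelevant to band selection, which is invariant to a global rescale.
  Edges are handled by the polynomial fit on the boundary windows, so
  output length equals input length and polynomial inputs are
  differentiated exactly everywhere.
* Wavelet denoising: 'db4', level 4, soft thresholding of all detail
  levels at the universal threshold σ̂·sqrt(2 ln P), σ̂ = MAD of the
  finest-level details / 0.6745. `threshold_rule="none"` gives the
  identity (to reconstruction round-off), which the tests use to isolate
  transform error from thresholding.
* MSC: each row regressed on a reference spectrum (default: column mean of
  the matrix at hand); at prediction time the calibration-set mean is
  frozen into the model bundle and passed explicitly.
* Pretreatment is applied after replicate averaging, matching the data
  flow in which the averaged spectrum is the unit of analysis.

## PLSR

NIPALS PLS2 on mean-centered X and Y (no autoscaling: absorbance columns
share units, and autoscaling would inflate noise-only channels). One
model serves all three responses (an, mono, total); per-response PLS1 is
possible by passing a single-column Y. Implementation details:

* Inner power iteration to a relative tolerance of 10⁻¹⁰ on the score
  vector (≤ 500 iterations).
* Sign convention: each weight vector is unit length with its first
  element of magnitude > 10⁻⁸ made positive, so scores/loadings are
  reproducible across runs and platforms.
* Rank exhaustion (residual X or Y numerically zero, as happens on
  noiseless rank-2 data) truncates extraction gracefully; the model
  reports the number of components actually extracted. Requesting more
  components than min(n−1, p) is an error.
* Per-LV variance contributions: LV a explains
  100·‖tₐpₐᵀ‖²_F / ‖X_c‖²_F percent of the predictor (molecular-structure)
  information and the analogous qₐ share of the response (content)
  information. Over a complete decomposition the predictor shares sum
  to 100%.
* Regression coefficients B = W(PᵀW)⁻¹Qᵀ; predictions are
  (X − x̄)B + ȳ.
* RMSEC tables by component count are produced by refitting per N; for
  NIPALS this is mathematically identical to truncating one deep model.
* Cross-validation is leave-one-out: with ~41 calibration samples it is
  cheap and has no fold-assignment randomness.
* The LV count N is the smallest whose anhydrate, monohydrate and total
  RMSEC are all below 0.3 w/w% (threshold configurable). The rule's input
  table must start at N = 1 but may thin out at large N, as printed
  tables do.

## Ant colony band selection

The published description fixes the colony size A, evaporation rate B and
subset size C but not the sampling law, deposit rule or iteration budget.
The package's choices:

* Selection probability ∝ τᵢᵅ with α = 1 and no heuristic-visibility
  term; C distinct bands drawn sequentially without replacement.
* Iteration-best elitist deposit Δ = Q / fitness with Q = 0.1 on the
  iteration's best subset, after evaporation τ ← (1−B)τ; pheromone floored
  at τ_min = 10⁻³ (τ_init = 1). A zero fitness caps the deposit at
  Q / 10⁻¹².
* Default 100 iterations with early stop after 25 stagnant iterations.
* Fitness: averaged (over the three responses) leave-one-out RMSECV by
  default; averaged held-out RMSEP in the orthogonal screen, matching the
  screen's evaluation criterion.
* Subsets are sets; the canonical form is sorted ascending, with the
  ant's discovery order kept for reporting.
* Subset fitnesses are memoised per run, so converged colonies cost
  little; a subset whose pretreated columns carry no signal at all (exact
  zeros at zero noise) scores +inf rather than raising.

## Orthogonal screen

The standard L9(3⁴) array assigns A ∈ {100, 200, 300}, B ∈ {0.3, 0.5,
0.7}, C ∈ {5, 10, 15}, D ∈ {SG1st, SG2nd, SG2nd+WT}. Per run: preprocess
per D, run the colony at (A, B, C) with RMSEP fitness, fit the final PLS
model on the selected bands, score on the validation set. One child seed
per run is derived from the master seed. Range analysis reports k1/k2/k3
(level means), R (spread), the factor ranking by descending R, and the
per-factor argmin combination. Because published screens sometimes prefer
a slightly suboptimal level for analysis efficiency (more bands separate
co-varying components at negligible cost), `RangeAnalysis.adjusted_combo`
can substitute a preferred level when its mean response is within a
tolerance (default 0.05 w/w%) of the factor's minimum. The screen's
factor ranking on synthetic data is data-dependent and is not asserted;
correctness is established by planted additive-effect recovery, where L9
balance recovers each factor's true effect spread exactly.

## Validation figures of merit

Mean prediction error is the mean absolute deviation |ŷ − y| over the
validation tablets (per response). Precision, repeatability and stability
— physical re-measurement protocols — are emulated synthetically as
independent noise redraws of one tablet at the 4.5 w/w% level (6 redraws
per mode by default): precision draws measurement noise only,
repeatability adds repack gain/offset scatter, stability adds baseline
drift. RSD is the sample standard deviation over the mean of the predicted
contents, in percent. LOD = 3.3 σ/s and LOQ = 10 σ/s use σ from the
precision redraws and s from the predicted-vs-reference calibration line;
their ratio is 10/3.3 by construction whenever σ > 0.

## Problem sizes in the test suite

The shipped tests run the full pipeline at reduced colony sizes (tens of
ants, ~20 iterations) — with memoised fitness and a 41-sample LOO this is
where the search has long converged on the synthetic datasets, and the
selected bands stabilise well before the defaults' budget. Planted-band
recovery uses 31 bands of 50 points with 40 samples (single planted band)
and 60 samples (planted pair): below roughly 40 samples the planted band
is not even the fitness argmin — with 50 predictors per band and few
training rows, estimation variance swamps the signal — so recovery is only
a meaningful claim about the search once the ground truth is identifiable.

## Known limitations

* The synthetic generator's simplifications listed above; in particular
  noiseless data is rank 2, so deep-LV behaviour (N = 5 and beyond) is
  exercised only on noisy data.
* MSC assumes a representative calibration-mean reference; wildly
  different validation matrices would need a reference transfer scheme.
* No outlier diagnostics (leverage, Q residuals), no uncertainty
  intervals on predictions, no calibration transfer between instruments.
* The colony is a single-colony, iteration-best elitist variant; Max–Min
  Ant System and rank-based variants are out of scope.
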