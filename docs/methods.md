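# Methods

This note documents the models implemented in `nirpls`, the conventions
and defaults chosen where the field admits more than one, and what the
synthetic-data tests do and do not demonstrate.

## Data model

A `SpectralDataset` holds a strictly increasing wavelength axis (nm), a
samples × wavelengths intensity matrix, sample labels, and per-analyte
reference concentrations (mg kg⁻¹, non-negative, finite). Reflectance
and absorbance are stored as-is under a mode flag; no automatic
log(1/R) conversion is applied, since reflectance spectra can be (and
routinely are) modeled directly. The reference axis for the full NIR
range is 1000–2500 nm; at 0.5 nm steps that is 3001 points. Interval
ranges are half-open `[start, stop)` and all indices are 0-based.

The CSV interchange layout is one file: header
`sample_id, <analytes…>, <wavelengths…>`, one row per sample. Reading
and writing round-trip to the declared decimal precision (`%.12g` by
default).

## Preprocessing

Eight transforms, each a scikit-learn transformer. Row-wise transforms
are stateless; MSC and mean centering learn calibration-set state and
apply it frozen to prediction samples, so no information leaks from the
prediction set into the model (cross-validation refits these states
inside each training fold for the same reason).

- **SNV**: per-spectrum standardization to mean 0, sample SD 1.
  Constant rows are an error.
- **MSC**: each spectrum is regressed by OLS on a reference spectrum
  (default: calibration-set mean — the conventional choice) and
  corrected to `(x − a)/b`. Slopes below 1e−12 in magnitude are an
  error.
- **Savitzky–Golay**: least-squares polynomial convolution; defaults
  17-point window, 2nd-degree polynomial, 1st derivative — the common
  NIR setting. Derivatives are scaled by the wavelength step, so output
  units are per-nm. Edges use a polynomial fit to the terminal window
  (scipy's `interp` mode), which keeps the filter exact on polynomials
  of the fitted degree at every point — the property the tests pin
  down.
- **Baseline**: three modes kept deliberately distinct because they
  behave differently on NIR baselines — `offset` (subtract the row
  minimum), `linear` (remove the no-intercept slope fit b·λ), and
  `offset_linear` (remove the full OLS line a + b·λ; residuals are
  orthogonal to [1, λ]).
- **Mean centering**: column means from the calibration set.
- **Moving average**: odd boxcar window (default 5; the width is a free
  choice and configurable) with symmetrically shrinking edge windows.
- **Mean reduction**: division of each spectrum by its row mean. The
  term is not standardized in the literature; this scatter-
  normalization reading (scale-invariant by construction) is isolated
  in its own transformer so an alternative definition can be swapped in
  without touching anything else.

Pipelines are ordered lists of `{"method": …, params}` entries; mean
centering may be placed before or after any scatter correction, and the
empty list is the raw-data pipeline.

## SPXy splitting

Joint-distance Kennard–Stone: `d(p,q) = d_x(p,q)/max d_x +
d_y(p,q)/max d_y` with Euclidean `d_x` on spectra and absolute `d_y` on
the response. The two most distant samples seed the calibration set;
samples are then added greedily by maximal minimum distance to the
selected set. Ties break toward the lowest row index (distances are
rounded to 12 decimals first so float noise cannot flip a tie), making
the split deterministic for a given row order. Default calibration
fraction 0.75 (76 of 101 samples).

One caveat worth stating: because the seed pair maximizes the *joint*
distance, the calibration set is not guaranteed to contain the exact
minimum and maximum of y (an X-space outlier can win the seeding). It
reliably covers a wide slice of the response range, which is what the
tests assert. Distances are computed on whatever matrix is passed in;
the comparison driver uses the preprocessed spectra by default
(configurable to raw), since that is the representation the model
actually sees.

## PLS1

NIPALS on column-centered X and centered y. Per latent variable: weight
`w ∝ X'y` (unit norm), scores `t = Xw`, loadings `p = X't/t't`,
`q = y't/t't`, deflation `X ← X − t p'`. The regression vector for any
truncation follows the rotation recurrence
`r_k = w_k − Σ_{j<k} (p_j'w_k) r_j`, `b_k = b_{k−1} + q_k r_k`, so a
single fit produces predictions for every LV count 1…k — this is what
makes RMSECV one fit per fold rather than one per (fold, LV).

Numerical guards: extraction stops early with a warning when the X
residual norm falls below 1e−12 of its initial scale (rank exhaustion);
the effective LV count is recorded. At full rank, PLS1 predictions
coincide with the minimum-norm least-squares fit (tested to 1e−6); the
implementation agrees with scikit-learn's NIPALS to better than 1e−8 on
random problems, but scikit-learn is used only as a test oracle, never
in the fit path.

**LV selection**: global minimum of RMSECV with smallest-LV
tie-breaking; no one-standard-error parsimony rule. RMSECV(h) =
√(Σ_folds Σ_i (y_i − ŷ_i^(−fold))² / n). Default CV scheme is venetian
blinds with 10 splits on the calibration set (sample i in fold
i mod k); leave-one-out is available. RMSEC uses denominator n, not
n−LV−1 — this affects RMSEC only and is stated here because both
conventions circulate.

## Interval selection

`make_intervals(n, k)` gives k−1 intervals of ⌊n/k⌋ and a final
interval taking the remainder (3001 variables, 20 intervals →
19×150 + 151).

All three selectors share one fitness: the RMSECV (at the CV-chosen LV,
capped by `max_lv`) of a PLS1 model on the union of the active
intervals. Fitness values are cached by the active-interval bitmask —
the decisive performance choice for the swarm search, where a 50×50 run
re-visits the same subsets constantly.

- **iPLS** fits one model per interval and returns the single interval
  with minimum RMSECV (classic single-interval mode). A forward mode
  that keeps adding intervals while RMSECV improves is provided but off
  by default.
- **iSPA-PLS** represents each interval by its mean spectrum across
  samples (a vector in sample space; the first singular vector is a
  plausible alternative and the representative computation is isolated
  for that reason). From every start interval a chain grows by
  appending the unused interval whose representative has the largest
  norm orthogonal to the span of the chain — exact duplicates project
  to zero and can never be appended, which is the collinearity
  suppression that motivates SPA. Every chain prefix up to
  `max_intervals` is scored; minimum RMSECV wins, ties to fewer
  intervals then lexicographic order.
- **FFiPLS** runs `ffpop` fireflies as continuous positions in [0,1]ᵏ,
  binarized at 0.5. Each generation t, every firefly moves once toward
  each brighter one:
  `pos_i ← w₀ᵗ·pos_i + β₀·exp(−γ·r²)·(pos_j − pos_i) + α·(u − ½)`,
  positions clipped to [0,1]. Defaults: 50 fireflies, 50 generations,
  w₀ = 0.97, γ = 1.0, α = 0.2, β₀ = 1.0. The published hyperparameter
  names (w₀, γ, α) admit more than one placement in the update rule;
  here w₀ is a per-generation inertia decay and α scales uniform
  per-coordinate noise — the reading that needs the fewest extra
  assumptions — and the update is isolated behind `FireflyConfig` so a
  sigmoid-stochastic binarization or a different w₀ role can be
  substituted. All-inactive vectors are repaired by activating the
  single interval with the best univariate fitness. The brightest
  firefly has no brighter neighbor and therefore never moves, which is
  elitism; the best-ever fitness trace is consequently non-increasing
  (asserted). No parsimony penalty on interval count is applied. Runs
  are bit-reproducible given (data, config, seed): one seeded generator
  drives initialization and noise.

**Selection bias of the fitness.** The reported fitness is the minimum
RMSECV over many examined subsets. On pure-noise data it therefore sits
systematically *below* the single full-spectrum RMSECV — by several
replicate standard deviations — without implying any predictive skill.
The honest no-signal check, which the test suite performs, is held-out:
on noise, selected models predict an independent set no better than the
response SD. Reported RMSECV values from any selector should be read
with this optimism in mind; RMSEP on a untouched prediction set is the
fair figure.

## Figures of merit

For a prediction set of size n: RMSEP = √(mean squared error), bias =
mean(ŷ − y), SDV = √(n(RMSEP² − bias²)/(n−1)) (the bias-corrected SEP;
the identity SDV²·(n−1)/n + bias² = RMSEP² is asserted on every
report), RPD = SD(reference values)/SDV (a switch allows SD/RMSEP,
since both circulate), REP = 100·RMSEP/mean(reference values), and R²
as the squared Pearson correlation of predicted vs reference (the
chemometric convention; 1 − SSE/SST differs in the presence of bias).
Bias is reported signed; comparison utilities that mimic published
tables compare magnitudes.

**EJCR**: OLS of ŷ on y gives (a, b); the exact joint confidence
region is `{(a₀,b₀) : n(a−a₀)² + 2Σyᵢ(a−a₀)(b−b₀) + Σyᵢ²(b−b₀)² ≤
2s²F(α; 2, n−2)}` with s² the residual mean square. A model is
accurate (jointly unbiased) when (0, 1) lies inside. A machine-epsilon
floor on the threshold keeps exact fits (s² = 0) classified as
containing the ideal point. Simulated coverage at α = 0.05 is nominal
(95% ± 1.5% over 2000 replicates).

**F-test on RMSEP**: F = (larger/smaller)², degrees of freedom the
respective prediction-set sizes, two-sided at level α via
F(α/2; df₁, df₂).

## Synthetic data

The generator emulates soil NIR reflectance: Gaussian bands at
1450/1950 nm (water), 2204 nm (clay OH) and 2280 nm
(carbonate/organics), analyte-band amplitudes linear in concentration,
nuisance bands with per-sample random amplitudes, log-normal
concentrations targeting ~30% RSD (soil surveys typically print
25–45%), log-normal multiplicative scatter, Gaussian additive offsets,
per-sample linear baseline drift, and iid noise. The default grid is
1000–2500 nm at 4 nm (376 points) for fast tests; the 0.5 nm/3001-point
instrument grid is a preset flag. Generation is bit-reproducible from
the seed.

`planted_benchmark` builds 10-interval recovery problems. With one
informative interval its band amplitude *is* the concentration. With
two, the first interval responds to concentration + interferent and the
second to the interferent alone, so accurate prediction requires both —
the construction that separates subset-capable selectors (FFiPLS) from
single-interval ones.

One physical point the generator makes explicit: with a
*single-constituent* spectrum, SNV/MSC row normalization erases the
concentration signal entirely (every corrected row is the same shape).
Scatter correction recovers quantitative information only in the
presence of a stable background against which band ratios are
meaningful; the scatter-recovery test therefore uses fixed-amplitude
background bands, under which SNV and MSC cut scatter-corrupted RMSECV
by an order of magnitude, to below 5% of SD(y).

**What the synthetic tests do not show.** Gaussian bands, linear
mixing and log-normal scatter are an idealization: no instrument line
shape, no water-content or particle-size confounding, no nonlinear
detector response, no wavelength-axis drift. Passing recovery tests
demonstrates algorithmic correctness (the selectors find what is
findable), not field performance on real soil spectra.

## Problem sizes and runtime choices

Benchmarks and simulations in the tests and the acceptance script use
50–60 samples, 100–376 variables, 10 intervals, venetian-5 CV and ≤8
LVs — sizes at which the exhaustive subset oracle (all 2¹⁰−1 interval
subsets) is computable in seconds and the full suite runs in about a
minute, while leaving the swarm a realistic search problem. The
stochastic rate checks (firefly optimum attainment ≥80/100 seeds,
interval recovery ≥90–95/100) use fixed benchmark constructions with
seeded replication; observed rates are 92–100%.

## Known limitations

- PLS1 only: no multi-response PLS2, no SIMPLS/kernel variants, no
  coefficient uncertainty intervals.
- Wavelength-point (non-interval) selection and other metaheuristics
  (GA, PSO) are out of scope.
- The firefly update equations follow the standard continuous firefly
  scheme; published interval-selection GUIs may differ in unstated
  details (binarization, w₀ semantics), which is why those pieces are
  configurable.
- `mean_reduction` implements one reading of an ambiguous term and is
  flagged experimental.
- JCAMP-DX/SPC instrument formats are not read; CSV only.
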