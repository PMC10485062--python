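# Methods

`fluxbridge` implements a framework for deciding, station by station,
whether a machine-learning flux model trained on a network of eddy-
covariance towers may be transferred to a meteorological station that
measures no fluxes — and for producing daily net ecosystem exchange (NEE)
and water flux (WF) series wherever the answer is yes. This note records
the models, conventions and design choices behind each stage.

## The transfer problem

A random-forest model ("RFM") trained on flux towers predicts daily NEE
(g C m⁻² d⁻¹) or WF (mm d⁻¹) from meteorological, remote-sensing and
static covariates. Its skill at a station it never saw depends on how
similar that station's environment is to the training towers — similar
drivers, similar response. The framework quantifies that similarity as
per-factor Euclidean distances between day-of-year climatologies, learns
how skill declines with distance from grouped cross-validation, and uses
the learned relation to predict the determination coefficient R² a model
would attain at an unmeasured station. Only a model whose predicted
R² ≥ 0.5 is transferred; among eligible models the one with the maximum
predicted R² is chosen.

## Stages

### 1. Preprocessing (`preprocess`)

* **VPD** is derived from air and dew-point temperature with the Magnus
  (FAO-56) saturation curve, es(T) = 0.6108·exp(17.27·T/(T+237.3)) kPa;
  vpd = es(Ta) − es(Td), clamped at zero (with a logged warning) when the
  dew point exceeds the air temperature. The Magnus coefficient set is a
  convention choice; any of the common variants differs by well under the
  synthetic noise level.
* **LE→WF**: a daily-mean latent-heat flux density (W m⁻²) is converted to
  a daily water flux as LE × 86 400 s × 0.408×10⁻⁶ mm per J m⁻², i.e. the
  daily energy total divided by the latent heat of vaporisation
  (λ ≈ 2.45 MJ kg⁻¹). Negative LE (condensation) maps to negative WF.
* **QC filtering** masks flux values whose quality flag is below the
  threshold (default 0.8, inclusive: a flag of exactly 0.8 keeps the
  value). Records without flags pass unchanged; covariates are never
  masked.
* **Gap filling** linearly interpolates interior missing runs of at most
  7 days in the remote-sensing factor series ("fill gaps of fewer than 8
  consecutive days"); longer runs and runs touching either end of the
  series stay missing. The filler is run-length aware — a 9-day gap is
  refused outright, not partially filled.

### 2. Categories and grouped cross-validation (`partition`)

Stations belong to exactly four of nine categories: one landscape
(Wetland / Cropland / Grassland / Forest, collapsed from IGBP land-cover
classes — savannas and woody savannas count as grassland, the five forest
classes as forest), one continent (Asia / Europe), one aridity class
(arid iff aridity index < 0.65; AI = 0.65 is non-arid), plus Overall.

Cross-validation is grouped at the station level: within each category the
stations are shuffled into k near-equal folds (sizes ⌊n/k⌋ or ⌈n/k⌉),
independently repeated p times. Each of the k×p training sets fits one
model per (scenario, target); each model is evaluated separately at each
of its held-out stations, so a category yields n×p per-station R² values.
With the canonical k = p = 10, nine categories, two feature scenarios
(RS: all factors; WRS: remote-sensing factors withheld) and two targets,
the full plan is 900 models per (scenario, target) and 3,600 in total.
Fold shuffles are per-category and seeded.

### 3. Flux models (`model`)

Random forests (scikit-learn) with hyperparameters chosen by random
search: n_iter draws (default 20) from trees 100–500, depth 5–30 or
unlimited, minimum leaf 1–10, feature fraction 0.3–1.0, scored by
out-of-bag R² and refit on the full training rows. Rows with any missing
feature or target are dropped, not imputed (counts logged). Evaluation at
a held-out station uses R² = 1 − SSres/SStot about the station's own mean
and RMSE = √(SSres/n); zero-variance stations are flagged and excluded
downstream. Negative R² values are retained — they are real outcomes of
transfer and carry information for the next stage.

`HyperSearchConfig.max_train_rows` caps training rows by deterministic
subsampling. Test-scale runs in this repository use small forests
(3–60 trees) and capped rows so a full 3,600-model plan trains in minutes;
the defaults are what a production run on real archives would use.

### 4. Transferability regression (`transferability`)

For each station, every daily factor is averaged by day of year over all
years (leap day dropped; DOY 1..365). For one factor, the distance between
two stations is the root-sum-of-squares of the climatology difference over
their common observed DOYs (requiring at least t_min = 30 common days;
static factors compare as single values). The distance between a station
and a model's training set is the mean of its pairwise distances to the
training stations. Distances are computed on raw factor units; a z-scoring
option exists but the regression absorbs scale either way.

Stacking the w per-factor distances gives the station-model distance
vector, and each grouped-CV evaluation pairs such a vector with a realized
R² ("Dataset 1"). Per (category, scenario, target) an ordinary-least-
squares regression

    R² = a₀ + a₁d₁ + … + a_w d_w

is fitted. Two numerical safeguards apply before fitting, both logged:
constant or (near-)collinear columns are removed (exact rank reduction via
pivoted QR, then iterative variance-inflation pruning at VIF ≤ 5), and —
in the pipeline — backward elimination removes terms insignificant at
α = 0.01. Both exist for the same reason: distance columns share the
station offsets that generate them, and with tens of samples a full
20-term fit retains chance correlates whose slopes misprice stations far
outside the fitted cloud. `fit_rsm` called directly defaults to the plain
full regression (VIF pruning only).

Predicted R² is the unclamped linear value; values above 1 are reported
as-is and only capped for quality-class binning. Quality classes follow
the dataset convention: class 1 (R² < 0.5), class 2 (0.5 ≤ R² < 0.7),
class 3 (R² ≥ 0.7); classification accuracy is the fraction of samples
whose true and predicted R² land in the same class.

### 5. Screening and simulation (`pipeline`)

A meteorological station's candidates are all models of the requested
(scenario, target) from its own four categories — a station is never
scored by another continent's regression. Each candidate is priced by its
category's regression at the station's distance vector; the maximum
predicted R² wins if it reaches 0.5, with deterministic tie-breaking
(canonical category order, then model id). Categories whose Dataset 1 is
too small to support a trustworthy regression (fewer than
`min_rsm_rows_per_term` ≈ 3 rows per term) contribute no scores. Chosen
models simulate fluxes for every feature-complete day; per-station CSVs
(id, lon, lat, year, month, day, doy, NEE, WF) and a station-information
table with the four quality-class columns are written.

## The synthetic network generator (`synthetic`)

Real flux archives cannot be redistributed, so the package ships a
generator whose output has the statistical skeleton the framework needs.
It is first-class, tested code — the study conditions, not a fixture.

**Covariates.** Daily series are seasonal harmonics plus first-order
autocorrelated noise: air temperature (amplitude ~10 °C), dew-point
depression (larger in arid cells), downward shortwave radiation, fPAR
(landscape-dependent base and amplitude), EVI and LSWI tied to fPAR, and
seven reflectance bands as linear transforms of EVI/LSWI plus noise
(redundant signal, as in reality). Static terrain/soil factors are drawn
once per station from landscape-conditional uniform ranges. Leap days are
generated so downstream DOY handling is exercised.

**Station heterogeneity.** Each station carries climate offsets (ta, dsr,
fPAR, dew-point depression) drawn from zero-mean normals; 25% of flux
stations are "fringe" stations whose offsets sit in a bounded ring of
1.3–2.0 offset-sd, so tower networks span a climate gradient wider than
their core — which is what makes the skill-vs-distance relation
identifiable over a useful range. Met stations draw from the core
distribution unless explicitly flagged out-of-distribution, in which case
every offset is shifted by `ood_shift` offset-sd.

**Flux truth.** Per station,

    NEE = −GPPmax · DSR/(DSR+k_I) · fPAR · exp(−k_V·VPD)
          + R0 · Q10^((Ta−10)/10) + ε
    WF  = c_R · DSR · fPAR + c_V · VPD + ε   (floored at 0)

with k_I = 150 W m⁻², k_V = 0.2 kPa⁻¹. GPPmax and R0 have landscape-level
means (9–11 and 1.8–2.2 g C m⁻² d⁻¹) with small (3%) residual scatter, and
drift with the station's thermal and vegetation offsets. The landscape
contrast is deliberately moderate: large enough that within-category
stations are more alike than across categories, small enough that a
pooled model trained across landscapes stays transferable under low
noise. Q10 carries a station-idiosyncratic deviation with random sign and
bounded-uniform magnitude that grows with the station's overall (RMS)
climate displacement beyond a core envelope of 1.2 offset-sd (clipped to
[1.3, 3.5]): inside the core, ecosystems respond near-identically; past
the niche boundary the response curve diverges increasingly, in a
direction no covariate reveals — so a model carried along the climate
gradient loses skill, in expectation, in proportion to how far beyond
the core it travels. That is the functional-dissimilarity premise that
makes climatology distance informative, and the idiosyncrasy matters: a
deterministic drift would be learnable from covariate position and would
leave nothing for distance to predict. The WF coefficients drift mildly
(10% per offset-sd) in the signed direction, keeping WF the easier, more
transferable target.

**Missingness** is injected into remote-sensing factors as bounded runs
(1..max_gap_days, guard days prevent merging) until the target fraction
is reached; an option inserts deliberately over-long gaps to exercise the
interpolation refusal path. Flux values are never removed.

**What the generator does not emulate:** MODIS retrieval artifacts,
footprint heterogeneity, energy-balance closure gaps, sub-daily structure,
instrument drift, or realistic geographic autocorrelation of stations.
Passing tests therefore demonstrate that the machinery is correct and that
the screening logic discriminates under the stated statistical structure —
not that any particular real-world accuracy would be attained.

## Problem sizes used in tests and the acceptance script

Verification runs use miniature but structurally complete configurations,
chosen as the smallest sizes at which each property is meaningful: full
3,600-task plans train with 3-tree forests on 1 year of data and capped
training rows; skill-recovery and screening experiments use 30 flux
stations over 3 years with 60-tree forests. Both experiments use a
single-cell (one landscape/continent/aridity) network: 30 stations cannot
densely cover the full 16-cell category grid — about two stations per
cell leaves no pooled learner enough analogues to transfer from — so the
properties are assessed where station density matches the learning
problem, and the distance effect is isolated from category composition.
The screening experiment compares in-distribution met stations against
stations shifted 3 offset-sd out.

## Known limitations

* The linear R²-simulation regression extrapolates; predictions far from
  the fitted distance cloud are used for screening (as the framework
  prescribes) but should not be read as calibrated R² estimates, and can
  exceed 1.
* With few stations per category the per-category regressions are skipped
  by the sample-size gate, so small-network runs effectively screen with
  the larger categories' regressions only.
* The generator's response drift is stylized; real cross-station
  functional dissimilarity is not a deterministic function of climate
  offsets.
* Station records are assumed daily and calendar-aligned; no sub-daily
  aggregation is performed.
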