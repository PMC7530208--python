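# Methods

## Measurement model

A culture dish photographed under fixed illumination, exposure and geometry
acts as a crude transmission/reflection photometer: as biomass (MLSS, g/L)
rises, the suspension absorbs and scatters more light and the stored 8-bit
pixel values fall. Two regimes are modelled per channel c ∈ {R, G, B}:

- **Linear calibration** over the full working range (here 0–15 g/L):
  `V_c = intercept_c + M_c·MLSS`, fitted by ordinary least squares with the
  channel intensity as the *response*. The slopes M_c are sensitivities in
  intensity units per g/L; MLSS is later estimated by inverting the line,
  never by re-regressing MLSS on intensity. The two directions differ for
  noisy data, and the intensity-on-MLSS direction is the one that defines
  the published-style slope and gray-coefficient values this package
  reproduces.
- **Beer–Lambert (optical-diffuse) regime** at low turbidity, default
  MLSS ≤ 8 g/L: `V_c = V₀_c·exp(−κ_c·MLSS)` with κ_c > 0 for a darkening
  culture. Above this range multiple scattering breaks the single-pass
  attenuation assumption and the linear fit is the better description.

The **gray composite** collapses the three channels into one index,
`Gray = K_R·R + K_G·G + K_B·B`, with `K_c = M_c / (M_R + M_G + M_B)`. The
weights sum to one by construction (a spectrally flat pixel keeps its
value) and are proportional to each channel's MLSS sensitivity, so the
composite concentrates on the informative part of the spectrum — in
practice the blue channel, whose absorption by a turbid bacterial culture
is strongest. The normalization uses the *signed* slopes and requires all
three to share a sign: on data where channels fade in opposite directions
the composite would be meaningless, and the fit fails loudly instead.

## Estimation and evaluation

Inverse prediction: `MLSS = (V − intercept)/M` (linear) or
`MLSS = ln(V₀/V)/κ` (exponential). Estimates below zero or beyond the
calibrated MLSS span are *flagged*, not clipped; an explicit `--clip-zero`
option applies max(0, ·) for operational use. Evaluation uses the standard
statistics RMSE, MAE, MAPE (%) and R² of predicted against known MLSS.
MAPE is undefined at MLSS = 0; such points are skipped and their count
reported (`n_excluded_mape`), so the rule is visible rather than silent.
Channel selection takes the highest R², with ties broken by lowest RMSE and
then the fixed order B, GRAY, G, R.

Exponential fitting is log-linear least squares — deterministic, no
starting values — rather than nonlinear least squares, which would weight
residuals differently but requires initialization. Because conventions
differ on which scale exponential fit quality is quoted, both the R² of the
straight-line fit on ln(V) and the R² of back-transformed predictions on
the intensity scale are always reported; on the bundled reference data they
are 0.981 and 0.976 for the blue channel.

## Image reduction

- Pixels are read as stored 8-bit sRGB values; no gamma linearization or
  color-space transform is applied, because the calibration is defined
  directly on stored values. Non-8-bit inputs are rejected rather than
  rescaled.
- A pixel belongs to a circular ROI iff its center satisfies
  (x−cx)² + (y−cy)² < r² — strict inequality, no antialiased partial
  weighting. Deterministic and exactly testable.
- The ROI radius is multiplied by a shrink factor (default **0.8**) before
  averaging, to keep the dish rim and meniscus highlights out of the mean.
  The rim-exclusion rule is this package's choice; the reference protocol
  cropped manually and states none.
- Replicate photographs (the reference protocol took three per sample) are
  averaged per channel, unweighted regardless of per-image pixel counts.
- QC: the fraction of in-ROI pixels with any channel at 255 is reported;
  above 1% the CLI warns that the exposure is too bright, since saturation
  biases means toward the truncation point.
- Automatic dish detection (Canny edges + circular Hough transform, largest
  well-supported circle) is a convenience for batch work; an explicit ROI
  always takes precedence, and a detected circle clipped by the frame is an
  error, not a result.

## Reference dataset

The bundled table has 23 printed rows of (MLSS, mean R, G, B), MLSS 0 to
14.901 g/L, each row the average of three photographs. The accompanying
study text reports **21** samples; refitting shows that excluding the rows
at MLSS 12.98 and 13.52 g/L reproduces every published slope to five
significant figures, so those two printed rows are not part of the
published calibration. `reference_dataset()` returns all 23 rows;
`reference_calibration_subset()` returns the 21-row calibration series,
which is what the tests and the acceptance script fit. On that subset the
package reproduces the published values: slopes (−5.3117, −8.9099,
−14.404), K = (0.1856, 0.3113, 0.5032), linear R² = 0.900/0.970/0.990
(R/G/B) and 0.992 for gray, blue-channel MAPE 13.848%. The published RMSE
column is internally inconsistent (its gray row has RMSE 0.045 < MAE 0.291,
impossible under the standard definitions) and is not reproduced; the MAE
and MAPE columns reproduce as above.

## Synthetic data generator

The renderer emulates exactly the optics the method assumes: a bright rim
annulus, a uniform background, and a dish interior at
`base_c·exp(−κ_c·MLSS)` per channel, plus additive Gaussian sensor noise
applied before rounding and clamping to 8-bit (clamping doubles as a
sensor-saturation model and exercises the QC path). Defaults emulate the
reference system, chosen once from its own fitted optics: `base_color`
(230, 232, 241) = fitted intensities at MLSS 0, `attenuation`
(0.017, 0.037, 0.090) per g/L = fitted Beer–Lambert coefficients on the
low-MLSS subset (preserving κ_B > κ_G > κ_R), `noise_sd` 1.0 intensity
units (a typical sensor-noise scale; the reference protocol states no noise
model), three replicates per sample, and a 0–15 g/L MLSS grid.

Randomness uses one root seed with per-image streams keyed by (sample
index, replicate index), so any single image regenerates in isolation and
a fixed configuration is byte-reproducible. `generate_series` defaults to
an analytic shortcut — replicate channel means drawn as the attenuated
color plus Gaussian error of sd `noise_sd/√n_pixels`, the sampling error of
a mean over the interior — and rasterizes real PNGs on request; tests cover
the rasterized extraction path separately at reduced image sizes
(240×240 px, 9–15 MLSS points), which keeps the suite fast while still
validating the full render → extract → calibrate loop. What the generator
deliberately omits: floc texture, vignetting, meniscus optics, specular
highlights, illumination drift. Passing tests therefore show the estimation
chain is correct under the method's own optical assumptions, not that a
particular camera rig satisfies them.

## Numerical choices and degenerate inputs

- OLS via `scipy.stats.linregress`; R² computed as 1 − SS_res/SS_tot (unit
  R² when SS_tot = 0 on a perfectly flat response).
- Fits require ≥ 3 samples and ≥ 2 distinct MLSS values; identical MLSS
  everywhere is a degeneracy error (CLI exit 4), unreadable or malformed
  inputs are input errors (exit 3), usage errors exit 2.
- Any non-positive intensity in the exponential subset is an error — the
  log transform has nothing sensible to do with it — as is inverting an
  exponential model at intensity ≤ 0 or a line with zero slope.
- MLSS = 0 samples participate in both linear and exponential fits (the
  reference table includes one); they are only excluded from MAPE.
- Model JSON serialization uses `repr`-faithful floats, so a written and
  re-read model is bit-identical in all fitted fields.

## Known limitations

- Calibrations are camera-, illumination- and geometry-specific; there is
  no calibration transfer between rigs.
- In-sample evaluation mirrors the reference analysis; no cross-validation
  or prediction intervals are provided.
- The linear/exponential regime boundary (default 8 g/L) is a configurable
  constant, not estimated from the data.
- Dish auto-detection assumes a single bright-rimmed dish on a plain
  background; cluttered scenes need an explicit ROI.
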