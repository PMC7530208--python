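# sludgecolor

Colorimetric quantification of activated-sludge biomass from macroscopic
dish photographs.

Activated-sludge plants steer their process by the mixed liquor suspended
solids concentration (MLSS, g/L), conventionally measured by filtering,
drying and weighing a sample — slow, manual, and offline. A sludge culture
darkens visibly as biomass grows, so a photograph of a sample in a petri
dish carries the same information: the mean red, green and blue intensities
of the dish interior fall roughly linearly with MLSS over the operational
range (0–15 g/L), and exponentially (Beer–Lambert) below ~8 g/L. This
package implements that measurement chain for operators and researchers who
want camera-based MLSS monitoring:

1. **Extraction** — reduce each dish photograph to mean 8-bit (R, G, B)
   over a circular region of interest (auto-detected by a Hough transform
   or given explicitly), with saturation QC and replicate averaging.
2. **Calibration** — ordinary least squares of each channel against known
   MLSS, `V_c = intercept_c + M_c·MLSS`, and a slope-normalized grayscale
   composite `Gray = K_R·R + K_G·G + K_B·B` with `K_c = M_c/(M_R+M_G+M_B)`,
   so the single gray index weights each channel by its MLSS sensitivity.
3. **Beer–Lambert regime** — for MLSS ≤ 8 g/L, `V = V₀·exp(−κ·MLSS)`
   fitted log-linearly, with fit quality reported on both the log and the
   intensity scale.
4. **Inverse prediction and evaluation** — MLSS from a new intensity by
   inverting the calibration (`MLSS = (V − intercept)/M` or
   `MLSS = ln(V₀/V)/κ`), scored by RMSE, MAE, MAPE and R²; out-of-range or
   negative estimates are flagged, never silently clipped.
5. **Synthetic data** — a dish-image renderer with per-channel exponential
   attenuation and Gaussian sensor noise, so the whole pipeline can be
   validated against known ground truth without a laboratory.

A reference calibration table (23 printed rows of MLSS vs mean RGB from an
activated-sludge imaging study; the published coefficients derive from a
21-row subset of it) ships with the package: `reference_dataset()` and
`reference_calibration_subset()`.

## Worked example

```sh
# write the bundled 21-row calibration series as a CSV table
python -c "from sludgecolor import *; s = reference_calibration_subset(); \
write_extraction_csv([(x.sample_id, x.mlss, x.rgb, x.n_replicates) for x in s], 'ref_table.csv')"

sludgecolor calibrate --table ref_table.csv --out model.json
# INFO calibrated on 21 samples: K = (0.186, 0.311, 0.503); wrote model.json

sludgecolor predict --model model.json --channel B --value 150 --value 100 --out pred.csv
# INFO value0: B linear -> MLSS 5.7962 g/L
# INFO value1: B linear -> MLSS 9.2674 g/L

sludgecolor evaluate --model model.json --table ref_table.csv --out metrics.json
# INFO best channel: GRAY (R^2 = 0.9925); wrote metrics.json
```

The gray coefficients K = (0.186, 0.311, 0.503) say the blue channel
carries half the composite's weight — blue sits nearest the UV end of the
spectrum, is absorbed most strongly by the turbid culture, and is therefore
the most sensitive single channel (calibration slope −14.40 intensity units
per g/L, R² = 0.990, versus 0.970 for green and 0.900 for red). A blue
reading of 150 inverts to 5.80 g/L of biomass. The gray composite edges out
blue slightly (R² = 0.992) on this dataset. For images instead of raw
values, `sludgecolor extract` turns photographs into the same table format,
and `sludgecolor simulate` renders synthetic dish series with known ground
truth.

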