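# thrombostage

Quantitative color-fraction analysis of HE-stained thrombus cross-sections
and staging of per-part elasticity time series, plus seeded synthetic-data
generators so the whole pipeline is testable without external data.

The package has four analysis stages:

* **io_model** — record types (section images, ROI masks, elasticity
  measurements) and readers/writers for 8-bit RGB PNG/TIFF images,
  single-channel PNG masks, measurement CSVs and JSON reports.
* **qpia** — pixel classification of a section into red (RBC/platelet),
  pink (fibrin), blue (nucleus/calcium) and background by nearest reference
  hue with brightness/saturation background gating; composition fractions
  (Rr, Rp, Rb) with optional nonlinear weighting of the red fractional
  intensity (`w = ((f_red − f0)/(1 − f0))^γ`, `γ = 0` disables weighting);
  triplicate and whole-thrombus (mean-of-three-parts) aggregation.
* **staging** — per-day series assembly, two-changepoint continuous
  piecewise-linear least-squares fitting by exhaustive search, sustained-
  increase (recanalization) detection, and within-/between-thrombus
  sample-SD heterogeneity.
* **synthetic** — generators for histology-like sections with planted
  label ground truth, piecewise-linear elasticity series with planted
  changepoints and day-growing noise, composition series with a planted
  reversal day, and full multi-animal cohorts (CSV + images + manifest).

## CLI

```sh
# generate a synthetic 3-animal cohort
thrombostage simulate --out-dir cohort --animals 3 --seed 42

# quantify one section into (Rr, Rp, Rb) percentages
thrombostage quantify cohort/animal01_day02_head.png \
    cohort/animal01_day02_head_mask.png --gamma 0 --out report.json

# fit transition points and heterogeneity from the measurement CSV
thrombostage stage cohort/measurements.csv --out staging.json
```

Palette, weighting and staging parameters can be set in a TOML config file
(`--config`, sections `[palette]`, `[weighting]`, `[staging]`); CLI flags
override the file, which overrides defaults. Every report embeds the
resolved configuration and package version. Exit codes: 0 success,
2 validation error, 3 I/O error, 4 invariant breach.

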