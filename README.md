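# vavr

Virtual aortic-valve-replacement hemodynamics toolkit: quantitative aortic
flow-profile metrics on cross-sectional velocity planes, a reduced-order
transvalvular pressure-gradient model with exercise (stress) scaling,
clinical stenosis / patient-prosthesis-mismatch grading, and rank-based
cohort statistics — exercised on synthetic 4D-flow-like data and on the
bundled 10-patient cohort fixtures.

## Modules

| module | contents |
| --- | --- |
| `vavr.synthetic` | eccentric-jet velocity planes (displacement, tilt, swirl, retrograde flow, noise) and whole synthetic cohorts on the 3-valve-size × rest/stress design, with known ground truth |
| `vavr.plane` | `VelocityPlane` container and its CSV + JSON-sidecar format |
| `vavr.metrics` | normalized flow displacement (NFD), degree of wall parallelism (WPD), flow angle, peak velocity, lumen geometry |
| `vavr.model` | simplified Bernoulli (DP = 4 V²), continuity through an effective orifice, EOA calibration, +25 % stress scaling, cube-law arch outflow splitting, Carreau–Yasuda blood viscosity |
| `vavr.grading` | stenosis severity by peak velocity, PPM class by indexed EOA, 3rd/97th-percentile normality flags |
| `vavr.stats` | relative effect p_rel, exact Wilcoxon signed-rank and Wilcoxon–Mann–Whitney tests (full permutation distributions on midranks), Benjamini–Hochberg adjustment, per-cell median summaries |
| `vavr.io` / `vavr.cli` | bundled cohort fixtures (checksummed), YAML config, the end-to-end pipeline and the `vavr` command line |

## CLI

```sh
# full pipeline (bundled fixture or synthetic cohort) -> report bundle
vavr simulate --config cfg.yaml --out out/
vavr report --dir out/

# flow-profile metrics for one velocity plane
vavr metrics --plane plane.csv

# gradient predictions per valve size and activity state
vavr predict --cohort patients.csv --eoa eoa.yaml --stress-factor 1.25

# median summary + paired test family from a results table
vavr stats --results results.csv --out summary.csv
```

A minimal config:

```yaml
source:
  synthetic:          # or: fixture: table4
    n_patients: 10
    stress_factor: 1.25
    stress_nonlinearity: 0.0
seed: 7
stats:
  family: per_metric  # Benjamini-Hochberg family
```

## Notes

- The per-patient gradients in the bundled outcome fixture come from CFD
  and are consumed as inputs; the package reproduces the statistics,
  reduced-order model and threshold logic on top of them.
- Healthy-reference medians ship with the package; the 3rd/97th
  percentile bounds in `vavr/data/reference_ranges.yaml` are placeholders
  (not published values) and are meant to be replaced per deployment.
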