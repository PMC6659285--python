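# streetpa

Synthetic end-to-end pipeline linking street-scene composition to
physical-activity (PA) outcomes:

1. **synthetic_data** — generates a planar street grid with sampling points
   every 100 m, neighbourhood centroids, per-image scene-composition vectors
   (Dirichlet draws with neighbourhood-level structure), a noisy volunteer
   rating oracle, and a survey of ~35 neighbourhoods × ~23 respondents whose
   transformed total-PA outcome follows a two-level linear model with known
   coefficients and variance components.
2. **scoring** — a human–machine adversarial loop: a per-indicator random
   forest recommends a score (0–10) for each new image, the oracle corrects
   it, the pair joins the training set, and calibration stops once the
   rolling RMSE over the last 100 images drops below the threshold.  A
   100-image holdout is validated by Pearson correlation.
3. **aggregation** — image scores → sampling-point means (four headings) →
   neighbourhood exposure (mean of point scores within a circular buffer
   around the centroid, 1 km and 1.5 km).
4. **mlm** — self-implemented two-level random-intercept linear model
   (profiled ML/REML over the variance ratio, GLS fixed effects, Wald z
   tests with the `*`/`**`/`***` convention), plus ICC and VIF diagnostics.
5. **pipeline** — orchestrates the chain into a seven-model suite
   (full model; excluding functionally restricted respondents; excluding
   ages > 70; 1.5 km buffers; light/moderate/vigorous outcomes) and runs
   parameter-recovery experiments (bias, CI coverage, type-I rate for the
   null indicator, ICC recovery, sign recovery, attenuation under exposure
   noise).

Everything is driven by one seed; two runs with the same seed produce
byte-identical output trees.

## CLI

```sh
streetpa run-all  --seed 1 --out out/            # full chain, default config
streetpa simulate --seed 1 --out sim/            # world + scenes + survey only
streetpa score     --scenes sim/scenes.csv --truth-oracle sim/truth.json \
                   --seed 1 --out scored/
streetpa aggregate --image-scores out/image_scores.csv \
                   --points out/points.geojson \
                   --neighbourhoods out/neighbourhoods.geojson \
                   --radius 1000 --out exposure.csv
streetpa fit       --survey out/survey.csv --exposure out/exposure_1000m.csv \
                   --exposure-alt out/exposure_1500m.csv --out fits/
streetpa recover   --seed 1 --replicates 100 --out recovery/
```

All knobs (world geometry, scoring loop, outcome transform, buffer radii)
live in a single optional YAML file passed with `--config`; see
`streetpa.config.PipelineConfig` for the schema and defaults.  Outputs are
plain text: GeoJSON (planar metre coordinates), CSV and JSON.

## Layout

```
src/streetpa/
  config.py          configs, ground truth, transforms, (de)serialisation
  synthetic_data.py  world/scene/rater/survey generators, GeoJSON/CSV writers
  scoring.py         adversarial calibration loop and holdout validation
  aggregation.py     point and buffer aggregation
  mlm.py             random-intercept model, ICC, VIF, Wald tables
  pipeline.py        model suite, recovery experiments, run-all, rendering
  cli.py             click command group
tests/               unit + property tests, oracles.py, test_acceptance.py
scripts/acceptance.py
```
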