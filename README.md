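# fruitspec

Two-band spectral reflectance index optimization and machine-learning
estimation of fruit quality parameters, for proximal-sensing work on ripening
mango and strawberry.

## The problem

Destructive laboratory assays of fruit quality — chlorophyll (SPAD), total
soluble solids (TSS, °Brix), firmness (N) and CIELAB peel color (L\*, b\*) —
do not scale to orchard-level ripeness monitoring. VIS/NIR reflectance of the
fruit surface (302–1148 nm at 2 nm here) changes systematically with these
traits: the chlorophyll absorption around 670 nm fades, the red edge shifts,
and fine NIR structure evolves as fruit ripens. `fruitspec` implements the
full analysis chain that turns such spectra into trait estimates:

1. **Spectra handling** — white-reference calibration
   (`R = counts / white_counts × panel_factor`), pooled averaging of repeated
   scans, and linear resampling on the canonical 424-band grid.
2. **Spectral reflectance indices (SRIs)** — a registry of 16 indices: the
   published GI (= R₅₅₄/R₆₇₇), PSRMI (= (R₇₅₀−R₆₇₈)/R₅₅₀),
   NAI (= (R₇₆₀−R₇₂₀)/(R₇₆₀+R₇₂₀)) and NDVI (= (R₇₈₀−R₆₇₀)/(R₇₈₀+R₆₇₀)),
   plus twelve two-band ratio indices RSI(λ₁,λ₂) = R₁/R₂ from the red and
   NIR regions.
3. **Band-pair optimization** — the correlogram: R² between RSI(λ₁,λ₂) and a
   trait for *every* ordered wavelength pair (424×423 cells), with
   deterministic selection of separated peak pairs. R² is the squared Pearson
   correlation, identical to simple-regression R².
4. **Stage statistics** — per-ripening-stage Min/Max/Mean/SD tables, one-way
   ANOVA, Duncan's multiple range test (protection level
   α_p = 1−(1−α)^(p−1), studentized-range critical values, compact letters
   with the largest mean lettered "a"), and the trait Pearson matrix.
5. **Prediction models** — ANN (SGD-trained MLP), random forest and decision
   tree regressions on threshold-selected indices, with a 70/30 split,
   exhaustive 5-fold cross-validated grid search (lowest mean CV MSE wins),
   and evaluation by MSE, MAE and R² = 1 − SS_res/SS_tot.
6. **Synthetic data** — a seeded generator producing stage-labelled traits
   (truncated normals, calibrated to published per-stage summaries) and
   trait-coupled spectra, so the whole pipeline is testable end to end with
   known ground truth.

The index, band-search and model stages are scikit-learn compatible
estimators (`SpectralIndexTransformer`, `BandPairCorrelogram`,
`SRIRegressor`) and compose with sklearn pipelines and model selection.

## Worked example

```python
import fruitspec as fs
from fruitspec.synthetic import GeneratorConfig, generate_dataset

ds = generate_dataset(GeneratorConfig.mango(seed=0))   # 75 samples, 25/stage

print(fs.describe_by_stage(ds.traits, "TSS").round(2).to_string(index=False))

c = fs.build_correlogram(ds.spectra, ds.traits, "TSS")
for rank, (l1, l2, r2) in enumerate(fs.select_best_pairs(c, k=3, min_separation=20), 1):
    print(f"{rank}. RSI({l1:g}, {l2:g})  R^2 = {r2:.3f}")

res = fs.run_trait_models(ds.spectra, ds.traits, "TSS", families=("rf",), seed=0)[0]
print(f"test R2={res.test.r2:.3f} MSE={res.test.mse:.3f}")
```

prints

```
trait    stage   min   max  mean   sd  n letter
  TSS   unripe  9.36 15.83 12.41 1.69 25      c
  TSS     ripe 16.69 18.83 17.80 0.65 25      b
  TSS overripe 17.91 21.70 20.19 0.99 25      a
1. RSI(1140, 858)  R^2 = 0.996
2. RSI(1138, 796)  R^2 = 0.996
3. RSI(1138, 816)  R^2 = 0.996
test R2=0.918 MSE=0.754
```

Reading the output: TSS rises across ripening and the three stages are
mutually significantly different (Duncan letters c/b/a, P ≤ 0.05). The
correlogram locates the strongest TSS band pairs on the NIR tilt that the
generator couples to TSS, and the grid-searched random forest explains ~92 %
of held-out TSS variance on this dataset.

The same workflow is available from a shell:

```bash
fruitspec simulate --fruit mango --seed 0 --out-dir fixtures/
fruitspec correlogram --spectra fixtures/mango_spectra.csv \
    --traits fixtures/mango_traits.csv --trait TSS --top-k 12 --min-sep 10
fruitspec train --spectra fixtures/mango_spectra.csv \
    --traits fixtures/mango_traits.csv --trait TSS --families rf,dt --seed 0
fruitspec run-all --fruit mango --seed 0 --out-dir out/
```

## Layout

```
src/fruitspec/
  spectra.py     containers, calibration, scan averaging, resampling, I/O
  indices.py     the 16-index registry, safe custom formulas, transformer
  bandsearch.py  exhaustive two-band correlogram + peak selection
  stats.py       ANOVA, Duncan's MRT, stage summaries, Pearson matrix
  models.py      split / selection / grid-search / metrics, SRIRegressor
  synthetic.py   seeded trait + spectra generator with ground truth
  pipeline.py    run_all orchestration and artifact writing
  cli.py         the `fruitspec` command group
docs/methods.md  modelling assumptions, parameter choices, limitations
```
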