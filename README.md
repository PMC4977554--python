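# nucmorph

Quantitative 3D nuclear architecture analysis for single-cell volumetric
microscopy — written for researchers studying how chromatin-modifying drugs
(HDAC inhibitors such as vorinostat) reorganize the interphase nucleus of
normal, pre-cancerous and malignant epithelial cells.

The package implements, as one tested pipeline:

* **3D nuclear morphometry** on absorption-convention single-cell volumes
  (optical-CT / hematoxylin imaging): nuclear volume (µm³), the
  nuclear-cytoplasmic (NC) ratio V_n / (V_cell − V_n), the nuclear shape
  concavity index 100·(V_hull − V_n)/V_hull, and the number of dense
  intra-nuclear chromatin clumps (adaptive mean + k·σ threshold,
  26-connected components);
* **FISH gene positioning**: spot detection in confocal stacks and the
  relative radial distance RRD = 1 − ‖s − c‖ / ‖b − c‖ of each allele,
  where c is the geometric nuclear center and b the boundary along the ray
  through the spot (0 = periphery, 1 = center), plus whole-nucleus Pearson
  colocalization with a euchromatin (H3K9ac) channel;
* **Dose-response IC50 fitting** with the variable-slope four-parameter
  logistic Y = Bottom + (Top − Bottom)/(1 + 10^((LogIC50 − X)·HillSlope)),
  X = log₁₀(dose), via a statsmodels-style model/results pair;
* **Statistical reporting**: mean ± SEM summaries, Mann-Whitney and
  Kolmogorov-Smirnov group comparisons with Bonferroni adjustment,
  Anderson-Darling normality (composite hypothesis, small-sample-corrected
  p), and Pfaffl efficiency-corrected qPCR fold changes
  E_t^ΔCt_t / E_ref^ΔCt_ref;
* **A synthetic-phantom generator** that plants every ground truth the
  pipeline measures — so each stage is validated by parameter recovery.

## Worked example

Generate a single-cell phantom with five planted chromatin clumps and one
surface invagination, segment it, and measure all four morphometric
parameters:

```python
import numpy as np
import nucmorph as nm

spec = nm.CellPhantomSpec(n_clumps=5, n_invaginations=1,
                          invagination_radius_um=2.5, noise_sd=0.02, seed=7)
vol, cell_truth, nuc_truth, truth = nm.make_cell_phantom(spec)

cell = nm.segment_cell(vol)
nuc = nm.segment_nucleus(vol, cell)
rec = nm.analyze_cell(vol, cell, nuc, cell_id="demo")
```

which prints (estimates against the generator's voxel-level ground truth):

```
nuclear volume    495.6 um3   (truth   496.1)
NC ratio          0.466       (truth   0.466)
concavity          3.17 %     (truth    3.93)
dense clumps          5       (truth       5)
```

Fit an IC50 from a simulated viability plate (10-point, 3-fold dilution
from 100 µM, 6 replicates/dose, noise sd 3 on a 0–100 viability scale,
planted IC50 0.94 µM):

```python
table = nm.make_viability_table((100.0, 0.0, np.log10(0.94), -1.0),
                                noise_sd=3.0, seed=1)
res = nm.FourParamLogistic.from_dataframe(table).fit()
print(res.summary())
```

```
Four-parameter logistic dose-response fit
================================================
n observations              60
residual SS                  391.7
converged                 True
------------------------------------------------
parameter       estimate     std err
Top              99.4810      0.7805
Bottom            0.8514      0.8681
LogIC50          -0.0406      0.0175
HillSlope        -1.0275      0.0399
------------------------------------------------
IC50 (µM)         0.9108      0.0367
```

The fitted IC50 (0.91 µM) recovers the planted 0.94 µM within its standard
error; `res.params`, `res.bse` and `res.predict(doses)` expose the fit
programmatically.

An end-to-end study (three cell lines × two treatments, cohorts →
segmentation → morphometry → comparisons, plus dose-response and FISH
arms) runs from one config:

```bash
nucmorph run-study --out study_report/          # built-in scaled-down study
nucmorph simulate cohort --n-cells 50 --seed 1 --out cohort/
nucmorph morphometry --in cohort/ --out features.csv
```

`study_report/` contains `features.csv`, `ground_truth.csv`,
`summaries.csv`, `comparisons.csv` (Mann-Whitney + KS with adjusted p),
`ddr_fits.json`, `fish_spots.csv`, `fish_coloc.csv` and `report.json`.

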