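# urbanscan

Spatial and spatio-temporal analysis of area-level event rates, built for
neighbourhood-scale epidemiology of rare adverse events (urban homicide
being the motivating case). Given a polygon layer of areal units with
populations and candidate covariates, plus a table of geocoded point
events with year labels, the package runs the full analysis chain a
spatial epidemiologist would assemble from GIS tooling, SaTScan and an
MGWR calibrator — as one tested, scriptable library:

* **Rate mapping** — raw rates per 100k, global empirical-Bayes (Marshall
  method-of-moments) smoothing toward the prior mean
  m = ΣO_i/Σn_i with weights w_i = A/(A + m/n_i), and exact Fisher–Jenks
  natural-breaks classification.
* **Hotspot surfaces** — kernel density estimation
  f(x,y) = (1/nh²) Σ_i K(d_i/h) with quartic or Gaussian kernels,
  probability or count normalization, on a text raster grid.
* **Spatial autocorrelation** — global Moran's
  I = (n/S₀)·(zᵀWz)/(zᵀz) with analytic-randomization or permutation
  inference, and Anselin's local I_i = (z_i/m₂)·Σ_j w_ij z_j with
  conditional permutation and HH/LL/HL/LH labelling.
* **Scan statistics** — Kulldorff discrete-Poisson purely temporal and
  cylindrical space-time scans: LLR = c·ln(c/e) + (C−c)·ln((C−c)/(C−e)),
  population-capped circular windows, RR/OE reporting and conditional
  Monte-Carlo inference.
* **Variable selection** — Pearson screen, iterative VIF gate (cut 7.5),
  all-subsets exploratory regression ranked by adjusted R², and backward
  p-value pruning of the final OLS, with every variable assigned a
  removal stage.
* **Local regression** — GWR y_i = β₀(u_i,v_i) + Σ_j β_j(u_i,v_i)x_ij + ε_i
  with adaptive bisquare kernels and golden-section AICc bandwidth
  search, and MGWR (one bandwidth per coefficient surface, calibrated by
  backfitting) with trace(S)/ENP_j accounting, adjusted-alpha local
  inference, and a Monte-Carlo surface-variability test.
* **Synthetic data** — lattice generators with spatially correlated
  covariate fields, smoothly varying coefficient surfaces and implanted
  space-time risk cylinders, so every inferential claim is validated
  against known ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
paper-scale synthetic fixture (144 areas, 10 years, two implanted
clusters, 25 candidate covariates of which 4 are active):

```bash
python analysis/01_simulate.py
python analysis/02_rates_hotspots.py
python analysis/03_clusters.py
python analysis/04_regression.py
```

The run prints, among other things:

```
global Moran I = 0.419 (z = 9.80, p = 1.1e-22)
space-time rank 1: 9 areas, (2015, 2019), RR = 7.02, p = 0.002, best Jaccard vs truth = 1.00
excluded 10 zero-event areas; n = 134
retained: ['commercial_density', 'large_buildings', 'noise_04', 'population_density']  (true actives recovered: 3/4)
OLS residual Moran I = 0.124 (p = 0.0054)
MGWR bandwidths: {'intercept': 133, 'commercial_density': 133, 'large_buildings': 105, 'noise_04': 69, 'population_density': 27}
 MGWR 270.719606 280.168183 0.683813 0.623293               21.694622                9.897622
MGWR residual Moran I = -0.039 (p = 0.51)
```

Reading: the smoothed rates are strongly spatially clustered; the
space-time scan recovers the implanted RR=3 cylinder exactly (Jaccard 1.0
against the ground truth); the selection funnel keeps three of the four
truly active covariates (plus one false positive); the OLS residuals are
significantly autocorrelated — the same misspecification signal that
motivates local models — while the MGWR residuals are indistinguishable
from noise, and MGWR's adjusted R² improves on OLS and GWR with
coefficient-specific bandwidths separating global from local effects.

The same pipeline is available as a config-driven CLI:

```bash
urbanscan fixture /tmp/study --preset paper-scale --seed 1
urbanscan run /tmp/study/config.yaml
```

which writes every stage artifact (counts, rates, KDE raster, LISA
table, scan cluster tables and GeoJSON, screening report, GWR/MGWR
per-area coefficients and diagnostics, model comparison) plus a
machine-parseable run log.

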