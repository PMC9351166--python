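# Methods

This note records the statistical models the package implements, the
defaults and numerical choices, what the synthetic generator does and
does not emulate, and the known limitations.

## Rate smoothing

Raw area rates r_i = O_i/n_i (events per person over the pooled study
period, reported per 100,000) are unstable where n_i is small. The
global empirical Bayes estimator (Marshall's method of moments) shrinks
each rate toward the population-weighted prior mean m = ΣO_i/Σn_i with

    A   = max(0, Σ n_i (r_i − m)² / Σn_i − m/(Σn_i/N))
    w_i = A/(A + m/n_i),       eb_i = w_i r_i + (1 − w_i) m.

A is a between-area variance and is floored at zero; when it is zero all
smoothed rates collapse to m. The smoothed rate always lies between the
raw rate and m, and areas with equal raw rates shrink more the smaller
their population. A local (neighbourhood-prior) EB variant is not
implemented; the global prior matches the single-prior-mean description
of the classical estimator. Zero-population areas are excluded with a
log entry rather than receiving an undefined rate.

Jenks natural breaks are computed by the exact Fisher dynamic program
(O(k n²) with prefix sums), which the tests verify against exhaustive
partition enumeration for small n. Default class count is 5, the
conventional choropleth choice.

## Kernel density surfaces

The surface evaluates f(x,y) = (1/nh²) Σ K(d_i/h) at cell centres.
Both supported kernels integrate to one under that normalization —
quartic K(u) = (3/π)(1−u²)² for u<1, and Gaussian K(u) = exp(−u²/2)/2π —
so `scale="probability"` integrates to ≈1 and `scale="count"` (default)
to ≈n, i.e. events per m² (×10⁶ for per-km² reporting). The quartic
kernel is the default: it is the convention of desktop GIS density
tools and its compact support allows per-event local accumulation. The
default grid pads the event bounding box by one bandwidth so that mass
conservation is exact up to discretization (verified to 0.5% at cell
sizes ≤ h/10). Evaluation is at cell centres; edge correction and
adaptive bandwidths are out of scope.

## Moran autocorrelation

Global Moran's I uses the cross-product form with weights as built
(queen contiguity, row-standardized, by default — under which
mean_i(I_i) = I exactly, an identity the tests assert to 1e-10).
Analytic inference uses the randomization-assumption variance (with the
kurtosis term b₂) and a two-sided normal p; permutation inference
shuffles the values and counts |I_perm − E| ≥ |I_obs − E| with
E = −1/(n−1), so p has floor 1/(n_perm+1). Constant inputs are
rejected (zero variance).

Local Moran uses conditional permutation: z_i is held fixed and the
remaining n−1 values are drawn without replacement into the neighbour
slots. The pseudo p-value is **two-sided** (twice the smaller tail):
a one-tailed-toward-observed rule, while common in software, rejects
~10% of areas at α = 0.05 under complete spatial randomness; the
two-sided rule restores the nominal level, which the calibration tests
check. Quadrant labels come from the signs of z_i and its lag and are
masked to `not-significant` by the (optionally Benjamini–Hochberg
adjusted) pseudo-p. Defaults: 999 permutations, α = 0.05, FDR off.

## Scan statistics

Both scans use the discrete-Poisson likelihood ratio conditioned on the
study total C, with 0·ln 0 = 0 and windows failing the direction
condition scoring zero. Expected counts are indirect person-time
standardization: population × window length, scaled to sum to C — no
covariate adjustment, since the scans address raw incidence against
population at risk.

The temporal scan enumerates contiguous year windows up to 50% of the
period (1-year cells). The space-time scan grows a circle around each
area centroid over nearest-centroid areas until 50% of the population,
crossed with the same year windows. Monte-Carlo replicates redistribute
C events multinomially with cell probabilities proportional to the
expectations; the p-value ranks each reported cluster's LLR among the
replicate maxima (floor 1/(n_sim+1)). Secondary clusters are reported
greedily, sharing no areas with any better-ranked cluster; at most 10
are kept. On a one-area panel the space-time scan reduces exactly to
the temporal scan.

Under the synthetic study conditions (12×12 lattice, populations
10k–30k, ~700 events, an implanted 9-area/3-year RR=3 cylinder) the
recovery tests show the maximum-likelihood cluster's year window is
found in >90% of replicates while the *spatial boundary* matches the
implanted disc at Jaccard ≥ 0.5 in roughly three quarters of
replicates — the ML window legitimately spreads or shrinks under
Poisson noise at this signal strength; this is a property of the scan
statistic, not of the implementation.

## Variable-selection funnel

Stage 1 screens each candidate against the smoothed rate by
product-moment correlation (two-sided t test, α = 0.05). Stage 2
iteratively removes the largest-VIF variable while any VIF exceeds 7.5,
recomputing after each drop (the fixed order makes the pass
deterministic). Stage 3 enumerates all subsets of the survivors up to
size 6 and keeps models in which every slope is significant and every
VIF admissible, ranking by adjusted R², ties by AICc then lexicographic
variable order. Stage 4 refits the best subset and prunes terms with
p > α one at a time, largest first. Every input variable ends in exactly
one stage (pearson / collinearity / subset-search / ols / retained).
If no subset clears both stage-3 gates the best-fitting subset is
carried forward with a warning so the pipeline still produces a model.
y and X are z-standardized before all model fits, making coefficients
comparable across variables and the intercept near zero.

## GWR and MGWR

GWR solves a weighted least-squares problem at every site with adaptive
bisquare weights w = (1 − (d/b_i)²)², b_i the distance to the site's
k-th nearest neighbour. The single k is chosen by golden-section search
over integers in [p+2, n] minimizing

    AICc = 2n ln σ̂ + n ln 2π + n(n + tr S)/(n − 2 − tr S),  σ̂² = RSS/n,

with S assembled from the local projectors. σ̂² uses RSS/n inside AICc
(comparability across models) but RSS/(n − tr S) for coefficient
standard errors. AIC = −2ℓ + 2(trS+1) and BIC = −2ℓ + (trS+1)ln n use
the same Gaussian log-likelihood; these conventions reproduce the
published AIC/AICc/BIC/log-likelihood relations of the reference
calibration software exactly. Local inference uses the
effective-parameter correction adj-α = α(p+1)/tr S and the two-sided
Student-t quantile at df = n − tr S. In the uniform-weight limit every
local fit equals the global OLS (coefficients to 1e-10, identical AICc)
— the tests' equivalence oracle. "Gaussian model" here means a Gaussian
(least-squares) response; the spatial kernel is bisquare.

MGWR gives each term (intercept included) its own bandwidth via
backfitting: initialize the additive contributions f_j from the GWR fit
at its optimal bandwidth, then cycle over terms, calibrating a
no-intercept univariate smooth of the partial residual e_j on x_j with
its own golden-section AICc-optimal k, until the root-mean-square
change of the f_j falls below 1e-5 (SOC-f; max 200 iterations, with a
`converged` flag on the result). Per-term smoother matrices are
propagated through the backfit (A_j ← S_j(I − Σ_{l≠j}A_l)), so
ENP_j = tr A_j partitions tr S exactly and per-term adjusted alphas
α/ENP_j are available. Per-term standard errors use the univariate WLS
sandwich at the converged bandwidth — an approximation that ignores
cross-term covariance. Local R² for MGWR is a kernel-weighted R² at the
intercept bandwidth, clamped to [0,1]; the clamp is needed because the
per-site WLS optimality that bounds GWR's local R² does not carry over
to an additive backfit. Note that freezing every bandwidth at a common
value reproduces the GWR fit only approximately: the backfit fixed
point is the additive-model solution, which coincides with joint local
WLS only for site-independent smoothers.

The Monte-Carlo surface-variability test takes var_i(β_j) as statistic,
permutes the site locations, re-runs the backfit at the frozen per-term
bandwidths, and ranks the observed variance among the permuted ones
(pseudo-p floor 1/(n_iter+1); default 1000 iterations, minimum 19).
Re-running the whole backfit — rather than recalibrating the single
term from the frozen partial residual — matters: the cheap variant is
badly anti-conservative (size ≈ 13–23% at α = 0.05 on constant
surfaces) because backfit leakage in the partial residual is smooth at
the true coordinates but not under permutation. The implemented test
measures size ≈ 2% and power ≈ 100% against hotspot surfaces in the
calibration suite.

## Synthetic data

The generator emulates a mid-size city's neighbourhood system: an
nx×ny lattice of 1 km square areas with uniform-integer populations
(default 10,000–30,000, totalling ~2.9M on the 12×12 default),
zero-mean unit-variance covariate fields with exponential spatial
correlation exp(−d/range) (coloured through the symmetric square root
of the correlation matrix), coefficient surfaces that are constant,
linear ramps, or Gaussian hotspot bumps, and Poisson counts

    counts[i,t] ~ Poisson(n_i · λ₀ · exp(Σ_j β_j(u_i,v_i) x_ij) · RR_it)

with RR from implanted space-time cylinders. The paper-scale fixture
uses λ₀ = 1.66e-5 events per person-year, calibrated so the expected
event total is ~700 over 10 years — the motivating study's scale (~700
events, ~140 areas, ~2.4 per 100k per year). Event points are scattered
uniformly inside their area polygon by rejection sampling, keeping the
count panel and the point table consistent by construction.

What the generator does **not** emulate: irregular polygon shapes and
sizes, street networks and within-area event microstructure,
population change over time, covariate measurement error, and
non-Poisson overdispersion. Tests passing on this test bed therefore
validate the estimators' arithmetic and calibration, not their
robustness to those real-data features.

## Pipeline and reproducibility

The pipeline executes aggregate → rates/Jenks → KDE → global/local
Moran → temporal scan → space-time scan → screening funnel (after
zero-event-area exclusion) → residual Moran → GWR → MGWR → model
comparison, each stage writing a CSV/JSON/GeoJSON artifact and a
key=value log line. All stage seeds derive from one global seed via
`numpy.random.SeedSequence(seed).spawn`, truncated to 31 bits, so one
integer reproduces the run exactly. Config validation collects every
schema violation before any computation. Coordinates must be projected
planar metres; lon/lat-looking input is refused rather than reprojected.
Default problem sizes (199 scan replicates in the pipeline config, 999
for standalone analyses; 12×12 lattice) keep a full run in seconds
while leaving Monte-Carlo resolution adequate for p = 0.05 decisions.

## Known limitations

* Queen contiguity and row-standardization are defaults, not detected
  from data; isolated areas are carried with empty weight rows.
* The scan uses circular (not elliptic) windows and no covariate
  adjustment.
* MGWR per-term standard errors ignore cross-term covariance (see
  above); the full propagated covariance would require the joint
  smoother inverse.
* The "degree of dependency" diagnostic printed by some MGWR software
  has no published closed form and is not reported.
* No CRS handling: inputs are assumed already projected to metres.
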