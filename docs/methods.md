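# Methods

## Model

The response is the cluster-level proportion of a population under five
years of age, `y_i ∈ [0, 1]`, observed at a recorded location `s_i`
(decimal degrees) and an integer survey-wave index `t_i`. The model is a
Gaussian process regression on the identity scale:

    y_i = x(s_i)'β + f(s_i, t_i) + ε_i,      ε_i ~ N(0, σ_e²)  iid,

with a separable space–time covariance for the zero-mean latent field `f`:

    Cov(f(s,t), f(s',t')) = σ² · (κh) K₁(κh) · ρ^|t−t'|,

`h` the Euclidean distance in degrees between `s` and `s'`, `K₁` the
modified Bessel function of the second kind. The Matérn smoothness is fixed
at ν = 1 (the two-dimensional default of the precision-based formulation
this family of models is usually fitted in); the nominal range — the
distance at which spatial correlation falls to about 0.1 — is `√(8ν)/κ`.
Distances are kept in degrees throughout; kilometres are presentation only,
converted at a documented constant of 111.32 km/degree with latitude
dependence ignored (appropriate for near-equatorial geographies).

A Gaussian likelihood on proportions (identity link) is a deliberate
modelling choice rather than a binomial one: cluster proportions aggregate
enough households that the Gaussian error is a reasonable description, and
it keeps every conditional distribution closed-form. Its known cost is that
predictions are not constrained to [0, 1]; surfaces are clipped with the
number of clipped cells logged and reported.

## Parameters

| parameter | meaning | units | default (generator) |
|---|---|---|---|
| `beta` | fixed effects incl. intercept | proportion per sd of covariate | intercept 0.1815, others ~±0.004 |
| `sigma2` | Matérn marginal variance | proportion² | 7e-4 |
| `kappa` | spatial scaling (range = √8/κ) | 1/degree | √8/4.5 ≈ 0.63 |
| `nugget` | measurement-error variance σ_e² | proportion² | 2.2e-3 |
| `rho` | AR(1) coefficient across waves | — | −0.47 |
| `nu` | Matérn smoothness | — | 1 (fixed) |

The generator defaults are the magnitudes a national multi-survey analysis
of this outcome produces; they make the synthetic studies realistic rather
than easy (the spatial signal σ² is a third of the nugget).

## Inference

β and the total variance `s² = σ² + nugget` have closed-form generalized
least-squares solutions given the correlation structure, so the likelihood
is concentrated down to three free parameters: the spatial variance share
`w = σ²/s²` (logit scale), `log κ`, and `atanh ρ`. A bounded L-BFGS-B search
runs from several dispersed starts (variance share × range guess × ρ sign);
the reported optimum is the best of the starts.

Identifiability floor: spatial structure with a range below the data spacing
is likelihood-equivalent to nugget variance. The nominal range is therefore
bounded below by twice the median nearest-neighbour distance among clusters,
which resolves the micro-scale/nugget confounding in the conventional
direction (sub-resolution variation belongs to the nugget).

Uncertainty is summarized Laplace-style: the numerical Hessian of the full
log-likelihood over `(β, log σ², log κ, atanh ρ, log nugget)` at the
optimum, inverted to a covariance. Quantiles for transformed parameters are
mapped back through the monotone transform (so variance quantiles stay
positive and |ρ| < 1); the reported natural-scale sd uses the delta method.
Summary tables carry mean / sd / 5% / 50% / 95% columns.

Because the covariance parameters are weakly identified at realistic
signal-to-noise, plug-in (profile) standard errors understate fixed-effect
and predictive uncertainty. Both are therefore integrated over covariance-
parameter uncertainty: ~60 draws from an over-dispersed (×1.5) Laplace
Gaussian on the transformed covariance parameters are re-weighted by the
restricted (β-integrated) likelihood, and the fixed-effect sd and —
optionally (`integrate_hyper=True`) — the predictive mean/variance are
mixture quantities over that ensemble (law of total variance). The top
draws covering 98% of the importance mass (max 25) are retained on the
`FitResult` for prediction. `predict_interval` goes one step further than
moment matching: the integrated predictive is a weighted Gaussian mixture,
and the interval endpoints solve the mixture CDF by bisection — wider in the
tails than a Gaussian of the same variance whenever the ensemble members
disagree, which is exactly when plug-in intervals undercover.

Model comparison uses DIC = D(θ̂) + 2·p_D with D(θ̂) = −2 log marginal
likelihood at the optimum and p_D the trace of the hat matrix that maps `y`
to the fitted structured mean (fixed effects + latent field) at plug-in
parameters — the Gaussian effective-parameter count. The reported
"marginal likelihood" is the GP marginal over the latent field; no
hyperparameter-level integration is claimed, and the fit result says so.

## Prediction

Universal kriging per cell:

    μ* = x*'β + k*' K⁻¹ (y − Xβ),
    var* = C(0,0) − k*' K⁻¹ k*  (+ β-uncertainty term)  (+ nugget),

with the β-uncertainty term `(x* − X'K⁻¹k*)' (X'K⁻¹X)⁻¹ (x* − X'K⁻¹k*)`
included by default. `include_nugget=False` (default) predicts the
noise-free latent proportion — the mapping target; `True` predicts a new
noisy observation and is used when scoring holdout clusters. Intervals are
central Gaussian intervals at a configurable level (default 95%; the
summary-table 5%/95% columns correspond to a 90% central interval — both
are available and outputs state which was used). Cells are processed in
tiles of 4096 so memory stays bounded; nodata cells propagate as NaN and
ASCII rasters store them as −9999.

## Validation

* Holdout: a seed-reproducible simple random split (test size =
  round(n·fraction); 10% of 1624 clusters gives 162). MPE is
  mean(predicted − observed) — the sign convention is stated because
  "over-prediction" language is otherwise ambiguous. MAE, RMSE and
  Pearson's r complete the score.
* CPO: with `Q = K⁻¹` and `r = Q(y − Xβ)`, the leave-one-out predictive for
  observation i is Gaussian with mean `y_i − r_i/Q_ii` and variance
  `1/Q_ii`, evaluated at `y_i`. Covariance parameters and β are held at
  their estimates (no per-i refit), which is exactly the delete-one
  conditional density of the fitted joint Gaussian; tests verify this
  against the naive oracle. In the iid limit (σ² = 0) it reduces to the
  normal density of the residual with variance = nugget, with no n/(n−1)
  adjustment — the plug-in convention, stated here.
* Semivariogram: `γ(b) = mean of ½(r_i − r_j)²` over pairs in distance bin
  b, on leave-one-out standardized residuals by default. Envelopes are
  pointwise min/max over 99 seed-controlled permutations of residuals across
  fixed locations. Two residuals are enough for the point estimate; the
  envelopes are only meaningful at realistic n. Empty bins are flagged, not
  errors.

## Synthetic data

The generator emulates what the model assumes: smooth standardized
covariate fields (plus an integer land-cover code in {0..5} and a
night-lights layer whose top decile defines "urban"), cluster placement
stratified urban/rural over the grid mask, a joint Kronecker draw of the
separable field across all waves (and optional held-out evaluation sites,
so calibration tests know the latent truth), Gaussian noise, and
count back-filling `n_under5 = round(p · n_people)` — `p_under5` stays the
continuous modelled response; readers check count consistency only to
rounding. Recorded coordinates are displaced like anonymised survey
clusters (uniform bearing, distance uniform on [0, D] with D = 2 km urban /
5 km rural / 10 km for a 1% far-rural fraction), while the response is
built at the *true* location — deliberately reproducing the
covariate-mismatch error source of real geomasked surveys.

What it does not emulate: probability-proportional-to-size two-stage
sampling and survey weights, within-urban covariate heterogeneity,
non-Gaussian measurement error, and covariate measurement error. Passing
recovery and calibration tests therefore demonstrates correctness of the
estimator under its own assumptions, not robustness to the full messiness
of real surveys.

## Coverage application

Proportion surfaces × population raster → under-five count surfaces
(mean/lower/upper cellwise). Zone totals sum cells per integer zone label;
NaN-zone or NaN-count cells fall into an explicit "unassigned" bucket so
national totals are conserved exactly. Zone bounds sum cellwise bounds — a
conservative envelope, since cell-level posterior correlation is not
retained in the surfaces (posterior-sample aggregation is the noted
extension). Comparator denominators: a flat national proportion (UN-style,
default 17.5%) and per-zone census-style proportions. Unprotected counts
are denominator × (1 − coverage) with coverage supplied per zone; whether
coverage proportions were age-restricted in their source is the caller's
responsibility and is not re-weighted here.

## Numerical choices

* Cholesky everywhere; escalating diagonal jitter from 1e-10 to 1e-6 of the
  mean diagonal, then a hard failure with eigenvalue diagnostics.
* Optimizer bounds: variance share logit in ±16, range between the
  nearest-neighbour floor and 5× the domain extent, |ρ| ≤ tanh(5) ≈ 0.9999.
* Best-subset ties break by (BIC, fewer covariates, lexicographic names);
  `k` in BIC counts intercept + slopes + variance.
* Land cover enters selection and fitting as a single numeric code column,
  mirroring analyses that report one "land cover" coefficient; dummy
  encoding is a caller-side alternative.
* Covariate extraction at cluster locations is nearest-cell by default;
  a buffer-averaged mode (configurable radius in degrees) is available to
  soften displacement error.
* Survey waves map calendar years to integer indices; concurrent surveys
  share an index (e.g. {2008, 2010, 2010} → {0, 1}), configurable.
* All randomness flows from explicit integer seeds; the pipeline derives
  per-stage seeds as `(root · 1_000_003 + crc32(stage)) mod 2³¹`.

## Study sizes used in the shipped checks

The replicated recovery study runs 20 replicates of 800 clusters over
2 waves on a 10°×10° domain at the default generating magnitudes, and pools
95%-interval calibration over 25 fresh sites per replicate (500 sites
total) — pooling matters because sites within one replicate share a field
realization and are far from independent. The study uses the faithful
generator, geomasking displacement included; at these magnitudes the
displacement (≤ 0.09°) is negligible against the 4.5° range and measurably
does not change the study's results (a `displace=False` switch exists for
diagnostics).

Interval calibration is checked at the full survey size (1624 clusters,
8 replicate fields, ~500 pooled fresh sites). A known, honestly-reported
size effect: at the default magnitudes the spatial variance is only a third
of the nugget, and in the scaled-down 800-cluster mode the variance/range
likelihood is wide enough that the integrated intervals cover the latent
truth at roughly 91% for a nominal 95% level, recovering to in-band
coverage at the full size (the same machinery measures ~95% when the
covariance parameters are supplied exactly). Both numbers are recomputed
and reported by the acceptance script (`prediction_interval95_coverage`
and `..._scaled`). This is the classic cost of estimating weakly identified
covariance parameters from smaller surveys. The demo pipeline runs a 50×50
grid with 300 clusters. These sizes are the package's reference
configuration for a desk-scale dense-GP implementation (n ≤ ~4,000 by
design; the sparse-precision route is an explicit non-goal here).

## Known limitations

* Dense covariance algebra bounds n at a few thousand clusters.
* Laplace/importance summaries approximate a posterior; heavy-tailed or
  multimodal hyperparameter likelihoods are summarized optimistically.
* Gaussian identity-scale likelihood can predict outside [0, 1] (clipped,
  logged).
* Zone interval bounds are conservative envelopes, not joint quantiles.
* The AR(1) wave process with 2–3 waves is weakly identified; ρ estimates
  carry wide intervals (as their summaries show).
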