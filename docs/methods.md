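# Methods

## Scope and data model

The pipeline estimates plot-level cotton yield (t·ha⁻¹) from 8-bit RGB plot
tiles. One `PlotSample` is a plot × observation-date record: a pixel-space
ROI (0-based half-open box, or WKT polygon rasterised with the
pixel-centre-inside rule), treatment labels (variety, defoliant
concentration C1–C4, spray time T1–T6, days after spraying), the measured
yield and an image reference. The interchange object between stages is the
`FeatureTable`: samples × named real-valued columns, each tagged with a
family (`color`, `vi`, `texture`), plus the yield target. Orthomosaic
stitching, georeferencing and radiometric calibration are out of scope; the
pipeline starts from cut plot tiles.

Ground truth follows the boll-survey arithmetic: single-boll weight =
10-plant yield / 10-plant boll count; theoretical yield = single-boll weight
× boll density, with 1 g·m⁻² = 0.01 t·ha⁻¹.

## Colour features and vegetation indices

Indices are evaluated at the ROI-mean colour, not per pixel (a per-pixel
mode exists behind a flag for sensitivity studies). The chromatic rows and
the 13 indices are implemented as quotients of the standard definitions;
two widely propagated typographical variants are resolved to the standard
forms: NGBDI = (g−b)/(g+b) and U = 0.493(B−Y). GLA is computed on raw
channel means as printed in its source, which is algebraically identical to
GLI on chromatic coordinates — both columns are kept. Denominators with
|d| < 1e−12 yield NaN (WI with r = g, VARI with g + r = b, all ratios on a
black plot); NaN propagates and the modelling stage drops NaN-containing
columns by default (row-drop is available). R, G, B enter HSV, L\*a\*b\*
(D65, 2°) and YIQ conversions through scikit-image on the unit scale.

## Texture

GLCMs use equal-width quantisation of the 8-bit range into L = 32 levels by
default (the choice is configurable; results are insensitive in the 16–64
range on the synthetic scenes), distance 1 px, symmetric accumulation, at
the four offsets 0°→(0,+d), 45°→(−d,+d), 90°→(−d,0), 135°→(−d,−d). Only
pairs with both pixels inside the ROI are counted; out-of-ROI neighbours
are skipped, never padded. Gray values default to rounded luminance
(0.299R + 0.587G + 0.114B); a per-band mode computes the statistics on each
channel and averages them, since plot-level practice varies. Entropy uses
the conventional minus sign and log base 2; contrast uses (i−j)²;
correlation is NaN when a marginal is degenerate. The four statistics are
aggregated across angles by mean and *population* SD.

## Screening

Raw scores per feature against yield: |Pearson r| (constant features score
0); MIC; random-forest impurity importance (500 trees, seeded); RFE with
ordinary linear regression on z-scored features, step 1, scored by inverse
elimination rank. Scores are min-max normalised to a [0, 1] screening
probability (all-equal scores map to 1.0 and selection falls back to column
order; ties break by column order). Selection keeps the top 6 within a
family, or the top 3 VIs plus top 3 texture features in fusion mode, each
screener producing its own set.

MIC is computed by a bundled quantile-grid approximation: over all grid
shapes (kx, ky) with kx·ky ≤ n^0.6 (per-axis bins capped at 15), both
variables are binned at empirical quantiles and normalised mutual
information I/log₂ min(kx, ky) is maximised. Because it is rank-based it is
exactly invariant under strictly monotone transforms and reaches 1 for
monotone functional relationships; it is an approximation in that it does
not optimise irregular axis partitions, which mainly lowers scores for
non-monotone relationships.

Screening always runs on the training split only; a canary test asserts
that a feature informative only on validation rows is never selected.

## Models

All models sit behind a z-scoring pipeline fit on training statistics only,
tuned by exhaustive grid search with seeded 5-fold CV minimising RMSE and
refit on the full training split (reported "Cal" metrics are refit-on-train,
not CV, metrics). Default grids: PLSR components 1..min(10, p); Elastic-Net
α ∈ 10^{−3..1}, l1_ratio ∈ {0.1, 0.5, 0.9}; KRR (RBF) and SVR (RBF)
α/C, γ over 10^{−3..1} with C ∈ {1, 10, 100}, ε ∈ {0.01, 0.1}; MLP one
hidden layer ∈ {8, 32, 128}, lbfgs solver (adam converges too slowly at
n ≈ 200); ELM hidden ∈ {20, 50, 100, 200}, ridge λ ∈ {0, 10⁻⁶, 10⁻³}.
"Elastic-Net" is the elastic-net linear regressor. KRR is conventionally
grouped with the linear methods here; with an RBF kernel it is of course a
nonlinear learner, which matters when interpreting linear-vs-nonlinear
comparisons (see Limitations).

The ELM is implemented from scratch: inputs are affinely mapped to [−1, 1]
by training min/max, input weights and biases are drawn i.i.d.
uniform(−1, 1) from a seeded generator and never trained, the hidden layer
is sigmoid (tanh available), and the output weights solve the centred ridge
system β = (HᵀHc + λI)⁻¹ Hᵀyc with an unpenalised intercept; λ = 0 uses the
minimum-norm least-squares solution. Refits are bit-identical given the
seed; with n_hidden ≥ n and λ = 0 the ELM interpolates generic training
data; a constant target is reproduced exactly for any input.

The default split is 199 training / 116 validation at n = 315 (ratio
199/315 ≈ 0.632), seeded.

## Metrics

R² is the *squared Pearson correlation* between measured and predicted
values — deliberately implemented in that form, so it is insensitive to
additive and multiplicative bias (a pure offset keeps R² = 1 while RMSE
grows); RMSE is in t·ha⁻¹ and rRMSE = 100·RMSE/x̄ with x̄ the mean measured
yield of the evaluated split. Constant predictions get R² = 0 by convention;
constant measured vectors are an error. The inversion table bins plots at
3.62 and 8.33 t·ha⁻¹ by default (configurable) and reports per-bin mean
signed error (predicted − measured) and RMSE: positive low-bin error is
low-yield overestimation, negative high-bin error is the saturation-driven
underestimation of high-yielding plots.

## Synthetic data: what it emulates, and what it does not

Two tiers. The **image tier** composites mulch-film strips and soil, green
canopy ellipses whose cover is `canopy_cover · (1 − defoliation)`, and
white boll disks (~3.5 cm diameter at the default 0.3 cm/px) whose count is
yield × 100 / boll weight × tile ground area, plus additive Gaussian DN
noise clipped to [0, 255]. A trial is 48 plots × 5 dates with defoliation
advancing over dates while each plot keeps one harvest yield. The **table
tier** skips rendering: VI columns are sign·(a·y/(y+k) + η_vi + ε) with a
Michaelis–Menten saturation constant k = 3 t·ha⁻¹ (the response visibly
flattens above ~6 t·ha⁻¹) and one family-wide latent η_vi; texture columns
are sign·(b·y + η_stat + ε) with one latent per GLCM statistic, so the six
variants of a statistic are nearly collinear while the four statistics form
partly independent channels. Greenness-type indices and ENT/CON fall with
yield; NDI, ExR, CIVE and ASM/COR rise.

Yields are truncated-normal on [0, 11.58] t·ha⁻¹ with the *truncated*
moments calibrated toward mean 3.00 and SD 2.91 t·ha⁻¹ (the descriptive
statistics of the emulated multi-treatment trial). The family cannot be
made that skewed: at mean 3 on this interval its CV ceiling is ≈ 87%, so
the fitted distribution lands at mean ≈ 3.0, SD ≈ 2.55 (CV ≈ 85%), the
closest member. The fit weights the mean 10:1 over the SD and is cached.

Noise calibration (defaults sd_vi = 0.14, sd_tex = 0.8 per column, latent
multiples 0.19/0.14 and 3.1/0.8): chosen so single-feature |Pearson r| with
yield lands in the 0.5–0.65 band typical of plot trials and so the family
ordering VI < texture < fused emerges from the structure rather than being
imposed. Setting noise to (0, 0) disables the latents too, giving exactly
monotone responses.

What the generator does **not** model: radiative transfer, sensor PSF,
illumination gradients, plot-edge effects, within-plot yield gradients,
date-specific yield trajectories (dates differ only through defoliation),
and any real-data covariance between families beyond the planted latents.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that the documented qualitative behaviours follow from the
assumed structure — not that a particular accuracy will be achieved on
field imagery.

## Numerical choices and degenerate inputs

Feature CSVs round-trip at 12 significant digits with NaN as empty fields;
columns are ordered colour → VI → texture → yield. GLCM construction raises
if an ROI admits no valid pair at an offset. Ties in screening break by
column order. Grid cells that fail on every CV fold are skipped with a
warning; an all-failing grid is an error. Yield predictions are unclipped
by default (a clip-at-zero flag exists). Seeds default to 42 and every
stochastic component (generator, splits, forests, MLP, ELM input weights)
takes an explicit seed.

## Known limitations

* The R² convention rewards correlated-but-biased predictors; compare RMSE
  alongside it.
* rRMSE uses the evaluated split's mean measured yield; splits with very
  low mean inflate it.
* The MIC approximation under-scores non-monotone dependence relative to
  the full partition-optimising estimator.
* KRR with an RBF kernel blurs the linear/nonlinear dichotomy; pairwise
  "nonlinear beats linear" claims are only asserted against the strictly
  linear regressors, with KRR handled at the ordering level.
* The truncated-normal yield family cannot reach the skew of a CV ≈ 97%
  trial; the generator approaches it from below (CV ≈ 85%).
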