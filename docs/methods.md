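# Methods

This note records the statistical models implemented in `immunosig`, the
defaults that matter, the numerical choices, and what the synthetic-data
suites do and do not demonstrate.

## Data model and preprocessing

The ground format is a samples × peptides matrix of raw fluorescence
(RFU, expected in [0, 65,500]; 16-bit scanner scale) with per-sample group
labels and per-peptide annotations, including an `empty_spot` flag for
printed positions carrying no peptide (used to gauge background; excluded
from testing and factoring). A minimal GenePix-results (GPR) dialect is
read by skipping ATF-style header lines and requiring
Block/Row/Column/Name/ID plus one signal column (default "F635 Median"),
one file per sample.

Preprocessing is per-slide median normalization followed by log10: each
sample row is divided by its own median and multiplied by the grand median
of per-sample medians, which removes global intensity bias while keeping
values on the RFU scale; the per-sample constants are stored so the
transform is invertible. No background subtraction is applied anywhere —
arrays of this type show low, consistent background (~150–300 RFU against
3+ logs of dynamic range), and subtracting it degrades reproducibility. A
`zero_offset` (default 1 RFU) is added before the log so occasional zero
spots survive; with backgrounds of hundreds of RFU this leaves real signal
essentially untouched. Group descriptives (mean/min/max/SD/variance/range)
pool every spot of every sample in a group and are computed on the **raw**
scale, where the 16-bit magnitudes are meaningful.

## Per-peptide screening

Two-group contrasts use the Welch t-test with Satterthwaite degrees of
freedom (df interpolates between min(n)−1 and n₁+n₂−2), two-tailed
p-values, one test per printed peptide, on the log10-normalized values.
Familywise error is controlled by Bonferroni with m equal to the number of
peptides actually tested (empty spots excluded from both m and the
output). Ranking ties are broken by |t| descending then peptide id, so
output order is reproducible. Degenerate input (zero variance in both
groups with equal means) returns t = 0, p = 1 by convention. Logistic and
multinomial logistic regressions (statsmodels IRLS) are provided as
covariate-capable alternatives; separation is reported through a
`converged` flag, not an exception.

## Exploratory factor analysis

Estimation is the OLS/eigen route: principal axis factoring with iterated
communalities, initialized at squared multiple correlations, iterating
eigendecompositions of the reduced correlation matrix until the largest
communality change falls below 1e-6 (default; max 200 iterations).
Communalities exceeding 1 (Heywood cases) are clipped to 1−1e-6 and
flagged per variable rather than raised. PCA is available as the
uniqueness-zero mode.

Rotations: varimax (Kaiser row-normalized, SVD ascent), promax
(varimax → |loading|^κ sign-preserving target → oblique procrustes;
κ = 4 by default, the classic choice, exposed as a parameter), and geomin
(gradient-projection minimization of the geomin criterion, ε = 0.01, 30
random orthogonal starts with the best criterion kept — the criterion is
multimodal). Every factor column is sign-flipped so its largest-|loading|
entry is positive, making output deterministic. Oblique rotations return
the pattern matrix and factor correlation R_f; the reconstruction
A R_f A′ + D² and the communalities are invariant across rotations of the
same unrotated solution.

Sample classification runs the analysis transposed — samples as variables,
peptides as observations — with one factor per disease group. A sample is
assigned to the factor carrying its largest |pattern loading| when that
loading reaches the threshold (default 0.3); below-threshold samples are
unclassified and never count as correct. Factors are mapped to groups by
the permutation maximizing matches (exhaustive; group counts here are
small), and accuracy is percent correct among labeled samples. Pattern
(not structure) loadings are used after oblique rotation.

The advisory factor count is the largest *relative* eigenvalue drop among
components with eigenvalue above 1.0 — an automated stand-in for visual
scree inspection. A ratio criterion is used because an elbow is a ratio
feature: with one strong and one moderate factor the largest absolute drop
sits after the first eigenvalue even when two factors are plainly present.
The count is advisory and user-overridable everywhere.

## Confirmatory factor analysis and SEM

The measurement model is x = Λξ + δ with covariance structure
Σ(θ) = ΛΦΛ′ + Θ. Each factor is scaled by one fixed nonzero loading
(default: first indicator at 1) or a fixed variance. Fitting minimizes
F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − v by L-BFGS-B with analytic gradients;
residual and factor variances are optimized on the log scale (enforcing
positivity, floored at 1e-8 with an at-bound flag), factor covariances
directly. Convergence tolerance 1e-10 on F_ML, max 500 iterations; start
values are moderate loadings on the observed scale with half the observed
variance as residual. χ² = (n−1)·F_ML; model df is v(v+1)/2 minus the
free-parameter count (covariance structure only). RMSEA uses the
non-centrality form clamped at zero; with df = 0 (just-identified models)
RMSEA and p are NaN markers while SRMR — computed over all v(v+1)/2 unique
elements of the residual matrix standardized by √(S_ii·S_jj), diagonal
included — is still reported. Standard errors come from the numerical
Hessian of the discrepancy (delta method back to the natural scale);
Huber–White sandwich standard errors are available as an option
(`robust=True`). Point estimates are plain ML throughout and the fit
indices use the plain ML χ².

Confirmatory sample classification transposes the data (samples as
indicators), fixes one randomly chosen (seed-controlled) reference sample
per group factor at loading 1, lets every other known sample load freely
on its group's factor only, and gives held-out samples free loadings on
all factors; assignment thresholds the standardized loading at 0.3, for
consistency with the exploratory rule.

Structural models regress disease status on the latent factors. The
default two-stage route fits the measurement model, computes Bartlett
factor scores ξ̂ = (Λ′Θ⁻¹Λ)⁻¹Λ′Θ⁻¹(x − x̄), and runs a logistic or
multinomial regression of status on the scores. The joint route integrates
the latent factors out with Gauss–Hermite quadrature (15 nodes per
dimension, one or two factors) and maximizes the full likelihood; its
structural standard errors come from the observed information. The
structural direction is disease ~ latent factor — the only direction under
which odds ratios for developing disease are defined. Odds ratios are per
unit of the factor on its scaling metric, with a per-SD column as a
secondary scale since the metric is arbitrary. A joint model with more
indicators than observations is refused with advice to use a top-k subset
or the two-stage route.

Second-order models let the first-order factors load on one common higher
factor. Identification: with two first-order factors both second-order
loadings are fixed at 1 and the higher factor's variance is free; with
three or more, the variance is fixed at 1 and the loadings are free. With
exactly two first-order factors the hierarchical structure is
covariance-equivalent to a correlated-factor model restricted to a
nonnegative covariance bounded by the factor variances — so rejection of
the shared-construct hypothesis at m = 2 manifests when that restriction
binds (e.g. negatively correlated factors), and the test suite exercises
exactly that regime. This equivalence is a property of the model class,
not of the implementation.

## Factor mixture models

A categorical latent class variable indexes class-specific parameters of a
factor model: within class k, y = V_k + Λ_k η + ε with η ~ N(0, Ψ_k) and
shared diagonal residuals Θ, giving class density N(V_k, Λ_kΨ_kΛ_k′ + Θ).
The default, minimal model frees only the intercepts V_k across classes
(loadings and residuals shared); fully class-specific loadings are a flag.
Ψ_k is fixed to the identity for identification and the reported per-class
loadings are rotated afterwards (geomin by default, promax fallback) —
rotation changes neither LL nor BIC nor posteriors.

Estimation is EM (the mixture-of-factor-analyzers form), with the number
of starts configurable (default 20): the first start is a k-means-style
partition, later starts perturb it; each start's final log-likelihood is
logged for local-solution inspection and the best is kept. The EM
log-likelihood is asserted non-decreasing at every iteration. Classes are
relabeled by descending weight so output is deterministic given the seed.
A class whose weight falls below 1/n triggers one restart and a flag.
Class enumeration uses BIC = −2LL + p·ln n (natural log); classification
crispness is summarized by the K × K average-latent-class-probability
matrix (entry (j,k): mean posterior of class k among observations modal in
j; empty modal classes yield NaN rows).

On well-separated two-class data a third class does not stay empty under a
well-optimized EM — splitting an existing cluster always raises the
likelihood — so the reproducible three-class diagnostics are a *higher*
BIC than K = 2 and a split that stays inside one true class rather than
straddling both; the suites test those.

## Synthetic generator

The generator draws the data-generating process the latent-factor models
assume. For sample i and peptide p,

    log10(RFU_ip) = b_p + Σ_f λ_pf η_fi + ε_ip

with peptide baselines b_p ~ N(2.5, 0.15) (≈320 RFU typical signal),
noise ε ~ N(0, 0.12) on the log scale (multiplicative on RFU, matching the
3+ logs of dynamic range), and latent antibody factors: factor f loads on
a configured set of peptides (disjoint between factors unless overlap is
requested) with |λ| drawn from a configured range and sign (+: reactivity
raised in the shifted group; −: suppressed). Factor scores are
η_fi ~ N(shift_g, sd_g²) with group-dependent mean and SD — an antibody a
group never raises contributes neither mean nor variance there. Values are
back-transformed, clipped to the 65,500 ceiling, and empty spots are drawn
uniformly from the 150–300 RFU background range. The default design
mirrors a three-group breast-cancer study: 52 normal / 98 single-tumor /
21 second-tumor samples and 10,375 peptides with 1,172 empty spots.
Competitive binding is represented only through its variance footprint in
ε, not as an explicit ligand-competition simulation — the estimators under
test see only second moments.

Two presets define the study conditions for the suites. The two-group
high-separation preset plants one antibody per group (25 peptides each,
loadings 0.25–0.45, shift 2 SD in its own group, SD 0.2 in the other);
under it the transposed promax EFA classifies ≥95% of samples. The
second-tumor preset combines a shared tumor antibody, a strong
second-tumor-specific antibody, a suppressed antibody (negative loadings,
lowering the second-tumor floor), and 1.4× second-tumor noise, reproducing
the qualitative pooled-range ordering second > single > normal. These
effect sizes are design choices, stated here once and tunable; the
simulation suites are scaled to a few hundred peptides (same structure as
the full 10,375-spot array), which keeps the default test run around a
minute and the acceptance script around two.

What passing suites show — and what they do not: the generator is
multivariate log-normal with exact low-rank-plus-diagonal structure,
independent samples, and disjoint loading sets. Real immunosignatures add
heavy tails, spatial artifacts, batch structure, cross-reactive overlap
between antibodies, and non-normal factor-score distributions. The suites
therefore validate *estimator correctness under the assumed model* (type-I
calibration, parameter recovery, model selection, fit-index behavior), not
clinical classification performance.

## Discovery pipeline

The orchestrated procedure: normalize → transposed-EFA sanity check (with
cross-loading samples reported, never removed) → Welch/Bonferroni
screening → EFA on the significant peptides with relative-eigenvalue-drop
factor-count inference (user-overridable) → CFA measurement model → SEM
odds ratios → direction annotation (increased vs decreased in the disease
group, from log-scale group means). Zero significant peptides stop the
pipeline after screening with an explicit notice rather than an exception.
When the retained peptides exceed the identification budget (default 30
indicators) the structural stage keeps the top-ranked peptides per factor
and says so. Factors whose scores correlate above 0.9 are flagged as
collinear and single-factor structural models are fitted alongside the
joint one, since shared variance can leave only one of two similar factors
significant in a joint regression. Reports are deterministic given inputs
and seed (byte-identical on re-run).

## Known limitations

- ML CFA assumes multivariate normal indicators; no categorical-indicator
  (probit/WLSMV) variant, no mean-structure or multi-group invariance
  testing, no modification indices, and no scaled (robust) χ² — the
  sandwich option adjusts standard errors only.
- Quadrature SEM supports at most two latent factors (tensor grids grow
  exponentially); larger structural models use the two-stage route.
- The mixture model shares residual variances across classes; per-class
  residuals would add v(K−1) parameters the small sample sizes here cannot
  support.
- Oblimin rotation, FDR-based screening, and latent transition models are
  out of scope.
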