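# Methods

## The measurement model

The factor-analyzable NEWS-Y-IPEN items follow a confirmatory factor model

    y = Λ η + ε,   η ~ N(0, Φ),   ε ~ N(0, Θ),   Σ(θ) = Λ Φ Λ′ + Θ,

with each item loading on exactly one of five latent factors —
Accessibility & walking facilities (AW, 5 items), Traffic safety (TS, 3),
Pedestrian infrastructure & safety (PI, 3), Safety from crime (CR, 4),
Aesthetics (AE, 3) — and the a priori (pre-respecification) model using six
factors over 22 items.  Items worded against walkability or safety (AW1,
TS1, TS3, CR1–CR4) carry negative loadings; no pre-reversal is applied in
the CFA, reversal belongs to scoring only.

Identification uses unit latent variances by default (all loadings free),
so the free inter-factor covariances are correlations and the estimates are
essentially standardized; marker scaling (first loading per factor fixed at
1, latent variances free) is available and yields the same degrees of
freedom and standardized solution, a property the test suite checks.  Model
df is p(p+1)/2 minus the free-parameter count.

### What is, and is not, authoritative in the built-in catalog

The published record gives per-country *counts* of freed inter-factor
covariances (recovered here from the published df: free = 135 − df − residual
pairs, which matches the printed count of significant inter-factor
correlations in nine of ten countries) and of correlated-error item pairs,
but not their identities, except the factor pair of the largest correlation.
The built-ins therefore place the published maximum-correlation pair first,
fill the remaining free covariances in a fixed canonical order, and draw
error pairs from a fixed within-factor list.  These choices reproduce the
published df exactly but are *not* authoritative as to which specific
covariances were freed; both sets are overridable on a hand-built spec.
For New Zealand the published df (128) implies seven free covariances while
five correlations are printed as significant; the df-consistent seven is
used so that the df reproduces.

## ML estimation

The discrepancy F_ML(θ) = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p is minimized by
L-BFGS-B with an analytic gradient (dF = tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹)·dΣ/dθ]).  Error
variances are log-parameterized (soft floor 10⁻⁶; hitting it flags a
Heywood case), unit-scaling factor correlations are bounded at ±0.995, and
a non-positive-definite Σ proposal returns a large penalty.  Starts are
loadings 0.7·sign·sd(item) (sign from reference loadings when known,
rescaled to the marker metric under marker scaling), error variances
0.51·s_ii, factor correlations 0.2.  A second polish pass from the first
solution guards against early ftol exits.  Convergence failures are
returned flagged on the results object, not raised.

χ² = n_eff · F_min with n_eff = N − 1 for raw data and N − G for pooled
within-cluster covariance input (singleton clusters are dropped and
counted).  Which multiplier convention the original EQS analyses used is
not documented; the difference is immaterial at these sample sizes but
prevents digit-exact replication of the published fit statistics even with
the raw data.

Fit indices: CFI = 1 − max(χ²−df, 0)/max(χ²_b−df_b, χ²−df, 0) with the
independence baseline in closed form (F_b = Σ ln s_ii − ln|S|,
df_b = p(p−1)/2); RMSEA = √(max(χ²−df,0)/(df·n_eff)) with the 95 % CI from
inverting the noncentral-χ² CDF in its noncentrality parameter (bisection
to 10⁻⁸, RMSEA reported as 0 with a flag when df = 0); SRMR is the root
mean square over all p(p+1)/2 unique standardized residuals *including the
diagonal* (the source never defines its "SRMS"; with free error variances
the diagonal residuals are near zero, so the inclusion is mostly
inconsequential and is documented here for reproducibility).  Standard
errors come from the inverse observed information (n_eff/2 times the
numerical Hessian of F in the natural parameterization); Wald z = est/SE
with normal p-values.  Modification indices are univariate score tests
((n_eff/2)·g²/h by central differences) for fixed-to-zero factor and error
covariances — reporting only, no automated re-specification, since the
original human-guided model search is out of scope.

Because no independent SEM implementation is available in this
environment, the engine is cross-checked in the tests against the Spearman
closed form for one-factor triads, a from-scratch Nelder-Mead minimization
of the textbook discrepancy on a two-factor model, perfect-fit and
saturated-model identities, and scale-invariance/marker-equivalence
properties.

## Scoring protocol

Residential density is Σ wᵢrᵢ with w = (1, 11, 25, 50, 75, 100) over
responses 0–4; the published theoretical range "0–1000" is inconsistent
with these weights (all-4 responses give 1048) — the weights are applied
as printed and not rescaled.  The duplicated "multi-family houses of 1–3
stories" description for items 2 and 3 (weights 11 and 25) is treated as a
transcription artifact.  Proximity subscales are plain means on 1–5; Likert
subscales are means on 1–4 after reverse-coding x → 5 − x of the
negative-loading items (the reversal set is inferred from the loading
signs, as it is not enumerated anywhere).  Missingness is listwise per
subscale; an optional "mean of ≥ 80 % answered" mode exists but is off by
default, matching the complete-data analyses.  Variants: Denmark drops the
sixth density item (weights 1–75); Nigeria uses six of the nine recreation
slots — the exact dropped facilities are configurable, defaulting to the
last three slots, since the supplementary scoring tables are not
reproduced here.

## Synthetic cohorts: what they emulate and what they do not

Per-country profiles carry the published sample sizes (total N = 5714),
age and sex summaries, and subscale means/SDs.  Subscale scores are
country mean + unit intercept + residual with the unit share of
within-country variance set by `unit_icc` (default 0.05 — no unit-level
ICCs are published; the value is small, plausible for administrative areas,
and configurable).  Each country gets 16 administrative units (four per
stratum of the 2×2 SES-by-walkability recruitment design; unit counts are
not published) with exposures assigned at unit level, balanced by
construction; ages are uniform on 11–19 and sex is Bernoulli at the
published country percentage.  Item responses are drawn from each country's
final measurement model: factors are multivariate normal with a uniform
inter-factor correlation on the free pairs (default: the published
average absolute correlation for that country; the full matrices are not
printed), items are λ·η + ε with residual variance 1 − λ², optionally
discretized to 1–4 at equal-probability normal cut points.  Likert
discretization attenuates correlations relative to continuous mode, which
the tests document qualitatively.

These cohorts match the study's *marginal* structure, not its joint
microdata: item responses are generated independently of the subscale-score
columns, exposure effects are injected additively on scores with the
published signs and magnitudes, non-normality and informative missingness
are absent, and New Zealand's adolescent-report status gets no
distributional adjustment (no generative parameters exist for it).  Passing
recovery tests therefore demonstrates correctness of the estimators under
the model, not fidelity to every feature of the real data.

## Variance decomposition and validity models

Both stages use statsmodels' `MixedLM`.  REML is the default: with only 15
countries, ML's divisor noticeably shrinks the country component relative
to the published shares.  The decomposition is an intercept-only model with
a random country intercept (plus a unit variance component when requested);
the share is 100·σ²_country/Σσ².  The default optimizer occasionally stalls
at zero-variance boundaries, so fitting falls back through Powell and CG,
keeping the first converged result (L-BFGS is excluded: it can report
convergence with untouched fixed effects on boundary problems).  On
balanced designs the REML components equal the one-way ANOVA
method-of-moments estimator, which serves as the independent oracle.

Validity models are identity-link linear mixed models (the published
"generalized" models with continuous outcomes reduce to this; the reported
unbounded coefficients are consistent with it): score ~ SES + walkability +
age + sex + country dummies, random intercepts for administrative unit
(school available as a nested component), Wald CIs b ± 1.96·SE with normal
p-values — deliberately simpler than Satterthwaite-type df corrections,
which matters little at thousands of observations.  Hypothesis evaluation
compares each estimate's sign and significance at α = 0.05 with the a
priori grid and labels unexpected significant associations.

## Problem sizes used in the checks

Loading recovery uses n = 20 000 continuous observations (every
standardized loading within ±0.03 of its generating value); the
self-consistency CFI check uses n = 2000; variance-share recovery simulates
all 15 countries at their published sizes, averaged over three seeds, and
lands within ±2 points of the published 42.2 % (Residential density) and
29.9 % (Safety from crime); type-I calibration of the validity exposure
tests runs 500 null replicates of a four-country, 600-respondent cohort —
sizes chosen to make Monte-Carlo error small relative to the tolerance
while keeping the default test run quick.

## Known limitations

Ordinal-data estimators (WLSMV etc.), full-information ML for missing
items, multi-group simultaneous fitting and invariance constraints,
random slopes and crossed random effects, and the iterative model-search
procedure are all out of scope.  The exact freed-covariance and
correlated-error identities in the built-in country models are documented
guesses, as above.  Published coefficient values from the real data
(fit statistics, loadings, association estimates) are carried as reference
inputs for simulation, not as quantities the package claims to reproduce
from raw data.
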