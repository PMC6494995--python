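# Methods

## Model

Observations are a genetic diversity response at points on a dendritic
stream network — one point per population (site) for `Ae`, `Fis`, `uHe`,
`Ho`, or one point per genotyped individual for `HL`.  The model is a
Gaussian linear mixed model

y = Xβ + ε,  Cov(ε) = Σ(θ) = Σ_c σ²_c R_c(α_c) + σ₀² I,

with up to one component per type (tail-up, tail-down, Euclidean) and a
nugget always present.  Assumptions: the network is a forest of rooted
trees (each segment drains to at most one downstream segment); basins are
hydrologically disjoint, so stream components contribute exactly zero
covariance between basins; the response is approximately Gaussian on its
natural scale; repeated or zero-distance points are legal, distinctness
being carried by the nugget.

### Distances and weights

For a pair of points in one basin, `D[i,j]` is the distance from *i*
downstream to the first point of *j*'s downstream path.  Flow-connected
pairs have one zero leg and total stream distance `h = D[i,j] + D[j,i]`;
flow-unconnected pairs have two positive legs `a ≤ b`.  A point lying
exactly at a junction is flow-connected to both branches (its leg is
zero).  Tail-up weights use the additive function value (AFV): each
segment's proportional influence (PI) at its confluence is its share of
*cumulative drainage area* among the converging segments (the additive
attribute is an open choice in the standard SSN workflow; area is always
available and encodes "stronger influence downstream"), and
`AFV = Π PI` down to the outlet.  The weight between flow-connected
points is `sqrt(AFV_up/AFV_down)`.

The hydrologic index `DA` is Σ(area × precipitation) over the point's
segment and all upstream segments, in km²·m (precipitation mm/1000), a
discharge surrogate that is non-decreasing downstream.

### Autocovariance functions

All forms are parameterised so the fitted range α is the *effective*
range — autocorrelation is zero (compact forms) or numerically zero
(factor e⁻³) at distance α.  With `r = h/α`, `ra = a/α`, `rb = b/α`:

| family | flow-connected (tail-up ×W, tail-down) | tail-down flow-unconnected |
|---|---|---|
| exponential | σ²e^(−3r) | σ²e^(−3(ra+rb)) |
| spherical | σ²(1 − 3r/2 + r³/2)·1{r≤1} | σ²(1 − 3ra/2 + rb/2)(1−rb)²·1{rb≤1} |
| linear-with-sill | σ²(1−r)·1{r≤1} | σ²(1−rb)·1{rb≤1} |
| mariah | σ²ln(90r+1)/(90r), σ² at r=0 | σ²(ln(90ra+1)−ln(90rb+1))/(90(ra−rb)); σ²/(90ra+1) if a=b |

Euclidean components use d/α with exponential, spherical, Gaussian
σ²e^(−3(d/α)²) and Cauchy σ²/(1+(d/α)²) forms.  Positive
semidefiniteness of every component and mixture is enforced by
construction and checked property-based over randomized networks
(minimum eigenvalue ≥ −10⁻⁸·trace).

### Estimation

β is profiled out by GLS; θ = (log σ²_c, log α_c, log σ₀²) is optimised
numerically (L-BFGS-B) on −2·log-likelihood, ML or REML (the REML
objective adds log|XᵀΣ⁻¹X|).  Likelihood surfaces are multimodal in the
ranges, so starts come from a deterministic grid — three range values
(0.1, 0.5, 1.5 × the largest relevant distance) per component, equal
variance split — pre-screened by objective value, keeping the best
`n_starts` (default 3) for full optimisation.  Ranges are box-bounded to
[10⁻² m, 10 × network diameter]; a fitted range on its bound is flagged
(`range_at_bound_`), not an error — a range of ~0 m is a legitimate
boundary answer meaning "no spatial structure at observable scale".
Ill-conditioned Σ gets an escalating diagonal ridge starting at
10⁻⁸·trace.  The nugget-only model bypasses the optimiser: β̂ = OLS and
σ̂₀² = RSS/(n−p) (REML) or RSS/n (ML), exactly.

AIC is computed from the ML log-likelihood at θ̂ with
k = p + (2·components + 1) parameters.  Coefficient tests are Wald t
with n−p degrees of freedom (the reference distribution is an open
choice; t is the conservative default for n ≈ 30 sites).

### Cross-validation and variance decomposition

Leave-one-out predictions are universal kriging with θ̂ held fixed,
computed with the projection identity: with
Q = Σ⁻¹ − Σ⁻¹X(XᵀΣ⁻¹X)⁻¹XᵀΣ⁻¹, the LOO residual at i is (Qy)_i/Q_ii.
This equals the explicit per-point (n−1)×(n−1) kriging solve (asserted
against that brute-force oracle in the tests) at a fraction of the cost.
RMSPE is the root mean square of those residuals.

The decomposition reports R² = corr(Xβ̂, y)² and residual shares
(1−R²)·σ̂²_c/(Σσ̂² + σ̂₀²), which sums to one by construction.  This
pseudo-R² is one of several possible definitions; it is chosen because
it guarantees the sum-to-one structure of the reported decomposition.
R² is defined as 0 for an intercept-only (constant) fit.

### Two-step selection

Step 1 fixes a permissive covariance structure — exponential tail-up +
tail-down + Euclidean + nugget, the most agnostic member of the model
space (which structure to fix is an open choice; fixing a maximal
mixture avoids biasing the covariate screen toward any one spatial
scale) — and fits all 2^k covariate subsets by ML, ranking by AIC with
ties broken by fewer covariates then name.  Step 2 freezes the winning
covariates and fits all 125 covariance skeletons by REML, ranking by
LOOCV RMSPE with ties broken by fewer covariance parameters then
enumeration order.  REML fits with different fixed effects are never
compared.  Non-convergent candidates are recorded with infinite RMSPE
rather than dropped.

## Genetic estimators

Per locus within a population with n scored individuals:
Ho = heterozygote fraction; He = 1 − Σp²; uHe = 2n/(2n−1)·He;
Ae = 1/Σp²; AR = allele count (plain count, no rarefaction); PA = alleles
absent from every other population in the dataset (dataset scope is the
stricter reading of "private"; per-region privacy can be recovered by
subsetting).  Population values are unweighted means over loci with
data.  Fis = 1 − mean(Ho)/mean(uHe) — the simple multilocus moment
estimator; no null-allele correction is attempted (a Bayesian
null-allele-aware Fis is a different method and out of scope here), so
Fis is interpretable jointly with the permutation p-values rather than
as an absolute inbreeding rate.

The Hardy–Weinberg test permutes alleles into new diploid pairs within
population × locus (n_perm ≥ 99, default 999) and uses multilocus Fis as
the statistic; p-values use the add-one estimator (never exactly zero):
P1 (excess) counts permutations with Fis ≤ observed, P2 (deficit)
with Fis ≥ observed.  Under permutation only Ho varies, so the
implementation recomputes only the heterozygote counts, vectorised.

Differentiation per group of populations: Hs = unweighted mean
within-population He, Ht = He of unweighted mean frequencies, averaged
over loci with ≥2 populations scored; Gst = (Ht−Hs)/Ht;
G'st = Gst·(k−1+Hs)/((k−1)(1−Hs)); D = (k/(k−1))·(Ht−Hs)/(1−Hs);
Weir–Cockerham θ uses the standard a, b, c components summed over
alleles and loci (ratio of sums, the canonical multilocus form).

Clone detection groups exactly identical multilocus genotypes (missing
pattern included — deterministic and conservative; near-matches are not
merged).  For each repeated genotype, p_gen = Π(p² or 2p_a p_b) over
scored loci with whole-dataset frequencies and
Psex = 1 − (1−p_gen)^(N−1).

Benjamini–Yekutieli: step-up with thresholds k·α/(m·c(m)),
c(m) = Σ1/i — valid under arbitrary dependence, as appropriate for
many correlated per-population tests.

## Synthetic data

The generator emulates the design the pipeline expects: ~8 independent
basins in 3 regions, ~30 sites, 6–55 diploid individuals per site
(skewed draw averaging ≈20, so study-scale totals of ≈600), 12
microsatellite loci with K = 8 ancestral alleles, ~1% clonal duplicates
and ~1% missing genotypes.

Networks are random recursive binary trees (lengths log-normal, median
2 km; incremental areas Gamma(2, 5) km²; precipitation a smooth
outlet-to-headwater gradient on a basin base value), embedded in the
plane by continuing each parent segment's bearing with bounded random
turns so Euclidean and in-stream distances are commensurate.  Site
covariates: ALT rises with distance upstream; the thermicity-like and
summer-drought-like indices follow two *different* planar gradients plus
noise, keeping their VIFs low as in real bioclimatic screens.

Allele frequencies follow a Dirichlet drift-with-admixture cascade over
*segments*: leaf segments draw Dir(τ_up·ancestral) (strong drift,
default τ_up = 20); every downstream segment draws
Dir(τ_down · PI-weighted mixture of its upstream segments) (mild drift
plus admixture, default τ_down = 200).  Running the cascade over
segments rather than sampled sites means every real confluence
contributes admixture, so allelic evenness — and hence Ae — accumulates
downstream by construction, which is the drift-hypothesis signature the
pipeline is meant to detect.  Genotypes are drawn with site inbreeding
F_s = expit(base + link·z_s) on a standardised covariate; the intercept
(default −6) keeps F ≈ 0 when the link is off, so the no-link case is
plain Hardy–Weinberg sampling.  Clones copy an earlier individual at
the same site; missingness hits whole genotypes.

What the generator does **not** emulate: mutation models (SMM/IAM),
linkage, null alleles and scoring error, pollen versus seed dispersal
mechanics, temporal dynamics, or coalescent genealogies.  Passing
recovery tests on these data therefore demonstrates correctness of the
estimators and of the fitting/selection machinery under the assumed
generating structure — not robustness to the measurement artefacts of
real microsatellite panels.

### Verification problem sizes

The parameter-recovery experiment uses 20 replicates of 100 sites placed
with shared segments on compact 25-segment basins: near-zero-distance
flow-connected pairs identify the nugget against the sill, and
spatially-close but flow-unconnected sibling branches discriminate
tail-up from Euclidean structure — a deliberately informative design for
a ratio that is weakly identified on sparse networks.  Calibration uses
200 null Hardy–Weinberg datasets (30 diploids × 5 loci, 199
permutations), a 5000-individual HWE draw, and 10 study-scale genotype
simulations for the downstream Ae–DA rank correlation.  Distance and
kriging oracles run on 100 random forests of ≤60 points and explicit
per-point solves respectively.

## Known limitations

* The pseudo-R² and the step-1 fixed structure are defensible choices
  among several; other software may report numerically different R² and
  step-1 rankings on the same data.
* Ranges are only weakly identified when sampling is sparse relative to
  the true range; expect boundary flags and wide sill/range trade-offs
  on small n.
* The permutation HWE test is exchangeable-allele based; it does not
  model null alleles, which inflate apparent deficit in real data.
* No spatial prediction at unsampled locations is provided beyond
  leave-one-out cross-validation.
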