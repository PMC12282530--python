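# Methods

## The modelling problem

Tomato inflorescences are normally unbranched or weakly branched; mutations
in the paralogue pairs *PLT3*/*PLT7* (PLETHORA transcription factors) and
*J2*/*EJ2* (SEPALLATA MADS-box genes, with *EJ2* represented by a series of
promoter alleles) release branching to varying degrees, and they do so
non-independently. The package models the total number of branching events
`y_i` counted across a plant's `t_i` scoreable inflorescences as an
overdispersed count with `t_i` acting as a known exposure:

    y_i ~ NegativeBinomial(mean = t_i * f^{-1}(mu(x_i)), overdispersion = alpha)

where `x_i` is the plant's genotype at the four loci and `f` is the link
(log throughout, identity only for the additive-vs-multiplicative
comparison). The NB2 variance is `m + alpha*m^2`; a single `alpha` shared
across plants captures plant-to-plant variability beyond Poisson noise.

### Genotype bases

Each biallelic locus is coded additively, `s_a in {-1, 0, +1}` for
homozygous wild type / heterozygote / homozygous mutant, plus a dominance
indicator `s_d in {0, 1, 0}` for the heterozygote's deviation from the
semi-dominant midpoint. The multi-allelic *EJ2* promoter locus is expanded
into six mutually exclusive biallelic loci (one per allele); plants not
carrying an allele code as wild type at it, and no interaction columns are
generated between two *EJ2* allele loci because no plant ever carries two.
The pairwise basis extends the additive one with the four products
(aa, ad, da, dd) for every compatible locus pair. Columns that are
constant, all-zero, duplicates, or sign-flipped duplicates of an earlier
column (which arise whenever a locus is fixed wild type, because its
additive code is the constant -1) are dropped, with reasons recorded, so
the same code handles any cross design.

### The hierarchical multilinear model

Within each paralogue pair the model is saturated: one free log-scale
effect per non-wild-type within-pair genotype class (`phi_PLT` over joint
PLT3/PLT7 states; `phi_SEP` over joint EJ2-allele/EJ2-state/J2 states),
equivalent to arbitrary dominance and epistasis within the pair. The two
pair phenotypes then combine through a single multilinear interaction and
an exponential inverse link:

    mu(x) = theta_WT + phi_PLT(x) + phi_SEP(x) - theta_Int * phi_PLT(x) * phi_SEP(x)
    E[y_i] = t_i * exp(mu(x_i))

`theta_Int > 0` means mutations in one pair progressively mask the effects
of the other: the fold effect of a PLT combination in a SEP-mutant
background with effect `phi_b` is `exp(phi_PLT * (1 - theta_Int*phi_b))`,
so log effects are linearly rescaled with slope `1 - theta_Int*phi_b`
(exactly 1 for every background under the multiplicative special case
`theta_Int = 0`). This slope law is what the background-rescaling analysis
estimates from genotype-season means, and what the total-least-squares
fits test.

Only classes observed in the data receive a parameter; unobserved classes
are excluded, not imputed. If only one pair segregates, `theta_Int` is
unidentifiable and is fixed at 0 with a warning.

## Fitting

GLM-style fits (`count_glms.fit_count_glm`) maximize the exact NB
likelihood directly with L-BFGS on analytic gradients, jointly over the
coefficients and `log(alpha)` (with `log(alpha)` box-bounded in
[log 1e-8, log 1e3] for numerical safety). The tests cross-check the
log-link NB fit against `statsmodels.NegativeBinomial` as an independent
oracle. Identity-link fits whose means go non-positive are refit through a
softplus barrier (scale 0.01 branching events, floored at 1e-10) and
flagged; the additive identity-link model genuinely predicts negative
means for weak genotype classes, which is part of why the log link is the
baseline.

The hierarchical fit uses the Adam optimizer (learning rate 0.01, 10,000
iterations by default, convergence declared when the maximum gradient
magnitude drops below 1e-5, checked every 100 iterations) followed by an
L-BFGS polish so results are deterministic to optimizer tolerance.
Gradients are analytic; no autodiff framework is used. Initialization
starts at the multiplicative model: `theta_WT` and the phi tables are
seeded from the additive log-link GLM's predictions, `theta_Int = 0`, and
`alpha` from the same fit. Confidence statements for `theta_Int` use the
profile likelihood (outward walk plus bisection to 1e-3), since the
curvature can be asymmetric near masking saturation; Wald intervals from
the observed information are available for the other parameters.

Genotype-season means are estimated jointly with one dummy per
genotype-season combination and a shared `alpha`: the means are solved by
per-group Newton iterations nested inside a scalar profile optimization
over `log(alpha)`, which makes the combination means exact stationary
points (with equal exposures they equal `sum(y)/sum(t)` to machine
precision). Wald 95% CIs are computed on the log scale and
back-transformed; combinations with all-zero counts sit on the boundary
and are flagged degenerate, and CIs spanning more than a thousand-fold
range are flagged for reporting (never used to filter fits).

### Numerical notes

- `negbin_loglik` switches to an exact finite-sum form of
  `gammaln(y+r) - gammaln(r)` when `1/alpha > 1e6`, where the naive
  difference cancels catastrophically; this makes the Poisson limit
  accurate to well below 1e-6 at `alpha = 1e-10`.
- Deviance is computed against the plant-level saturated model at each
  fit's own `alpha` (zero-count plants contribute zero in the limit).
  Because the saturated likelihood moves with `alpha`, percent deviance
  explained is only guaranteed monotone across nested bases at a common
  `alpha`; `fit_count_glm(fixed_alpha=...)` provides that variant.
- Covariances come from finite differences of the analytic gradient
  (central, relative step 1e-5), symmetrized and inverted.
- Total least squares is the principal axis of the centred point cloud via
  SVD; a vertical principal axis or a degenerate cloud raises.

## Model comparison and cross-validation

Model fits are compared by percent deviance explained against the
intercept-only model, likelihood-ratio tests (noting that the NB-vs-Poisson
test sits on the `alpha >= 0` boundary, where the chi-square(1) tail is
conservative), and AIC evidence ratios `exp((AIC_b - AIC_a)/2)`. Synergy
contrasts measure a within-pair double mutant against the multiplicative
expectation, `mu(double) - mu(single1) - mu(single2) + mu(WT)` on the log
scale of the pairwise fit, with Wald CIs and two-sided z-tests and no
multiple-testing correction.

Cross-validation holds out whole seasons or genotype groups, fits on the
remainder, and scores the squared Pearson correlation between
`log(1+predicted mean)` and `log(1+held-out genotype-season MLE mean)`
per fold, averaged over folds. The `log(1+x)` scale and the MLE-based
held-out summary are recorded in the result metadata because other R²
conventions (plant-level, pooled) give different numbers.

## The synthetic-data generator

The generator emulates the study design: six F2 populations (one *EJ2*
promoter allele each, 384 plants by default, assignable to seasons with
optional log-scale season offsets), each segregating PLT3, PLT7, J2 and
the population's EJ2 allele independently at 1:2:1. Phenotypes come from
the hierarchical model: each plant draws a gamma multiplier with mean 1
and variance `alpha`, shared across its (default 10) inflorescences, whose
counts are conditionally Poisson, so plant totals are exactly NB2.
Observational artifacts are reproduced: per-inflorescence counts above the
censor value (60) are recorded as "too many to count" and treated as 60
at summarization, and inflorescences can be marked proliferated/inhibited
(excluded from both `t` and `y`) with configurable probabilities, 0 by
default.

The default truth tables are anchored on the study's published effect
sizes: wild-type mean 0.2 branching events per inflorescence, an 11.24-fold
homozygous *plt3* effect, a ~2-fold *plt7* effect, near-cryptic single
*EJ2* promoter alleles (5-25% effects), a modest *j2* effect, within-pair
synergies of the magnitude reported for each pair (about 3.3-fold excess
for *plt3*-*plt7* combinations and 6-17-fold for *EJ2*-*j2* doubles,
scaled down for heterozygous combinations), `theta_Int = 0.12` and
`alpha = 0.3`. These values were fixed once, from the published magnitudes,
as the generator's study conditions.

What the generator does not emulate: linkage (loci assort independently;
the real loci sit on different chromosomes but no map is modelled),
selection or transplanting losses, spatial field effects, season-by-genotype
interactions, and genotyping error. Passing closed-loop tests therefore
demonstrates correctness of the estimators under the model's own
assumptions, not robustness to these real-data features.

## Design choices on open points

- Censoring is applied at summarization (a TMTC inflorescence contributes
  exactly 60) and no censored-likelihood correction is attempted,
  matching the study's treatment; plants with no countable inflorescences
  are dropped because the likelihood requires `t >= 1`.
- The hierarchical model is fit pooled across seasons (no season terms in
  the mean); season labels matter only for genotype-season MLEs and
  cross-validation folds.
- Background-rescaling pairs estimates either within matched seasons or on
  season-pooled log means (`season_handling`), pooled by default; the
  choice is recorded in each slope's metadata.
- The nested-model check of the multiplicative reduction (`theta_Int = 0`)
  is run on a cross where each pair has one segregating locus, so the
  hierarchical model has exactly one parameter more than the
  multiplicative model and the expected log-likelihood gap is half a
  chi-square(1); on richer designs the saturated within-pair tables add
  tens of degrees of freedom and a likelihood gap of that order is the
  expected behaviour of nested models, not evidence of masking.
- Problem sizes in the test suite (for example 20 replicates of ~4,000
  plants for recovery, one population at 2,000 plants/season for the
  closed-loop cross-validation check) were chosen as the smallest designs
  at which the corresponding statistical property is comfortably
  identified.

## Known limitations

- The pairwise basis retains 84 interaction columns on the full
  six-population design; retained/dropped counts are reported per fit so
  they can be reconciled with any externally stated term count.
- Identity-link NB fits rely on the softplus barrier when the additive
  model predicts non-positive means; the resulting deviance is a
  barrier-regularized quantity and such fits carry an explanatory note.
- Wald CIs for genotype-season means undercover slightly at very small
  per-combination sample sizes (2-3 plants), as Wald intervals do.
- `theta_Int` is a single scalar; asymmetric masking (PLT masking SEP more
  than the reverse) is outside the model family.
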