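# hierbranch

Genotype–phenotype modelling of inflorescence branching in multi-locus
tomato crosses, built around a **hierarchical multilinear epistasis
model** of how two paralogue pairs — the PLETHORA transcription factors
*PLT3*/*PLT7* and the SEPALLATA MADS-box genes *J2*/*EJ2* (the latter a
series of promoter alleles) — jointly set the mean number of branching
events per inflorescence.

The package is for quantitative geneticists analysing branching counts
from segregating populations: it provides the count likelihoods, the
genotype design bases, the hierarchical model with its derived
quantities (fold effects, response surfaces, background-rescaling
slopes), and a Mendelian F2 simulator so every estimator can be
validated closed-loop without field data.

## The model

A plant with genotype *x* and *t* countable inflorescences accumulates
branching events

&nbsp;&nbsp;&nbsp;&nbsp;*y* ~ NB(*t* · e^{μ(x)}, α),&nbsp;&nbsp;Var(*y*) = *m* + α·*m*²,

where α is a single overdispersion parameter shared across plants.
Three nested descriptions of μ(x) are supported:

1. **Multiplicative** (additive on the log scale): μ = θ₀ + Σ_l θ_l^a s_l^a + θ_l^d s_l^d,
   with additive coding s^a ∈ {−1, 0, 1} and dominance coding
   s^d ∈ {0, 1, 0} per locus.
2. **Pairwise epistasis**: the additive basis extended with the four
   products (aa, ad, da, dd) for every compatible locus pair.
3. **Hierarchical multilinear**: free effects φ_PLT and φ_SEP for every
   within-pair genotype class (equivalent to arbitrary dominance and
   epistasis *within* each pair), combined *between* pairs by a single
   masking parameter:

&nbsp;&nbsp;&nbsp;&nbsp;μ(x) = θ_WT + φ_PLT(x) + φ_SEP(x) − θ_Int · φ_PLT(x) · φ_SEP(x).

With θ_Int = 0 the pairs combine multiplicatively on the count scale;
θ_Int > 0 means mutations in one pair linearly rescale — mask — the log
effects of the other, so the effect of a PLT combination in a SEP
background with effect φ_b shrinks to φ_PLT·(1 − θ_Int·φ_b). That slope
law is testable directly from genotype–season mean estimates via total
least squares.

Fits are exact maximum likelihood: L-BFGS with analytic gradients for
the GLMs, and Adam (10,000 iterations with a convergence check) plus an
L-BFGS polish for the hierarchical model, with profile-likelihood
confidence intervals for θ_Int. See `docs/methods.md` for assumptions,
numerical choices and limitations.

## Worked example

```python
from hierbranch import *

# simulate a study-scale cross and fit the three models
design = CrossDesign()                       # six F2 populations, 384 plants each
truth = default_truth()                      # theta_int=0.12, alpha=0.3
records = simulate_dataset(design, SimulationConfig(truth=truth, seed=7))
print(f"{len(records)} plants, "
      f"{len({r.genotype.label() for r in records})} genotype classes")

null = fit_count_glm(records, ModelSpec("intercept", "log", "negbin"))
mult = fit_count_glm(records, MULTIPLICATIVE)
pw = fit_count_glm(records, PAIRWISE)
hier = fit_hierarchical(records)

print(f"deviance explained: multiplicative {deviance_explained(mult, null):.2f}%, "
      f"pairwise {deviance_explained(pw, null):.2f}%")
print(f"AIC hierarchical - pairwise: {hier.aic - pw.aic:.2f} "
      f"(evidence ratio {relative_likelihood(hier.aic, pw.aic):.3g})")
print(f"masking parameter theta_int = {hier.params.theta_int:.3f}, "
      f"alpha = {hier.params.alpha:.3f}")

fold_wt = fold_effect(hier.params, {"PLT3": LocusState.MUT_HOM})
fold_bg = fold_effect(hier.params, {"PLT3": LocusState.MUT_HOM},
                      {"J2": LocusState.MUT_HOM, "EJ2pro8": LocusState.MUT_HOM})
print(f"plt3 homozygous fold effect: {fold_wt:.2f} in WT, {fold_bg:.2f} in j2 EJ2pro8")
```

Output:

```
2304 plants, 333 genotype classes
deviance explained: multiplicative 9.94%, pairwise 10.03%
AIC hierarchical - pairwise: -43.46 (evidence ratio 2.74e+09)
masking parameter theta_int = 0.121, alpha = 0.290
plt3 homozygous fold effect: 10.64 in WT, 5.39 in j2 EJ2pro8
```

Reading this: the pairwise model barely improves percent deviance
explained over the multiplicative one on this dataset, but the
hierarchical model is decisively preferred by AIC despite having far
fewer parameters, because one masking parameter (recovered here as
θ_Int ≈ 0.121 against a generating value of 0.12) captures the
systematic between-pair interaction. The same masking shows up as the
~10.6-fold effect of a homozygous *plt3* mutation in a wild-type
background shrinking to ~5.4-fold in a *j2 EJ2* mutant background.

A command-line interface mirrors the library
(`hierbranch simulate | fit | fit-hier | compare | contrast | cv | mle |
slopes | surface | recover`), reading and writing delimited-text tables
and JSON reports. Real data enter through the same tables: one row per
plant (genotype at the four loci, population, season, `t`, `y`) or one
row per inflorescence with an outcome column (a count, `TMTC`,
`proliferated` or `inhibited`), which the reader summarizes with the
standard censoring and exclusion rules (TMTC → 60; proliferated and
inhibited excluded).

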