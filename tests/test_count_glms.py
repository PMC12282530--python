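"""Likelihoods, GLM fitting, model comparison and synergy contrasts."""

import numpy as np
import pytest
from scipy import special, stats

from hierbranch.count_glms import (
    MULTIPLICATIVE,
    PAIRWISE,
    FitResult,
    LRTResult,
    ModelSpec,
    build_design,
    cross_validate,
    deviance_explained,
    fit_count_glm,
    likelihood_ratio_test,
    negbin_loglik,
    poisson_loglik,
    predict_mean,
    relative_likelihood,
    synergy_fold_excess,
)
from hierbranch.genotype_encoding import Genotype, LocusState
from hierbranch.phenotype_data import PlantRecord
from hierbranch.synthetic_data import (
    CrossDesign,
    SimulationConfig,
    default_truth,
    multiplicative_truth,
    simulate_dataset,
)

from .conftest import make_records, plt_j2_genotypes, random_genotypes

WT, HET, MUT = LocusState.WT_HOM, LocusState.HET, LocusState.MUT_HOM


# ---------------------------------------------------------------------------
# Likelihoods


def test_poisson_loglik_closed_forms():
    assert poisson_loglik([0], [1], [1.0]) == pytest.approx(-1.0, abs=1e-12)
    # direct evaluation of m^y e^-m / y! with m = 3
    m = 2 * 1.5
    expected = 2 * np.log(m) - m - np.log(2)
    assert poisson_loglik([2], [2], [1.5]) == pytest.approx(expected, abs=1e-12)


def test_poisson_loglik_vanishing_exposure_limit():
    base = poisson_loglik([1], [1], [2.0])
    with_tiny = poisson_loglik([1, 0], [1, 1e-9], [2.0, 2.0])
    assert abs(with_tiny - base) < 1e-6


def test_negbin_zero_count_closed_form():
    """P(y=0) = (1 + alpha*m)^(-1/alpha): log P = -2*log(2) at alpha=0.5, m=2."""
    assert negbin_loglik([0], [1], [2.0], 0.5) == pytest.approx(-2 * np.log(2), abs=1e-10)


def test_negbin_poisson_limit_random_fixtures():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = rng.integers(1, 8)
        y = rng.integers(0, 30, size=n)
        t = rng.integers(1, 12, size=n).astype(float)
        mu = rng.uniform(0.1, 8.0, size=n)
        assert abs(negbin_loglik(y, t, mu, 1e-10) - poisson_loglik(y, t, mu)) < 1e-6
    assert negbin_loglik([3], [2], [1.0], 0.0) == poisson_loglik([3], [2], [1.0])


def test_likelihood_domain_errors():
    with pytest.raises(ValueError):
        negbin_loglik([1], [1], [1.0], -0.1)
    with pytest.raises(ValueError):
        poisson_loglik([1], [1], [0.0])
    with pytest.raises(ValueError):
        poisson_loglik([1], [0], [1.0])


def test_negbin_concave_in_alpha_at_mle(small_records):
    """The profile in alpha is maximal at the jointly fitted alpha."""
    fit = fit_count_glm(small_records, MULTIPLICATIVE)
    y = [r.y for r in small_records]
    t = [r.t for r in small_records]
    mu = predict_mean(fit, [r.genotype for r in small_records])
    ll_hat = negbin_loglik(y, t, mu, fit.alpha)
    for factor in (0.7, 0.9, 1.1, 1.4):
        assert negbin_loglik(y, t, mu, fit.alpha * factor) <= ll_hat + 1e-8


# ---------------------------------------------------------------------------
# Fitting


def test_single_genotype_log_negbin_mean_is_total_ratio():
    records = make_records([Genotype()] * 6, [3, 0, 7, 2, 5, 1], t=4)
    fit = fit_count_glm(records, MULTIPLICATIVE)
    mean = predict_mean(fit, [Genotype()])[0]
    assert mean == pytest.approx(sum(r.y for r in records) / sum(r.t for r in records), abs=1e-8)


def test_fit_matches_statsmodels_oracle(small_records):
    """Independent check against the NB2 MLE from statsmodels."""
    import statsmodels.api as sm

    dm = build_design(small_records, MULTIPLICATIVE)
    y = np.array([r.y for r in small_records])
    t = np.array([r.t for r in small_records], dtype=float)
    ours = fit_count_glm(small_records, MULTIPLICATIVE)
    theirs = sm.NegativeBinomial(y, dm.values, exposure=t).fit(disp=0, maxiter=200)
    np.testing.assert_allclose(ours.coefficients.values, theirs.params[:-1], atol=1e-4)
    assert ours.alpha == pytest.approx(theirs.params[-1], abs=1e-3)
    assert ours.loglik == pytest.approx(theirs.llf, abs=1e-4)
    # covariance of coefficients agrees with statsmodels' observed-information SEs
    np.testing.assert_allclose(
        np.sqrt(np.diag(ours.covariance.values)), theirs.bse[:-1], rtol=0.02
    )


def test_aic_identity_and_param_count(small_records):
    for spec in (MULTIPLICATIVE, ModelSpec("additive", "log", "poisson")):
        fit = fit_count_glm(small_records, spec)
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik, abs=1e-9)
        expected_p = len(fit.coefficients) + (1 if spec.family == "negbin" else 0)
        assert fit.n_params == expected_p


def test_fit_is_deterministic(small_records):
    a = fit_count_glm(small_records, MULTIPLICATIVE)
    b = fit_count_glm(small_records, MULTIPLICATIVE)
    np.testing.assert_array_equal(a.coefficients.values, b.coefficients.values)
    assert a.loglik == b.loglik


def test_poisson_loglik_below_negbin_on_overdispersed_data(small_records):
    pois = fit_count_glm(small_records, ModelSpec("additive", "log", "poisson"))
    nb = fit_count_glm(small_records, MULTIPLICATIVE)
    assert pois.loglik < nb.loglik


def test_coefficient_recovery_within_wald_bands():
    """Simulate from a known log-link additive model; ~all coefficients
    should fall within 3 SE of truth."""
    rng = np.random.default_rng(123)
    genos = random_genotypes(3000, seed=321)
    dm_spec = ModelSpec("additive", "log", "negbin")
    from hierbranch.genotype_encoding import design_matrix_additive

    dm = design_matrix_additive(genos)
    beta = np.zeros(dm.values.shape[1])
    beta[0] = 0.3
    beta[1:] = rng.normal(0, 0.25, size=len(beta) - 1)
    mu = np.exp(dm.values @ beta)
    t = 10
    alpha = 0.3
    r = 1 / alpha
    m = t * mu
    y = rng.negative_binomial(r, r / (r + m))
    records = make_records(genos, y, t=t)
    fit = fit_count_glm(records, dm_spec)
    est = fit.coefficients.reindex(dm.column_names).values
    se = np.sqrt(np.diag(fit.covariance.reindex(index=dm.column_names, columns=dm.column_names).values))
    inside = np.abs(est - beta) <= 3 * se
    assert inside.mean() >= 0.9
    assert fit.alpha == pytest.approx(alpha, rel=0.15)


def test_identity_link_fit_runs_and_flags():
    truth = multiplicative_truth()
    records = simulate_dataset(
        CrossDesign(populations=(("pro3", 400),)), SimulationConfig(truth=truth, seed=9)
    )
    fit = fit_count_glm(records, ModelSpec("additive", "identity", "negbin"))
    assert np.isfinite(fit.loglik)
    mu = predict_mean(fit, [r.genotype for r in records])
    assert np.all(mu > 0) or not fit.converged


# ---------------------------------------------------------------------------
# Deviance and model comparison


def _nb_deviance_oracle(y, t, mu, alpha):
    """Explicit NB2 deviance formula, independent of the package path."""
    y = np.asarray(y, float)
    m = np.asarray(t, float) * np.asarray(mu, float)
    r = 1 / alpha
    terms = np.where(
        y > 0,
        y * np.log(np.where(y > 0, y, 1) / m) - (y + r) * np.log((y + r) / (m + r)),
        -r * np.log(r / (m + r)),
    )
    return 2 * float(np.sum(terms))


def test_deviance_explained_matches_closed_form_oracle():
    """4-plant, two-genotype fixture vs the explicit NB deviance formula."""
    genos = [Genotype(), Genotype(), Genotype(plt3=MUT), Genotype(plt3=MUT)]
    records = make_records(genos, [2, 4, 30, 40], t=10)
    spec = ModelSpec("additive", "log", "negbin")
    null = fit_count_glm(records, ModelSpec("intercept", "log", "negbin"))
    fit = fit_count_glm(records, spec)
    y = [r.y for r in records]
    t = [r.t for r in records]
    d_model = _nb_deviance_oracle(y, t, predict_mean(fit, genos), fit.alpha)
    d_null = _nb_deviance_oracle(y, t, predict_mean(null, genos), null.alpha)
    expected = 100 * (d_null - d_model) / d_null
    assert deviance_explained(fit, null) == pytest.approx(expected, abs=1e-6)


def test_deviance_explained_trivial_cases(small_records):
    null = fit_count_glm(small_records, ModelSpec("intercept", "log", "negbin"))
    assert deviance_explained(null, null) == 0.0
    with pytest.raises(ValueError):
        deviance_explained(null, fit_count_glm(small_records, ModelSpec("intercept", "log", "poisson")))


def test_deviance_explained_nesting_at_common_alpha(small_records):
    """At a shared alpha, the pairwise basis explains at least as much
    deviance as the additive basis."""
    alpha = fit_count_glm(small_records, MULTIPLICATIVE).alpha
    null = fit_count_glm(small_records, ModelSpec("intercept", "log", "negbin"), fixed_alpha=alpha)
    add = fit_count_glm(small_records, MULTIPLICATIVE, fixed_alpha=alpha)
    pw = fit_count_glm(small_records, PAIRWISE, fixed_alpha=alpha)
    assert deviance_explained(pw, null) >= deviance_explained(add, null) - 1e-6


def _dummy_fit(loglik, n_params, family="negbin", n_obs=100):
    import pandas as pd

    return FitResult(
        spec=ModelSpec("additive", "log", family),
        coefficients=pd.Series([0.0]),
        covariance=pd.DataFrame([[1.0]]),
        alpha=0.1 if family == "negbin" else None,
        loglik=loglik,
        deviance=0.0,
        aic=2 * n_params - 2 * loglik,
        n_params=n_params,
        converged=True,
        column_meta=[],
        n_obs=n_obs,
    )


def test_likelihood_ratio_test_quantiles():
    res = likelihood_ratio_test(_dummy_fit(-100.0, 3), _dummy_fit(-100.0, 5))
    assert (res.statistic, res.p) == (0.0, 1.0)
    res = likelihood_ratio_test(_dummy_fit(-101.92, 3), _dummy_fit(-100.0, 4))
    assert res.statistic == pytest.approx(3.84, abs=1e-9)
    assert res.p == pytest.approx(0.05, abs=0.001)
    with pytest.raises(ValueError):
        likelihood_ratio_test(_dummy_fit(-1.0, 5), _dummy_fit(-1.0, 3))


def test_negbin_vs_poisson_lrt_on_overdispersed_data():
    """Strong overdispersion (alpha=0.5, n=500) is detected at P < 1e-16."""
    rng = np.random.default_rng(77)
    rejections = 0
    for rep in range(5):
        alpha, mu, t, n = 0.5, 2.0, 10, 500
        r = 1 / alpha
        m = t * mu
        y = rng.negative_binomial(r, r / (r + m), size=n)
        records = make_records([Genotype()] * n, y, t=t)
        pois = fit_count_glm(records, ModelSpec("intercept", "log", "poisson"))
        nb = fit_count_glm(records, ModelSpec("intercept", "log", "negbin"))
        res = likelihood_ratio_test(pois, nb)
        assert "boundary" in res.note
        rejections += res.p < 1e-16
    assert rejections == 5


def test_relative_likelihood_closed_forms():
    assert relative_likelihood(10.0, 10.0) == 1.0
    assert relative_likelihood(12.0, 10.0) == pytest.approx(np.exp(-1.0), abs=1e-12)
    # an AIC difference of -19.64 is an evidence ratio of roughly 18,358
    # (the ratio matches the rounded difference to within rounding slack)
    assert relative_likelihood(-19.64, 0.0) == pytest.approx(18358, rel=0.005)


# ---------------------------------------------------------------------------
# Synergy contrasts


def test_synergy_fold_excess_null_is_one(small_records):
    fit = fit_count_glm(small_records, PAIRWISE)
    for name, meta in zip(fit.coefficients.index, fit.column_meta):
        if meta.kind == "product":
            fit.coefficients[name] = 0.0
    res = synergy_fold_excess(fit, ("PLT3", "J2"), (MUT, MUT))
    assert res.fold == pytest.approx(1.0, abs=1e-12)
    assert res.z == 0.0 and res.p == 1.0


def test_synergy_contrast_equals_prediction_difference(small_records):
    """The contrast equals the log-mean prediction combination on the four
    genotypes (double, singles, WT) to numerical precision."""
    fit = fit_count_glm(small_records, PAIRWISE)
    combo = (MUT, HET)
    res = synergy_fold_excess(fit, ("PLT3", "PLT7"), combo)
    g_wt = Genotype()
    g1 = Genotype(plt3=MUT)
    g2 = Genotype(plt7=HET)
    g12 = Genotype(plt3=MUT, plt7=HET)
    mus = np.log(predict_mean(fit, [g12, g1, g2, g_wt]))
    assert res.log_estimate == pytest.approx(mus[0] - mus[1] - mus[2] + mus[3], abs=1e-10)


def test_synergy_fold_recovery_from_known_interaction():
    """A 3-fold injected within-pair excess is recovered by the pairwise fit."""
    from dataclasses import replace

    truth = multiplicative_truth(alpha=0.3)
    phi = dict(truth.phi_plt)
    phi["PLT3=MUT/PLT7=MUT"] += np.log(3.0)
    truth = replace(truth, phi_plt=phi)
    folds = []
    rng = np.random.default_rng(2027)
    for rep in range(5):
        records = simulate_dataset(
            CrossDesign(populations=tuple((a, 500) for a, _ in CrossDesign().populations)),
            SimulationConfig(truth=truth, seed=int(rng.integers(2**31))),
        )
        fit = fit_count_glm(records, PAIRWISE)
        folds.append(synergy_fold_excess(fit, ("PLT3", "PLT7"), (MUT, MUT)).fold)
    assert np.mean(folds) == pytest.approx(3.0, rel=0.10)


def test_synergy_contrast_dropped_column_error():
    genos = [Genotype(), Genotype(plt3=HET), Genotype(plt3=MUT)] * 4
    records = make_records(genos, list(range(12)))
    fit = fit_count_glm(records, PAIRWISE)
    with pytest.raises(ValueError, match="dropped"):
        synergy_fold_excess(fit, ("PLT3", "PLT7"), (MUT, MUT))


# ---------------------------------------------------------------------------
# Cross-validation


@pytest.fixture(scope="module")
def low_noise_records():
    """One population, 2000 plants/season over 3 seasons, near-noiseless
    multiplicative truth, so held-out genotype-season MLEs are precise."""
    design = CrossDesign(
        populations=(("pro8", 6000),),
        seasons=(("S1", 0.0), ("S2", 0.0), ("S3", 0.0)),
    )
    truth = multiplicative_truth(alpha=0.05)
    return simulate_dataset(design, SimulationConfig(truth=truth, seed=99))


def test_cross_validation_closed_loop(low_noise_records):
    """A well-specified model predicts held-out seasons almost perfectly."""
    result = cross_validate(low_noise_records, [MULTIPLICATIVE], scheme="leave-season-out")
    name = next(iter(result.averages))
    assert result.averages[name] > 0.99
    assert len(result.per_fold) == 3


def test_cross_validation_negative_control(low_noise_records):
    """Permuting genotype labels destroys predictive power."""
    rng = np.random.default_rng(5)
    genos = [r.genotype for r in low_noise_records]
    perm = rng.permutation(len(genos))
    from dataclasses import replace as dc_replace

    shuffled = [
        dc_replace(r, genotype=genos[j]) for r, j in zip(low_noise_records, perm)
    ]
    result = cross_validate(shuffled, [MULTIPLICATIVE], scheme="leave-season-out")
    assert next(iter(result.averages.values())) < 0.2


def test_cross_validation_genotype_scheme(low_noise_records):
    result = cross_validate(
        low_noise_records, [MULTIPLICATIVE], scheme="leave-genotype-out", seed=3, n_folds=4
    )
    assert next(iter(result.averages.values())) > 0.95
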