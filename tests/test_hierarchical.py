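"""Hierarchical multilinear model: predictions, fitting, derived quantities."""

from dataclasses import replace

import numpy as np
import pytest

from hierbranch.count_glms import MULTIPLICATIVE, PAIRWISE, fit_count_glm, predict_mean
from hierbranch.genotype_encoding import Genotype, LocusState
from hierbranch.hierarchical_epistasis import (
    FitSettings,
    HierarchicalParams,
    fit_hierarchical,
    fold_effect,
    multiplicative_expectation,
    predict_log_mean,
    profile_ci_theta_int,
    response_surface,
)
from hierbranch.synthetic_data import (
    CrossDesign,
    SimulationConfig,
    default_truth,
    multiplicative_truth,
    simulate_dataset,
)

WT, HET, MUT = LocusState.WT_HOM, LocusState.HET, LocusState.MUT_HOM


@pytest.fixture(scope="module")
def truth():
    return default_truth()


@pytest.fixture(scope="module")
def hier_fit(small_records):
    return fit_hierarchical(small_records)


def test_predict_wt_genotype_is_theta_wt(truth):
    assert predict_log_mean(truth, Genotype()) == truth.theta_wt


def test_zero_masking_reduces_to_multiplicative(truth):
    """With theta_int = 0 the pair effects add on the log scale."""
    t0 = replace(truth, theta_int=0.0)
    g = Genotype(plt3=MUT, j2=MUT)
    expected = t0.theta_wt + t0.phi_plt["PLT3=MUT/PLT7=WT"] + t0.phi_sep["EJ2=WT/J2=MUT"]
    assert predict_log_mean(t0, g) == pytest.approx(expected, abs=1e-12)


def test_sensitivity_derivative_matches_analytic_form(truth):
    """d mu / d phi_sep = 1 - theta_int * phi_plt (finite-difference check)."""
    for u in (0.0, 1.0, 2.5):
        h = 1e-6
        v = 0.7
        s_hi = np.log(response_surface(truth, [u], [v + h])[0, 0])
        s_lo = np.log(response_surface(truth, [u], [v - h])[0, 0])
        deriv = (s_hi - s_lo) / (2 * h)
        assert deriv == pytest.approx(1 - truth.theta_int * u, abs=1e-6)


def test_unknown_class_error_lists_known_classes(truth):
    small = replace(truth, phi_plt={"PLT3=MUT/PLT7=WT": 1.0})
    with pytest.raises(KeyError, match="PLT3=MUT/PLT7=WT"):
        predict_log_mean(small, Genotype(plt3=HET))


def test_params_validation():
    with pytest.raises(ValueError):
        HierarchicalParams(0.0, 0.0, {"WT": 1.0}, {}, 0.1)
    with pytest.raises(ValueError):
        HierarchicalParams(0.0, 0.0, {}, {}, -0.5)
    with pytest.raises(ValueError):
        HierarchicalParams(np.inf, 0.0, {}, {}, 0.1)


def test_json_round_trip(truth):
    back = HierarchicalParams.from_json(truth.to_json())
    assert back == truth


# ---------------------------------------------------------------------------
# Fitting


def test_fit_improves_on_multiplicative_start(small_records, hier_fit):
    mult = fit_count_glm(small_records, MULTIPLICATIVE)
    assert hier_fit.loglik >= mult.loglik - 1e-6


def test_fit_deterministic_across_seed_argument(small_records, hier_fit):
    again = fit_hierarchical(small_records, settings=FitSettings(seed=99))
    assert again.params == hier_fit.params
    assert again.loglik == hier_fit.loglik


def test_hierarchical_fewer_params_than_pairwise(small_records, hier_fit):
    pw = fit_count_glm(small_records, PAIRWISE)
    assert hier_fit.n_params < pw.n_params


def test_param_count_bookkeeping(hier_fit):
    p = hier_fit.params
    assert hier_fit.n_params == 2 + len(p.phi_plt) + len(p.phi_sep) + 1
    assert hier_fit.aic == pytest.approx(2 * hier_fit.n_params - 2 * hier_fit.loglik, abs=1e-9)


def test_reduction_equivalence_with_additive_glm(small_records):
    """theta_int = 0 plus phi tables built from the additive GLM reproduces
    the additive GLM's predictions exactly (cross-module equivalence)."""
    from hierbranch.hierarchical_epistasis import _genotype_for_class, _Problem

    add = fit_count_glm(small_records, MULTIPLICATIVE)
    problem = _Problem(small_records, fix_theta_int=False)
    wt_mu = float(np.log(predict_mean(add, [Genotype()])[0]))
    params = HierarchicalParams(
        theta_wt=wt_mu,
        theta_int=0.0,
        phi_plt={
            l: float(np.log(predict_mean(add, [_genotype_for_class(l)])[0])) - wt_mu
            for l in problem.plt_classes
        },
        phi_sep={
            l: float(np.log(predict_mean(add, [_genotype_for_class(l)])[0])) - wt_mu
            for l in problem.sep_classes
        },
        alpha=add.alpha,
    )
    genos = [r.genotype for r in small_records]
    hier_mu = np.array([predict_log_mean(params, g) for g in genos])
    glm_mu = np.log(predict_mean(add, genos))
    np.testing.assert_allclose(hier_mu, glm_mu, atol=1e-10)


def test_theta_int_fixed_when_one_pair_segregates():
    design = CrossDesign(populations=(("pro3", 200),), fixed_wt=("J2", "EJ2"))
    records = simulate_dataset(design, SimulationConfig(truth=default_truth(), seed=4))
    fit = fit_hierarchical(records)
    assert fit.theta_int_fixed
    assert fit.params.theta_int == 0.0
    with pytest.raises(ValueError):
        profile_ci_theta_int(records, fit)


def test_masking_parameter_recovery_single_replicate():
    """theta_int = 0.12 is recovered within its profile CI on one
    4000-plant cross (the multi-replicate version runs in acceptance)."""
    design = CrossDesign(populations=tuple((a, 667) for a, _ in CrossDesign().populations))
    records = simulate_dataset(design, SimulationConfig(truth=default_truth(), seed=42))
    fit = fit_hierarchical(records)
    lo, hi = profile_ci_theta_int(records, fit)
    assert lo <= 0.12 <= hi
    assert fit.params.theta_int == pytest.approx(0.12, abs=0.05)
    assert fit.params.alpha == pytest.approx(0.3, rel=0.1)


# ---------------------------------------------------------------------------
# Derived quantities


def test_fold_effect_identities(truth):
    assert fold_effect(truth, {}) == 1.0
    assert fold_effect(truth, {}, {"J2": MUT}) == 1.0
    t0 = replace(truth, theta_int=0.0)
    combo = {"PLT3": MUT}
    assert fold_effect(t0, combo, {}) == pytest.approx(
        fold_effect(t0, combo, {"J2": MUT, "EJ2pro8": MUT}), rel=1e-12
    )
    with pytest.raises(ValueError, match="disjoint"):
        fold_effect(truth, {"PLT3": MUT}, {"PLT3": HET})


def test_fold_effect_shrinks_with_background_severity(truth):
    """The paradigm case: a homozygous plt3 effect is large in WT and
    progressively masked in stronger SEP backgrounds."""
    combo = {"PLT3": MUT}
    backgrounds = [{}, {"J2": MUT}, {"EJ2pro8": MUT, "J2": MUT}]
    phis = [0.0] + [
        truth.phi_sep[k] for k in ("EJ2=WT/J2=MUT", "EJ2pro8=MUT/J2=MUT")
    ]
    folds = [fold_effect(truth, combo, bg) for bg in backgrounds]
    assert folds[0] == pytest.approx(11.24, rel=1e-10)
    assert folds[0] > folds[1] > folds[2]
    # analytic: log fold = phi_plt * (1 - theta_int * phi_sep_background)
    phi_plt = truth.phi_plt["PLT3=MUT/PLT7=WT"]
    for f, phi_b in zip(folds, phis):
        assert np.log(f) == pytest.approx(phi_plt * (1 - truth.theta_int * phi_b), abs=1e-10)


def test_response_surface_structure(truth):
    u = np.linspace(0, 3, 7)
    surf = response_surface(truth, u, u)
    # symmetric in its axes
    np.testing.assert_allclose(surf, surf.T, rtol=1e-12)
    # phi_plt = 0 row is a pure exponential transect
    np.testing.assert_allclose(surf[0], np.exp(truth.theta_wt + u), rtol=1e-12)
    # at phi_sep = 1/theta_int the surface is flat in phi_plt (complete masking)
    v_star = 1.0 / truth.theta_int
    col = response_surface(truth, u, [v_star])[:, 0]
    np.testing.assert_allclose(col, col[0], rtol=1e-10)


def test_multiplicative_expectation(truth):
    assert multiplicative_expectation(truth, {}, {}) == pytest.approx(
        np.exp(truth.theta_wt), rel=1e-12
    )
    t0 = replace(truth, theta_int=0.0)
    c1, c2 = {"PLT3": MUT}, {"J2": MUT}
    joint = np.exp(predict_log_mean(t0, Genotype(plt3=MUT, j2=MUT)))
    assert multiplicative_expectation(t0, c1, c2) == pytest.approx(joint, rel=1e-12)


def test_within_pair_excess_vs_multiplicative_expectation():
    """Observed/expected for a within-pair double equals the injected synergy."""
    truth = default_truth(theta_int=0.0)
    c1, c2 = {"PLT3": MUT}, {"PLT7": MUT}
    observed = np.exp(predict_log_mean(truth, Genotype(plt3=MUT, plt7=MUT)))
    expected = multiplicative_expectation(truth, c1, c2)
    injected = truth.phi_plt["PLT3=MUT/PLT7=MUT"] - (
        truth.phi_plt["PLT3=MUT/PLT7=WT"] + truth.phi_plt["PLT3=WT/PLT7=MUT"]
    )
    assert observed / expected == pytest.approx(np.exp(injected), rel=1e-10)
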