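"""Poisson and negative-binomial count GLMs with per-plant exposure.

A plant's branching total ``y_i`` is modelled as Poisson or NB2 with
mean ``t_i * f^{-1}(mu(x_i))`` where ``t_i`` is the number of countable
inflorescences (the exposure), ``f`` the link (log or identity) and
``mu(x_i)`` the linear predictor on the genotype design basis.  The NB2
variance is ``m + alpha*m**2``: a single overdispersion parameter
``alpha`` shared across plants captures plant-to-plant variability
beyond Poisson.

Fitting is direct maximum likelihood (L-BFGS on analytic gradients)
jointly over the coefficients and ``log(alpha)``.  Deviance is computed
against the plant-level saturated model at the fit's own ``alpha``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .genotype_encoding import (
    DEFAULT_LOCI,
    ColumnMeta,
    DesignMatrix,
    Genotype,
    LocusSet,
    LocusState,
    column_value,
    design_matrix_additive,
    design_matrix_pairwise,
)
from .phenotype_data import PlantRecord

logger = logging.getLogger(__name__)

_MIN_ALPHA = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: basis (additive | pairwise | intercept), link, family."""

    basis: str = "additive"
    link: str = "log"
    family: str = "negbin"

    def __post_init__(self) -> None:
        if self.basis not in ("additive", "pairwise", "intercept"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.link not in ("log", "identity"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.family not in ("poisson", "negbin"):
            raise ValueError(f"unknown family {self.family!r}")


MULTIPLICATIVE = ModelSpec("additive", "log", "negbin")
PAIRWISE = ModelSpec("pairwise", "log", "negbin")


# ---------------------------------------------------------------------------
# Likelihoods


def _as_arrays(y, t, mu=None):
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("all exposures t must be > 0")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts y must be non-negative integers")
    if mu is None:
        return y, t
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("all means mu must be > 0")
    return y, t, mu


def poisson_loglik(y, t, mu) -> float:
    """Sum of Poisson log-probabilities with plant means ``m_i = t_i * mu_i``."""
    y, t, mu = _as_arrays(y, t, mu)
    m = t * mu
    return float(np.sum(y * np.log(m) - m - special.gammaln(y + 1)))


def negbin_loglik(y, t, mu, alpha: float) -> float:
    """NB2 log-likelihood with mean ``m_i = t_i*mu_i`` and variance ``m + alpha*m**2``.

    ``alpha = 0`` returns the Poisson log-likelihood (the continuous limit).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0:
        return poisson_loglik(y, t, mu)
    y, t, mu = _as_arrays(y, t, mu)
    m = t * mu
    r = 1.0 / alpha
    if r > 1e6:
        # gammaln(y+r) - gammaln(r) cancels catastrophically at huge r;
        # with integer y it equals sum_{k<y} log(r+k) exactly.
        yi = y.astype(np.int64)
        ymax = int(yi.max(initial=0))
        tail = len(yi) - np.cumsum(np.bincount(yi, minlength=ymax + 1))[:ymax]
        ks = np.arange(ymax)
        rising = float(np.sum(tail * np.log(r + ks)))
        return float(
            rising
            - np.sum(special.gammaln(y + 1))
            - r * np.sum(np.log1p(m / r))
            + np.sum(y * (np.log(m) - np.log(r + m)))
        )
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + m))
            + y * np.log(m / (r + m))
        )
    )


def _saturated_loglik(y: np.ndarray, family: str, alpha: float) -> float:
    """Plant-level saturated log-likelihood (each plant at its own mean y_i)."""
    pos = y > 0
    m = y[pos]
    if len(m) == 0:
        return 0.0
    if family == "poisson" or alpha == 0:
        ll = float(np.sum(m * np.log(m) - m - special.gammaln(m + 1)))
    else:
        ll = negbin_loglik(m, np.ones_like(m), m, alpha)
    return ll  # zero-count plants contribute 0 at m -> 0


# ---------------------------------------------------------------------------
# Fit result


@dataclass
class FitResult:
    """Maximum-likelihood fit of one count GLM."""

    spec: ModelSpec
    coefficients: pd.Series
    covariance: pd.DataFrame
    alpha: float | None
    loglik: float
    deviance: float
    aic: float
    n_params: int
    converged: bool
    column_meta: list[ColumnMeta]
    dropped_columns: list[tuple[ColumnMeta, str]] = field(default_factory=list)
    n_obs: int = 0
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "spec": vars(self.spec),
            "coefficients": self.coefficients.to_dict(),
            "alpha": self.alpha,
            "loglik": self.loglik,
            "deviance": self.deviance,
            "aic": self.aic,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "dropped_columns": [(m.name, r) for m, r in self.dropped_columns],
            "notes": self.notes,
        }

    def summary(self) -> str:
        se = np.sqrt(np.diag(self.covariance.values))
        lines = [
            f"{self.spec.family} GLM, {self.spec.link} link, basis={self.spec.basis}",
            f"n={self.n_obs}  loglik={self.loglik:.3f}  deviance={self.deviance:.3f}  "
            f"AIC={self.aic:.3f}  params={self.n_params}  converged={self.converged}",
        ]
        if self.alpha is not None:
            lines.append(f"alpha (overdispersion) = {self.alpha:.4f}")
        lines.append(f"{'term':<24}{'estimate':>12}{'SE':>12}")
        for name, est, s in zip(self.coefficients.index, self.coefficients.values, se):
            lines.append(f"{name:<24}{est:>12.4f}{s:>12.4f}")
        if self.dropped_columns:
            lines.append(f"dropped columns: {[(m.name, r) for m, r in self.dropped_columns]}")
        return "\n".join(lines)


def build_design(records: Sequence[PlantRecord], spec: ModelSpec, loci: LocusSet = DEFAULT_LOCI) -> DesignMatrix:
    genotypes = [r.genotype for r in records]
    if spec.basis == "intercept":
        return DesignMatrix(np.ones((len(records), 1)), [ColumnMeta("intercept")])
    if spec.basis == "additive":
        return design_matrix_additive(genotypes, loci)
    return design_matrix_pairwise(genotypes, loci)


def _softplus_mean(eta: np.ndarray, eps: float = 1e-2):
    """Smooth positive extension of the identity link: ~eta for eta >> eps.

    Floored away from zero so the likelihood stays finite when the
    additive identity-link model predicts strongly negative means.
    """
    z = eta / eps
    mu = eps * np.where(z > 30, z, np.log1p(np.exp(np.minimum(z, 30))))
    dmu = special.expit(z)
    return np.maximum(mu, 1e-10), dmu


def _negloglik_and_grad(params, X, y, t, link, family, barrier, fixed_alpha=None):
    p = X.shape[1]
    beta = params[:p]
    eta = X @ beta
    if link == "log":
        mu = np.exp(eta)
        dmu_deta = mu
    else:
        if barrier:
            mu, dmu_deta = _softplus_mean(eta)
        else:
            mu = eta
            dmu_deta = np.ones_like(eta)
        if np.any(mu <= 0):
            return 1e12, np.zeros_like(params)
    m = t * mu
    if family == "poisson":
        ll = np.sum(y * np.log(m) - m - special.gammaln(y + 1))
        dll_dm = y / m - 1.0
        grad_beta = X.T @ (dll_dm * t * dmu_deta)
        return -ll, -grad_beta
    if fixed_alpha is not None:
        r = 1.0 / fixed_alpha
    else:
        log_alpha = params[-1]
        r = np.exp(-log_alpha)
    ll = np.sum(
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1)
        + r * np.log(r / (r + m))
        + y * np.log(m / (r + m))
    )
    dll_dm = y / m - (y + r) / (r + m)
    grad_beta = X.T @ (dll_dm * t * dmu_deta)
    if fixed_alpha is not None:
        return -ll, -grad_beta
    dll_dr = np.sum(
        special.digamma(y + r)
        - special.digamma(r)
        + np.log(r / (r + m))
        + (m - y) / (r + m)
    )
    grad_la = dll_dr * (-r)
    return -ll, -np.append(grad_beta, grad_la)


def _numeric_hessian(fun, x0: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Finite-difference Hessian from an analytic gradient (central differences)."""
    n = len(x0)
    H = np.zeros((n, n))
    for i in range(n):
        h = step * max(1.0, abs(x0[i]))
        xp = x0.copy(); xp[i] += h
        xm = x0.copy(); xm[i] -= h
        gp = fun(xp)[1]
        gm = fun(xm)[1]
        H[i] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def fit_count_glm(
    records: Sequence[PlantRecord],
    spec: ModelSpec = MULTIPLICATIVE,
    loci: LocusSet = DEFAULT_LOCI,
    design: DesignMatrix | None = None,
    fixed_alpha: float | None = None,
) -> FitResult:
    """Maximum-likelihood fit of a count GLM on plant records.

    ``fixed_alpha`` holds the NB overdispersion at a given value instead
    of estimating it (useful for comparing deviances at a common alpha).

    Coefficients and (for negbin) ``alpha`` are estimated jointly; the
    covariance comes from the observed information at the optimum.  A
    failed line search or gradient tolerance leaves ``converged=False``
    on the result rather than raising.  Identity-link fits whose means
    go non-positive are refit through a softplus barrier and flagged.
    """
    if not records:
        raise ValueError("no records to fit")
    dm = design if design is not None else build_design(records, spec, loci)
    X = dm.values
    y = np.array([r.y for r in records], dtype=float)
    t = np.array([r.t for r in records], dtype=float)
    n, p = X.shape
    if n < p:
        logger.warning("fewer records (%d) than design columns (%d)", n, p)
    notes: list[str] = []

    # init from (weighted) least squares on the link scale
    if spec.link == "log":
        target = np.log((y + 0.5) / t)
    else:
        target = y / t
    beta0, *_ = np.linalg.lstsq(X, target, rcond=None)
    if spec.family == "negbin" and fixed_alpha is None:
        mu0 = np.exp(X @ beta0) if spec.link == "log" else np.maximum(X @ beta0, 1e-3)
        m0 = t * mu0
        alpha0 = float(np.sum((y - m0) ** 2 - m0) / np.sum(m0**2))
        alpha0 = min(max(alpha0, 1e-3), 10.0)
        x0 = np.append(beta0, np.log(alpha0))
    else:
        x0 = beta0
    if fixed_alpha is not None:
        if spec.family != "negbin":
            raise ValueError("fixed_alpha only applies to the negbin family")
        if fixed_alpha <= 0:
            raise ValueError("fixed_alpha must be > 0")
        notes.append(f"alpha fixed at {fixed_alpha:g} (not estimated)")

    barrier = False
    args = (X, y, t, spec.link, spec.family)

    estimates_alpha = spec.family == "negbin" and fixed_alpha is None
    bounds = None
    if estimates_alpha:
        # keep log(alpha) in a numerically safe range (alpha in [1e-8, 1e3])
        bounds = [(None, None)] * p + [(np.log(1e-8), np.log(1e3))]

    def run(x_init, barrier_flag):
        return optimize.minimize(
            _negloglik_and_grad,
            x_init,
            args=(*args, barrier_flag, fixed_alpha),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8},
        )

    if spec.link == "identity":
        mu_init = X @ beta0
        if np.any(mu_init <= 0):
            barrier = True
    res = run(x0, barrier)
    converged = bool(res.success)
    if spec.link == "identity" and not barrier:
        mu_fit = X @ res.x[:p]
        if np.any(mu_fit <= 0):
            barrier = True
            notes.append("identity-link means went non-positive; softplus barrier refit")
            res = run(res.x, True)
            converged = bool(res.success)
    if barrier and "softplus" not in " ".join(notes):
        notes.append("identity-link fit used softplus positivity barrier")
    if not converged:
        notes.append(f"optimizer: {res.message}")

    xhat = res.x
    beta = xhat[:p]
    if spec.link == "log":
        mu = np.exp(X @ beta)
    else:
        mu = _softplus_mean(X @ beta)[0] if barrier else X @ beta
    if spec.family == "negbin":
        alpha = fixed_alpha if fixed_alpha is not None else float(np.exp(xhat[-1]))
        ll = negbin_loglik(y, t, mu, alpha)
        n_params = p + (1 if fixed_alpha is None else 0)
    else:
        alpha = None
        ll = poisson_loglik(y, t, mu)
        n_params = p

    fun = lambda x: _negloglik_and_grad(x, *args, barrier, fixed_alpha)
    H = _numeric_hessian(fun, xhat)
    try:
        cov_all = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(H)
        notes.append("observed information singular; pseudo-inverse covariance")
    names = dm.column_names
    cov = pd.DataFrame(cov_all[:p, :p], index=names, columns=names)

    ll_sat = _saturated_loglik(y, spec.family, alpha if alpha is not None else 0.0)
    deviance = 2.0 * (ll_sat - ll)
    aic = 2.0 * n_params - 2.0 * ll
    return FitResult(
        spec=spec,
        coefficients=pd.Series(beta, index=names),
        covariance=cov,
        alpha=alpha,
        loglik=ll,
        deviance=deviance,
        aic=aic,
        n_params=n_params,
        converged=converged,
        column_meta=list(dm.column_meta),
        dropped_columns=list(dm.dropped_columns),
        n_obs=n,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Prediction


def design_row(fit: FitResult, genotype: Genotype) -> np.ndarray:
    return np.array([column_value(m, genotype) for m in fit.column_meta])


def predict_mean(fit: FitResult, genotypes: Sequence[Genotype]) -> np.ndarray:
    """Predicted branching events per inflorescence for each genotype."""
    rows = np.array([design_row(fit, g) for g in genotypes])
    eta = rows @ fit.coefficients.values
    return np.exp(eta) if fit.spec.link == "log" else eta


# ---------------------------------------------------------------------------
# Model comparison


def deviance_explained(fit: FitResult, null_fit: FitResult) -> float:
    """Percent deviance explained, ``100*(D_null - D_model)/D_null``.

    ``null_fit`` must be the intercept-only model of the same family and
    link on the same records; each deviance is evaluated at that model's
    own MLE against the plant-level saturated model.
    """
    if null_fit.spec.family != fit.spec.family or null_fit.spec.link != fit.spec.link:
        raise ValueError("null fit must share family and link")
    if null_fit.n_obs != fit.n_obs:
        raise ValueError("null fit must be on the same records")
    if null_fit.deviance == 0:
        raise ValueError("null deviance is zero; deviance explained undefined")
    return 100.0 * (null_fit.deviance - fit.deviance) / null_fit.deviance


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p: float
    note: str = ""


def likelihood_ratio_test(nested: FitResult, full: FitResult) -> LRTResult:
    """Chi-square LRT of a nested model against a fuller one.

    For the NB-vs-Poisson comparison the single extra parameter sits on
    the boundary (alpha >= 0); the df=1 chi-square tail is conservative
    there, which the result notes.
    """
    if nested.n_params >= full.n_params:
        raise ValueError("nested model must have fewer parameters")
    if nested.n_obs != full.n_obs:
        raise ValueError("fits must be on the same records")
    stat = 2.0 * (full.loglik - nested.loglik)
    note = ""
    if stat < -1e-6:
        note = "full model log-likelihood below nested: refit recommended (optimizer failure)"
        logger.warning(note)
    stat = max(stat, 0.0)
    df = full.n_params - nested.n_params
    if nested.spec.family == "poisson" and full.spec.family == "negbin" and df == 1:
        note = (note + "; " if note else "") + (
            "alpha tested on its boundary: chi-square(1) tail is conservative"
        )
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(float(stat), int(df), p, note)


def relative_likelihood(aic_a: float, aic_b: float) -> float:
    """Evidence ratio of model a over model b, ``exp((AIC_b - AIC_a)/2)``."""
    return float(np.exp((aic_b - aic_a) / 2.0))


# ---------------------------------------------------------------------------
# Synergy contrasts


@dataclass(frozen=True)
class ContrastResult:
    """Fold change in excess of the multiplicative expectation (log-link fit)."""

    log_estimate: float
    fold: float
    ci95: tuple[float, float]
    z: float
    p: float


def _genotype_with(assignments: dict[str, LocusState]) -> Genotype:
    kw: dict = {}
    for locus, state in assignments.items():
        if locus == "PLT3":
            kw["plt3"] = state
        elif locus == "PLT7":
            kw["plt7"] = state
        elif locus == "J2":
            kw["j2"] = state
        elif locus.startswith("EJ2"):
            if state is not LocusState.WT_HOM:
                kw["ej2_allele"] = locus[3:]
                kw["ej2_state"] = state
        else:
            raise KeyError(f"unknown locus {locus!r}")
    return Genotype(**kw)


def synergy_fold_excess(
    pairwise_fit: FitResult,
    locus_pair: tuple[str, str],
    combo: tuple[LocusState, LocusState],
) -> ContrastResult:
    """Observed double-mutant effect relative to the multiplicative expectation.

    Builds the log-scale contrast mu(double) - mu(single1) - mu(single2)
    + mu(WT) in an otherwise-wild-type background from the pairwise fit,
    and returns the fold (exp of the contrast), a Wald 95% CI and a
    two-sided z-test.  Additive and dominance terms cancel; only the
    product columns of the pair contribute.
    """
    if pairwise_fit.spec.link != "log":
        raise ValueError("synergy contrast requires a log-link fit")
    la, lb = locus_pair
    g_wt = _genotype_with({})
    g1 = _genotype_with({la: combo[0]})
    g2 = _genotype_with({lb: combo[1]})
    g12 = _genotype_with({la: combo[0], lb: combo[1]})

    def full_row(g: Genotype, meta: Sequence[ColumnMeta]) -> np.ndarray:
        return np.array([column_value(m, g) for m in meta])

    retained = pairwise_fit.column_meta
    c = (
        full_row(g12, retained)
        - full_row(g1, retained)
        - full_row(g2, retained)
        + full_row(g_wt, retained)
    )
    dropped_meta = [m for m, _ in pairwise_fit.dropped_columns]
    if dropped_meta:
        c_dropped = (
            full_row(g12, dropped_meta)
            - full_row(g1, dropped_meta)
            - full_row(g2, dropped_meta)
            + full_row(g_wt, dropped_meta)
        )
        touched = [m.name for m, v in zip(dropped_meta, c_dropped) if abs(v) > 1e-12]
        if touched:
            raise ValueError(f"contrast touches dropped design columns: {touched}")
    est = float(c @ pairwise_fit.coefficients.values)
    var = float(c @ pairwise_fit.covariance.values @ c)
    se = np.sqrt(max(var, 0.0))
    if se == 0:
        z, p = 0.0, 1.0
    else:
        z = est / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    ci = (float(np.exp(est - 1.96 * se)), float(np.exp(est + 1.96 * se)))
    return ContrastResult(est, float(np.exp(est)), ci, float(z), max(p, np.finfo(float).tiny))


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVResult:
    scheme: str
    per_fold: pd.DataFrame  # columns: model, fold, r2, n_points
    averages: dict[str, float]
    metadata: dict = field(default_factory=dict)


def _fold_assignments(records, scheme, seed, n_folds):
    if scheme == "leave-season-out":
        seasons = sorted({r.season_id for r in records})
        return {s: [i for i, r in enumerate(records) if r.season_id == s] for s in seasons}
    if scheme == "leave-genotype-out":
        labels = sorted({r.genotype.label() for r in records})
        rng = np.random.default_rng(seed)
        rng.shuffle(labels)
        k = min(n_folds, len(labels))
        fold_of = {lab: i % k for i, lab in enumerate(labels)}
        folds: dict[str, list[int]] = {f"fold{j}": [] for j in range(k)}
        for i, r in enumerate(records):
            folds[f"fold{fold_of[r.genotype.label()]}"].append(i)
        return folds
    raise ValueError(f"unknown scheme {scheme!r}")


def cross_validate(
    records: Sequence[PlantRecord],
    specs: Sequence[ModelSpec | str],
    scheme: str = "leave-season-out",
    seed: int = 0,
    n_folds: int = 10,
    loci: LocusSet = DEFAULT_LOCI,
) -> CVResult:
    """Held-out R² of genotype(-season) mean predictions.

    For each fold, models are fit on the retained plants and compared to
    genotype-season MLE means computed on the held-out plants alone; R²
    is the squared Pearson correlation between ``log(1+predicted)`` and
    ``log(1+held-out MLE)`` per fold, averaged over folds per model.  A
    spec may be the string ``"hierarchical"`` to include the
    hierarchical epistasis model.
    """
    from .background_analysis import genotype_season_mle
    from .hierarchical_epistasis import FitSettings, fit_hierarchical, predict_log_mean

    folds = _fold_assignments(records, scheme, seed, n_folds)
    if len(folds) < 2:
        raise ValueError("need at least 2 folds")
    rows = []
    for fold_name, test_idx in folds.items():
        test_set = set(test_idx)
        train = [r for i, r in enumerate(records) if i not in test_set]
        test = [records[i] for i in test_idx]
        if not train or not test:
            logger.warning("fold %s empty on one side; skipped", fold_name)
            continue
        try:
            held_out = genotype_season_mle(test)
        except ValueError:
            logger.warning("fold %s: no estimable held-out genotypes; skipped", fold_name)
            continue
        estimable = [e for e in held_out.estimates if not e.degenerate]
        if len(estimable) < 2:
            logger.warning("fold %s: <2 estimable held-out genotypes; skipped", fold_name)
            continue
        genotypes = [e.genotype for e in estimable]
        observed = np.log1p([e.mean for e in estimable])
        for spec in specs:
            name = spec if isinstance(spec, str) else f"{spec.basis}-{spec.link}-{spec.family}"
            try:
                if spec == "hierarchical":
                    hfit = fit_hierarchical(train, loci=loci, settings=FitSettings())
                    pred = np.exp([predict_log_mean(hfit.params, g) for g in genotypes])
                else:
                    f = fit_count_glm(train, spec, loci)
                    pred = predict_mean(f, genotypes)
            except Exception as exc:  # fit failure: record and move on
                logger.warning("fold %s model %s failed: %s", fold_name, name, exc)
                continue
            predicted = np.log1p(np.maximum(pred, 0.0))
            if np.std(predicted) == 0 or np.std(observed) == 0:
                r2 = 0.0
            else:
                r2 = float(np.corrcoef(predicted, observed)[0, 1] ** 2)
            rows.append({"model": name, "fold": fold_name, "r2": r2, "n_points": len(observed)})
    per_fold = pd.DataFrame(rows)
    averages = (
        per_fold.groupby("model")["r2"].mean().to_dict() if len(per_fold) else {}
    )
    meta = {
        "scheme": scheme,
        "seed": seed,
        "r2_definition": "squared Pearson correlation of log(1+predicted genotype mean) "
        "vs log(1+held-out genotype-season MLE mean), averaged over folds",
    }
    return CVResult(scheme, per_fold, averages, meta)
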