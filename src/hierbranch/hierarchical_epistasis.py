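"""Hierarchical multilinear epistasis model for branching counts.

Each paralogue pair contributes a free log-scale effect per within-pair
genotype class (phi tables: one value for every non-wild-type
combination of states at PLT3/PLT7, and at EJ2/J2, observed in the
data), which is equivalent to allowing arbitrary dominance and pairwise
epistasis within the pair.  The two pair phenotypes combine through a
single multilinear masking parameter::

    mu(x) = theta_wt + phi_plt(x) + phi_sep(x) - theta_int * phi_plt(x) * phi_sep(x)

and a plant's branching total is NB2 with mean ``t * exp(mu)`` and
overdispersion ``alpha``.  With ``theta_int = 0`` the pairs combine
multiplicatively on the count scale; ``theta_int > 0`` means mutations
in one pair progressively mask the effects of the other.

Fitting maximizes the NB likelihood by Adam (analytic gradients,
10,000 iterations by default with a convergence check) followed by an
L-BFGS polish so results are deterministic to optimizer tolerance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats

from . import count_glms
from .count_glms import ModelSpec, fit_count_glm, negbin_loglik, predict_mean
from .genotype_encoding import (
    DEFAULT_LOCI,
    Genotype,
    LocusSet,
    LocusState,
    within_pair_class,
)
from .phenotype_data import PlantRecord

logger = logging.getLogger(__name__)


@dataclass
class HierarchicalParams:
    """Parameters of the hierarchical model.

    ``phi_plt``/``phi_sep`` map non-WT within-pair class labels to log
    effects; the WT class is implicitly zero and never stored.
    """

    theta_wt: float
    theta_int: float
    phi_plt: dict[str, float]
    phi_sep: dict[str, float]
    alpha: float

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if "WT" in self.phi_plt or "WT" in self.phi_sep:
            raise ValueError("WT class carries phi = 0 and must not be stored")
        vals = [self.theta_wt, self.theta_int, self.alpha, *self.phi_plt.values(), *self.phi_sep.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("all parameters must be finite")

    @property
    def n_params(self) -> int:
        return 2 + len(self.phi_plt) + len(self.phi_sep) + 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "theta_wt": self.theta_wt,
                "theta_int": self.theta_int,
                "phi_plt": self.phi_plt,
                "phi_sep": self.phi_sep,
                "alpha": self.alpha,
            },
            indent=2,
            sort_keys=True,
        )

    @staticmethod
    def from_json(text: str) -> "HierarchicalParams":
        d = json.loads(text)
        return HierarchicalParams(
            d["theta_wt"], d["theta_int"], d["phi_plt"], d["phi_sep"], d["alpha"]
        )


def _phi_lookup(table: Mapping[str, float], label: str, pair: str) -> float:
    if label == "WT":
        return 0.0
    if label not in table:
        raise KeyError(
            f"unknown {pair} class {label!r}; known classes: {sorted(table)}"
        )
    return float(table[label])


def predict_log_mean(params: HierarchicalParams, genotype: Genotype) -> float:
    """Log expected branching events per inflorescence for one genotype."""
    p = _phi_lookup(params.phi_plt, within_pair_class(genotype, "PLT"), "PLT")
    s = _phi_lookup(params.phi_sep, within_pair_class(genotype, "SEP"), "SEP")
    return params.theta_wt + p + s - params.theta_int * p * s


def predict_log_means(params: HierarchicalParams, genotypes: Sequence[Genotype]) -> np.ndarray:
    return np.array([predict_log_mean(params, g) for g in genotypes])


# ---------------------------------------------------------------------------
# Fitting


@dataclass(frozen=True)
class FitSettings:
    """Optimizer settings: Adam with convergence check, then L-BFGS polish."""

    learning_rate: float = 0.01
    iterations: int = 10_000
    check_every: int = 100
    grad_tol: float = 1e-5
    init: str = "additive"  # or "flat"
    seed: int = 0
    polish: bool = True


@dataclass
class HierarchicalFit:
    params: HierarchicalParams
    loglik: float
    aic: float
    deviance: float
    n_params: int
    n_obs: int
    grad_norm: float
    converged: bool
    n_iter: int
    theta_int_fixed: bool = False
    notes: list[str] = field(default_factory=list)


class _Problem:
    """Vectorized likelihood with class-index bookkeeping."""

    def __init__(self, records: Sequence[PlantRecord], fix_theta_int: bool):
        self.y = np.array([r.y for r in records], dtype=float)
        self.t = np.array([r.t for r in records], dtype=float)
        plt_labels = [within_pair_class(r.genotype, "PLT") for r in records]
        sep_labels = [within_pair_class(r.genotype, "SEP") for r in records]
        self.plt_classes = sorted({l for l in plt_labels if l != "WT"})
        self.sep_classes = sorted({l for l in sep_labels if l != "WT"})
        p_idx = {l: i + 1 for i, l in enumerate(self.plt_classes)}
        s_idx = {l: i + 1 for i, l in enumerate(self.sep_classes)}
        self.ip = np.array([p_idx.get(l, 0) for l in plt_labels])
        self.isep = np.array([s_idx.get(l, 0) for l in sep_labels])
        self.kp = len(self.plt_classes)
        self.ks = len(self.sep_classes)
        self.fix_theta_int = fix_theta_int
        # parameter vector: [theta_wt, theta_int, phi_plt.., phi_sep.., log_alpha]
        self.n_free = 2 + self.kp + self.ks + 1

    def unpack(self, x):
        th_wt = x[0]
        th_int = 0.0 if self.fix_theta_int else x[1]
        phip = np.concatenate(([0.0], x[2 : 2 + self.kp]))
        phis = np.concatenate(([0.0], x[2 + self.kp : 2 + self.kp + self.ks]))
        log_alpha = x[-1]
        return th_wt, th_int, phip, phis, log_alpha

    def negloglik_grad(self, x):
        th_wt, th_int, phip, phis, log_alpha = self.unpack(x)
        p = phip[self.ip]
        s = phis[self.isep]
        mu = th_wt + p + s - th_int * p * s
        m = self.t * np.exp(mu)
        r = np.exp(-log_alpha)
        y = self.y
        ll = np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + m))
            + y * np.log(m / (r + m))
        )
        dll_dmu = (y - m) * r / (r + m)
        g = np.zeros_like(x)
        g[0] = np.sum(dll_dmu)
        if not self.fix_theta_int:
            g[1] = -np.sum(dll_dmu * p * s)
        gp = np.bincount(self.ip, weights=dll_dmu * (1.0 - th_int * s), minlength=self.kp + 1)[1:]
        gs = np.bincount(self.isep, weights=dll_dmu * (1.0 - th_int * p), minlength=self.ks + 1)[1:]
        g[2 : 2 + self.kp] = gp
        g[2 + self.kp : 2 + self.kp + self.ks] = gs
        dll_dr = np.sum(
            special.digamma(y + r)
            - special.digamma(r)
            + np.log(r / (r + m))
            + (m - y) / (r + m)
        )
        g[-1] = dll_dr * (-r)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite hierarchical loss; diagnostics: "
                                     f"theta_wt={th_wt}, theta_int={th_int}, alpha={np.exp(log_alpha)}")
        return -ll, -g


def _init_vector(records, problem: _Problem, loci: LocusSet, settings: FitSettings) -> np.ndarray:
    x0 = np.zeros(problem.n_free)
    y, t = problem.y, problem.t
    base_rate = max(np.sum(y) / np.sum(t), 1e-3)
    x0[0] = np.log(base_rate)
    x0[-1] = np.log(0.3)
    if settings.init == "flat":
        return x0
    try:
        add = fit_count_glm(records, ModelSpec("additive", "log", "negbin"), loci)
    except Exception as exc:  # fall back to flat init
        logger.warning("additive init failed (%s); using flat init", exc)
        return x0
    wt_mean = float(predict_mean(add, [Genotype()])[0])
    x0[0] = np.log(max(wt_mean, 1e-6))
    for j, label in enumerate(problem.plt_classes):
        g = _genotype_for_class(label)
        x0[2 + j] = float(np.log(predict_mean(add, [g])[0])) - x0[0]
    for j, label in enumerate(problem.sep_classes):
        g = _genotype_for_class(label)
        x0[2 + problem.kp + j] = float(np.log(predict_mean(add, [g])[0])) - x0[0]
    x0[-1] = np.log(max(add.alpha, 1e-3))
    return x0


_SHORT_TO_STATE = {"WT": LocusState.WT_HOM, "HET": LocusState.HET, "MUT": LocusState.MUT_HOM}


def _genotype_for_class(label: str) -> Genotype:
    """Representative genotype of a within-pair class label (other pair WT)."""
    kw: dict = {}
    for part in label.split("/"):
        locus, state = part.split("=")
        state_v = _SHORT_TO_STATE[state]
        if locus == "PLT3":
            kw["plt3"] = state_v
        elif locus == "PLT7":
            kw["plt7"] = state_v
        elif locus == "J2":
            kw["j2"] = state_v
        elif locus.startswith("EJ2"):
            allele = locus[3:]
            if allele and state_v is not LocusState.WT_HOM:
                kw["ej2_allele"] = allele
                kw["ej2_state"] = state_v
        else:
            raise ValueError(f"bad class label {label!r}")
    return Genotype(**kw)


def _adam(problem: _Problem, x0: np.ndarray, settings: FitSettings):
    x = x0.copy()
    m = np.zeros_like(x)
    v = np.zeros_like(x)
    b1, b2, eps = 0.9, 0.999, 1e-8
    n_iter = settings.iterations
    for it in range(1, settings.iterations + 1):
        loss, g = problem.negloglik_grad(x)
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        mhat = m / (1 - b1**it)
        vhat = v / (1 - b2**it)
        x -= settings.learning_rate * mhat / (np.sqrt(vhat) + eps)
        if it % settings.check_every == 0 and np.max(np.abs(g)) < settings.grad_tol:
            n_iter = it
            break
    return x, n_iter


def fit_hierarchical(
    records: Sequence[PlantRecord],
    loci: LocusSet = DEFAULT_LOCI,
    settings: FitSettings = FitSettings(),
) -> HierarchicalFit:
    """Maximum-likelihood fit of the hierarchical model.

    Initialization seeds ``theta_wt`` and the phi tables from the
    additive log-link GLM (the multiplicative model), ``theta_int = 0``
    and ``alpha`` from that fit, so optimization starts at the
    multiplicative model.  If only one pair segregates, ``theta_int`` is
    unidentifiable and is fixed at 0 with a warning.
    """
    if not records:
        raise ValueError("no records to fit")
    probe = _Problem(records, fix_theta_int=False)
    fix = probe.kp == 0 or probe.ks == 0
    if fix:
        logger.warning("only one paralogue pair segregates; theta_int fixed at 0")
    problem = _Problem(records, fix_theta_int=fix)
    x0 = _init_vector(records, problem, loci, settings)
    x, n_iter = _adam(problem, x0, settings)
    notes: list[str] = []
    if settings.polish:
        res = optimize.minimize(
            problem.negloglik_grad,
            x,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-13, "gtol": 1e-9},
        )
        if res.fun <= problem.negloglik_grad(x)[0]:
            x = res.x
        else:  # pragma: no cover - polish can only improve in practice
            notes.append("polish step rejected (no improvement)")
    loss, grad = problem.negloglik_grad(x)
    ll0 = -problem.negloglik_grad(x0)[0]
    if -loss < ll0 - 1e-6:
        notes.append("log-likelihood below init; optimizer diverged")
    grad_free = grad if not fix else np.delete(grad, 1)
    grad_norm = float(np.max(np.abs(grad_free)))
    converged = bool(grad_norm < max(settings.grad_tol, 1e-4 * max(1.0, abs(loss))))

    th_wt, th_int, phip, phis, log_alpha = problem.unpack(x)
    params = HierarchicalParams(
        theta_wt=float(th_wt),
        theta_int=float(th_int),
        phi_plt={l: float(phip[i + 1]) for i, l in enumerate(problem.plt_classes)},
        phi_sep={l: float(phis[i + 1]) for i, l in enumerate(problem.sep_classes)},
        alpha=float(np.exp(log_alpha)),
    )
    n_params = params.n_params - (1 if fix else 0)
    ll = float(-loss)
    ll_sat = count_glms._saturated_loglik(problem.y, "negbin", params.alpha)
    return HierarchicalFit(
        params=params,
        loglik=ll,
        aic=2.0 * n_params - 2.0 * ll,
        deviance=2.0 * (ll_sat - ll),
        n_params=n_params,
        n_obs=len(records),
        grad_norm=grad_norm,
        converged=converged,
        n_iter=n_iter,
        theta_int_fixed=fix,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Profile confidence interval for theta_int


def _fit_fixed_theta_int(problem: _Problem, x_start: np.ndarray, theta_int: float) -> tuple[np.ndarray, float]:
    """Maximize over all parameters except theta_int (held fixed)."""
    free_idx = [i for i in range(problem.n_free) if i != 1]

    def fun(z):
        x = x_start.copy()
        x[free_idx] = z
        x[1] = theta_int
        f, g = problem.negloglik_grad(x)
        return f, g[free_idx]

    res = optimize.minimize(
        fun,
        x_start[free_idx],
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-13, "gtol": 1e-9},
    )
    x = x_start.copy()
    x[free_idx] = res.x
    x[1] = theta_int
    return x, float(-res.fun)


def profile_ci_theta_int(
    records: Sequence[PlantRecord],
    fit: HierarchicalFit,
    level: float = 0.95,
    tol: float = 1e-3,
    max_expand: int = 40,
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for the masking parameter.

    Walks outward from the MLE in both directions, re-maximizing the
    remaining parameters at each fixed ``theta_int``, until the profile
    log-likelihood drops by ``chi2_{1,level}/2``, then bisects.
    """
    if fit.theta_int_fixed:
        raise ValueError("theta_int was fixed (unidentifiable); no profile CI")
    problem = _Problem(records, fix_theta_int=False)
    # rebuild parameter vector from the fit
    x_hat = np.zeros(problem.n_free)
    x_hat[0] = fit.params.theta_wt
    x_hat[1] = fit.params.theta_int
    for i, l in enumerate(problem.plt_classes):
        x_hat[2 + i] = fit.params.phi_plt[l]
    for i, l in enumerate(problem.sep_classes):
        x_hat[2 + problem.kp + i] = fit.params.phi_sep[l]
    x_hat[-1] = np.log(fit.params.alpha)
    ll_max = fit.loglik
    drop = stats.chi2.ppf(level, 1) / 2.0

    def profile_ll(theta, x_warm):
        return _fit_fixed_theta_int(problem, x_warm, theta)

    bounds = []
    for direction in (-1.0, +1.0):
        step = max(0.02, 0.25 * abs(fit.params.theta_int))
        theta_in = fit.params.theta_int
        ll_in = ll_max
        x_warm = x_hat
        theta_out = None
        for _ in range(max_expand):
            theta_try = theta_in + direction * step
            x_warm, ll_try = profile_ll(theta_try, x_warm)
            if ll_max - ll_try > drop:
                theta_out = theta_try
                ll_out = ll_try
                break
            theta_in, ll_in = theta_try, ll_try
            step *= 1.6
        if theta_out is None:
            bounds.append(direction * np.inf)
            continue
        lo, hi = theta_in, theta_out
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            x_warm, ll_mid = profile_ll(mid, x_warm)
            if ll_max - ll_mid > drop:
                hi = mid
            else:
                lo = mid
            if abs(hi - lo) < tol:
                break
        bounds.append(0.5 * (lo + hi))
    return (min(bounds), max(bounds))


# ---------------------------------------------------------------------------
# Derived quantities


def _merge_assignments(*assignment_sets: Mapping[str, LocusState]) -> Genotype:
    merged: dict[str, LocusState] = {}
    for assignments in assignment_sets:
        for locus, state in assignments.items():
            if locus in merged:
                raise ValueError(f"overlapping locus assignment for {locus!r}")
            merged[locus] = state
    return count_glms._genotype_with(merged)


def fold_effect(
    params: HierarchicalParams,
    combo: Mapping[str, LocusState],
    background: Mapping[str, LocusState] | None = None,
) -> float:
    """Fold change in expected branching caused by ``combo`` in a background.

    ``exp(mu(background + combo) - mu(background))``; with
    ``theta_int > 0`` the same combo produces a smaller fold in
    backgrounds that already carry mutations in the other pair.
    """
    background = background or {}
    if set(combo) & set(background):
        raise ValueError("combo and background must touch disjoint loci")
    g_bg = count_glms._genotype_with(dict(background))
    g_all = _merge_assignments(background, combo)
    return float(np.exp(predict_log_mean(params, g_all) - predict_log_mean(params, g_bg)))


def response_surface(
    params: HierarchicalParams,
    phi_plt_grid: Sequence[float],
    phi_sep_grid: Sequence[float],
) -> np.ndarray:
    """Predicted branching events over a grid of within-pair log effects.

    Entry (i, j) is ``exp(theta_wt + u_i + v_j - theta_int*u_i*v_j)``;
    the axes are in log-fold units so multiplicative combination is
    additive along them.
    """
    u = np.asarray(phi_plt_grid, dtype=float)[:, None]
    v = np.asarray(phi_sep_grid, dtype=float)[None, :]
    return np.exp(params.theta_wt + u + v - params.theta_int * u * v)


def multiplicative_expectation(
    params: HierarchicalParams,
    combo1: Mapping[str, LocusState],
    combo2: Mapping[str, LocusState],
) -> float:
    """No-epistasis reference mean: WT mean times the WT-background folds."""
    return float(
        np.exp(params.theta_wt)
        * fold_effect(params, combo1, {})
        * fold_effect(params, combo2, {})
    )
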