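"""Genotype-season mean estimates and background-rescaling slope analysis.

The phenotype of a genotype in one season is summarized by the
maximum-likelihood mean number of branching events per inflorescence
under an NB model with one dummy per genotype-season combination and a
single overdispersion parameter shared by all combinations.  Wald 95%
confidence intervals are computed on the log scale and back-transformed.

The slope analysis asks how the log-scale effects of mutations in one
paralogue pair transform when moved from the wild-type background into
backgrounds mutant for the other pair.  Under a multiplicative model the
relationship is linear with slope exactly 1; under the hierarchical
model the slope in background class ``b`` is ``1 - theta_int * phi_b``,
so slopes decreasing with background severity are the signature of
multilinear masking.  Slopes are fit by total least squares (orthogonal
regression), since both axes are estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .genotype_encoding import Genotype, within_pair_class
from .phenotype_data import PlantRecord

logger = logging.getLogger(__name__)

WIDE_CI_FOLD = 1000.0


@dataclass
class GenotypeSeasonEstimate:
    genotype: Genotype
    season_id: str
    mean: float
    ci95: tuple[float, float]
    n_plants: int
    n_inflorescences: int
    degenerate: bool = False
    wide_ci: bool = False


@dataclass
class MleResult:
    estimates: list[GenotypeSeasonEstimate]
    alpha: float
    loglik: float
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.estimates:
            rows.append(
                {
                    "genotype": e.genotype.label(),
                    "season": e.season_id,
                    "mean": e.mean,
                    "ci_low": e.ci95[0],
                    "ci_high": e.ci95[1],
                    "n_plants": e.n_plants,
                    "n_inflorescences": e.n_inflorescences,
                    "degenerate": e.degenerate,
                    "wide_ci": e.wide_ci,
                }
            )
        df = pd.DataFrame(rows)
        df.attrs["alpha"] = self.alpha
        return df


def _negloglik_grad(x, y, t, idx, n_groups):
    """Joint NB loglik over per-group log-means + shared log-alpha (vectorized)."""
    log_alpha = x[-1]
    r = np.exp(-log_alpha)
    m = t * np.exp(x[idx])
    ll = np.sum(
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1)
        + r * np.log(r / (r + m))
        + y * np.log(m / (r + m))
    )
    grad = np.zeros_like(x)
    dll_dmu = (y - m) * r / (r + m)
    grad[:-1] = -np.bincount(idx, weights=dll_dmu, minlength=n_groups)
    dll_dr = np.sum(
        special.digamma(y + r)
        - special.digamma(r)
        + np.log(r / (r + m))
        + (m - y) / (r + m)
    )
    grad[-1] = dll_dr * r
    return -ll, grad


def genotype_season_mle(records: Sequence[PlantRecord]) -> MleResult:
    """Joint NB MLE of per-combination means with a shared overdispersion.

    With equal exposures within a combination the estimated mean is the
    closed form ``sum(y)/sum(t)``.  Combinations with all-zero counts
    sit on the boundary (mean 0) and are flagged degenerate rather than
    entering the joint optimization.  Estimates whose 95% CI spans more
    than a thousand-fold range are flagged ``wide_ci`` (a reporting
    flag only).
    """
    if not records:
        raise ValueError("no records")
    combos: dict[tuple[str, str], list[PlantRecord]] = {}
    for r in records:
        combos.setdefault((r.genotype.label(), r.season_id), []).append(r)
    keys = sorted(combos)
    live_keys = []
    zero_keys = []
    for k in keys:
        recs = combos[k]
        if sum(r.y for r in recs) == 0:
            zero_keys.append(k)
        else:
            live_keys.append(k)

    estimates: list[GenotypeSeasonEstimate] = []
    alpha = 0.0
    ll = 0.0
    converged = True
    if live_keys:
        key_index = {k: i for i, k in enumerate(live_keys)}
        live_records = [r for k in live_keys for r in combos[k]]
        y = np.array([r.y for r in live_records], dtype=float)
        t = np.array([r.t for r in live_records], dtype=float)
        idx = np.array(
            [key_index[(r.genotype.label(), r.season_id)] for r in live_records]
        )
        n_groups = len(live_keys)
        sum_y = np.bincount(idx, weights=y, minlength=n_groups)
        sum_t = np.bincount(idx, weights=t, minlength=n_groups)
        logm0 = np.log(sum_y / sum_t)
        args = (y, t, idx, n_groups)

        def _means_at(log_alpha: float) -> np.ndarray:
            """Per-group Newton solve of the mean score equations at fixed alpha."""
            r = np.exp(-log_alpha)
            logm = logm0.copy()
            for _ in range(60):
                m = t * np.exp(logm[idx])
                w = r / (r + m)
                score = np.bincount(idx, weights=(y - m) * w, minlength=n_groups)
                # d score / d logm: -m*w - (y - m)*m*w/(r + m), summed per group
                curv = np.bincount(
                    idx, weights=-m * w - (y - m) * m * w / (r + m), minlength=n_groups
                )
                step = score / np.where(curv < -1e-300, curv, -1.0)
                logm -= np.clip(step, -2.0, 2.0)
                if np.max(np.abs(step)) < 1e-13:
                    break
            return logm

        def _profile_nll(log_alpha: float) -> float:
            logm = _means_at(log_alpha)
            return _negloglik_grad(np.append(logm, log_alpha), *args)[0]

        opt = optimize.minimize_scalar(
            _profile_nll, bounds=(np.log(1e-8), np.log(1e3)), method="bounded",
            options={"xatol": 1e-10},
        )
        converged = bool(opt.success)
        log_alpha = float(opt.x)
        xhat = np.append(_means_at(log_alpha), log_alpha)
        alpha = float(np.exp(log_alpha))
        ll = float(-_negloglik_grad(xhat, *args)[0])
        # Wald SEs on the log scale from the observed information
        H = _numeric_hessian(lambda x: _negloglik_grad(x, *args), xhat)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        ses = np.sqrt(np.maximum(np.diag(cov)[:-1], 0.0))
        for k, logm, se in zip(live_keys, xhat[:-1], ses):
            recs = combos[k]
            lo, hi = float(np.exp(logm - 1.96 * se)), float(np.exp(logm + 1.96 * se))
            estimates.append(
                GenotypeSeasonEstimate(
                    genotype=recs[0].genotype,
                    season_id=k[1],
                    mean=float(np.exp(logm)),
                    ci95=(lo, hi),
                    n_plants=len(recs),
                    n_inflorescences=int(sum(r.t for r in recs)),
                    wide_ci=bool(hi / max(lo, np.finfo(float).tiny) > WIDE_CI_FOLD),
                )
            )
    for k in zero_keys:
        recs = combos[k]
        estimates.append(
            GenotypeSeasonEstimate(
                genotype=recs[0].genotype,
                season_id=k[1],
                mean=0.0,
                ci95=(0.0, np.inf),
                n_plants=len(recs),
                n_inflorescences=int(sum(r.t for r in recs)),
                degenerate=True,
                wide_ci=True,
            )
        )
    estimates.sort(key=lambda e: (e.genotype.label(), e.season_id))
    return MleResult(estimates, alpha, ll, converged)


def _numeric_hessian(fun, x0: np.ndarray, step: float = 1e-5) -> np.ndarray:
    n = len(x0)
    H = np.zeros((n, n))
    for i in range(n):
        h = step * max(1.0, abs(x0[i]))
        xp = x0.copy(); xp[i] += h
        xm = x0.copy(); xm[i] -= h
        H[i] = (fun(xp)[1] - fun(xm)[1]) / (2 * h)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# Total least squares


def total_least_squares(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Orthogonal (principal-axis) regression slope and intercept.

    The line is the first principal axis of the centred point cloud; the
    slope's sign matches the sign of the cross-covariance.  Requires at
    least two distinct points and a non-degenerate cloud.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need >= 2 paired points")
    xc = x - x.mean()
    yc = y - y.mean()
    M = np.column_stack([xc, yc])
    if not np.any(M):
        raise ValueError("degenerate point cloud (zero total variance)")
    _, _, vt = np.linalg.svd(M, full_matrices=False)
    v = vt[0]
    if v[0] == 0:
        raise ValueError("principal axis is vertical; slope undefined")
    slope = v[1] / v[0]
    cross = float(np.dot(xc, yc))
    if cross != 0 and np.sign(slope) != np.sign(cross):  # pragma: no cover - guard
        slope = -slope
    intercept = float(y.mean() - slope * x.mean())
    return float(slope), intercept


# ---------------------------------------------------------------------------
# Background rescaling


@dataclass
class BackgroundSlope:
    background: str
    slope: float
    intercept: float
    n_points: int
    points: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def estimates_from_params(params, genotypes: Sequence[Genotype]) -> list[GenotypeSeasonEstimate]:
    """Noiseless pseudo-estimates from hierarchical parameters (for slope checks)."""
    from .hierarchical_epistasis import predict_log_mean

    out = []
    for g in genotypes:
        m = float(np.exp(predict_log_mean(params, g)))
        out.append(GenotypeSeasonEstimate(g, "all", m, (m, m), 0, 0))
    return out


def background_rescaling(
    estimates: Sequence[GenotypeSeasonEstimate],
    focal_pair: str,
    backgrounds: Sequence[str] | None = None,
    season_handling: str = "pooled",
    log1p_scale: bool = False,
) -> list[BackgroundSlope]:
    """Per-background TLS slopes of focal-pair effects vs the WT background.

    For each background class ``b`` of the non-focal pair, pairs the log
    mean of each focal-pair mutant class in the WT background (x) with
    its log mean in background ``b`` (y) and fits a total-least-squares
    line.  ``season_handling`` is ``"pooled"`` (average log means across
    seasons per genotype) or ``"matched"`` (pair within seasons, then
    pool the points).  Backgrounds sharing fewer than two focal classes
    with the WT background are skipped with a log message.
    """
    if focal_pair not in ("PLT", "SEP"):
        raise ValueError("focal_pair must be 'PLT' or 'SEP'")
    other = "SEP" if focal_pair == "PLT" else "PLT"
    trans = np.log1p if log1p_scale else np.log

    usable = [e for e in estimates if not e.degenerate and e.mean > 0]
    # (focal class, background class, season) -> list of log means
    cell: dict[tuple[str, str, str], list[float]] = {}
    for e in usable:
        f = within_pair_class(e.genotype, focal_pair)
        b = within_pair_class(e.genotype, other)
        season = e.season_id if season_handling == "matched" else "all"
        cell.setdefault((f, b, season), []).append(float(trans(e.mean)))
    mean_cell = {k: float(np.mean(v)) for k, v in cell.items()}

    all_backgrounds = sorted({k[1] for k in mean_cell if k[1] != "WT"})
    if backgrounds is None:
        backgrounds = all_backgrounds
    out: list[BackgroundSlope] = []
    for b in backgrounds:
        pts = []
        for (f, bb, season), yv in mean_cell.items():
            if bb != b or f == "WT":
                continue
            xv = mean_cell.get((f, "WT", season))
            if xv is None:
                continue
            pts.append({"focal_class": f, "season": season, "log_mean_wt_bg": xv, "log_mean_bg": yv})
        if len(pts) < 2:
            logger.warning("background %s has %d shared focal classes (<2); skipped", b, len(pts))
            continue
        df = pd.DataFrame(pts)
        slope, intercept = total_least_squares(df["log_mean_wt_bg"], df["log_mean_bg"])
        out.append(
            BackgroundSlope(
                background=b,
                slope=slope,
                intercept=intercept,
                n_points=len(df),
                points=df,
                metadata={
                    "focal_pair": focal_pair,
                    "season_handling": season_handling,
                    "scale": "log1p(mean)" if log1p_scale else "log(mean)",
                },
            )
        )
    return out
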