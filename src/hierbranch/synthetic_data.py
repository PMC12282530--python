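"""Generative stand-in for the field data: F2 crosses + hierarchical NB phenotypes.

Six F2 populations each segregate four unlinked loci 1:2:1 (PLT3, PLT7,
J2 and one EJ2 promoter allele per population).  Phenotypes are drawn
from the hierarchical multilinear model: each plant receives a shared
gamma multiplier (mean 1, variance ``alpha``) so that its branching
total over ``t`` inflorescences is exactly NB2 with mean
``t * exp(mu)`` and variance ``m + alpha*m**2`` — the plant-to-plant
variability the shared overdispersion parameter represents.  The
observational artifacts of field scoring are reproduced: counts above
the censor value are recorded as "too many to count", and inflorescences
can be marked proliferated or inhibited with configurable probabilities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .genotype_encoding import (
    EJ2_ALLELES,
    DEFAULT_LOCI,
    Genotype,
    LocusSet,
    LocusState,
    within_pair_class,
)
from .hierarchical_epistasis import HierarchicalParams, predict_log_mean
from .phenotype_data import (
    DEFAULT_CENSOR,
    InflorescenceObservation,
    Outcome,
    OutcomeTag,
    PlantMeta,
    PlantRecord,
    summarize_plants,
)

logger = logging.getLogger(__name__)

_STATES = (LocusState.WT_HOM, LocusState.HET, LocusState.MUT_HOM)


@dataclass(frozen=True)
class CrossDesign:
    """Which F2 populations to simulate and how many plants each."""

    populations: tuple[tuple[str, int], ...] = tuple((a, 384) for a in EJ2_ALLELES)
    loci: LocusSet = DEFAULT_LOCI
    seasons: tuple[tuple[str, float], ...] = (
        ("NY-1", 0.0),
        ("FL-1", 0.0),
        ("NY-2", 0.0),
        ("FL-2", 0.0),
    )
    fixed_wt: tuple[str, ...] = ()  # loci held homozygous WT (e.g. ("PLT7", "EJ2"))

    def __post_init__(self) -> None:
        for allele, n in self.populations:
            if allele not in EJ2_ALLELES:
                raise ValueError(f"unknown EJ2 allele {allele!r}")
            if n <= 0:
                raise ValueError("n_plants must be > 0")
        for locus in self.fixed_wt:
            if locus not in ("PLT3", "PLT7", "J2", "EJ2"):
                raise ValueError(f"fixed_wt locus must be PLT3/PLT7/J2/EJ2, got {locus!r}")


@dataclass(frozen=True)
class SimulationConfig:
    truth: HierarchicalParams
    inflorescences_per_plant: int = 10
    censor_value: int = DEFAULT_CENSOR
    p_proliferated: float = 0.0
    p_inhibited: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_proliferated <= 1 and 0 <= self.p_inhibited <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.p_proliferated + self.p_inhibited > 1:
            raise ValueError("exclusion probabilities must sum to <= 1")
        if self.inflorescences_per_plant < 1:
            raise ValueError("inflorescences_per_plant must be >= 1")


def default_truth(theta_int: float = 0.12, alpha: float = 0.3) -> HierarchicalParams:
    """Study-like hierarchical truth.

    Log effects are anchored on the field estimates: a homozygous plt3
    mutation alone is an ~11.2-fold effect, plt7 alone ~2-fold, EJ2
    promoter alleles are near-cryptic alone, j2 alone modest, and
    within-pair double mutants carry synergy of the magnitude seen in
    the pairwise-fit contrasts (roughly 3-17-fold in excess of
    multiplicative, varying by allele).  The wild-type mean is 0.2
    branching events per inflorescence.
    """
    plt_single = {"PLT3": {"HET": 0.35, "MUT": float(np.log(11.24))},
                  "PLT7": {"HET": 0.10, "MUT": 0.70}}
    # log fold-excess of within-pair synergy for PLT combos
    plt_excess = {
        ("HET", "HET"): float(np.log(1.5)),
        ("HET", "MUT"): float(np.log(3.29)),
        ("MUT", "HET"): float(np.log(3.27)),
        ("MUT", "MUT"): float(np.log(1.6)),
    }
    phi_plt: dict[str, float] = {}
    for s3 in ("WT", "HET", "MUT"):
        for s7 in ("WT", "HET", "MUT"):
            if s3 == "WT" and s7 == "WT":
                continue
            v = plt_single["PLT3"].get(s3, 0.0) + plt_single["PLT7"].get(s7, 0.0)
            v += plt_excess.get((s3, s7), 0.0)
            phi_plt[f"PLT3={s3}/PLT7={s7}"] = v

    ej2_hom = {"pro1": 0.12, "pro3": 0.10, "pro4": 0.08, "pro6": 0.15, "pro7": 0.05, "pro8": 0.25}
    j2_single = {"HET": 0.05, "MUT": 0.40}
    sep_excess_hom = {  # log fold-excess for EJ2-hom x j2-hom per allele
        "pro1": float(np.log(7.05)),
        "pro3": float(np.log(6.81)),
        "pro4": float(np.log(9.32)),
        "pro6": float(np.log(6.49)),
        "pro7": float(np.log(16.97)),
        "pro8": float(np.log(5.95)),
    }
    phi_sep: dict[str, float] = {}
    for sj in ("HET", "MUT"):
        phi_sep[f"EJ2=WT/J2={sj}"] = j2_single[sj]
    for allele, hom in ej2_hom.items():
        singles = {"HET": 0.4 * hom, "MUT": hom}
        for se in ("HET", "MUT"):
            for sj in ("WT", "HET", "MUT"):
                v = singles[se] + j2_single.get(sj, 0.0)
                if sj != "WT":
                    frac = {("MUT", "MUT"): 1.0, ("MUT", "HET"): 0.5,
                            ("HET", "MUT"): 0.5, ("HET", "HET"): 0.25}[(se, sj)]
                    v += frac * sep_excess_hom[allele]
                phi_sep[f"EJ2{allele}={se}/J2={sj}"] = v
    return HierarchicalParams(
        theta_wt=float(np.log(0.2)),
        theta_int=theta_int,
        phi_plt=phi_plt,
        phi_sep=phi_sep,
        alpha=alpha,
    )


def multiplicative_truth(alpha: float = 0.3) -> HierarchicalParams:
    """Truth with no masking and no within-pair synergy (purely multiplicative)."""
    t = default_truth(theta_int=0.0, alpha=alpha)
    plt_single = {"PLT3": {"HET": 0.35, "MUT": float(np.log(11.24))},
                  "PLT7": {"HET": 0.10, "MUT": 0.70}}
    phi_plt = {}
    for s3 in ("WT", "HET", "MUT"):
        for s7 in ("WT", "HET", "MUT"):
            if s3 == "WT" and s7 == "WT":
                continue
            phi_plt[f"PLT3={s3}/PLT7={s7}"] = (
                plt_single["PLT3"].get(s3, 0.0) + plt_single["PLT7"].get(s7, 0.0)
            )
    ej2_hom = {"pro1": 0.12, "pro3": 0.10, "pro4": 0.08, "pro6": 0.15, "pro7": 0.05, "pro8": 0.25}
    j2_single = {"HET": 0.05, "MUT": 0.40}
    phi_sep = {}
    for sj in ("HET", "MUT"):
        phi_sep[f"EJ2=WT/J2={sj}"] = j2_single[sj]
    for allele, hom in ej2_hom.items():
        for se, sv in (("HET", 0.4 * hom), ("MUT", hom)):
            for sj in ("WT", "HET", "MUT"):
                phi_sep[f"EJ2{allele}={se}/J2={sj}"] = sv + j2_single.get(sj, 0.0)
    return replace(t, phi_plt=phi_plt, phi_sep=phi_sep)


def reachable_genotype_classes(design: CrossDesign) -> set[str]:
    """Genotype labels reachable by the design (enumeration oracle)."""
    out: set[str] = set()
    for allele, _ in design.populations:
        for s3 in _STATES:
            for s7 in _STATES:
                for sj in _STATES:
                    for se in _STATES:
                        g = Genotype(
                            plt3=s3, plt7=s7, j2=sj,
                            ej2_allele=allele if se is not LocusState.WT_HOM else None,
                            ej2_state=se,
                        )
                        out.add(g.label())
    return out


def simulate_f2_genotypes(
    design: CrossDesign, seed: int | np.random.Generator = 0
) -> list[tuple[str, Genotype]]:
    """Draw Mendelian F2 genotypes: each segregating locus 1:2:1, unlinked."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[tuple[str, Genotype]] = []
    for allele, n in design.populations:
        pop_id = f"F2-{allele}"
        draws = rng.choice(3, size=(n, 4), p=[0.25, 0.5, 0.25])
        for locus, col in (("PLT3", 0), ("PLT7", 1), ("J2", 2), ("EJ2", 3)):
            if locus in design.fixed_wt:
                draws[:, col] = 0
        for row in draws:
            s3, s7, sj, se = (_STATES[i] for i in row)
            out.append(
                (
                    pop_id,
                    Genotype(
                        plt3=s3, plt7=s7, j2=sj,
                        ej2_allele=allele if se is not LocusState.WT_HOM else None,
                        ej2_state=se,
                    ),
                )
            )
    return out


def simulate_phenotypes(
    genotypes: Sequence[tuple[str, Genotype]],
    config: SimulationConfig,
    design: CrossDesign | None = None,
) -> tuple[list[InflorescenceObservation], dict[str, PlantMeta]]:
    """Simulate per-inflorescence observations for a list of plants.

    Plants are assigned to the design's seasons round-robin; a season's
    optional log-scale multiplier shifts its means.  Per plant, a shared
    gamma deviate scales the per-inflorescence Poisson rate so plant
    totals are exactly NB2; counts above ``censor_value`` become TMTC
    records.
    """
    rng = np.random.default_rng(config.seed)
    truth = config.truth
    seasons = design.seasons if design is not None else (("S1", 0.0),)
    observations: list[InflorescenceObservation] = []
    meta: dict[str, PlantMeta] = {}
    for i, (pop_id, g) in enumerate(genotypes):
        season_id, season_mult = seasons[i % len(seasons)]
        plant_id = f"{pop_id}-p{i:05d}"
        mu = predict_log_mean(truth, g) + season_mult
        rate = float(np.exp(mu))
        if truth.alpha > 0:
            shape = 1.0 / truth.alpha
            gamma_mult = rng.gamma(shape, truth.alpha)
        else:
            gamma_mult = 1.0
        meta[plant_id] = PlantMeta(g, pop_id, season_id)
        for k in range(config.inflorescences_per_plant):
            u = rng.random()
            if u < config.p_proliferated:
                outcome = Outcome(OutcomeTag.PROLIFERATED)
            elif u < config.p_proliferated + config.p_inhibited:
                outcome = Outcome(OutcomeTag.INHIBITED)
            else:
                count = int(rng.poisson(gamma_mult * rate))
                if config.censor_value is not None and count > config.censor_value:
                    outcome = Outcome(OutcomeTag.TMTC)
                else:
                    outcome = Outcome.count_(count)
            observations.append(InflorescenceObservation(plant_id, k + 1, outcome))
    return observations, meta


def simulate_dataset(
    design: CrossDesign, config: SimulationConfig
) -> list[PlantRecord]:
    """Simulate genotypes and phenotypes and summarize to plant records."""
    rng = np.random.default_rng(config.seed)
    genotypes = simulate_f2_genotypes(design, rng)
    obs, meta = simulate_phenotypes(genotypes, replace(config, seed=int(rng.integers(2**31))), design)
    return summarize_plants(obs, meta, censor_value=config.censor_value or DEFAULT_CENSOR)


# ---------------------------------------------------------------------------
# Closed-loop recovery experiment


def recovery_experiment(
    design: CrossDesign,
    config: SimulationConfig,
    n_replicates: int = 20,
    seed: int = 0,
    profile_ci: bool = True,
    fit_pairwise: bool = True,
) -> dict:
    """Simulate -> summarize -> fit multiplicative/pairwise/hierarchical, repeatedly.

    Per replicate, records AICs, percent deviance explained, the
    theta_int estimate with its profile CI (and whether it covers the
    truth), and the recovered within-PLT-pair fold excess.  Fit failures
    are recorded per replicate, never fatal.  The aggregated report is
    deterministic given the master seed.
    """
    from .count_glms import (
        MULTIPLICATIVE,
        PAIRWISE,
        ModelSpec,
        deviance_explained,
        fit_count_glm,
        synergy_fold_excess,
    )
    from .hierarchical_epistasis import FitSettings, fit_hierarchical, profile_ci_theta_int

    rng = np.random.default_rng(seed)
    truth = config.truth
    replicates = []
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(2**31))
        entry: dict = {"replicate": rep, "seed": rep_seed}
        try:
            records = simulate_dataset(design, replace(config, seed=rep_seed))
            entry["n_plants"] = len(records)
            null = fit_count_glm(records, ModelSpec("intercept", "log", "negbin"), design.loci)
            mult = fit_count_glm(records, MULTIPLICATIVE, design.loci)
            entry["aic_multiplicative"] = mult.aic
            entry["dev_expl_multiplicative"] = deviance_explained(mult, null)
            if fit_pairwise:
                pw = fit_count_glm(records, PAIRWISE, design.loci)
                entry["aic_pairwise"] = pw.aic
                entry["dev_expl_pairwise"] = deviance_explained(pw, null)
                try:
                    contrast = synergy_fold_excess(
                        pw, ("PLT3", "PLT7"), (LocusState.MUT_HOM, LocusState.HET)
                    )
                    entry["fold_excess_plt3_plt7het"] = contrast.fold
                except ValueError as exc:
                    entry["fold_excess_error"] = str(exc)
            hier = fit_hierarchical(records, design.loci)
            entry["aic_hierarchical"] = hier.aic
            entry["theta_wt_hat"] = hier.params.theta_wt
            entry["theta_int_hat"] = hier.params.theta_int
            entry["alpha_hat"] = hier.params.alpha
            entry["hier_converged"] = hier.converged
            entry["dev_expl_hierarchical"] = 100.0 * (null.deviance - hier.deviance) / null.deviance
            if profile_ci and not hier.theta_int_fixed:
                lo, hi = profile_ci_theta_int(records, hier)
                entry["theta_int_ci"] = [lo, hi]
                entry["theta_int_covered"] = bool(lo <= truth.theta_int <= hi)
        except Exception as exc:
            entry["error"] = f"{type(exc).__name__}: {exc}"
            logger.warning("replicate %d failed: %s", rep, exc)
        replicates.append(entry)

    ok = [r for r in replicates if "error" not in r]
    report: dict = {
        "n_replicates": n_replicates,
        "master_seed": seed,
        "truth": {
            "theta_wt": truth.theta_wt,
            "theta_int": truth.theta_int,
            "alpha": truth.alpha,
        },
        "replicates": replicates,
        "n_failed": n_replicates - len(ok),
    }
    if ok:
        for key, true_val in (
            ("theta_wt_hat", truth.theta_wt),
            ("theta_int_hat", truth.theta_int),
            ("alpha_hat", truth.alpha),
        ):
            vals = [r[key] for r in ok if key in r]
            if vals:
                mean = float(np.mean(vals))
                report[key.replace("_hat", "_mean")] = mean
                if true_val != 0:
                    report[key.replace("_hat", "_relative_bias")] = (mean - true_val) / true_val
        covered = [r.get("theta_int_covered") for r in ok if "theta_int_covered" in r]
        if covered:
            report["theta_int_coverage"] = float(np.mean(covered))
        if fit_pairwise:
            ranks = [
                r["aic_hierarchical"] < r["aic_pairwise"] < r["aic_multiplicative"]
                for r in ok
                if "aic_pairwise" in r
            ]
            if ranks:
                report["aic_rank_hier_lt_pw_lt_mult_fraction"] = float(np.mean(ranks))
    return report


def _json_default(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, default=_json_default)
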