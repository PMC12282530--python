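import itertools

import numpy as np
import pytest
from hypothesis import settings as _hsettings

_hsettings.register_profile("deterministic", derandomize=True, deadline=None)
_hsettings.load_profile("deterministic")

from hierbranch.genotype_encoding import EJ2_ALLELES, Genotype, LocusState
from hierbranch.phenotype_data import PlantRecord
from hierbranch.synthetic_data import (
    CrossDesign,
    SimulationConfig,
    default_truth,
    simulate_dataset,
)

STATES = (LocusState.WT_HOM, LocusState.HET, LocusState.MUT_HOM)


def random_genotype(rng: np.random.Generator) -> Genotype:
    s3, s7, sj, se = (STATES[i] for i in rng.integers(0, 3, size=4))
    allele = str(rng.choice(EJ2_ALLELES)) if se is not LocusState.WT_HOM else None
    return Genotype(plt3=s3, plt7=s7, j2=sj, ej2_allele=allele,
                    ej2_state=se if allele else LocusState.WT_HOM)


def random_genotypes(n: int, seed: int = 0) -> list[Genotype]:
    rng = np.random.default_rng(seed)
    return [random_genotype(rng) for _ in range(n)]


def plt_j2_genotypes() -> list[Genotype]:
    """All 27 genotypes over PLT3 x PLT7 x J2 (EJ2 wild type)."""
    return [
        Genotype(plt3=a, plt7=b, j2=c)
        for a, b, c in itertools.product(STATES, STATES, STATES)
    ]


def make_records(genotypes, y, t=10, season="S1", population="P1"):
    y = np.atleast_1d(y)
    return [
        PlantRecord(f"plant{i}", g, population, season, int(np.atleast_1d(t)[i % len(np.atleast_1d(t))]), int(yy))
        for i, (g, yy) in enumerate(zip(genotypes, y))
    ]


@pytest.fixture(scope="session")
def study_records():
    """One study-scale synthetic dataset (six F2 populations, 384 plants each)."""
    return simulate_dataset(CrossDesign(), SimulationConfig(truth=default_truth(), seed=20260927))


@pytest.fixture(scope="session")
def small_records():
    """A small single-population dataset for fast fitting tests."""
    design = CrossDesign(populations=(("pro3", 300),))
    return simulate_dataset(design, SimulationConfig(truth=default_truth(), seed=7))
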