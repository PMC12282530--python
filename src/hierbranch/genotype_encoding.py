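"""Genotype data model and additive/dominance/pairwise design matrices.

Genotypes live on four functional loci: the paralogue pair *PLT3*/*PLT7*
and the SEPALLATA pair *J2*/*EJ2*, where the EJ2 locus is multi-allelic
(a set of promoter alleles, at most one carried per plant).  The
multi-allelic locus is represented as six mutually exclusive biallelic
loci so that per-allele effects can be estimated inside one pooled model.

Each biallelic locus is coded with an additive score
``s_a in {-1, 0, +1}`` (homozygous wild type, heterozygous, homozygous
mutant) and a dominance score ``s_d in {0, 1, 0}`` measuring the
deviation of the heterozygote from the semi-dominant midpoint.
"""

from __future__ import annotations

import enum
import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LocusState",
    "Genotype",
    "LocusSet",
    "DEFAULT_LOCI",
    "EJ2_ALLELES",
    "ColumnMeta",
    "DesignMatrix",
    "additive_dominance_code",
    "parse_locus_state",
    "design_matrix_additive",
    "design_matrix_pairwise",
    "within_pair_class",
    "enumerate_pair_classes",
]


class LocusState(enum.Enum):
    """Genotype state at one biallelic locus."""

    WT_HOM = 0
    HET = 1
    MUT_HOM = 2

    @property
    def short(self) -> str:
        return {"WT_HOM": "WT", "HET": "HET", "MUT_HOM": "MUT"}[self.name]


WT = LocusState.WT_HOM
EJ2_ALLELES: tuple[str, ...] = ("pro1", "pro3", "pro4", "pro6", "pro7", "pro8")


@dataclass(frozen=True)
class Genotype:
    """Multi-locus genotype of one plant.

    ``ej2_allele`` identifies which EJ2 promoter allele the plant's F2
    population segregates; it is ``None`` if and only if the plant is
    homozygous wild type at EJ2 (alleles never co-occur because each
    population carries a single allele).
    """

    plt3: LocusState = WT
    plt7: LocusState = WT
    j2: LocusState = WT
    ej2_allele: str | None = None
    ej2_state: LocusState = WT

    def __post_init__(self) -> None:
        if (self.ej2_allele is None) != (self.ej2_state is WT):
            raise ValueError(
                f"ej2_allele={self.ej2_allele!r} inconsistent with "
                f"ej2_state={self.ej2_state}: allele is None iff state is WT_HOM"
            )
        if self.ej2_allele is not None and self.ej2_allele not in EJ2_ALLELES:
            raise ValueError(f"unknown EJ2 allele {self.ej2_allele!r}")

    def state_at(self, label: str) -> LocusState:
        """State at a biallelic locus label (EJ2 alleles not carried code WT)."""
        if label == "PLT3":
            return self.plt3
        if label == "PLT7":
            return self.plt7
        if label == "J2":
            return self.j2
        if label.startswith("EJ2"):
            allele = label[3:]
            if allele not in EJ2_ALLELES:
                raise KeyError(f"unknown locus label {label!r}")
            return self.ej2_state if allele == self.ej2_allele else WT
        raise KeyError(f"unknown locus label {label!r}")

    def label(self) -> str:
        """Compact human-readable genotype label."""
        parts = []
        for locus, state in (("plt3", self.plt3), ("plt7", self.plt7), ("j2", self.j2)):
            if state is not WT:
                parts.append(f"{locus}:{state.short}")
        if self.ej2_allele is not None:
            parts.append(f"EJ2{self.ej2_allele}:{self.ej2_state.short}")
        return "|".join(parts) if parts else "WT"


DEFAULT_LOCUS_LABELS: tuple[str, ...] = (
    "PLT3",
    "PLT7",
    "J2",
    "EJ2pro1",
    "EJ2pro3",
    "EJ2pro4",
    "EJ2pro6",
    "EJ2pro7",
    "EJ2pro8",
)


@dataclass(frozen=True)
class LocusSet:
    """Ordered biallelic locus labels; EJ2 allele loci are mutually exclusive."""

    labels: tuple[str, ...] = DEFAULT_LOCUS_LABELS
    mutually_exclusive: frozenset[str] = frozenset(
        l for l in DEFAULT_LOCUS_LABELS if l.startswith("EJ2")
    )

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("locus labels must be unique")

    def compatible_pairs(self) -> list[tuple[str, str]]:
        """Unordered locus pairs for which product columns are generated."""
        pairs = []
        for a, b in itertools.combinations(self.labels, 2):
            if a in self.mutually_exclusive and b in self.mutually_exclusive:
                continue
            pairs.append((a, b))
        return pairs


DEFAULT_LOCI = LocusSet()


def additive_dominance_code(state: LocusState) -> tuple[float, float]:
    """Return ``(s_a, s_d)``: WT_HOM -> (-1, 0), HET -> (0, 1), MUT_HOM -> (1, 0)."""
    if state is LocusState.WT_HOM:
        return (-1.0, 0.0)
    if state is LocusState.HET:
        return (0.0, 1.0)
    return (1.0, 0.0)


_STATE_VOCAB: dict[str, LocusState] = {
    "wt": WT,
    "+/+": WT,
    "wt_hom": WT,
    "0": WT,
    "het": LocusState.HET,
    "m/+": LocusState.HET,
    "+/m": LocusState.HET,
    "1": LocusState.HET,
    "hom": LocusState.MUT_HOM,
    "m/m": LocusState.MUT_HOM,
    "mut": LocusState.MUT_HOM,
    "mut_hom": LocusState.MUT_HOM,
    "2": LocusState.MUT_HOM,
}


def parse_locus_state(token: str, synonyms: Mapping[str, LocusState] | None = None) -> LocusState:
    """Parse a genotype token (case-insensitive) into a :class:`LocusState`.

    Raises ``ValueError`` naming the token if it is not in the vocabulary.
    """
    vocab = dict(_STATE_VOCAB)
    if synonyms:
        vocab.update({k.strip().lower(): v for k, v in synonyms.items()})
    key = str(token).strip().lower()
    if key not in vocab:
        raise ValueError(f"unparseable genotype token {token!r}")
    return vocab[key]


@dataclass(frozen=True)
class ColumnMeta:
    """Provenance of one design-matrix column.

    ``kind`` is one of ``intercept``, ``additive``, ``dominance`` or
    ``product``; for products ``product_kind`` is ``aa``/``ad``/``da``/``dd``
    where the first letter refers to the lexicographically earlier locus.
    """

    kind: str
    loci: tuple[str, ...] = ()
    product_kind: str | None = None

    @property
    def name(self) -> str:
        if self.kind == "intercept":
            return "intercept"
        if self.kind in ("additive", "dominance"):
            return f"{self.kind[0]}({self.loci[0]})"
        return f"{self.product_kind}({self.loci[0]},{self.loci[1]})"


@dataclass
class DesignMatrix:
    """Plants-by-columns design matrix with per-column provenance."""

    values: np.ndarray
    column_meta: list[ColumnMeta]
    dropped_columns: list[tuple[ColumnMeta, str]] = field(default_factory=list)

    @property
    def column_names(self) -> list[str]:
        return [m.name for m in self.column_meta]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)

    def restrict(self, kinds: set[str]) -> "DesignMatrix":
        idx = [i for i, m in enumerate(self.column_meta) if m.kind in kinds]
        return DesignMatrix(
            self.values[:, idx],
            [self.column_meta[i] for i in idx],
            [d for d in self.dropped_columns if d[0].kind in kinds],
        )


def _base_column(genotypes: Sequence[Genotype], locus: str, kind: str) -> np.ndarray:
    codes = [additive_dominance_code(g.state_at(locus)) for g in genotypes]
    return np.array([c[0] if kind == "additive" else c[1] for c in codes])


def column_value(meta: ColumnMeta, genotype: Genotype) -> float:
    """Value of one design column for one genotype (used to build predict rows)."""
    if meta.kind == "intercept":
        return 1.0
    if meta.kind in ("additive", "dominance"):
        sa, sd = additive_dominance_code(genotype.state_at(meta.loci[0]))
        return sa if meta.kind == "additive" else sd
    a, b = meta.loci
    sa1, sd1 = additive_dominance_code(genotype.state_at(a))
    sa2, sd2 = additive_dominance_code(genotype.state_at(b))
    first = sa1 if meta.product_kind[0] == "a" else sd1
    second = sa2 if meta.product_kind[1] == "a" else sd2
    return first * second


def _drop_columns(values: np.ndarray, meta: list[ColumnMeta]) -> DesignMatrix:
    retained_idx: list[int] = []
    dropped: list[tuple[ColumnMeta, str]] = []
    for j, m in enumerate(meta):
        col = values[:, j]
        if m.kind != "intercept" and np.ptp(col) == 0:
            reason = "all-zero" if col[0] == 0 else f"constant (= {col[0]:g})"
            dropped.append((m, reason))
            continue
        dup = next(
            (k for k in retained_idx if np.array_equal(values[:, k], col)), None
        )
        if dup is not None:
            dropped.append((m, f"duplicate of {meta[dup].name}"))
            continue
        neg = next(
            (k for k in retained_idx if np.array_equal(values[:, k], -col)), None
        )
        if neg is not None:
            dropped.append((m, f"negated duplicate of {meta[neg].name}"))
            continue
        retained_idx.append(j)
    if dropped:
        logger.debug("dropped %d design columns: %s", len(dropped), [d[0].name for d in dropped])
    return DesignMatrix(values[:, retained_idx], [meta[i] for i in retained_idx], dropped)


def _build(genotypes: Sequence[Genotype], loci: LocusSet, pairwise: bool) -> DesignMatrix:
    if len(genotypes) == 0:
        raise ValueError("empty genotype list")
    n = len(genotypes)
    meta: list[ColumnMeta] = [ColumnMeta("intercept")]
    cols: list[np.ndarray] = [np.ones(n)]
    base: dict[tuple[str, str], np.ndarray] = {}
    for locus in loci.labels:
        for kind in ("additive", "dominance"):
            col = _base_column(genotypes, locus, kind)
            base[(locus, kind[0])] = col
            meta.append(ColumnMeta(kind, (locus,)))
            cols.append(col)
    if pairwise:
        for a, b in loci.compatible_pairs():
            a, b = sorted((a, b))
            for ka, kb in (("a", "a"), ("a", "d"), ("d", "a"), ("d", "d")):
                meta.append(ColumnMeta("product", (a, b), ka + kb))
                cols.append(base[(a, ka)] * base[(b, kb)])
    return _drop_columns(np.column_stack(cols), meta)


def design_matrix_additive(genotypes: Sequence[Genotype], loci: LocusSet = DEFAULT_LOCI) -> DesignMatrix:
    """Intercept + per-locus additive and dominance columns, constants dropped."""
    return _build(genotypes, loci, pairwise=False)


def design_matrix_pairwise(genotypes: Sequence[Genotype], loci: LocusSet = DEFAULT_LOCI) -> DesignMatrix:
    """Additive basis extended with aa/ad/da/dd products for compatible pairs.

    Mutually exclusive locus pairs (two EJ2 promoter alleles) generate no
    product columns; constant, all-zero and duplicate columns are dropped
    with reasons recorded in ``dropped_columns``.
    """
    return _build(genotypes, loci, pairwise=True)


# ---------------------------------------------------------------------------
# Within-pair genotype classes for the hierarchical model


def within_pair_class(genotype: Genotype, pair: str) -> str:
    """Class label of a genotype within one paralogue pair.

    ``pair`` is ``"PLT"`` (joint PLT3/PLT7 state, 9 classes) or ``"SEP"``
    (joint EJ2-allele/EJ2-state/J2 state).  The all-wild-type class is the
    distinguished label ``"WT"`` and carries zero effect in the
    hierarchical model.
    """
    if pair == "PLT":
        if genotype.plt3 is WT and genotype.plt7 is WT:
            return "WT"
        return f"PLT3={genotype.plt3.short}/PLT7={genotype.plt7.short}"
    if pair == "SEP":
        if genotype.ej2_state is WT and genotype.j2 is WT:
            return "WT"
        ej2 = (
            "EJ2=WT"
            if genotype.ej2_state is WT
            else f"EJ2{genotype.ej2_allele}={genotype.ej2_state.short}"
        )
        return f"{ej2}/J2={genotype.j2.short}"
    raise ValueError(f"pair must be 'PLT' or 'SEP', got {pair!r}")


def enumerate_pair_classes(pair: str, alleles: Iterable[str] = EJ2_ALLELES) -> list[str]:
    """All non-WT within-pair class labels reachable by the cross design."""
    states = list(LocusState)
    labels: list[str] = []
    if pair == "PLT":
        for s1, s2 in itertools.product(states, states):
            g = Genotype(plt3=s1, plt7=s2)
            lab = within_pair_class(g, "PLT")
            if lab != "WT":
                labels.append(lab)
        return labels
    if pair == "SEP":
        seen = set()
        for allele in list(alleles) + [None]:
            ej2_states = [WT] if allele is None else states
            for es, js in itertools.product(ej2_states, states):
                g = Genotype(j2=js, ej2_allele=allele if es is not WT else None,
                             ej2_state=es if es is not WT else WT)
                lab = within_pair_class(g, "SEP")
                if lab != "WT" and lab not in seen:
                    seen.add(lab)
                    labels.append(lab)
        return labels
    raise ValueError(f"pair must be 'PLT' or 'SEP', got {pair!r}")
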