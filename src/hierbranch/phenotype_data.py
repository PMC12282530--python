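"""Plant-level phenotype records and per-inflorescence observation handling.

Branching is scored inflorescence by inflorescence.  An inflorescence is
either counted (a non-negative number of branching events), recorded as
"too many to count" (TMTC, treated as the censor value, 60 by default),
or excluded as proliferated/inhibited.  The likelihoods consume one row
per plant: the number of countable inflorescences ``t`` (the exposure)
and the total branching events ``y`` across them.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_encoding import (
    EJ2_ALLELES,
    Genotype,
    LocusState,
    parse_locus_state,
    within_pair_class,
)

logger = logging.getLogger(__name__)

DEFAULT_CENSOR = 60


class OutcomeTag(enum.Enum):
    COUNT = "count"
    TMTC = "tmtc"
    PROLIFERATED = "proliferated"
    INHIBITED = "inhibited"


@dataclass(frozen=True)
class Outcome:
    """Tagged outcome of scoring one inflorescence."""

    tag: OutcomeTag
    count: int | None = None

    def __post_init__(self) -> None:
        if self.tag is OutcomeTag.COUNT:
            if self.count is None or self.count < 0 or int(self.count) != self.count:
                raise ValueError(f"Count outcome requires a non-negative integer, got {self.count!r}")
        elif self.count is not None:
            raise ValueError(f"{self.tag.value} outcome carries no count")

    @staticmethod
    def count_(n: int) -> "Outcome":
        return Outcome(OutcomeTag.COUNT, int(n))


TMTC = Outcome(OutcomeTag.TMTC)
PROLIFERATED = Outcome(OutcomeTag.PROLIFERATED)
INHIBITED = Outcome(OutcomeTag.INHIBITED)


@dataclass(frozen=True)
class InflorescenceObservation:
    plant_id: str
    inflorescence_index: int
    outcome: Outcome

    def __post_init__(self) -> None:
        if self.inflorescence_index < 1:
            raise ValueError("inflorescence_index must be >= 1")


@dataclass(frozen=True)
class PlantMeta:
    """Per-plant annotations that ride along with the observations."""

    genotype: Genotype
    population_id: str
    season_id: str


@dataclass(frozen=True)
class PlantRecord:
    """One plant: genotype, labels, exposure ``t`` and branching total ``y``."""

    plant_id: str
    genotype: Genotype
    population_id: str
    season_id: str
    t: int
    y: int

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError(f"plant {self.plant_id}: t must be >= 1, got {self.t}")
        if self.y < 0:
            raise ValueError(f"plant {self.plant_id}: y must be >= 0, got {self.y}")


def summarize_plants(
    observations: Iterable[InflorescenceObservation],
    plant_meta: Mapping[str, PlantMeta],
    censor_value: int = DEFAULT_CENSOR,
) -> list[PlantRecord]:
    """Collapse per-inflorescence observations into plant-level records.

    TMTC inflorescences contribute ``censor_value`` branching events;
    proliferated and inhibited inflorescences are excluded and count
    toward neither ``t`` nor ``y``.  Plants left with zero countable
    inflorescences are omitted (with a warning): the likelihood requires
    ``t >= 1``.
    """
    if censor_value <= 0:
        raise ValueError("censor_value must be positive")
    per_plant: dict[str, list[InflorescenceObservation]] = {}
    for obs in observations:
        per_plant.setdefault(obs.plant_id, []).append(obs)
    records: list[PlantRecord] = []
    for plant_id, obs_list in per_plant.items():
        t = 0
        y = 0
        for obs in obs_list:
            if obs.outcome.tag is OutcomeTag.COUNT:
                t += 1
                y += obs.outcome.count
            elif obs.outcome.tag is OutcomeTag.TMTC:
                t += 1
                y += censor_value
            elif obs.outcome.tag in (OutcomeTag.PROLIFERATED, OutcomeTag.INHIBITED):
                continue
            else:  # pragma: no cover - enum is closed
                raise ValueError(f"unknown outcome tag {obs.outcome.tag!r}")
        if t == 0:
            logger.warning("plant %s has no countable inflorescences; dropped", plant_id)
            continue
        meta = plant_meta[plant_id]
        records.append(
            PlantRecord(plant_id, meta.genotype, meta.population_id, meta.season_id, t, y)
        )
    return records


# ---------------------------------------------------------------------------
# Delimited-text I/O

GENOTYPE_COLUMNS = ("PLT3", "PLT7", "J2", "EJ2_allele", "EJ2")
DEFAULT_SCHEMA = {
    "plant_id": "plant_id",
    "population": "population",
    "season": "season",
    "t": "t",
    "y": "y",
    "inflorescence_index": "inflorescence_index",
    "outcome": "outcome",
    **{c: c for c in GENOTYPE_COLUMNS},
}


def _parse_genotype(row: Mapping[str, object]) -> Genotype:
    allele_token = str(row["EJ2_allele"]).strip().lower()
    allele = None if allele_token in ("", "none", "nan", "wt") else allele_token
    if allele is not None and allele not in EJ2_ALLELES:
        raise ValueError(f"unknown EJ2 allele {allele_token!r}")
    ej2_state = parse_locus_state(row["EJ2"])
    if ej2_state is LocusState.WT_HOM:
        allele = None
    elif allele is None:
        raise ValueError("non-WT EJ2 state requires an EJ2_allele")
    return Genotype(
        plt3=parse_locus_state(row["PLT3"]),
        plt7=parse_locus_state(row["PLT7"]),
        j2=parse_locus_state(row["J2"]),
        ej2_allele=allele,
        ej2_state=ej2_state,
    )


def parse_outcome(token: object) -> Outcome:
    """Parse a long-format outcome token: integer, TMTC, proliferated, inhibited."""
    s = str(token).strip().lower()
    if s == "tmtc":
        return TMTC
    if s == "proliferated":
        return PROLIFERATED
    if s == "inhibited":
        return INHIBITED
    try:
        n = int(float(s)) if float(s) == int(float(s)) else None
    except ValueError:
        n = None
    if n is None or n < 0:
        raise ValueError(f"unparseable outcome token {token!r}")
    return Outcome.count_(n)


def read_phenotype_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str = ",",
    censor_value: int = DEFAULT_CENSOR,
) -> list[PlantRecord]:
    """Read a plant-level (wide) or per-inflorescence (long) delimited table.

    The dialect is auto-detected by the presence of an outcome column.
    Rows that fail validation are rejected and logged with their row
    number; remaining rows are returned.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, delimiter=delimiter, dtype=str, keep_default_na=False)
    missing = [
        colmap[k]
        for k in ("plant_id", "population", "season", *GENOTYPE_COLUMNS)
        if colmap[k] not in df.columns
    ]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items() if v in df.columns})
    long_format = "outcome" in df.columns

    if long_format:
        observations: list[InflorescenceObservation] = []
        meta: dict[str, PlantMeta] = {}
        for i, row in enumerate(df.to_dict("records")):
            try:
                pid = str(row["plant_id"])
                if pid not in meta:
                    meta[pid] = PlantMeta(
                        _parse_genotype(row), str(row["population"]), str(row["season"])
                    )
                idx = int(row.get("inflorescence_index") or len(observations) + 1)
                observations.append(
                    InflorescenceObservation(pid, idx, parse_outcome(row["outcome"]))
                )
            except (ValueError, KeyError) as exc:
                logger.warning("row %d rejected: %s", i + 2, exc)
        return summarize_plants(observations, meta, censor_value=censor_value)

    records: list[PlantRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.to_dict("records")):
        try:
            pid = str(row["plant_id"])
            if pid in seen:
                raise ValueError(f"duplicate plant_id {pid!r}")
            rec = PlantRecord(
                plant_id=pid,
                genotype=_parse_genotype(row),
                population_id=str(row["population"]),
                season_id=str(row["season"]),
                t=int(row["t"]),
                y=int(row["y"]),
            )
            seen.add(pid)
            records.append(rec)
        except (ValueError, KeyError) as exc:
            logger.warning("row %d rejected: %s", i + 2, exc)
    return records


def records_to_frame(records: Sequence[PlantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        g = r.genotype
        rows.append(
            {
                "plant_id": r.plant_id,
                "population": r.population_id,
                "season": r.season_id,
                "PLT3": g.plt3.short,
                "PLT7": g.plt7.short,
                "J2": g.j2.short,
                "EJ2_allele": g.ej2_allele or "none",
                "EJ2": g.ej2_state.short,
                "t": r.t,
                "y": r.y,
            }
        )
    return pd.DataFrame(rows)


def write_phenotype_table(records: Sequence[PlantRecord], path: str | Path, delimiter: str = ",") -> None:
    """Write plant-level records as a wide delimited table (round-trips with the reader)."""
    records_to_frame(records).to_csv(path, sep=delimiter, index=False)


def write_observation_table(
    observations: Sequence[InflorescenceObservation],
    plant_meta: Mapping[str, PlantMeta],
    path: str | Path,
    delimiter: str = ",",
) -> None:
    """Write per-inflorescence observations as a long delimited table."""
    rows = []
    for obs in observations:
        m = plant_meta[obs.plant_id]
        g = m.genotype
        if obs.outcome.tag is OutcomeTag.COUNT:
            outcome = str(obs.outcome.count)
        else:
            outcome = {"tmtc": "TMTC"}.get(obs.outcome.tag.value, obs.outcome.tag.value)
        rows.append(
            {
                "plant_id": obs.plant_id,
                "population": m.population_id,
                "season": m.season_id,
                "PLT3": g.plt3.short,
                "PLT7": g.plt7.short,
                "J2": g.j2.short,
                "EJ2_allele": g.ej2_allele or "none",
                "EJ2": g.ej2_state.short,
                "inflorescence_index": obs.inflorescence_index,
                "outcome": outcome,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------


def genotype_group_label(record: PlantRecord) -> str:
    return record.genotype.label()


def dispersion_summary(
    records: Sequence[PlantRecord], grouping: str = "genotype"
) -> pd.DataFrame:
    """Per-group overdispersion diagnostics on branching rates.

    For each group (genotype, or genotype x season) with at least two
    plants the table reports the mean branching rate per inflorescence,
    the variance of per-plant rates, and a variance/mean index scaled by
    the mean exposure so that Poisson-distributed totals give an index
    near 1.  An index well above 1 indicates overdispersion (NB variance
    mu + alpha*mu^2 gives an expected index of 1 + alpha*mu*t).  Groups
    with fewer than two plants are listed with index NaN.
    """
    if not records:
        raise ValueError("empty record list")
    if grouping not in ("genotype", "genotype-season"):
        raise ValueError("grouping must be 'genotype' or 'genotype-season'")
    groups: dict[str, list[PlantRecord]] = {}
    for r in records:
        key = r.genotype.label()
        if grouping == "genotype-season":
            key = f"{key}@{r.season_id}"
        groups.setdefault(key, []).append(r)
    rows = []
    for key, recs in sorted(groups.items()):
        rates = np.array([r.y / r.t for r in recs])
        tbar = float(np.mean([r.t for r in recs]))
        mean_rate = float(np.mean(rates))
        if len(recs) < 2:
            rows.append({"group": key, "n_plants": len(recs), "mean_rate": mean_rate,
                         "var_rate": np.nan, "index": np.nan, "skipped": True})
            continue
        var_rate = float(np.var(rates, ddof=1))
        index = 0.0 if var_rate == 0 else (var_rate * tbar / mean_rate if mean_rate > 0 else np.inf)
        rows.append({"group": key, "n_plants": len(recs), "mean_rate": mean_rate,
                     "var_rate": var_rate, "index": index, "skipped": False})
    return pd.DataFrame(rows)
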