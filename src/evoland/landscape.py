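"""Genetic-interaction fitness landscape.

A landscape is a table of gene-pair records from an SGA-style screen: the
relative fitness of each single deletion mutant, the fitness of the double
mutant, its standard deviation, the interaction score epsilon (GIS) and an
associated p-value.  Fitness is dimensionless, wild type = 1.

Two classifications are built on top of the table:

* interaction *sign* under a confidence filter — lenient (p < 0.05) or
  stringent (p < 0.05 and GIS > 0.16 or < -0.12, the conventional SGA
  thresholds);
* the *landscape effect* of inactivating the array gene in the query
  deletion background — beneficial / deleterious when the single-vs-double
  fitness difference exceeds three standard deviations of the double-mutant
  fitness, neutral otherwise.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = [
    "ConfidenceFilter",
    "EffectClass",
    "InteractionSign",
    "InteractionRecord",
    "FitnessLandscape",
    "normalize_gene",
    "epistasis_score",
    "classify_interaction",
    "landscape_effect",
    "effect_of_inactivation",
    "interactors_of",
    "mean_degree",
    "mean_degree_from_counts",
    "load_landscape",
]

# Stringent SGA confidence thresholds on the interaction score.
STRINGENT_POSITIVE_GIS = 0.16
STRINGENT_NEGATIVE_GIS = -0.12
SIGNIFICANCE_P = 0.05


def normalize_gene(name: str) -> str:
    """Case-normalize a gene identifier (yeast convention: upper case)."""
    name = str(name).strip()
    if not name:
        raise ValueError("empty gene identifier")
    return name.upper()


class ConfidenceFilter(enum.Enum):
    """Confidence filtration threshold for calling an interaction.

    Every record passing ``STRINGENT`` also passes ``LENIENT``.
    """

    LENIENT = "lenient"
    STRINGENT = "stringent"


class InteractionSign(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NONE = "none"


class EffectClass(enum.Enum):
    """Predicted fitness effect of inactivating a gene in a deletion background.

    ``UNKNOWN`` is returned if and only if the landscape holds no record for
    the pair; unknown pairs are excluded from downstream tallies, never
    imputed as neutral.
    """

    BENEFICIAL = "beneficial"
    DELETERIOUS = "deleterious"
    NEUTRAL = "neutral"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class InteractionRecord:
    """One gene-pair record of the landscape.

    ``query`` is the background deletion (e.g. cog7Δ), ``array`` the second
    deletion.  Fitnesses are relative (wild type = 1); ``score`` is the
    interaction score epsilon.
    """

    query: str
    array: str
    fitness_query: float
    fitness_array: float
    fitness_double: float
    sd_double: float
    score: float
    p_value: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "query", normalize_gene(self.query))
        object.__setattr__(self, "array", normalize_gene(self.array))
        for name in ("fitness_query", "fitness_array", "fitness_double"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if not math.isnan(self.sd_double) and self.sd_double < 0:
            raise ValueError(f"sd_double must be >= 0, got {self.sd_double}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value must be in [0, 1], got {self.p_value}")


def epistasis_score(fitness_a: float, fitness_b: float, fitness_ab: float) -> float:
    """Interaction score under the multiplicative null: f_ab − f_a·f_b.

    Positive values mean the double mutant is fitter than expected from the
    two single mutants (positive epistasis); negative values, less fit.
    """
    for name, v in (("fitness_a", fitness_a), ("fitness_b", fitness_b),
                    ("fitness_ab", fitness_ab)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return fitness_ab - fitness_a * fitness_b


def classify_interaction(
    record: InteractionRecord, filter: ConfidenceFilter
) -> InteractionSign:
    """Sign of an interaction under a confidence filter.

    Stringent: positive iff p < 0.05 and GIS > 0.16; negative iff p < 0.05
    and GIS < −0.12.  Lenient: the sign of the score whenever p < 0.05.
    """
    if record.p_value >= SIGNIFICANCE_P:
        return InteractionSign.NONE
    if filter is ConfidenceFilter.STRINGENT:
        if record.score > STRINGENT_POSITIVE_GIS:
            return InteractionSign.POSITIVE
        if record.score < STRINGENT_NEGATIVE_GIS:
            return InteractionSign.NEGATIVE
        return InteractionSign.NONE
    if record.score > 0:
        return InteractionSign.POSITIVE
    if record.score < 0:
        return InteractionSign.NEGATIVE
    return InteractionSign.NONE


def landscape_effect(record: InteractionRecord) -> EffectClass:
    """Effect of inactivating ``array`` in the ``query`` deletion background.

    Beneficial or deleterious when |f_double − f_query| strictly exceeds
    3·sd_double; ties and smaller differences are neutral.  The rule depends
    only on the fitness difference and the double-mutant SD.
    """
    if record.sd_double is None or math.isnan(record.sd_double):
        raise ValueError(
            f"record ({record.query}, {record.array}) lacks sd_double"
        )
    diff = record.fitness_double - record.fitness_query
    if abs(diff) > 3.0 * record.sd_double:
        return EffectClass.BENEFICIAL if diff > 0 else EffectClass.DELETERIOUS
    return EffectClass.NEUTRAL


@dataclass
class FitnessLandscape:
    """Indexed collection of interaction records.

    Lookups are directional: the record for (background, target) is the one
    whose query is the background deletion.  If the data set carries both
    (A, B) and (B, A), they stay distinct — the effect rule is directional.
    """

    records: list[InteractionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_pair: dict[tuple[str, str], InteractionRecord] = {}
        self._by_gene: dict[str, list[InteractionRecord]] = {}
        for rec in self.records:
            self._index(rec)

    def _index(self, rec: InteractionRecord) -> None:
        key = (rec.query, rec.array)
        if key in self._by_pair:
            raise ValueError(f"duplicate record for pair {key}")
        self._by_pair[key] = rec
        self._by_gene.setdefault(rec.query, []).append(rec)
        self._by_gene.setdefault(rec.array, []).append(rec)

    def add(self, rec: InteractionRecord) -> None:
        self.records.append(rec)
        self._index(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[InteractionRecord]:
        return iter(self.records)

    def lookup(self, background: str, target: str) -> InteractionRecord | None:
        return self._by_pair.get((normalize_gene(background), normalize_gene(target)))

    def genes(self) -> set[str]:
        return set(self._by_gene)

    def records_of(self, gene: str) -> list[InteractionRecord]:
        return list(self._by_gene.get(normalize_gene(gene), []))


def effect_of_inactivation(
    landscape: FitnessLandscape, background: str, target: str
) -> EffectClass:
    """Landscape effect of inactivating ``target`` in the ``background``
    deletion strain; ``UNKNOWN`` when the pair has no record."""
    rec = landscape.lookup(background, target)
    if rec is None:
        return EffectClass.UNKNOWN
    return landscape_effect(rec)


def interactors_of(
    landscape: FitnessLandscape, gene: str, filter: ConfidenceFilter
) -> set[str]:
    """Genes whose record with ``gene`` calls an interaction under ``filter``.

    The stringent set is a subset of the lenient set by construction of the
    thresholds.
    """
    gene = normalize_gene(gene)
    out: set[str] = set()
    for rec in landscape.records_of(gene):
        if classify_interaction(rec, filter) is not InteractionSign.NONE:
            partner = rec.array if rec.query == gene else rec.query
            out.add(partner)
    out.discard(gene)
    return out


def mean_degree(landscape: FitnessLandscape) -> float:
    """Average interactions per gene: non-redundant records / unique genes."""
    if len(landscape) == 0:
        raise ValueError("empty landscape")
    return mean_degree_from_counts(len(landscape), len(landscape.genes()))


def mean_degree_from_counts(n_records: int, n_genes: int) -> float:
    """Records-per-gene average from summary counts (records / genes)."""
    if n_records <= 0 or n_genes <= 0:
        raise ValueError("record and gene counts must be positive")
    return n_records / n_genes


DEFAULT_COLUMNS = {
    "query": "query_gene",
    "array": "array_gene",
    "fitness_query": "fitness_query",
    "fitness_array": "fitness_array",
    "fitness_double": "fitness_double",
    "sd_double": "sd_double",
    "score": "score",
    "p_value": "p_value",
}


def load_landscape(
    path: str | Path, columns: dict[str, str] | None = None
) -> FitnessLandscape:
    """Load a landscape from a TSV with a header.

    Default header matches a Costanzo-style export: query_gene, array_gene,
    fitness_query, fitness_array, fitness_double, sd_double, score, p_value.
    ``columns`` remaps field → column name.  '#'-prefixed lines are ignored.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", comment="#", encoding="utf-8")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"landscape file {path} lacks columns: {missing}")
    records = [
        InteractionRecord(
            query=row[cols["query"]],
            array=row[cols["array"]],
            fitness_query=float(row[cols["fitness_query"]]),
            fitness_array=float(row[cols["fitness_array"]]),
            fitness_double=float(row[cols["fitness_double"]]),
            sd_double=float(row[cols["sd_double"]]),
            score=float(row[cols["score"]]),
            p_value=float(row[cols["p_value"]]),
        )
        for _, row in df.iterrows()
    ]
    return FitnessLandscape(records)


def write_landscape(landscape: FitnessLandscape, path: str | Path) -> None:
    """Write a landscape to the default TSV layout."""
    rows = [
        {
            "query_gene": r.query,
            "array_gene": r.array,
            "fitness_query": r.fitness_query,
            "fitness_array": r.fitness_array,
            "fitness_double": r.fitness_double,
            "sd_double": r.sd_double,
            "score": r.score,
            "p_value": r.p_value,
        }
        for r in landscape
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
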