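"""Concordance of evolved changes with the interaction-network fitness
landscape.

Three cross-analyses of the upstream pipelines:

* loss-of-function concordance — classify each gene inactivated during
  evolution by its predicted effect in the strain's deletion background and
  tally beneficial / neutral / deleterious / unknown (the "one in eight"
  style summary);
* DEG direction vs predicted effect — the (down, up) x (deleterious,
  beneficial) contingency table per strain with a two-sided Fisher exact
  test of under-representation of down-regulated deleterious genes;
* GI overlap — the fraction of a DEG (or mutated-gene) set that genetically
  interacts with a query gene under a confidence filter, with a
  hypergeometric null for the expected overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from scipy import stats

from .expression import DEGSet
from .landscape import (
    ConfidenceFilter,
    EffectClass,
    FitnessLandscape,
    effect_of_inactivation,
    interactors_of,
    normalize_gene,
)

__all__ = [
    "LofConcordanceReport",
    "DirectionEffectTable",
    "FisherResult",
    "GiOverlapReport",
    "lof_concordance",
    "direction_effect_table",
    "fisher_exact_2x2",
    "gi_overlap",
    "overlap_null_expectation",
]


@dataclass
class LofConcordanceReport:
    """Per-gene landscape effects of loss-of-function events in one strain
    background, with class tallies.

    The concordant fraction is beneficial / (beneficial + neutral +
    deleterious): the share of inactivations the landscape predicted to
    help.  Genes without a landscape record are counted as unknown and kept
    out of the fraction.
    """

    background: str
    entries: list[tuple[str, EffectClass]] = field(default_factory=list)

    def count(self, cls: EffectClass) -> int:
        return sum(1 for _, c in self.entries if c is cls)

    @property
    def counts(self) -> dict[str, int]:
        return {cls.value: self.count(cls) for cls in EffectClass}

    @property
    def concordant_fraction(self) -> float | None:
        known = (
            self.count(EffectClass.BENEFICIAL)
            + self.count(EffectClass.NEUTRAL)
            + self.count(EffectClass.DELETERIOUS)
        )
        if known == 0:
            return None
        return self.count(EffectClass.BENEFICIAL) / known


def lof_concordance(
    lof_genes: Iterable[str], background: str, landscape: FitnessLandscape
) -> LofConcordanceReport:
    """Classify loss-of-function genes by predicted effect in ``background``."""
    background = normalize_gene(background)
    entries = [
        (g, effect_of_inactivation(landscape, background, g))
        for g in sorted({normalize_gene(g) for g in lof_genes})
    ]
    return LofConcordanceReport(background=background, entries=entries)


@dataclass(frozen=True)
class FisherResult:
    """Two-sided Fisher exact test result; odds_ratio is ad/bc, math.inf
    when bc = 0 with ad > 0."""

    odds_ratio: float
    p_value: float


def fisher_exact_2x2(cells: tuple[int, int, int, int]) -> FisherResult:
    """Two-sided Fisher exact test of a 2x2 table (a, b, c, d).

    The p-value sums hypergeometric probabilities of every table with the
    observed margins whose probability does not exceed that of the observed
    table (the point-probability method).
    """
    a, b, c, d = cells
    if min(a, b, c, d) < 0 or any(x != int(x) for x in cells):
        raise ValueError("cells must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return FisherResult(odds_ratio=float(odds), p_value=float(p))


@dataclass
class DirectionEffectTable:
    """(down, up) x (deleterious, beneficial) DEG counts for one background.

    Only DEGs whose predicted inactivation effect is deleterious or
    beneficial enter the cells; neutral and unknown DEGs are counted in
    ``excluded_neutral`` / ``excluded_unknown`` and reported, never silently
    dropped.
    """

    background: str
    down_deleterious: int = 0
    up_deleterious: int = 0
    down_beneficial: int = 0
    up_beneficial: int = 0
    excluded_neutral: int = 0
    excluded_unknown: int = 0

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """(down-deleterious, up-deleterious, down-beneficial, up-beneficial)."""
        return (
            self.down_deleterious,
            self.up_deleterious,
            self.down_beneficial,
            self.up_beneficial,
        )

    @property
    def excluded(self) -> int:
        return self.excluded_neutral + self.excluded_unknown

    def fisher(self) -> FisherResult:
        """Fisher exact test on the table as printed: rows are effect
        classes, columns the DEG direction."""
        return fisher_exact_2x2(self.cells)

    def fisher_vs_background(self, genome_down: int, genome_up: int) -> FisherResult:
        """Secondary construction: deleterious DEGs against all remaining
        DEGs of the strain (genome-wide direction background)."""
        rest_down = genome_down - self.down_deleterious
        rest_up = genome_up - self.up_deleterious
        if rest_down < 0 or rest_up < 0:
            raise ValueError("genome-wide counts smaller than table cells")
        return fisher_exact_2x2(
            (self.down_deleterious, self.up_deleterious, rest_down, rest_up)
        )


def direction_effect_table(
    degs: DEGSet, background: str, landscape: FitnessLandscape
) -> DirectionEffectTable:
    """Cross each up/down DEG with its predicted inactivation effect in
    ``background``.  Ambiguous DEGs are excluded upstream by construction."""
    table = DirectionEffectTable(background=normalize_gene(background))
    for direction, genes in (("down", degs.down), ("up", degs.up)):
        for gene in genes:
            effect = effect_of_inactivation(landscape, background, gene)
            if effect is EffectClass.DELETERIOUS:
                if direction == "down":
                    table.down_deleterious += 1
                else:
                    table.up_deleterious += 1
            elif effect is EffectClass.BENEFICIAL:
                if direction == "down":
                    table.down_beneficial += 1
                else:
                    table.up_beneficial += 1
            elif effect is EffectClass.NEUTRAL:
                table.excluded_neutral += 1
            else:
                table.excluded_unknown += 1
    return table


@dataclass
class GiOverlapReport:
    """Overlap of a gene set with the interactors of a query gene."""

    query: str
    set_size: int
    overlap: int
    filter: ConfidenceFilter
    overlapping_genes: set[str] = field(default_factory=set)

    @property
    def percentage(self) -> float | None:
        if self.set_size == 0:
            return None
        return 100.0 * self.overlap / self.set_size


def gi_overlap(
    gene_set: Iterable[str],
    query: str,
    landscape: FitnessLandscape,
    filter: ConfidenceFilter = ConfidenceFilter.STRINGENT,
) -> GiOverlapReport:
    """Overlap of ``gene_set`` (DEGs or mutated genes) with the interactors
    of ``query`` under the given confidence filter."""
    genes = {normalize_gene(g) for g in gene_set}
    inter = interactors_of(landscape, query, filter)
    hit = genes & inter
    return GiOverlapReport(
        query=normalize_gene(query),
        set_size=len(genes),
        overlap=len(hit),
        filter=filter,
        overlapping_genes=hit,
    )


@dataclass(frozen=True)
class OverlapNull:
    expected: float
    p_upper: float  # P(X >= observed) under the hypergeometric null
    p_lower: float  # P(X <= observed)


def overlap_null_expectation(
    set_size: int,
    interactor_count: int,
    universe_size: int,
    observed: int | None = None,
) -> OverlapNull:
    """Hypergeometric null for the overlap of a random ``set_size`` draw with
    ``interactor_count`` marked genes out of ``universe_size``.

    Expected overlap is set_size * interactor_count / universe_size; tail
    probabilities are computed at ``observed`` (defaults to the rounded
    expectation).
    """
    if universe_size <= 0:
        raise ValueError("universe_size must be positive")
    if not (0 <= interactor_count <= universe_size and 0 <= set_size <= universe_size):
        raise ValueError("counts inconsistent with universe size")
    expected = set_size * interactor_count / universe_size
    k = int(round(expected)) if observed is None else int(observed)
    rv = stats.hypergeom(universe_size, interactor_count, set_size)
    p_upper = float(rv.sf(k - 1))
    p_lower = float(rv.cdf(k))
    return OverlapNull(expected=expected, p_upper=p_upper, p_lower=p_lower)
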