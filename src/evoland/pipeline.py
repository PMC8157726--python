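"""End-to-end variant processing for one population.

Chains the filtering, TR masking and annotation steps in the order the
study applied them: read-support/frequency filter, tandem-repeat mask,
region annotation with precedence, coding-effect classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .variants import (
    MutationRecord,
    GeneModel,
    VariantCall,
    annotate_variants,
    filter_variants,
    mask_tandem_repeats,
)

__all__ = ["PopulationResult", "process_population"]


@dataclass
class PopulationResult:
    """Outcome of the variant pipeline for one population."""

    records: list[MutationRecord]
    masked: list[VariantCall] = field(default_factory=list)
    removed_low_support: int = 0

    @property
    def lof_genes(self) -> set[str]:
        return {r.gene for r in self.records if r.is_lof and r.gene}

    @property
    def mutated_genes(self) -> set[str]:
        return {r.gene for r in self.records if r.gene}


def process_population(
    calls: Sequence[VariantCall],
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    tr_regions: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    min_reads: int = 10,
    min_frequency: float = 0.5,
    promoter_bp: int = 500,
    terminator_bp: int = 250,
) -> PopulationResult:
    """Filter, mask and annotate one population's variant calls."""
    kept = filter_variants(calls, min_reads=min_reads, min_frequency=min_frequency)
    removed = len(calls) - len(kept)
    masked: list[VariantCall] = []
    if tr_regions:
        kept, masked = mask_tandem_repeats(kept, tr_regions)
    records = annotate_variants(
        kept, genes, genome, promoter_bp=promoter_bp, terminator_bp=terminator_bp
    )
    return PopulationResult(
        records=records, masked=masked, removed_low_support=removed
    )
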