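"""Population variant filtering, annotation and coding-effect calls.

The pipeline starts from variant call tables of evolved whole-population
sequencing (population-scale allele frequencies, not clonal genotypes) and

* filters calls on supporting reads (>= 10) and population frequency
  (>= 50%),
* masks calls falling in tandem-repeat (TR) regions,
* assigns each call to ORF / promoter (<= 500 nt upstream of the start
  codon) / terminator (<= 250 nt downstream of the stop codon) / intergenic,
  strand-aware, with precedence ORF > promoter > terminator > intergenic,
* classifies coding effects (synonymous / nonsynonymous / nonsense /
  frameshift / in-frame indel) and flags loss-of-function calls
  (nonsense or frameshift),
* computes fixed mutation rates (mutations per nucleotide per replication
  cycle) and genotype-specific / parallel-evolution gene sets.

Coordinates are 1-based inclusive (VCF/GFF convention); BED inputs are
converted from 0-based half-open on load.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .landscape import normalize_gene

__all__ = [
    "RegionClass",
    "CodingEffect",
    "VariantCall",
    "GeneModel",
    "MutationRecord",
    "PopulationSample",
    "UnclassifiableVariant",
    "filter_variants",
    "mask_tandem_repeats",
    "annotate_region",
    "resolve_region_precedence",
    "classify_coding_effect",
    "annotate_variants",
    "fixed_mutation_rate",
    "genotype_specific_mutations",
    "parallel_evolution",
    "read_vcf",
    "read_variants_tsv",
    "load_gene_models_gff3",
    "load_genome_fasta",
    "load_tr_mask_bed",
    "mutation_records_to_frame",
]

PROMOTER_BP = 500
TERMINATOR_BP = 250
MIN_READS = 10
MIN_FREQUENCY = 0.5


class RegionClass(enum.Enum):
    ORF = "ORF"
    PROMOTER = "promoter"
    TERMINATOR = "terminator"
    INTERGENIC = "intergenic"
    TANDEM_REPEAT = "tandem_repeat"


#: precedence for collapsing multi-gene annotations to one category
_REGION_PRECEDENCE = [
    RegionClass.ORF,
    RegionClass.PROMOTER,
    RegionClass.TERMINATOR,
    RegionClass.INTERGENIC,
]


class CodingEffect(enum.Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    NONCODING = "noncoding"


LOF_EFFECTS = frozenset({CodingEffect.NONSENSE, CodingEffect.FRAMESHIFT})


class UnclassifiableVariant(Exception):
    """Raised when a codon carries an ambiguous base and cannot be translated."""


@dataclass(frozen=True)
class VariantCall:
    """One alt allele at one site in one population sample.

    ``frequency`` is the population-scale allele frequency alt_reads/depth.
    Multi-allelic sites are split into one call per alt allele upstream.
    """

    chrom: str
    pos: int  # 1-based position of the first affected base
    ref: str
    alt: str
    alt_reads: int
    depth: int
    population_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.alt_reads > self.depth:
            raise ValueError("alt_reads exceeds depth")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")

    @property
    def frequency(self) -> float:
        return self.alt_reads / self.depth if self.depth else 0.0

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive interval of reference bases affected."""
        return self.pos, self.pos + len(self.ref) - 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass(frozen=True)
class GeneModel:
    """A single-CDS gene model with 1-based inclusive CDS coordinates."""

    gene: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    coding: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_gene(self.gene))
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.cds_start > self.cds_end:
            raise ValueError("cds_start > cds_end")

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1


@dataclass(frozen=True)
class MutationRecord:
    """A filtered, annotated variant: one genomic category, optional gene,
    coding effect and loss-of-function flag."""

    variant: VariantCall
    gene: str | None
    region: RegionClass
    effect: CodingEffect
    is_lof: bool

    def __post_init__(self) -> None:
        if self.is_lof != (self.effect in LOF_EFFECTS):
            raise ValueError("is_lof inconsistent with effect")
        if (self.effect is CodingEffect.NONCODING) != (self.region is not RegionClass.ORF):
            raise ValueError("effect/region inconsistency")


@dataclass(frozen=True)
class PopulationSample:
    """An evolved population: strain genotype, replicate and generations.

    Mutator populations carry the msh2Δ mismatch-repair deletion and were
    propagated longer (ca. 350 vs 200 replication cycles).
    """

    strain_genotype: str
    replicate: int
    generations: float
    mutator: bool

    def __post_init__(self) -> None:
        if self.generations <= 0:
            raise ValueError("generations must be > 0")


# ---------------------------------------------------------------------------
# filtering and masking


def filter_variants(
    calls: Sequence[VariantCall],
    min_reads: int = MIN_READS,
    min_frequency: float = MIN_FREQUENCY,
) -> list[VariantCall]:
    """High-frequency variant filter: keep calls with at least ``min_reads``
    supporting reads and population frequency >= ``min_frequency``.

    Order-preserving and idempotent.
    """
    return [
        c for c in calls
        if c.alt_reads >= min_reads and c.frequency >= min_frequency
    ]


def _tr_trees(
    tr_regions: Mapping[str, Iterable[tuple[int, int]]]
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, ivals in tr_regions.items():
        tree = IntervalTree()
        for start, end in ivals:
            if start > end:
                raise ValueError(f"malformed interval ({start}, {end}) on {chrom}")
            if start == end:
                continue
            tree.addi(start, end)
        trees[chrom] = tree
    return trees


def mask_tandem_repeats(
    calls: Sequence[VariantCall],
    tr_regions: Mapping[str, Iterable[tuple[int, int]]],
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Split calls into (retained, masked) against a tandem-repeat mask.

    ``tr_regions`` maps chrom -> 0-based half-open intervals.  A call is
    masked iff any base of its reference span overlaps a TR interval.
    """
    trees = _tr_trees(tr_regions)
    retained: list[VariantCall] = []
    masked: list[VariantCall] = []
    for c in calls:
        lo, hi = c.span  # 1-based inclusive -> 0-based half-open
        tree = trees.get(c.chrom)
        if tree is not None and tree.overlap(lo - 1, hi):
            masked.append(c)
        else:
            retained.append(c)
    return retained, masked


# ---------------------------------------------------------------------------
# region annotation


def _regions_for_gene(
    pos: int, gene: GeneModel, promoter_bp: int, terminator_bp: int
) -> RegionClass | None:
    if gene.cds_start <= pos <= gene.cds_end:
        return RegionClass.ORF
    if gene.strand == "+":
        promoter = (gene.cds_start - promoter_bp, gene.cds_start - 1)
        terminator = (gene.cds_end + 1, gene.cds_end + terminator_bp)
    else:
        promoter = (gene.cds_end + 1, gene.cds_end + promoter_bp)
        terminator = (gene.cds_start - terminator_bp, gene.cds_start - 1)
    if promoter[0] <= pos <= promoter[1]:
        return RegionClass.PROMOTER
    if terminator[0] <= pos <= terminator[1]:
        return RegionClass.TERMINATOR
    return None


def annotate_region(
    call: VariantCall,
    genes: Sequence[GeneModel],
    promoter_bp: int = PROMOTER_BP,
    terminator_bp: int = TERMINATOR_BP,
) -> list[tuple[str | None, RegionClass]]:
    """Per-gene region annotations of a call.

    Promoter windows extend ``promoter_bp`` nt 5' of the start codon on the
    gene's coding strand; terminator windows ``terminator_bp`` nt 3' of the
    stop codon.  Windows are not truncated by neighbouring genes, so a call
    may annotate to several genes.  A call hitting no window returns the
    single entry ``(None, INTERGENIC)``.
    """
    hits: list[tuple[str | None, RegionClass]] = []
    for gene in genes:
        if gene.chrom != call.chrom:
            continue
        region = _regions_for_gene(call.pos, gene, promoter_bp, terminator_bp)
        if region is not None:
            hits.append((gene.gene, region))
    if not hits:
        return [(None, RegionClass.INTERGENIC)]
    return hits


def resolve_region_precedence(
    annotations: Sequence[tuple[str | None, RegionClass]]
) -> RegionClass:
    """Collapse multi-gene annotations to one genome-wide category with
    precedence ORF > promoter > terminator > intergenic."""
    present = {region for _, region in annotations}
    for region in _REGION_PRECEDENCE:
        if region in present:
            return region
    return RegionClass.INTERGENIC


# ---------------------------------------------------------------------------
# coding effect


def _coding_sequences(
    call: VariantCall, gene: GeneModel, genome: Mapping[str, str]
) -> tuple[str, str]:
    """Reference and mutated CDS on the coding strand."""
    chrom_seq = genome[call.chrom]
    cds = chrom_seq[gene.cds_start - 1 : gene.cds_end]
    offset = call.pos - gene.cds_start
    ref_in_cds = cds[offset : offset + len(call.ref)]
    expected = call.ref[: len(ref_in_cds)]
    if ref_in_cds.upper() != expected.upper():
        raise ValueError(
            f"ref allele {call.ref!r} at {call.chrom}:{call.pos} does not match "
            f"genome sequence {ref_in_cds!r}"
        )
    mutated = cds[:offset] + call.alt + cds[offset + len(call.ref):]
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
        mutated = str(Seq(mutated).reverse_complement())
    return cds, mutated


def classify_coding_effect(
    call: VariantCall, gene: GeneModel, genome: Mapping[str, str]
) -> CodingEffect:
    """Coding effect of a call inside a gene's ORF.

    Substitutions are translated on the coding strand with the standard
    nuclear code: an alt codon that becomes a stop is nonsense; otherwise
    nonsynonymous or synonymous.  A multi-base substitution confined to one
    codon is translated jointly.  Indels are frameshift when the length
    change is not divisible by 3, in-frame otherwise.  Nonsense and
    frameshift are loss-of-function.
    """
    if not gene.coding:
        raise ValueError(f"gene {gene.gene} is non-coding")
    lo, hi = call.span
    if not (gene.cds_start <= call.pos <= gene.cds_end):
        raise ValueError(
            f"call at {call.chrom}:{call.pos} outside CDS of {gene.gene}"
        )
    if call.is_indel:
        shift = abs(len(call.ref) - len(call.alt)) % 3
        return CodingEffect.FRAMESHIFT if shift else CodingEffect.INFRAME_INDEL

    ref_cds, alt_cds = _coding_sequences(call, gene, genome)
    # affected codon range on the coding strand
    if gene.strand == "+":
        first = call.pos - gene.cds_start
        last = min(hi, gene.cds_end) - gene.cds_start
    else:
        first = gene.cds_end - min(hi, gene.cds_end)
        last = gene.cds_end - call.pos
    codon_lo = (first // 3) * 3
    codon_hi = (last // 3) * 3 + 3
    ref_codons = ref_cds[codon_lo:codon_hi]
    alt_codons = alt_cds[codon_lo:codon_hi]
    if any(b not in "ACGTacgt" for b in ref_codons + alt_codons):
        raise UnclassifiableVariant(
            f"ambiguous base in codon at {call.chrom}:{call.pos}"
        )
    ref_aa = str(Seq(ref_codons).translate())
    alt_aa = str(Seq(alt_codons).translate())
    if "*" in alt_aa and "*" not in ref_aa:
        return CodingEffect.NONSENSE
    if alt_aa == ref_aa:
        return CodingEffect.SYNONYMOUS
    return CodingEffect.NONSYNONYMOUS


def annotate_variants(
    calls: Sequence[VariantCall],
    genes: Sequence[GeneModel],
    genome: Mapping[str, str] | None = None,
    promoter_bp: int = PROMOTER_BP,
    terminator_bp: int = TERMINATOR_BP,
) -> list[MutationRecord]:
    """Annotate filtered calls to MutationRecords.

    Each call gets the precedence-resolved region; ORF calls additionally get
    a coding effect (which requires ``genome``).  The reported gene is the
    lexicographically first gene carrying the resolved region class, keeping
    output deterministic when windows of two genes overlap.  Calls whose
    codon cannot be translated are excluded.  Output is sorted by
    (chrom, pos, alt).
    """
    records: list[MutationRecord] = []
    gene_by_name = {g.gene: g for g in genes}
    for call in sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt)):
        hits = annotate_region(call, genes, promoter_bp, terminator_bp)
        region = resolve_region_precedence(hits)
        candidates = sorted(g for g, r in hits if r is region and g is not None)
        gene_name = candidates[0] if candidates else None
        if region is RegionClass.ORF and gene_name is not None:
            if genome is None:
                raise ValueError("genome sequence required to classify ORF calls")
            try:
                effect = classify_coding_effect(call, gene_by_name[gene_name], genome)
            except UnclassifiableVariant:
                continue
        else:
            effect = CodingEffect.NONCODING
        records.append(
            MutationRecord(
                variant=call,
                gene=gene_name,
                region=region,
                effect=effect,
                is_lof=effect in LOF_EFFECTS,
            )
        )
    return records


# ---------------------------------------------------------------------------
# rates and cross-population set statistics


def fixed_mutation_rate(
    n_mutations: int, genome_size: int, generations: float
) -> float:
    """Fixed mutation rate in mutations per nucleotide per replication cycle.

    "Fixed" means at >= 50% population frequency; averaging across replicate
    populations is the arithmetic mean of per-population rates.
    """
    if genome_size <= 0 or generations <= 0:
        raise ValueError("genome_size and generations must be positive")
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    return n_mutations / (genome_size * generations)


def genotype_specific_mutations(
    mutations_by_strain: Mapping[str, set[str]],
    group: Mapping[str, str],
) -> dict[str, set[str]]:
    """Genes mutated in one strain and in no other strain of its group.

    ``group`` maps strain -> experimental group label (e.g. 'non-mutator' /
    'mutator'); every strain must be assigned.
    """
    missing = set(mutations_by_strain) - set(group)
    if missing:
        raise ValueError(f"strains without group assignment: {sorted(missing)}")
    out: dict[str, set[str]] = {}
    for strain, genes in mutations_by_strain.items():
        others: set[str] = set()
        for other, other_genes in mutations_by_strain.items():
            if other != strain and group[other] == group[strain]:
                others |= other_genes
        out[strain] = set(genes) - others
    return out


def parallel_evolution(
    mutations_by_population: Mapping[tuple[str, int], set[str]],
) -> tuple[dict[str, set[str]], set[str]]:
    """Parallel-evolution gene sets.

    Returns ``(within_genotype, across_all)``: per strain, the genes mutated
    in at least two of its replicate populations; and the genes mutated in at
    least two populations over all strains and replicates.
    """
    if not mutations_by_population:
        raise ValueError("at least one population required")
    per_strain: dict[str, list[set[str]]] = {}
    for (strain, _rep), genes in mutations_by_population.items():
        per_strain.setdefault(strain, []).append(set(genes))
    within: dict[str, set[str]] = {}
    for strain, sets in per_strain.items():
        counts: dict[str, int] = {}
        for s in sets:
            for g in s:
                counts[g] = counts.get(g, 0) + 1
        shared = {g for g, n in counts.items() if n >= 2}
        if shared:
            within[strain] = shared
    counts_all: dict[str, int] = {}
    for genes in mutations_by_population.values():
        for g in set(genes):
            counts_all[g] = counts_all.get(g, 0) + 1
    across = {g for g, n in counts_all.items() if n >= 2}
    return within, across


# ---------------------------------------------------------------------------
# IO


def read_vcf(path: str | Path, population_id: str | None = None) -> list[VariantCall]:
    """Read variant calls from a VCF (v4.2, plain text or bgzipped).

    Per-allele supporting reads are taken from the sample AD field and total
    depth from DP (fallback: sum of AD).  Multi-allelic sites are split into
    one call per alt allele.
    """
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise ValueError(f"VCF {path} has no sample column")
        sample = samples[0]
        pid = population_id if population_id is not None else sample
        for rec in vf:
            fmt = rec.samples[sample]
            ad = fmt.get("AD")
            dp = fmt.get("DP")
            if ad is None:
                raise ValueError(f"VCF {path} lacks AD at {rec.chrom}:{rec.pos}")
            depth = int(dp) if dp is not None else int(sum(x or 0 for x in ad))
            for i, alt in enumerate(rec.alts or ()):
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        alt_reads=int(ad[i + 1] or 0),
                        depth=depth,
                        population_id=pid,
                    )
                )
    return calls


def read_variants_tsv(path: str | Path, population_id: str = "") -> list[VariantCall]:
    """TSV fallback reader: columns chrom, pos, ref, alt, alt_reads, depth."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    required = ["chrom", "pos", "ref", "alt", "alt_reads", "depth"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"variant TSV {path} lacks columns: {missing}")
    pid_col = df["population_id"] if "population_id" in df.columns else None
    return [
        VariantCall(
            chrom=row.chrom,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            alt_reads=int(row.alt_reads),
            depth=int(row.depth),
            population_id=str(pid_col.iloc[i]) if pid_col is not None else population_id,
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]


def load_gene_models_gff3(path: str | Path) -> list[GeneModel]:
    """Load single-CDS gene models from a GFF3 (gene + CDS features)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        cdss = list(db.children(gene, featuretype="CDS"))
        if not cdss:
            continue
        start = min(c.start for c in cdss)
        end = max(c.end for c in cdss)
        name = gene.attributes.get("Name", [gene.id])[0]
        models.append(
            GeneModel(
                gene=name,
                chrom=gene.seqid,
                strand=gene.strand,
                cds_start=start,
                cds_end=end,
            )
        )
    models.sort(key=lambda g: (g.chrom, g.cds_start))
    return models


def load_genome_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_tr_mask_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Load a tandem-repeat mask BED (0-based half-open, kept half-open)."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start > end:
                raise ValueError(f"malformed BED interval {line!r}")
            out.setdefault(chrom, []).append((start, end))
    return out


def mutation_records_to_frame(records: Sequence[MutationRecord]) -> pd.DataFrame:
    """Flatten MutationRecords to a tidy frame (one row per record)."""
    return pd.DataFrame(
        [
            {
                "population_id": r.variant.population_id,
                "chrom": r.variant.chrom,
                "pos": r.variant.pos,
                "ref": r.variant.ref,
                "alt": r.variant.alt,
                "alt_reads": r.variant.alt_reads,
                "depth": r.variant.depth,
                "frequency": r.variant.frequency,
                "gene": r.gene or "",
                "region": r.region.value,
                "effect": r.effect.value,
                "is_lof": r.is_lof,
            }
            for r in records
        ]
    )
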