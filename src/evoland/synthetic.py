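"""Synthetic study inputs with a ground-truth manifest.

Generates every input the analysis needs — a toy genome with single-CDS
genes (FASTA + GFF3), a tandem-repeat mask (BED), evolved-population variant
tables (VCF), a gene-pair fitness landscape (TSV) and replicate log2-ratio
expression matrices (TSV) — together with a manifest of everything planted,
so filtering, annotation, classification and concordance can be tested for
exact recovery without any external download.

The defaults emulate the study conditions: three replicate populations per
genotype; ~115 mutations per non-mutator population (ca. 100-130 reported)
and ~275 per mutator population (ca. 200-350); promoter:ORF mutation ratios
of 10 (non-mutator) and 8 (mutator) with most mutations in tandem repeats;
113x mean sequencing depth; planted expression effects of +-1.5 log2 units
on a noise SD of 0.2.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .expression import ExpressionMatrix
from .landscape import FitnessLandscape, InteractionRecord, write_landscape
from .variants import CodingEffect, GeneModel, RegionClass, VariantCall

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticGenome",
    "generate_genome",
    "simulate_population_variants",
    "simulate_landscape",
    "simulate_expression",
    "simulate_all",
    "default_genotypes",
]

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")


def default_genotypes() -> list[tuple[str, bool, float]]:
    """Study genotypes as (label, mutator, generations)."""
    return [
        ("wt", False, 200.0),
        ("cog7", False, 200.0),
        ("nup133", False, 200.0),
        ("msh2", True, 350.0),
        ("cog7_msh2", True, 350.0),
        ("nup133_msh2", True, 350.0),
    ]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Rates are expected mutations per population (Poisson means); the region
    weights set the promoter:ORF allocation with the remaining mass going to
    terminators, intergenic space and tandem repeats (where, as in real
    population data, most variants land).  ``noise_free()`` gives the
    deterministic variant/expression regime used for exact-recovery tests.
    """

    seed: int = 0
    n_genes: int = 30
    gene_length_range: tuple[int, int] = (300, 900)  # nt, multiples of 3
    intergenic_gap: int = 1200  # nt; keeps all 500/250-nt windows gene-unique
    tr_length: int = 40
    n_populations: int = 3
    nonmutator_rate: float = 115.0
    mutator_rate: float = 275.0
    nonmutator_promoter_to_orf: float = 10.0
    mutator_promoter_to_orf: float = 8.0
    terminator_weight: float = 1.5
    intergenic_weight: float = 1.5
    tr_weight: float = 14.0
    orf_effect_weights: dict = field(
        default_factory=lambda: {
            "nonsynonymous": 0.5,
            "synonymous": 0.2,
            "nonsense": 0.15,
            "frameshift": 0.15,
        }
    )
    mean_depth: float = 113.0
    subpolymorphic_fraction: float = 0.15
    read_noise: bool = True
    deg_effect: float = 1.5
    deg_fraction: float = 0.1
    noise_sd: float = 0.2
    landscape_fractions: tuple[float, float, float] = (0.125, 0.25, 0.625)
    # fractions of pairs planted to pass the stringent filter, the lenient
    # filter only, or neither
    stringent_fraction: float = 0.25
    lenient_only_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.nonmutator_rate <= 0 or self.mutator_rate <= 0:
            raise ValueError("mutation rates must be positive")
        if abs(sum(self.landscape_fractions) - 1.0) > 1e-9:
            raise ValueError("landscape fractions must sum to 1")
        if not 0 <= self.subpolymorphic_fraction <= 1:
            raise ValueError("subpolymorphic_fraction must be in [0, 1]")

    def noise_free(self) -> "SyntheticConfig":
        """Copy of this config with sampling noise off: every planted variant
        is fully fixed and read counts/expression carry no noise."""
        return dataclasses.replace(
            self, read_noise=False, subpolymorphic_fraction=0.0, noise_sd=0.0
        )

    def rate_for(self, mutator: bool) -> float:
        return self.mutator_rate if mutator else self.nonmutator_rate

    def promoter_ratio_for(self, mutator: bool) -> float:
        return (
            self.mutator_promoter_to_orf if mutator else self.nonmutator_promoter_to_orf
        )


@dataclass
class SyntheticGenome:
    """Toy genome: one chromosome, non-overlapping single-CDS genes on
    alternating strands, TR intervals in free intergenic space."""

    chrom: str
    sequence: str
    genes: list[GeneModel]
    tr_intervals: list[tuple[int, int]]  # 0-based half-open
    region_pools: dict[RegionClass, list[int]]  # 1-based positions

    @property
    def genome(self) -> dict[str, str]:
        return {self.chrom: self.sequence}

    def coding_sequence(self, gene: GeneModel) -> str:
        cds = self.sequence[gene.cds_start - 1 : gene.cds_end]
        if gene.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, len(self.sequence), 70):
                fh.write(self.sequence[i : i + 70] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {self.chrom} 1 {len(self.sequence)}\n")
            for g in self.genes:
                attrs = f"ID=gene:{g.gene};Name={g.gene}"
                fh.write(
                    f"{self.chrom}\tevoland\tgene\t{g.cds_start}\t{g.cds_end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
                fh.write(
                    f"{self.chrom}\tevoland\tCDS\t{g.cds_start}\t{g.cds_end}\t.\t"
                    f"{g.strand}\t0\tID=cds:{g.gene};Parent=gene:{g.gene}\n"
                )

    def write_tr_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, (start, end) in enumerate(self.tr_intervals):
                fh.write(f"{self.chrom}\t{start}\t{end}\tTR{i + 1}\n")


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """Random CDS of ``length`` nt: ATG, internal codons without stops, one
    terminal stop codon."""
    n_internal = length // 3 - 2
    codons = ["ATG"]
    while len(codons) < n_internal + 1:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if codon not in _STOPS:
            codons.append(codon)
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def generate_genome(config: SyntheticConfig, rng: np.random.Generator | None = None) -> SyntheticGenome:
    """Build the toy genome, gene models and TR mask.

    Genes alternate strands (+, -, +, ...), every CDS length is divisible by
    3 and gaps are wide enough that each promoter/terminator window belongs
    to exactly one gene and never overlaps another window class.  One TR
    interval is centred in each gap's window-free zone.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    chrom = "chrI"
    gap = config.intergenic_gap
    if gap < 1000 + config.tr_length + 20:
        raise ValueError(
            "intergenic_gap too small for gene-unique windows plus a TR interval"
        )
    lo, hi = config.gene_length_range
    parts: list[str] = []
    genes: list[GeneModel] = []
    trs: list[tuple[int, int]] = []
    cursor = 0  # 0-based length assembled so far
    leading = gap // 2
    parts.append("".join(rng.choice(list(_BASES), size=leading)))
    cursor += leading
    for i in range(config.n_genes):
        length = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
        strand = "+" if i % 2 == 0 else "-"
        cds = _random_cds(rng, length)
        genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
        start1 = cursor + 1  # 1-based
        parts.append(genomic)
        cursor += length
        genes.append(
            GeneModel(
                gene=f"GENE{i + 1:03d}",
                chrom=chrom,
                strand=strand,
                cds_start=start1,
                cds_end=cursor,
            )
        )
        if i < config.n_genes - 1:
            # TR centred in the gap; the flanking 500-nt windows never reach it
            tr_start0 = cursor + gap // 2 - config.tr_length // 2
            tr = ("AC" * config.tr_length)[: config.tr_length]
            gap_seq = "".join(rng.choice(list(_BASES), size=gap))
            gap_seq = (
                gap_seq[: tr_start0 - cursor]
                + tr
                + gap_seq[tr_start0 - cursor + config.tr_length :]
            )
            parts.append(gap_seq)
            trs.append((tr_start0, tr_start0 + config.tr_length))
            cursor += gap
    trailing = gap // 2
    parts.append("".join(rng.choice(list(_BASES), size=trailing)))
    cursor += trailing
    sequence = "".join(parts)
    assert len(sequence) == cursor

    pools = _region_pools(chrom, sequence, genes, trs, config)
    return SyntheticGenome(
        chrom=chrom,
        sequence=sequence,
        genes=genes,
        tr_intervals=trs,
        region_pools=pools,
    )


def _region_pools(
    chrom: str,
    sequence: str,
    genes: Sequence[GeneModel],
    trs: Sequence[tuple[int, int]],
    config: SyntheticConfig,
) -> dict[RegionClass, list[int]]:
    """1-based position pools per region class, mutually exclusive by the
    genome's spacing construction."""
    n = len(sequence)
    labels = np.full(n + 1, "i", dtype="<U1")  # index 1..n
    labels[0] = ""
    for g in genes:
        labels[g.cds_start : g.cds_end + 1] = "o"
        if g.strand == "+":
            prom = range(max(1, g.cds_start - 500), g.cds_start)
            term = range(g.cds_end + 1, min(n, g.cds_end + 250) + 1)
        else:
            prom = range(g.cds_end + 1, min(n, g.cds_end + 500) + 1)
            term = range(max(1, g.cds_start - 250), g.cds_start)
        for p in prom:
            labels[p] = "p"
        for p in term:
            labels[p] = "t"
    for start0, end0 in trs:
        labels[start0 + 1 : end0 + 1] = "r"
    code = {
        RegionClass.ORF: "o",
        RegionClass.PROMOTER: "p",
        RegionClass.TERMINATOR: "t",
        RegionClass.INTERGENIC: "i",
        RegionClass.TANDEM_REPEAT: "r",
    }
    return {
        region: [int(i) for i in np.nonzero(labels == c)[0]]
        for region, c in code.items()
    }


# ---------------------------------------------------------------------------
# variants


def _complement(base: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}[base]


def _plant_orf_substitution(
    rng: np.random.Generator,
    genome: SyntheticGenome,
    gene: GeneModel,
    target: str,
) -> tuple[int, str, str] | None:
    """Find a single-base substitution in ``gene`` with the requested coding
    effect.  Returns (1-based genome pos, ref base, alt base) or None."""
    cds = genome.coding_sequence(gene)
    n_codons = len(cds) // 3
    order = rng.permutation(n_codons - 2) + 1  # skip start and stop codons
    for ci in order:
        codon = cds[ci * 3 : ci * 3 + 3]
        aa = str(Seq(codon).translate())
        for within in rng.permutation(3):
            for alt in _BASES:
                if alt == codon[within]:
                    continue
                mutated = codon[:within] + alt + codon[within + 1 :]
                new_aa = str(Seq(mutated).translate())
                ok = (
                    (target == "nonsense" and new_aa == "*")
                    or (target == "synonymous" and new_aa == aa)
                    or (target == "nonsynonymous" and new_aa not in (aa, "*"))
                )
                if not ok:
                    continue
                coding_off = int(ci) * 3 + int(within)
                if gene.strand == "+":
                    pos = gene.cds_start + coding_off
                    return pos, codon[within], alt
                pos = gene.cds_end - coding_off
                return pos, _complement(codon[within]), _complement(alt)
    return None


@dataclass
class PlantedVariant:
    population_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    region: str
    gene: str | None
    effect: str
    frequency: float
    alt_reads: int
    depth: int

    @property
    def fixed(self) -> bool:
        """Passes the >= 10 supporting reads and >= 50% frequency filters as
        emitted."""
        return self.alt_reads >= 10 and self.alt_reads / self.depth >= 0.5

    def to_call(self) -> VariantCall:
        return VariantCall(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            alt_reads=self.alt_reads,
            depth=self.depth,
            population_id=self.population_id,
        )


def _sample_frequency(rng: np.random.Generator, config: SyntheticConfig) -> float:
    """Population frequency: fixed variants above 0.5 (Beta-shaped), an
    optional sub-threshold polymorphic fraction below it."""
    if rng.random() < config.subpolymorphic_fraction:
        return float(0.45 * rng.beta(2.0, 2.0))
    if not config.read_noise:
        return 1.0
    return float(0.55 + 0.45 * rng.beta(2.0, 2.0))


def simulate_population_variants(
    config: SyntheticConfig,
    genome: SyntheticGenome,
    population_id: str,
    mutator: bool,
    rng: np.random.Generator,
) -> list[PlantedVariant]:
    """Plant one population's mutations.

    Draws a Poisson count with the genotype's mean, allocates regions with
    the configured promoter:ORF ratio (remaining mass to terminator /
    intergenic / TR), samples population frequencies, and draws read depths
    around ``mean_depth`` with binomial alt counts when read noise is on.
    """
    ratio = config.promoter_ratio_for(mutator)
    regions = [
        RegionClass.ORF,
        RegionClass.PROMOTER,
        RegionClass.TERMINATOR,
        RegionClass.INTERGENIC,
        RegionClass.TANDEM_REPEAT,
    ]
    weights = np.array(
        [1.0, ratio, config.terminator_weight, config.intergenic_weight, config.tr_weight]
    )
    probs = weights / weights.sum()
    n = int(rng.poisson(config.rate_for(mutator)))
    used_spans: list[tuple[int, int]] = []

    def collides(lo: int, hi: int) -> bool:
        return any(not (hi < a or lo > b) for a, b in used_spans)

    def window_owner(pos: int, region: RegionClass) -> str | None:
        for g in genome.genes:
            if g.strand == "+":
                prom = (g.cds_start - 500, g.cds_start - 1)
                term = (g.cds_end + 1, g.cds_end + 250)
            else:
                prom = (g.cds_end + 1, g.cds_end + 500)
                term = (g.cds_start - 250, g.cds_start - 1)
            win = prom if region is RegionClass.PROMOTER else term
            if win[0] <= pos <= win[1]:
                return g.gene
        return None

    effects = list(config.orf_effect_weights)
    effect_p = np.array([config.orf_effect_weights[e] for e in effects])
    effect_p = effect_p / effect_p.sum()

    planted: list[PlantedVariant] = []
    attempts = 0
    while len(planted) < n and attempts < 50 * n + 100:
        attempts += 1
        region = regions[int(rng.choice(len(regions), p=probs))]
        gene_name: str | None = None
        effect = CodingEffect.NONCODING.value
        if region is RegionClass.ORF:
            gene = genome.genes[int(rng.integers(len(genome.genes)))]
            target = effects[int(rng.choice(len(effects), p=effect_p))]
            if target == "frameshift":
                # 1- or 2-base deletion anchored inside the CDS
                del_len = int(rng.integers(1, 3))
                anchor = int(
                    rng.integers(gene.cds_start, gene.cds_end - del_len)
                )
                ref = genome.sequence[anchor - 1 : anchor + del_len]
                found = (anchor, ref, ref[0])
            else:
                found = _plant_orf_substitution(rng, genome, gene, target)
                if found is None:
                    continue
            pos, ref, alt = found
            gene_name = gene.gene
            effect = target
        elif region is RegionClass.TANDEM_REPEAT:
            pool = genome.region_pools[region]
            pos = int(pool[int(rng.integers(len(pool)))])
            # indel inside the repeat, as in real TR variation
            ref = genome.sequence[pos - 1 : pos + 1]
            if len(ref) < 2:
                continue
            alt = ref[0]
        else:
            pool = genome.region_pools[region]
            pos = int(pool[int(rng.integers(len(pool)))])
            ref = genome.sequence[pos - 1]
            alt = str(rng.choice([b for b in _BASES if b != ref]))
            if region in (RegionClass.PROMOTER, RegionClass.TERMINATOR):
                gene_name = window_owner(pos, region)
        lo, hi = pos, pos + len(ref) - 1
        if collides(lo, hi):
            continue
        used_spans.append((lo, hi))

        freq = _sample_frequency(rng, config)
        depth = max(20, int(rng.poisson(config.mean_depth)))
        if config.read_noise:
            alt_reads = int(rng.binomial(depth, freq))
        else:
            alt_reads = int(round(freq * depth))
        planted.append(
            PlantedVariant(
                population_id=population_id,
                chrom=genome.chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                region=region.value,
                gene=gene_name,
                effect=effect,
                frequency=freq,
                alt_reads=alt_reads,
                depth=depth,
            )
        )
    planted.sort(key=lambda v: (v.chrom, v.pos, v.alt))
    return planted


def write_vcf(
    planted: Sequence[PlantedVariant],
    genome: SyntheticGenome,
    path: str | Path,
    population_id: str,
) -> None:
    """Write one population's planted variants as an uncompressed VCF with
    per-sample AD and DP fields."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={genome.chrom},length={len(genome.sequence)}>")
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Read depth per allele">'
    )
    header.add_line(
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">'
    )
    header.add_sample(population_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in planted:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            rec.samples[population_id]["AD"] = (v.depth - v.alt_reads, v.alt_reads)
            rec.samples[population_id]["DP"] = v.depth
            out.write(rec)


# ---------------------------------------------------------------------------
# landscape


def simulate_landscape(
    config: SyntheticConfig,
    genes: Sequence[str],
    backgrounds: Sequence[str],
    rng: np.random.Generator,
) -> tuple[FitnessLandscape, dict[str, dict[str, dict[str, str]]]]:
    """Plant a landscape with known effect classes and filter categories.

    Beneficial/deleterious pairs get |f_double - f_query| at 4-8 standard
    deviations (strictly beyond the 3-SD rule); neutral pairs stay within 2.
    Interaction scores and p-values are planted so configured fractions pass
    the stringent filter, the lenient filter only, or neither.
    """
    frac_ben, frac_del, frac_neu = config.landscape_fractions
    landscape = FitnessLandscape()
    truth: dict[str, dict[str, dict[str, str]]] = {}
    classes = ["beneficial", "deleterious", "neutral"]
    class_p = np.array([frac_ben, frac_del, frac_neu])
    for bg in backgrounds:
        truth[bg.upper()] = {}
        for gene in genes:
            if gene.upper() == bg.upper():
                continue
            cls = classes[int(rng.choice(3, p=class_p))]
            fq = float(rng.uniform(0.7, 1.0))
            fa = float(rng.uniform(0.7, 1.0))
            sd = float(rng.uniform(0.01, 0.03))
            if cls == "beneficial":
                fd = fq + float(rng.uniform(4.0, 8.0)) * sd
            elif cls == "deleterious":
                fd = max(0.0, fq - float(rng.uniform(4.0, 8.0)) * sd)
            else:
                fd = fq + float(rng.uniform(-2.0, 2.0)) * sd
            u = rng.random()
            if u < config.stringent_fraction:
                category = "stringent"
                score = float(rng.choice([1, -1]) * rng.uniform(0.2, 0.5))
                if score < 0:
                    score = min(score, -0.15)
                p_value = float(rng.uniform(0.0, 0.04))
            elif u < config.stringent_fraction + config.lenient_only_fraction:
                category = "lenient"
                score = float(rng.choice([1, -1]) * rng.uniform(0.02, 0.10))
                p_value = float(rng.uniform(0.0, 0.04))
            else:
                category = "none"
                score = float(rng.choice([1, -1]) * rng.uniform(0.02, 0.5))
                p_value = float(rng.uniform(0.1, 1.0))
            landscape.add(
                InteractionRecord(
                    query=bg,
                    array=gene,
                    fitness_query=fq,
                    fitness_array=fa,
                    fitness_double=fd,
                    sd_double=sd,
                    score=score,
                    p_value=p_value,
                )
            )
            truth[bg.upper()][gene.upper()] = {"class": cls, "category": category}
    return landscape, truth


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    config: SyntheticConfig,
    genotypes: Sequence[str],
    genes: Sequence[str],
    rng: np.random.Generator,
    n_replicates: int = 3,
) -> tuple[ExpressionMatrix, dict[str, dict[str, list[str]]]]:
    """Replicate log2-ratio matrices with planted DEGs.

    Baseline ratios are N(0, noise_sd); for each genotype a ``deg_fraction``
    of genes receives an additive effect of magnitude ``deg_effect`` (sign =
    planted direction) in every replicate.  The manifest records gene,
    direction and genotype.
    """
    genes = [g.upper() for g in genes]
    cols = pd.MultiIndex.from_tuples(
        [(g, r + 1) for g in genotypes for r in range(n_replicates)],
        names=["genotype", "replicate"],
    )
    values = rng.normal(0.0, config.noise_sd, size=(len(genes), len(cols)))
    truth: dict[str, dict[str, list[str]]] = {}
    n_degs = int(round(config.deg_fraction * len(genes)))
    for gi, genotype in enumerate(genotypes):
        chosen = rng.choice(len(genes), size=n_degs, replace=False)
        up: list[str] = []
        down: list[str] = []
        for idx in chosen:
            direction = 1.0 if rng.random() < 0.5 else -1.0
            col0 = gi * n_replicates
            values[idx, col0 : col0 + n_replicates] += direction * config.deg_effect
            (up if direction > 0 else down).append(genes[int(idx)])
        truth[genotype] = {"up": sorted(up), "down": sorted(down)}
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols))
    return matrix, truth


# ---------------------------------------------------------------------------
# whole-study bundle


@dataclass
class SyntheticTruth:
    """Ground-truth manifest of one simulated study."""

    variants: dict[str, list[PlantedVariant]]
    landscape_classes: dict[str, dict[str, dict[str, str]]]
    degs: dict[str, dict[str, list[str]]]
    genotypes: list[tuple[str, bool, float]]

    def fixed_variants(self, population_id: str) -> list[PlantedVariant]:
        return [v for v in self.variants[population_id] if v.fixed]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variants": {
                pid: [dataclasses.asdict(v) for v in vs]
                for pid, vs in self.variants.items()
            },
            "landscape_classes": self.landscape_classes,
            "degs": self.degs,
            "genotypes": [list(g) for g in self.genotypes],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            variants={
                pid: [PlantedVariant(**v) for v in vs]
                for pid, vs in payload["variants"].items()
            },
            landscape_classes=payload["landscape_classes"],
            degs=payload["degs"],
            genotypes=[tuple(g) for g in payload["genotypes"]],
        )


@dataclass
class SyntheticStudy:
    """In-memory bundle of all simulated inputs plus the truth manifest."""

    config: SyntheticConfig
    genome: SyntheticGenome
    landscape: FitnessLandscape
    expression: ExpressionMatrix
    truth: SyntheticTruth

    def population_calls(self, population_id: str) -> list[VariantCall]:
        return [v.to_call() for v in self.truth.variants[population_id]]


def simulate_all(
    config: SyntheticConfig,
    out_dir: str | Path | None = None,
    genotypes: Sequence[tuple[str, bool, float]] | None = None,
    backgrounds: Sequence[str] = ("COG7", "NUP133", "MSH2"),
) -> SyntheticStudy:
    """Simulate the whole study; optionally write all files to ``out_dir``.

    Emits genome.fasta, genes.gff3, tr_mask.bed, <population>.vcf per
    population, landscape.tsv, expression.tsv and truth.json.  Identical
    configs give identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    genome = generate_genome(config, rng)
    genotypes = list(genotypes) if genotypes is not None else default_genotypes()
    gene_names = [g.gene for g in genome.genes]
    landscape, landscape_truth = simulate_landscape(
        config, gene_names, list(backgrounds), rng
    )
    variants: dict[str, list[PlantedVariant]] = {}
    for label, mutator, _gens in genotypes:
        for rep in range(1, config.n_populations + 1):
            pid = f"{label}_{rep}"
            variants[pid] = simulate_population_variants(
                config, genome, pid, mutator, rng
            )
    expression, deg_truth = simulate_expression(
        config, [g[0] for g in genotypes], gene_names, rng
    )
    truth = SyntheticTruth(
        variants=variants,
        landscape_classes=landscape_truth,
        degs=deg_truth,
        genotypes=genotypes,
    )
    study = SyntheticStudy(
        config=config,
        genome=genome,
        landscape=landscape,
        expression=expression,
        truth=truth,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        genome.write_fasta(out / "genome.fasta")
        genome.write_gff3(out / "genes.gff3")
        genome.write_tr_bed(out / "tr_mask.bed")
        for pid, planted in variants.items():
            write_vcf(planted, genome, out / f"{pid}.vcf", pid)
        write_landscape(landscape, out / "landscape.tsv")
        expression.to_tsv(out / "expression.tsv")
        truth.to_json(out / "truth.json")
    return study
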