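# Methods

## Scope and data model

`evoland` analyses evolved gene-deletion yeast populations against the
fitness landscape implied by a genetic-interaction dataset. The pipeline
deliberately starts downstream of raw data processing: variant *tables*
(VCF or TSV), post-normalization log2 expression ratios, and a gene-pair
fitness table are the inputs. Read alignment, variant calling, microarray
normalization and GO enrichment are out of scope.

## Interaction score and confidence filters

The interaction score is defined against the multiplicative null,
`ε = f_ab − f_a·f_b`. We use the multiplicative convention — even though
fitness epistasis is often introduced verbally as deviation from an
"additive" expectation — because the stringent thresholds the analysis
relies on (ε > 0.16 or ε < −0.12 at p < 0.05) are defined on the
multiplicative SGA score; mixing an additive score with those thresholds
would be incoherent. The lenient filter is p < 0.05 with the sign of ε.
Thresholds are strict inequalities; a score of exactly 0.16 is not a
stringent positive. By construction every stringent call passes the lenient
filter, and the test suite asserts this nesting property on random records
and whole synthetic landscapes.

## Landscape effect rule

Inactivating the array gene in the query deletion background is called
beneficial/deleterious when `|f_double − f_query| > 3·sd_double`, strictly
— a tie classifies as neutral, the conservative reading of "higher than".
The rule depends only on the fitness difference and the double-mutant SD (a
property test shifts both fitnesses by a constant). Lookups are
directional: the record for (background, target) is used and, when a
dataset carries both orientations of a pair, they are kept distinct, since
the question "what happens if I lose *B* in *aΔ*?" is not symmetric.
Pairs without a record return `unknown` and are excluded from every
downstream tally, never imputed as neutral. `mean_degree` follows the
records-per-gene convention (non-redundant records divided by unique
genes), not the average endpoint degree, matching how network summary
statistics are usually quoted.

## Variant pipeline

Coordinates are 1-based inclusive throughout (VCF/GFF convention); BED
inputs are converted from 0-based half-open on load. Filtering keeps calls
with ≥ 10 supporting reads and ≥ 50% population frequency (both
inclusive); the filter is idempotent and commutes with tandem-repeat
masking, which removes any call whose reference span overlaps a masked
interval by at least one base. Tandem repeats are supplied as a mask file
rather than detected internally, keeping the exclusion explicit and
testable.

Region annotation is strand-aware: the promoter window is the 500 nt 5′ of
the start codon on the coding strand, the terminator the 250 nt 3′ of the
stop codon. Windows are not truncated by neighbouring genes; instead
multi-gene annotations are preserved and a precedence rule
(ORF > promoter > terminator > intergenic) collapses each variant to one
category for tally purposes, on the view that a coding change is the
strongest functional signal. When two genes tie at the resolved class the
lexicographically first gene is reported, keeping output deterministic.

Coding effects translate the affected codon(s) on the coding strand with
the standard nuclear code: substitutions are synonymous / nonsynonymous /
nonsense (a multi-base substitution confined to one codon is translated
jointly); indels are frameshift unless the length change is divisible
by 3. Nonsense and frameshift calls are loss-of-function. Codons containing
ambiguous bases raise and the variant is excluded from annotation output. A
suite oracle re-translates the entire mutated CDS for every planted
substitution and compares protein sequences.

The fixed mutation rate is `n / (genome size × generations)`; per-genotype
averages are arithmetic means of per-population rates.
Genotype-specific genes are those mutated in one strain and no other strain
of the same experimental group (non-mutator vs mutator); parallel evolution
is reported both within genotype (≥ 2 replicates of one strain) and across
all populations (≥ 2 populations, any strain).

## Expression

DEG calling uses the replicate-consistency rule (|log2| ≥ 1 in ≥ 2 of 3
biological replicates) rather than a variance model, matching the study
design the package emulates; missing values never count toward the quorum.
A gene satisfying both direction predicates (possible when `min_replicates`
is lowered) is classified *ambiguous* and excluded from concordance tallies
— the alternative, picking a direction, would fabricate information.
Euclidean distances use complete-pairs deletion for missing values,
preserving the plain sum-of-squares form without imputation; an empty
overlap is an error rather than a zero. The similarity tree is
average-linkage agglomerative clustering with labels sorted before linkage
so ties break deterministically; output is Newick with ultrametric branch
lengths (leaf-to-node height = merge distance / 2). The Pfaffl ratio is
implemented exactly as `E_t^ΔCq_t / E_ref^ΔCq_ref` with efficiencies
constrained to (1, 2.2].

## Concordance statistics

The DEG-direction × predicted-effect table is tested with a two-sided
Fisher exact test using the point-probability definition (sum of
hypergeometric probabilities of margin-consistent tables no more probable
than the observed one), computed via `scipy.stats.fisher_exact`; the test
suite verifies it against an exact rational-arithmetic enumeration oracle
on every 2×2 table with total count ≤ 30. The odds ratio is the sample
odds ratio ad/bc, with infinity encoded explicitly when bc = 0. The
contingency layout is the printed one — rows deleterious/beneficial,
columns down/up — because it uses exactly the published counts; a secondary
construction testing deleterious DEGs against the strain's genome-wide
direction totals is exposed as `fisher_vs_background` and reported
separately when used. No multiple-testing correction is applied across
strains (per-table significance only).

GI-overlap reports use a configurable denominator (the DEG set size by
default) since published percentages do not state theirs; the
hypergeometric null (`overlap_null_expectation`) makes the "no different
from random" comparison explicit instead of asserted.

## Synthetic data generator

The generator's defaults encode the study conditions: three replicate
populations per genotype; Poisson mutation counts with means 115
(non-mutator, ~200 generations) and 275 (mutator, ~350 generations),
inside the reported 100–130 and 200–350 ranges; promoter:ORF allocation
ratios of 10 and 8 with the largest share of mutations in tandem repeats;
sequencing depth Poisson around 113×; alt-read counts binomial in the
planted frequency. Fixed-variant frequencies are drawn from a Beta-shaped
distribution above 0.5 with a configurable sub-threshold polymorphic
fraction (15% by default) — the real frequency spectrum below 50% is
unreported, so this is a modelling choice, not an estimate. Sequencing
noise is binomial read sampling only; there is no base-error model, which
is sufficient to exercise the depth/frequency filters but does not emulate
caller artefacts.

The toy genome places single-CDS genes on alternating strands with 1200-nt
intergenic gaps. Two adjacent promoter windows can face the same gap, so
gaps must exceed 1000 nt for every window to be gene-unique; 1200 nt
guarantees that and leaves a window-free zone where one 40-nt tandem-repeat
interval is centred per gap. CDS lengths are multiples of 3 with no
internal stop codons, so every planted coding substitution has a
well-defined effect. ORF mutations are planted *by construction* to be
synonymous, nonsynonymous, nonsense (weights 0.2/0.5/0.15) or 1–2-nt
frameshift deletions (0.15); landscape classes are planted with
|f_double − f_query| at 4–8 SD for beneficial/deleterious and within 2 SD
for neutral, strictly clear of the 3-SD boundary, so class recovery must be
100%. Planted expression effects are ±1.5 log2 units added to all three
replicates over N(0, 0.2) noise. A `noise_free()` config variant (all
variants fully fixed, zero expression noise) defines the regime where
end-to-end recovery of the truth manifest is exact, and the suite asserts
exactly that.

Everything is generated from one `numpy` Generator seeded by the config:
identical configs give byte-identical files. Emitted files are standard
formats (FASTA, GFF3, BED, VCF with per-sample AD/DP, TSV) and round-trip
through the package's own readers.

What passing on synthetic data does *not* show: performance on real
population sequencing with alignment artefacts, repetitive-region
miscalls, or microarray-specific noise structure; the generator validates
the logic of the pipeline, not the upstream calling.

## Problem sizes and runtime choices

Tests use 6–12-gene genomes (18 populations), 150–200-gene expression
matrices and 10-seed recovery loops; the exhaustive Fisher cross-check
enumerates all 46,375 tables with total ≤ 30. These sizes keep the full
suite under a minute while leaving every statistical check
non-degenerate. The acceptance script uses the same sizes and finishes in
a few seconds.

## Known limitations

* Gene models are single-CDS; introns and multi-exon CDS are not modelled.
* Multi-allelic VCF records are split per alt allele, but multi-nucleotide
  substitutions spanning codon boundaries are classified from the joint
  translation of the affected codon range rather than decomposed.
* The landscape loader expects one record per (query, array) orientation;
  conflicting duplicates are an error rather than averaged.
* DEG percentages depend on an explicit denominator supplied by the caller;
  the package does not guess an array-design gene universe.
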