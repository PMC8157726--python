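# evoland

Does short-term compensatory evolution follow the fitness landscape implied
by a genetic-interaction network? `evoland` is a Python library for testing
that question in gene-deletion yeast populations: it crosses the mutations
and transcriptional changes that accumulate during laboratory evolution with
the fitness predictions of an SGA-style (Synthetic Genetic Array)
interaction dataset, and reports how often the observed changes are the ones
the landscape predicts to be beneficial.

It is aimed at microbial experimental-evolution and systems-biology groups
who have population variant tables, replicate expression ratios and a
gene-pair fitness table, and want the whole concordance analysis — variant
filtering and annotation, loss-of-function calling, DEG calling, contingency
statistics — as tested, composable functions rather than a spreadsheet
pipeline.

## The model and statistics

**Interaction sign.** For a gene pair with single-mutant fitnesses `f_a`,
`f_b` and double-mutant fitness `f_ab` (wild type = 1), the interaction
score is the deviation from the multiplicative expectation,
`ε = f_ab − f_a·f_b`. Calls use two confidence filters on the dataset's
score and p-value: *lenient* (p < 0.05) and *stringent* (p < 0.05 and
ε > 0.16 or ε < −0.12); every stringent call is also a lenient call.

**Landscape effect.** Inactivating gene *B* in the *aΔ* background is
*beneficial* (or *deleterious*) when `|f_ab − f_a| > 3·SD(f_ab)` with the
double mutant fitter (or less fit) than the single mutant; otherwise
*neutral*; *unknown* when the pair has no record.

**Variant pipeline.** Population-scale calls are kept when supported by
≥ 10 reads at ≥ 50% frequency, masked against tandem repeats, assigned to
ORF / promoter (≤ 500 nt upstream of the start codon) / terminator
(≤ 250 nt downstream of the stop codon) / intergenic with precedence
ORF > promoter > terminator, and classified by codon translation
(synonymous / nonsynonymous / nonsense / frameshift / in-frame indel;
nonsense and frameshift are loss-of-function). The *fixed mutation rate* is
mutations per nucleotide per replication cycle.

**Expression.** A gene is differentially expressed when
`|log2(evolved/preadapted)| ≥ 1` in at least two of three biological
replicates, with a direction. Transcriptomes are compared by Euclidean
distance `√Σ(p_i − q_i)²` and clustered with average linkage; RT-qPCR
validation uses the Pfaffl ratio `E_t^ΔCq_t / E_ref^ΔCq_ref`.

**Concordance.** Loss-of-function genes are tallied by predicted effect
class; up/down DEGs are crossed with predicted effects in a 2×2 table
tested with a two-sided Fisher exact test; GI-overlap percentages come with
a hypergeometric null.

A synthetic-study generator (`evoland.synthetic`) emulates the study design
— toy genome with strand-aware windows, per-population VCFs at 113× depth,
a landscape with planted effect classes, replicate expression matrices with
planted DEGs — and records a ground-truth manifest so the entire pipeline
is testable for exact recovery.

## Worked example

```python
from evoland import fisher_exact_2x2, lof_concordance, mean_degree_from_counts
```

Running `python examples/concordance_analysis.py` prints:

```
LoF concordance: {'beneficial': 1, 'deleterious': 2, 'neutral': 5, 'unknown': 0} -> concordant fraction 0.125
cog7Δ: deleterious down/up = 12/45, beneficial down/up = 6/2 -> odds ratio 0.089, two-sided Fisher p = 4.28e-03
msh2Δ: deleterious down/up = 14/68, beneficial down/up = 24/10 -> odds ratio 0.086, two-sided Fisher p = 5.47e-08
```

The first line says that of eight genes inactivated during evolution only
one (12.5%) was predicted beneficial in its background — the landscape
rarely anticipates the observed inactivations, most of which are predicted
neutral. The Fisher lines test the direction of expression changes against
predicted effects: with p < 0.01, genes whose loss would be deleterious are
significantly *under*-represented among down-regulated DEGs, i.e.
expression changes avoid mimicking harmful gene loss.

The other scripts in `examples/` walk through the landscape queries, the
variant pipeline on a simulated population, and DEG calling / clustering.

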