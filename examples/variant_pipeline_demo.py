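"""Filter and annotate a simulated evolved population's variants.

Simulates one synthetic study, runs the read-support/frequency filter, the
tandem-repeat mask and region annotation for every population, and prints
per-region counts, fixed mutation rates and parallel-evolution gene sets.
"""

from collections import Counter

from evoland import (
    SyntheticConfig,
    fixed_mutation_rate,
    parallel_evolution,
    process_population,
    simulate_all,
)

study = simulate_all(SyntheticConfig(seed=1, n_genes=12))
genome = study.genome
trs = {genome.chrom: genome.tr_intervals}

mutated_genes: dict[tuple[str, int], set[str]] = {}
for label, mutator, generations in study.truth.genotypes:
    for rep in (1, 2, 3):
        pid = f"{label}_{rep}"
        result = process_population(
            study.population_calls(pid), genome.genes, genome.genome, trs
        )
        regions = Counter(r.region.value for r in result.records)
        rate = fixed_mutation_rate(
            len(result.records) + len(result.masked), len(genome.sequence), generations
        )
        print(
            f"{pid:14s} kept={len(result.records):3d} TR-masked={len(result.masked):3d} "
            f"low-support={result.removed_low_support:2d} regions={dict(regions)} "
            f"rate={rate:.2e} mut/nuc/rep"
        )
        mutated_genes[(label, rep)] = {
            r.gene for r in result.records if r.gene and r.region.value == "ORF"
        }

within, across = parallel_evolution(mutated_genes)
print("\ngenes mutated in >=2 replicates of one genotype:", within or "none")
print("genes mutated in >=2 populations across all strains:", sorted(across) or "none")
print(
    "  (mutator populations carry more mutations and higher fixed rates, as "
    "expected from the msh2Δ mismatch-repair defect)"
)
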