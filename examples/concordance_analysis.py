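"""Cross evolved changes with the fitness landscape: the headline statistics.

Reproduces the study's three concordance analyses: the loss-of-function
tally against predicted effects, the DEG-direction vs predicted-effect
contingency table with its Fisher exact test (on the published counts), and
the GI-overlap percentage of a DEG set, with its hypergeometric null.
"""

from evoland import (
    ConfidenceFilter,
    FitnessLandscape,
    InteractionRecord,
    call_degs,
    direction_effect_table,
    fisher_exact_2x2,
    gi_overlap,
    lof_concordance,
    overlap_null_expectation,
    simulate_all,
    SyntheticConfig,
)

# -- loss-of-function concordance: the eight inactivation events -----------
classes = {
    "RIM15": "beneficial",
    "WHI2": "neutral", "ACE2": "neutral", "ECM21": "neutral",
    "MEC3": "neutral", "URE2": "neutral",
    "SAP30": "deleterious", "TAH1": "deleterious",
}
landscape = FitnessLandscape()
for gene, cls in classes.items():
    fq, sd = 0.9, 0.01
    fd = {"beneficial": fq + 6 * sd, "deleterious": fq - 6 * sd, "neutral": fq}[cls]
    landscape.add(InteractionRecord("BG1", gene, fq, 0.9, fd, sd, 0.2, 0.01))
report = lof_concordance(classes, "BG1", landscape)
print(
    f"LoF concordance: {report.counts} -> concordant fraction "
    f"{report.concordant_fraction:.3f}"
)
print("  (only 1 of 8 inactivations was predicted beneficial; most are neutral)")

# -- direction vs effect tables: published counts --------------------------
for strain, cells in (("cog7Δ", (12, 45, 6, 2)), ("msh2Δ", (14, 68, 24, 10))):
    res = fisher_exact_2x2(cells)
    print(
        f"{strain}: deleterious down/up = {cells[0]}/{cells[1]}, "
        f"beneficial down/up = {cells[2]}/{cells[3]} -> "
        f"odds ratio {res.odds_ratio:.3f}, two-sided Fisher p = {res.p_value:.2e}"
    )
print("  (p < 0.01: down-regulation of deleterious-to-lose genes is under-represented)")

# -- GI overlap of a DEG set on a synthetic landscape ----------------------
study = simulate_all(SyntheticConfig(seed=2, n_genes=12))
degs = call_degs(study.expression, "cog7", threshold=0.5)
overlap = gi_overlap(
    degs.up | degs.down, "COG7", study.landscape, ConfidenceFilter.STRINGENT
)
print(
    f"\nDEGs interacting with COG7 (stringent): {overlap.overlap}/{overlap.set_size}"
    + (f" = {overlap.percentage:.1f}%" if overlap.percentage is not None else "")
)
null = overlap_null_expectation(
    overlap.set_size, interactor_count=4, universe_size=12, observed=overlap.overlap
)
print(
    f"hypergeometric null: expected {null.expected:.2f}, "
    f"P(X >= observed) = {null.p_upper:.2f}"
)
print("  (a large tail probability means no enrichment beyond chance)")
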