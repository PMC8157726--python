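"""Classify gene-pair interactions and inactivation effects on a landscape.

Builds a tiny SGA-style fitness landscape, applies the lenient/stringent
confidence filters and the three-standard-deviation effect rule, and prints
the network's mean degree.
"""

from evoland import (
    ConfidenceFilter,
    FitnessLandscape,
    InteractionRecord,
    classify_interaction,
    effect_of_inactivation,
    epistasis_score,
    interactors_of,
    mean_degree,
    mean_degree_from_counts,
)

landscape = FitnessLandscape()
for array, fd, score, p in [
    ("RIM15", 0.97, 0.22, 0.003),   # double mutant fitter: beneficial
    ("TAH1", 0.80, -0.20, 0.010),   # double mutant less fit: deleterious
    ("WHI2", 0.895, -0.05, 0.020),  # within 3 SD: neutral, lenient-only call
    ("MEC3", 0.90, 0.30, 0.40),     # not significant: no interaction call
]:
    landscape.add(
        InteractionRecord(
            query="NUP133", array=array, fitness_query=0.9, fitness_array=0.9,
            fitness_double=fd, sd_double=0.01, score=score, p_value=p,
        )
    )

print("epistasis score for (0.9, 0.9, 0.95):", epistasis_score(0.9, 0.9, 0.95))
print("  (> 0 means the double mutant beats the multiplicative expectation)")

for rec in landscape:
    sign_l = classify_interaction(rec, ConfidenceFilter.LENIENT).value
    sign_s = classify_interaction(rec, ConfidenceFilter.STRINGENT).value
    effect = effect_of_inactivation(landscape, "NUP133", rec.array).value
    print(
        f"NUP133 x {rec.array}: lenient={sign_l:8s} stringent={sign_s:8s} "
        f"inactivation effect={effect}"
    )
print("  (effect = predicted fitness impact of losing the gene in nup133Δ)")

stringent = interactors_of(landscape, "NUP133", ConfidenceFilter.STRINGENT)
lenient = interactors_of(landscape, "NUP133", ConfidenceFilter.LENIENT)
print(f"interactors of NUP133: stringent={sorted(stringent)} lenient={sorted(lenient)}")

print("toy landscape mean degree:", mean_degree(landscape))
print(
    "yeast network summary (443,432 records / 5,962 genes):",
    round(mean_degree_from_counts(443_432, 5_962)),
    "interactions per gene on average",
)
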