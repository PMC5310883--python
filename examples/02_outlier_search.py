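"""Recursive Grubbs outlier search across GO levels.

The most interesting term is the one whose average fold change is extreme
relative to the other terms at the same GO level.  The search starts at the
deepest (most specific) annotated level and climbs toward the root until an
outlier appears.
"""

from exprgo import (
    ScenarioSpec,
    compute_enrichment,
    compute_levels,
    find_significant_terms,
    make_scenario,
    propagate,
)

spec = ScenarioSpec(noise_sd=0.1, seed=42)
graph, ann, expr = make_scenario(spec)
table = compute_enrichment(expr, propagate(ann, graph), graph=graph)
levels = compute_levels(graph)

report = find_significant_terms(
    table, graph, levels, "biological_process", alpha=0.05
)
print("levels searched:", report.levels_searched)
print("terms tested per level:", report.n_terms_tested_per_level)
print("outlier found at level:", report.level_found)
for rec in report.outliers:
    print(
        f"  {rec.label} ({graph.terms[rec.label].name}): "
        f"log2 fold {rec.value:.3f}, G = {rec.g_statistic:.3f} > "
        f"critical {rec.critical_value:.3f}, direction {rec.direction}"
    )

print(
    "\nAt the deepest level the planted term's log2 average fold (~2) sits"
    "\nfar outside the near-zero folds of its 8 peers, so the two-sided"
    "\nGrubbs statistic exceeds its critical value at alpha = 0.05 and the"
    "\nsearch stops at the first level it visits. With no planted signal the"
    "\nsearch would report every level down to 1 and level_found = None."
)
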