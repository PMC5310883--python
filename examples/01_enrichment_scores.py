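"""Expression-weighted enrichment scores on a small synthetic transcriptome.

Builds a toy GO DAG (1 root, 3 mid-level terms, 9 specific terms; 20 genes
directly annotated per specific term), simulates an RPKM table for 3 ordered
samples in which one term's genes carry a 4-fold-per-step signal, and prints
the per-term scores and derived fold changes.
"""

from exprgo import (
    ScenarioSpec,
    compute_enrichment,
    compute_levels,
    make_scenario,
    propagate,
)

spec = ScenarioSpec(noise_sd=0.1, seed=42)  # planted term: first deepest term
graph, ann, expr = make_scenario(spec)
ann = propagate(ann, graph)  # true-path rule: ancestors inherit annotations
table = compute_enrichment(expr, ann, graph=graph)
levels = compute_levels(graph)

print(f"{expr.n_genes} genes x {expr.n_samples} samples, {len(table.es)} scored terms\n")
print("term        level  ES_s1    ES_s2    ES_s3    F_avg_lin  F_avg_log2  mono_up")
for term in sorted(table.es.index):
    es = table.es.loc[term]
    print(
        f"{term}  {levels[term]:>5}  "
        + "  ".join(f"{v:7.1f}" for v in es)
        + f"  {table.f_avg_linear[term]:9.3f}  {table.f_avg_log[term]:10.3f}"
        + f"  {bool(table.monotone_up[term])!s:>7}"
    )

print(
    "\nES(t, s) = sum over genes annotated to t of log2(RPKM + 1): a term's"
    "\nscore grows with both how many genes it has and how hard they are"
    "\ntranscribed. The planted term GO:0000005 quadruples its score at each"
    "\nstep (F_avg_lin ~ 4, i.e. ~2 on the log2 scale), every other deepest"
    "\nterm drifts around fold 1; parents inherit their children's genes, so"
    "\nroot and mid-level scores dominate and the root is monotone whenever"
    "\nthe planted signal outweighs the noise."
)
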