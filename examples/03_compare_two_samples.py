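"""Whole-distribution comparison of two samples' GO enrichment.

Per-term statistics (fold changes, outliers) say which single term moved;
the chi-square and Kolmogorov-Smirnov tests ask instead whether the two
samples' overall enrichment-score distributions differ, binning one GO term
as one bin with its score as the bin count.
"""

from exprgo import (
    ScenarioSpec,
    compare_chi2,
    compare_ks,
    compute_enrichment,
    make_scenario,
    propagate,
)

spec = ScenarioSpec(n_samples=2, noise_sd=0.1, seed=42)
graph, ann, expr = make_scenario(spec)
table = compute_enrichment(expr, propagate(ann, graph), graph=graph)

chi2 = compare_chi2(table, "s1", "s2")
ks = compare_ks(table, "s1", "s2")

print(f"bins (terms): {len(chi2.bins)}")
print(f"chi-square: statistic = {chi2.statistic:.3f}, df = {chi2.df}, "
      f"p = {chi2.p_value:.3g}")
for w in chi2.warnings:
    print(f"  warning: {w}")
print(f"KS two-sample: D = {ks.statistic:.3f}, p = {ks.p_value:.3g}")

print(
    "\nThe chi-square test treats the 13 term scores of each sample as"
    "\ncounts in a 2 x 13 homogeneity table; the planted 4-fold shift in one"
    "\nterm (and its ancestors) makes sample s2's score distribution deviate"
    "\nfrom s1's. KS compares the two empirical score distributions instead"
    "\nand is insensitive to the overall score scale; with only 13 terms per"
    "\nsample it is the blunter of the two."
)
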