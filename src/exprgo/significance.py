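"""Outlier detection over GO levels and two-sample enrichment comparison.

The most interesting term in a multi-sample experiment is the one whose
average fold change is extreme relative to its peers.  Peers are the terms
at the same GO level: the search starts at the deepest annotated level (the
most specific terms), applies a two-sided Grubbs outlier test to the log2
average fold changes there, and — if nothing is flagged — ascends to more
general levels until an outlier is found or the level below the root is
reached.

The Grubbs statistic is G = max_i |x_i - mean| / sd with the exact critical
value  ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)),  t the upper alpha/(2n)
quantile of Student's t with n-2 degrees of freedom.  The test is formally a
single-outlier test; sequential (iterative) removal is available as an
option for surfacing several candidates, with the usual caveat that each
extra pass spends a further ~alpha of type-I probability.

Two whole-sample comparisons are provided: a chi-square homogeneity test
with one bin per GO term (the term's enrichment score used directly as the
bin count) and a two-sample Kolmogorov-Smirnov test on the two per-term
score lists.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .enrichment import EnrichmentTable
from .errors import DegenerateDataError, DomainError
from .ontology import OntologyGraph, TermLevels, resolve_namespace

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OutlierRecord:
    """One flagged value from a Grubbs test."""

    label: str
    value: float
    g_statistic: float
    critical_value: float
    direction: str  # 'up' | 'down'
    iteration_index: int


@dataclass
class OutlierReport:
    """Result of the recursive Grubbs search through GO levels."""

    namespace: str
    alpha: float
    levels_searched: list[int] = field(default_factory=list)
    level_found: int | None = None
    outliers: list[OutlierRecord] = field(default_factory=list)
    n_terms_tested_per_level: dict[int, int] = field(default_factory=dict)
    skipped_levels: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "namespace": self.namespace,
            "alpha": self.alpha,
            "levels_searched": self.levels_searched,
            "level_found": self.level_found,
            "n_terms_tested_per_level": {
                str(k): v for k, v in sorted(self.n_terms_tested_per_level.items())
            },
            "skipped_levels": self.skipped_levels,
            "outliers": [
                {
                    "term_id": r.label,
                    "f_avg_log": r.value,
                    "g_statistic": r.g_statistic,
                    "critical_value": r.critical_value,
                    "direction": r.direction,
                    "iteration_index": r.iteration_index,
                }
                for r in self.outliers
            ],
        }


@dataclass
class ComparisonReport:
    """Two-sample comparison of binned enrichment scores."""

    test: str  # 'chi_square' | 'kolmogorov_smirnov'
    statistic: float
    df: int | None
    p_value: float
    bins: list[str]
    sample_a: str
    sample_b: str
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "sample_a": self.sample_a,
            "sample_b": self.sample_b,
            "n_bins": len(self.bins),
            "bins": self.bins,
            "warnings": self.warnings,
        }


# ---------------------------------------------------------------------------
# Grubbs test
# ---------------------------------------------------------------------------


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value for sample size ``n`` at ``alpha``."""
    if n < 3:
        raise DomainError("Grubbs undefined below 3 observations")
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(
    values: Sequence[float],
    alpha: float = 0.05,
    iterative: bool = False,
    labels: Sequence[str] | None = None,
) -> list[OutlierRecord]:
    """Two-sided Grubbs outlier test.

    Flags the most extreme value when G = max|x - mean|/sd exceeds the
    critical value; values tied at the maximum deviation are flagged in the
    same iteration.  With ``iterative=True`` flagged values are removed and
    the test repeats on the remainder until nothing is flagged or fewer than
    3 observations remain.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise DomainError("grubbs_test expects a 1-D sequence")
    if not np.isfinite(x).all():
        raise DomainError("grubbs_test requires finite values")
    if x.size < 3:
        raise DomainError("Grubbs undefined below 3 observations")
    labs = [str(i) for i in range(x.size)] if labels is None else [str(l) for l in labels]
    if len(labs) != x.size:
        raise DomainError("labels must match values in length")

    remaining = np.arange(x.size)
    records: list[OutlierRecord] = []
    iteration = 0
    while remaining.size >= 3:
        sub = x[remaining]
        mean = sub.mean()
        sd = sub.std(ddof=1)
        if sd == 0.0:
            if iteration == 0:
                raise DegenerateDataError(
                    "zero standard deviation: Grubbs statistic undefined"
                )
            break
        dev = np.abs(sub - mean)
        g = dev.max() / sd
        crit = grubbs_critical(remaining.size, alpha)
        if g <= crit:
            break
        tied = np.isclose(dev, dev.max(), rtol=0.0, atol=0.0)
        flagged_local = np.flatnonzero(tied)
        for j in flagged_local:
            records.append(
                OutlierRecord(
                    label=labs[remaining[j]],
                    value=float(sub[j]),
                    g_statistic=float(g),
                    critical_value=float(crit),
                    direction="up" if sub[j] > mean else "down",
                    iteration_index=iteration,
                )
            )
        if not iterative:
            break
        remaining = np.delete(remaining, flagged_local)
        iteration += 1
    return records


# ---------------------------------------------------------------------------
# Recursive level search
# ---------------------------------------------------------------------------


def find_significant_terms(
    table: EnrichmentTable,
    graph: OntologyGraph,
    levels: TermLevels,
    namespace: str,
    alpha: float = 0.05,
    iterative: bool = False,
) -> OutlierReport:
    """Grubbs search for outlying average fold changes, deepest level first.

    Enrichment is first examined at the deepest annotated level of the
    namespace; levels offering fewer than 3 included terms (or no spread) are
    recorded as skipped; the search stops at the first level yielding at
    least one outlier or after visiting level 1.
    """
    namespace = resolve_namespace(namespace)
    if table.f_avg_log is None or table.included is None:
        raise DomainError(
            "average fold changes not computed; run stepwise_fold/average_fold first"
        )
    report = OutlierReport(namespace=namespace, alpha=alpha)
    ns_terms = [
        t
        for t in table.es.index
        if t in graph.terms
        and graph.terms[t].namespace == namespace
        and not graph.terms[t].obsolete
        and t in levels.level
    ]
    if not ns_terms:
        logger.warning("no annotated %s terms in the enrichment table", namespace)
        return report
    start = max(levels.level[t] for t in ns_terms)
    by_level: dict[int, list[str]] = {}
    for t in ns_terms:
        if bool(table.included.loc[t]):
            by_level.setdefault(levels.level[t], []).append(t)

    for L in range(start, 0, -1):
        terms_here = sorted(by_level.get(L, []))
        report.levels_searched.append(L)
        report.n_terms_tested_per_level[L] = len(terms_here)
        if len(terms_here) < 3:
            report.skipped_levels.append(L)
            continue
        vals = table.f_avg_log.loc[terms_here].to_numpy(dtype=float)
        if np.std(vals, ddof=1) == 0.0:
            logger.info(
                "%s level %d: all %d average fold changes identical; skipped",
                namespace, L, len(terms_here),
            )
            report.skipped_levels.append(L)
            continue
        outliers = grubbs_test(vals, alpha=alpha, iterative=iterative, labels=terms_here)
        if outliers:
            report.level_found = L
            report.outliers = outliers
            break
    if report.level_found is None:
        logger.info(
            "%s: no outlying term found down to level 1 (levels searched: %s)",
            namespace, report.levels_searched,
        )
    return report


# ---------------------------------------------------------------------------
# Two-sample comparisons
# ---------------------------------------------------------------------------


def _two_sample_scores(
    table: EnrichmentTable,
    sample_a: str,
    sample_b: str,
    term_subset: Iterable[str] | None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    for s in (sample_a, sample_b):
        if s not in table.es.columns:
            raise DomainError(f"sample {s!r} not in enrichment table")
    subset = sorted(set(term_subset)) if term_subset is not None else list(table.es.index)
    missing = [t for t in subset if t not in table.es.index]
    if missing:
        raise DomainError(f"terms absent from enrichment table: {missing[:5]}")
    a = table.es.loc[subset, sample_a].to_numpy(dtype=float)
    b = table.es.loc[subset, sample_b].to_numpy(dtype=float)
    return a, b, [str(t) for t in subset]


def compare_chi2(
    table: EnrichmentTable,
    sample_a: str,
    sample_b: str,
    term_subset: Iterable[str] | None = None,
) -> ComparisonReport:
    """Chi-square homogeneity test on term-binned enrichment scores.

    One GO term is one bin and the (real-valued) enrichment score is used
    directly as the bin count, so the statistic scales with the overall
    score magnitude; bins with expected value below 5 trigger a warning.
    Terms scoring zero in both samples are dropped (they contribute no
    information and would produce zero expected counts).
    """
    a, b, bins = _two_sample_scores(table, sample_a, sample_b, term_subset)
    warnings: list[str] = []
    keep = (a + b) > 0
    if (~keep).any():
        warnings.append(f"{int((~keep).sum())} bins with zero score in both samples dropped")
        a, b = a[keep], b[keep]
        bins = [t for t, k in zip(bins, keep) if k]
    if len(bins) < 2:
        raise DomainError("chi-square comparison needs at least 2 non-empty bins")
    if a.sum() == 0 or b.sum() == 0:
        raise DomainError("zero total enrichment score in one sample")
    observed = np.vstack([a, b])
    statistic, p_value, df, expected = stats.chi2_contingency(observed, correction=False)
    n_small = int((expected < 5).sum())
    if n_small:
        warnings.append(
            f"{n_small} of {expected.size} expected bin counts below 5; "
            f"chi-square approximation may be poor"
        )
    for w in warnings:
        logger.warning("chi2 %s vs %s: %s", sample_a, sample_b, w)
    return ComparisonReport(
        test="chi_square",
        statistic=float(statistic),
        df=int(df),
        p_value=float(p_value),
        bins=bins,
        sample_a=str(sample_a),
        sample_b=str(sample_b),
        warnings=warnings,
    )


def compare_ks(
    table: EnrichmentTable,
    sample_a: str,
    sample_b: str,
    term_subset: Iterable[str] | None = None,
) -> ComparisonReport:
    """Two-sample Kolmogorov-Smirnov test on the per-term score lists.

    Each sample's scores over the term subset form one empirical
    distribution; D = sup |ECDF_a - ECDF_b| with the asymptotic p-value.
    The per-term pairing is preserved only in the report's bin listing.
    """
    a, b, bins = _two_sample_scores(table, sample_a, sample_b, term_subset)
    if len(bins) < 2:
        raise DomainError("KS comparison needs at least 2 terms")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return ComparisonReport(
        test="kolmogorov_smirnov",
        statistic=float(res.statistic),
        df=None,
        p_value=float(min(res.pvalue, 1.0)),
        bins=bins,
        sample_a=str(sample_a),
        sample_b=str(sample_b),
    )
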