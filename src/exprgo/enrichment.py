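"""Expression-weighted GO enrichment scores and cross-sample statistics.

The core statistic is the per-term, per-sample enrichment score

    ES(t, s) = sum_i  log2(e(i, s) + 1) * I(i, t)        (abundance mode)
    ES(t, s) = sum_i  log2(2**e(i, s) + 1) * I(i, t)     (log-fold-change mode)

where e(i, s) is the expression of gene i in sample s (RPKM/FPKM in
abundance mode, microarray log2 fold change otherwise) and I(i, t) indicates
annotation of gene i by term t.  Every expressed gene contributes — a gene
does not need to pass a differential-expression cut-off to influence a term,
and weakly expressed genes act cumulatively.

From the scores follow, per term t over the K ordered samples:

* stepwise fold changes  F(t, s) = ES(t, s+1) / ES(t, s),
* the average fold change, either as the geometric mean
  F(t) = (prod_s F(t, s)) ** (1/(K-1)) or as its log2 form
  (1/(K-1)) * sum_s log2 F(t, s) — the two are exp2-related and telescope to
  (ES(t, K) / ES(t, 1)) ** (1/(K-1)),
* enrichment proportions EP(t, s) = ES(t, s) / sum_t' ES(t', s), which sum
  to 1 per sample over the term set used,
* monotone-pattern flags (non-decreasing / non-increasing across samples).

Sample order is experiment order and is preserved end-to-end: the average
fold change is deliberately sensitive to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .ontology import AnnotationSet, OntologyGraph

logger = logging.getLogger(__name__)

MODES = ("abundance", "log_fold_change")

_LN2 = np.log(2.0)


@dataclass
class ExpressionMatrix:
    """Genes x ordered samples with a mode flag.

    ``data`` is indexed by gene id with one column per sample, in experiment
    order.  In abundance mode all values must be finite and non-negative
    (RPKM/FPKM); in log_fold_change mode values must be finite but may be
    negative.
    """

    data: pd.DataFrame
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise DomainError(f"unknown expression mode: {self.mode!r} (use one of {MODES})")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValidationError(
                f"duplicated gene_id in expression matrix: {list(dupes[:5])}"
            )
        try:
            values = self.data.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric expression values: {exc}") from exc
        if self.data.shape[1] < 1:
            raise ValidationError("expression matrix needs at least one sample column")
        bad = ~np.isfinite(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite expression value for gene {self.data.index[i]!r} "
                f"in sample {self.data.columns[j]!r}"
            )
        if self.mode == "abundance" and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance for gene {self.data.index[i]!r} in sample "
                f"{self.data.columns[j]!r}: {values[i, j]} (abundance mode "
                f"requires values >= 0)"
            )
        self.data = self.data.astype(float)

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def sample_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def log_scores(self) -> pd.DataFrame:
        """Per-gene contribution to ES before the annotation indicator.

        abundance: log2(e + 1); log_fold_change: log2(2**e + 1).  Both are
        strictly increasing in e; in log-fold-change mode a zero-change gene
        still contributes one unit.
        """
        v = self.data.to_numpy()
        if self.mode == "abundance":
            scores = np.log1p(v) / _LN2
        else:
            scores = np.logaddexp2(v, 0.0)
        return pd.DataFrame(scores, index=self.data.index, columns=self.data.columns)


@dataclass
class EnrichmentTable:
    """Per-term, per-sample enrichment scores and derived statistics.

    Terms with a zero score in any sample cannot enter the fold-change
    statistics (division by zero / log of zero); they are flagged
    ``included=False`` and carry NaN in the fold columns rather than a
    manufactured pseudocount value.
    """

    es: pd.DataFrame  # terms x samples
    mode: str
    included: pd.Series | None = None
    f_step: pd.DataFrame | None = None
    f_avg_linear: pd.Series | None = None
    f_avg_log: pd.Series | None = None
    ep: pd.DataFrame | None = None
    monotone_up: pd.Series | None = None
    monotone_down: pd.Series | None = None

    @property
    def term_ids(self) -> list[str]:
        return [str(t) for t in self.es.index]

    @property
    def sample_names(self) -> list[str]:
        return [str(c) for c in self.es.columns]

    @property
    def n_samples(self) -> int:
        return self.es.shape[1]


def enrichment_scores(
    expr: ExpressionMatrix,
    ann: AnnotationSet,
    terms: Iterable[str] | None = None,
    propagated: bool = True,
    graph: OntologyGraph | None = None,
) -> EnrichmentTable:
    """Compute ES(t, s) for the requested terms.

    ``terms`` defaults to every annotated term; when a ``graph`` is supplied
    requested terms must exist in it.  Genes present in the annotations but
    absent from the expression matrix contribute nothing; expressed genes
    without annotation are counted and logged but never scored.
    """
    index = ann.term_to_genes(propagated=propagated)
    term_list = sorted(set(terms)) if terms is not None else sorted(index)
    if not term_list:
        raise DomainError("empty term set: nothing to score")
    if graph is not None:
        missing = [t for t in term_list if t not in graph]
        if missing:
            raise DomainError(f"requested terms absent from ontology: {missing[:5]}")

    contrib = expr.log_scores()
    values = contrib.to_numpy()
    gene_pos = {g: i for i, g in enumerate(expr.genes)}
    es = np.zeros((len(term_list), expr.n_samples))
    for row, term in enumerate(term_list):
        idx = [gene_pos[g] for g in index.get(term, ()) if g in gene_pos]
        if idx:
            es[row] = values[np.array(idx, dtype=int)].sum(axis=0)

    annotated_genes = set().union(*index.values()) if index else set()
    n_unannotated = sum(1 for g in expr.genes if g not in annotated_genes)
    if n_unannotated:
        logger.info(
            "%d of %d expressed genes carry no annotation and contribute to "
            "no term", n_unannotated, expr.n_genes,
        )
    return EnrichmentTable(
        es=pd.DataFrame(es, index=pd.Index(term_list, name="term_id"),
                        columns=expr.data.columns),
        mode=expr.mode,
    )


def stepwise_fold(table: EnrichmentTable) -> EnrichmentTable:
    """Fill consecutive-sample fold changes F(t, s) = ES(t, s+1)/ES(t, s).

    Terms with any zero ES are marked ``included=False``; no division is
    performed for them and their fold entries stay NaN.
    """
    if table.n_samples < 2:
        raise DomainError("stepwise fold changes need at least 2 samples")
    es = table.es.to_numpy()
    included = (es > 0).all(axis=1)
    n_excluded = int((~included).sum())
    if n_excluded:
        logger.info(
            "%d of %d terms have a zero enrichment score in some sample and "
            "are excluded from fold statistics", n_excluded, es.shape[0],
        )
    ratios = np.full((es.shape[0], es.shape[1] - 1), np.nan)
    np.divide(es[:, 1:], es[:, :-1], out=ratios, where=included[:, None])
    cols = [
        f"{a}->{b}" for a, b in zip(table.sample_names[:-1], table.sample_names[1:])
    ]
    table.included = pd.Series(included, index=table.es.index, name="included")
    table.f_step = pd.DataFrame(ratios, index=table.es.index, columns=cols)
    return table


def average_fold(table: EnrichmentTable) -> EnrichmentTable:
    """Fill the average fold change, linear (geometric mean) and log2 forms.

    For included terms the geometric mean telescopes:
    F(t) = (ES(t, K)/ES(t, 1)) ** (1/(K-1)); excluded terms carry NaN, never
    a silent zero.
    """
    if table.f_step is None or table.included is None:
        stepwise_fold(table)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.log2(table.f_step.to_numpy())
    f_avg_log = np.where(table.included.to_numpy(), logs.mean(axis=1), np.nan)
    table.f_avg_log = pd.Series(f_avg_log, index=table.es.index, name="f_avg_log")
    table.f_avg_linear = pd.Series(
        np.exp2(f_avg_log), index=table.es.index, name="f_avg_linear"
    )
    return table


def enrichment_proportions(
    table: EnrichmentTable, term_subset: Iterable[str] | None = None
) -> pd.DataFrame:
    """EP(t, s) = ES(t, s) / sum over the subset of ES in sample s.

    Columns sum to 1 over the subset used.  Raises :class:`DomainError` when
    a sample's total score over the subset is zero (no proportion defined).
    The result is also stored on ``table.ep`` (rows = subset terms).
    """
    subset = sorted(set(term_subset)) if term_subset is not None else list(table.es.index)
    if not subset:
        raise DomainError("empty term subset: no proportions defined")
    missing = [t for t in subset if t not in table.es.index]
    if missing:
        raise DomainError(f"terms absent from enrichment table: {missing[:5]}")
    block = table.es.loc[subset]
    totals = block.sum(axis=0)
    zero = totals[totals == 0]
    if not zero.empty:
        raise DomainError(
            f"total enrichment score is zero in sample {zero.index[0]!r}; "
            f"proportions undefined"
        )
    ep = block / totals
    table.ep = ep
    return ep


def monotone_patterns(table: EnrichmentTable) -> EnrichmentTable:
    """Flag terms whose ES never decreases (up) / never increases (down).

    The comparison is non-strict, so a constant row satisfies both flags.
    """
    if table.n_samples < 2:
        raise DomainError("monotone patterns need at least 2 samples")
    es = table.es.to_numpy()
    diff = np.diff(es, axis=1)
    table.monotone_up = pd.Series(
        (diff >= 0).all(axis=1), index=table.es.index, name="monotone_up"
    )
    table.monotone_down = pd.Series(
        (diff <= 0).all(axis=1), index=table.es.index, name="monotone_down"
    )
    return table


def compute_enrichment(
    expr: ExpressionMatrix,
    ann: AnnotationSet,
    terms: Iterable[str] | None = None,
    propagated: bool = True,
    graph: OntologyGraph | None = None,
) -> EnrichmentTable:
    """Scores plus all derived statistics in one call.

    Fold changes and patterns require K >= 2 samples; with a single sample
    only the scores and proportions are filled.
    """
    table = enrichment_scores(expr, ann, terms=terms, propagated=propagated, graph=graph)
    if table.n_samples >= 2:
        stepwise_fold(table)
        average_fold(table)
        monotone_patterns(table)
    try:
        enrichment_proportions(table)
    except DomainError as exc:
        logger.warning("enrichment proportions skipped: %s", exc)
    return table
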