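"""End-to-end pipeline: read inputs, score, search, compare, write reports.

Outputs are deterministic: rows are sorted by (level descending, |log2
average fold| descending, term id) and every number is serialised with 12
significant digits, so reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .enrichment import (
    EnrichmentTable,
    ExpressionMatrix,
    average_fold,
    enrichment_proportions,
    enrichment_scores,
    monotone_patterns,
    stepwise_fold,
)
from .errors import DomainError, ParseError, ValidationError
from .ontology import (
    DEFAULT_RELATIONS,
    AnnotationSet,
    OntologyGraph,
    TermLevels,
    compute_levels,
    load_annotations,
    parse_obo,
    propagate,
    resolve_namespace,
    terms_at_level,
)
from .significance import (
    ComparisonReport,
    OutlierReport,
    compare_chi2,
    compare_ks,
    find_significant_terms,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("enrich", "outliers", "compare")


@dataclass
class RunConfig:
    """Everything one pipeline run needs, recorded in the output manifest."""

    obo_path: Path
    annotation_path: Path
    expression_path: Path
    output_dir: Path
    annotation_format: str = "tsv"
    mode: str = "abundance"
    namespaces: tuple[str, ...] = (
        "biological_process",
        "molecular_function",
        "cellular_component",
    )
    alpha: float = 0.05
    relations: frozenset[str] = DEFAULT_RELATIONS
    propagate: bool = True
    iterative_grubbs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise DomainError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not self.namespaces:
            raise DomainError("at least one namespace must be selected")
        self.namespaces = tuple(resolve_namespace(ns) for ns in self.namespaces)
        for attr in ("obo_path", "annotation_path", "expression_path", "output_dir"):
            setattr(self, attr, Path(getattr(self, attr)))
        self.relations = frozenset(self.relations)


@dataclass
class NamespaceResult:
    table: EnrichmentTable
    ep_by_level: pd.DataFrame | None = None
    outliers: OutlierReport | None = None
    chi2: ComparisonReport | None = None
    ks: ComparisonReport | None = None


@dataclass
class PipelineResult:
    config: RunConfig
    graph: OntologyGraph
    levels: TermLevels
    annotations: AnnotationSet
    expression: ExpressionMatrix
    per_namespace: dict[str, NamespaceResult] = field(default_factory=dict)
    written: list[Path] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Expression TSV reader
# ---------------------------------------------------------------------------


def read_expression_tsv(path: str | Path, mode: str) -> ExpressionMatrix:
    """Read the expression dialect: tab-separated, first column gene ids,
    one numeric column per sample in experiment order, ``#`` comments
    ignored.  The mode is never inferred from the data.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"expression file not found: {path}")
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", index_col=0, dtype=str,
            skip_blank_lines=True,
        )
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValidationError(
            f"{path}: found {df.shape[1]} sample column(s); at least 2 ordered "
            f"samples are required for fold-change analysis"
        )
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.lower() != "nan")
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: non-numeric value {df.loc[gene, col]!r} for gene "
                f"{gene!r} in sample column {col!r}"
            )
        numeric[col] = converted
    matrix = ExpressionMatrix(data=numeric, mode=mode)
    logger.info(
        "expression matrix: %d genes x %d samples (%s); per-sample means: %s",
        matrix.n_genes, matrix.n_samples, mode,
        ", ".join(f"{c}={numeric[c].mean():.4g}" for c in numeric.columns),
    )
    return matrix


# ---------------------------------------------------------------------------
# Serialisation helpers
# ---------------------------------------------------------------------------


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, (bool, np.bool_)):
        return "true" if x else "false"
    if isinstance(x, (float, np.floating)):
        if math.isnan(x):
            return "NA"
        return f"{float(x):.12g}"
    return str(x)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, frozenset):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _header(config: RunConfig) -> str:
    return f"# exprgo v{__version__} seed={config.seed}"


def _sorted_terms(table: EnrichmentTable, levels: TermLevels) -> list[str]:
    def key(t: str):
        lv = levels.level.get(t, -1)
        fa = table.f_avg_log.loc[t] if table.f_avg_log is not None else float("nan")
        mag = -abs(fa) if fa is not None and not math.isnan(fa) else math.inf
        return (-lv, mag, t)

    return sorted((str(t) for t in table.es.index), key=key)


def write_enrichment_tsv(
    result: NamespaceResult,
    graph: OntologyGraph,
    levels: TermLevels,
    config: RunConfig,
    path: Path,
) -> None:
    table = result.table
    samples = table.sample_names
    cols = ["namespace", "level", "term_id", "term_name", "included"]
    cols += [f"ES_{s}" for s in samples]
    if table.f_step is not None:
        cols += [f"F_{c}" for c in table.f_step.columns]
        cols += ["F_avg_linear", "F_avg_log2"]
    cols += [f"EP_{s}" for s in samples]
    if table.monotone_up is not None:
        cols += ["monotone_up", "monotone_down"]

    lines = [_header(config), "\t".join(cols)]
    ep = result.ep_by_level
    for t in _sorted_terms(table, levels):
        term = graph.terms[t]
        row = [
            term.namespace or "NA",
            _fmt(levels.level.get(t)),
            t,
            term.name,
            _fmt(bool(table.included.loc[t]) if table.included is not None else None),
        ]
        row += [_fmt(table.es.loc[t, s]) for s in table.es.columns]
        if table.f_step is not None:
            row += [_fmt(v) for v in table.f_step.loc[t]]
            row += [_fmt(table.f_avg_linear.loc[t]), _fmt(table.f_avg_log.loc[t])]
        for s in table.es.columns:
            row.append(_fmt(ep.loc[t, s]) if ep is not None and t in ep.index else "NA")
        if table.monotone_up is not None:
            row += [_fmt(bool(table.monotone_up.loc[t])),
                    _fmt(bool(table.monotone_down.loc[t]))]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_outlier_tsv(
    report: OutlierReport,
    table: EnrichmentTable,
    graph: OntologyGraph,
    levels: TermLevels,
    config: RunConfig,
    path: Path,
) -> None:
    cols = [
        "namespace", "level", "term_id", "term_name", "F_avg_log2",
        "F_avg_linear", "G_statistic", "critical_value", "direction",
        "iteration",
    ]
    lines = [_header(config), "\t".join(cols)]
    for rec in report.outliers:
        t = rec.label
        lines.append("\t".join([
            report.namespace,
            _fmt(levels.level.get(t)),
            t,
            graph.terms[t].name if t in graph.terms else "NA",
            _fmt(rec.value),
            _fmt(table.f_avg_linear.loc[t] if table.f_avg_linear is not None else None),
            _fmt(rec.g_statistic),
            _fmt(rec.critical_value),
            rec.direction,
            str(rec.iteration_index),
        ]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_json(payload: dict, config: RunConfig, path: Path) -> None:
    payload = {"tool": "exprgo", "version": __version__, "seed": config.seed, **payload}
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _ep_by_level(
    table: EnrichmentTable, graph: OntologyGraph, levels: TermLevels, namespace: str
) -> pd.DataFrame | None:
    """Enrichment proportions normalised within each GO level.

    A level pie chart answers "which of the equally specific terms dominates
    this sample", so proportions are taken over the terms of one level at a
    time.  Levels whose total score is zero in some sample are skipped with
    a log message.
    """
    blocks = []
    present = set(map(str, table.es.index))
    for L in range(levels.max_level[namespace], -1, -1):
        terms_here = sorted(terms_at_level(graph, levels, namespace, L) & present)
        if not terms_here:
            continue
        try:
            blocks.append(enrichment_proportions(table, terms_here))
        except DomainError as exc:
            logger.info("EP skipped at %s level %d: %s", namespace, L, exc)
    if not blocks:
        return None
    ep = pd.concat(blocks)
    table.ep = ep
    return ep


def run_pipeline(
    config: RunConfig, stages: Iterable[str] = ALL_STAGES
) -> PipelineResult:
    """Run the requested stages for every selected namespace.

    * ``enrich``: ES, stepwise and average fold changes, per-level
      enrichment proportions, monotone flags.
    * ``outliers``: recursive Grubbs search from the deepest level.
    * ``compare``: chi-square and KS comparison — emitted only when the
      expression matrix holds exactly two samples.

    All reports are written to ``config.output_dir`` as TSV and JSON plus a
    run manifest; partially written outputs are removed on failure.
    """
    stages = set(stages)
    unknown = stages - set(ALL_STAGES)
    if unknown:
        raise DomainError(f"unknown pipeline stages: {sorted(unknown)}")

    graph = parse_obo(config.obo_path)
    ann = load_annotations(config.annotation_path, config.annotation_format, graph)
    if config.propagate:
        ann = propagate(ann, graph, config.relations)
    use_propagated = config.propagate
    annotated_terms = set()
    for ts in ann.annotations(propagated=use_propagated).values():
        annotated_terms |= ts
    levels = compute_levels(graph, config.relations, annotated=annotated_terms)
    expr = read_expression_tsv(config.expression_path, config.mode)

    result = PipelineResult(
        config=config, graph=graph, levels=levels, annotations=ann, expression=expr
    )
    term_index = ann.term_to_genes(propagated=use_propagated)
    two_samples = expr.n_samples == 2
    if "compare" in stages and not two_samples:
        logger.info(
            "comparison reports skipped: they are defined for exactly 2 "
            "samples, input has %d", expr.n_samples,
        )

    for ns in config.namespaces:
        ns_terms = {
            t for t in term_index
            if t in graph.terms
            and graph.terms[t].namespace == ns
            and not graph.terms[t].obsolete
            and t in levels.level
        }
        if not ns_terms:
            logger.info("namespace %s: no annotated terms; skipped", ns)
            continue
        table = enrichment_scores(expr, ann, ns_terms, propagated=use_propagated)
        stepwise_fold(table)
        average_fold(table)
        monotone_patterns(table)
        ns_result = NamespaceResult(table=table)
        ns_result.ep_by_level = _ep_by_level(table, graph, levels, ns)
        if "outliers" in stages:
            ns_result.outliers = find_significant_terms(
                table, graph, levels, ns,
                alpha=config.alpha, iterative=config.iterative_grubbs,
            )
        if "compare" in stages and two_samples:
            a, b = table.sample_names
            ns_result.chi2 = compare_chi2(table, a, b)
            ns_result.ks = compare_ks(table, a, b)
        result.per_namespace[ns] = ns_result

    _write_outputs(result, stages)
    return result


def _write_outputs(result: PipelineResult, stages: set[str]) -> None:
    config = result.config
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        for ns, ns_result in sorted(result.per_namespace.items()):
            base = outdir / f"enrichment_{ns}"
            if "enrich" in stages or "outliers" in stages or "compare" in stages:
                p = base.with_suffix(".tsv")
                write_enrichment_tsv(ns_result, result.graph, result.levels, config, p)
                written.append(p)
            if ns_result.outliers is not None:
                p = outdir / f"outliers_{ns}.tsv"
                write_outlier_tsv(
                    ns_result.outliers, ns_result.table, result.graph,
                    result.levels, config, p,
                )
                written.append(p)
                p = outdir / f"outliers_{ns}.json"
                _write_json(ns_result.outliers.to_dict(), config, p)
                written.append(p)
            for rep in (ns_result.chi2, ns_result.ks):
                if rep is not None:
                    p = outdir / f"comparison_{rep.test}_{ns}.json"
                    _write_json(rep.to_dict(), config, p)
                    written.append(p)
        manifest = {
            "config": {
                **{k: v for k, v in dataclasses.asdict(config).items()},
            },
            "inputs": {
                str(p): _sha256(p)
                for p in (config.obo_path, config.annotation_path,
                          config.expression_path)
            },
            "n_genes": result.expression.n_genes,
            "n_samples": result.expression.n_samples,
            "namespaces_analysed": sorted(result.per_namespace),
        }
        p = outdir / "manifest.json"
        _write_json(manifest, config, p)
        written.append(p)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    result.written = written
    logger.info("wrote %d report files to %s", len(written), outdir)
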