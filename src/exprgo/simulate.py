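"""Deterministic toy ontologies and expression matrices with planted signal.

The generator emulates the structure of a whole-transcriptome study: a
gene x ordered-sample table of RPKM-like abundances (log-normal baseline,
median ~10, wide dynamic range) annotated against a small layered GO-style
DAG.  One deepest-level term can carry a *planted* multiplicative signal:
the log2(e+1) contribution of each of its genes is scaled by ``planted_fold``
at every consecutive-sample step, so the term's enrichment score grows
geometrically and its theoretical average fold change equals
``planted_fold`` exactly in the noiseless limit — ground truth is closed
form.  All randomness is derived from a single seed; the same seed yields
byte-identical serialisations.

The written files (OBO, two-column annotation TSV, expression TSV) are the
same formats the main pipeline consumes, so synthetic and real data follow
identical code paths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import ExpressionMatrix
from .errors import DomainError
from .ontology import AnnotationSet, OntologyGraph, Term, write_obo

logger = logging.getLogger(__name__)

NAMESPACE = "biological_process"


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic scenario.

    ``n_terms_per_level`` counts terms per level starting at the root
    (element 0 must be 1); the deepest entry defines the most specific
    level, whose terms each directly annotate ``genes_per_term`` distinct
    genes.  ``planted_term`` may be a term accession, ``"auto"`` (the first
    deepest-level term) or ``None`` (null scenario).  ``noise_sd`` is the
    standard deviation of Gaussian noise added to log2(e+1) at each
    consecutive-sample step, i.e. multiplicative noise on e+1.
    """

    n_terms_per_level: tuple[int, ...] = (1, 3, 9)
    n_genes: int = 200
    genes_per_term: int = 20
    n_samples: int = 3
    baseline_median: float = 10.0  # median RPKM of the log-normal baseline
    baseline_sigma: float = 1.5  # sd of ln(e) in the baseline draw
    planted_term: str | None = "auto"
    planted_fold: float = 4.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_terms_per_level) < 2:
            raise DomainError("scenario depth must be at least 2 levels")
        if self.n_terms_per_level[0] != 1:
            raise DomainError("level 0 must hold exactly the root term")
        if any(n < 1 for n in self.n_terms_per_level):
            raise DomainError("every level needs at least one term")
        if self.genes_per_term < 1:
            raise DomainError("genes_per_term must be >= 1")
        needed = self.n_terms_per_level[-1] * self.genes_per_term
        if self.n_genes < needed:
            raise DomainError(
                f"infeasible scenario: {needed} annotated genes requested but "
                f"n_genes={self.n_genes}"
            )
        if self.n_samples < 2:
            raise DomainError("need at least 2 samples for fold changes")
        if self.planted_fold <= 0:
            raise DomainError("planted_fold must be positive")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")

    @property
    def depth(self) -> int:
        """Number of levels including the root (deepest level = depth - 1)."""
        return len(self.n_terms_per_level)

    @property
    def sample_names(self) -> list[str]:
        return [f"s{i + 1}" for i in range(self.n_samples)]


def _term_id(i: int) -> str:
    return f"GO:{i:07d}"


def _gene_id(i: int) -> str:
    return f"g{i + 1:05d}"


def make_toy_ontology(spec: ScenarioSpec) -> tuple[OntologyGraph, AnnotationSet]:
    """Layered single-namespace DAG plus direct deepest-level annotations.

    Each non-root term takes one ``is_a`` parent from the level above and,
    with some probability, a second ``part_of`` parent — so both default
    relations are exercised while the layered construction keeps every
    term's shortest-path level equal to its layer index.
    """
    rng = np.random.default_rng([spec.seed, 0])
    terms: dict[str, Term] = {}
    layers: list[list[str]] = []
    counter = 1
    for L, n_here in enumerate(spec.n_terms_per_level):
        layer_ids = [_term_id(counter + j) for j in range(n_here)]
        counter += n_here
        for k, tid in enumerate(layer_ids):
            if L == 0:
                parents: dict[str, frozenset[str]] = {}
                name = "toy root process"
            else:
                prev = layers[L - 1]
                primary = prev[int(rng.integers(len(prev)))]
                parents = {"is_a": frozenset({primary})}
                if len(prev) >= 2 and rng.random() < 0.3:
                    others = [p for p in prev if p != primary]
                    extra = others[int(rng.integers(len(others)))]
                    parents["part_of"] = frozenset({extra})
                name = f"toy process level {L} term {k + 1}"
            terms[tid] = Term(
                term_id=tid, name=name, namespace=NAMESPACE, parents=parents
            )
        layers.append(layer_ids)

    direct: dict[str, set[str]] = {}
    gene_cursor = 0
    for tid in layers[-1]:
        for _ in range(spec.genes_per_term):
            direct.setdefault(_gene_id(gene_cursor), set()).add(tid)
            gene_cursor += 1
    graph = OntologyGraph(terms=terms)
    ann = AnnotationSet(direct={g: frozenset(t) for g, t in direct.items()})
    return graph, ann


def resolve_planted_term(spec: ScenarioSpec, graph: OntologyGraph) -> str | None:
    """Concrete accession of the planted term ('auto' -> first deepest term)."""
    if spec.planted_term is None:
        return None
    if spec.planted_term == "auto":
        first_deepest = 1 + sum(spec.n_terms_per_level[:-1]) + 1
        return _term_id(first_deepest - 1)
    if spec.planted_term not in graph:
        raise DomainError(f"planted term {spec.planted_term} not in toy ontology")
    return spec.planted_term


def make_expression(spec: ScenarioSpec, ann: AnnotationSet) -> ExpressionMatrix:
    """Abundance matrix with the planted geometric signal.

    Baseline abundances are log-normal (median ``baseline_median``, ln-sd
    ``baseline_sigma``).  Working in y = log2(e+1) space, each step applies
    y -> planted_fold * y for the planted term's genes (identity for the
    rest) plus N(0, noise_sd) noise; negative abundances arising from noise
    are clipped at 0 with a logged count.
    """
    rng = np.random.default_rng([spec.seed, 1])
    genes = [_gene_id(i) for i in range(spec.n_genes)]
    baseline = rng.lognormal(
        mean=math.log(spec.baseline_median), sigma=spec.baseline_sigma,
        size=spec.n_genes,
    )
    y = np.empty((spec.n_genes, spec.n_samples))
    y[:, 0] = np.log1p(baseline) / math.log(2.0)

    planted_genes: set[str] = set()
    if spec.planted_term is not None:
        # the planted term must be resolvable from annotations alone
        annotated_terms = set().union(*ann.direct.values()) if ann.direct else set()
        if spec.planted_term == "auto":
            target = sorted(annotated_terms)[0] if annotated_terms else None
        else:
            target = spec.planted_term
        if target is None or target not in annotated_terms:
            raise DomainError(f"planted term {target!r} has no annotated genes")
        planted_genes = {g for g, ts in ann.direct.items() if target in ts}
    planted_mask = np.array([g in planted_genes for g in genes])

    for s in range(1, spec.n_samples):
        y[:, s] = y[:, s - 1]
        y[planted_mask, s] *= spec.planted_fold
        if spec.noise_sd > 0:
            y[:, s] += rng.normal(0.0, spec.noise_sd, spec.n_genes)

    e = np.exp2(y) - 1.0
    n_clipped = int((e < 0).sum())
    if n_clipped:
        logger.info("clipped %d negative abundances at 0", n_clipped)
        e = np.clip(e, 0.0, None)
    data = pd.DataFrame(e, index=pd.Index(genes, name="gene_id"),
                        columns=spec.sample_names)
    return ExpressionMatrix(data=data, mode="abundance")


def make_scenario(spec: ScenarioSpec) -> tuple[OntologyGraph, AnnotationSet, ExpressionMatrix]:
    """Ontology, annotations and expression for one spec (one-stop helper)."""
    graph, ann = make_toy_ontology(spec)
    expr = make_expression(spec, ann)
    return graph, ann, expr


def write_scenario(spec: ScenarioSpec, outdir: str | Path) -> dict[str, Path]:
    """Write toy.obo, annotations.tsv and expression.tsv under ``outdir``.

    Serialisation is fully deterministic: the same spec produces
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph, ann, expr = make_scenario(spec)

    obo_path = outdir / "toy.obo"
    write_obo(graph, obo_path)

    ann_path = outdir / "annotations.tsv"
    lines = ["gene_id\tgo_id"]
    for gene in sorted(ann.direct):
        for term in sorted(ann.direct[gene]):
            lines.append(f"{gene}\t{term}")
    ann_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    expr_path = outdir / "expression.tsv"
    rows = ["gene_id\t" + "\t".join(expr.sample_names)]
    for gene, row in expr.data.iterrows():
        rows.append(gene + "\t" + "\t".join(f"{v:.12g}" for v in row))
    expr_path.write_text("\n".join(rows) + "\n", encoding="utf-8")

    logger.info(
        "scenario written to %s (%d terms, %d genes, %d samples)",
        outdir, len(graph), expr.n_genes, expr.n_samples,
    )
    return {"obo": obo_path, "annotations": ann_path, "expression": expr_path}
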