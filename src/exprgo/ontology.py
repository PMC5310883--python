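"""Gene Ontology handling: OBO parsing, term levels, annotation propagation.

The GO DAG is held per namespace (biological_process, molecular_function,
cellular_component); cross-namespace edges are ignored and each namespace is
analysed independently.  A term's *level* is the length of the shortest
directed path from the term to its namespace root over a configurable set of
relations (``is_a`` and ``part_of`` by default), with the root at level 0.
The deepest ("last") level therefore holds the most specific terms, which is
where the outlier search starts.

Annotations follow the true-path rule when propagated: a gene annotated to a
term is implicitly annotated to every ancestor of that term within the same
namespace.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .errors import DomainError, IntegrityError, OboParseError, ParseError

logger = logging.getLogger(__name__)

GO_ID_RE = re.compile(r"GO:\d{7}")

#: Relations used for both level computation and propagation by default.
#: ``regulates``-type relations are deliberately excluded, matching common
#: GO-browser practice.
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})

NAMESPACES = (
    "biological_process",
    "molecular_function",
    "cellular_component",
)

#: Short aliases accepted wherever a namespace is requested.
NAMESPACE_ALIASES = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
}


def resolve_namespace(name: str) -> str:
    ns = NAMESPACE_ALIASES.get(name.upper(), name)
    if ns not in NAMESPACES:
        raise DomainError(f"unknown GO namespace: {name!r}")
    return ns


@dataclass(frozen=True)
class Term:
    """One GO term record."""

    term_id: str
    name: str
    namespace: str | None
    #: relation type -> set of parent accessions (e.g. {"is_a": {...}}).
    parents: Mapping[str, frozenset[str]]
    obsolete: bool = False
    replaced_by: tuple[str, ...] = ()

    def parent_ids(self, relations: Iterable[str] = DEFAULT_RELATIONS) -> frozenset[str]:
        out: set[str] = set()
        for rel in relations:
            out.update(self.parents.get(rel, ()))
        return frozenset(out)


@dataclass
class OntologyGraph:
    """The GO DAG: terms, namespaces, parent relations.

    ``alt_ids`` maps secondary accessions to their canonical term id so that
    annotations written against merged accessions still resolve.
    """

    terms: dict[str, Term]
    alt_ids: dict[str, str] = field(default_factory=dict)
    _dg_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._check_acyclic(("is_a",))

    # -- basic queries ---------------------------------------------------
    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def namespaces(self) -> list[str]:
        seen = {t.namespace for t in self.terms.values() if t.namespace}
        return [ns for ns in NAMESPACES if ns in seen] + sorted(
            ns for ns in seen if ns not in NAMESPACES
        )

    def canonical(self, accession: str) -> str | None:
        """Resolve an accession (primary or alt_id) to its canonical term id."""
        if accession in self.terms:
            return accession
        return self.alt_ids.get(accession)

    def terms_in_namespace(
        self, namespace: str, include_obsolete: bool = False
    ) -> set[str]:
        namespace = resolve_namespace(namespace)
        return {
            t.term_id
            for t in self.terms.values()
            if t.namespace == namespace and (include_obsolete or not t.obsolete)
        }

    # -- graph views -----------------------------------------------------
    def parent_digraph(
        self, namespace: str, relations: Iterable[str] = DEFAULT_RELATIONS
    ) -> nx.DiGraph:
        """Child -> parent digraph restricted to one namespace.

        Obsolete terms and cross-namespace edges are dropped.  The result is
        cached per (namespace, relations).
        """
        namespace = resolve_namespace(namespace)
        key = (namespace, frozenset(relations))
        if key in self._dg_cache:
            return self._dg_cache[key]
        nodes = self.terms_in_namespace(namespace)
        dg = nx.DiGraph()
        dg.add_nodes_from(nodes)
        for tid in nodes:
            for pid in self.terms[tid].parent_ids(relations):
                if pid in nodes:  # same-namespace, non-obsolete parents only
                    dg.add_edge(tid, pid)
        self._dg_cache[key] = dg
        return dg

    def ancestors(
        self, term_id: str, relations: Iterable[str] = DEFAULT_RELATIONS
    ) -> set[str]:
        """All ancestors of ``term_id`` within its namespace (excl. itself)."""
        term = self.terms[term_id]
        if term.obsolete or term.namespace is None:
            return set()
        dg = self.parent_digraph(term.namespace, relations)
        if term_id not in dg:
            return set()
        # edges point child -> parent, so graph-descendants are GO-ancestors
        return set(nx.descendants(dg, term_id))

    def parent_edges(
        self, namespace: str, relations: Iterable[str] = DEFAULT_RELATIONS
    ) -> list[tuple[str, str]]:
        """(child, parent) pairs of the namespace-restricted DAG."""
        return list(self.parent_digraph(namespace, relations).edges())

    def _check_acyclic(self, relations: Iterable[str]) -> None:
        dg = nx.DiGraph()
        for term in self.terms.values():
            for pid in term.parent_ids(relations):
                dg.add_edge(term.term_id, pid)
        if dg.number_of_edges() and not nx.is_directed_acyclic_graph(dg):
            cycle = nx.find_cycle(dg)
            raise IntegrityError(
                f"cycle detected in {'/'.join(sorted(relations))} closure: {cycle}"
            )


@dataclass
class TermLevels:
    """Shortest-path distance of each term from its namespace root."""

    level: dict[str, int]
    max_level: dict[str, int]
    roots: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, term_id: str) -> int:
        return self.level[term_id]


@dataclass
class AnnotationSet:
    """Gene -> GO term incidence, direct and (optionally) propagated.

    This realises the indicator I(i, t): gene *i* is annotated by term *t*
    iff *t* is in the gene's (propagated) term set.
    """

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]] | None = None
    load_stats: dict = field(default_factory=dict)
    _index_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def annotations(self, propagated: bool = True) -> dict[str, frozenset[str]]:
        if propagated:
            if self.propagated is None:
                raise DomainError(
                    "annotations have not been propagated; call propagate() "
                    "or request propagated=False"
                )
            return self.propagated
        return self.direct

    def term_to_genes(self, propagated: bool = True) -> dict[str, frozenset[str]]:
        """Invert the gene->terms map (cached)."""
        key = bool(propagated)
        if key not in self._index_cache:
            index: dict[str, set[str]] = defaultdict(set)
            for gene, terms in self.annotations(propagated).items():
                for t in terms:
                    index[t].add(gene)
            self._index_cache[key] = {t: frozenset(g) for t, g in index.items()}
        return self._index_cache[key]

    @property
    def genes(self) -> set[str]:
        return set(self.direct)


# ---------------------------------------------------------------------------
# OBO parsing / writing
# ---------------------------------------------------------------------------

_ACCESSION_KEYS = {"id", "alt_id", "is_a", "replaced_by"}


def _validate_obo_accessions(path: Path) -> None:
    """Pre-scan [Term] stanzas so malformed accessions are reported by line."""
    stanza = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("!", 1)[0].strip()
            if line.startswith("["):
                stanza = line
                continue
            if stanza != "[Term]" or not line or ":" not in line:
                continue
            key, _, val = line.partition(":")
            key = key.strip()
            val = val.split("{", 1)[0].strip()
            acc = None
            if key in _ACCESSION_KEYS:
                acc = val.split()[0] if val else ""
            elif key == "relationship":
                parts = val.split()
                acc = parts[1] if len(parts) >= 2 else ""
            if acc is not None and not GO_ID_RE.fullmatch(acc):
                raise OboParseError(
                    f"{path}: line {lineno}: malformed GO accession {acc!r} "
                    f"in '{key}' clause"
                )


def parse_obo(path: str | Path) -> OntologyGraph:
    """Read an OBO 1.2/1.4 file into an :class:`OntologyGraph`.

    Obsolete terms are kept but flagged (they are excluded from level
    computation and enrichment); alt_id accessions resolve to their canonical
    term.  A cycle in the ``is_a`` closure raises :class:`IntegrityError`.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"OBO file not found: {path}")
    _validate_obo_accessions(path)
    try:
        net = obonet.read_obo(str(path), ignore_obsolete=False)
    except Exception as exc:  # stanza-level failure inside obonet
        raise OboParseError(f"{path}: {exc}") from exc

    default_ns = None
    dns = net.graph.get("default-namespace")
    if dns:
        default_ns = dns[0] if isinstance(dns, list) else dns

    terms: dict[str, Term] = {}
    alt_ids: dict[str, str] = {}
    for node, data in net.nodes(data=True):
        parents: dict[str, set[str]] = defaultdict(set)
        for _, parent, rel in net.out_edges(node, keys=True):
            parents[rel].add(parent)
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        terms[node] = Term(
            term_id=node,
            name=data.get("name", node),
            namespace=data.get("namespace", default_ns),
            parents={rel: frozenset(p) for rel, p in parents.items()},
            obsolete=obsolete,
            replaced_by=tuple(data.get("replaced_by", ())),
        )
        for alt in data.get("alt_id", ()):
            if alt in alt_ids and alt_ids[alt] != node:
                logger.warning("alt_id %s claimed by %s and %s", alt, alt_ids[alt], node)
                continue
            alt_ids[alt] = node
    graph = OntologyGraph(terms=terms, alt_ids=alt_ids)
    logger.info(
        "parsed %s: %d terms (%d obsolete), %d alt_ids",
        path.name,
        len(terms),
        sum(t.obsolete for t in terms.values()),
        len(alt_ids),
    )
    return graph


def write_obo(graph: OntologyGraph, path: str | Path, ontology_name: str = "exprgo-toy") -> None:
    """Serialise a graph back to OBO 1.2 (deterministic term order)."""
    path = Path(path)
    lines = [f"format-version: 1.2", f"ontology: {ontology_name}", ""]
    rev_alt: dict[str, list[str]] = defaultdict(list)
    for alt, canon in graph.alt_ids.items():
        rev_alt[canon].append(alt)
    for tid in sorted(graph.terms):
        t = graph.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {t.term_id}")
        lines.append(f"name: {t.name}")
        if t.namespace:
            lines.append(f"namespace: {t.namespace}")
        for alt in sorted(rev_alt.get(tid, ())):
            lines.append(f"alt_id: {alt}")
        for parent in sorted(t.parents.get("is_a", ())):
            lines.append(f"is_a: {parent}")
        for rel in sorted(t.parents):
            if rel == "is_a":
                continue
            for parent in sorted(t.parents[rel]):
                lines.append(f"relationship: {rel} {parent}")
        if t.obsolete:
            lines.append("is_obsolete: true")
            for rep in t.replaced_by:
                lines.append(f"replaced_by: {rep}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# Levels
# ---------------------------------------------------------------------------


def compute_levels(
    graph: OntologyGraph,
    relations: Iterable[str] = DEFAULT_RELATIONS,
    annotated: set[str] | None = None,
) -> TermLevels:
    """Shortest-path level of every non-obsolete term, per namespace.

    The root of each namespace (the unique term without parents) is level 0;
    every other term's level is ``1 + min(level(parent))``.  ``max_level`` is
    the deepest level per namespace, restricted to ``annotated`` terms when a
    set is given (the outlier search starts from the deepest *annotated*
    level).

    Raises :class:`IntegrityError` for a cyclic relation closure, a namespace
    without exactly one root, or a term with no path to its root.
    """
    relations = frozenset(relations)
    level: dict[str, int] = {}
    max_level: dict[str, int] = {}
    roots: dict[str, str] = {}
    for ns in graph.namespaces:
        dg = graph.parent_digraph(ns, relations)
        if dg.number_of_edges() and not nx.is_directed_acyclic_graph(dg):
            raise IntegrityError(f"cycle in {ns} over relations {sorted(relations)}")
        ns_roots = sorted(n for n in dg.nodes if dg.out_degree(n) == 0)
        if len(ns_roots) != 1:
            raise IntegrityError(
                f"namespace {ns}: expected exactly one root, found "
                f"{len(ns_roots)}: {ns_roots[:5]}"
            )
        root = ns_roots[0]
        roots[ns] = root
        lengths = nx.single_source_shortest_path_length(dg.reverse(copy=False), root)
        missing = sorted(set(dg.nodes) - set(lengths))
        if missing:
            raise IntegrityError(
                f"namespace {ns}: term {missing[0]} has no path to root {root}"
            )
        level.update(lengths)
        pool = set(dg.nodes)
        if annotated is not None:
            restricted = pool & annotated
            if restricted:
                pool = restricted
        max_level[ns] = max(lengths[t] for t in pool)
    return TermLevels(level=level, max_level=max_level, roots=roots)


def terms_at_level(
    graph: OntologyGraph, levels: TermLevels, namespace: str, L: int
) -> set[str]:
    """Non-obsolete terms of ``namespace`` at level exactly ``L``."""
    namespace = resolve_namespace(namespace)
    if namespace not in levels.max_level:
        raise DomainError(f"no levels computed for namespace {namespace}")
    if not 0 <= L <= levels.max_level[namespace]:
        raise DomainError(
            f"level {L} out of range [0, {levels.max_level[namespace]}] "
            f"for {namespace}"
        )
    return {
        t
        for t in graph.terms_in_namespace(namespace)
        if levels.level.get(t) == L
    }


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def _resolve_annotation(graph: OntologyGraph, accession: str) -> tuple[str | None, str]:
    """Map an accession to a usable canonical term.

    Returns (term_id or None, reason) where reason is one of
    'ok', 'remapped', 'unknown', 'obsolete'.
    """
    canon = graph.canonical(accession)
    if canon is None:
        return None, "unknown"
    remapped = canon != accession
    term = graph.terms[canon]
    if term.obsolete:
        for rep in term.replaced_by:
            rep_canon = graph.canonical(rep)
            if rep_canon is not None and not graph.terms[rep_canon].obsolete:
                return rep_canon, "remapped"
        return None, "obsolete"
    return canon, ("remapped" if remapped else "ok")


def _read_tsv_annotations(path: Path) -> list[tuple[str, str, int]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().lower() == "gene_id":
                continue  # optional header
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns "
                    f"(gene_id, go_id), found {len(fields)}"
                )
            rows.append((fields[0].strip(), fields[1].strip(), lineno))
    return rows


def _read_gaf_annotations(
    path: Path, exclude_evidence: frozenset[str]
) -> list[tuple[str, str, int]]:
    rows = []
    n_not = n_evidence = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 15:
                raise ParseError(
                    f"{path}: line {lineno}: GAF rows need >=15 tab-separated "
                    f"columns, found {len(fields)}"
                )
            qualifier = fields[3]
            if "NOT" in qualifier.split("|"):
                n_not += 1
                continue
            if fields[6] in exclude_evidence:
                n_evidence += 1
                continue
            rows.append((fields[1], fields[4], lineno))
    if n_not:
        logger.info("dropped %d GAF rows with NOT qualifier", n_not)
    if n_evidence:
        logger.info("dropped %d GAF rows by evidence-code exclusion", n_evidence)
    return rows


def load_annotations(
    path: str | Path,
    format: str,
    graph: OntologyGraph,
    exclude_evidence: Iterable[str] = (),
) -> AnnotationSet:
    """Read gene -> GO annotations from GAF 2.x or two-column TSV.

    Rows with a NOT qualifier (GAF) are excluded; annotations to accessions
    unknown to the graph are dropped with a warning; annotations to obsolete
    terms are remapped through alt_id/replaced_by where possible.  Genes not
    present in the expression matrix are retained here — filtering happens at
    scoring time.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"annotation file not found: {path}")
    if format == "tsv":
        raw_rows = _read_tsv_annotations(path)
    elif format == "gaf":
        raw_rows = _read_gaf_annotations(path, frozenset(exclude_evidence))
    else:
        raise DomainError(f"unknown annotation format: {format!r} (use 'gaf' or 'tsv')")

    direct: dict[str, set[str]] = defaultdict(set)
    stats = {"rows": len(raw_rows), "unknown": 0, "obsolete": 0, "remapped": 0}
    for gene, accession, lineno in raw_rows:
        term_id, reason = _resolve_annotation(graph, accession)
        if term_id is None:
            stats[reason] += 1
            logger.warning(
                "%s: line %d: dropped annotation %s -> %s (%s term)",
                path.name, lineno, gene, accession, reason,
            )
            continue
        if reason == "remapped":
            stats["remapped"] += 1
        direct[gene].add(term_id)
    logger.info(
        "loaded %d annotation rows for %d genes (%d unknown dropped, "
        "%d obsolete dropped, %d remapped)",
        stats["rows"], len(direct), stats["unknown"], stats["obsolete"],
        stats["remapped"],
    )
    return AnnotationSet(
        direct={g: frozenset(t) for g, t in direct.items()}, load_stats=stats
    )


def propagate(
    ann: AnnotationSet,
    graph: OntologyGraph,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> AnnotationSet:
    """Close annotations over ancestors (true-path rule), per namespace.

    Idempotent: propagating an already propagated set changes nothing.
    """
    relations = frozenset(relations)
    closure_cache: dict[str, frozenset[str]] = {}

    def closure(term_id: str) -> frozenset[str]:
        if term_id not in closure_cache:
            closure_cache[term_id] = frozenset({term_id} | graph.ancestors(term_id, relations))
        return closure_cache[term_id]

    propagated: dict[str, frozenset[str]] = {}
    for gene, terms in ann.direct.items():
        out: set[str] = set()
        for t in terms:
            if t in graph.terms and not graph.terms[t].obsolete:
                out |= closure(t)
            else:
                out.add(t)  # keep terms outside the graph as-is
        propagated[gene] = frozenset(out)
    return AnnotationSet(direct=ann.direct, propagated=propagated, load_stats=ann.load_stats)
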