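import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from exprgo import (
    AnnotationSet,
    EnrichmentTable,
    OntologyGraph,
    ScenarioSpec,
    Term,
    average_fold,
    make_scenario,
    monotone_patterns,
    propagate,
    stepwise_fold,
)

settings.register_profile(
    "exprgo",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("exprgo")


def build_graph(edges, namespace="biological_process", obsolete=(), extra_terms=()):
    """Ontology from (child, parent, relation) triples; ids used verbatim."""
    parents = {}
    nodes = set(extra_terms)
    for child, parent, rel in edges:
        parents.setdefault(child, {}).setdefault(rel, set()).add(parent)
        nodes.update((child, parent))
    terms = {
        tid: Term(
            term_id=tid,
            name=f"name of {tid}",
            namespace=namespace,
            parents={r: frozenset(p) for r, p in parents.get(tid, {}).items()},
            obsolete=tid in obsolete,
        )
        for tid in nodes
    }
    return OntologyGraph(terms=terms)


def chain_graph(n=4):
    """root <- A <- B <- ... is_a chain of n+1 terms, ids GO:000000{1..}."""
    ids = [f"GO:{i:07d}" for i in range(1, n + 2)]
    edges = [(ids[i + 1], ids[i], "is_a") for i in range(n)]
    return build_graph(edges), ids


def table_from_es(es_rows, samples=None):
    """EnrichmentTable with all derived statistics, from raw ES rows."""
    es = pd.DataFrame(es_rows, dtype=float).T if isinstance(es_rows, dict) else None
    if es is None:
        es = pd.DataFrame(np.asarray(es_rows, dtype=float))
        es.index = [f"GO:{i + 1:07d}" for i in range(es.shape[0])]
    if samples is not None:
        es.columns = samples
    else:
        es.columns = [f"s{j + 1}" for j in range(es.shape[1])]
    table = EnrichmentTable(es=es, mode="abundance")
    stepwise_fold(table)
    average_fold(table)
    monotone_patterns(table)
    return table


@pytest.fixture(scope="session")
def noiseless_scenario():
    spec = ScenarioSpec(noise_sd=0.0, seed=11)
    graph, ann, expr = make_scenario(spec)
    return spec, graph, ann, expr


@pytest.fixture(scope="session")
def noisy_scenario():
    spec = ScenarioSpec(noise_sd=0.1, seed=5)
    graph, ann, expr = make_scenario(spec)
    return spec, graph, ann, expr
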