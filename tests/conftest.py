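"""Shared fixtures: tiny hand-built ontologies and synthetic study inputs."""

import numpy as np
import pytest

from pathnet.datasets import Dataset, GeneRecord
from pathnet.fixtures import (
    FixtureSpec,
    build_datasets,
    build_interactions,
    build_ontology,
)
from pathnet.ontology import Ontology, OntologyTerm, propagate_annotations


def make_ontology(edges, genes=None, levels=None):
    """Build an ontology from (parent, child) pairs and per-term gene sets."""
    ont = Ontology()
    ids = set()
    for p, c in edges:
        ids |= {p, c}
    ids |= set(genes or {})
    for tid in sorted(ids):
        ont.add_term(
            OntologyTerm(
                term_id=tid,
                name=tid.lower(),
                level=(levels or {}).get(tid),
                genes=set((genes or {}).get(tid, set())),
            )
        )
    for p, c in edges:
        ont.add_edge(p, c)
    return ont


def make_dataset(name, genes, background=None, **kw):
    return Dataset(
        name=name,
        records=[GeneRecord(symbol=g) for g in sorted(genes)],
        background=set(background) if background is not None else None,
        **kw,
    )


def random_dag_ontology(rng: np.random.Generator, n_terms: int,
                        edge_prob: float = 0.15, gene_pool: int = 60):
    """Random DAG with random direct annotations (acyclic by construction)."""
    ont = Ontology()
    for i in range(n_terms):
        n_genes = int(rng.integers(0, 5))
        picked = rng.choice(gene_pool, size=n_genes, replace=False)
        ont.add_term(
            OntologyTerm(
                term_id=f"T{i:02d}",
                genes={f"G{int(g):02d}" for g in picked},
            )
        )
    for child in range(1, n_terms):
        for parent in range(child):
            if rng.random() < edge_prob:
                ont.add_edge(f"T{parent:02d}", f"T{child:02d}")
    return ont


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def fixture_ontology(fixture_spec):
    ont, leaves = build_ontology(fixture_spec)
    return propagate_annotations(ont), leaves


@pytest.fixture(scope="session")
def fixture_network(fixture_spec, fixture_ontology):
    ont, _ = fixture_ontology
    return build_interactions(fixture_spec, ont)


@pytest.fixture(scope="session")
def fixture_datasets(fixture_spec, fixture_ontology):
    ont, _ = fixture_ontology
    return build_datasets(fixture_spec, ont)
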