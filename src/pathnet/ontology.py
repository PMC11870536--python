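"""Hierarchical ontologies and the weighted SCP-SCP interaction network.

An ontology is a DAG of terms (SCPs, GO terms, ...) with gene annotations.
Parent-child edges come from ``is_a``/``part_of`` relations in OBO files or
from explicit parent columns in the flat tab-delimited dialect; edges of the
GO "regulates" family are kept separately and only surface as optional
regulatory edges in network assembly.  Gene identity is by symbol,
normalized to uppercase.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import obonet

from pathnet.errors import ParameterError, ParseError, StructureError

logger = logging.getLogger(__name__)

#: OBO relations treated as parent-child.
HIERARCHY_RELATIONS = frozenset({"is_a", "part_of"})
#: OBO relations treated as regulatory (kept out of the hierarchy).
REGULATORY_RELATIONS = frozenset(
    {"regulates", "positively_regulates", "negatively_regulates"}
)

MERGED_PREFIX = "MERGED::"


def normalize_symbol(symbol: str) -> str:
    """Uppercase, whitespace-stripped gene symbol."""
    return symbol.strip().upper()


@dataclass
class OntologyTerm:
    """One ontology term (an SCP, a GO term, or a user-defined merged term).

    ``level`` follows the MBCO convention: 1 is the most general level and
    children sit exactly one level below their parents.  GO terms carry no
    level.  ``genes`` holds normalized symbols; after annotation propagation
    it includes every gene annotated to any descendant.
    """

    term_id: str
    name: str = ""
    level: Optional[int] = None
    genes: set[str] = field(default_factory=set)
    parent_ids: set[str] = field(default_factory=set)
    child_ids: set[str] = field(default_factory=set)
    namespace: str = ""

    def copy(self) -> "OntologyTerm":
        return OntologyTerm(
            term_id=self.term_id,
            name=self.name,
            level=self.level,
            genes=set(self.genes),
            parent_ids=set(self.parent_ids),
            child_ids=set(self.child_ids),
            namespace=self.namespace,
        )


class Ontology:
    """A DAG of :class:`OntologyTerm` with symmetric parent/child references."""

    def __init__(self, terms: Optional[Iterable[OntologyTerm]] = None):
        self.terms: dict[str, OntologyTerm] = {}
        #: directed (regulator, regulated) pairs, outside the hierarchy
        self.regulatory_edges: set[tuple[str, str]] = set()
        if terms:
            for t in terms:
                self.add_term(t)

    # -- construction -------------------------------------------------
    def add_term(self, term: OntologyTerm) -> None:
        if term.term_id in self.terms:
            raise StructureError(f"duplicate term id {term.term_id!r}")
        self.terms[term.term_id] = term

    def add_edge(self, parent_id: str, child_id: str) -> None:
        self.terms[parent_id].child_ids.add(child_id)
        self.terms[child_id].parent_ids.add(parent_id)

    # -- queries -------------------------------------------------------
    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def root_ids(self) -> set[str]:
        return {tid for tid, t in self.terms.items() if not t.parent_ids}

    @property
    def annotated_universe(self) -> set[str]:
        universe: set[str] = set()
        for t in self.terms.values():
            universe |= t.genes
        return universe

    def levels(self) -> list[int]:
        """Sorted distinct levels present (empty for level-less ontologies)."""
        return sorted({t.level for t in self.terms.values() if t.level is not None})

    def terms_at_level(self, level: Optional[int]) -> list[OntologyTerm]:
        return [t for t in self.terms.values() if t.level == level]

    def ancestors(self, term_id: str) -> set[str]:
        """All proper ancestors (transitive parents)."""
        seen: set[str] = set()
        stack = list(self.terms[term_id].parent_ids)
        while stack:
            tid = stack.pop()
            if tid not in seen:
                seen.add(tid)
                stack.extend(self.terms[tid].parent_ids)
        return seen

    def descendants(self, term_id: str) -> set[str]:
        """All proper descendants (transitive children)."""
        seen: set[str] = set()
        stack = list(self.terms[term_id].child_ids)
        while stack:
            tid = stack.pop()
            if tid not in seen:
                seen.add(tid)
                stack.extend(self.terms[tid].child_ids)
        return seen

    def to_networkx(self) -> nx.DiGraph:
        """Parent -> child directed graph over all terms."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for c in t.child_ids:
                g.add_edge(t.term_id, c)
        return g

    def validate(self) -> None:
        """Check reference symmetry and acyclicity; raise on violation."""
        for t in self.terms.values():
            for p in t.parent_ids:
                if p not in self.terms:
                    raise StructureError(
                        f"term {t.term_id!r} references unknown parent {p!r}"
                    )
                if t.term_id not in self.terms[p].child_ids:
                    raise StructureError(
                        f"asymmetric edge between {p!r} and {t.term_id!r}"
                    )
            for c in t.child_ids:
                if c not in self.terms:
                    raise StructureError(
                        f"term {t.term_id!r} references unknown child {c!r}"
                    )
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise StructureError(f"hierarchy contains a cycle: {cycle}")

    def copy(self) -> "Ontology":
        out = Ontology()
        for t in self.terms.values():
            out.terms[t.term_id] = t.copy()
        out.regulatory_edges = set(self.regulatory_edges)
        return out


class InteractionNetwork:
    """Weighted undirected term-term edges (functional SCP relatedness).

    Edges are unordered pairs with a finite non-negative weight; self-edges
    and duplicate pairs are rejected.
    """

    def __init__(self, edges: Optional[Iterable[tuple[str, str, float]]] = None):
        self.weights: dict[tuple[str, str], float] = {}
        if edges:
            for a, b, w in edges:
                self.add_edge(a, b, w)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a == b:
            raise ParameterError(f"self-edge on {a!r} not allowed")
        if not math.isfinite(weight) or weight < 0:
            raise ParameterError(f"edge weight must be finite and >= 0, got {weight}")
        key = self._key(a, b)
        if key in self.weights:
            raise ParameterError(f"duplicate edge {key}")
        self.weights[key] = float(weight)

    @property
    def edges(self) -> set[tuple[str, str, float]]:
        return {(a, b, w) for (a, b), w in self.weights.items()}

    def __len__(self) -> int:
        return len(self.weights)

    def has_edge(self, a: str, b: str) -> bool:
        return self._key(a, b) in self.weights

    def subgraph(self, term_ids: set[str]) -> "InteractionNetwork":
        """Edges with both endpoints inside ``term_ids``."""
        out = InteractionNetwork()
        for (a, b), w in self.weights.items():
            if a in term_ids and b in term_ids:
                out.weights[(a, b)] = w
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for (a, b), w in self.weights.items():
            g.add_edge(a, b, weight=w)
        return g

    def validate_against(self, ontology: Ontology) -> None:
        for (a, b) in self.weights:
            for tid in (a, b):
                if tid not in ontology:
                    raise StructureError(
                        f"interaction endpoint {tid!r} is not an ontology term"
                    )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_obo(path: str | Path) -> Ontology:
    """Read an OBO 1.2 file into an :class:`Ontology`.

    ``is_a`` and ``part_of`` become parent edges; "regulates"-family
    relationships are stored in :attr:`Ontology.regulatory_edges`.  Obsolete
    terms are excluded.  Gene sets are empty pending GAF annotation.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"cannot read OBO file: {path}")
    graph = obonet.read_obo(str(path))  # excludes obsolete terms

    ont = Ontology()
    for tid, data in graph.nodes(data=True):
        ont.add_term(
            OntologyTerm(
                term_id=tid,
                name=data.get("name", ""),
                namespace=data.get("namespace", ""),
            )
        )
    # obonet edges point child -> parent, keyed by the relation name
    for child, parent, relation in graph.edges(keys=True):
        if parent not in ont.terms or child not in ont.terms:
            continue
        if relation in HIERARCHY_RELATIONS:
            ont.add_edge(parent, child)
        elif relation in REGULATORY_RELATIONS:
            ont.regulatory_edges.add((child, parent))
    ont.validate()
    return ont


def read_gaf(path: str | Path, ontology: Ontology) -> Ontology:
    """Attach direct GAF 2.x annotations to a loaded ontology.

    Rows with a NOT qualifier are skipped; rows annotating a term absent
    from the ontology are skipped with a logged count.  Returns a new
    ontology; the input is untouched.
    """
    path = Path(path)
    out = ontology.copy()
    n_unknown = 0
    n_attached = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("!") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 17:
                raise ParseError(
                    f"{path}:{lineno}: expected 17 tab-separated columns, "
                    f"got {len(fields)}"
                )
            symbol = normalize_symbol(fields[2])
            qualifier = fields[3]
            go_id = fields[4].strip()
            if "NOT" in qualifier.split("|"):
                continue
            if go_id not in out.terms:
                n_unknown += 1
                continue
            out.terms[go_id].genes.add(symbol)
            n_attached += 1
    if n_unknown:
        logger.info(
            "read_gaf: skipped %d annotation rows to terms absent from the "
            "ontology (%d attached)", n_unknown, n_attached,
        )
    return out


FLAT_COLUMNS = ["term_id", "term_name", "level", "parent_id", "gene_symbol"]
INTERACTION_COLUMNS = ["term_a", "term_b", "weight"]


def read_flat_ontology(
    path: str | Path,
    interactions_path: str | Path | None = None,
) -> tuple[Ontology, Optional[InteractionNetwork]]:
    """Read the generic tab-delimited ontology dialect.

    The file carries one row per (term, parent, gene) combination with the
    headered columns ``term_id  term_name  level  parent_id  gene_symbol``;
    an empty ``parent_id`` marks a root and an empty ``gene_symbol`` adds no
    annotation.  Levels are explicit integers and every child must sit
    exactly one level below its parent.

    A companion interaction table (``term_a  term_b  weight``) is read from
    ``interactions_path`` when given, otherwise from
    ``<stem>_interactions<suffix>`` next to the ontology file when present.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"cannot read flat ontology file: {path}")

    ont = Ontology()
    pending_edges: list[tuple[str, str]] = []  # (parent, child)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != FLAT_COLUMNS:
            raise ParseError(
                f"{path}: expected header {FLAT_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ParseError(
                    f"{path}:{lineno}: expected 5 columns, got {len(fields)}"
                )
            tid, tname, level_s, parent, gene = (f.strip() for f in fields)
            try:
                level = int(level_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: level {level_s!r} is not an int")
            if level < 1:
                raise ParseError(f"{path}:{lineno}: level must be >= 1, got {level}")
            if tid not in ont.terms:
                ont.add_term(OntologyTerm(term_id=tid, name=tname, level=level))
            elif ont.terms[tid].level != level:
                raise StructureError(
                    f"term {tid!r} appears with conflicting levels "
                    f"{ont.terms[tid].level} and {level}"
                )
            if parent:
                pending_edges.append((parent, tid))
            if gene:
                ont.terms[tid].genes.add(normalize_symbol(gene))

    for parent, child in pending_edges:
        if parent not in ont.terms:
            raise StructureError(
                f"term {child!r} references unknown parent {parent!r}"
            )
        p, c = ont.terms[parent], ont.terms[child]
        if c.level != p.level + 1:
            raise StructureError(
                f"level inconsistency: child {child!r} (level {c.level}) under "
                f"parent {parent!r} (level {p.level}); child level must be "
                f"parent level + 1"
            )
        ont.add_edge(parent, child)
    ont.validate()

    if interactions_path is None:
        candidate = path.with_name(path.stem + "_interactions" + path.suffix)
        interactions_path = candidate if candidate.exists() else None
    network = None
    if interactions_path is not None:
        network = read_interactions(interactions_path)
        network.validate_against(ont)
    return ont, network


def read_interactions(path: str | Path) -> InteractionNetwork:
    """Read a ``term_a  term_b  weight`` TSV into an :class:`InteractionNetwork`."""
    path = Path(path)
    net = InteractionNetwork()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != INTERACTION_COLUMNS:
            raise ParseError(
                f"{path}: expected header {INTERACTION_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            a, b, w_s = (f.strip() for f in fields)
            try:
                w = float(w_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: weight {w_s!r} is not a number")
            net.add_edge(a, b, w)
    return net


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def propagate_annotations(ontology: Ontology) -> Ontology:
    """Populate every term with the genes of all its descendants.

    After propagation each term's gene set equals its direct annotations
    union the (propagated) gene sets of its children.  Idempotent; returns
    a new ontology.
    """
    ontology.validate()
    out = ontology.copy()
    g = out.to_networkx()
    # children before parents
    for tid in reversed(list(nx.topological_sort(g))):
        term = out.terms[tid]
        for c in term.child_ids:
            term.genes |= out.terms[c].genes
    return out


def filter_by_size(ontology: Ontology, min_genes: int, max_genes: int) -> Ontology:
    """Drop terms whose propagated gene count lies outside [min, max].

    The hierarchy is re-closed: each surviving term is connected to its
    nearest surviving ancestors (the transitive reduction of the induced
    ancestor relation), so chains broken by a removed middle term stay
    connected.
    """
    if min_genes > max_genes:
        raise ParameterError(
            f"min_genes ({min_genes}) must be <= max_genes ({max_genes})"
        )
    survivors = {
        tid
        for tid, t in ontology.terms.items()
        if min_genes <= len(t.genes) <= max_genes
    }
    anc = {tid: ontology.ancestors(tid) for tid in ontology.terms}

    out = Ontology()
    for tid in survivors:
        t = ontology.terms[tid].copy()
        t.parent_ids = set()
        t.child_ids = set()
        out.add_term(t)
    for tid in survivors:
        candidates = anc[tid] & survivors
        # nearest = candidates not themselves ancestors of another candidate
        nearest = {
            a for a in candidates
            if not any(a in anc[b] for b in candidates if b != a)
        }
        for a in nearest:
            out.add_edge(a, tid)
    out.regulatory_edges = {
        (a, b) for (a, b) in ontology.regulatory_edges
        if a in survivors and b in survivors
    }
    return out


def top_percent_interactions(
    network: InteractionNetwork, percent: float
) -> InteractionNetwork:
    """Keep the top ``percent`` % highest-weight edges, boundary ties included.

    Retains ceil(percent/100 * |edges|) edges plus any further edges tied
    with the weakest retained weight, so the result is order-independent.
    """
    if not (0 < percent <= 100):
        raise ParameterError(f"percent must be in (0, 100], got {percent}")
    if not network.weights:
        raise ParameterError("cannot take top percent of an empty network")
    n_keep = math.ceil(percent / 100.0 * len(network.weights))
    ranked = sorted(network.weights.items(), key=lambda kv: -kv[1])
    threshold = ranked[n_keep - 1][1]
    out = InteractionNetwork()
    for key, w in network.weights.items():
        if w >= threshold:
            out.weights[key] = w
    return out


def merged_scp_id(member_ids: Iterable[str]) -> str:
    """Deterministic id for a merged term: sorted member ids joined by '+'."""
    return MERGED_PREFIX + "+".join(sorted(set(member_ids)))


def define_custom_scp(
    ontology: Ontology, member_ids: list[str], new_name: str
) -> Ontology:
    """Merge existing terms into a new user-defined SCP added to the ontology.

    The merged term's genes are the union of the members' gene sets; the
    members become its children.  When all members carry levels the new term
    sits one level above the shallowest member (floored at level 1).
    """
    members = sorted(set(member_ids))
    if not members:
        raise ParameterError("member list must not be empty")
    for m in members:
        if m not in ontology:
            raise ParameterError(f"unknown member term {m!r}")
    new_id = merged_scp_id(members)
    if new_id in ontology:
        raise StructureError(f"custom SCP {new_id!r} already exists")

    out = ontology.copy()
    genes: set[str] = set()
    levels: list[int] = []
    for m in members:
        genes |= out.terms[m].genes
        if out.terms[m].level is not None:
            levels.append(out.terms[m].level)
    level = max(1, min(levels) - 1) if len(levels) == len(members) else None
    out.add_term(
        OntologyTerm(term_id=new_id, name=new_name, level=level, genes=genes)
    )
    for m in members:
        out.add_edge(new_id, m)
    return out
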