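"""Deterministic synthetic inputs with planted enrichment structure.

The generator emulates the shape of a small MBCO-style study: a 3-level
ontology (1 root, 3 branches, 9 leaf SCPs) over a 2,000-gene universe,
weighted within-level SCP interactions, and gene-list datasets built as a
*planted* fraction of one SCP's genes plus uniform background noise.
Split-signal pairs distribute one shared signal over two interacting SCPs
so that the merged pair — not either member alone — carries the strongest
enrichment, which is exactly the situation dynamic enrichment is built to
detect.

Every output is a plain-text file in the package's own input dialects
(flat ontology TSV, OBO, GAF, interaction TSV, dataset TSVs with
``_bgGenes`` companions) and is byte-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from pathnet.datasets import BG_SUFFIX, Dataset, GeneRecord
from pathnet.errors import ParameterError
from pathnet.ontology import (
    InteractionNetwork,
    Ontology,
    OntologyTerm,
)

NAMESPACE = "synthetic_process"
TIMEPOINTS = ("d1", "d3", "d7")


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study.

    Defaults encode the benchmark conditions used throughout the test
    suite: a 2,000-gene universe, 40-gene leaf SCPs with a 5-gene overlap
    into the next leaf, one planted SCP contributing 80% of its genes to
    each dataset, and a 5% per-gene background noise rate.
    """

    seed: int = 0
    n_levels: int = 3
    branching_factor: int = 3
    genes_per_leaf: int = 40
    leaf_overlap: int = 5
    gene_universe_size: int = 2000
    n_datasets: int = 3
    #: (term_id, fraction of the term's genes inserted into each dataset);
    #: None plants 80% of the first leaf
    planted_terms: Optional[list[tuple[str, float]]] = None
    #: interacting same-level term pairs sharing one split signal
    split_signal_pairs: list[tuple[str, str]] = field(default_factory=list)
    #: fraction of each split-pair member's genes entering each dataset
    split_fraction: float = 0.25
    #: per-gene probability of entering a dataset as noise
    background_fraction: float = 0.05
    interaction_density: float = 0.3
    weight_low: float = 0.0
    weight_high: float = 1.0
    integration_group: str = "group1"

    def __post_init__(self):
        for frac in (self.split_fraction, self.background_fraction):
            if not (0 <= frac <= 1):
                raise ParameterError(f"fractions must lie in [0, 1], got {frac}")
        if self.planted_terms:
            for _, f in self.planted_terms:
                if not (0 <= f <= 1):
                    raise ParameterError(f"planted fraction {f} outside [0, 1]")


def gene_name(i: int) -> str:
    return f"GENE{i:05d}"


def _term_id(index: int) -> str:
    return f"SCP:{index:07d}"


def build_ontology(spec: FixtureSpec) -> tuple[Ontology, list[str]]:
    """The synthetic ontology with direct (unpropagated) annotations.

    A complete ``branching_factor``-ary tree of ``n_levels`` levels.  Leaf
    i gets its own disjoint block of ``genes_per_leaf`` genes plus the
    first ``leaf_overlap`` genes of leaf i+1's block; all genes not
    claimed by a leaf are annotated directly to the root, so the annotated
    universe is exactly ``gene_universe_size`` genes.
    """
    ont = Ontology()
    counter = [0]

    def new_term(level: int) -> OntologyTerm:
        counter[0] += 1
        t = OntologyTerm(
            term_id=_term_id(counter[0]),
            name=f"synthetic process {counter[0]} (level {level})",
            level=level,
            namespace=NAMESPACE,
        )
        ont.add_term(t)
        return t

    frontier = [new_term(1)]
    for level in range(2, spec.n_levels + 1):
        next_frontier = []
        for parent in frontier:
            for _ in range(spec.branching_factor):
                child = new_term(level)
                ont.add_edge(parent.term_id, child.term_id)
                next_frontier.append(child)
        frontier = next_frontier
    leaves = [t.term_id for t in frontier]

    n_leaves = len(leaves)
    needed = n_leaves * spec.genes_per_leaf
    if needed > spec.gene_universe_size:
        raise ParameterError(
            f"universe of {spec.gene_universe_size} genes too small for "
            f"{n_leaves} leaves x {spec.genes_per_leaf} genes"
        )
    for i, leaf in enumerate(leaves):
        block = range(i * spec.genes_per_leaf, (i + 1) * spec.genes_per_leaf)
        genes = {gene_name(g) for g in block}
        nxt = (i + 1) % n_leaves
        overlap = range(
            nxt * spec.genes_per_leaf,
            nxt * spec.genes_per_leaf + spec.leaf_overlap,
        )
        genes |= {gene_name(g) for g in overlap}
        ont.terms[leaf].genes = genes
    root = ont.terms[_term_id(1)]
    root.genes = {gene_name(g) for g in range(needed, spec.gene_universe_size)}
    return ont, leaves


def default_planted(spec: FixtureSpec, leaves: list[str]) -> list[tuple[str, float]]:
    if spec.planted_terms is not None:
        return spec.planted_terms
    return [(leaves[0], 0.8)]


def build_interactions(
    spec: FixtureSpec, ontology: Ontology, rng: Optional[np.random.Generator] = None
) -> InteractionNetwork:
    """Within-level interaction edges at ``interaction_density``.

    Weights are uniform on [weight_low, weight_high); split-signal pairs
    are always present with top-decile weights, so they survive any
    top-percent selection down to 10%.
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    net = InteractionNetwork()
    forced = {tuple(sorted(p)) for p in spec.split_signal_pairs}
    span = spec.weight_high - spec.weight_low
    for level in ontology.levels():
        ids = sorted(t.term_id for t in ontology.terms_at_level(level))
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if (a, b) in forced:
                    w = spec.weight_high - 0.1 * span * float(rng.random())
                    net.add_edge(a, b, w)
                elif float(rng.random()) < spec.interaction_density:
                    w = spec.weight_low + span * float(rng.random())
                    net.add_edge(a, b, w)
    for a, b in forced:
        if not net.has_edge(a, b):
            raise ParameterError(
                f"split pair ({a}, {b}) is not a same-level pair"
            )
    return net


def build_datasets(
    spec: FixtureSpec,
    ontology: Ontology,
    rng: Optional[np.random.Generator] = None,
) -> list[Dataset]:
    """Gene-list datasets with planted enrichment and background noise.

    Each dataset contains the planted fraction of every planted term's
    genes, the split fraction of every split-pair member's genes, and each
    remaining universe gene independently with probability
    ``background_fraction``.  Values are significance-like: planted and
    split genes get values in [1e-6, 1e-3), noise in [1e-4, 0.049), so the
    default max-value cutoff of 0.05 keeps them all.
    """
    rng = rng or np.random.default_rng(spec.seed + 2)
    leaves = sorted(
        tid for tid, t in ontology.terms.items() if not t.child_ids
    )
    planted = default_planted(spec, leaves)
    universe = sorted(
        {g for t in ontology.terms.values() for g in t.genes}
    )
    datasets = []
    for d in range(spec.n_datasets):
        signal: set[str] = set()
        for term_id, frac in planted:
            genes = sorted(ontology.terms[term_id].genes)
            n_pick = int(round(frac * len(genes)))
            picked = rng.choice(len(genes), size=n_pick, replace=False)
            signal |= {genes[i] for i in sorted(picked)}
        for a, b in spec.split_signal_pairs:
            for term_id in (a, b):
                genes = sorted(ontology.terms[term_id].genes)
                n_pick = int(round(spec.split_fraction * len(genes)))
                picked = rng.choice(len(genes), size=n_pick, replace=False)
                signal |= {genes[i] for i in sorted(picked)}
        noise_draw = rng.random(len(universe))
        noise = {
            g for g, u in zip(universe, noise_draw)
            if u < spec.background_fraction and g not in signal
        }
        records = []
        for g in sorted(signal | noise):
            if g in signal:
                value = 1e-6 + (1e-3 - 1e-6) * float(rng.random())
            else:
                value = 1e-4 + (0.049 - 1e-4) * float(rng.random())
            records.append(
                GeneRecord(
                    symbol=g,
                    value=value,
                    timepoint=TIMEPOINTS[d % len(TIMEPOINTS)],
                    direction="up",
                )
            )
        datasets.append(
            Dataset(
                name=f"fixture - DS{d + 1} - up",
                integration_group=spec.integration_group,
                color=f"#{0x1f77b4 + d * 0x202020 & 0xFFFFFF:06x}",
                order_index=d,
                records=records,
                background=set(universe),
            )
        )
    return datasets


# ---------------------------------------------------------------------------
# file writers
# ---------------------------------------------------------------------------

def write_flat_ontology(ontology: Ontology, path: Path) -> Path:
    lines = ["\t".join(["term_id", "term_name", "level", "parent_id",
                        "gene_symbol"])]
    for tid in sorted(ontology.terms):
        t = ontology.terms[tid]
        parents = sorted(t.parent_ids) or [""]
        genes = sorted(t.genes) or [""]
        first = True
        for p in parents:
            for g in genes if first else [""]:
                lines.append("\t".join([tid, t.name, str(t.level), p, g]))
            first = False
    path.write_text("\n".join(lines) + "\n")
    return path


def write_obo(ontology: Ontology, path: Path) -> Path:
    chunks = ["format-version: 1.2", ""]
    for tid in sorted(ontology.terms):
        t = ontology.terms[tid]
        chunks.append("[Term]")
        chunks.append(f"id: {tid}")
        chunks.append(f"name: {t.name}")
        chunks.append(f"namespace: {t.namespace or NAMESPACE}")
        for p in sorted(t.parent_ids):
            chunks.append(f"is_a: {p} ! {ontology.terms[p].name}")
        chunks.append("")
    path.write_text("\n".join(chunks))
    return path


def write_gaf(ontology: Ontology, path: Path) -> Path:
    lines = ["!gaf-version: 2.2"]
    for tid in sorted(ontology.terms):
        for g in sorted(ontology.terms[tid].genes):
            fields = [
                "FIX", g, g, "", tid, "FIX:0000001", "IEA", "", "P",
                "", "", "protein", "taxon:9606", "20250101", "FIX", "", "",
            ]
            lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_interactions(network: InteractionNetwork, path: Path) -> Path:
    lines = ["\t".join(["term_a", "term_b", "weight"])]
    for (a, b) in sorted(network.weights):
        lines.append("\t".join([a, b, repr(network.weights[(a, b)])]))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_dataset_files(datasets: list[Dataset], out_dir: Path) -> list[Path]:
    """One import-dialect TSV plus a ``_bgGenes`` companion per dataset."""
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, ds in enumerate(datasets):
        stem = f"fixture_ds{i:02d}"
        lines = ["\t".join(["gene_symbol", "dataset", "integration_group",
                            "color", "value", "timepoint", "direction"])]
        for r in ds.records:
            lines.append("\t".join([
                r.symbol, ds.name, ds.integration_group, ds.color,
                repr(r.value), r.timepoint or "", r.direction,
            ]))
        fpath = out_dir / f"{stem}.txt"
        fpath.write_text("\n".join(lines) + "\n")
        written.append(fpath)
        if ds.background is not None:
            bpath = out_dir / f"{stem}{BG_SUFFIX}.txt"
            bpath.write_text("\n".join(sorted(ds.background)) + "\n")
            written.append(bpath)
    return written


def generate_ontology(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the synthetic ontology in all three dialects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ont, _ = build_ontology(spec)
    return {
        "flat": write_flat_ontology(ont, out_dir / "ontology.txt"),
        "obo": write_obo(ont, out_dir / "ontology.obo"),
        "gaf": write_gaf(ont, out_dir / "annotations.gaf"),
    }


def generate_interactions(spec: FixtureSpec, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ont, _ = build_ontology(spec)
    net = build_interactions(spec, ont)
    return write_interactions(net, out_dir / "ontology_interactions.txt")


def generate_datasets(spec: FixtureSpec, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    ont, _ = build_ontology(spec)
    datasets = build_datasets(spec, ont)
    return write_dataset_files(datasets, out_dir / "datasets")


def generate_all(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write the complete synthetic input tree used by the end-to-end tests."""
    out_dir = Path(out_dir)
    paths = generate_ontology(spec, out_dir)
    paths["interactions"] = generate_interactions(spec, out_dir)
    paths["datasets"] = generate_datasets(spec, out_dir)
    return paths
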