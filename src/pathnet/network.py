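"""Integrated SCP networks with pie-chart nodes and yEd graphml export.

Significant SCPs of all datasets in one integration group are merged into
one network.  Each SCP node is a pie chart: one slice per dataset that
predicted the SCP, slice value = that dataset's -log10(p).  Edges are
typed: hierarchical (parent -> child, directed), functional (top-percent
SCP interactions, undirected), regulatory (directed, off by default) and
gene-membership (SCP -> gene child nodes, dashed).  Unpredicted ancestor
terms can be inserted to keep the hierarchy connected, either only where
they lie on a path between two predicted terms or as the full ancestor
closure.

The graphml writer targets the yEd extension namespace: multi-slice nodes
are embedded-SVG pies, single-slice and helper nodes plain ellipses, so
the files open directly in the yEd graph editor.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from lxml import etree

from pathnet.datasets import Dataset
from pathnet.enrichment import EnrichmentResult
from pathnet.errors import ParameterError
from pathnet.ontology import InteractionNetwork, Ontology, top_percent_interactions

GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"
YED_NS = "http://www.yworks.com/xml/graphml"

ANCESTOR_FILLER_COLOR = "#d3d3d3"


@dataclass
class PieSlice:
    """One dataset's contribution to an SCP node."""

    dataset_name: str
    color: str
    value: float  # -log10 p (significance mode) or unit weight
    angle_fraction: float = 0.0


@dataclass
class NetworkNode:
    node_id: str
    kind: str  # scp | gene
    label: str = ""
    term_id: Optional[str] = None
    slices: list[PieSlice] = field(default_factory=list)
    area: float = 1.0
    label_size: float = 8.0
    level: Optional[int] = None
    group_box: Optional[str] = None
    color: str = ""  # fill for gene / filler nodes
    is_filler: bool = False  # inserted ancestor, not predicted by any dataset

    @property
    def total_value(self) -> float:
        return math.fsum(s.value for s in self.slices)

    @property
    def diameter(self) -> float:
        return 2.0 * math.sqrt(self.area / math.pi)


@dataclass
class NetworkEdge:
    source_id: str
    target_id: str
    kind: str  # hierarchical | functional | regulatory | gene_membership
    directed: bool = True


@dataclass
class NetworkOptions:
    """Assembly and styling options for SCP networks."""

    hierarchical_edges: bool = True
    functional_edges: bool = False
    regulatory_edges: bool = False
    ancestor_mode: str = "intermediate_only"  # or all_ancestors
    scaling_mode: str = "significance"  # dataset_count | color_count | uniform
    scaling_context: str = "per_network"  # or shared
    label_scaling: bool = True
    min_label: float = 8.0
    max_label: float = 24.0
    box_levels: bool = False
    add_gene_children: bool = False
    top_interaction_percent: float = 25.0
    reference_diameter: float = 80.0

    def __post_init__(self):
        if self.min_label > self.max_label:
            raise ParameterError(
                f"min_label ({self.min_label}) must be <= max_label "
                f"({self.max_label})"
            )
        if self.ancestor_mode not in ("intermediate_only", "all_ancestors"):
            raise ParameterError(f"unknown ancestor_mode {self.ancestor_mode!r}")
        if self.scaling_mode not in (
            "significance", "dataset_count", "color_count", "uniform"
        ):
            raise ParameterError(f"unknown scaling_mode {self.scaling_mode!r}")
        if self.scaling_context not in ("per_network", "shared"):
            raise ParameterError(
                f"unknown scaling_context {self.scaling_context!r}"
            )


class SCPNetwork:
    """Nodes and typed edges of one integrated pathway network."""

    def __init__(self, name: str = ""):
        self.name = name
        self.nodes: dict[str, NetworkNode] = {}
        self.edges: list[NetworkEdge] = []

    def add_node(self, node: NetworkNode) -> None:
        self.nodes[node.node_id] = node

    def add_edge(self, edge: NetworkEdge) -> None:
        if edge.source_id not in self.nodes or edge.target_id not in self.nodes:
            raise ParameterError(
                f"edge {edge.source_id}->{edge.target_id} references an "
                "unknown node"
            )
        self.edges.append(edge)

    def scp_nodes(self) -> list[NetworkNode]:
        return [n for n in self.nodes.values() if n.kind == "scp"]


@dataclass
class SCPSelectionGroup:
    """Named SCPs (optionally with all their descendants) shown regardless
    of significance cutoffs."""

    name: str
    term_ids: list[str]
    include_descendants: bool = False


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def insert_ancestors(
    predicted: set[str], ontology: Ontology, mode: str
) -> tuple[set[str], list[tuple[str, str]]]:
    """Ancestor terms and hierarchical edges connecting predicted terms.

    ``intermediate_only`` adds exactly the unpredicted terms lying on a
    directed ancestor path between two predicted terms; ``all_ancestors``
    adds the full ancestor closure.  Returned edges are the ontology's
    direct parent -> child edges induced on predicted + added terms.
    """
    if mode not in ("intermediate_only", "all_ancestors"):
        raise ParameterError(f"unknown ancestor mode {mode!r}")
    for t in predicted:
        if t not in ontology:
            raise ParameterError(f"predicted term {t!r} not in ontology")
    if mode == "all_ancestors":
        added: set[str] = set()
        for t in predicted:
            added |= ontology.ancestors(t)
        added -= predicted
    else:
        # descendants-of-a-predicted ∩ ancestors-of-a-predicted
        below: set[str] = set()
        above: set[str] = set()
        for t in predicted:
            below |= ontology.descendants(t)
            above |= ontology.ancestors(t)
        added = (below & above) - predicted
    node_set = predicted | added
    edges = [
        (p, c)
        for p in sorted(node_set)
        for c in sorted(ontology.terms[p].child_ids)
        if c in node_set
    ]
    return added, edges


def apply_scp_selection(
    results_by_dataset: dict[str, list[EnrichmentResult]],
    selection_groups: list[SCPSelectionGroup],
    ontology: Ontology,
) -> dict[str, dict[str, list[EnrichmentResult]]]:
    """Restrict results to SCP selection groups, bypassing significance.

    For every group, each dataset's results are filtered to the group's
    terms (plus descendants for branch selections) and marked significant
    so downstream figures and networks include them.  Returns
    {group name: {dataset: results}}.
    """
    out: dict[str, dict[str, list[EnrichmentResult]]] = {}
    for group in selection_groups:
        wanted: set[str] = set()
        for tid in group.term_ids:
            if tid not in ontology:
                raise ParameterError(
                    f"selection group {group.name!r} names unknown term {tid!r}"
                )
            wanted.add(tid)
            if group.include_descendants:
                wanted |= ontology.descendants(tid)
        out[group.name] = {
            ds: [
                replace(
                    r,
                    significant=True,
                    overlap_genes=set(r.overlap_genes),
                    contributing_merged_ids=set(r.contributing_merged_ids),
                )
                for r in results
                if r.term_id in wanted
            ]
            for ds, results in results_by_dataset.items()
        }
    return out


def build_network(
    results_by_dataset: dict[str, list[EnrichmentResult]],
    datasets: list[Dataset],
    ontology: Ontology,
    interactions: Optional[InteractionNetwork] = None,
    options: Optional[NetworkOptions] = None,
    name: str = "",
    scaling_reference: Optional[float] = None,
) -> SCPNetwork:
    """Assemble the integrated network for one integration group.

    Nodes are the union over datasets of significant SCPs, one pie slice
    per (SCP, dataset) prediction with value -log10(p); slice order follows
    dataset order_index.  Hierarchical edges are inserted per the ancestor
    mode; functional edges are the top-percent interaction edges with both
    endpoints present.  ``scaling_reference`` carries the shared maximum
    scaling metric when ``options.scaling_context == 'shared'``.
    """
    options = options or NetworkOptions()
    ds_by_name = {d.name: d for d in datasets}
    net = SCPNetwork(name=name)

    ordered = sorted(
        results_by_dataset.items(),
        key=lambda kv: (
            ds_by_name[kv[0]].order_index if kv[0] in ds_by_name else 0,
            kv[0],
        ),
    )
    included: dict[str, list[tuple[str, EnrichmentResult]]] = {}
    for ds_name, results in ordered:
        for r in results:
            if r.significant and r.term_id in ontology:
                included.setdefault(r.term_id, []).append((ds_name, r))

    for tid in sorted(included):
        term = ontology.terms[tid]
        node = NetworkNode(
            node_id=tid, kind="scp", label=term.name or tid,
            term_id=tid, level=term.level,
        )
        for ds_name, r in included[tid]:
            color = ds_by_name[ds_name].color if ds_name in ds_by_name else ""
            node.slices.append(
                PieSlice(
                    dataset_name=ds_name, color=color or "#808080",
                    value=r.minus_log10_p,
                )
            )
        net.add_node(node)

    predicted = set(included)
    if options.hierarchical_edges and predicted:
        added, h_edges = insert_ancestors(
            predicted, ontology, options.ancestor_mode
        )
        for tid in sorted(added):
            term = ontology.terms[tid]
            net.add_node(
                NetworkNode(
                    node_id=tid, kind="scp", label=term.name or tid,
                    term_id=tid, level=term.level,
                    color=ANCESTOR_FILLER_COLOR, is_filler=True,
                )
            )
        for p, c in h_edges:
            net.add_edge(NetworkEdge(p, c, kind="hierarchical", directed=True))

    if options.functional_edges and interactions is not None and len(interactions):
        top = top_percent_interactions(
            interactions, options.top_interaction_percent
        )
        for (a, b) in sorted(top.weights):
            if a in net.nodes and b in net.nodes:
                net.add_edge(
                    NetworkEdge(a, b, kind="functional", directed=False)
                )

    if options.regulatory_edges:
        for (a, b) in sorted(ontology.regulatory_edges):
            if a in net.nodes and b in net.nodes:
                net.add_edge(
                    NetworkEdge(a, b, kind="regulatory", directed=True)
                )

    if options.add_gene_children:
        flat: dict[str, list[EnrichmentResult]] = {}
        for pairs in included.values():
            for ds_name, r in pairs:
                flat.setdefault(ds_name, []).append(r)
        add_gene_children(net, flat, datasets)

    if options.box_levels:
        for node in net.nodes.values():
            if node.kind == "scp" and node.level is not None:
                node.group_box = f"level_{node.level}"

    scale_nodes(net, options, context_max=scaling_reference)
    if options.label_scaling:
        scale_labels(net, options.min_label, options.max_label)
    else:
        for node in net.nodes.values():
            node.label_size = options.min_label
    return net


def scaling_metric(node: NetworkNode, mode: str) -> float:
    if mode == "significance":
        return node.total_value
    if mode == "dataset_count":
        return float(len(node.slices))
    if mode == "color_count":
        return float(len({s.color for s in node.slices}))
    return 1.0  # uniform


def max_scaling_metric(networks: list[SCPNetwork], options: NetworkOptions) -> float:
    """Largest node metric across networks (for shared scaling contexts)."""
    best = 0.0
    for net in networks:
        for node in net.scp_nodes():
            if not node.is_filler:
                best = max(best, scaling_metric(node, options.scaling_mode))
    return best


def scale_nodes(
    network: SCPNetwork,
    options: NetworkOptions,
    context_max: Optional[float] = None,
) -> SCPNetwork:
    """Assign node areas and slice angle fractions.

    In significance mode area is proportional to the node's summed
    -log10(p) and slice angles to each dataset's share; the other modes use
    dataset count, distinct color count, or a constant, with equal slice
    angles.  The constant is chosen so the largest node in the scaling
    context (this network, or the shared maximum passed via
    ``context_max``) gets the reference diameter.  Inserted ancestors get a
    fixed small area (reference diameter / 4).
    """
    ref_area = math.pi * (options.reference_diameter / 2.0) ** 2
    filler_area = math.pi * (options.reference_diameter / 8.0) ** 2
    metrics = {
        nid: scaling_metric(n, options.scaling_mode)
        for nid, n in network.nodes.items()
        if n.kind == "scp" and not n.is_filler
    }
    max_metric = context_max if context_max is not None else max(
        metrics.values(), default=0.0
    )
    scale = ref_area / max_metric if max_metric > 0 else 0.0
    for nid, node in network.nodes.items():
        if node.kind != "scp":
            node.area = filler_area / 4.0
            continue
        if node.is_filler:
            node.area = filler_area
            continue
        node.area = metrics[nid] * scale if scale > 0 else filler_area
        total = node.total_value
        for s in node.slices:
            if options.scaling_mode == "significance" and total > 0:
                s.angle_fraction = s.value / total
            else:
                s.angle_fraction = 1.0 / len(node.slices)
    return network


def scale_labels(
    network: SCPNetwork, min_label: float, max_label: float
) -> SCPNetwork:
    """Map node areas linearly onto the [min_label, max_label] font range."""
    if min_label > max_label:
        raise ParameterError(
            f"min_label ({min_label}) must be <= max_label ({max_label})"
        )
    scp = network.scp_nodes()
    if not scp:
        return network
    areas = [n.area for n in scp]
    lo, hi = min(areas), max(areas)
    for n in scp:
        if hi == lo:
            n.label_size = min_label
        else:
            n.label_size = (
                min_label + (n.area - lo) / (hi - lo) * (max_label - min_label)
            )
    return network


def add_gene_children(
    network: SCPNetwork,
    results_by_dataset: dict[str, list[EnrichmentResult]],
    datasets: list[Dataset],
) -> SCPNetwork:
    """Attach overlap genes of predicted SCPs as child nodes.

    One node per distinct gene, linked by a gene-membership edge from every
    SCP node whose recorded overlap contains it.  The gene node takes the
    color of the contributing dataset with the lowest order index.
    """
    ds_by_name = {d.name: d for d in datasets}
    memberships: dict[str, set[str]] = {}  # gene -> scp node ids
    gene_color: dict[str, tuple[int, str]] = {}
    for ds_name, results in results_by_dataset.items():
        ds = ds_by_name.get(ds_name)
        order = ds.order_index if ds else 0
        color = (ds.color if ds else "") or "#808080"
        for r in results:
            if r.term_id not in network.nodes:
                continue
            for g in r.overlap_genes:
                memberships.setdefault(g, set()).add(r.term_id)
                if g not in gene_color or order < gene_color[g][0]:
                    gene_color[g] = (order, color)
    for g in sorted(memberships):
        nid = f"gene::{g}"
        if nid not in network.nodes:
            network.add_node(
                NetworkNode(
                    node_id=nid, kind="gene", label=g, color=gene_color[g][1]
                )
            )
        for tid in sorted(memberships[g]):
            network.add_edge(
                NetworkEdge(tid, nid, kind="gene_membership", directed=False)
            )
    return network


def network_filename(ontology_name: str, group: str, analysis: str) -> str:
    """``<ontology>_<group>_<standard|dynamic>.graphml``"""
    return f"{ontology_name}_{group}_{analysis}.graphml"


# ---------------------------------------------------------------------------
# graphml export
# ---------------------------------------------------------------------------

def _svg_pie(node: NetworkNode) -> str:
    """Standalone SVG drawing the node's pie with its slice fractions."""
    d = node.diameter
    r = d / 2.0
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{d:.3f}" '
        f'height="{d:.3f}" viewBox="0 0 {d:.3f} {d:.3f}">'
    ]
    angle = -0.5 * math.pi  # start at 12 o'clock
    for s in node.slices:
        frac = s.angle_fraction
        if frac <= 0:
            continue
        if frac >= 1.0 - 1e-12:
            parts.append(
                f'<circle cx="{r:.3f}" cy="{r:.3f}" r="{r:.3f}" '
                f'fill="{s.color}" stroke="black" stroke-width="0.5"/>'
            )
            angle += 2 * math.pi * frac
            continue
        a0, a1 = angle, angle + 2 * math.pi * frac
        x0, y0 = r + r * math.cos(a0), r + r * math.sin(a0)
        x1, y1 = r + r * math.cos(a1), r + r * math.sin(a1)
        large = 1 if frac > 0.5 else 0
        parts.append(
            f'<path d="M {r:.3f} {r:.3f} L {x0:.3f} {y0:.3f} '
            f'A {r:.3f} {r:.3f} 0 {large} 1 {x1:.3f} {y1:.3f} Z" '
            f'fill="{s.color}" stroke="black" stroke-width="0.5"/>'
        )
        angle = a1
    parts.append("</svg>")
    return "".join(parts)


_EDGE_STYLE = {
    "hierarchical": ("line", "standard"),
    "regulatory": ("line", "standard"),
    "functional": ("line", "none"),
    "gene_membership": ("dashed", "none"),
}


def write_graphml(
    network: SCPNetwork, path: str | Path, options: Optional[NetworkOptions] = None
) -> Path:
    """Write the network as yEd-compatible graphml.

    Multi-slice SCP nodes become embedded-SVG pie nodes; single-slice,
    ancestor and gene nodes are plain ellipses.  Hierarchical and
    regulatory edges carry target arrows, functional edges none,
    gene-membership edges are dashed.  Machine-readable node data (kind,
    area, total value, slice composition) is emitted alongside the yEd
    styling so the file round-trips losslessly.
    """
    options = options or NetworkOptions()
    path = Path(path)
    nsmap = {None: GRAPHML_NS, "y": YED_NS}
    root = etree.Element(f"{{{GRAPHML_NS}}}graphml", nsmap=nsmap)

    def key(kid, target, name=None, attr_type=None, yfiles=None):
        el = etree.SubElement(root, f"{{{GRAPHML_NS}}}key", id=kid)
        el.set("for", target)
        if yfiles:
            el.set("yfiles.type", yfiles)
        else:
            el.set("attr.name", name)
            el.set("attr.type", attr_type)
        return el

    key("d_ng", "node", yfiles="nodegraphics")
    key("d_eg", "edge", yfiles="edgegraphics")
    key("d_res", "graphml", yfiles="resources")
    key("d_kind", "node", "kind", "string")
    key("d_area", "node", "area", "double")
    key("d_total", "node", "total_value", "double")
    key("d_slices", "node", "slices", "string")
    key("d_level", "node", "level", "string")
    key("d_ekind", "edge", "kind", "string")

    graph = etree.SubElement(
        root, f"{{{GRAPHML_NS}}}graph", id=network.name or "G",
        edgedefault="directed",
    )

    resources: list[tuple[str, str]] = []
    boxes: dict[str, etree._Element] = {}

    def box_graph(box_id: str) -> etree._Element:
        if box_id not in boxes:
            gnode = etree.SubElement(
                graph, f"{{{GRAPHML_NS}}}node", id=f"box::{box_id}"
            )
            gnode.set("yfiles.foldertype", "group")
            data = etree.SubElement(gnode, f"{{{GRAPHML_NS}}}data", key="d_ng")
            pab = etree.SubElement(data, f"{{{YED_NS}}}ProxyAutoBoundsNode")
            realizers = etree.SubElement(pab, f"{{{YED_NS}}}Realizers")
            realizers.set("active", "0")
            gn = etree.SubElement(realizers, f"{{{YED_NS}}}GroupNode")
            lbl = etree.SubElement(gn, f"{{{YED_NS}}}NodeLabel")
            lbl.text = box_id
            boxes[box_id] = etree.SubElement(
                gnode, f"{{{GRAPHML_NS}}}graph",
                id=f"box::{box_id}:", edgedefault="directed",
            )
        return boxes[box_id]

    for node in network.nodes.values():
        parent = box_graph(node.group_box) if node.group_box else graph
        el = etree.SubElement(parent, f"{{{GRAPHML_NS}}}node", id=node.node_id)
        d = node.diameter
        data = etree.SubElement(el, f"{{{GRAPHML_NS}}}data", key="d_ng")
        multi = node.kind == "scp" and len(node.slices) > 1
        if multi:
            svg_node = etree.SubElement(data, f"{{{YED_NS}}}SVGNode")
            geom = etree.SubElement(svg_node, f"{{{YED_NS}}}Geometry")
            label = etree.SubElement(svg_node, f"{{{YED_NS}}}NodeLabel")
            model = etree.SubElement(svg_node, f"{{{YED_NS}}}SVGModel")
            model.set("svgBoundsPolicy", "0")
            content = etree.SubElement(model, f"{{{YED_NS}}}SVGContent")
            rid = str(len(resources) + 1)
            content.set("refid", rid)
            resources.append((rid, _svg_pie(node)))
        else:
            shape_node = etree.SubElement(data, f"{{{YED_NS}}}ShapeNode")
            geom = etree.SubElement(shape_node, f"{{{YED_NS}}}Geometry")
            fill = etree.SubElement(shape_node, f"{{{YED_NS}}}Fill")
            if node.slices:
                fill.set("color", node.slices[0].color)
            else:
                fill.set("color", node.color or ANCESTOR_FILLER_COLOR)
            label = etree.SubElement(shape_node, f"{{{YED_NS}}}NodeLabel")
            shape = etree.SubElement(shape_node, f"{{{YED_NS}}}Shape")
            shape.set("type", "ellipse")
        geom.set("width", f"{d:.6f}")
        geom.set("height", f"{d:.6f}")
        geom.set("x", "0")
        geom.set("y", "0")
        label.set("fontSize", str(int(round(node.label_size))))
        label.text = node.label

        def dval(k, v):
            dd = etree.SubElement(el, f"{{{GRAPHML_NS}}}data", key=k)
            dd.text = v

        dval("d_kind", node.kind)
        dval("d_area", repr(node.area))
        dval("d_total", repr(node.total_value))
        dval("d_level", "" if node.level is None else str(node.level))
        dval("d_slices", json.dumps([
            {
                "dataset": s.dataset_name,
                "color": s.color,
                "value": s.value,
                "angle_fraction": s.angle_fraction,
            }
            for s in node.slices
        ]))

    for i, edge in enumerate(network.edges):
        el = etree.SubElement(
            graph, f"{{{GRAPHML_NS}}}edge", id=f"e{i}",
            source=edge.source_id, target=edge.target_id,
        )
        data = etree.SubElement(el, f"{{{GRAPHML_NS}}}data", key="d_eg")
        ple = etree.SubElement(data, f"{{{YED_NS}}}PolyLineEdge")
        line_type, arrow = _EDGE_STYLE[edge.kind]
        ls = etree.SubElement(ple, f"{{{YED_NS}}}LineStyle")
        ls.set("type", line_type)
        ls.set("width", "1.0")
        arrows = etree.SubElement(ple, f"{{{YED_NS}}}Arrows")
        arrows.set("source", "none")
        arrows.set("target", arrow if edge.directed else "none")
        dk = etree.SubElement(el, f"{{{GRAPHML_NS}}}data", key="d_ekind")
        dk.text = edge.kind

    res_data = etree.SubElement(root, f"{{{GRAPHML_NS}}}data", key="d_res")
    res_el = etree.SubElement(res_data, f"{{{YED_NS}}}Resources")
    for rid, svg in resources:
        r = etree.SubElement(res_el, f"{{{YED_NS}}}Resource", id=rid)
        r.text = etree.CDATA(svg)

    path.parent.mkdir(parents=True, exist_ok=True)
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    return path


def read_graphml_summary(path: str | Path) -> SCPNetwork:
    """Re-parse an emitted graphml file into an :class:`SCPNetwork`.

    Restores node ids, kinds, areas, levels and slice compositions from the
    machine-readable data keys; used for round-trip verification.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    net = SCPNetwork()
    for el in root.iter(f"{{{GRAPHML_NS}}}node"):
        nid = el.get("id")
        if nid.startswith("box::"):
            continue
        fields = {
            d.get("key"): (d.text or "")
            for d in el.findall(f"{{{GRAPHML_NS}}}data")
        }
        if "d_kind" not in fields:
            continue
        node = NetworkNode(
            node_id=nid,
            kind=fields["d_kind"],
            area=float(fields["d_area"]),
            level=int(fields["d_level"]) if fields.get("d_level") else None,
        )
        for s in json.loads(fields.get("d_slices") or "[]"):
            node.slices.append(
                PieSlice(
                    dataset_name=s["dataset"], color=s["color"],
                    value=s["value"], angle_fraction=s["angle_fraction"],
                )
            )
        net.add_node(node)
    for el in root.iter(f"{{{GRAPHML_NS}}}edge"):
        kind = ""
        for d in el.findall(f"{{{GRAPHML_NS}}}data"):
            if d.get("key") == "d_ekind":
                kind = d.text or ""
        net.edges.append(
            NetworkEdge(el.get("source"), el.get("target"), kind=kind)
        )
    return net
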