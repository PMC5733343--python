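"""Microbial degradation pathways as DAGs with fate overlays.

A pathway is a directed acyclic graph of compounds connected by typed
transformations (deglycosylation, C-ring cleavage, dehydroxylation,
oxidations, ...).  Three fixtures are bundled: the naringenin-glycoside
route, the catechin / flavan-3-ol route and the salicylic-alcohol route.

Overlaying triage fates assigns each node a role — a compound that
disappears is a PRECURSOR, one that rises and falls an INTERMEDIATE, one
that accumulates a TERMINAL_METABOLITE — and each edge a verdict.  An
edge is CONSISTENT when something consumed or transient feeds something
transient or accumulating, and also when two accumulating metabolites
are chained (an upstream metabolite can keep rising while slowly feeding
the next).  A terminal metabolite feeding a rise-and-fall intermediate is
INCONSISTENT; any edge touching an unobserved compound is UNDETERMINED.
Nodes flagged ``expected_undetectable`` (weak negative-mode ionization or
onward fermentation to short-chain acids) are expected to stay
UNDETERMINED rather than count against the pathway.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import yaml

from .triage import FateLabel, FateRecord

__all__ = [
    "TransformationType",
    "NodeRole",
    "EdgeVerdict",
    "PathwayNode",
    "PathwayGraph",
    "Overlay",
    "load_pathway",
    "bundled_pathways",
    "role_from_fate",
    "overlay_fates",
    "fates_by_compound",
    "coverage_report",
]


class TransformationType(str, enum.Enum):
    DEGLYCOSYLATION = "DEGLYCOSYLATION"
    C_RING_CLEAVAGE = "C_RING_CLEAVAGE"
    DEHYDROXYLATION = "DEHYDROXYLATION"
    REDUCTION = "REDUCTION"
    OXIDATION = "OXIDATION"
    BETA_OXIDATION = "BETA_OXIDATION"
    ALPHA_OXIDATION = "ALPHA_OXIDATION"
    HYDROLYSIS = "HYDROLYSIS"
    OTHER = "OTHER"


class NodeRole(str, enum.Enum):
    PRECURSOR = "PRECURSOR"
    INTERMEDIATE = "INTERMEDIATE"
    TERMINAL_METABOLITE = "TERMINAL_METABOLITE"
    UNKNOWN = "UNKNOWN"


class EdgeVerdict(str, enum.Enum):
    CONSISTENT = "CONSISTENT"
    INCONSISTENT = "INCONSISTENT"
    UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class PathwayNode:
    name: str
    peak_id: int | None = None
    formula: str | None = None
    expected_undetectable: bool = False


@dataclass
class PathwayGraph:
    """A validated DAG of compounds and typed transformations."""

    name: str
    graph: nx.DiGraph

    def __post_init__(self) -> None:
        for u, v in self.graph.edges:
            for endpoint in (u, v):
                if endpoint not in self.graph.nodes or "node" not in self.graph.nodes[endpoint]:
                    raise ValueError(f"pathway {self.name!r}: edge endpoint {endpoint!r} is not a declared node")
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"pathway {self.name!r} contains a cycle: {cycle}")

    @property
    def nodes(self) -> list[PathwayNode]:
        return [data["node"] for _, data in self.graph.nodes(data=True)]

    def node(self, name: str) -> PathwayNode:
        return self.graph.nodes[name]["node"]

    def edges(self) -> list[tuple[str, str, TransformationType]]:
        return [
            (u, v, data["type"]) for u, v, data in self.graph.edges(data=True)
        ]

    def peak_ids(self) -> dict[int, str]:
        """Map of library peak id -> node name for annotated nodes."""
        return {
            n.peak_id: n.name for n in self.nodes if n.peak_id is not None
        }


_BUNDLED = {
    "catechin": "pathway_catechin.yaml",
    "naringenin": "pathway_naringenin.yaml",
    "salicyl_alcohol": "pathway_salicyl_alcohol.yaml",
}


def bundled_pathways() -> list[str]:
    return sorted(_BUNDLED)


def load_pathway(source: str | Path) -> PathwayGraph:
    """Load a pathway fixture by bundled name or from a YAML file.

    The fixture lists nodes (name, optional library peak_id, formula and
    expected_undetectable flag) and typed directed edges.  Cycles, edges
    to undeclared nodes and unknown transformation types are load errors.
    """
    if isinstance(source, str) and source in _BUNDLED:
        text = resources.files("salixfate.data").joinpath(_BUNDLED[source]).read_text()
    else:
        text = Path(source).read_text()
    data = yaml.safe_load(text)
    graph = nx.DiGraph()
    for entry in data.get("nodes", []):
        node = PathwayNode(
            name=str(entry["name"]),
            peak_id=int(entry["peak_id"]) if entry.get("peak_id") is not None else None,
            formula=entry.get("formula"),
            expected_undetectable=bool(entry.get("expected_undetectable", False)),
        )
        graph.add_node(node.name, node=node)
    for entry in data.get("edges", []):
        u, v = str(entry["from"]), str(entry["to"])
        for endpoint in (u, v):
            if endpoint not in graph.nodes:
                raise ValueError(
                    f"pathway {data.get('name')!r}: edge references undeclared node {endpoint!r}"
                )
        graph.add_edge(u, v, type=TransformationType(entry["type"]))
    return PathwayGraph(name=str(data.get("name", "pathway")), graph=graph)


def role_from_fate(label: FateLabel | str | None) -> NodeRole:
    """Node role implied by a triage fate; a pure function of the label."""
    if label is None:
        return NodeRole.UNKNOWN
    label = FateLabel(label)
    if label in (FateLabel.DECREASING, FateLabel.FAST_METABOLIZED):
        return NodeRole.PRECURSOR
    if label is FateLabel.INTERMEDIATE:
        return NodeRole.INTERMEDIATE
    if label is FateLabel.INCREASING:
        return NodeRole.TERMINAL_METABOLITE
    return NodeRole.UNKNOWN


@dataclass
class Overlay:
    """Fates projected onto one pathway graph."""

    pathway: str
    node_fates: dict[str, FateLabel | None]
    node_roles: dict[str, NodeRole]
    node_detected: dict[str, bool]
    edge_verdicts: dict[tuple[str, str], EdgeVerdict]
    coverage: float


def _edge_verdict(role_u: NodeRole, role_v: NodeRole) -> EdgeVerdict:
    if NodeRole.UNKNOWN in (role_u, role_v):
        return EdgeVerdict.UNDETERMINED
    if role_u is NodeRole.TERMINAL_METABOLITE:
        return (
            EdgeVerdict.INCONSISTENT
            if role_v is NodeRole.INTERMEDIATE
            else EdgeVerdict.CONSISTENT
            if role_v is NodeRole.TERMINAL_METABOLITE
            else EdgeVerdict.UNDETERMINED
        )
    if role_v in (NodeRole.INTERMEDIATE, NodeRole.TERMINAL_METABOLITE):
        return EdgeVerdict.CONSISTENT
    return EdgeVerdict.UNDETERMINED


def overlay_fates(
    graph: PathwayGraph, compound_fates: Mapping[object, FateLabel | str]
) -> Overlay:
    """Project per-compound fates onto a pathway.

    ``compound_fates`` maps node names and/or library peak ids to fate
    labels (see :func:`fates_by_compound` for deriving such a mapping from
    triage records plus annotations).  Keys naming compounds absent from
    the graph raise a warning, not an error.
    """
    by_peak = graph.peak_ids()
    fates: dict[str, FateLabel | None] = {n.name: None for n in graph.nodes}
    for key, label in compound_fates.items():
        if isinstance(key, int) and key in by_peak:
            fates[by_peak[key]] = FateLabel(label)
        elif key in fates:
            fates[str(key)] = FateLabel(label)
        else:
            warnings.warn(
                f"compound {key!r} is not a node of pathway {graph.name!r}", stacklevel=2
            )
    roles = {name: role_from_fate(label) for name, label in fates.items()}
    detected = {name: label is not None for name, label in fates.items()}
    verdicts = {
        (u, v): _edge_verdict(roles[u], roles[v]) for u, v, _ in graph.edges()
    }
    coverage = sum(detected.values()) / len(detected) if detected else 0.0
    return Overlay(
        pathway=graph.name,
        node_fates=fates,
        node_roles=roles,
        node_detected=detected,
        edge_verdicts=verdicts,
        coverage=coverage,
    )


def fates_by_compound(
    records: Sequence[FateRecord],
    annotations,
    concentration: float,
) -> dict[int, FateLabel]:
    """Per-compound fate mapping from triage records and annotation hits.

    ``annotations`` is the frame produced by ``annotate.annotate_table``
    (one row per feature/compound hit).  For each compound the
    best-matching annotated feature (smallest |delta ppm|) that has a fate
    at the requested concentration wins.
    """
    fate_of = {
        r.feature_id: r.label
        for r in records
        if float(r.concentration) == float(concentration)
    }
    best: dict[int, tuple[float, FateLabel]] = {}
    for _, row in annotations.iterrows():
        fid = row["feature_id"]
        if fid not in fate_of:
            continue
        peak_id = int(row["peak_id"])
        candidate = (abs(float(row["delta_ppm"])), fate_of[fid])
        if peak_id not in best or candidate[0] < best[peak_id][0]:
            best[peak_id] = candidate
    return {peak_id: label for peak_id, (_, label) in best.items()}


def coverage_report(overlay: Overlay) -> dict:
    """Counts per role and edge-verdict fractions for one overlay."""
    n_nodes = len(overlay.node_roles)
    n_detected = sum(overlay.node_detected.values())
    role_counts = {role.value: 0 for role in NodeRole}
    for role in overlay.node_roles.values():
        role_counts[role.value] += 1
    verdict_counts = {verdict.value: 0 for verdict in EdgeVerdict}
    for verdict in overlay.edge_verdicts.values():
        verdict_counts[verdict.value] += 1
    n_edges = len(overlay.edge_verdicts)
    return {
        "pathway": overlay.pathway,
        "n_nodes": n_nodes,
        "n_detected": n_detected,
        "n_undetected": n_nodes - n_detected,
        "coverage": overlay.coverage,
        "roles": role_counts,
        "edges": verdict_counts,
        "consistent_fraction": verdict_counts["CONSISTENT"] / n_edges if n_edges else 0.0,
        "inconsistent_fraction": verdict_counts["INCONSISTENT"] / n_edges if n_edges else 0.0,
    }
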