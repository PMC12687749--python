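"""Pathway-map (IPPM) construction from denoised foci and a CTL.

An IPPM is a DAG ``M = (V, E)``: nodes are the temporal foci of
transforms (plus one node per referenced sensory input stream, at
latency zero), and directed edges follow the dependency structure of
the candidate transform list.  Consecutive foci of the same transform
are linked by *identity* edges (the information is copied unchanged to
another hexel); parent-to-child links are *transform* edges from the
parent's final (latest) focus to the child's initial (earliest) focus.

Edges follow CTL direction regardless of latency: a child focus earlier
than its parent's is legal at build time and is what the causality
violation metric measures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .expression import (
    CandidateTransformList,
    CTLError,
    ExpressionPoint,
    ParameterError,
    validate_ctl,
)

__all__ = [
    "IPPMNode",
    "IPPMGraph",
    "chain_foci",
    "build_ippm",
    "export_graph",
    "graph_from_json",
]


@dataclass(frozen=True)
class IPPMNode:
    node_id: str
    transform: str
    latency_ms: float
    surprisal: float
    hexel_id: int | None
    is_input_stream: bool = False


def _node_id(transform: str, latency_ms: float, hexel_id: int) -> str:
    return f"{transform}@{latency_ms:g}#{hexel_id}"


class IPPMGraph:
    """A DAG of expression foci with typed edges (``transform``/``identity``)."""

    def __init__(self) -> None:
        self._nodes: dict[str, IPPMNode] = {}
        self._edges: dict[tuple[str, str], str] = {}

    # -- construction -------------------------------------------------
    def add_node(self, node: IPPMNode) -> None:
        self._nodes[node.node_id] = node

    def add_edge(self, src: str, dst: str, kind: str = "transform") -> None:
        if kind not in ("transform", "identity"):
            raise ParameterError(f"unknown edge kind {kind!r}")
        if src not in self._nodes or dst not in self._nodes:
            raise KeyError("both endpoints must exist before adding an edge")
        self._edges[(src, dst)] = kind

    # -- views ---------------------------------------------------------
    @property
    def nodes(self) -> dict[str, IPPMNode]:
        return dict(self._nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self._edges)

    def edge_kind(self, src: str, dst: str) -> str:
        return self._edges[(src, dst)]

    @property
    def transforms(self) -> set[str]:
        return {n.transform for n in self._nodes.values() if not n.is_input_stream}

    @property
    def input_streams(self) -> set[str]:
        return {n.transform for n in self._nodes.values() if n.is_input_stream}

    def latency(self, node_id: str) -> float:
        return self._nodes[node_id].latency_ms

    def __len__(self) -> int:
        return len(self._nodes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IPPMGraph):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for nid, n in self._nodes.items():
            g.add_node(
                nid,
                transform=n.transform,
                latency_ms=n.latency_ms,
                logp=n.surprisal,
                hexel=-1 if n.hexel_id is None else n.hexel_id,
                is_input=n.is_input_stream,
            )
        for (u, v), kind in self._edges.items():
            g.add_edge(u, v, kind=kind)
        return g

    def is_dag(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    # -- serialization -------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "id": n.node_id,
                    "transform": n.transform,
                    "latency_ms": n.latency_ms,
                    "logp": n.surprisal,
                    "hexel": n.hexel_id,
                    "is_input": n.is_input_stream,
                }
                for n in sorted(self._nodes.values(), key=lambda n: n.node_id)
            ],
            "edges": [
                {"src": u, "dst": v, "kind": kind}
                for (u, v), kind in sorted(self._edges.items())
            ],
        }

    @classmethod
    def from_json_dict(cls, doc: Mapping) -> "IPPMGraph":
        g = cls()
        for nd in doc["nodes"]:
            g.add_node(
                IPPMNode(
                    node_id=nd["id"],
                    transform=nd["transform"],
                    latency_ms=float(nd["latency_ms"]),
                    surprisal=float(nd["logp"]),
                    hexel_id=None if nd["hexel"] is None else int(nd["hexel"]),
                    is_input_stream=bool(nd["is_input"]),
                )
            )
        for ed in doc["edges"]:
            g.add_edge(ed["src"], ed["dst"], ed["kind"])
        return g


def chain_foci(
    transform: str, foci: Sequence[ExpressionPoint]
) -> tuple[list[IPPMNode], list[tuple[str, str]]]:
    """One node per focus, linked in latency order by identity edges.

    The earliest focus is the transform's *initial* node (target of
    incoming transform edges), the latest its *final* node (source of
    outgoing ones).
    """
    ordered = sorted(foci, key=lambda p: (p.latency_ms, p.hexel_id))
    nodes = [
        IPPMNode(
            node_id=_node_id(transform, p.latency_ms, p.hexel_id),
            transform=transform,
            latency_ms=p.latency_ms,
            surprisal=p.surprisal,
            hexel_id=p.hexel_id,
        )
        for p in ordered
    ]
    edges = [
        (nodes[i].node_id, nodes[i + 1].node_id) for i in range(len(nodes) - 1)
    ]
    return nodes, edges


def build_ippm(
    foci_map: Mapping[str, Sequence[ExpressionPoint]],
    ctl: CandidateTransformList,
    missing_policy: str = "bypass",
) -> IPPMGraph:
    """Build the pathway map from per-transform foci and a CTL.

    For every parent→child pair in the CTL with both sides detected, a
    transform edge runs from the parent's final node to the child's
    initial node; parents that are input streams connect from a stream
    node at latency 0 (materialized only when referenced).

    ``missing_policy`` controls children whose parent transform was not
    detected: ``"bypass"`` routes edges through the missing transform to
    its nearest detected ancestors (falling back to input streams);
    ``"prune"`` omits such edges.
    """
    if missing_policy not in ("bypass", "prune"):
        raise ParameterError(f"unknown missing_policy {missing_policy!r}")
    validate_ctl(ctl)
    for t in foci_map:
        if t not in ctl.parents:
            raise CTLError(f"focus transform {t!r} is not in the CTL")

    g = IPPMGraph()
    initial: dict[str, str] = {}
    final: dict[str, str] = {}
    detected = {t for t, foci in foci_map.items() if foci}
    for t in sorted(detected):
        nodes, identity_edges = chain_foci(t, foci_map[t])
        for n in nodes:
            g.add_node(n)
        for u, v in identity_edges:
            g.add_edge(u, v, "identity")
        initial[t] = nodes[0].node_id
        final[t] = nodes[-1].node_id

    def stream_node(name: str) -> str:
        if name not in g.nodes:
            g.add_node(
                IPPMNode(
                    node_id=name,
                    transform=name,
                    latency_ms=0.0,
                    surprisal=0.0,
                    hexel_id=None,
                    is_input_stream=True,
                )
            )
        return name

    resolved: dict[str, tuple[str, ...]] = {}

    def resolve(label: str) -> tuple[str, ...]:
        """Node id(s) standing for a parent label, skipping undetected transforms."""
        if label in ctl.input_streams:
            return (stream_node(label),)
        if label in detected:
            return (final[label],)
        if missing_policy == "prune":
            return ()
        if label not in resolved:
            resolved[label] = ()  # break-glass for (impossible) cycles
            endpoints: list[str] = []
            for parent in ctl.parents[label]:
                endpoints.extend(resolve(parent))
            resolved[label] = tuple(dict.fromkeys(endpoints))
        return resolved[label]

    for child in sorted(detected):
        endpoints: list[str] = []
        for parent in ctl.parents[child]:
            endpoints.extend(resolve(parent))
        for src in dict.fromkeys(endpoints):
            g.add_edge(src, initial[child], "transform")

    assert g.is_dag(), "builder produced a cyclic graph"
    return g


def _dot_escape(s: str) -> str:
    return s.replace('"', '\\"')


def _to_dot(g: IPPMGraph) -> str:
    """Minimal DOT serialization (latency as x-position hint, transform as class)."""
    lines = ["digraph ippm {", "  rankdir=LR;"]
    for n in sorted(g.nodes.values(), key=lambda n: n.node_id):
        shape = "box" if n.is_input_stream else "ellipse"
        lines.append(
            f'  "{_dot_escape(n.node_id)}" [label="{_dot_escape(n.transform)}\\n'
            f'{n.latency_ms:g} ms", shape={shape}, transform="{_dot_escape(n.transform)}", '
            f'latency_ms={n.latency_ms:g}];'
        )
    for u, v in sorted(g.edges):
        kind = g.edge_kind(u, v)
        style = ", style=dashed" if kind == "identity" else ""
        lines.append(
            f'  "{_dot_escape(u)}" -> "{_dot_escape(v)}" [kind="{kind}"{style}];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_graph(g: IPPMGraph, path: str | Path, format: str = "json") -> None:
    """Write the graph as ``json`` (lossless), ``dot`` or ``graphml``."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(g.to_json_dict(), indent=2))
    elif format == "dot":
        path.write_text(_to_dot(g))
    elif format == "graphml":
        nx.write_graphml(g.to_networkx(), path)
    else:
        raise ParameterError(f"unknown export format {format!r}")


def graph_from_json(path: str | Path) -> IPPMGraph:
    return IPPMGraph.from_json_dict(json.loads(Path(path).read_text()))
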