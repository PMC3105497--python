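"""Workflow process graphs with loosely specified branches.

A process model is a directed graph of service instances (a node carries a
unique id and the name of the service it executes) with an initial node.
Edges may carry a branch label and a *loose* flag: a loose edge stands for an
underspecified part of the workflow that synthesis will replace with a
concrete service sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import yaml

from .errors import ContractViolation, ParseError


@dataclass(frozen=True)
class Edge:
    src: str
    dst: str
    label: str | None = None
    loose: bool = False


@dataclass
class ProcessModel:
    """Nodes (id -> service name), directed edges, and the initial node id."""

    nodes: dict[str, str] = field(default_factory=dict)
    edges: list[Edge] = field(default_factory=list)
    initial: str = ""

    def __post_init__(self) -> None:
        if self.initial and self.initial not in self.nodes:
            raise ValueError(f"initial node {self.initial!r} not among nodes")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node ids")
        for e in self.edges:
            for end in (e.src, e.dst):
                if end not in self.nodes:
                    raise ValueError(f"edge endpoint {end!r} is not a node")

    def service_of(self, node_id: str) -> str:
        return self.nodes[node_id]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for nid, svc in self.nodes.items():
            g.add_node(nid, service=svc)
        for e in self.edges:
            g.add_edge(e.src, e.dst, label=e.label, loose=e.loose)
        return g

    def loose_edges(self) -> list[Edge]:
        return [e for e in self.edges if e.loose]

    def successors(self, node_id: str) -> list[str]:
        return [e.dst for e in self.edges if e.src == node_id]

    def sinks(self) -> set[str]:
        with_out = {e.src for e in self.edges}
        return set(self.nodes) - with_out

    # -- loose-edge completion ------------------------------------------------

    def replace_loose_edge(self, edge: Edge, services: list[str]) -> "ProcessModel":
        """Replace a loose edge with a concrete chain of service nodes.

        An empty sequence turns the loose edge into a direct concrete edge.
        Fresh node ids ``syn1, syn2, ...`` are chosen to avoid collisions; all
        other nodes and edges are preserved.
        """
        if edge not in self.edges:
            raise ContractViolation(f"edge {edge} does not belong to this process")
        nodes = dict(self.nodes)
        new_ids: list[str] = []
        counter = 1
        for svc in services:
            while f"syn{counter}" in nodes:
                counter += 1
            nid = f"syn{counter}"
            nodes[nid] = svc
            new_ids.append(nid)
            counter += 1
        chain = [edge.src, *new_ids, edge.dst]
        new_edges: list[Edge] = []
        for e in self.edges:
            if e == edge:
                for a, b in zip(chain, chain[1:]):
                    new_edges.append(Edge(a, b, label=e.label if a == edge.src else None))
            else:
                new_edges.append(e)
        return ProcessModel(nodes=nodes, edges=new_edges, initial=self.initial)


# ---------------------------------------------------------------------------
# Process files (YAML)
# ---------------------------------------------------------------------------

def process_to_dict(process: ProcessModel) -> dict:
    edges = []
    for e in process.edges:
        entry: dict = {"src": e.src, "dst": e.dst}
        if e.label is not None:
            entry["label"] = e.label
        if e.loose:
            entry["loose"] = True
        edges.append(entry)
    return {"initial": process.initial, "nodes": dict(process.nodes), "edges": edges}


def process_from_dict(data: Mapping) -> ProcessModel:
    for key in ("initial", "nodes", "edges"):
        if key not in data:
            raise ParseError(f"process file missing required key {key!r}")
    try:
        edges = [
            Edge(e["src"], e["dst"], label=e.get("label"), loose=bool(e.get("loose", False)))
            for e in data["edges"]
        ]
        return ProcessModel(nodes=dict(data["nodes"]), edges=edges, initial=data["initial"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed process file: {exc}") from None


def write_process(process: ProcessModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(process_to_dict(process), fh, sort_keys=False)


def read_process(path) -> ProcessModel:
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            raise ParseError(
                f"invalid YAML in process file: {getattr(exc, 'problem', exc)}",
                line=None if mark is None else mark.line + 1,
            ) from None
    if not isinstance(data, Mapping):
        raise ParseError("process file does not contain a mapping")
    return process_from_dict(data)
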