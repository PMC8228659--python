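"""Causal-graph reconstruction from an estimated flow matrix.

The reconstruction is the significance-gated rule: start from isolated
vertices, add the directed edge j -> i whenever the estimated flow
T[j -> i] is significant at the configured level (after any multiplicity
correction), and flag a node as a self-loop when its self-influence is
significant.  Directed cycles are allowed by design; the absence of an edge
between two correlated nodes driven by a common cause is an *output* of the
method (nil causality), not a post-processing rule.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .estimator import FlowMatrixResult
from .exceptions import ParameterError
from .significance import SignificanceReport, significance_report

__all__ = ["CausalEdge", "SelfLoop", "CausalGraph", "reconstruct", "export_graph", "import_graph"]

_FORMATS = ("edgelist", "dot", "graphml", "adjacency")


@dataclass(frozen=True)
class CausalEdge:
    source: str
    target: str
    T: float
    tau: float
    se: float
    p: float


@dataclass(frozen=True)
class SelfLoop:
    node: str
    dH_self: float
    se: float
    p: float
    significant: bool


@dataclass(frozen=True)
class CausalGraph:
    """Directed graph with flow-annotated edges and per-node self-loop flags."""

    nodes: tuple[str, ...]
    edges: tuple[CausalEdge, ...]
    self_loops: tuple[SelfLoop, ...]

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for i, name in enumerate(self.nodes):
            loop = self.self_loops[i]
            g.add_node(
                name,
                dH_self=loop.dH_self,
                self_se=loop.se,
                self_p=loop.p,
                self_loop=bool(loop.significant),
            )
        for e in self.edges:
            g.add_edge(e.source, e.target, T=e.T, tau=e.tau, se=e.se, p=e.p)
        return g


def reconstruct(
    result: FlowMatrixResult, report: SignificanceReport | None = None
) -> CausalGraph:
    """Build the causal graph from a flow matrix and its significance report."""
    rep = report or significance_report(result)
    d = result.n_vars
    if rep.se_T.shape != (d, d):
        raise ParameterError("significance report does not match the flow matrix dimension")
    names = result.names
    edges = []
    for j in range(d):
        for i in range(d):
            if j != i and rep.significant[j, i]:
                edges.append(
                    CausalEdge(
                        source=names[j],
                        target=names[i],
                        T=float(result.T[j, i]),
                        tau=float(result.tau[j, i]),
                        se=float(rep.se_T[j, i]),
                        p=float(rep.p_T[j, i]),
                    )
                )
    loops = tuple(
        SelfLoop(
            node=names[i],
            dH_self=float(result.dH_self[i]),
            se=float(rep.se_self[i]),
            p=float(rep.p_self[i]),
            significant=bool(rep.self_significant[i]),
        )
        for i in range(d)
    )
    return CausalGraph(nodes=names, edges=tuple(edges), self_loops=loops)


def _to_edgelist(g: CausalGraph) -> str:
    lines = ["source\ttarget\tT\ttau\tp"]
    for e in g.edges:
        lines.append(f"{e.source}\t{e.target}\t{e.T:.10g}\t{e.tau:.10g}\t{e.p:.6g}")
    return "\n".join(lines) + "\n"


def _to_dot(g: CausalGraph) -> str:
    out = ["digraph causal {"]
    for loop in g.self_loops:
        attrs = [f'label="{loop.node}"']
        if loop.significant:
            attrs.append('peripheries=2')
        out.append(f'  "{loop.node}" [{", ".join(attrs)}];')
    for loop in g.self_loops:
        if loop.significant:
            out.append(
                f'  "{loop.node}" -> "{loop.node}" '
                f'[label="dH*={loop.dH_self:.3g}", style=dashed];'
            )
    for e in g.edges:
        out.append(f'  "{e.source}" -> "{e.target}" [label="T={e.T:.3g}"];')
    out.append("}")
    return "\n".join(out) + "\n"


def _to_adjacency(g: CausalGraph) -> str:
    d = len(g.nodes)
    idx = {n: i for i, n in enumerate(g.nodes)}
    mat = np.zeros((d, d))
    for e in g.edges:
        mat[idx[e.source], idx[e.target]] = e.T
    lines = ["\t".join(("",) + g.nodes)]
    for i, name in enumerate(g.nodes):
        lines.append(name + "\t" + "\t".join(f"{v:.10g}" for v in mat[i]))
    return "\n".join(lines) + "\n"


def export_graph(g: CausalGraph, format: str = "edgelist") -> str:
    """Serialise the graph; row/source-first conventions throughout.

    ``edgelist``: TSV of (source, target, T, tau, p); ``dot``: Graphviz text
    with self-loops as dashed loop edges; ``graphml``: typed edge/node
    attributes; ``adjacency``: d x d signed flow matrix with zeros for
    non-edges.
    """
    if format == "edgelist":
        return _to_edgelist(g)
    if format == "dot":
        return _to_dot(g)
    if format == "adjacency":
        return _to_adjacency(g)
    if format == "graphml":
        buf = io.BytesIO()
        nx.write_graphml(g.to_networkx(), buf)
        return buf.getvalue().decode("utf-8")
    raise ParameterError(f"unknown graph format {format!r}; choose from {_FORMATS}")


def import_graph(text: str, format: str = "edgelist") -> CausalGraph:
    """Parse a graph previously written by :func:`export_graph`.

    Supports ``edgelist`` and ``graphml`` (the formats that carry full edge
    attributes).  Self-loop statistics are recovered from graphml node
    attributes; the edgelist format does not carry them.
    """
    if format == "edgelist":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].split("\t")
        if header[:2] != ["source", "target"]:
            raise ParameterError("not an infoflow edgelist (missing header)")
        nodes: list[str] = []
        edges = []
        for ln in lines[1:]:
            s, t, T, tau, p = ln.split("\t")
            for n in (s, t):
                if n not in nodes:
                    nodes.append(n)
            edges.append(CausalEdge(s, t, float(T), float(tau), se=float("nan"), p=float(p)))
        loops = tuple(
            SelfLoop(n, float("nan"), float("nan"), float("nan"), False) for n in nodes
        )
        return CausalGraph(nodes=tuple(nodes), edges=tuple(edges), self_loops=loops)
    if format == "graphml":
        gx = nx.read_graphml(io.BytesIO(text.encode("utf-8")))
        nodes = tuple(gx.nodes)
        edges = tuple(
            CausalEdge(s, t, float(a["T"]), float(a["tau"]), float(a["se"]), float(a["p"]))
            for s, t, a in gx.edges(data=True)
        )
        loops = tuple(
            SelfLoop(
                n,
                float(gx.nodes[n].get("dH_self", "nan")),
                float(gx.nodes[n].get("self_se", "nan")),
                float(gx.nodes[n].get("self_p", "nan")),
                bool(gx.nodes[n].get("self_loop", False)),
            )
            for n in nodes
        )
        return CausalGraph(nodes=nodes, edges=edges, self_loops=loops)
    raise ParameterError(f"import supports edgelist and graphml, got {format!r}")
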