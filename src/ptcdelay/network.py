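"""Aggregate directed care-network graph of a cohort's pathways.

Every pathway contributes a walk Onset -> e1 -> ... -> eN -> STEP through
the node-type catalogue; stacking all walks yields a weighted directed
graph whose edge weights count transitions and whose node annotations count
encounters. Virtual terminals ``Onset`` and ``STEP`` are explicit nodes so
that flow conservation is checkable: every pathway enters the graph once at
Onset and leaves once at STEP, and at every caregiver node the in-flow,
out-flow and encounter count agree. Consecutive encounters at the same node
type are kept as self-loop traffic for the same reason.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .delays import DEMAND, decompose_delays
from .model import Cohort
from .nodes import ONSET, STEP, NODE_TYPES


@dataclass
class TransitionGraph:
    """Directed graph of aggregate node-to-node traffic.

    ``graph`` is a networkx DiGraph whose edges carry a ``count`` attribute
    and whose non-terminal nodes carry ``total``, ``demand``, ``supply``
    (encounter counts by side) and ``participants`` (unique participants).
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def n_pathways(self) -> int:
        return sum(d["count"] for _, _, d in
                   self.graph.out_edges(ONSET, data=True))

    def edge_count(self, u: str, v: str) -> int:
        return self.graph.edges[u, v]["count"] if self.graph.has_edge(u, v) else 0

    def node_stat(self, node: str, stat: str = "total") -> int:
        return self.graph.nodes[node].get(stat, 0)

    def check_flow_conservation(self) -> list[str]:
        """Return all violated balance identities (empty list = conserved)."""
        g = self.graph
        bad = []
        out_onset = sum(d["count"] for *_, d in g.out_edges(ONSET, data=True))
        in_step = sum(d["count"] for *_, d in g.in_edges(STEP, data=True))
        if out_onset != in_step:
            bad.append(f"Onset out-flow {out_onset} != STEP in-flow {in_step}")
        if g.in_degree(ONSET) != 0:
            bad.append("Onset has in-edges")
        if g.out_degree(STEP) != 0:
            bad.append("STEP has out-edges")
        for node in g.nodes:
            if node in (ONSET, STEP):
                continue
            inflow = sum(d["count"] for *_, d in g.in_edges(node, data=True))
            outflow = sum(d["count"] for *_, d in g.out_edges(node, data=True))
            total = g.nodes[node].get("total", 0)
            if not (inflow == outflow == total):
                bad.append(
                    f"{node}: in {inflow}, out {outflow}, encounters {total}")
        return bad


def build_transition_graph(c: Cohort) -> TransitionGraph:
    """Tally transition and encounter counts over every pathway in a cohort.

    Deterministic for a fixed cohort and invariant to participant order;
    merging two cohorts sums their graphs edge-by-edge.
    """
    if not c.pathways:
        raise ValueError("empty cohort")
    g = nx.DiGraph()
    g.add_node(ONSET)
    g.add_node(STEP)

    def bump_edge(u, v, side):
        # side stratification: a transition is labelled with the side of the
        # encounter it enters (source side for edges into STEP)
        if not g.has_edge(u, v):
            g.add_edge(u, v, count=0, demand=0, supply=0)
        g.edges[u, v]["count"] += 1
        g.edges[u, v][side] += 1

    seen: dict[str, set] = {}
    for pid in sorted(c.pathways):
        p = c.pathways[pid]
        d = decompose_delays(p)
        sides = {m.seq_index: m.side for m in d.marginal_delays}
        prev, prev_side = ONSET, DEMAND
        for e in p.encounters:
            if e.node_type not in g:
                g.add_node(e.node_type, total=0, demand=0, supply=0,
                           participants=0)
            nd = g.nodes[e.node_type]
            side = sides[e.seq_index]
            nd["total"] += 1
            nd["demand" if side == DEMAND else "supply"] += 1
            seen.setdefault(e.node_type, set()).add(pid)
            bump_edge(prev, e.node_type, side)
            prev, prev_side = e.node_type, side
        bump_edge(prev, STEP, prev_side)
    for node, pids in seen.items():
        g.nodes[node]["participants"] = len(pids)
    return TransitionGraph(graph=g)


# ---------------------------------------------------------------------------
# export / import

_NODE_FIELDS = ["node", "total", "demand", "supply", "participants"]
_EDGE_FIELDS = ["from", "to", "count", "demand", "supply"]


def export_graph(g: TransitionGraph, path, format: str) -> Path:
    """Write the graph as GraphViz DOT or as a node/edge count table.

    DOT scaling is purely presentational: edge penwidth grows linearly with
    transition count and node width with the square root of its encounter
    count (area roughly proportional to encounters), with a floor so rarely
    visited nodes stay legible. The CSV exports are lossless: re-importing
    the pair reconstructs the graph exactly.
    """
    path = Path(path)
    if format == "dot":
        path.write_text(_to_dot(g))
    elif format == "node_csv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(_NODE_FIELDS)
            for node in sorted(g.graph.nodes):
                if node in (ONSET, STEP):
                    continue
                nd = g.graph.nodes[node]
                w.writerow([node, nd["total"], nd["demand"], nd["supply"],
                            nd["participants"]])
    elif format == "edge_csv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(_EDGE_FIELDS)
            for u, v, d in sorted(g.graph.edges(data=True)):
                w.writerow([u, v, d["count"], d.get("demand", 0),
                            d.get("supply", 0)])
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path


def _to_dot(g: TransitionGraph) -> str:
    lines = ["digraph ptc {", "  rankdir=LR;"]
    max_total = max(
        [g.graph.nodes[n].get("total", 0) for n in g.graph.nodes], default=1
    ) or 1
    max_count = max(
        [d["count"] for *_, d in g.graph.edges(data=True)], default=1
    ) or 1
    for node in sorted(g.graph.nodes):
        if node in (ONSET, STEP):
            lines.append(f'  "{node}" [shape=doublecircle];')
            continue
        nd = g.graph.nodes[node]
        width = max(0.5, 2.5 * (nd["total"] / max_total) ** 0.5)
        shape = ("ellipse" if NODE_TYPES[node].value == "clinical" else "box")
        lines.append(
            f'  "{node}" [shape={shape}, width={width:.2f}, '
            f'label="{node}\\n{nd["total"]}"];'
        )
    for u, v, d in sorted(g.graph.edges(data=True)):
        pen = max(0.5, 6.0 * d["count"] / max_count)
        lines.append(
            f'  "{u}" -> "{v}" [penwidth={pen:.2f}, label="{d["count"]}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def import_graph(node_csv, edge_csv) -> TransitionGraph:
    """Rebuild a TransitionGraph from its exported CSV tables."""
    g = nx.DiGraph()
    g.add_node(ONSET)
    g.add_node(STEP)
    with Path(node_csv).open() as fh:
        for row in csv.DictReader(fh):
            g.add_node(row["node"], total=int(row["total"]),
                       demand=int(row["demand"]), supply=int(row["supply"]),
                       participants=int(row["participants"]))
    with Path(edge_csv).open() as fh:
        for row in csv.DictReader(fh):
            g.add_edge(row["from"], row["to"], count=int(row["count"]),
                       demand=int(row["demand"]), supply=int(row["supply"]))
    return TransitionGraph(graph=g)
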