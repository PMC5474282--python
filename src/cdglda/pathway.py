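"""Topic-label sequences and directly-follows process graphs.

Once each clinical day carries a small topic label (its dominant clinical
goals), a patient trace becomes a short sequence of labels and the
treatment process can be rendered as a directly-follows graph: nodes are
labels, an edge ℓ1→ℓ2 counts how often ℓ2 immediately follows ℓ1 across
traces.  This is a deliberately simple miner — order relations with
frequency thresholds — sufficient to recover a staged pathway from
day-level labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

__all__ = [
    "START",
    "END",
    "TopicSequence",
    "to_sequences",
    "directly_follows",
    "export_graph",
    "read_graphml",
]

START = "<start>"
END = "<end>"


@dataclass
class TopicSequence:
    """One trace as an ordered list of day labels (each a tuple of topic ids)."""

    trace_id: str
    labels: list  # list of sorted tuples of topic ids


def canonical(label) -> str:
    """Render a topic set as its canonical node name, e.g. ``"6,7,8"``."""
    return ",".join(str(k) for k in sorted(label))


def to_sequences(labels, corpus, collapse: bool = True):
    """Per-trace label sequences from per-day labels.

    ``labels[i]`` is the label of ``corpus.days[i]``.  Days are grouped by
    trace in day order; with ``collapse`` (default) consecutive identical
    labels are merged, so multi-day stretches of one clinical goal appear
    once.
    """
    if len(labels) != corpus.D:
        raise ValueError("need one label per clinical day")
    by_trace: dict = {}
    for i, day in enumerate(corpus.days):
        by_trace.setdefault(day.trace_id, []).append(i)
    sequences = []
    for trace_id, idx in by_trace.items():
        seq = []
        for i in idx:
            lab = tuple(sorted(labels[i]))
            if not lab:
                raise ValueError("day labels must be nonempty")
            if collapse and seq and seq[-1] == lab:
                continue
            seq.append(lab)
        sequences.append(TopicSequence(trace_id=trace_id, labels=seq))
    return sequences


def directly_follows(sequences, min_edge_freq: int = 1,
                     min_trace_support: int = 1) -> nx.DiGraph:
    """Build the directly-follows graph over label sequences.

    Interior edges below ``min_edge_freq`` total occurrences or
    ``min_trace_support`` distinct traces are removed; a node whose interior
    edges were all filtered away is dropped entirely, so a high enough
    threshold reduces the graph to its start/end markers.  Virtual
    ``<start>``/``<end>`` edges mark sequence boundaries and are never
    filtered themselves, so in the unfiltered graph the flow out of
    ``<start>`` equals the number of sequences.
    """
    if not sequences:
        raise ValueError("no sequences to mine")
    freq: dict = {}
    support: dict = {}
    for seq in sequences:
        nodes = [START] + [canonical(l) for l in seq.labels] + [END]
        seen = set()
        for a, b in zip(nodes[:-1], nodes[1:]):
            freq[(a, b)] = freq.get((a, b), 0) + 1
            if (a, b) not in seen:
                support[(a, b)] = support.get((a, b), 0) + 1
                seen.add((a, b))
    had_interior: set = set()
    survives: set = set()
    for (a, b), f in freq.items():
        if a == START or b == END:
            continue
        had_interior.update((a, b))
        if f >= min_edge_freq and support[(a, b)] >= min_trace_support:
            survives.update((a, b))
    dropped = had_interior - survives
    g = nx.DiGraph()
    g.add_node(START, kind="start")
    g.add_node(END, kind="end")
    for (a, b), f in freq.items():
        virtual = a == START or b == END
        if virtual:
            if a in dropped or b in dropped:
                continue
        elif a not in survives or b not in survives or (
                f < min_edge_freq or support[(a, b)] < min_trace_support):
            continue
        g.add_edge(a, b, freq=f, support=support[(a, b)])
    return g


def _dot_quote(s: str) -> str:
    return '"' + s.replace('"', r'\"') + '"'


def export_graph(graph: nx.DiGraph, path, fmt: str | None = None) -> None:
    """Write the graph as DOT (default, by extension) or GraphML.

    DOT node names are quoted so labels like ``"2,3"`` stay valid; edges
    carry their frequency as the edge label.
    """
    path = str(path)
    if fmt is None:
        fmt = "graphml" if path.endswith(".graphml") else "dot"
    if fmt == "graphml":
        nx.write_graphml(graph, path)
        return
    if fmt != "dot":
        raise ValueError(f"unknown format {fmt!r}")
    lines = ["digraph pathway {", "  rankdir=LR;"]
    for n, data in graph.nodes(data=True):
        shape = "circle" if data.get("kind") in ("start", "end") else "box"
        lines.append(f"  {_dot_quote(n)} [shape={shape}];")
    for a, b, data in graph.edges(data=True):
        label = str(data.get("freq", ""))
        lines.append(f"  {_dot_quote(a)} -> {_dot_quote(b)} [label={_dot_quote(label)}];")
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_graphml(path) -> nx.DiGraph:
    """Re-import a GraphML export (round-trip counterpart of :func:`export_graph`)."""
    return nx.read_graphml(path)
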