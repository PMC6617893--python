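"""Spacer graphs: construction, chain compression, orientation inference.

A *spacer graph* summarises a group of spacer-sharing CRISPR arrays: one node
per spacer-cluster label, and a directed edge u -> v with support k when v
immediately follows u in k array positions.  A single array (a, b, c, d)
yields four nodes and three edges; adding the array (a, d) adds the edge
a -> d, exposing a spacer-loss (or gain) variant as a branch.

The *compressed* spacer graph collapses non-branching chains of nodes into
blocks (the unitig-style contraction used for assembly graphs): an edge
u -> v is contracted when u has exactly one outgoing edge and v exactly one
incoming edge.  Maximal chains of contractible edges become blocks; all other
nodes stay as singleton blocks.  Every observed array then spells a
contiguous walk through blocks, entering or leaving a block part-way only at
its own (possibly fragmented) ends.  Blocks without incoming edges (sources)
tend to hold newly gained leader-end spacers; the block without outgoing
edges (sink) holds the conserved trailer-end "anchor" spacer.

Orientation of a group (which physical end is the leader) is inferred from
two independent signals and reported honestly when they disagree:

* terminal-repeat degeneracy — the repeat copy at the trailer end of an
  array is typically degenerate, so the end whose terminal repeats deviate
  more from the consensus repeat is called the trailer;
* graph topology — the leader end accumulates new spacers, so the side of
  the compressed graph with more, and more label-diverse, terminal blocks is
  called the leader.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

import networkx as nx

from .errors import DomainError, UndefinedScoreError, ValidationError
from .io_formats import CrisprArrayRecord, LabeledArray

logger = logging.getLogger(__name__)

Orientation = Literal["as_given", "reversed", "undetermined"]


# --- uncompressed graph ------------------------------------------------------

@dataclass
class SpacerGraph:
    """Directed adjacency graph of spacer-cluster labels for one group."""

    graph: nx.DiGraph
    array_paths: dict[str, list[int]]
    array_flags: dict[str, tuple[bool, bool]]

    @property
    def nodes(self) -> set[int]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> dict[tuple[int, int], int]:
        return {(u, v): d["support"] for u, v, d in self.graph.edges(data=True)}


def build_spacer_graph(arrays: Sequence[LabeledArray]) -> SpacerGraph:
    """One node per distinct label; edge support counts adjacent occurrences
    summed over all arrays and positions."""
    g = nx.DiGraph()
    paths: dict[str, list[int]] = {}
    flags: dict[str, tuple[bool, bool]] = {}
    for arr in arrays:
        if arr.array_id in paths:
            raise ValidationError(f"duplicate array id {arr.array_id!r}")
        paths[arr.array_id] = list(arr.labels)
        flags[arr.array_id] = (arr.left_complete, arr.right_complete)
        g.add_nodes_from(arr.labels)
        for u, v in zip(arr.labels, arr.labels[1:]):
            if g.has_edge(u, v):
                g[u][v]["support"] += 1
            else:
                g.add_edge(u, v, support=1)
    return SpacerGraph(graph=g, array_paths=paths, array_flags=flags)


# --- compression -------------------------------------------------------------

@dataclass
class Walk:
    """An array's route through the compressed graph.

    ``first_offset``/``last_offset`` locate the first and last label inside
    the first and last block — a fragmented array may enter or leave a block
    part-way, but only at its own ends.
    """

    block_ids: list[int]
    first_offset: int
    last_offset: int


@dataclass
class CompressedSpacerGraph:
    blocks: list[list[int]]
    block_edges: dict[tuple[int, int], int]
    walks: dict[str, Walk]
    array_flags: dict[str, tuple[bool, bool]]
    dominant_path: list[int] | None = None
    label_to_block: dict[int, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.label_to_block:
            for bid, block in enumerate(self.blocks):
                for off, lab in enumerate(block):
                    self.label_to_block[lab] = (bid, off)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def in_degree(self, bid: int) -> int:
        return sum(1 for (u, v) in self.block_edges if v == bid)

    def out_degree(self, bid: int) -> int:
        return sum(1 for (u, v) in self.block_edges if u == bid)

    @property
    def sources(self) -> list[int]:
        with_in = {v for (_, v) in self.block_edges}
        return [b for b in range(len(self.blocks)) if b not in with_in]

    @property
    def sinks(self) -> list[int]:
        with_out = {u for (u, _) in self.block_edges}
        return [b for b in range(len(self.blocks)) if b not in with_out]

    def walk_labels(self, array_id: str) -> list[int]:
        """Reconstruct an array's label sequence from its stored walk."""
        w = self.walks[array_id]
        if len(w.block_ids) == 1:
            return list(self.blocks[w.block_ids[0]][w.first_offset : w.last_offset + 1])
        labels = list(self.blocks[w.block_ids[0]][w.first_offset :])
        for bid in w.block_ids[1:-1]:
            labels.extend(self.blocks[bid])
        labels.extend(self.blocks[w.block_ids[-1]][: w.last_offset + 1])
        return labels


def compress(sg: SpacerGraph, *, strict_degree: bool = False) -> CompressedSpacerGraph:
    """Collapse non-branching chains of the spacer graph into blocks.

    The default contraction merges across an edge u -> v whenever u's only
    outgoing edge is (u, v) and v's only incoming edge is (u, v).  With
    ``strict_degree=True`` both endpoints must additionally have total
    in-degree and out-degree at most one, which declines to absorb chains
    that hang off a junction.  Labels occurring more than once within a
    single array are never merged (kept as singleton blocks) so that walks
    stay unambiguous.  Both rules reach an order-independent fixed point in
    one pass over maximal contractible chains, and the operation is
    idempotent.
    """
    g = sg.graph
    repeated: set[int] = set()
    for path in sg.array_paths.values():
        counts = Counter(path)
        repeated.update(lab for lab, c in counts.items() if c > 1)

    def contractible(u: int, v: int) -> bool:
        if u == v or u in repeated or v in repeated:
            return False
        if g.out_degree(u) != 1 or g.in_degree(v) != 1:
            return False
        if strict_degree and (g.in_degree(u) > 1 or g.out_degree(v) > 1):
            return False
        return True

    nxt: dict[int, int] = {}
    prv: dict[int, int] = {}
    for u, v in g.edges:
        if contractible(u, v):
            nxt[u] = v  # unique: out_degree(u) == 1
            prv[v] = u  # unique: in_degree(v) == 1

    blocks: list[list[int]] = []
    seen: set[int] = set()
    for node in g.nodes:
        if node in seen or node in prv:
            continue  # not a chain start
        chain = [node]
        seen.add(node)
        while chain[-1] in nxt:
            chain.append(nxt[chain[-1]])
            seen.add(chain[-1])
        blocks.append(chain)
    # isolated nodes unreachable above only if part of a cycle of chain edges;
    # a fully cyclic chain has no start — break it deterministically.
    for node in g.nodes:
        if node not in seen:
            chain = [node]
            seen.add(node)
            while chain[-1] in nxt and nxt[chain[-1]] not in seen:
                chain.append(nxt[chain[-1]])
                seen.add(chain[-1])
            blocks.append(chain)

    blocks.sort(key=lambda b: b[0])
    lab2block: dict[int, tuple[int, int]] = {}
    for bid, block in enumerate(blocks):
        for off, lab in enumerate(block):
            lab2block[lab] = (bid, off)

    block_edges: dict[tuple[int, int], int] = {}
    for u, v, d in g.edges(data=True):
        if nxt.get(u) == v:
            continue  # contracted inside a block
        bu, bv = lab2block[u][0], lab2block[v][0]
        block_edges[(bu, bv)] = block_edges.get((bu, bv), 0) + d["support"]

    walks: dict[str, Walk] = {}
    for aid, path in sg.array_paths.items():
        bids: list[int] = []
        first_off = 0
        prev_bid = prev_off = None
        for i, lab in enumerate(path):
            bid, off = lab2block[lab]
            if i == 0:
                bids.append(bid)
                first_off = off
            elif bid == prev_bid and off == prev_off + 1:
                pass  # advancing inside the current block
            else:
                if off != 0:  # mid-block entry is only legal at a walk start
                    raise ValidationError(
                        f"array {aid!r}: discontiguous walk at block {bid}"
                    )
                bids.append(bid)
            prev_bid, prev_off = bid, off
        walks[aid] = Walk(bids, first_off, prev_off if prev_off is not None else 0)

    return CompressedSpacerGraph(
        blocks=blocks,
        block_edges=block_edges,
        walks=walks,
        array_flags=dict(sg.array_flags),
    )


# --- dominant path and terminals ---------------------------------------------

def dominant_path(cgraph: CompressedSpacerGraph, arrays: Sequence[LabeledArray]) -> list[int]:
    """Block walk of the most frequently observed array organization.

    Organizations are counted over complete arrays (both ends captured) when
    any exist, since fragments of the dominant organization would otherwise
    dilute it; ties prefer the longer organization, then the
    lexicographically smallest.  The result is stored on the graph for
    rendering.
    """
    if not arrays:
        cgraph.dominant_path = []
        return []
    complete = [a for a in arrays if a.left_complete and a.right_complete]
    pool = complete if complete else list(arrays)
    counts = Counter(tuple(a.labels) for a in pool)
    best = min(counts, key=lambda org: (-counts[org], -len(org), org))
    rep = next(a for a in pool if tuple(a.labels) == best)
    walk = cgraph.walks[rep.array_id].block_ids
    cgraph.dominant_path = list(walk)
    return list(walk)


def classify_terminals(cgraph: CompressedSpacerGraph) -> tuple[list[int], list[int]]:
    """(source block ids, sink block ids) — no incoming / no outgoing edges."""
    return cgraph.sources, cgraph.sinks


# --- orientation -------------------------------------------------------------

@dataclass
class OrientationCall:
    group_id: int | None
    orientation: Orientation
    degeneracy_score: float | None
    topology_score: float | None
    confidence: Literal["high", "low"]


@dataclass
class TrailerReport:
    group_id: int | None
    anchor_label: int | None
    n_supporting: int
    n_eligible: int
    conservation: float | None


def _consensus_repeat(records: Sequence[CrisprArrayRecord]) -> str:
    all_repeats = [r for rec in records for r in rec.repeats]
    if not all_repeats:
        raise UndefinedScoreError("no repeats available for a consensus")
    modal_len = Counter(len(r) for r in all_repeats).most_common(1)[0][0]
    same_len = [r for r in all_repeats if len(r) == modal_len]
    cols = []
    for i in range(modal_len):
        counts = Counter(r[i] for r in same_len)
        # deterministic tie-break: higher count first, then base order
        base = min(counts, key=lambda b: (-counts[b], b))
        cols.append(base)
    return "".join(cols)


def _repeat_mismatches(repeat: str, consensus: str) -> int:
    m = sum(1 for a, b in zip(repeat, consensus) if a != b)
    return m + abs(len(repeat) - len(consensus))


def repeat_degeneracy_score(records: Sequence[CrisprArrayRecord]) -> float:
    """Mean mismatch excess of trailer-side terminal repeats over leader-side.

    Computed against the majority-consensus repeat: (mean mismatches of the
    last repeat, over arrays with a complete right end) minus (mean
    mismatches of the first repeat, over arrays with a complete left end).
    Positive means the right end is the more degenerate — i.e. the trailer,
    under the convention that the trailer-end repeat copy decays.  Raises
    :class:`UndefinedScoreError` when either side has no complete end to
    measure.
    """
    consensus = _consensus_repeat(records)
    left = [
        _repeat_mismatches(rec.repeats[0], consensus)
        for rec in records
        if rec.left_complete and rec.repeats
    ]
    right = [
        _repeat_mismatches(rec.repeats[-1], consensus)
        for rec in records
        if rec.right_complete and rec.repeats
    ]
    if not left or not right:
        raise UndefinedScoreError(
            "repeat degeneracy undefined: no complete end on one or both sides"
        )
    return sum(right) / len(right) - sum(left) / len(left)


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def infer_orientation(
    records: Sequence[CrisprArrayRecord],
    cgraph: CompressedSpacerGraph,
    group_id: int | None = None,
) -> OrientationCall:
    """Combine repeat degeneracy with compressed-graph topology.

    The topology score counts *excess* terminal blocks on each side —
    ``(n_sources - 1) x labels held by sources`` minus the same for sinks.
    New spacers accumulate at the leader, so gained variants splay into
    multiple source blocks, while the conserved trailer funnels into one
    sink; a graph with exactly one source and one sink (e.g. a single
    internal loss variant) is topologically uninformative and scores zero.
    Agreement of both signs gives a high-confidence call; a single
    informative signal gives a low-confidence call; disagreement is surfaced
    as ``undetermined`` with both scores reported rather than silently
    resolved.
    """
    try:
        deg: float | None = repeat_degeneracy_score(records)
    except UndefinedScoreError:
        deg = None

    sources, sinks = cgraph.sources, cgraph.sinks
    src_div = sum(len(cgraph.blocks[b]) for b in sources)
    sink_div = sum(len(cgraph.blocks[b]) for b in sinks)
    topo = float(
        max(len(sources) - 1, 0) * src_div - max(len(sinks) - 1, 0) * sink_div
    )

    s_d = _sign(deg) if deg is not None else 0
    s_t = _sign(topo)

    def _orient(s: int) -> Orientation:
        return "as_given" if s > 0 else "reversed"

    if s_d == 0 and s_t == 0:
        orientation, confidence = "undetermined", "low"
    elif s_d == 0:
        orientation, confidence = _orient(s_t), "low"
    elif s_t == 0:
        orientation, confidence = _orient(s_d), "low"
    elif s_d == s_t:
        orientation, confidence = _orient(s_d), "high"
    else:
        logger.warning(
            "group %s: degeneracy (%.3g) and topology (%.3g) signals conflict; "
            "orientation left undetermined",
            group_id, deg, topo,
        )
        orientation, confidence = "undetermined", "low"
    return OrientationCall(
        group_id=group_id,
        orientation=orientation,
        degeneracy_score=deg,
        topology_score=topo,
        confidence=confidence,
    )


def trailer_conservation(
    arrays: Sequence[LabeledArray],
    orientation: Orientation,
    group_id: int | None = None,
) -> TrailerReport:
    """Modal trailer-end spacer (the "anchor") and its conservation.

    Only arrays whose trailer-side end is complete are eligible — a
    fragmented end says nothing about the true terminal spacer.  With the
    arrays as given, the trailer is the right end; under ``reversed`` it is
    the left end.  Conservation is the fraction of eligible arrays whose
    trailer-end label equals the anchor (undefined when nothing is eligible).
    """
    if orientation == "undetermined":
        raise DomainError("trailer conservation needs a resolved orientation")
    if orientation == "as_given":
        eligible = [a for a in arrays if a.right_complete]
        ends = [a.labels[-1] for a in eligible]
    else:
        eligible = [a for a in arrays if a.left_complete]
        ends = [a.labels[0] for a in eligible]
    if not ends:
        return TrailerReport(group_id, None, 0, 0, None)
    counts = Counter(ends)
    anchor = min(counts, key=lambda lab: (-counts[lab], lab))
    n_sup = counts[anchor]
    return TrailerReport(group_id, anchor, n_sup, len(ends), n_sup / len(ends))
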