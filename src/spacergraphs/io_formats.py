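"""On-disk representations of CRISPR arrays, spacer clusters, array groups and graphs.

A CRISPR array extracted from a single long read is an ordered run of
repeat/spacer units.  Because reads are finite, an array may be truncated at
either end; the two completeness flags record whether each end of the locus
was captured intact on the read (a truncated end can never contribute
terminal-end evidence downstream).  Coordinates are 0-based half-open
throughout, and spacer order always follows the read as sequenced
(left to right).

File formats
------------
* array table — tab-separated, header ``array_id  read_id  left_complete
  right_complete  spacers  repeats`` (optionally ``read_start  read_end``);
  sequence lists are semicolon-delimited, booleans are serialized as 0/1.
* spacer FASTA — standard multi-line FASTA.
* cluster table — ``spacer_id  cluster_id  is_representative``.
* group table — ``group_id  array_id  reference_flag``.
* graphs — Graphviz DOT (leader end drawn on the left).

The native output of upstream CRISPR detectors is deliberately not parsed
here; converting a detector's output into the array table above is an
extension point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from Bio import SeqIO

from .errors import ParseError, ValidationError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .spacer_graph import CompressedSpacerGraph

DNA_ALPHABET = frozenset("ACGTN")

ARRAY_TSV_COLUMNS = (
    "array_id",
    "read_id",
    "left_complete",
    "right_complete",
    "spacers",
    "repeats",
)


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValidationError(f"empty {what} sequence")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValidationError(f"non-DNA character(s) {sorted(bad)} in {what}")
    return seq


@dataclass
class CrisprArrayRecord:
    """One CRISPR array observed on one read.

    ``repeats`` holds one sequence per repeat unit; a fully captured array
    carries ``len(spacers) + 1`` repeats (both flanks present), while an
    array truncated inside a terminal repeat may carry ``len(spacers)``.
    When ``left_complete`` is true, ``repeats[0]`` is the intact left
    flanking repeat (symmetrically for the right end).
    """

    array_id: str
    read_id: str
    spacers: list[str]
    repeats: list[str]
    left_complete: bool
    right_complete: bool
    source_interval: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        if not self.spacers:
            raise ValidationError(f"array {self.array_id!r}: no spacers")
        self.spacers = [_check_dna(s, "spacer") for s in self.spacers]
        self.repeats = [_check_dna(r, "repeat") for r in self.repeats]
        n, m = len(self.spacers), len(self.repeats)
        if m not in (n, n + 1):
            raise ValidationError(
                f"array {self.array_id!r}: {m} repeats for {n} spacers "
                f"(expected {n} or {n + 1})"
            )


@dataclass
class LabeledArray:
    """A CRISPR array reduced to its ordered spacer-cluster labels."""

    array_id: str
    labels: list[int]
    left_complete: bool = True
    right_complete: bool = True

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValidationError(f"array {self.array_id!r}: no labels")


def _parse_bool(token: str, line: int) -> bool:
    t = token.strip().lower()
    if t in ("1", "true"):
        return True
    if t in ("0", "false"):
        return False
    raise ParseError(f"cannot parse boolean {token!r}", line)


def _split_seqs(token: str, what: str, line: int) -> list[str]:
    parts = token.split(";") if token else []
    out = []
    for p in parts:
        if not p:
            raise ParseError(f"empty {what} field in {token!r}", line)
        if set(p.upper()) - DNA_ALPHABET:
            raise ParseError(f"non-DNA character in {what} {p!r}", line)
        out.append(p.upper())
    return out


def read_arrays_tsv(path: str | Path) -> list[CrisprArrayRecord]:
    """Read an array table; raises :class:`ParseError` with the line number
    on malformed rows and :class:`ValidationError` on duplicate array ids."""
    path = Path(path)
    records: list[CrisprArrayRecord] = []
    seen: set[str] = set()
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(ARRAY_TSV_COLUMNS)] != list(ARRAY_TSV_COLUMNS):
            raise ParseError(
                f"unexpected header {header!r}; expected columns "
                f"{list(ARRAY_TSV_COLUMNS)}",
                1,
            )
        has_interval = header[len(ARRAY_TSV_COLUMNS):][:2] == ["read_start", "read_end"]
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            fields = raw.split("\t")
            want = len(ARRAY_TSV_COLUMNS) + (2 if has_interval else 0)
            if len(fields) != want:
                raise ParseError(
                    f"expected {want} columns, found {len(fields)}", lineno
                )
            array_id, read_id, lc, rc, spacers_f, repeats_f = fields[:6]
            if array_id in seen:
                raise ValidationError(f"duplicate array_id {array_id!r}")
            seen.add(array_id)
            spacers = _split_seqs(spacers_f, "spacer", lineno)
            if not spacers:
                raise ParseError("no spacers in row", lineno)
            repeats = _split_seqs(repeats_f, "repeat", lineno)
            interval = None
            if has_interval:
                try:
                    interval = (read_id, int(fields[6]), int(fields[7]))
                except ValueError as exc:
                    raise ParseError(f"bad interval: {exc}", lineno) from exc
            try:
                rec = CrisprArrayRecord(
                    array_id=array_id,
                    read_id=read_id,
                    spacers=spacers,
                    repeats=repeats,
                    left_complete=_parse_bool(lc, lineno),
                    right_complete=_parse_bool(rc, lineno),
                    source_interval=interval,
                )
            except ValidationError as exc:
                raise ParseError(str(exc), lineno) from exc
            records.append(rec)
    return records


def write_arrays_tsv(records: Iterable[CrisprArrayRecord], path: str | Path) -> None:
    path = Path(path)
    any_interval = any(r.source_interval is not None for r in records)
    cols = list(ARRAY_TSV_COLUMNS) + (["read_start", "read_end"] if any_interval else [])
    with path.open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [
                r.array_id,
                r.read_id,
                "1" if r.left_complete else "0",
                "1" if r.right_complete else "0",
                ";".join(r.spacers),
                ";".join(r.repeats),
            ]
            if any_interval:
                if r.source_interval is None:
                    raise ValidationError(
                        f"array {r.array_id!r}: missing source interval in a "
                        "table that carries intervals"
                    )
                row += [str(r.source_interval[1]), str(r.source_interval[2])]
            fh.write("\t".join(row) + "\n")


def read_spacer_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercased sequence) pairs."""
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        out.append((rec.id, str(rec.seq).upper()))
    return out


def write_spacer_fasta(spacers: Iterable[tuple[str, str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sid, seq in spacers:
            fh.write(f">{sid}\n{seq}\n")


def write_clusters_tsv(cluster_map, path: str | Path) -> None:
    """Write a spacer-cluster assignment table (``spacer_id  cluster_id
    is_representative``)."""
    with Path(path).open("w") as fh:
        fh.write("spacer_id\tcluster_id\tis_representative\n")
        for cl in cluster_map.clusters:
            for sid in cl.member_ids:
                rep = "1" if sid == cl.representative_id else "0"
                fh.write(f"{sid}\t{cl.cluster_id}\t{rep}\n")


def read_clusters_tsv(path: str | Path):
    """Read a cluster table back into a :class:`~spacergraphs.spacer_clustering.SpacerClusterMap`.

    The identity threshold and strand mode are not stored in the table; the
    returned map carries the package defaults for provenance only.
    """
    from .spacer_clustering import SpacerCluster, SpacerClusterMap

    members: dict[int, list[str]] = {}
    reps: dict[int, str] = {}
    assignment: dict[str, int] = {}
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["spacer_id", "cluster_id", "is_representative"]:
            raise ParseError(f"unexpected cluster table header {header!r}", 1)
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            try:
                sid, cid_s, rep_s = raw.split("\t")
                cid = int(cid_s)
            except ValueError as exc:
                raise ParseError(f"malformed row: {exc}", lineno) from exc
            if sid in assignment:
                raise ValidationError(f"spacer {sid!r} assigned twice")
            assignment[sid] = cid
            members.setdefault(cid, []).append(sid)
            if rep_s == "1":
                if cid in reps:
                    raise ValidationError(f"cluster {cid} has two representatives")
                reps[cid] = sid
    clusters = []
    for cid in sorted(members):
        if cid not in reps:
            raise ValidationError(f"cluster {cid} has no representative")
        clusters.append(SpacerCluster(cid, reps[cid], members[cid]))
    return SpacerClusterMap(clusters=clusters, assignment=assignment)


def write_groups_tsv(groups, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("group_id\tarray_id\treference_flag\n")
        for g in groups:
            for aid in g.member_array_ids:
                ref = "1" if aid == g.reference_array_id else "0"
                fh.write(f"{g.group_id}\t{aid}\t{ref}\n")


def read_groups_tsv(path: str | Path):
    from .array_clustering import ArrayGroup

    members: dict[int, list[str]] = {}
    refs: dict[int, str] = {}
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["group_id", "array_id", "reference_flag"]:
            raise ParseError(f"unexpected group table header {header!r}", 1)
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            try:
                gid_s, aid, ref_s = raw.split("\t")
                gid = int(gid_s)
            except ValueError as exc:
                raise ParseError(f"malformed row: {exc}", lineno) from exc
            members.setdefault(gid, []).append(aid)
            if ref_s == "1":
                refs[gid] = aid
    groups = []
    for gid in sorted(members):
        if gid not in refs:
            raise ValidationError(f"group {gid} has no reference array")
        groups.append(ArrayGroup(gid, refs[gid], members[gid]))
    return groups


# --- Graphviz DOT export -----------------------------------------------------

_SOURCE_FILL = "#87CEFA"  # light blue: likely newly gained spacers
_SINK_FILL = "#FFD700"    # yellow: the conserved trailer (anchor) end


def block_display_label(block: Sequence[int]) -> str:
    """Human-readable label for a block of spacer-cluster ids, e.g. ``7-11``."""
    if len(block) == 1:
        return str(block[0])
    return f"{block[0]}-{block[-1]}"


def write_dot(
    cgraph: "CompressedSpacerGraph",
    path: str | Path,
    *,
    graph_name: str = "spacer_graph",
    highlight_dominant: bool = True,
) -> None:
    """Render a compressed spacer graph as Graphviz DOT.

    Source blocks (no incoming edges) are filled blue — they tend to hold
    newly gained leader-end spacers; sink blocks (no outgoing edges) are
    filled yellow — the conserved trailer/anchor end.  A block that is both
    source and sink (a group without branching) takes the sink styling.
    Edges on the dominant path — the most frequent array organization — are
    drawn red and every edge is labeled with its support count.
    The graph is laid out left to right so the leader end sits on the left.
    """
    dom_edges: set[tuple[int, int]] = set()
    if highlight_dominant and cgraph.dominant_path:
        walk = cgraph.dominant_path
        dom_edges = set(zip(walk, walk[1:]))
    lines = [f"digraph {graph_name} {{", "  rankdir=LR;", '  node [shape=box, style=filled, fillcolor=white];']
    sources = set(cgraph.sources)
    sinks = set(cgraph.sinks)
    for bid, block in enumerate(cgraph.blocks):
        attrs = [f'label="{block_display_label(block)}"']
        if bid in sinks:  # sink styling wins for isolated single blocks
            attrs.append(f'fillcolor="{_SINK_FILL}"')
        elif bid in sources:
            attrs.append(f'fillcolor="{_SOURCE_FILL}"')
        lines.append(f"  b{bid} [{', '.join(attrs)}];")
    for (u, v), support in sorted(cgraph.block_edges.items()):
        attrs = [f'label="{support}"']
        if (u, v) in dom_edges:
            attrs.append('color="red"')
        lines.append(f"  b{u} -> b{v} [{', '.join(attrs)}];")
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
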