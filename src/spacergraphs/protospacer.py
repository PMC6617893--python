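"""Intra-sample protospacer search: match spacers back against raw reads.

Each spacer was originally copied from an invader genome (its protospacer).
Searching spacers against reads from the *same* sample finds invader
sequences co-existing with the defending hosts.  Matches that fall inside a
predicted CRISPR array are not protospacers — they are the spacer itself —
so any hit overlapping a declared CRISPR interval by at least one base is
retained but flagged ``excluded`` (auditable, never silently dropped).
Reads with at least one surviving hit are the putative invader reads.

The matcher is a deterministic seed-and-extend scan: exact k-mer seeds
(k = 12 by default, both strands) anchor a banded full-spacer alignment
around each seed; spacers shorter than k fall back to an exhaustive
alignment scan of every read.  Self-targeting spacers are reported like any
other hit — whether a match is genuinely an invader must be judged case by
case downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import edlib

from .errors import DomainError, ValidationError
from .spacer_clustering import reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_SEED_K = 12
DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MIN_COVERAGE = 0.95
_BAND = 5  # slack around a seed-implied window, in bp

# N must not match anything in identity computations; edlib treats equal
# letters as equal, so N is recoded differently in queries and targets.
_QUERY_N = str.maketrans("N", "#")
_TARGET_N = str.maketrans("N", "%")


@dataclass
class ProtospacerHit:
    spacer_cluster_id: str
    read_id: str
    start: int  # 0-based half-open on the read
    end: int
    strand: Literal["+", "-"]
    identity: float
    coverage: float
    excluded: bool = False
    exclusion_reason: Literal["in_crispr_region", "none"] = "none"


def _align_stats(spacer: str, window: str) -> tuple[int, int, int, int] | None:
    """Best infix alignment of ``spacer`` in ``window``.

    Returns (matches, aligned_query_bases, start, end) with end exclusive,
    or None when no alignment exists.
    """
    res = edlib.align(
        spacer.translate(_QUERY_N),
        window.translate(_TARGET_N),
        mode="HW",
        task="path",
    )
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end_incl = res["locations"][0]
    if start is None:
        start = 0
    matches = aligned = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            matches += n
            aligned += n
        elif ch == "X":
            aligned += n
    return matches, aligned, start, end_incl + 1


def _overlaps(intervals: Sequence[tuple[int, int]], start: int, end: int) -> bool:
    return any(s < end and start < e for s, e in intervals)


def find_protospacers(
    spacers: Sequence[tuple[str, str]],
    reads: Sequence[tuple[str, str]],
    crispr_intervals: Iterable[tuple[str, int, int]] = (),
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    seed_k: int = DEFAULT_SEED_K,
) -> list[ProtospacerHit]:
    """Locate candidate protospacers for ``(id, sequence)`` spacers in reads.

    ``crispr_intervals`` are 0-based half-open ``(read_id, start, end)``
    spans of predicted CRISPR arrays; hits overlapping one are flagged
    ``excluded="in_crispr_region"``.  Hits are reported when identity (of
    the whole spacer) >= ``min_identity`` and aligned coverage >=
    ``min_coverage``, ordered by (read_id, start, spacer id).
    """
    if not 0 < min_identity <= 1 or not 0 < min_coverage <= 1:
        raise DomainError("identity/coverage thresholds must be in (0, 1]")
    read_ids = {rid for rid, _ in reads}
    if len(read_ids) != len(reads):
        raise ValidationError("duplicate read ids")
    by_read: dict[str, list[tuple[int, int]]] = {}
    for rid, s, e in crispr_intervals:
        if rid not in read_ids:
            logger.warning("CRISPR interval on unknown read %r ignored", rid)
            continue
        by_read.setdefault(rid, []).append((s, e))

    # Seed index: k-mer -> (spacer index, strand, offset of k-mer in the
    # oriented spacer).  The oriented spacer is the sequence as it would
    # appear on the read's forward strand.
    oriented: list[tuple[str, str, str]] = []  # (spacer_id, strand, seq)
    for sid, seq in spacers:
        if not seq:
            raise ValidationError(f"spacer {sid!r} has empty sequence")
        seq = seq.upper()
        oriented.append((sid, "+", seq))
        rc = reverse_complement(seq)
        if rc != seq:
            oriented.append((sid, "-", rc))

    seeds: dict[str, list[tuple[int, int]]] = {}
    short: list[int] = []  # oriented indices needing exhaustive scan
    for oi, (_, _, seq) in enumerate(oriented):
        if len(seq) < seed_k:
            short.append(oi)
            continue
        for off in range(len(seq) - seed_k + 1):
            kmer = seq[off : off + seed_k]
            if "N" in kmer:
                continue
            seeds.setdefault(kmer, []).append((oi, off))

    hits: dict[tuple[str, str, int, str], ProtospacerHit] = {}

    def _try(oi: int, rid: str, rseq: str, est_start: int) -> None:
        sid, strand, sseq = oriented[oi]
        w_start = max(0, est_start - _BAND)
        w_end = min(len(rseq), est_start + len(sseq) + _BAND)
        stats = _align_stats(sseq, rseq[w_start:w_end])
        if stats is None:
            return
        matches, aligned, a_start, a_end = stats
        identity = matches / len(sseq)
        coverage = aligned / len(sseq)
        if identity < min_identity or coverage < min_coverage:
            return
        start, end = w_start + a_start, w_start + a_end
        key = (rid, sid, start, strand)
        if key in hits and hits[key].identity >= identity:
            return
        excl = _overlaps(by_read.get(rid, ()), start, end)
        hits[key] = ProtospacerHit(
            spacer_cluster_id=sid,
            read_id=rid,
            start=start,
            end=end,
            strand=strand,
            identity=identity,
            coverage=coverage,
            excluded=excl,
            exclusion_reason="in_crispr_region" if excl else "none",
        )

    for rid, rseq in reads:
        rseq = rseq.upper()
        if seeds:
            tried: set[tuple[int, int]] = set()
            for pos in range(len(rseq) - seed_k + 1):
                kmer = rseq[pos : pos + seed_k]
                for oi, off in seeds.get(kmer, ()):
                    est = pos - off
                    key = (oi, est)
                    if key in tried:
                        continue
                    tried.add(key)
                    _try(oi, rid, rseq, est)
        for oi in short:
            # exhaustive fallback: scan the whole read for tiny spacers
            sid, strand, sseq = oriented[oi]
            res = edlib.align(
                sseq.translate(_QUERY_N),
                rseq.translate(_TARGET_N),
                mode="HW",
                task="locations",
                k=int(len(sseq) * (1 - min_identity)) + 1,
            )
            if res["editDistance"] < 0:
                continue
            for loc_start, _ in res["locations"]:
                _try(oi, rid, rseq, loc_start or 0)

    out = sorted(
        hits.values(), key=lambda h: (h.read_id, h.start, h.spacer_cluster_id, h.strand)
    )
    return out


def invader_read_set(hits: Iterable[ProtospacerHit]) -> list[str]:
    """Reads with at least one non-excluded hit: putative invader sources,
    the input set a long-read assembler would take downstream."""
    return sorted({h.read_id for h in hits if not h.excluded})


def write_hits_tsv(hits: Sequence[ProtospacerHit], path) -> None:
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write(
            "spacer_cluster_id\tread_id\tstart\tend\tstrand\tidentity\t"
            "coverage\texcluded\texclusion_reason\n"
        )
        for h in hits:
            fh.write(
                f"{h.spacer_cluster_id}\t{h.read_id}\t{h.start}\t{h.end}\t"
                f"{h.strand}\t{h.identity:.4f}\t{h.coverage:.4f}\t"
                f"{1 if h.excluded else 0}\t{h.exclusion_reason}\n"
            )
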