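"""Greedy identity clustering of spacer sequences.

Spacers extracted from different reads may differ by a few bases through
sequencing error or genuine point mutation, yet still represent the same
acquisition event.  Clustering spacers at 90% identity and treating each
cluster as one spacer identity turns every CRISPR array into a sequence of
integer labels, which is the representation all downstream comparison works
on.

The clustering follows the greedy longest-first scheme of classic sequence
clusterers: sequences are sorted by length (descending), each sequence joins
the first existing cluster whose *representative* it matches at or above the
identity threshold, otherwise it founds a new cluster.  Membership is only
ever checked against representatives, so the procedure is deterministic and
single-pass.

Identity between two sequences is the number of aligned matching bases from
an optimal alignment (gaps free, so the match count equals the length of the
longest common subsequence) divided by the length of the shorter sequence —
the shorter-sequence denominator mirrors cd-hit's convention and lets a
fragmented spacer co-cluster with its full-length form.  ``N`` bases never
match anything, including other ``N`` s.  Under ``strand_mode="both"`` a pair
is scored on both the given strand and the reverse complement, and the better
strand counts: spacers called from arrays reported on opposite strands must
co-cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import DomainError, ValidationError
from .io_formats import CrisprArrayRecord, LabeledArray

StrandMode = Literal["both", "forward"]

DEFAULT_IDENTITY_THRESHOLD = 0.90

# Base encoding: A/C/G/T -> 1..4, N (and padding) -> 0; code 0 never matches.
_ENCODE = np.zeros(256, dtype=np.int8)
for _i, _b in enumerate("ACGT", start=1):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _lcs_matches_batch(query: np.ndarray, targets: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Match counts (LCS lengths) of ``query`` against each padded row of
    ``targets``; padding is code 0 and never matches."""
    n_t, width = targets.shape
    # dp[:, j] = best match count of full query vs target[:j]
    dp = np.zeros((n_t, width + 1), dtype=np.int32)
    for c in query:
        if c == 0:  # N in the query matches nothing; row is unchanged
            continue
        diag = dp[:, :-1] + (targets == c)
        np.maximum(dp[:, 1:], diag, out=diag)
        dp[:, 1:] = np.maximum.accumulate(diag, axis=1)
    return dp[np.arange(n_t), lengths]


def sequence_identity(a: str, b: str, strand_mode: StrandMode = "both") -> float:
    """Fractional identity of two DNA sequences in ``[0, 1]``.

    Defined as aligned match count over the length of the shorter sequence;
    symmetric in its arguments.  With ``strand_mode="both"`` the reverse
    complement of ``b`` is also tried and the larger identity returned.
    """
    if not a or not b:
        raise DomainError("sequence_identity requires non-empty sequences")
    qa = _encode(a)
    variants = [b] if strand_mode == "forward" else [b, reverse_complement(b)]
    rows = np.zeros((len(variants), max(len(v) for v in variants)), dtype=np.int8)
    lengths = np.empty(len(variants), dtype=np.int64)
    for i, v in enumerate(variants):
        enc = _encode(v)
        rows[i, : len(enc)] = enc
        lengths[i] = len(enc)
    matches = _lcs_matches_batch(qa, rows, lengths)
    return float(matches.max()) / min(len(a), len(b))


@dataclass
class SpacerCluster:
    cluster_id: int
    representative_id: str
    member_ids: list[str]


@dataclass
class SpacerClusterMap:
    """A partition of spacer sequences into identity clusters."""

    clusters: list[SpacerCluster]
    assignment: dict[str, int]
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
    strand_mode: StrandMode = "both"

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_spacers(self) -> int:
        return len(self.assignment)


def cluster_spacers(
    spacers: Sequence[tuple[str, str]],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    strand_mode: StrandMode = "both",
) -> SpacerClusterMap:
    """Greedily cluster ``(id, sequence)`` pairs at ``threshold`` identity.

    Sequences are processed longest first (ties broken by id, ascending); a
    sequence joins the first cluster, in founding order, whose representative
    it matches at >= ``threshold``, else it founds a new cluster.  Exact
    duplicate sequences are collapsed before alignment — they necessarily
    receive the same assignment — which makes highly redundant spacer sets
    (the long-read regime) cheap to cluster.
    """
    if not 0.0 < threshold <= 1.0:
        raise DomainError(f"identity threshold {threshold} outside (0, 1]")
    ids = [sid for sid, _ in spacers]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate spacer ids: {dupes[:5]}")
    for sid, seq in spacers:
        if not seq:
            raise ValidationError(f"spacer {sid!r} has empty sequence")

    # Collapse exact duplicates (case-insensitive) keeping first-seen order
    # of the unique sequence under the same (length desc, id asc) sort key.
    order = sorted(spacers, key=lambda p: (-len(p[1]), p[0]))
    uniq: dict[str, list[str]] = {}
    for sid, seq in order:
        uniq.setdefault(seq.upper(), []).append(sid)

    rep_rows: list[np.ndarray] = []  # encoded representatives (fwd)
    rep_seqs: list[str] = []
    clusters: list[SpacerCluster] = []
    assignment: dict[str, int] = {}
    width = 0

    rep_matrix = np.zeros((0, 0), dtype=np.int8)
    rep_lengths = np.zeros(0, dtype=np.int64)

    for seq, members in uniq.items():
        target = None
        if clusters:
            q_fwd = _encode(seq)
            matches = _lcs_matches_batch(q_fwd, rep_matrix, rep_lengths)
            if strand_mode == "both":
                q_rev = _encode(reverse_complement(seq))
                matches = np.maximum(matches, _lcs_matches_batch(q_rev, rep_matrix, rep_lengths))
            denom = np.minimum(len(seq), rep_lengths)
            hits = np.nonzero(matches >= threshold * denom - 1e-9)[0]
            if hits.size:
                target = int(hits[0])
        if target is None:
            cid = len(clusters)
            clusters.append(SpacerCluster(cid, members[0], list(members)))
            enc = _encode(seq)
            rep_rows.append(enc)
            rep_seqs.append(seq)
            if len(enc) > width:
                width = len(enc)
                rep_matrix = np.zeros((len(rep_rows), width), dtype=np.int8)
                for i, row in enumerate(rep_rows):
                    rep_matrix[i, : len(row)] = row
            else:
                rep_matrix = np.vstack([rep_matrix, np.pad(enc, (0, width - len(enc)))])
            rep_lengths = np.append(rep_lengths, len(enc))
        else:
            cid = clusters[target].cluster_id
            clusters[target].member_ids.extend(members)
        for sid in members:
            assignment[sid] = cid

    return SpacerClusterMap(
        clusters=clusters,
        assignment=assignment,
        identity_threshold=threshold,
        strand_mode=strand_mode,
    )


def collect_spacers(records: Iterable[CrisprArrayRecord]) -> list[tuple[str, str]]:
    """Enumerate every spacer of every array as ``(array_id:position, seq)``."""
    out = []
    for rec in records:
        for i, seq in enumerate(rec.spacers):
            out.append((f"{rec.array_id}:{i}", seq))
    return out


def label_arrays(
    records: Iterable[CrisprArrayRecord], cluster_map: SpacerClusterMap
) -> list[LabeledArray]:
    """Rewrite each array as its ordered sequence of spacer-cluster labels."""
    labeled = []
    for rec in records:
        labels = []
        for i in range(len(rec.spacers)):
            key = f"{rec.array_id}:{i}"
            if key not in cluster_map.assignment:
                raise ValidationError(f"spacer {key!r} missing from cluster map")
            labels.append(cluster_map.assignment[key])
        labeled.append(
            LabeledArray(
                array_id=rec.array_id,
                labels=labels,
                left_complete=rec.left_complete,
                right_complete=rec.right_complete,
            )
        )
    return labeled
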