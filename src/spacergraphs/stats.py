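"""Dataset-level summaries: spacer redundancy and per-group reports."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .array_clustering import ArrayGroup
from .errors import DomainError
from .spacer_graph import CompressedSpacerGraph, OrientationCall, TrailerReport

logger = logging.getLogger(__name__)


@dataclass
class RedundancyReport:
    """Spacer redundancy: predicted spacers per spacer cluster.

    Long reads observe the same spacer on many overlapping arrays, so their
    redundancy is high (~9 in a gut microbiome), whereas short-read
    assemblies collapse repeats and hover near 1 — redundancy is the signal
    that array-dynamics analysis is possible at all.
    """

    n_spacers: int
    n_clusters: int

    @property
    def redundancy(self) -> float:
        return self.n_spacers / self.n_clusters

    def rounded(self, ndigits: int = 2) -> float:
        """Presentation-layer rounding; internal value keeps full precision."""
        return round(self.redundancy, ndigits)


def redundancy(n_spacers: int, n_clusters: int) -> RedundancyReport:
    if n_clusters < 1:
        raise DomainError("redundancy undefined for zero clusters")
    if n_spacers < n_clusters:
        raise DomainError(
            f"{n_spacers} spacers cannot fall into {n_clusters} non-empty clusters"
        )
    return RedundancyReport(n_spacers=n_spacers, n_clusters=n_clusters)


def group_report(
    groups: Sequence[ArrayGroup],
    graphs: Mapping[int, CompressedSpacerGraph],
    trailer_reports: Mapping[int, TrailerReport] | None = None,
    orientations: Mapping[int, OrientationCall] | None = None,
) -> pd.DataFrame:
    """One descriptive row per group.

    Columns: group size, distinct labels, block/source/sink counts from the
    compressed graph, anchor conservation, and the orientation call.  Groups
    without a graph (e.g. below the reporting size) keep empty graph fields.
    """
    trailer_reports = trailer_reports or {}
    orientations = orientations or {}
    rows = []
    for g in groups:
        row: dict[str, object] = {
            "group_id": g.group_id,
            "size": g.member_count,
            "reference_array_id": g.reference_array_id,
            "n_labels": pd.NA,
            "n_blocks": pd.NA,
            "n_sources": pd.NA,
            "n_sinks": pd.NA,
            "anchor_label": pd.NA,
            "anchor_conservation": pd.NA,
            "orientation": pd.NA,
        }
        cg = graphs.get(g.group_id)
        if cg is None:
            logger.warning("group %d: no compressed graph; graph fields left empty", g.group_id)
        else:
            row["n_labels"] = sum(len(b) for b in cg.blocks)
            row["n_blocks"] = cg.n_blocks
            row["n_sources"] = len(cg.sources)
            row["n_sinks"] = len(cg.sinks)
        tr = trailer_reports.get(g.group_id)
        if tr is not None and tr.conservation is not None:
            row["anchor_label"] = tr.anchor_label
            row["anchor_conservation"] = tr.conservation
        oc = orientations.get(g.group_id)
        if oc is not None:
            row["orientation"] = oc.orientation
        rows.append(row)
    return pd.DataFrame(rows)
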