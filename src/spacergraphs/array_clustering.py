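"""Greedy grouping of CRISPR arrays that share spacer-cluster labels.

Arrays observed on different reads belong to the same CRISPR locus (in some
member of the population) when they share spacers.  Grouping is greedy:
the largest unclustered array founds a group as its *reference*, then
unclustered arrays are swept repeatedly in size order, each joining the first
existing group (founding order) containing a member it shares at least one
label with, until a sweep adds nothing; then the next reference is chosen.
Sweeping to a fixpoint closes each group under sharing, so with the default
settings each group is a connected component of the "shares >= 1 label"
graph — the sweep formulation matters only under the non-transitive variant,
where membership requires sharing with the group's reference itself.

Every array ends up in exactly one group; singletons are kept as groups of
size one.  The minimum group size used when reporting (by convention 10
arrays, the size at which a spacer graph becomes informative) is a reporting
filter, never a clustering parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .errors import DomainError, ValidationError
from .io_formats import LabeledArray

Sharing = Literal["transitive", "reference"]

DEFAULT_MIN_GROUP_REPORT = 10


@dataclass
class ArrayGroup:
    """One group of spacer-sharing arrays.

    ``member_array_ids`` is in join order: the reference first, and every
    later member shared at least one label with some member listed before it
    at the moment it joined.
    """

    group_id: int
    reference_array_id: str
    member_array_ids: list[str]

    @property
    def member_count(self) -> int:
        return len(self.member_array_ids)


def cluster_arrays(
    arrays: Sequence[LabeledArray],
    *,
    sharing: Sharing = "transitive",
    min_shared: int = 1,
) -> list[ArrayGroup]:
    """Partition labeled arrays into spacer-sharing groups.

    Parameters
    ----------
    arrays:
        Labeled arrays; each must carry at least one label.
    sharing:
        ``"transitive"`` (default): an array may join through any current
        member of a group.  ``"reference"``: it must share with the group's
        founding reference itself.
    min_shared:
        Minimum number of distinct shared labels required to join (1 by
        convention).
    """
    if min_shared < 1:
        raise DomainError("min_shared must be >= 1")
    ids = [a.array_id for a in arrays]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate array ids in input")
    for a in arrays:
        if not a.labels:
            raise ValidationError(f"array {a.array_id!r} has no labels")

    order = sorted(arrays, key=lambda a: (-len(a.labels), a.array_id))
    label_sets = {a.array_id: set(a.labels) for a in arrays}
    unclustered: list[LabeledArray] = list(order)
    groups: list[ArrayGroup] = []
    group_labels: list[set[int]] = []  # union of member labels per group

    def _shares(candidate: set[int], gidx: int) -> bool:
        pool = group_labels[gidx] if sharing == "transitive" else label_sets[groups[gidx].reference_array_id]
        return len(candidate & pool) >= min_shared

    while unclustered:
        ref = unclustered.pop(0)
        groups.append(ArrayGroup(len(groups), ref.array_id, [ref.array_id]))
        group_labels.append(set(label_sets[ref.array_id]))
        changed = True
        while changed:
            changed = False
            remaining: list[LabeledArray] = []
            for a in unclustered:
                cand = label_sets[a.array_id]
                for gidx in range(len(groups)):
                    if _shares(cand, gidx):
                        groups[gidx].member_array_ids.append(a.array_id)
                        group_labels[gidx] |= cand
                        changed = True
                        break
                else:
                    remaining.append(a)
            unclustered = remaining
    return groups


def group_summary(groups: Iterable[ArrayGroup], min_size: int = DEFAULT_MIN_GROUP_REPORT) -> dict[str, int]:
    """Counts of groups, singleton groups, and groups of at least ``min_size``."""
    if min_size < 1:
        raise DomainError("min_size must be >= 1")
    sizes = [g.member_count for g in groups]
    return {
        "n_groups": len(sizes),
        "n_singletons": sum(1 for s in sizes if s == 1),
        "n_at_least_min": sum(1 for s in sizes if s >= min_size),
    }
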