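"""Forward simulator of CRISPR array evolution with ground truth.

A single ancestral array (random spacers flanked by identical repeats, with
a planted-degenerate final repeat at the trailer end) is evolved
independently along each sampled lineage:

* spacer gains — Poisson-distributed per lineage, always novel random
  sequences inserted at the leader (left) end, mirroring polarised
  leader-end acquisition;
* segmental losses — Poisson-distributed deletions of geometric-length
  blocks, by default never removing the trailer-end spacer (trailer/anchor
  conservation is the empirically observed regime, and the knob to switch
  it off exists precisely to test its detection);
* point mutations — per-base substitutions on spacer sequences, emulating
  sequencing error plus real divergence below the clustering threshold;
* read fragmentation — optional truncation of either array end, clearing
  the corresponding completeness flag.

Every emitted array carries an event list; replaying the events on the
ancestor reproduces the array exactly, which is the core invariant the
simulator is tested on.  All randomness flows through one seeded generator,
so output is byte-identical across runs with the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import DomainError, ValidationError
from .io_formats import CrisprArrayRecord
from .spacer_clustering import reverse_complement

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def random_reads(n_reads: int, length: int, seed: int) -> list[tuple[str, str]]:
    """Uniform-random background reads, for protospacer planting."""
    rng = np.random.default_rng(seed)
    return [(f"read{i:05d}", _random_seq(rng, length)) for i in range(n_reads)]


# --- configuration -----------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for one simulated group of spacer-sharing arrays.

    Rates are per sampled lineage; lengths in bp.  ``loss_block_mean`` is the
    mean of the geometric block-length distribution (support >= 1).
    ``trailer_repeat_degeneracy`` is the number of mismatches planted into
    the trailer-end repeat copy of every array, the signal used for
    repeat-based orientation inference.
    """

    seed: int = 0
    n_ancestral_spacers: int = 15
    spacer_length: int = 30
    repeat_length: int = 30
    population_size: int = 20
    gain_rate: float = 0.3
    loss_rate: float = 0.1
    loss_block_mean: float = 3.0
    mutation_rate: float = 0.005
    trailer_repeat_degeneracy: int = 3
    fragmentation_prob: float = 0.0
    protect_trailer: bool = True
    strand_randomization: bool = False

    def __post_init__(self) -> None:
        if self.n_ancestral_spacers < 1 or self.population_size < 1:
            raise DomainError("need at least one ancestral spacer and one lineage")
        if min(self.spacer_length, self.repeat_length) < 1:
            raise DomainError("sequence lengths must be positive")
        for name in ("gain_rate", "loss_rate", "loss_block_mean"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        for name in ("mutation_rate", "fragmentation_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise DomainError(f"{name} must be in [0, 1]")
        if not 0 <= self.trailer_repeat_degeneracy <= self.repeat_length:
            raise DomainError("trailer_repeat_degeneracy outside repeat length")


# --- events ------------------------------------------------------------------

@dataclass
class Gain:
    """Leader-end insertion of one novel spacer (applied leftmost)."""

    label: int
    sequence: str


@dataclass
class Loss:
    """Deletion of ``length`` consecutive spacers starting at ``start``."""

    start: int
    length: int


@dataclass
class Substitution:
    """Point substitution in spacer ``unit`` at ``pos`` (post-gain/loss indexing)."""

    unit: int
    pos: int
    base: str


@dataclass
class Truncation:
    side: Literal["left", "right"]
    n_units: int
    drop_outer_repeat: bool = False


@dataclass
class Flip:
    """Reverse-complement the whole array (opposite-strand read)."""


Event = Gain | Loss | Substitution | Truncation | Flip


@dataclass
class _ArrayState:
    labels: list[int]
    spacers: list[str]
    repeats: list[str]
    left_complete: bool = True
    right_complete: bool = True


def _apply_event(state: _ArrayState, ev: Event, ancestral_repeat: str) -> None:
    if isinstance(ev, Gain):
        state.labels.insert(0, ev.label)
        state.spacers.insert(0, ev.sequence)
        state.repeats.insert(0, ancestral_repeat)
    elif isinstance(ev, Loss):
        i, j = ev.start, ev.start + ev.length
        if not (0 <= i < j <= len(state.spacers)):
            raise ValidationError(f"loss {ev} outside array of {len(state.spacers)}")
        del state.spacers[i:j]
        del state.labels[i:j]
        del state.repeats[i + 1 : j + 1]
    elif isinstance(ev, Substitution):
        s = state.spacers[ev.unit]
        state.spacers[ev.unit] = s[: ev.pos] + ev.base + s[ev.pos + 1 :]
    elif isinstance(ev, Truncation):
        k = ev.n_units
        if k >= len(state.spacers):
            raise ValidationError("truncation would empty the array")
        if ev.side == "left":
            del state.spacers[:k]
            del state.labels[:k]
            del state.repeats[:k]
            if ev.drop_outer_repeat:
                del state.repeats[0]
            state.left_complete = False
        else:
            if k:
                del state.spacers[-k:]
                del state.labels[-k:]
                del state.repeats[-k:]
            if ev.drop_outer_repeat:
                del state.repeats[-1]
            state.right_complete = False
    elif isinstance(ev, Flip):
        state.labels.reverse()
        state.spacers = [reverse_complement(s) for s in reversed(state.spacers)]
        state.repeats = [reverse_complement(r) for r in reversed(state.repeats)]
        state.left_complete, state.right_complete = (
            state.right_complete,
            state.left_complete,
        )
    else:  # pragma: no cover
        raise TypeError(f"unknown event {ev!r}")


# --- ground truth ------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything needed to audit a simulated population.

    ``true_labels`` are the pre-mutation spacer identities of each emitted
    array in emitted order (ancestral spacers are labels ``0..n-1`` from
    leader to trailer; gained spacers get fresh labels).  ``true_orientation``
    maps each array to ``as_given`` (leader on the left as emitted) or
    ``reversed`` for strand-randomized arrays.
    """

    config: SimulationConfig
    ancestral_spacers: list[str]
    ancestral_repeat: str
    trailer_repeat: str
    events: dict[str, list[Event]]
    true_labels: dict[str, list[int]]
    true_orientation: dict[str, Literal["as_given", "reversed"]]
    true_anchor_label: int
    gained_labels: dict[str, list[int]]

    def ancestral_state(self) -> _ArrayState:
        n = len(self.ancestral_spacers)
        return _ArrayState(
            labels=list(range(n)),
            spacers=list(self.ancestral_spacers),
            repeats=[self.ancestral_repeat] * n + [self.trailer_repeat],
        )

    def replay(self, array_id: str) -> CrisprArrayRecord:
        """Re-apply the recorded events on the ancestor; must reproduce the
        emitted array exactly."""
        state = self.ancestral_state()
        for ev in self.events[array_id]:
            _apply_event(state, ev, self.ancestral_repeat)
        return CrisprArrayRecord(
            array_id=array_id,
            read_id=array_id.replace("array", "read", 1),
            spacers=list(state.spacers),
            repeats=list(state.repeats),
            left_complete=state.left_complete,
            right_complete=state.right_complete,
        )


# --- simulation --------------------------------------------------------------

def simulate_population(
    config: SimulationConfig,
) -> tuple[list[CrisprArrayRecord], GroundTruth]:
    """Evolve one group of spacer-sharing arrays from a common ancestor."""
    rng = np.random.default_rng(config.seed)
    n = config.n_ancestral_spacers
    ancestral_spacers = [_random_seq(rng, config.spacer_length) for _ in range(n)]
    ancestral_repeat = _random_seq(rng, config.repeat_length)

    trailer_repeat = ancestral_repeat
    if config.trailer_repeat_degeneracy:
        pos = rng.choice(config.repeat_length, size=config.trailer_repeat_degeneracy, replace=False)
        chars = list(ancestral_repeat)
        for p in sorted(pos):
            alt = [b for b in "ACGT" if b != chars[p]]
            chars[p] = alt[rng.integers(0, 3)]
        trailer_repeat = "".join(chars)

    next_label = n
    records: list[CrisprArrayRecord] = []
    truth = GroundTruth(
        config=config,
        ancestral_spacers=ancestral_spacers,
        ancestral_repeat=ancestral_repeat,
        trailer_repeat=trailer_repeat,
        events={},
        true_labels={},
        true_orientation={},
        true_anchor_label=n - 1,
        gained_labels={},
    )

    for i in range(config.population_size):
        array_id = f"array{i:04d}"
        for _attempt in range(100):
            events: list[Event] = []
            state = truth.ancestral_state()
            gained: list[int] = []
            trial_label = next_label

            n_gain = rng.poisson(config.gain_rate)
            for _ in range(n_gain):
                ev = Gain(label=trial_label, sequence=_random_seq(rng, config.spacer_length))
                gained.append(trial_label)
                trial_label += 1
                events.append(ev)
                _apply_event(state, ev, ancestral_repeat)

            n_loss = rng.poisson(config.loss_rate)
            ok = True
            for _ in range(n_loss):
                length = int(min(rng.geometric(1.0 / config.loss_block_mean), len(state.spacers)))
                limit = len(state.spacers) - (1 if config.protect_trailer else 0)
                if limit - length < 0:
                    length = limit
                if length < 1:
                    ok = False
                    break
                start = int(rng.integers(0, limit - length + 1))
                ev = Loss(start=start, length=length)
                events.append(ev)
                _apply_event(state, ev, ancestral_repeat)
                if not state.spacers:
                    ok = False
                    break
            if not ok or not state.spacers:
                continue  # resample this lineage

            if config.mutation_rate > 0:
                for unit, spacer in enumerate(state.spacers):
                    hit = np.nonzero(rng.random(len(spacer)) < config.mutation_rate)[0]
                    for p in hit:
                        alt = [b for b in "ACGT" if b != spacer[int(p)]]
                        ev = Substitution(unit=unit, pos=int(p), base=alt[rng.integers(0, 3)])
                        events.append(ev)
                        _apply_event(state, ev, ancestral_repeat)
                        spacer = state.spacers[unit]

            orientation: Literal["as_given", "reversed"] = "as_given"
            if config.strand_randomization and rng.random() < 0.5:
                ev = Flip()
                events.append(ev)
                _apply_event(state, ev, ancestral_repeat)
                orientation = "reversed"

            next_label = trial_label
            truth.events[array_id] = events
            truth.true_labels[array_id] = list(state.labels)
            truth.true_orientation[array_id] = orientation
            truth.gained_labels[array_id] = gained
            records.append(
                CrisprArrayRecord(
                    array_id=array_id,
                    read_id=f"read{i:04d}",
                    spacers=list(state.spacers),
                    repeats=list(state.repeats),
                    left_complete=True,
                    right_complete=True,
                )
            )
            break
        else:  # pragma: no cover - requires pathological rates
            raise ValidationError(f"lineage {array_id} could not be sampled")

    if config.fragmentation_prob > 0:
        records = fragment_reads(
            records, config.fragmentation_prob, int(rng.integers(0, 2**31)), truth=truth
        )
    return records, truth


def fragment_reads(
    arrays: Sequence[CrisprArrayRecord],
    fragmentation_prob: float,
    seed: int,
    truth: GroundTruth | None = None,
) -> list[CrisprArrayRecord]:
    """Truncate array ends to emulate reads that cut into a locus.

    Each end is independently truncated with ``fragmentation_prob``; a
    truncated end loses a uniform number (>= 1) of terminal spacer-repeat
    units — never all of them — and its completeness flag.  With probability
    one half, a truncated end also loses its outermost repeat (the read
    boundary fell inside the repeat rather than between units); at most one
    end does, keeping the repeat count within one of the spacer count.
    """
    if not 0 <= fragmentation_prob <= 1:
        raise DomainError("fragmentation_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[CrisprArrayRecord] = []
    for rec in arrays:
        n = len(rec.spacers)
        want_left = rng.random() < fragmentation_prob
        want_right = rng.random() < fragmentation_prob
        # allocate removable units (n - 1 in total) so that a requested cut
        # always removes at least one unit and at least one spacer survives
        cut_left = want_left and n >= (3 if want_right else 2)
        cut_right = want_right and n >= 2
        k_left = int(rng.integers(1, n - 1 if cut_right else n)) if cut_left else 0
        k_right = int(rng.integers(1, n - k_left)) if cut_right else 0
        if not cut_left and not cut_right:
            out.append(rec)
            continue
        full_flanks = len(rec.repeats) == n + 1
        state = _ArrayState(
            labels=list(range(n)),
            spacers=list(rec.spacers),
            repeats=list(rec.repeats),
            left_complete=rec.left_complete,
            right_complete=rec.right_complete,
        )
        events: list[Event] = []
        dropped = False
        if cut_left:
            drop = bool(full_flanks and rng.random() < 0.5)
            events.append(Truncation("left", k_left, drop_outer_repeat=drop))
            dropped = drop
        if cut_right:
            drop = bool((not dropped) and full_flanks and rng.random() < 0.5)
            events.append(Truncation("right", k_right, drop_outer_repeat=drop))
        for ev in events:
            _apply_event(state, ev, "")
        out.append(
            CrisprArrayRecord(
                array_id=rec.array_id,
                read_id=rec.read_id,
                spacers=state.spacers,
                repeats=state.repeats,
                left_complete=state.left_complete,
                right_complete=state.right_complete,
                source_interval=rec.source_interval,
            )
        )
        if truth is not None and rec.array_id in truth.events:
            truth.events[rec.array_id].extend(events)
            labels = truth.true_labels[rec.array_id]
            truth.true_labels[rec.array_id] = labels[k_left : len(labels) - k_right]
    return out


def plant_protospacers(
    reads: Sequence[tuple[str, str]],
    spacers: Sequence[tuple[str, str]],
    n_plants: int,
    error_rate: float,
    seed: int,
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Insert spacer copies into reads at recorded positions and strands.

    Plants never overlap each other on a read.  Per-base substitution errors
    at ``error_rate`` emulate divergence between spacer and protospacer.
    Returns the modified reads and a truth table of dicts with keys
    ``read_id, start, end, strand, spacer_id, n_errors``.
    """
    if not 0 <= error_rate <= 1:
        raise DomainError("error_rate must be in [0, 1]")
    if n_plants < 0:
        raise DomainError("n_plants must be >= 0")
    if n_plants and (not reads or not spacers):
        raise ValidationError("cannot plant into empty reads/spacers")
    rng = np.random.default_rng(seed)
    seqs = {rid: seq for rid, seq in reads}
    occupied: dict[str, list[tuple[int, int]]] = {rid: [] for rid in seqs}
    table: list[dict] = []
    for _ in range(n_plants):
        for _attempt in range(1000):
            sid, sseq = spacers[rng.integers(0, len(spacers))]
            rid = reads[rng.integers(0, len(reads))][0]
            if len(seqs[rid]) < len(sseq):
                continue
            start = int(rng.integers(0, len(seqs[rid]) - len(sseq) + 1))
            end = start + len(sseq)
            if any(s < end and start < e for s, e in occupied[rid]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            insert = sseq if strand == "+" else reverse_complement(sseq)
            n_err = 0
            if error_rate:
                chars = list(insert)
                hit = np.nonzero(rng.random(len(chars)) < error_rate)[0]
                for p in hit:
                    alt = [b for b in "ACGT" if b != chars[int(p)]]
                    chars[int(p)] = alt[rng.integers(0, 3)]
                n_err = len(hit)
                insert = "".join(chars)
            seqs[rid] = seqs[rid][:start] + insert + seqs[rid][end:]
            occupied[rid].append((start, end))
            table.append(
                {
                    "read_id": rid,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "spacer_id": sid,
                    "n_errors": n_err,
                }
            )
            break
        else:
            raise ValidationError("could not place a plant without overlap")
    return [(rid, seqs[rid]) for rid, _ in reads], table
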