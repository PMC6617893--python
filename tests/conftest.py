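"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import pytest

from spacergraphs.synthetic_data import SimulationConfig, simulate_population

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def dp_identity(a: str, b: str, strand_mode: str = "both") -> float:
    """Independent alignment-identity oracle: plain O(nm) dynamic program
    maximizing matches (gaps free), over min length; N matches nothing."""

    def matches(x: str, y: str) -> int:
        prev = [0] * (len(y) + 1)
        for ca in x:
            cur = [0]
            for j, cb in enumerate(y, start=1):
                eq = 1 if (ca == cb and ca != "N") else 0
                cur.append(max(prev[j], cur[j - 1], prev[j - 1] + eq))
            prev = cur
        return prev[-1]

    best = matches(a, b)
    if strand_mode == "both":
        best = max(best, matches(a, rc(b)))
    return best / min(len(a), len(b))


def greedy_cluster_oracle(spacers, threshold=0.9, strand_mode="both"):
    """Re-implementation of the greedy clustering rule on a full pairwise
    identity matrix; returns spacer_id -> cluster index."""
    order = sorted(spacers, key=lambda p: (-len(p[1]), p[0]))
    reps: list[tuple[str, str]] = []
    assign: dict[str, int] = {}
    for sid, seq in order:
        target = None
        for ci, (_, rep_seq) in enumerate(reps):
            if dp_identity(seq, rep_seq, strand_mode) >= threshold - 1e-9:
                target = ci
                break
        if target is None:
            reps.append((sid, seq))
            target = len(reps) - 1
        assign[sid] = target
    return assign


@pytest.fixture(scope="session")
def default_population():
    """One population at the package's default study conditions."""
    cfg = SimulationConfig(seed=42, population_size=15)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def fragmented_population():
    cfg = SimulationConfig(seed=7, population_size=20, fragmentation_prob=0.3)
    return simulate_population(cfg)
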