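"""Graph construction, chain compression, orientation and anchor statistics."""

from __future__ import annotations

import numpy as np
import pytest

from spacergraphs import (
    CrisprArrayRecord,
    DomainError,
    LabeledArray,
    UndefinedScoreError,
    build_spacer_graph,
    classify_terminals,
    cluster_spacers,
    collect_spacers,
    compress,
    dominant_path,
    infer_orientation,
    label_arrays,
    repeat_degeneracy_score,
    trailer_conservation,
)
from spacergraphs.synthetic_data import SimulationConfig, simulate_population


def la(aid, labels, left=True, right=True):
    return LabeledArray(aid, labels, left, right)


class TestBuildSpacerGraph:
    def test_single_array_chain(self):
        sg = build_spacer_graph([la("a", [0, 1, 2, 3])])
        assert sg.nodes == {0, 1, 2, 3}
        assert sg.edges == {(0, 1): 1, (1, 2): 1, (2, 3): 1}

    def test_second_array_adds_skip_edge(self):
        sg = build_spacer_graph([la("a", [0, 1, 2, 3]), la("b", [0, 3])])
        assert len(sg.nodes) == 4
        assert sg.edges == {(0, 1): 1, (1, 2): 1, (2, 3): 1, (0, 3): 1}

    def test_support_counts_duplicates(self):
        sg = build_spacer_graph([la("a", [5, 6]), la("b", [5, 6])])
        assert sg.edges == {(5, 6): 2}

    def test_empty_input(self):
        sg = build_spacer_graph([])
        assert sg.nodes == set() and sg.edges == {}

    def test_edge_support_conservation(self, default_population):
        records, truth = default_population
        arrays = [la(r.array_id, truth.true_labels[r.array_id]) for r in records]
        sg = build_spacer_graph(arrays)
        assert sum(sg.edges.values()) == sum(len(a.labels) - 1 for a in arrays)


class TestCompress:
    def test_worked_example_three_blocks_three_edges(self):
        sg = build_spacer_graph([la("a", [0, 1, 2, 3]), la("b", [0, 3])])
        cg = compress(sg)
        assert cg.blocks == [[0], [1, 2], [3]]
        assert set(cg.block_edges) == {(0, 1), (1, 2), (0, 2)}
        assert all(s == 1 for s in cg.block_edges.values())

    def test_single_array_collapses_to_one_block(self):
        cg = compress(build_spacer_graph([la("a", [0, 1, 2, 3])]))
        assert cg.blocks == [[0, 1, 2, 3]]
        assert cg.block_edges == {}

    def test_idempotence_via_walk_rebuild(self):
        # compressing the block sequence of every walk must not change it:
        # rebuild a graph whose labels are block ids and compress again
        rng = np.random.default_rng(2)
        for seed in range(30):
            recs, truth = simulate_population(
                SimulationConfig(seed=300 + seed, population_size=10,
                                 gain_rate=0.5, loss_rate=0.3)
            )
            arrays = [la(r.array_id, truth.true_labels[r.array_id]) for r in recs]
            cg = compress(build_spacer_graph(arrays))
            walk_arrays = [
                LabeledArray(aid, list(w.block_ids)) for aid, w in cg.walks.items()
            ]
            cg2 = compress(build_spacer_graph(walk_arrays))
            assert all(len(b) == 1 for b in cg2.blocks) or [
                b for b in cg2.blocks if len(b) > 1
            ] == []  # no further collapsible pair exists

    def test_path_preservation_on_simulated_groups(self):
        for seed in range(30):
            recs, truth = simulate_population(
                SimulationConfig(seed=600 + seed, population_size=12,
                                 gain_rate=0.6, loss_rate=0.3, fragmentation_prob=0.3)
            )
            arrays = [
                la(r.array_id, truth.true_labels[r.array_id], r.left_complete, r.right_complete)
                for r in recs
            ]
            cg = compress(build_spacer_graph(arrays))
            for a in arrays:
                assert cg.walk_labels(a.array_id) == a.labels
            # node conservation
            assert sorted(l for b in cg.blocks for l in b) == sorted(
                {l for a in arrays for l in a.labels}
            )

    def test_repeated_label_kept_as_singleton_block(self):
        cg = compress(build_spacer_graph([la("a", [0, 1, 0, 2])]))
        assert [0] in cg.blocks  # the duplicated label is not merged
        assert cg.walk_labels("a") == [0, 1, 0, 2]

    def test_consecutive_duplicate_label_self_loop(self):
        cg = compress(build_spacer_graph([la("a", [3, 3, 4])]))
        assert cg.walk_labels("a") == [3, 3, 4]
        assert (0, 0) in cg.block_edges  # self-loop on block of label 3

    def test_strict_degree_declines_junction_adjacent_merge(self):
        # v has in-degree 2; with the default rule v's chain into w merges,
        # the strictly-literal rule refuses
        arrays = [la("a", [0, 2, 3]), la("b", [1, 2, 3])]
        default = compress(build_spacer_graph(arrays))
        strict = compress(build_spacer_graph(arrays), strict_degree=True)
        assert [2, 3] in default.blocks
        assert [2, 3] not in strict.blocks
        for a in arrays:  # both preserve paths
            assert default.walk_labels(a.array_id) == a.labels
            assert strict.walk_labels(a.array_id) == a.labels

    def test_fixed_point_independent_of_insertion_order(self):
        rng = np.random.default_rng(9)
        recs, truth = simulate_population(
            SimulationConfig(seed=77, population_size=10, gain_rate=0.5, loss_rate=0.3)
        )
        arrays = [la(r.array_id, truth.true_labels[r.array_id]) for r in recs]
        ref = compress(build_spacer_graph(arrays))
        for _ in range(5):
            perm = list(arrays)
            rng.shuffle(perm)
            got = compress(build_spacer_graph(perm))
            assert got.blocks == ref.blocks
            assert got.block_edges == ref.block_edges


class TestDominantPath:
    def test_most_frequent_organization_wins(self):
        xs = [la(f"x{i}", [0, 1, 2, 3]) for i in range(5)]
        ys = [la(f"y{i}", [0, 3]) for i in range(2)]
        cg = compress(build_spacer_graph(xs + ys))
        walk = dominant_path(cg, xs + ys)
        assert cg.walk_labels(xs[0].array_id) == [0, 1, 2, 3]
        assert walk == cg.walks["x0"].block_ids

    def test_all_identical_gives_single_walk(self):
        arrays = [la(f"a{i}", [7, 8]) for i in range(4)]
        cg = compress(build_spacer_graph(arrays))
        assert dominant_path(cg, arrays) == cg.walks["a0"].block_ids == [0]

    def test_tie_broken_by_longer_walk(self):
        long = [la(f"l{i}", [0, 1, 2, 3, 4, 5, 6]) for i in range(3)]
        short = [la(f"s{i}", [0, 10, 11, 6]) for i in range(3)]
        cg = compress(build_spacer_graph(long + short))
        walk = dominant_path(cg, long + short)
        assert walk == cg.walks["l0"].block_ids

    def test_no_arrays_empty_path(self):
        cg = compress(build_spacer_graph([]))
        assert dominant_path(cg, []) == []


class TestTerminals:
    def test_worked_example(self):
        cg = compress(build_spacer_graph([la("a", [0, 1, 2, 3]), la("b", [0, 3])]))
        sources, sinks = classify_terminals(cg)
        assert [cg.blocks[b] for b in sources] == [[0]]
        assert [cg.blocks[b] for b in sinks] == [[3]]

    def test_single_block_is_both(self):
        cg = compress(build_spacer_graph([la("a", [0, 1])]))
        sources, sinks = classify_terminals(cg)
        assert sources == sinks == [0]

    def test_gained_spacers_lie_in_source_blocks(self):
        for seed in range(10):
            recs, truth = simulate_population(
                SimulationConfig(seed=900 + seed, population_size=25,
                                 gain_rate=0.8, loss_rate=0.0, mutation_rate=0.0)
            )
            arrays = [la(r.array_id, truth.true_labels[r.array_id]) for r in recs]
            cg = compress(build_spacer_graph(arrays))
            src_labels = {l for b in cg.sources for l in cg.blocks[b]}
            gained = {l for labs in truth.gained_labels.values() for l in labs}
            assert gained <= src_labels


def _records_with_repeats(last_mm, first_mm, n=6, rep="ACGTACGTAC"):
    """Arrays whose terminal repeats differ from consensus at given counts."""

    def mutate(r, k):
        out = list(r)
        for i in range(k):
            out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
        return "".join(out)

    recs = []
    for i in range(n):
        repeats = [rep] * 4
        repeats[0] = mutate(rep, first_mm)
        repeats[-1] = mutate(rep, last_mm)
        recs.append(
            CrisprArrayRecord(f"a{i}", f"r{i}", ["ACG"] * 3, repeats, True, True)
        )
    return recs


class TestRepeatDegeneracy:
    def test_uniform_repeats_score_zero(self):
        assert repeat_degeneracy_score(_records_with_repeats(0, 0)) == 0.0

    def test_degenerate_last_repeat_positive_three(self):
        assert repeat_degeneracy_score(_records_with_repeats(3, 0)) == 3.0

    def test_mirrored_case_antisymmetric(self):
        assert repeat_degeneracy_score(_records_with_repeats(0, 3)) == -3.0

    def test_no_complete_ends_raises(self):
        recs = [
            CrisprArrayRecord("a", "r", ["ACG"], ["AAAA", "AAAA"], False, False)
        ]
        with pytest.raises(UndefinedScoreError):
            repeat_degeneracy_score(recs)


class TestInferOrientation:
    def _pipeline(self, records):
        cmap = cluster_spacers(collect_spacers(records))
        arrays = label_arrays(records, cmap)
        cg = compress(build_spacer_graph(arrays))
        return arrays, cg

    def test_simulated_group_recovered_high_confidence(self):
        recs, truth = simulate_population(
            SimulationConfig(seed=5, population_size=15, gain_rate=0.8,
                             loss_rate=0.1, trailer_repeat_degeneracy=3)
        )
        arrays, cg = self._pipeline(recs)
        call = infer_orientation(recs, cg)
        assert call.orientation == "as_given"
        assert call.confidence == "high"
        assert call.degeneracy_score > 0 and call.topology_score > 0

    def test_all_identical_arrays_undetermined(self):
        recs, _ = simulate_population(
            SimulationConfig(seed=6, population_size=8, gain_rate=0, loss_rate=0,
                             mutation_rate=0, trailer_repeat_degeneracy=0)
        )
        arrays, cg = self._pipeline(recs)
        call = infer_orientation(recs, cg)
        assert call.orientation == "undetermined"

    def test_conflicting_signals_surfaced(self):
        # the degenerate repeat is moved to the gain (leader) end while gains
        # stay on the left: topology says leader-left, repeat degeneracy says
        # trailer-left -> undetermined, both scores reported
        recs, truth = simulate_population(
            SimulationConfig(seed=8, population_size=15, gain_rate=1.0,
                             loss_rate=0.0, mutation_rate=0.0,
                             trailer_repeat_degeneracy=3)
        )
        flipped = [
            CrisprArrayRecord(
                r.array_id, r.read_id, r.spacers, r.repeats[::-1],
                r.left_complete, r.right_complete,
            )
            for r in recs
        ]
        arrays, cg = self._pipeline(flipped)
        call = infer_orientation(flipped, cg)
        assert call.orientation == "undetermined"
        assert call.degeneracy_score is not None and call.topology_score is not None
        assert call.degeneracy_score * call.topology_score < 0


class TestTrailerConservation:
    def test_direct_count(self):
        arrays = [la(f"a{i}", [0, 1, 2]) for i in range(9)] + [la("b", [0, 1, 7])]
        rep = trailer_conservation(arrays, "as_given")
        assert rep.anchor_label == 2
        assert rep.n_supporting == 9 and rep.n_eligible == 10
        assert rep.conservation == pytest.approx(0.9)

    def test_reversed_orientation_uses_left_end(self):
        arrays = [la(f"a{i}", [5, 1, 2]) for i in range(3)]
        rep = trailer_conservation(arrays, "reversed")
        assert rep.anchor_label == 5 and rep.conservation == 1.0

    def test_fragmented_trailer_ends_ineligible(self):
        arrays = [la("a", [0, 1, 2]), la("b", [0, 1, 9], right=False)]
        rep = trailer_conservation(arrays, "as_given")
        assert rep.n_eligible == 1 and rep.conservation == 1.0

    def test_zero_eligible_reported_not_raised(self):
        arrays = [la("a", [0, 1], right=False)]
        rep = trailer_conservation(arrays, "as_given")
        assert rep.n_eligible == 0 and rep.conservation is None

    def test_undetermined_orientation_rejected(self):
        with pytest.raises(DomainError):
            trailer_conservation([la("a", [0])], "undetermined")

    def test_protected_trailer_fully_conserved(self):
        for seed in range(10):
            recs, truth = simulate_population(
                SimulationConfig(seed=1200 + seed, population_size=15,
                                 gain_rate=0.5, loss_rate=0.4,
                                 fragmentation_prob=0.3, protect_trailer=True)
            )
            arrays = [
                la(r.array_id, truth.true_labels[r.array_id], r.left_complete, r.right_complete)
                for r in recs
            ]
            rep = trailer_conservation(arrays, "as_given")
            if rep.n_eligible:
                assert rep.conservation == 1.0
                assert rep.anchor_label == truth.true_anchor_label
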