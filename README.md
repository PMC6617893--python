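# spacergraphs

Characterising the diversity and dynamics of CRISPR arrays in a microbiome
from long reads.

CRISPR arrays — runs of near-identical repeats interleaved with ~30-bp
spacers sampled from past invaders — are hard to assemble from short reads,
but a single long read captures a whole array in order. Across a microbial
population the same locus is seen on many reads in slightly different
states: new spacers gained at the leader end, internal blocks lost, the
trailer-end spacer conserved. `spacergraphs` turns a table of per-read
arrays into these population-level observations. It is aimed at
microbiome researchers who already have per-read CRISPR array calls (from
any detector) and want to study array dynamics rather than detection.

## What it computes

1. **Spacer clustering.** Spacers are greedily clustered at 90% sequence
   identity (longest-first, members matched against cluster
   representatives, both strands), so sequencing errors and point mutations
   collapse into one spacer identity; each array becomes a sequence of
   integer labels. Identity of a pair is the aligned match count divided by
   the shorter length.
2. **Redundancy.** `#spacers / #spacer clusters`. High redundancy (~9 on
   gut-microbiome long reads, vs ~1.01 on short-read assemblies) is what
   makes the rest of the analysis possible.
3. **Array grouping.** A greedy procedure founds a group on the largest
   unclustered array and sweeps arrays sharing ≥ 1 spacer label into it
   until closure, then repeats — partitioning arrays into spacer-sharing
   groups.
4. **Compressed spacer graphs.** Per group, a directed graph with one node
   per spacer label and an edge u→v with support *k* when v follows u in
   *k* array positions; non-branching chains are collapsed into blocks
   (unitig-style contraction). Arrays `(a,b,c,d)` and `(a,d)` compress to
   three blocks `a, [b-c], d` and three edges. Every observed array is a
   contiguous walk through the blocks; the most frequent organization is
   the dominant path (drawn red in DOT output), sources are blue, the sink
   (anchor end) yellow.
5. **Orientation and anchor conservation.** The leader side is inferred
   from two independent signals — excess terminal-repeat degeneracy at the
   trailer end, and the excess of source blocks created by leader-end
   gains — with conflicts surfaced as `undetermined`, never silently
   resolved. The modal trailer-end spacer (the "anchor") and the fraction
   of complete trailer ends carrying it quantify trailer conservation.
6. **Protospacer search.** Spacers are matched back against reads of the
   same sample (exact 12-mer seeds, both strands, banded extension); hits
   inside declared CRISPR intervals are flagged excluded, and the
   remaining hit-bearing reads are the putative invader set.
7. **Simulator.** A forward simulator of array evolution (leader gains,
   segmental losses, point mutations, trailer-repeat degeneracy, read
   fragmentation, protospacer planting) with a full event-level ground
   truth, so every stage is testable without any external data.

## Worked example

```python
from spacergraphs import (
    SimulationConfig, simulate_population, collect_spacers, cluster_spacers,
    label_arrays, cluster_arrays, build_spacer_graph, compress, dominant_path,
    infer_orientation, trailer_conservation, redundancy,
)

cfg = SimulationConfig(seed=3, population_size=15, fragmentation_prob=0.2)
records, truth = simulate_population(cfg)
cmap = cluster_spacers(collect_spacers(records))
print(f"{cmap.n_spacers} spacers -> {cmap.n_clusters} clusters "
      f"(redundancy {redundancy(cmap.n_spacers, cmap.n_clusters).rounded():.2f})")
arrays = label_arrays(records, cmap)
groups = cluster_arrays(arrays)
print(f"{len(groups)} spacer-sharing group(s); sizes {[g.member_count for g in groups]}")
cg = compress(build_spacer_graph(arrays))
dominant_path(cg, arrays)
print(f"compressed spacer graph: {cg.n_blocks} blocks, {len(cg.block_edges)} edges, "
      f"{len(cg.sources)} source(s), {len(cg.sinks)} sink(s)")
call = infer_orientation(records, cg, group_id=0)
print(f"orientation: {call.orientation} ({call.confidence}; degeneracy "
      f"{call.degeneracy_score:+.1f}, topology {call.topology_score:+.1f})")
rep = trailer_conservation(arrays, call.orientation)
print(f"anchor spacer: cluster {rep.anchor_label}, conserved in "
      f"{rep.n_supporting}/{rep.n_eligible} complete trailer ends ({rep.conservation:.2f})")
```

prints

```
209 spacers -> 18 clusters (redundancy 11.61)
1 spacer-sharing group(s); sizes [15]
compressed spacer graph: 8 blocks, 10 edges, 3 source(s), 1 sink(s)
orientation: as_given (high; degeneracy +3.0, topology +6.0)
anchor spacer: cluster 6, conserved in 13/13 complete trailer ends (1.00)
```

Fifteen arrays descended from one 15-spacer ancestor collapse to 18 spacer
identities (the 3 extras are leader-end gains), form one spacer-sharing
group whose compressed graph branches only at the leader side, and keep
the ancestral trailer spacer on every intact trailer end — the "anchor"
pattern.

The same pipeline is available from the shell:

```sh
spacergraphs simulate --seed 3 --out-prefix sim
spacergraphs run-all --arrays sim.arrays.tsv --out-dir out/
```

which writes `clusters.tsv`, `groups.tsv`, per-group Graphviz `.dot`
files, `summary.tsv`, and `redundancy.json`.

## Input format

Arrays are supplied as a tab-separated table with header
`array_id  read_id  left_complete  right_complete  spacers  repeats`;
sequence lists are semicolon-delimited, booleans 0/1, coordinates 0-based
half-open. Converters from specific CRISPR detectors are an extension
point — see `docs/methods.md` for details and design rationale.
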