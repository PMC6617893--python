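# Methods

This note records the models, parameter choices and numerical conventions
behind `spacergraphs`, and what the simulation-based tests do and do not
demonstrate.

## Spacer identity and clustering

Two spacers are compared by optimal alignment in which only matches score:
the identity is (number of aligned matching bases) / (length of the
shorter sequence). Because gaps and mismatches carry no penalty beyond not
matching, the match count equals the longest-common-subsequence length,
computed with a vectorised dynamic program. The shorter-sequence
denominator lets a truncated spacer co-cluster with its full-length form.
`N` never matches anything, including another `N` — an ambiguous base is
evidence of nothing. Under the default `strand_mode="both"` the reverse
complement of the second sequence is also tried and the better strand
used, since arrays called on opposite strands yield reverse-complementary
spacers.

Clustering is greedy and longest-first: sequences sorted by length
(descending, ties by id), each joining the first cluster in founding order
whose *representative* it matches at ≥ 0.90 identity, else founding a new
cluster. The representative-only comparison and first-match assignment
mirror the behaviour of classic greedy clusterers; the 0.90 default
absorbs a small number of sequencing errors or real mutations while
keeping distinct ~30-bp spacers apart (two random 30-mers score far below
the threshold). Exact duplicate sequences are collapsed before any
alignment; this is provably assignment-preserving (a duplicate makes
exactly the decisions its twin made) and makes the highly redundant
long-read regime cheap. The word-size/strand settings of external
clustering tools are not emulated; the definition above is this package's
own and is exercised against an independent O(nm) dynamic-programming
oracle in the tests.

## Array grouping

Arrays sharing ≥ 1 spacer label are grouped greedily: the largest
unclustered array founds a group, then unclustered arrays are swept in
size order, each joining the first group (founding order) containing any
member it shares a label with, until a sweep adds nothing; then the next
group is founded. Sweeping to a fixpoint closes groups under sharing, so
the default output equals the connected components of the sharing graph —
verified exhaustively against a component oracle on small instances. A
`sharing="reference"` variant (membership requires sharing with the
founding reference itself) is available because reasonable
implementations differ here; transitive closure is the default since a
newly joined member's spacers are as much part of the group as the
reference's. Ties on spacer count break by array id for determinism.
Singletons are retained as groups; the minimum group size used in
reporting (default 10) only filters which groups get graphs drawn.

## Compressed spacer graphs

The group graph has one node per spacer label and edge (u, v) with support
equal to the number of array positions where v immediately follows u. The
compression contracts edge u→v when u's only outgoing edge is (u, v) and
v's only incoming edge is (u, v) — the standard unitig-style chain
contraction. Maximal contractible chains become blocks in a single pass;
this is already the fixed point (contracting a chain changes no degree
that the rule consults), so compression is idempotent and independent of
edge order. A `strict_degree=True` variant additionally requires both
endpoints to have total in- and out-degree ≤ 1, declining chains that
hang off a junction; the two rules differ only there and both reproduce
the canonical two-array worked example. Labels occurring more than once
within one array are never merged (kept as singleton blocks) so that each
array's walk through the blocks stays unambiguous; self-adjacent
duplicates become self-loop edges.

Every array maps to a contiguous block walk, stored with entry/exit
offsets: a fragmented array may enter its first or leave its last block
part-way, but interior discontiguity is impossible under the contraction
rule (interior chain nodes have no other edges) and is asserted. Sources
(no incoming edges) and sinks (no outgoing) are classified on the block
graph. The dominant path is the walk of the most frequent array
organization, counted over complete (both-ends-intact) arrays when any
exist so that fragments do not dilute the count; ties prefer the longer,
then lexicographically smaller organization.

## Orientation inference

Two independent signals are combined; each is reduced to a sign.

*Repeat degeneracy.* A consensus repeat is built by positionwise majority
over all repeat copies (modal length; ties broken by base order for
determinism). The score is (mean mismatches of the last repeat over
arrays with complete right ends) − (same for first repeats over complete
left ends); length differences count as mismatches. Positive means the
right end is more degenerate, hence the trailer, under the convention
that the trailer-side terminal repeat decays. Fragmented ends never
contribute; if either side has no complete end the score is undefined and
signalled, never silently zero.

*Graph topology.* Leader-end gains splay a group into several source
blocks while the conserved trailer funnels into one sink, so the score is
`(n_sources − 1) × labels in sources − (n_sinks − 1) × labels in sinks`.
Counting only the *excess* beyond one terminal block per side is
deliberate: a graph with exactly one source and one sink (e.g. a single
internal-loss variant) says nothing about polarity — the relative lengths
of its end blocks are arbitrary — and an earlier formulation that weighted
plain source/sink counts by block length mis-called exactly those
loss-only groups. A single-block (branchless) graph scores zero.

Agreeing signs give a high-confidence call; one informative signal gives
a low-confidence call; conflicting signs yield `undetermined` with both
scores reported — orientation from sequence composition is known to be
unreliable enough that conflicts must be surfaced, not resolved by fiat.
Orientation is reported so that the leader (gain) end is on the left.

*Trailer conservation.* Given an orientation, the anchor is the modal
trailer-end label among arrays whose trailer-side end is complete
(ties: smallest label); conservation is the supporting fraction, reported
as undefined when no array is eligible.

## Protospacer matching

The matcher is seed-and-extend: exact k-mer seeds (k = 12) from both
strands of every spacer are indexed, each read is scanned once, and every
seed candidate is extended by an infix alignment (edlib) of the whole
spacer against a ±5 bp window. Identity is matches / spacer length and
coverage is aligned spacer bases / spacer length; defaults of 0.90 / 0.95
are this package's choices. An exact match of length ≥ k always contains
an exact seed, so exact planted spacers are recovered at any position and
strand — the property the acceptance test certifies over 1,000 random
placements. Spacers shorter than k fall back to an exhaustive edlib scan.
Hits overlapping a declared CRISPR interval by ≥ 1 bp (0-based half-open
BED semantics) are kept but flagged excluded, keeping the audit trail;
self-targeting spacers are reported, not filtered.

## Simulator

Defaults: 15 ancestral spacers of 30 bp, 30-bp repeat, 20 lineages,
Poisson(0.3) leader gains and Poisson(0.1) segmental losses per lineage,
geometric loss-block length with mean 3, per-base substitution 0.005,
3 mismatches planted in the trailer repeat, no fragmentation. These are
the conditions under which the orientation-recovery and
anchor-conservation checks run (200 groups of 12 arrays); graph-invariant
sweeps use mixed rates (gain 0–1, loss 0–0.6, fragmentation 0–0.4) over
1,000 seeds with 12-bp sequences to keep the suite fast — the graph
layer sees only labels, so sequence length is immaterial there.

Gains are always novel random sequences (leader-end spacers are observed
to be group-specific; re-acquisition and ectopic mid-array insertion are
deliberately out of the default model). Losses are contiguous blocks and,
with `protect_trailer` (default), never remove the trailer spacer — the
empirically observed regime, and switchable off to test its detection.
Substitutions apply to spacers only; repeat copies stay clean apart from
the planted trailer degeneracy, so the degeneracy score at default
settings is exactly +3. Fragmentation removes whole terminal units (each
end independently, never emptying the array), clears the end's
completeness flag, and with probability ½ also removes the outermost
repeat copy on one truncated end, exercising the
`len(repeats) == len(spacers)` corner of the array format.

Every lineage carries an ordered event list (gain, loss, substitution,
truncation, strand flip) and `GroundTruth.replay` re-applies it to the
ancestor; tests assert byte-identical reproduction of every emitted
array. All draws flow through one `numpy` generator seeded from the
config, so populations are reproducible bit-for-bit.

What the simulator does **not** model: sequencing-error profiles of any
platform (errors enter only as uniform substitutions), GC bias, chimeric
reads, multi-ancestor recombination (groups joined by a single shared
spacer), and inter-group spacer sharing. Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
model, not detector accuracy or robustness to real instrument artefacts.

## Numerical and format conventions

Coordinates are 0-based half-open everywhere; spacer order is read
orientation. Booleans serialize as 0/1 in TSVs; sequence lists are
semicolon-delimited. Redundancy is kept at full precision internally and
rounded to two decimals only for presentation. DOT output draws leader on
the left (`rankdir=LR`); a block that is both source and sink takes the
sink (yellow) styling. Native outputs of CRISPR detectors are not parsed;
the documented array table is the interchange point, and a
detector-specific converter is an extension hook.

## Known limitations

Orientation inference is a heuristic pair of signals; groups with no
branching and uniform repeats are honestly `undetermined`. The greedy
spacer clustering is order-dependent by design (as greedy clusterers
are); the tests pin its behaviour to the documented rule rather than to
any external tool's binary output. The protospacer matcher guarantees
recovery only down to its identity/coverage thresholds and seed length;
heavily diverged protospacers (< 90% identity) are out of scope.
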