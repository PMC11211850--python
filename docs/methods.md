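# Methods

This note records the model implemented by `mladbg`, the choices made where
the design was genuinely open, and what the synthetic data does and does not
emulate.

## Graph model

The graph is a node-centric DBG of order k: nodes are k-mers stored **as
written** (non-canonical), and (v₁, v₂) is an edge exactly when
v₁[2:k] = v₂[1:k−1]. Annotations map each node to a non-empty set of sample
labels. Reverse-complement handling is pushed entirely to the query side:
each read is aligned in both orientations and all records are reported with
their strand. A seed-length-l suffix index (l-mer → nodes with that suffix)
serves both seeding and the suffix queries that a variable-order DBG would
answer natively; no succinct or variable-order structure is maintained
beyond that.

Per-sample cleaning mirrors light assembly-graph cleaning: a noise-count
threshold is chosen by walking down the error flank of the k-mer count
histogram from count 1 until it rises (falling back to 2 when the histogram
is monotone, as at very low depth); unitigs whose median k-mer count is
below the threshold are dropped; dead-end unitigs spelling fewer than 2k
characters that hang off a junction are clipped. Isolated short unitigs are
*kept*: at 1–2× depth they are the sample's signal, and removing them would
empty the graph.

Walk covers are built per label by greedy unitig joining: maximal unitigs,
then joins across branch nodes choosing the lexicographically smallest
unused successor (deterministic), then one two-node walk per edge not
realised by any stored walk. The cover gives O(memberships) traversal
distances via a node → (walk, offset) index; no node-to-walk distance
matrix is stored, so distances between nodes that share no cover walk are
reported unknown and forbid chaining connections. Cover widths are a
by-product of the heuristic and are not calibrated against any external
width statistic.

## Scoring model

Edit operations use integer scores, match positive, everything else
negative, with affine gaps `ΔG(g) = open + (g−1)·extend`. Two additional
operations extend the model:

- **Label change**: `Δ_LC(ℓ₁→ℓ₂) = ⌊λ_LC log₂ Pr(ℓ₁|ℓ₂)⌋` with
  `Pr(ℓ₁|ℓ₂) = |V(ℓ₁)∩V(ℓ₂)|/|V(ℓ₂)|`; zero for ℓ₁=ℓ₂, never positive.
  Flooring (rather than rounding) keeps the integer penalty conservative.
  The intersection is estimated by inclusion–exclusion from per-label
  HyperLogLog union sketches plus exact per-label cardinalities, clipped to
  [0, 1]. A probability estimate of zero maps to a large finite sentinel
  (−2³⁰) rather than literal −∞ so that sums of a few forbidden terms can
  never overflow or poison float arithmetic; the sentinel exceeds any
  achievable chain score by orders of magnitude.
- **Node length change**: free when staying at order k or growing by one;
  `(k−l₂)·Δ_J` when dropping from a full-order node to length l₂ < k;
  forbidden otherwise. Because each skipped character costs at least
  |Δ_J|, an all-short-node walk scores strictly below the plain-match
  bound, which is what prevents degenerate searches. With one label and no
  length changes the model reduces exactly to standard sequence-to-graph
  scoring; the test suite asserts this reduction end to end.

The HyperLogLog uses the smallest register count whose standard error
1.04/√m is at or below the configured error (0.05 → 512 registers), 64-bit
keyed Blake2b hashing (deterministic across processes), and linear counting
for small ranges. Only order-of-magnitude accuracy matters: the quantity
consumed downstream is ⌊log₂ p⌋.

## Chaining

Both stages share one local colinear chaining DP over anchors sorted by end
position, parameterised by a connect callback. Scores are initialised to
`match · length` and updated within a band on anchor end distance; the band
starts at b (default 400) and grows geometrically (default 4×) until the
cost equivalent of the best score found, `⌈2(|Q| − s_best/match)⌉`
(computed in rational arithmetic), is covered by the band last used — a
better chain would need a gap wider than its own cost, so nothing outside
the explored band can improve on it. The forward pass also stops once the
band covers the full anchor span, at which point a single ascending pass is
the exact DP. When anchors outnumber query characters the stage falls back
to a single fixed-band pass with plain affine gap costs on query distance
(graph distances ignored). Backtracking emits chains in decreasing score
order, each anchor joining at most one chain, stopping a trace at the first
already-used anchor; all chains tied at the score cut-off are kept. Ties
among equal-scoring predecessors break towards the smaller query gap, then
the smaller index, making output deterministic.

Connection spans (query gap or traversal distance) above `max_connect_gap`
(default 2000) are refused in the single-label connect. This keeps the
junction alignment dense-matrix-sized; longer joins remain expressible in
the multi-label stage, whose sentinel-gap case is penalty-only and needs no
DP.

## SCA

Anchors are one-per (l-mer occurrence, node, label); runs of same-label
anchors at consecutive offsets whose nodes are adjacent are merged when the
link is unique in both directions within the label (ambiguous runs stay
unmerged; an optional flag additionally requires query-side uniqueness).
Merged anchors store only the terminal node — the walk is re-derived on
demand from the unambiguous predecessor structure.

Per-label chains are scored with `match · (new query chars) +
ΔG(|query-end difference − traversal distance|)`; an unknown traversal
distance forbids the connection. The globally top ⌈ρ|Q|⌉ chains (with
ties) are backtracked and extended in score order, skipping chains that
overlap a completed same-label alignment. Consecutive anchors are joined by
global affine alignment of the intervening query characters against the
spelling of the minimal shared cover walk; chain ends get ends-free
extension: a best-first, banded, X-drop-limited search over label-consistent
walks (the boundary node's unconsumed spelling is consumed before stepping
to neighbours), after which the chosen target string is re-aligned exactly
so the stored edit operations always reproduce the stored score. The
default X-drop is 2·(|open| + 5·|extend|) = 12 and is configurable;
correctness-vs-DP tests use a generous cutoff because they probe the
scoring model, not the pruning heuristic.

## MLC

Anchors are re-extracted at every query offset of every pool alignment
where l consecutive operations are matches and the covering walk node's
l-suffix equals the window. An anchor interior to a run — sole anchor at
its offset with same-alignment anchors on both sides — carries no chaining
information (same-alignment connections telescope through prefix scores)
and is pruned; run heads and tails are kept so chains can enter and leave,
and shared offsets are kept because overlap hops fire at matching offsets.
Pruning provably leaves best chain scores unchanged (tested on fuzzed
pools).

The connection score has three cases: (i) same alignment — the prefix-score
difference; (ii) disjoint alignments — the source alignment's remaining
score, the target's prefix score, the label change, a deletion open for a
sentinel `$` in the spelled target, and an insertion penalty for skipped
query characters; (iii) overlapping alignments (overlap strictly between 0
and k−1, both segments at least k long) — a hop through an intermediate
anchor of the target alignment at the same query offset, paying the label
change plus `(k−l)·Δ_J` when the hop lands on a different node. The hop
penalty deliberately depends on k−l, not on the actual longest common
suffix length, so equally likely single-substitution events score equally.
Among multiple intermediate candidates the scorer prefers the identical
node (no NC), then the longest common suffix, then lexicographic order.
One chain is backtracked per distinct terminal-anchor label, anchors
globally single-use, and each chain is stitched by splicing pool segments
at anchor boundaries. The stitched total — segment prefix-score
differences, with the opening seed scored as bare matches, plus junction
terms — must equal the chain score exactly; the stitcher raises on any
mismatch, making the identity an enforced invariant rather than a hope.

Reported output in the multi-label modes includes the single-label pool
alongside the stitched alignments: a single-label alignment is a degenerate
multi-label alignment, and chains truncate at their terminal anchors, so
the pool record can legitimately outscore its stitched counterpart on
intact regions. `sca+lc` disables case-(iii) hops onto different nodes
(no node length changes) but keeps same-node hops and sentinel gaps.

## Synthetic cohorts

The generator evolves n genomes from a random root down a random binary
tree (substitutions at the per-branch rate, short indels at a tenth of it),
samples reads to a target depth with parametric profiles
(`short-accurate` ≈ 150 bp, 0.12% error; `long-noisy` ≈ 5–20 kb
log-uniform, 10% error; `long-accurate` ≈ 5–20 kb, 0.5% error), counts
strand-symmetric spectra (each read plus its reverse complement, matching
how canonical-k-mer graph builders treat double-stranded data), cleans each
sample, and merges the survivors into the annotated graph. The simulation
tree doubles as the evaluation taxonomy, one leaf per sample.

Default cohort conditions — six genomes of ~50 kb at 2% divergence per
branch, depths drawn uniformly from 1–2×, twenty `long-noisy` queries —
produce per-sample subgraphs retaining roughly half of each genome's
k-mers in many fragments, the regime the method targets. What the
generator does **not** emulate: real base-quality profiles, chimeric or
multi-pass reads, repeat structure and compositional bias of real genomes,
and cohort sizes beyond a handful of samples. Passing tests therefore
demonstrate the model's behaviour under idealised fragmentation and
divergence, not performance on real sequencing archives; on real data the
label-change statistics in particular would be shaped by shared repeats
that random sequences lack.

## Evaluation

Reported alignments carry covered query intervals (a multi-label alignment
covers its segments, not its sentinel gaps). For a relative-score cut-off
(score divided by query length) the reported set is the greedy disjoint
pick by decreasing relative score, judged on covered intervals. Recall at a
cut-off is the fraction of reads with a reported alignment; taxonomic
profiles weight each accession by its covered-character share; profile
error is classical normalized abundance-weighted UniFrac on the simulation
tree (computed by scikit-bio), and accuracy is one minus the error — a
deliberate substitution for rank-calibrated variants of the measure, which
need a reference taxonomy with named ranks. Sweeps run cut-offs 0.00–1.00
in steps of 0.02. The headline fragmentation-rescue comparison uses the
coverage of each read's best-scoring alignment, the statistic that isolates
alignment contiguity from pool union coverage.

## Problem sizes and numerics

The shipped experiment sizes (six 50 kb genomes, twenty queries, and
fuzzing batches of 100–500 instances) were chosen as the smallest sizes at
which every claimed property is exercised with clear margins. All chain and
alignment scores are integers end to end; the only floating-point
quantities are sketch estimates (inside a floored log) and evaluation
summaries. Determinism: all randomness flows through explicitly seeded
generators, tie-breaks are total orders, and the sketch hash is fixed, so
every pipeline output is bit-reproducible given the seed.

## Known limitations

- Traversal distances exist only along cover walks, so legitimate
  single-label connections crossing cover-walk boundaries are invisible to
  SCA (they surface later as MLC sentinel joins); a richer distance index
  would lengthen pool alignments.
- Ends-free extension is heuristic (banded best-first with X-drop and an
  expansion cap); on highly branching subgraphs it may miss the optimal
  extension walk.
- The chain-forward fallback for anchor-rich queries ignores graph
  distances entirely; its chains are re-scored through the model and may be
  dropped if they contain forbidden junctions.
- Multi-label chains cannot connect alignments overlapping by k−1 or more;
  in dense cohorts where samples overlap heavily, the model (by design)
  leaves such pairs to single-label alignment.
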