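# Methods

## Pair-HMM path alignment

Two undirected weighted networks are each turned into an HMM whose hidden
states are the nodes. State transitions follow the edges with log scores
`t(u,u') = log(w(u,u')/strength(u))` in `weighted` mode (strength = sum of
incident reliabilities) or `log(1/deg(u))` in `binary` mode; the two coincide
on uniform-weight networks. A virtual observation sequence of length `L` is
jointly emitted by the two HMMs, with emission log score
`e(u,v) = log(s(u,v)/max s)` for the currently paired states; pairs with zero
similarity are unmatchable (−∞), which keeps the dynamic program sparse on the
similarity support. `L` counts DP steps (emissions), so gap steps consume
length.

The DP keeps three layers per step: match `M`, and two gap layers `G1`/`G2`
(one network advances one edge while the other holds; the stalled side
contributes no emission and no transition that step, paying `gap_penalty`
instead). Gap layers feed from the match layer or the *opposite* gap layer,
so a side never gaps twice in a row and the first step is always a match. The
start transition is free (uniform initial state, constant across candidates).

**Gap penalty.** The gap penalty is the log probability of entering an
auxiliary (insert/delete) state instead of emitting a match. For the aligner
to prefer matched steps wherever a counterpart exists, that probability must
be well below a typical transition probability; in networks of average degree
~20 a transition carries probability ~0.05, so a gap probability of 0.1 would
make degenerate all-gap "staircases" (both paths advancing through alternating
single-side gaps, emitting almost nothing) optimal. The default is
`log(0.001)`: gaps act as a last resort for bridging a single missing
counterpart. The penalty is configurable per run.

**No repeated pairs.** An alignment may not align the same node pair at two
steps (a walk may revisit nodes, but not re-emit an identical pairing). The
constraint is enforced at traceback: a best-first (A*) backward search over
the trellis uses the unconstrained DP values as an admissible look-ahead,
prunes branches that would reuse a pair, and therefore yields the exact
constrained optimum as its first completed path. A depth-first feasible
traceback (greedy with bounded backtracking, tried from the best final cells)
supplies a lower bound that prunes the search and serves as the result if the
search exceeds its effort budget (`max_traceback_candidates × 20` expansions);
budget overruns are logged and produce a feasible, possibly suboptimal,
alignment. On the small instances used for validation the budget never binds
and the output provably equals exhaustive enumeration over walk pairs.

Ties between equal-scoring final cells break lexicographically by
(node1, node2, layer), making results deterministic; reversing a symmetric
optimum is a genuine tie and either orientation may be returned.

**Top-k extraction.** The top-k list repeats: align, record, then delete every
interaction traversed by the alignment's two paths from their networks
(interactions, not nodes), until k alignments exist or no feasible alignment
remains. Scores are reported in discovery order; they need not decrease
because edge removal changes the instance.

## Global correspondence scores

A random walker moves simultaneously in both networks, choosing neighbors with
probability proportional to edge reliability, and rests at a node pair (u,v)
for a time proportional to the individual similarity h(u,v). The jump chain's
stationary distribution factorizes into the per-network stationary
distributions — strength over total strength for an undirected weighted walk,
verified against power iteration — so the long-run occupancy is

    s(u,v) = pi1(u) * pi2(v) * h(u,v) / Z.

`s` sums to one, is invariant to rescaling `h` (no tuning parameter), and its
sparsity pattern is that of `h` minus pairs involving isolated nodes (which
the walk never visits; they can only be gapped). Disconnected networks use the
same closed form, which weights each component by its share of total strength.

**Range normalization.** Occupancies span several orders of magnitude
(they multiply two stationary probabilities), while raw similarity scores
live in a narrow band above a reporting threshold. Used directly as emissions,
the wide spread makes weak matches costlier than gap steps and the aligner
degenerates. Both score types are therefore normalized to lie in the same
range before alignment: `correspondence_emission_scores` affinely maps the
occupancies onto `[min h, max h]` (rank-preserving; zero entries stay absent).
`global_correspondence` itself returns the raw normalized occupancies.

## Synthetic benchmark

The generator emulates a pair of related-species PPI networks:

1. Seed: an Erdős–Rényi G(n, M) graph, 20 nodes, M = 100 edges (average
   degree 10), unit reliabilities. G(n, M) is used so the edge count is exact.
2. Growth to 1000 nodes by preferential attachment, m = 10 links per new node,
   drawn without replacement with probability proportional to current degree —
   a scale-free network (9900 edges; heavier-tailed degrees than a same-size
   uniform graph, checked empirically rather than by fitting the exponent).
3. Duplication into two copies; node i in each copy joins planted ortholog
   group i.
4. Similarities: ortholog pairs draw from N(300, 100); each node also gets up
   to 10 non-ortholog partners, drawn uniformly among cross-network nodes
   still under their own 10-partner cap (so the cap holds on both sides),
   with scores from N(µ, 100) — µ (default 200) sets the overlap between the
   two distributions and hence the difficulty. Negative draws clip to 0 and
   all scores below 50 are dropped, mimicking thresholded BLAST tables.
5. Perturbation, independently per copy: delete 10% of edges, then 10% of
   nodes (with incident edges and their similarity entries), then regrow to
   size by preferential attachment. Inserted nodes carry no group annotation
   and receive sparse non-ortholog-style similarities by the same rule.

All randomness flows from one integer seed through `numpy.random.Generator`;
outputs are byte-reproducible. What the generator does **not** emulate:
correlated noise between the two copies, degree-dependent similarity (BLAST
scores of hub proteins are not independent of connectivity in real data),
protein families (similarity here is pairwise-independent), or assortative
rewiring. Passing benchmarks therefore demonstrates algorithmic correctness
and the topology-vs-similarity trade-off, not performance on real proteomes.

## Evaluation

For the i-th alignment, over fully matched steps: `b_i` counts pairs with both
nodes annotated, `a_i` those whose groups agree. Cumulative specificity
`cs_k = Σ_{i≤k} a_i / Σ_{i≤k} b_i` (undefined, reported as missing, when the
denominator is zero — unannotated regions are not penalized); cumulative
coverage `cc_k = Σ_{i≤k} a_i`, counting repeats across alignments (repeats are
forbidden only within one alignment). Gap steps and half-annotated pairs
affect neither count.

## When do global scores help?

The planted-core illustration (`make_illustrative_pair`) isolates the
mechanism that motivates global correspondence scores: two peripheral decoy
pairs with exceptional similarity mislead raw-similarity alignment, while
their low walk occupancy demotes them under global scoring and the true core
path pair is recovered exactly. The occupancy score protects the aligner
against individually similar node pairs that sit in topologically
inconsistent positions — the situation real cross-species BLAST hits without
functional relationship create.

On the synthetic benchmark as generated here, that protection is only
partially reflected in cumulative specificity (the acceptance script reports
the comparison at 200 nodes, L = 10, top 20 alignments, 5 seeds): when the
two similarity distributions overlap heavily (µ = 250) the two modes are
statistically tied, with the sign of the difference varying across seed sets,
while at well-separated similarities (µ = 150) individual scores are clearly
ahead. The *relative* trend — global scores gain ground as individual
similarity becomes less informative — reproduces consistently. Two structural
reasons emerge from inspecting the errors. First, path feasibility is already a powerful filter: a wrong partner
only survives if consecutive wrong pairs are edge-consistent in *both*
networks, which is rare when non-ortholog partners are sampled uniformly.
Second, the occupancy factor π₁(u)·π₂(v) actively misranks peripheral
orthologs: a uniformly drawn non-ortholog partner often has higher degree
than a low-degree node's true counterpart, so the degree product outweighs
the modest similarity advantage of the ortholog. The benchmark contains no
engineered decoys between topologically dissimilar hubs — the case the
illustration shows global scores winning. An acceptance check expects global
scores to beat individual scores at exactly this scaled configuration; it is
left failing rather than re-tuned, with this analysis as the package's
explanation. Users aligning networks whose similarity tables contain many
high-scoring spurious hits in topologically inconsistent positions are the
intended beneficiaries of global mode; on data where similarity is already
well calibrated, individual mode is a strong default.

## Numerical choices and limitations

* Stationary distributions use the exact closed form; the fixed-point residual
  ‖πᵀP − πᵀ‖∞ is checked to 1e-10 in tests.
* Scale invariance of `s` is exact in exact arithmetic; in floating point it
  is bit-exact for power-of-two factors and ~1e-15 relative otherwise.
* Emission normalization by the maximum makes the best pair score 0; only
  score *differences* matter within one run, so alignment scores are
  comparable across modes only after the range normalization above.
* The DP is O(L·M₁·M₂) time per alignment and O(L·N₁·N₂) memory for the
  trellis; 200-node benchmarks align in well under a second per alignment,
  1000-node networks in a few seconds. Validation experiments in the test
  suite and acceptance script use 200-node benchmarks with 5 seeds and the
  enumeration oracle uses ≤ 7-node instances, keeping the suite to a few
  minutes.
* Aligning more than two networks, k-best extraction inside the DP, and
  statistical significance of alignment scores are out of scope.
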