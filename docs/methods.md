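# Methods

## Semantic similarity from GO annotation

Annotations are propagated transitively: a protein directly annotated to a
term is annotated to every ancestor of that term. Parentage follows `is_a`
edges by default; `part_of` is opt-in (`--include-part-of`), since `is_a`
is the one unambiguously transitive relation. All three GO namespaces are
pooled by default and S_max is the global maximum annotation size; a
`--namespace` flag restricts to one namespace. All GAF evidence codes are
used unless excluded (`--exclude-evidence IEA ...`).

The similarity between proteins x and y uses the annotation size m of the
most specific term they share: S_sem = 1 − ln(m)/ln(S_max), clamped to
[0, 1]. This realizes the intended qualitative behavior — normalized range,
1 when the shared term annotates a single protein, 0 when only a namespace
root is shared, and monotone: a more specific shared term never lowers the
score. The number of shared terms |C(x, y)| enters only through m in the
default scheme; the scheme is a pluggable callable `(m, c_size, s_max) ->
score`, so variants that use |C(x, y)| directly can be swapped in without
touching any caller. Proteins without usable annotation participate in the
network with S_sem = 0 on all their edges. S_max < 2 (a corpus with a
single annotated protein) leaves every scheme undefined and is a hard
error. Identifiers are case-sensitive exact strings; no aliasing layer.

## Edge, vertex weights and the seed queue

The topology weight of edge (u, v) is |N(u) ∩ N(v)|, and the edge weight is
its unscaled sum with S_sem. The two components live on different scales
(integer counts vs a unit interval) and the shared-neighbor count dominates
in dense graphs; this is deliberate, matching the method as published. An
optional `--normalize-topo` divides topology weights by the graph-wide
maximum for users who want commensurate scales.

Vertex weight is the sum of incident edge weights. The seed queue sorts
vertices by weight, ties by degree, final ties by ascending id — the
published ordering specifies only the first two levels; the lexicographic
tie-break is ours, added so that identical inputs always produce
byte-identical outputs.

## Cluster expansion

E_vK = e_vK / w_K, the candidate's total edge weight into the cluster over
the cluster's internal edge weight. From a singleton seed w_K = 0 and E_vK
is undefined, so the first admission takes the heaviest-edge neighbor
unconditionally (the diameter condition is vacuous for a single edge) and
is logged with a sentinel; this mirrors the seed-edge behavior of the
seeded-expansion family this method belongs to. Candidate priority is E_vK,
ties by larger absolute e_vK, then ascending id. Admission requires
E_vK ≥ T_in and induced-subgraph diameter of K + v at most d; a
disconnected K + v has sentinel diameter ∞ and fails automatically. The
diameter bound is interpreted as the full induced diameter (not just the
candidate's eccentricity), the stricter and more common reading. After each
admission all candidates are re-ranked on the updated cluster.

Defaults T_in = 0.4 (the threshold with the best benchmark F-measure),
d = 2, min_size = 2. Removal from the seed queue only disqualifies vertices
as future seeds; they may still join later clusters, so predictions can
overlap. Exact duplicate member sets are reported once; proper subsets are
kept. A cluster whose internal weight is 0 after the bootstrap admission
(possible only when every incident weight is exactly 0) cannot be judged
further and is closed as a pair.

## Evaluation metrics

NA(p, b) = |V_p ∩ V_b|²/(|V_p||V_b|); p and b match when NA ≥ ω (default
0.25). Precision = N_cp/|P|, recall = N_cb/|B|, F their harmonic mean
(defined 0 when both are 0). Sn, PPV and Acc = √(Sn·PPV) come from the
benchmark-by-prediction overlap-count matrix; PPV is defined 0 when the
matrix is all zero. The hypergeometric functional-homogeneity p-value is
the upper tail P(X ≥ k), the standard one-sided enrichment convention,
computed with scipy's log-space implementation; the reported fraction of
significant clusters uses raw p-values at α = 0.01 with no multiplicity
correction, matching how such fractions are conventionally reported for
this task. Functional groups default to the protein sets of directly
annotated GO terms when no explicit group file is given. An optional
`--min-benchmark-size` restricts matching to benchmark complexes above a
size floor (e.g. 3 to count only complexes larger than two proteins).

## Synthetic data

The generator emulates what the method assumes about real data: dense,
functionally homogeneous complexes in a sparse background. Each planted
complex is an Erdős–Rényi group at internal probability `p_in` over a
disjoint member set; all cross-group and background pairs are wired at
`p_out` < `p_in`. Members are annotated to a complex-specific leaf term of
a three-level toy ontology (root → family → complex term) with probability
`annotation_fidelity`; the benchmark file is exactly the planted truth. One
explicit integer seed drives all randomness; the same seed gives
byte-identical files. Default conditions: 5 complexes of size 4–6, p_in =
1.0, p_out = 0.0, 20 background proteins, fidelity 1.0 — the noiseless
regime in which the algorithm must recover the truth exactly. Test suites
use 8–30 complexes with p_in = 0.9 and p_out = 0.02–0.05, sizes chosen so
the whole suite runs in seconds on one core.

What the generator does *not* emulate: the heavy-tailed degree
distributions of real PPI data, overlapping or nested true complexes,
correlated false-positive edges from specific assays, and the
16 000-term scale of the real GO. Passing tests therefore demonstrate
correctness of the algorithms and metrics, not field performance on
Gavin/BioGrid-scale data — the CLI accepts those files, but their headline
benchmark numbers depend on the specific releases used.

## Numerical and design notes

- All orderings (seed queue, candidate ranking, output files) are fully
  deterministic; every tie chain ends in a lexicographic id comparison.
- E_vK comparisons are exact float comparisons; candidate E values are
  ratios with a common denominator, so ranking is stable.
- Degenerate inputs fail fast with typed errors: cyclic ontologies, GAF
  files with zero usable rows, empty edge lists, empty complexes in NA,
  inconsistent hypergeometric counts.
- The published account leaves three quantities implicit, fixed here as:
  the similarity closed form above; E_vK = e_vK/w_K (the ratio its variable
  definitions imply); and d = 2. One published worked NA value (0.816667
  for a printed 13-member cluster) is inconsistent with any integer
  overlap/benchmark size under the adopted NA form, likely reflecting a
  differing member count in the original run; the three consistent worked
  values are reproduced exactly.
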