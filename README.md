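# oiip — protein complex detection on GO-weighted interaction networks

Protein complexes leave two footprints: they are dense subgraphs of the
physical protein–protein interaction (PPI) network, and their members share
biological function. High-throughput PPI data are noisy, so clustering the
raw graph alone mixes true complexes with spurious edges. `oiip` implements
the OIIP approach: it first converts the unweighted PPI network into a
weighted graph whose edge weights score interaction *reliability* — a Gene
Ontology (GO) semantic similarity between the two proteins plus a
shared-neighbor topology weight — and then grows complexes greedily from
high-weight seed vertices. It is aimed at computational biologists who want
a small, fully scriptable complex-detection pipeline with built-in
benchmarking.

## Model

**Edge weights.** For proteins *x*, *y* annotated in GO, let *m* =
min<sub>j</sub>|S<sub>j</sub>(x, y)| be the annotation size of the most
specific GO term shared by both (annotations propagate transitively to the
namespace root), and S<sub>max</sub> the largest annotation size in the DAG.
The default similarity scheme is

&nbsp;&nbsp;&nbsp;&nbsp;S<sub>sem</sub>(x, y) = 1 − ln *m* / ln S<sub>max</sub> ∈ [0, 1],

which is 1 when the shared term is maximally specific and 0 when only a
root is shared (the scheme is pluggable). The edge weight is
w(u, v) = S<sub>sem</sub>(u, v) + |N(u) ∩ N(v)|, the second term being the
number of neighbors shared by the endpoints.

**Clustering.** Each vertex weighs the sum of its incident edge weights;
vertices enter a seed queue Sq sorted by weight (ties: degree, then id).
From each seed, the cluster K repeatedly admits the external neighbor *v*
with the highest interaction probability E<sub>vK</sub> =
e<sub>vK</sub>/w<sub>K</sub> (v's edge weight into K over K's internal
weight), provided E<sub>vK</sub> ≥ T<sub>in</sub> and the induced diameter
of K + v stays ≤ d. Members of a finished cluster leave the queue; clusters
may overlap. Defaults: T<sub>in</sub> = 0.4, d = 2, minimum reported size 2.

**Evaluation.** Predictions are scored against a benchmark catalogue with
the neighborhood affinity NA(p, b) = |V<sub>p</sub> ∩ V<sub>b</sub>|² /
(|V<sub>p</sub>|·|V<sub>b</sub>|) at matching threshold ω (default 0.25),
yielding precision/recall/F; with the cluster-wise Sn/PPV/Acc triple from
the overlap-count matrix T<sub>ij</sub>; and with hypergeometric
upper-tail enrichment p-values (functional homogeneity).

## Worked example

Generate a synthetic data set with five planted complexes (90 % internal
edge density, 2 % background noise, 90 % annotation fidelity), detect
complexes, and score them against the planted truth:

```sh
oiip simulate --seed 11 --out demo/data --n-complexes 5 \
     --p-in 0.9 --p-out 0.02 --n-background 15 --fidelity 0.9
oiip cluster  --network demo/data/network.tsv --obo demo/data/ontology.obo \
     --gaf demo/data/annotations.gaf --out demo/run
oiip evaluate --predictions demo/run/clusters.txt \
     --benchmark demo/data/benchmark.txt --out demo/eval
```

The evaluate step prints:

```
precision=0.428571 recall=1.000000 f=0.600000 sn=0.962963 ppv=1.000000 acc=0.981307
```

Every planted complex was recovered (recall = 1; Sn = 0.96 means 96 % of
benchmark protein slots are covered by some predicted cluster), while the
noise edges additionally produced small spurious clusters that depress
precision — the usual trade-off this family of seeded expanders shows on
noisy networks. `demo/run/clusters.txt` holds one complex per line;
`clusters_verbose.tsv` records each cluster's seed and admission trace.
Real data drop in the same way: a two-column edge list, a GO release in OBO
format, and a GAF 2.x annotation file (`oiip cluster --help` lists
namespace/evidence-code filters), with `oiip cluster --tin-grid
0.1:0.9:0.1` sweeping the admission threshold.

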