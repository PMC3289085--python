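"""Seeded synthetic inputs: toy ontologies, annotations and planted-complex networks.

The planted-network generator emulates the statistical structure the
clustering method assumes — dense, functionally homogeneous protein groups
embedded in a sparse noisy background — with the planted truth doubling as
the benchmark catalogue, so the whole pipeline is testable end to end
without any external download.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from pathlib import Path

_NS_ASPECT = {
    "biological_process": "P",
    "molecular_function": "F",
    "cellular_component": "C",
}
_CHROM = "ABCDEFGHIJKLMNOP"


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted-complex network.

    p_in / p_out are the within-complex and background edge probabilities;
    annotation_fidelity is the probability that a complex member carries a
    direct annotation to its complex's dedicated GO term.
    """

    n_complexes: int = 5
    complex_size_range: tuple[int, int] = (4, 6)
    p_in: float = 1.0
    p_out: float = 0.0
    n_background_proteins: int = 20
    annotation_fidelity: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.complex_size_range
        if lo < 3 or hi < lo:
            raise FixtureError("complex sizes must be >= 3 and the range ordered")
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise FixtureError("require 0 <= p_out < p_in <= 1")
        if not 0.0 <= self.annotation_fidelity <= 1.0:
            raise FixtureError("annotation_fidelity must be in [0, 1]")
        if self.n_complexes < 1:
            raise FixtureError("need at least one planted complex")
        if self.rng_seed is None:
            raise FixtureError("an explicit rng_seed is mandatory")


@dataclass
class FixtureBundle:
    """The four generated text files plus the planted truth."""

    obo_text: str
    gaf_text: str
    edge_list_text: str
    benchmark_text: str
    truth: list[frozenset[str]]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "obo": out / "ontology.obo",
            "gaf": out / "annotations.gaf",
            "edges": out / "network.tsv",
            "benchmark": out / "benchmark.txt",
        }
        paths["obo"].write_text(self.obo_text)
        paths["gaf"].write_text(self.gaf_text)
        paths["edges"].write_text(self.edge_list_text)
        paths["benchmark"].write_text(self.benchmark_text)
        return paths


def _protein_id(n: int) -> str:
    """Deterministic yeast-ORF-like identifier (purely cosmetic)."""
    chrom = _CHROM[(n // 200) % len(_CHROM)]
    arm = "LR"[(n // 100) % 2]
    strand = "WC"[n % 2]
    return f"Y{chrom}{arm}{n % 1000:03d}{strand}"


def _obo_header() -> list[str]:
    return ["format-version: 1.2", "ontology: toy-go", ""]


def _term_stanza(tid: str, name: str, namespace: str, parents: list[str]) -> list[str]:
    lines = ["[Term]", f"id: {tid}", f"name: {name}", f"namespace: {namespace}"]
    lines += [f"is_a: {p} ! parent" for p in parents]
    lines.append("")
    return lines


def make_toy_ontology(
    n_terms_per_namespace: int = 8,
    depth: int = 3,
    rng_seed: int = 0,
    namespaces: tuple[str, ...] = ("biological_process",),
) -> str:
    """Generate OBO text: one root per namespace, a layered DAG below it.

    Terms are spread over ``depth - 1`` levels under the root; each picks one
    parent in the level above and, with probability 0.25, a second parent,
    so the result is a genuine DAG rather than a tree.
    """
    if depth < 2:
        raise FixtureError("depth must be >= 2")
    if n_terms_per_namespace < 2:
        raise FixtureError("need at least a root and one child per namespace")
    rng = random.Random(rng_seed)
    lines = _obo_header()
    for ns_idx, ns in enumerate(namespaces):
        base = 100000 * (ns_idx + 1)
        root = f"GO:{base:07d}"
        lines += _term_stanza(root, f"{ns} root", ns, [])
        levels: list[list[str]] = [[root]]
        n_children = n_terms_per_namespace - 1
        per_level = max(1, n_children // (depth - 1))
        made = 0
        for level in range(1, depth):
            level_terms: list[str] = []
            quota = n_children - made if level == depth - 1 else per_level
            for _ in range(quota):
                made += 1
                tid = f"GO:{base + made:07d}"
                parents = [rng.choice(levels[level - 1])]
                if len(levels[level - 1]) > 1 and rng.random() < 0.25:
                    second = rng.choice(levels[level - 1])
                    if second not in parents:
                        parents.append(second)
                lines += _term_stanza(tid, f"{ns} term {made}", ns, parents)
                level_terms.append(tid)
            if level_terms:
                levels.append(level_terms)
    return "\n".join(lines) + "\n"


def _gaf_row(protein: str, term: str, namespace: str) -> str:
    aspect = _NS_ASPECT[namespace]
    cols = [
        "TOY", protein, protein, "", term, "TOY:0001", "IDA", "",
        aspect, f"{protein} protein", "", "protein", "taxon:4932",
        "20110101", "TOY",
    ]
    return "\t".join(cols)


def make_planted_network(spec: FixtureSpec, max_retries: int = 50) -> FixtureBundle:
    """Generate a planted-complex bundle from *spec*.

    Each complex is an Erdős–Rényi-dense group at ``p_in`` over a dedicated
    disjoint protein set; background proteins and all cross-group pairs are
    wired at ``p_out``.  Complex members are annotated to a complex-specific
    leaf GO term with probability ``annotation_fidelity``; the ontology is a
    three-level DAG (root → family → complex term) in the biological_process
    namespace.  The benchmark text is exactly the planted truth.
    """
    rng = random.Random(spec.rng_seed)
    ns = "biological_process"
    lo, hi = spec.complex_size_range

    sizes = [rng.randint(lo, hi) for _ in range(spec.n_complexes)]
    counter = itertools.count()
    complexes = [
        frozenset(_protein_id(next(counter)) for _ in range(size)) for size in sizes
    ]
    background = [_protein_id(next(counter)) for _ in range(spec.n_background_proteins)]
    membership = {p: i for i, c in enumerate(complexes) for p in c}

    # ontology: root, one intermediate, one leaf per complex
    base = 100000
    root = f"GO:{base:07d}"
    mid = f"GO:{base + 1:07d}"
    leaf = {i: f"GO:{base + 2 + i:07d}" for i in range(spec.n_complexes)}
    lines = _obo_header()
    lines += _term_stanza(root, "biological_process root", ns, [])
    lines += _term_stanza(mid, "complex assembly family", ns, [root])
    for i in range(spec.n_complexes):
        lines += _term_stanza(leaf[i], f"planted complex {i} process", ns, [mid])
    obo_text = "\n".join(lines) + "\n"

    # internal edges, regenerating any complex that came out edgeless
    edges: set[tuple[str, str]] = set()
    for i, c in enumerate(complexes):
        members = sorted(c)
        for attempt in range(max_retries):
            internal = {
                (u, v)
                for u, v in itertools.combinations(members, 2)
                if rng.random() < spec.p_in
            }
            if internal:
                break
        else:
            raise FixtureError(f"complex {i} has no internal edges after {max_retries} tries")
        edges |= internal

    all_proteins = sorted(set(membership) | set(background))
    for u, v in itertools.combinations(all_proteins, 2):
        if membership.get(u) is not None and membership.get(u) == membership.get(v):
            continue
        if rng.random() < spec.p_out:
            edges.add((u, v) if u < v else (v, u))

    gaf_rows = []
    for i, c in enumerate(complexes):
        for p in sorted(c):
            if rng.random() < spec.annotation_fidelity:
                gaf_rows.append(_gaf_row(p, leaf[i], ns))
    gaf_text = "!gaf-version: 2.1\n" + "\n".join(gaf_rows) + "\n"

    edge_list_text = "# planted-complex toy network\n" + "\n".join(
        f"{u}\t{v}" for u, v in sorted(edges)
    ) + "\n"
    benchmark_text = "\n".join("\t".join(sorted(c)) for c in complexes) + "\n"
    return FixtureBundle(
        obo_text=obo_text,
        gaf_text=gaf_text,
        edge_list_text=edge_list_text,
        benchmark_text=benchmark_text,
        truth=list(complexes),
    )
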