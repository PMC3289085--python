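"""Gene Ontology structure, annotation propagation and protein semantic similarity.

The similarity between two proteins is derived from the *annotation size* of
the most specific GO term both are annotated to: a term annotating few
proteins is specific, one annotating many (ultimately a namespace root) is
uninformative.  Annotations propagate transitively: a protein annotated to a
term is annotated to every ancestor of that term up to the namespace root.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import obonet

logger = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies or annotation corpora."""


@dataclass(frozen=True)
class GOTerm:
    """A single non-obsolete GO term with its ``is_a`` (optionally ``part_of``) parents."""

    id: str
    name: str
    namespace: str
    parents: frozenset[str] = frozenset()
    obsolete: bool = False


class OntologyDAG:
    """GO terms indexed by accession, with memoised ancestor closures.

    Parameters
    ----------
    terms
        Mapping of accession to :class:`GOTerm`.  Must be acyclic; every
        term must reach a parentless root of its namespace.
    """

    def __init__(self, terms: Mapping[str, GOTerm]):
        self.terms: dict[str, GOTerm] = dict(terms)
        self._check_acyclic()
        self.roots: dict[str, str] = {}
        for t in self.terms.values():
            if not t.parents:
                # one root per namespace; ties are not expected from GO but tolerated
                self.roots.setdefault(t.namespace, t.id)
        self._anc_cache: dict[str, frozenset[str]] = {}

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def _check_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        color = dict.fromkeys(self.terms, WHITE)
        for start in self.terms:
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, Iterable[str]]] = [(start, iter(self._parents(start)))]
            color[start] = GREY
            while stack:
                node, it = stack[-1]
                for nxt in it:
                    if color.get(nxt, BLACK) == GREY:
                        raise OntologyError(f"cycle detected in ontology involving {nxt}")
                    if color.get(nxt, BLACK) == WHITE:
                        color[nxt] = GREY
                        stack.append((nxt, iter(self._parents(nxt))))
                        break
                else:
                    color[node] = BLACK
                    stack.pop()

    def _parents(self, term_id: str) -> frozenset[str]:
        term = self.terms.get(term_id)
        if term is None:
            return frozenset()
        return frozenset(p for p in term.parents if p in self.terms)

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Reflexive ancestor closure of ``term_id`` (includes the term itself)."""
        cached = self._anc_cache.get(term_id)
        if cached is not None:
            return cached
        if term_id not in self.terms:
            raise KeyError(term_id)
        out = {term_id}
        frontier = list(self._parents(term_id))
        while frontier:
            p = frontier.pop()
            if p not in out:
                out.add(p)
                frontier.extend(self._parents(p))
        result = frozenset(out)
        self._anc_cache[term_id] = result
        return result


def parse_obo(obo_text: str, include_part_of: bool = False) -> OntologyDAG:
    """Parse OBO 1.2/1.4 text into an :class:`OntologyDAG`.

    Obsolete terms are dropped.  Parentage follows ``is_a`` edges;
    ``part_of`` relationships are included only when *include_part_of* is
    set.  Terms without a namespace are rejected with a logged warning.
    """
    graph = obonet.read_obo(io.StringIO(obo_text), ignore_obsolete=True)
    terms: dict[str, GOTerm] = {}
    rejected = 0
    relations = ("is_a", "part_of") if include_part_of else ("is_a",)
    for node, data in graph.nodes(data=True):
        ns = data.get("namespace")
        if ns is None:
            rejected += 1
            logger.warning("term %s has no namespace; rejected", node)
            continue
        parents = {
            parent
            for _, parent, key in graph.out_edges(node, keys=True)
            if key in relations
        }
        terms[node] = GOTerm(
            id=node,
            name=data.get("name", node),
            namespace=ns,
            parents=frozenset(parents),
        )
    if rejected:
        logger.warning("%d term(s) rejected for missing namespace", rejected)
    # drop dangling parent references (e.g. parents that were obsolete)
    cleaned = {
        tid: GOTerm(t.id, t.name, t.namespace, frozenset(p for p in t.parents if p in terms))
        for tid, t in terms.items()
    }
    return OntologyDAG(cleaned)


def parse_gaf(
    gaf_text: str,
    dag: OntologyDAG,
    exclude_evidence: Iterable[str] = (),
    id_column: str = "id",
) -> dict[str, set[str]]:
    """Read GAF 2.x annotation rows into a protein -> direct-term map.

    Rows whose qualifier contains ``NOT``, whose term is absent from *dag*,
    whose evidence code is excluded, or that have fewer than 15 columns are
    skipped (each category counted and logged).  Raises
    :class:`OntologyError` when no usable row remains.

    *id_column* selects the protein identifier: ``"id"`` uses the DB Object
    ID column, ``"symbol"`` the DB Object Symbol column.
    """
    if id_column not in ("id", "symbol"):
        raise ValueError(f"id_column must be 'id' or 'symbol', got {id_column!r}")
    col = 1 if id_column == "id" else 2
    excluded = set(exclude_evidence)
    direct: dict[str, set[str]] = {}
    n_malformed = n_not = n_unknown = n_evidence = 0
    for line in gaf_text.splitlines():
        if not line.strip() or line.startswith("!"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 15:
            n_malformed += 1
            continue
        qualifier, term, evidence = fields[3], fields[4], fields[6]
        if "NOT" in qualifier.split("|"):
            n_not += 1
            continue
        if evidence in excluded:
            n_evidence += 1
            continue
        if term not in dag:
            n_unknown += 1
            continue
        direct.setdefault(fields[col], set()).add(term)
    for label, n in (
        ("malformed", n_malformed),
        ("NOT-qualified", n_not),
        ("unknown/obsolete-term", n_unknown),
        ("excluded-evidence", n_evidence),
    ):
        if n:
            logger.warning("skipped %d %s GAF row(s)", n, label)
    if not direct:
        raise OntologyError("no usable annotation rows in GAF input")
    return direct


@dataclass
class AnnotationIndex:
    """Transitively propagated protein/term annotation maps.

    ``transitive_by_term[t]`` is the set of proteins annotated (directly or
    through descendants) to term ``t``; ``s_max`` is the largest such set —
    the annotation size of the busiest namespace root.
    """

    direct: dict[str, set[str]]
    transitive_by_term: dict[str, frozenset[str]]
    terms_by_protein: dict[str, frozenset[str]]
    s_max: int
    corpus: frozenset[str] = field(default_factory=frozenset)

    def annotation_size(self, term_id: str) -> int:
        return len(self.transitive_by_term.get(term_id, ()))


def propagate_annotations(
    direct: Mapping[str, set[str]],
    dag: OntologyDAG,
    namespace: str | None = None,
) -> AnnotationIndex:
    """Propagate direct annotations up the DAG and build the index.

    Each protein's transitive term set is the union of the reflexive
    ancestor closures of its direct terms.  With *namespace* set, terms
    outside that namespace are ignored; by default all three namespaces are
    pooled and ``s_max`` is the global maximum annotation size.
    """
    if not direct:
        raise OntologyError("empty annotation map: no corpus to index")
    terms_by_protein: dict[str, frozenset[str]] = {}
    by_term: dict[str, set[str]] = {}
    for protein, term_ids in direct.items():
        closure: set[str] = set()
        for t in term_ids:
            if t not in dag:
                raise OntologyError(f"direct annotation to unknown term {t}")
            if namespace is not None and dag.terms[t].namespace != namespace:
                continue
            closure |= dag.ancestors(t)
        terms_by_protein[protein] = frozenset(closure)
        for t in closure:
            by_term.setdefault(t, set()).add(protein)
    if not by_term:
        raise OntologyError("no annotations remain after namespace filtering")
    transitive = {t: frozenset(ps) for t, ps in by_term.items()}
    s_max = max(len(ps) for ps in transitive.values())
    corpus = frozenset(p for p, ts in terms_by_protein.items() if ts)
    return AnnotationIndex(
        direct={p: set(ts) for p, ts in direct.items()},
        transitive_by_term=transitive,
        terms_by_protein=terms_by_protein,
        s_max=s_max,
        corpus=corpus,
    )


def common_annotation_stats(x: str, y: str, index: AnnotationIndex) -> tuple[int, int]:
    """Count shared terms and the size of the most specific one.

    Returns ``(C_size, m)`` where ``C_size`` is the number of terms whose
    transitive annotation contains both *x* and *y*, and ``m`` the minimum
    annotation size among them.  With no shared term, ``m`` is reported as
    ``s_max`` (the maximally non-informative value).
    """
    tx = index.terms_by_protein.get(x, frozenset())
    ty = index.terms_by_protein.get(y, frozenset())
    common = tx & ty
    if not common:
        return 0, index.s_max
    m = min(len(index.transitive_by_term[t]) for t in common)
    return len(common), m


# A similarity scheme maps (m, c_size, s_max) -> score in [0, 1].
SimilarityScheme = Callable[[int, int, int], float]


def log_ratio_scheme(m: int, c_size: int, s_max: int) -> float:
    """Default scheme: 1 - ln(m)/ln(S_max); 1 at m=1, 0 at m=S_max."""
    score = 1.0 - math.log(m) / math.log(s_max)
    return min(1.0, max(0.0, score))


def semantic_similarity(
    x: str,
    y: str,
    index: AnnotationIndex,
    scheme: SimilarityScheme = log_ratio_scheme,
) -> float:
    """Semantic similarity between proteins *x* and *y* in ``[0, 1]``.

    Symmetric; 0 when the proteins share no informative term (including
    when either is unannotated).  The *scheme* is pluggable but must be
    non-increasing in ``m`` so that sharing a more specific term never
    lowers the score.
    """
    if index.s_max < 2:
        raise OntologyError("similarity undefined: S_max < 2 (degenerate corpus)")
    c_size, m = common_annotation_stats(x, y, index)
    if c_size == 0:
        return 0.0
    return scheme(m, c_size, index.s_max)
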