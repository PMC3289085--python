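"""Scoring predicted complexes against a benchmark catalogue.

Three metric families: neighborhood-affinity matching with
precision/recall/F, the complex-wise Sn/PPV/accuracy triple from the
benchmark-vs-prediction overlap matrix, and hypergeometric functional
homogeneity of individual clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom


class EvaluationError(ValueError):
    pass


@dataclass
class BenchmarkSet:
    """Reference complexes (set B), deduplicated, no empty complex allowed."""

    complexes: list[frozenset[str]]
    source: str = ""

    def __len__(self) -> int:
        return len(self.complexes)


def read_benchmark(text: str, source: str = "") -> BenchmarkSet:
    """One complex per line, whitespace-separated protein ids; duplicates dropped."""
    seen: set[frozenset[str]] = set()
    complexes: list[frozenset[str]] = []
    for line in text.splitlines():
        ids = line.split()
        if not ids or line.lstrip().startswith("#"):
            continue
        c = frozenset(ids)
        if c not in seen:
            seen.add(c)
            complexes.append(c)
    if not complexes:
        raise EvaluationError("benchmark contains no complexes")
    return BenchmarkSet(complexes=complexes, source=source)


def na_score(p_members: Iterable[str], b_members: Iterable[str]) -> float:
    """Neighborhood affinity |Vp ∩ Vb|² / (|Vp| · |Vb|).

    1 iff the sets are identical, 0 iff disjoint.
    """
    p, b = set(p_members), set(b_members)
    if not p or not b:
        raise EvaluationError("NA undefined for an empty complex")
    inter = len(p & b)
    return inter * inter / (len(p) * len(b))


def match_complexes(
    predicted: Sequence[frozenset[str]],
    benchmark: Sequence[frozenset[str]],
    omega: float = 0.25,
) -> tuple[int, int, list[tuple[int, int, float]]]:
    """Count matched complexes on both sides at NA threshold *omega*.

    Returns (n_cp, n_cb, pairs) where pairs lists (predicted index,
    benchmark index, NA) for every matching pair.
    """
    if not 0.0 < omega <= 1.0:
        raise EvaluationError(f"omega must be in (0, 1], got {omega}")
    pairs: list[tuple[int, int, float]] = []
    matched_p: set[int] = set()
    matched_b: set[int] = set()
    for j, p in enumerate(predicted):
        for i, b in enumerate(benchmark):
            na = na_score(p, b)
            if na >= omega:
                pairs.append((j, i, na))
                matched_p.add(j)
                matched_b.add(i)
    return len(matched_p), len(matched_b), pairs


def precision_recall_f(n_cp: int, n_cb: int, n_pred: int, n_bench: int) -> tuple[float, float, float]:
    """Precision = N_cp/|P|, Recall = N_cb/|B|, F = harmonic mean (0 when both 0)."""
    if n_pred <= 0 or n_bench <= 0:
        raise EvaluationError("both complex sets must be nonempty")
    precision = n_cp / n_pred
    recall = n_cb / n_bench
    f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f


@dataclass
class OverlapMatrix:
    """T_ij overlap counts (benchmark i × predicted j) and benchmark sizes N_i."""

    t: np.ndarray
    n_i: np.ndarray


def build_overlap_matrix(
    benchmark: Sequence[frozenset[str]], predicted: Sequence[frozenset[str]]
) -> OverlapMatrix:
    t = np.array(
        [[len(b & p) for p in predicted] for b in benchmark], dtype=np.int64
    ).reshape(len(benchmark), len(predicted))
    n_i = np.array([len(b) for b in benchmark], dtype=np.int64)
    return OverlapMatrix(t=t, n_i=n_i)


def sn_ppv_acc(overlap: OverlapMatrix) -> tuple[float, float, float]:
    """Complex-wise sensitivity, positive predictive value and their geometric mean."""
    t, n_i = overlap.t, overlap.n_i
    if t.size == 0 or n_i.sum() <= 0:
        raise EvaluationError("empty overlap matrix")
    sn = t.max(axis=1).sum() / n_i.sum()
    denom = t.sum()
    ppv = 0.0 if denom == 0 else t.max(axis=0).sum() / denom
    acc = float(np.sqrt(sn * ppv))
    return float(sn), float(ppv), acc


@dataclass
class MatchReport:
    n_cp: int
    n_cb: int
    precision: float
    recall: float
    f_measure: float
    sn: float
    ppv: float
    acc: float
    omega: float

    def to_tsv(self) -> str:
        head = "n_cp\tn_cb\tprecision\trecall\tf_measure\tsn\tppv\tacc\tomega"
        row = (
            f"{self.n_cp}\t{self.n_cb}\t{self.precision:.6f}\t{self.recall:.6f}\t"
            f"{self.f_measure:.6f}\t{self.sn:.6f}\t{self.ppv:.6f}\t{self.acc:.6f}\t{self.omega}"
        )
        return head + "\n" + row + "\n"


def evaluate_predictions(
    predicted: Sequence[frozenset[str]],
    benchmark: BenchmarkSet,
    omega: float = 0.25,
    min_benchmark_size: int = 1,
) -> MatchReport:
    """Full match report at NA threshold *omega*.

    *min_benchmark_size* restricts the benchmark side (e.g. 3 to count only
    complexes of size > 2).
    """
    bench = [b for b in benchmark.complexes if len(b) >= min_benchmark_size]
    if not predicted or not bench:
        raise EvaluationError("nothing to evaluate")
    n_cp, n_cb, _ = match_complexes(predicted, bench, omega)
    precision, recall, f = precision_recall_f(n_cp, n_cb, len(predicted), len(bench))
    sn, ppv, acc = sn_ppv_acc(build_overlap_matrix(bench, predicted))
    return MatchReport(n_cp, n_cb, precision, recall, f, sn, ppv, acc, omega)


def hypergeometric_pvalue(network_size: int, group_size: int, cluster_size: int, k: int) -> float:
    """Upper-tail P(X >= k) of the hypergeometric law.

    Probability that a random cluster of ``cluster_size`` proteins drawn
    from a network of ``network_size`` contains at least ``k`` of the
    ``group_size`` proteins in a functional group.
    """
    if k < 0 or k > min(group_size, cluster_size):
        raise EvaluationError("k exceeds the group or cluster size")
    if group_size > network_size or cluster_size > network_size:
        raise EvaluationError("group/cluster larger than the network")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, network_size, group_size, cluster_size))


def functional_homogeneity(
    cluster: Iterable[str],
    groups: Mapping[str, frozenset[str] | set[str]],
    network_size: int,
) -> tuple[float, str | None]:
    """Smallest enrichment p-value of *cluster* over all functional groups.

    Only groups sharing at least one protein with the cluster compete; with
    no overlap at all the cluster is maximally non-significant (p = 1,
    group = None).  Ties go to the lexicographically first group id.
    """
    if not groups:
        raise EvaluationError("no functional groups supplied")
    members = set(cluster)
    best_p, best_group = 1.0, None
    for gid in sorted(groups):
        k = len(members & set(groups[gid]))
        if k == 0:
            continue
        p = hypergeometric_pvalue(network_size, len(groups[gid]), len(members), k)
        if p < best_p:
            best_p, best_group = p, gid
    return best_p, best_group


def significant_fraction(
    clusters: Sequence[Iterable[str]],
    groups: Mapping[str, frozenset[str] | set[str]],
    network_size: int,
    alpha: float = 0.01,
) -> float:
    """Fraction of clusters with functional homogeneity below *alpha* (raw p-values)."""
    if not 0.0 < alpha < 1.0:
        raise EvaluationError(f"alpha must be in (0, 1), got {alpha}")
    if not clusters:
        return 0.0
    n_sig = sum(
        1 for c in clusters if functional_homogeneity(c, groups, network_size)[0] < alpha
    )
    return n_sig / len(clusters)


def groups_from_annotations(direct: Mapping[str, set[str]]) -> dict[str, frozenset[str]]:
    """Default functional groups: the protein set of each directly annotated term."""
    by_term: dict[str, set[str]] = {}
    for protein, terms in direct.items():
        for t in terms:
            by_term.setdefault(t, set()).add(protein)
    return {t: frozenset(ps) for t, ps in by_term.items()}
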