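"""Greedy incremental sequence clustering and representative selection.

Reimplements the greedy longest-first clustering scheme used to build
redundancy-reduced representative sets (F99/F70/F40) and the bidirectional-
coverage reduction of unassigned domains. The alignment kernel is local
Smith-Waterman with BLOSUM62 and gap open/extend 11/1; exact k-mer sharing is
used only as a speed prefilter and never changes identity values.
"""

from __future__ import annotations

from datetime import date
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from sklearn.base import BaseEstimator, ClusterMixin

from .types import Cluster, ClusterParams, SeqRecord

__all__ = [
    "F_LEVELS",
    "local_identity",
    "greedy_cluster",
    "GreedySequenceClusterer",
    "select_representative",
    "reduce_unassigned",
    "audit_clusters",
]

#: Per-level (identity, coverage, word size) triples for representative sets.
F_LEVELS: Dict[str, ClusterParams] = {
    "F99": ClusterParams(identity=0.99, coverage=0.9, coverage_mode="local_query", word_size=5),
    "F70": ClusterParams(identity=0.70, coverage=0.7, coverage_mode="local_query", word_size=4),
    "F40": ClusterParams(identity=0.40, coverage=0.7, coverage_mode="local_query", word_size=2),
    "unassigned": ClusterParams(identity=0.70, coverage=0.7, coverage_mode="bidirectional", word_size=4),
}


def _aligner() -> PairwiseAligner:
    return PairwiseAligner(
        mode="local",
        substitution_matrix=substitution_matrices.load("BLOSUM62"),
        open_gap_score=-11.0,
        extend_gap_score=-1.0,
    )


def local_identity(a: str, b: str) -> Tuple[float, float, float]:
    """Best local alignment identity and per-sequence coverage.

    Identity is matches over aligned columns (gap columns included);
    coverage of each sequence is the aligned span on that sequence divided by
    its full length.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _aligner().align(a, b)[0]
    counts = aln.counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    if cols == 0:
        return 0.0, 0.0, 0.0
    identity = counts.identities / cols
    spans_a, spans_b = aln.aligned
    cov_a = (spans_a[-1][1] - spans_a[0][0]) / len(a)
    cov_b = (spans_b[-1][1] - spans_b[0][0]) / len(b)
    return float(identity), float(cov_a), float(cov_b)


def _kmers(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _passes(identity: float, cov_member: float, cov_rep: float,
            p: ClusterParams, len_member: int, len_rep: int) -> bool:
    if identity < p.identity:
        return False
    if p.coverage_mode == "bidirectional":
        return cov_member >= p.coverage and cov_rep >= p.coverage
    # local_query: coverage of the shorter sequence
    cov_short = cov_member if len_member <= len_rep else cov_rep
    return cov_short >= p.coverage


def greedy_cluster(
    records: Sequence[SeqRecord],
    p: ClusterParams,
    best_fit: bool = False,
) -> List[Cluster]:
    """Greedy longest-first incremental clustering.

    Records are processed by decreasing length (ties by id). Each record joins
    the first existing cluster whose representative (the founder) satisfies
    the identity and coverage constraints — or, with ``best_fit``, the
    satisfying cluster with the highest identity — otherwise it founds a new
    cluster. A pair is only aligned when it shares at least one exact k-mer
    of length ``p.word_size``.
    """
    if not records:
        raise ValueError("no records to cluster")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    clusters: List[Cluster] = []
    rep_seqs: List[str] = []
    rep_kmers: List[set] = []
    for rec in ordered:
        km = _kmers(rec.sequence, p.word_size)
        chosen, chosen_stats = None, None
        for ci, cl in enumerate(clusters):
            if not (km & rep_kmers[ci]):
                continue
            ident, cov_m, cov_r = local_identity(rec.sequence, rep_seqs[ci])
            if _passes(ident, cov_m, cov_r, p, len(rec.sequence), len(rep_seqs[ci])):
                if not best_fit:
                    chosen, chosen_stats = ci, (ident, cov_m, cov_r)
                    break
                if chosen_stats is None or ident > chosen_stats[0]:
                    chosen, chosen_stats = ci, (ident, cov_m, cov_r)
        if chosen is None:
            clusters.append(Cluster(
                representative_id=rec.id,
                member_ids=[rec.id],
                identities={rec.id: 1.0},
                coverages={rec.id: (1.0, 1.0)},
            ))
            rep_seqs.append(rec.sequence)
            rep_kmers.append(km)
        else:
            ident, cov_m, cov_r = chosen_stats
            cl = clusters[chosen]
            cl.member_ids.append(rec.id)
            cl.identities[rec.id] = ident
            cl.coverages[rec.id] = (cov_m, cov_r)
    return clusters


class GreedySequenceClusterer(BaseEstimator, ClusterMixin):
    """sklearn-style wrapper around :func:`greedy_cluster`.

    Parameters mirror :class:`ClusterParams`. ``fit`` accepts a sequence of
    :class:`SeqRecord` (or (id, sequence) tuples) and exposes ``labels_``
    (cluster index per input record, in input order), ``clusters_`` and
    ``representative_ids_``.
    """

    def __init__(self, identity: float = 0.7, coverage: float = 0.7,
                 coverage_mode: str = "local_query", word_size: int = 4,
                 best_fit: bool = False):
        self.identity = identity
        self.coverage = coverage
        self.coverage_mode = coverage_mode
        self.word_size = word_size
        self.best_fit = best_fit

    def _params(self) -> ClusterParams:
        return ClusterParams(
            identity=self.identity, coverage=self.coverage,
            coverage_mode=self.coverage_mode, word_size=self.word_size,
        )

    def fit(self, X, y=None):
        records = [
            r if isinstance(r, SeqRecord) else SeqRecord(id=r[0], sequence=r[1])
            for r in X
        ]
        self.clusters_ = greedy_cluster(records, self._params(), best_fit=self.best_fit)
        by_member = {m: ci for ci, cl in enumerate(self.clusters_) for m in cl.member_ids}
        self.labels_ = np.array([by_member[r.id] for r in records])
        self.representative_ids_ = [cl.representative_id for cl in self.clusters_]
        self.n_clusters_ = len(self.clusters_)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


_METHOD_RANK = {"xray": 0, "em": 1, "nmr": 1, "other": 2}


def select_representative(cluster: Cluster, records: Dict[str, SeqRecord]) -> str:
    """Pick a cluster's output representative by the priority policy.

    Order: previous representatives, then manually curated, then provisional
    manual; among the rest, x-ray entries win, then better (lower) resolution,
    then later release date, then lexicographically smallest id.
    """
    if not cluster.member_ids:
        raise ValueError("empty cluster")

    def key(member_id: str):
        r = records[member_id]
        date_ord = (
            -date.fromisoformat(r.release_date).toordinal()
            if r.release_date else float("inf")
        )
        return (
            not r.is_previous_rep,
            not r.is_manual,
            not r.is_provisional_manual,
            _METHOD_RANK.get(r.method, 2) != 0,
            r.resolution if r.resolution is not None else float("inf"),
            date_ord,  # later release preferred
            r.id,
        )

    return min(cluster.member_ids, key=key)


def reduce_unassigned(domains: Sequence[SeqRecord]) -> List[SeqRecord]:
    """Reduce unassigned-domain sequences to one representative per cluster.

    Clusters at identity 0.7 with bidirectional 70% coverage; the longest
    member (ties by id) represents each cluster.
    """
    by_id = {r.id: r for r in domains}
    clusters = greedy_cluster(domains, F_LEVELS["unassigned"])
    reps = []
    for cl in clusters:
        rep = min(cl.member_ids, key=lambda m: (-len(by_id[m].sequence), m))
        reps.append(by_id[rep])
    return reps


def audit_clusters(clusters: Sequence[Cluster], records: Dict[str, SeqRecord],
                   p: ClusterParams) -> None:
    """Re-verify every member against its representative; raise on violation."""
    for cl in clusters:
        rep = records[cl.representative_id]
        for m in cl.member_ids:
            if m == cl.representative_id:
                continue
            ident, cov_m, cov_r = local_identity(records[m].sequence, rep.sequence)
            if not _passes(ident, cov_m, cov_r, p,
                           len(records[m].sequence), len(rep.sequence)):
                raise AssertionError(
                    f"cluster audit failed: {m} vs {cl.representative_id} "
                    f"identity={ident:.3f} cov=({cov_m:.3f},{cov_r:.3f})"
                )


def write_clusters(clusters: Sequence[Cluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("rep_id\tmember_id\tidentity\tcov_a\tcov_b\n")
        for cl in clusters:
            for m in cl.member_ids:
                cov_a, cov_b = cl.coverages[m]
                fh.write(f"{cl.representative_id}\t{m}\t{cl.identities[m]:.4f}"
                         f"\t{cov_a:.4f}\t{cov_b:.4f}\n")
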