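"""PAE-guided domain parsing.

The parsing stage runs in four steps: (1) flag flexible/disordered residues
from the PAE matrix, (2) split the remaining ordered runs into short segments,
(3) agglomeratively cluster segments into domain candidates using the
same-domain pair probability with average linkage, and (4) merge or drop
candidates that came out shorter than a minimum domain length.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from .pairmodel import PairDomainClassifier
from .types import (
    DomainCandidate,
    HomologyHit,
    PredictedModel,
    ResidueRange,
    Segment,
    Thresholds,
)

__all__ = [
    "flag_flexible_residues",
    "build_segments",
    "agglomerate",
    "cluster_segments",
    "merge_small_candidates",
    "parse_domains",
]


def flag_flexible_residues(model: PredictedModel, t: Thresholds) -> np.ndarray:
    """Boolean mask: True where a residue is non-globular by PAE.

    A residue is flexible when fewer than ``t.flex_min_partners`` residues at
    sequence separation > ``t.flex_seq_sep`` have symmetrized PAE below
    ``t.flex_partner_pae``: it sits in confident spatial contact with almost
    nothing outside its local stretch of chain.
    """
    if model.pae is None:
        raise ValueError("PAE required")
    pae = model.pae_sym()
    n = model.n_residues
    idx = np.arange(n)
    far = np.abs(idx[:, None] - idx[None, :]) > t.flex_seq_sep
    partners = ((pae < t.flex_partner_pae) & far).sum(axis=1)
    return partners < t.flex_min_partners


def build_segments(model: PredictedModel, flexible_mask: np.ndarray,
                   t: Thresholds) -> List[Segment]:
    """Split maximal ordered runs into consecutive segments of ``segment_len``.

    A remainder of 1-2 residues is folded into the previous segment (length
    6-7); a remainder of 3-4 stands as its own segment. Ordered runs shorter
    than 3 residues yield no segment (their residues stay unparsed and are
    treated as flexible downstream).
    """
    mask = np.asarray(flexible_mask, dtype=bool)
    if mask.shape[0] != model.n_residues:
        raise ValueError("mask length must equal model length")
    segments: List[Segment] = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            i += 1
            continue
        j = i
        while j < n and not mask[j]:
            j += 1
        run_start, run_end = i + 1, j  # 1-based inclusive
        run_len = run_end - run_start + 1
        if run_len >= 3:
            k, r = divmod(run_len, t.segment_len)
            if k == 0:
                bounds = [(run_start, run_end)]
            else:
                bounds = [
                    (run_start + m * t.segment_len,
                     run_start + (m + 1) * t.segment_len - 1)
                    for m in range(k)
                ]
                if r in (1, 2):
                    s, _ = bounds[-1]
                    bounds[-1] = (s, run_end)
                elif r:
                    bounds.append((run_end - r + 1, run_end))
            for s, e in bounds:
                segments.append(Segment(index=len(segments), start=s, end=e))
        i = j
    return segments


def _linkage(aff: np.ndarray, ca: Sequence[int], cb: Sequence[int]) -> float:
    """Average linkage: mean segment-pair affinity between two clusters."""
    return float(aff[np.ix_(list(ca), list(cb))].mean())


def agglomerate(affinity: np.ndarray, cut: float) -> List[List[int]]:
    """Greedy average-linkage merging of segment indices.

    Repeatedly merges the cluster pair with the highest linkage while that
    linkage is >= ``cut``. Ties break deterministically toward the pair with
    the lowest minimum segment index (then the lowest other index).
    """
    k = affinity.shape[0]
    clusters: List[List[int]] = [[i] for i in range(k)]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                link = _linkage(affinity, clusters[a], clusters[b])
                key = (-link, min(clusters[a][0], clusters[b][0]),
                       max(clusters[a][0], clusters[b][0]))
                if best is None or key < best[0]:
                    best = (key, a, b, link)
        if best is None or best[3] < cut:
            break
        _, a, b, _ = best
        merged = sorted(clusters[a] + clusters[b])
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
        clusters.sort(key=lambda c: c[0])
    return sorted(clusters, key=lambda c: c[0])


def _restrict_hits(hits: Sequence[HomologyHit], rng: ResidueRange,
                   n: int) -> List[HomologyHit]:
    """Hits whose query range lies mostly (>= 50% of its residues) in ``rng``."""
    mask = rng.to_mask(n)
    kept = []
    for h in hits:
        hmask = h.query_range.to_mask(n)
        if hmask.sum() and (hmask & mask).sum() / hmask.sum() >= 0.5:
            kept.append(h)
    return kept


def _make_candidate(residues: np.ndarray, segment_ids: List[int],
                    model: PredictedModel,
                    hits: Sequence[HomologyHit]) -> DomainCandidate:
    rng = ResidueRange.from_residues(residues)
    return DomainCandidate(
        range=rng,
        segment_ids=sorted(segment_ids),
        mean_plddt=float(model.plddt[residues - 1].mean()),
        hits=_restrict_hits(hits, rng, model.n_residues),
    )


def segment_affinity_matrix(segments: Sequence[Segment],
                            P: np.ndarray) -> np.ndarray:
    """Mean pair probability over cross-segment residue pairs."""
    k = len(segments)
    aff = np.ones((k, k))
    for a in range(k):
        ra = segments[a].residues() - 1
        for b in range(a + 1, k):
            rb = segments[b].residues() - 1
            aff[a, b] = aff[b, a] = float(P[np.ix_(ra, rb)].mean())
    return aff


def cluster_segments(
    segments: Sequence[Segment],
    model: PredictedModel,
    hits: Sequence[HomologyHit],
    pair_model: PairDomainClassifier,
    t: Thresholds,
    P: Optional[np.ndarray] = None,
) -> List[DomainCandidate]:
    """Agglomerate segments into domain candidates.

    ``P`` (the residue-pair probability matrix) can be passed to avoid
    recomputation; it is derived from ``pair_model`` otherwise.
    """
    if not segments:
        return []
    if P is None:
        P = pair_model.probability_matrix(model, hits)
    aff = segment_affinity_matrix(segments, P)
    clusters = agglomerate(aff, t.pair_prob_cut)
    candidates = []
    for cluster in clusters:
        residues = np.concatenate([segments[i].residues() for i in cluster])
        candidates.append(_make_candidate(np.sort(residues), list(cluster), model, hits))
    candidates.sort(key=lambda c: c.range.start)
    return candidates


def merge_small_candidates(
    candidates: List[DomainCandidate],
    model: PredictedModel,
    pair_model: PairDomainClassifier,
    t: Thresholds,
    hits: Sequence[HomologyHit] = (),
    P: Optional[np.ndarray] = None,
    merge_prob_min: float = 0.3,
) -> List[DomainCandidate]:
    """Merge short over-split candidates into a sequence-adjacent neighbor.

    Candidates shorter than ``t.min_domain_len`` are processed smallest-first:
    each is merged into whichever sequence-adjacent candidate has the higher
    mean inter-candidate pair probability, provided that probability is at
    least ``merge_prob_min``; otherwise the candidate is dropped and its
    residues revert to unparsed. Iterates until stable.
    """
    if not candidates:
        return []
    if P is None:
        P = pair_model.probability_matrix(model, hits)

    cands = sorted(candidates, key=lambda c: c.range.start)

    def inter_prob(a: DomainCandidate, b: DomainCandidate) -> float:
        ra = a.range.residues() - 1
        rb = b.range.residues() - 1
        return float(P[np.ix_(ra, rb)].mean())

    while True:
        smalls = sorted(
            (c for c in cands if len(c) < t.min_domain_len),
            key=lambda c: (len(c), c.range.start),
        )
        if not smalls:
            break
        c = smalls[0]
        pos = cands.index(c)
        neighbors = []
        if pos > 0:
            neighbors.append(cands[pos - 1])
        if pos + 1 < len(cands):
            neighbors.append(cands[pos + 1])
        best, best_p = None, -1.0
        for nb in neighbors:
            p = inter_prob(c, nb)
            if p > best_p:
                best, best_p = nb, p
        cands.remove(c)
        if best is not None and best_p >= merge_prob_min:
            residues = np.sort(np.concatenate([
                c.range.residues(), best.range.residues()
            ]))
            merged = _make_candidate(
                residues, c.segment_ids + best.segment_ids, model, hits
            )
            cands[cands.index(best)] = merged
            cands.sort(key=lambda x: x.range.start)
        # else: dropped — residues revert to unparsed
    return cands


def parse_domains(
    model: PredictedModel,
    hits: Sequence[HomologyHit],
    pair_model: PairDomainClassifier,
    t: Optional[Thresholds] = None,
) -> Tuple[List[DomainCandidate], np.ndarray]:
    """Full parse: flag -> segment -> cluster -> merge.

    Returns the final candidates plus the flexible mask covering every residue
    not in a candidate (flagged residues, sub-segment runs, and residues of
    dropped candidates), so candidates and mask partition the chain exactly.
    """
    t = t or Thresholds()
    flexible = flag_flexible_residues(model, t)
    segments = build_segments(model, flexible, t)
    P = pair_model.probability_matrix(model, hits)
    candidates = cluster_segments(segments, model, hits, pair_model, t, P=P)
    candidates = merge_small_candidates(
        candidates, model, pair_model, t, hits=hits, P=P
    )
    covered = np.zeros(model.n_residues, dtype=bool)
    for c in candidates:
        cmask = c.range.to_mask(model.n_residues)
        if np.any(covered & cmask):
            raise ValueError("parser contract violated: overlapping candidates")
        covered |= cmask
    return candidates, ~covered
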