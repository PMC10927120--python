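"""Domain parsing: flexibility flag, segmentation, clustering, merging.

The agglomerative clusterer is checked against a brute-force oracle that
(a) re-runs the greedy procedure naively, rescanning every cluster pair from
the raw affinities at every step, and (b) exhaustively enumerates all
partitions reachable by merge sequences whose every merge meets the linkage
threshold, verifying the output is a terminal member of that set.
"""

from itertools import combinations

import numpy as np
import pytest

from afdomain import DomainCandidate, ResidueRange, Thresholds
from afdomain.parse import (
    agglomerate,
    build_segments,
    cluster_segments,
    flag_flexible_residues,
    merge_small_candidates,
    parse_domains,
    segment_affinity_matrix,
)
from afdomain.simulate import Block, SyntheticSpec, generate_model
from afdomain.types import PredictedModel, Segment


def _flat_model(n, pae_value, plddt=90.0):
    """Chain on a line with uniform off-diagonal PAE."""
    pae = np.full((n, n), float(pae_value))
    np.fill_diagonal(pae, 0.2)
    return PredictedModel(
        model_id="FLAT",
        sequence="A" * n,
        ca_coords=np.column_stack([3.8 * np.arange(n), np.zeros(n), np.zeros(n)]),
        plddt=np.full(n, plddt),
        pae=pae,
    )


class TestFlexibleFlag:
    def test_all_high_pae_all_flexible(self):
        mask = flag_flexible_residues(_flat_model(50, 30.0), Thresholds())
        assert mask.all()

    def test_all_low_pae_none_flexible(self):
        mask = flag_flexible_residues(_flat_model(50, 2.0), Thresholds())
        assert not mask.any()

    def test_missing_pae_rejected(self):
        model = _flat_model(10, 2.0)
        model.pae = None
        with pytest.raises(ValueError, match="PAE required"):
            flag_flexible_residues(model, Thresholds())

    def test_linker_flagged_domains_not(self):
        """Two domains joined by a 15-residue linker (seed 3)."""
        spec = SyntheticSpec(
            blocks=[Block("domain", 60, group_id="H0"), Block("linker", 15),
                    Block("domain", 60, group_id="H1")],
            seed=3,
        )
        model, truth = generate_model(spec)
        mask = flag_flexible_residues(model, Thresholds())
        labels = truth.label_array()
        assert mask[labels == "FLEXIBLE"].mean() >= 0.8
        assert mask[labels == "ASSIGNED"].mean() <= 0.05


class TestBuildSegments:
    def _segments_for(self, run_len):
        model = _flat_model(run_len, 2.0)
        mask = np.zeros(run_len, dtype=bool)
        return build_segments(model, mask, Thresholds())

    def test_twelve_residue_run_remainder_merged(self):
        segs = self._segments_for(12)
        assert [(s.start, s.end) for s in segs] == [(1, 5), (6, 12)]

    def test_exact_run_single_segment(self):
        segs = self._segments_for(5)
        assert [(s.start, s.end) for s in segs] == [(1, 5)]

    def test_remainder_three_kept_separate(self):
        segs = self._segments_for(13)
        assert [(s.start, s.end) for s in segs] == [(1, 5), (6, 10), (11, 13)]

    def test_two_residue_run_yields_nothing(self):
        model = _flat_model(10, 2.0)
        mask = np.ones(10, dtype=bool)
        mask[3:5] = False  # ordered run of 2
        assert build_segments(model, mask, Thresholds()) == []

    def test_all_lengths_between_3_and_7(self):
        for n in range(3, 40):
            for s in self._segments_for(n):
                assert 3 <= len(s) <= 7


# ---------------------------------------------------------------------------
# brute-force oracles for the agglomerative clusterer


def naive_greedy(aff, cut):
    """From-scratch reference: rescan all cluster pairs every iteration."""
    clusters = [[i] for i in range(len(aff))]
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            vals = [aff[i][j] for i in clusters[a] for j in clusters[b]]
            link = sum(vals) / len(vals)
            key = (-link, min(clusters[a][0], clusters[b][0]),
                   max(clusters[a][0], clusters[b][0]))
            if best is None or key < best[0]:
                best = (key, a, b, link)
        if best[3] < cut:
            break
        _, a, b, _ = best
        merged = sorted(clusters[a] + clusters[b])
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
        clusters.sort(key=lambda c: c[0])
    return sorted(clusters, key=lambda c: c[0])


def reachable_terminal_partitions(aff, cut):
    """All partitions reachable by threshold-feasible merges with no merge left."""
    k = len(aff)

    def linkage(ca, cb):
        vals = [aff[i][j] for i in ca for j in cb]
        return sum(vals) / len(vals)

    start = frozenset(frozenset([i]) for i in range(k))
    seen, terminals = set(), set()
    stack = [start]
    while stack:
        part = stack.pop()
        if part in seen:
            continue
        seen.add(part)
        clusters = list(part)
        merges = []
        for a, b in combinations(range(len(clusters)), 2):
            if linkage(clusters[a], clusters[b]) >= cut:
                nxt = (set(part) - {clusters[a], clusters[b]}) | {
                    frozenset(clusters[a] | clusters[b])
                }
                merges.append(frozenset(nxt))
        if not merges:
            terminals.add(part)
        else:
            stack.extend(merges)
    return terminals


def _as_partition(clusters):
    return frozenset(frozenset(c) for c in clusters)


class TestAgglomerate:
    def test_all_high_affinity_merges_to_one(self):
        aff = np.ones((2, 2))
        assert agglomerate(aff, 0.5) == [[0, 1]]

    def test_all_zero_affinity_stays_apart(self):
        aff = np.zeros((2, 2))
        assert agglomerate(aff, 0.5) == [[0], [1]]

    def test_chain_merge_via_average_linkage(self):
        """A-B=0.9, B-C=0.9, A-C=0.2: after A+B the average to C is 0.55 >= 0.5."""
        aff = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.9], [0.2, 0.9, 1.0]])
        assert agglomerate(aff, 0.5) == [[0, 1, 2]]

    def test_matches_brute_force_on_random_instances(self):
        """200 random instances, <= 8 segments: greedy output equals the naive
        reference and is a terminal partition of the exhaustive search."""
        rng = np.random.default_rng(42)
        for trial in range(200):
            k = int(rng.integers(2, 9))
            aff = rng.random((k, k))
            aff = 0.5 * (aff + aff.T)
            np.fill_diagonal(aff, 1.0)
            cut = 0.5
            result = agglomerate(aff, cut)
            assert result == naive_greedy(aff, cut), f"trial {trial}"
            terminals = reachable_terminal_partitions(aff, cut)
            assert _as_partition(result) in terminals, f"trial {trial}"

    def test_candidate_count_monotone_in_cut(self, pair_model):
        spec = SyntheticSpec(
            blocks=[Block("domain", 60, group_id="H0"), Block("linker", 15),
                    Block("domain", 60, group_id="H1", geometry="sheet_sandwich")],
            seed=12,
        )
        model, _ = generate_model(spec)
        t0 = Thresholds()
        mask = flag_flexible_residues(model, t0)
        segments = build_segments(model, mask, t0)
        counts = []
        for cut in (0.2, 0.35, 0.5, 0.65, 0.8):
            t = Thresholds(pair_prob_cut=cut)
            cands = cluster_segments(segments, model, [], pair_model, t)
            counts.append(len(cands))
        assert counts == sorted(counts)


class TestMergeSmallCandidates:
    def _setup(self, inter_prob):
        model = _flat_model(90, 2.0)
        P = np.full((90, 90), inter_prob)
        cands = [
            DomainCandidate(range=ResidueRange.single(1, 10), mean_plddt=90.0),
            DomainCandidate(range=ResidueRange.single(11, 90), mean_plddt=90.0),
        ]
        return model, P, cands

    def test_small_candidate_absorbed(self, pair_model):
        model, P, cands = self._setup(0.8)
        out = merge_small_candidates(cands, model, pair_model, Thresholds(), P=P)
        assert len(out) == 1
        assert out[0].range == ResidueRange.single(1, 90)

    def test_isolated_small_candidate_dropped(self, pair_model):
        model, P, cands = self._setup(0.1)
        out = merge_small_candidates(cands, model, pair_model, Thresholds(), P=P)
        assert len(out) == 1
        assert out[0].range == ResidueRange.single(11, 90)

    def test_large_candidates_untouched(self, pair_model):
        model = _flat_model(100, 2.0)
        P = np.full((100, 100), 0.9)
        cands = [
            DomainCandidate(range=ResidueRange.single(1, 50), mean_plddt=90.0),
            DomainCandidate(range=ResidueRange.single(51, 100), mean_plddt=90.0),
        ]
        out = merge_small_candidates(cands, model, pair_model, Thresholds(), P=P)
        assert [c.range for c in out] == [c.range for c in cands]


class TestParseDomains:
    def test_single_domain_recovered(self, pair_model):
        spec = SyntheticSpec(blocks=[Block("domain", 60, group_id="H0")], seed=3)
        model, truth = generate_model(spec)
        cands, mask = parse_domains(model, [], pair_model, Thresholds())
        assert len(cands) == 1
        true_range, _ = truth.true_partition[0]
        covered = len(true_range.residue_set() & cands[0].range.residue_set())
        assert covered / len(true_range) >= 0.9

    def test_all_disordered_yields_no_candidates(self, pair_model):
        spec = SyntheticSpec(blocks=[Block("disordered_tail", 50)], seed=4)
        model, _ = generate_model(spec)
        cands, mask = parse_domains(model, [], pair_model, Thresholds())
        assert cands == []
        assert mask.all()

    def test_candidates_and_mask_partition_chain(self, classified50, proteome50):
        """Every residue is in exactly one candidate or in the flexible mask."""
        for model in proteome50.models:
            cands = classified50["candidates"][model.model_id]
            covered = np.zeros(model.n_residues, dtype=int)
            for c in cands:
                covered += c.range.to_mask(model.n_residues)
            assert covered.max() <= 1
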