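"""Region classification: SSE detection, scoring, precedence, summaries."""

import numpy as np
import pytest

from afdomain import (
    DomainCandidate,
    HomologyHit,
    RegionLabel,
    ResidueRange,
    Thresholds,
)
from afdomain.classify import (
    assign_sse,
    classify_model,
    residue_labels,
    score_candidate,
    summarize_proteome,
)
from afdomain.simulate import Block, SyntheticSpec, generate_model, helix_coords
from afdomain.types import ClassifiedRegion, PredictedModel


def _model_from_coords(coords, plddt=90.0, pae_value=2.0):
    n = len(coords)
    pae = np.full((n, n), float(pae_value))
    np.fill_diagonal(pae, 0.2)
    return PredictedModel(
        model_id="GEO", sequence="A" * n, ca_coords=coords,
        plddt=np.full(n, plddt), pae=pae,
    )


class TestAssignSse:
    def test_ideal_helix_is_one_element(self):
        """20 residues on an ideal helix (rise 1.5 A, radius 2.3 A, 100 deg)."""
        model = _model_from_coords(helix_coords(20))
        states, n_sse = assign_sse(model, ResidueRange.single(1, 20))
        assert n_sse == 1
        assert (states[:17] == "H").all()  # core residues helical

    def test_straight_line_has_no_sse(self):
        """Ca on a line at 3.8 A spacing: d(i,i+2) = 7.6 A misses both windows."""
        coords = np.column_stack([3.8 * np.arange(20), np.zeros(20), np.zeros(20)])
        _, n_sse = assign_sse(_model_from_coords(coords), ResidueRange.single(1, 20))
        assert n_sse == 0

    def test_short_range_has_no_sse(self):
        model = _model_from_coords(helix_coords(20))
        _, n_sse = assign_sse(model, ResidueRange.single(1, 4))
        assert n_sse == 0

    def test_range_outside_model_rejected(self):
        model = _model_from_coords(helix_coords(10))
        with pytest.raises(ValueError, match="outside model"):
            assign_sse(model, ResidueRange.single(5, 30))


def _hit(conf, cov, group="H7"):
    return HomologyHit(
        source="sequence_profile", query_id="M", query_range=ResidueRange.single(1, 60),
        ref_domain_id="d7", ref_group_id=group, confidence=conf, ref_coverage=cov,
    )


class TestScoreCandidate:
    def _cand(self, hits):
        return DomainCandidate(range=ResidueRange.single(1, 60), hits=hits, mean_plddt=90)

    def test_confident_high_coverage_assigned(self):
        score, label, group = score_candidate(self._cand([_hit(0.95, 0.9)]))
        assert score == pytest.approx(0.855)
        assert label is RegionLabel.ASSIGNED
        assert group == "H7"

    def test_confident_low_coverage_partial(self):
        _, label, group = score_candidate(self._cand([_hit(0.9, 0.3)]))
        assert label is RegionLabel.PARTIAL
        assert group == "H7"

    def test_no_hits_unassigned(self):
        score, label, group = score_candidate(self._cand([]))
        assert score is None and group is None
        assert label is RegionLabel.UNASSIGNED

    def test_coverage_gray_zone_unassigned(self):
        _, label, _ = score_candidate(self._cand([_hit(0.9, 0.6)]))
        assert label is RegionLabel.UNASSIGNED

    def test_best_hit_maximizes_product(self):
        weak, strong = _hit(0.85, 0.75, group="HA"), _hit(0.95, 0.92, group="HB")
        score, label, group = score_candidate(self._cand([weak, strong]))
        assert group == "HB"
        assert score == pytest.approx(0.95 * 0.92)


class TestClassifyModel:
    def _domain_model(self, plddt=None, seed=3):
        spec = SyntheticSpec(blocks=[Block("domain", 60, group_id="H0")], seed=seed)
        model, _ = generate_model(spec)
        if plddt is not None:
            model.plddt = np.full(model.n_residues, float(plddt))
        return model

    def test_low_plddt_beats_hits(self):
        """Confidence filter dominates: good hits cannot rescue a low-plDDT region."""
        model = self._domain_model(plddt=50.0)
        cand = DomainCandidate(range=ResidueRange.single(1, 60), hits=[_hit(0.95, 0.9)])
        regions = classify_model(model, [cand], np.zeros(60, dtype=bool))
        assert regions[0].label is RegionLabel.LOW_CONFIDENCE
        assert regions[0].h_group is None

    def test_few_sse_beats_hits(self):
        """A single-helix candidate with a confident hit is still SIMPLE."""
        spec = SyntheticSpec(blocks=[Block("simple_helix", 30)], seed=5)
        model, _ = generate_model(spec)
        cand = DomainCandidate(
            range=ResidueRange.single(1, 30),
            hits=[HomologyHit(source="sequence_profile", query_id="M",
                              query_range=ResidueRange.single(1, 30),
                              ref_domain_id="d", ref_group_id="H1",
                              confidence=0.95, ref_coverage=0.9)],
        )
        regions = classify_model(model, [cand], np.zeros(30, dtype=bool))
        assert regions[0].label is RegionLabel.SIMPLE
        assert regions[0].n_sse <= 2

    def test_outside_candidates_split_by_plddt(self):
        model = self._domain_model()
        model.plddt = np.concatenate([np.full(30, 85.0), np.full(30, 50.0)])
        regions = classify_model(model, [], np.ones(60, dtype=bool))
        assert [r.label for r in regions] == [RegionLabel.FLEXIBLE,
                                              RegionLabel.LOW_CONFIDENCE]
        assert regions[0].range == ResidueRange.single(1, 30)

    def test_overlapping_candidates_rejected(self):
        model = self._domain_model()
        c1 = DomainCandidate(range=ResidueRange.single(1, 40))
        c2 = DomainCandidate(range=ResidueRange.single(30, 60))
        with pytest.raises(ValueError, match="parser contract"):
            classify_model(model, [c1, c2], np.zeros(60, dtype=bool))

    def test_every_residue_labelled_once(self, classified50, proteome50):
        for model in proteome50.models:
            # residue_labels raises on double or missing labels
            labels = classified50["pred"][model.model_id]
            assert len(labels) == model.n_residues


class TestSummarizeProteome:
    def test_residue_weighted_fractions(self):
        regions = [
            ClassifiedRegion("M", ResidueRange.single(1, 60), RegionLabel.ASSIGNED,
                             h_group="H0", score=0.8, mean_plddt=90, n_sse=4),
            ClassifiedRegion("M", ResidueRange.single(61, 100), RegionLabel.FLEXIBLE,
                             mean_plddt=85),
        ]
        s = summarize_proteome(regions)
        assert s.fractions[RegionLabel.ASSIGNED] == pytest.approx(0.6)
        assert s.fractions[RegionLabel.FLEXIBLE] == pytest.approx(0.4)
        assert s.n_domains == 1
        assert s.total_residues == 100

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_proteome([])

    def test_fractions_conserved_on_proteome(self, classified50):
        s = summarize_proteome(classified50["all_regions"])
        assert sum(s.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert s.total_residues == sum(s.counts.values())

    def test_recovered_fractions_match_truth(self, classified50, proteome50):
        """Summary fractions land within 0.05 of the ground-truth fractions."""
        s = summarize_proteome(classified50["all_regions"])
        for lab in RegionLabel:
            assert s.fractions[lab] == pytest.approx(
                proteome50.expected_fractions[lab.value], abs=0.05
            )
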