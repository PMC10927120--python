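"""Six-category region classification and proteome summaries.

Every residue of a parsed model receives exactly one of six labels. Parsed
candidates are demoted to LOW_CONFIDENCE when their mean plDDT is below the
confidence floor, to SIMPLE when they contain 2 or fewer secondary structure
elements, and are otherwise labelled from their best homology hit (ASSIGNED /
PARTIAL / UNASSIGNED). Residues outside all candidates are FLEXIBLE or
LOW_CONFIDENCE depending on their own plDDT.

Confidence filters take precedence over homology calls: a low-plDDT region
cannot be assigned to a domain however good its hits look.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from .types import (
    ClassifiedRegion,
    DomainCandidate,
    PredictedModel,
    ProteomeSummary,
    RegionLabel,
    ResidueRange,
    Thresholds,
    DOMAIN_LABELS,
)

__all__ = [
    "assign_sse",
    "sse_states",
    "score_candidate",
    "classify_model",
    "summarize_proteome",
    "residue_labels",
]

# C-alpha-only secondary structure windows (Angstrom): a residue is helical
# when its i..i+2 and i..i+3 distances fall in the helix windows, strand when
# they fall in the extended windows; helix wins where the windows overlap.
H_D2 = (5.0, 6.0)
H_D3 = (4.7, 6.1)
E_D2 = (5.9, 7.3)
E_D3 = (9.0, 11.5)

MIN_HELIX_RUN = 6
MIN_STRAND_RUN = 3


def sse_states(model: PredictedModel) -> np.ndarray:
    """Per-residue secondary structure state in {H, E, C} for the whole chain."""
    n = model.n_residues
    states = np.full(n, "C", dtype="<U1")
    if n < 4:
        return states
    x = model.ca_coords
    d2 = np.linalg.norm(x[2:] - x[:-2], axis=1)  # i -> i+2, defined for i < n-2
    d3 = np.linalg.norm(x[3:] - x[:-3], axis=1)  # i -> i+3, defined for i < n-3
    m = n - 3
    is_h = (H_D2[0] <= d2[:m]) & (d2[:m] <= H_D2[1]) & (H_D3[0] <= d3) & (d3 <= H_D3[1])
    is_e = (E_D2[0] <= d2[:m]) & (d2[:m] <= E_D2[1]) & (E_D3[0] <= d3) & (d3 <= E_D3[1])
    states[:m][is_e] = "E"
    states[:m][is_h] = "H"  # helix wins on overlap
    return states


def _count_runs(states: Sequence[str]) -> int:
    n_sse = 0
    i = 0
    while i < len(states):
        s = states[i]
        j = i
        while j < len(states) and states[j] == s:
            j += 1
        run = j - i
        if (s == "H" and run >= MIN_HELIX_RUN) or (s == "E" and run >= MIN_STRAND_RUN):
            n_sse += 1
        i = j
    return n_sse


def assign_sse(model: PredictedModel, rng: ResidueRange) -> Tuple[np.ndarray, int]:
    """SSE states for the residues of ``rng`` and the number of elements.

    An element is a maximal run of >= 6 helical or >= 3 strand residues lying
    inside one contiguous segment of the range.
    """
    n = model.n_residues
    if rng.end > n:
        raise ValueError(f"range {rng.segments} outside model of length {n}")
    states = sse_states(model)
    out = []
    n_sse = 0
    for s, e in rng.segments:
        seg_states = states[s - 1 : e]
        out.append(seg_states)
        n_sse += _count_runs(seg_states)
    return np.concatenate(out), n_sse


def score_candidate(
    c: DomainCandidate, t: Optional[Thresholds] = None
) -> Tuple[Optional[float], RegionLabel, Optional[str]]:
    """Score a candidate from its best hit and give a provisional label.

    The best hit maximizes confidence x reference coverage; that product is
    the assignment score. ASSIGNED requires confidence >= conf_min and
    coverage >= cov_assign; PARTIAL requires confidence >= conf_min with
    coverage < cov_partial; anything else (the coverage gray zone included,
    and the no-hit case) is UNASSIGNED.
    """
    t = t or Thresholds()
    if not c.hits:
        return None, RegionLabel.UNASSIGNED, None
    best = max(c.hits, key=lambda h: h.confidence * h.ref_coverage)
    score = float(best.confidence * best.ref_coverage)
    if best.confidence >= t.conf_min and best.ref_coverage >= t.cov_assign:
        return score, RegionLabel.ASSIGNED, best.ref_group_id
    if best.confidence >= t.conf_min and best.ref_coverage < t.cov_partial:
        return score, RegionLabel.PARTIAL, best.ref_group_id
    return score, RegionLabel.UNASSIGNED, None


def classify_model(
    model: PredictedModel,
    candidates: Sequence[DomainCandidate],
    flexible_mask: np.ndarray,
    t: Optional[Thresholds] = None,
) -> List[ClassifiedRegion]:
    """Label every residue of one model exactly once.

    Candidate precedence: low mean plDDT -> LOW_CONFIDENCE; too few SSEs ->
    SIMPLE; otherwise the hit-based provisional label. Non-candidate residues
    are LOW_CONFIDENCE below the plDDT floor, FLEXIBLE above it, emitted as
    contiguous runs of equal label.
    """
    t = t or Thresholds()
    n = model.n_residues
    covered = np.zeros(n, dtype=bool)
    for c in candidates:
        cmask = c.range.to_mask(n)
        if np.any(covered & cmask):
            raise ValueError("parser contract violated: overlapping candidates")
        covered |= cmask

    regions: List[ClassifiedRegion] = []
    for c in candidates:
        _, n_sse = assign_sse(model, c.range)
        mean_plddt = float(model.plddt[c.range.residues() - 1].mean())
        if mean_plddt < t.plddt_min:
            label, score, group = RegionLabel.LOW_CONFIDENCE, None, None
        elif n_sse < t.sse_min_for_globular:
            label, score, group = RegionLabel.SIMPLE, None, None
        else:
            score, label, group = score_candidate(c, t)
        regions.append(ClassifiedRegion(
            model_id=model.model_id,
            range=c.range,
            label=label,
            h_group=group,
            score=score,
            mean_plddt=mean_plddt,
            n_sse=n_sse,
        ))

    # residues outside candidates, as contiguous equal-label runs
    outside = ~covered
    low = model.plddt < t.plddt_min
    i = 0
    while i < n:
        if not outside[i]:
            i += 1
            continue
        j = i
        while j < n and outside[j] and low[j] == low[i]:
            j += 1
        label = RegionLabel.LOW_CONFIDENCE if low[i] else RegionLabel.FLEXIBLE
        regions.append(ClassifiedRegion(
            model_id=model.model_id,
            range=ResidueRange.single(i + 1, j),
            label=label,
            mean_plddt=float(model.plddt[i:j].mean()),
            n_sse=0,
        ))
        i = j
    regions.sort(key=lambda r: r.range.start)
    return regions


def residue_labels(regions: Sequence[ClassifiedRegion], n: int) -> np.ndarray:
    """Per-residue label array (dtype str) for one model's regions."""
    out = np.full(n, "", dtype="<U16")
    for r in regions:
        for idx in r.range.residues():
            if out[idx - 1]:
                raise ValueError(f"residue {idx} labelled twice")
            out[idx - 1] = r.label.value
    if np.any(out == ""):
        raise ValueError("unlabelled residues")
    return out


def summarize_proteome(
    regions: Sequence[ClassifiedRegion], proteome_id: str = "proteome"
) -> ProteomeSummary:
    """Residue-weighted category fractions over all models of a proteome."""
    if not regions:
        raise ValueError("no regions to summarize")
    counts = {lab: 0 for lab in RegionLabel}
    models = set()
    n_domains = 0
    for r in regions:
        counts[r.label] += len(r.range)
        models.add(r.model_id)
        if r.label in DOMAIN_LABELS:
            n_domains += 1
    total = sum(counts.values())
    fractions = {lab: c / total for lab, c in counts.items()}
    return ProteomeSummary(
        proteome_id=proteome_id,
        counts=counts,
        fractions=fractions,
        n_models=len(models),
        n_domains=n_domains,
    )


def write_summary(summaries, path) -> None:
    """One row per proteome; category columns in the fixed six-label order."""
    labels = [lab.value for lab in RegionLabel]
    with open(path, "w") as fh:
        fh.write("proteome_id\tn_models\tn_domains\ttotal_residues\t"
                 + "\t".join(f"frac_{l}" for l in labels) + "\n")
        for s in summaries:
            fh.write(
                f"{s.proteome_id}\t{s.n_models}\t{s.n_domains}\t{s.total_residues}\t"
                + "\t".join(f"{s.fractions[RegionLabel(l)]:.4f}" for l in labels)
                + "\n"
            )
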