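"""Comparison of parsed domains against sequence-annotation intervals.

Covers two tasks: mapping obsolete protein records to current ones by exact
sequence identity, and measuring how much of a parsed domain is covered by
existing sequence-classification intervals (bulk protein-to-domain rows).
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

from .types import AnnotationInterval, ObsoleteMapping, ResidueRange, SeqRecord

__all__ = ["map_obsolete", "domain_annotation_coverage"]


def map_obsolete(
    obsolete: Sequence[SeqRecord], current: Sequence[SeqRecord]
) -> ObsoleteMapping:
    """Map obsolete records to current ones by 100% sequence identity.

    Exact string equality (which implies identical length) is required.
    No match maps to None; multiple matches map to the lexicographically
    smallest current id and set the ambiguity flag. Deterministic regardless
    of the input order of the current set.
    """
    by_seq: Dict[str, list] = {}
    for rec in current:
        by_seq.setdefault(rec.sequence, []).append(rec.id)
    mapping, ambiguous = {}, set()
    for rec in obsolete:
        matches = sorted(by_seq.get(rec.sequence, []))
        if not matches:
            mapping[rec.id] = None
        else:
            mapping[rec.id] = matches[0]
            if len(matches) > 1:
                ambiguous.add(rec.id)
    return ObsoleteMapping(mapping=mapping, ambiguous=ambiguous)


def domain_annotation_coverage(
    domain: ResidueRange,
    annotations: Sequence[AnnotationInterval],
    theta: float = 0.5,
) -> Tuple[float, bool]:
    """Fraction of a domain's residues inside the union of annotation intervals.

    A domain counts as covered by an existing sequence classification when the
    covered fraction reaches ``theta`` (default 0.5).
    """
    dom = domain.residue_set()
    covered = set()
    for a in annotations:
        covered.update(range(a.start, a.end + 1))
    frac = len(dom & covered) / len(dom)
    return frac, frac >= theta
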