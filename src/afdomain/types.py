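"""Shared domain types for predicted-structure domain classification.

Residue indexing is 1-based inclusive everywhere (matching the range-string
dialect used by structural domain catalogs); PAE matrices are indexed 0-based
internally and converted at the boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "RegionLabel",
    "ResidueRange",
    "PredictedModel",
    "HomologyHit",
    "ReferenceDomain",
    "ReferenceCatalog",
    "Thresholds",
    "Segment",
    "PairFeatures",
    "DomainCandidate",
    "ClassifiedRegion",
    "ProteomeSummary",
    "GroundTruth",
    "SeqRecord",
    "ClusterParams",
    "Cluster",
    "AnnotationInterval",
    "ObsoleteMapping",
    "CLASS5",
]

#: The five structural classes used to bin architectures.
CLASS5 = ("all-α", "all-β", "α/β", "α+β", "few-SSE")


class RegionLabel(str, enum.Enum):
    """Six per-residue region categories.

    ASSIGNED
        Globular domain with a well-defined homologous link to a reference domain.
    UNASSIGNED
        Globular with well-defined secondary structure, but no confident link to
        the reference could be determined.
    PARTIAL
        High-confidence homologous link but no high-coverage alignment — often
        pseudogenes or genome-annotation errors.
    SIMPLE
        Region with 2 or fewer secondary structure elements (single helices,
        coiled coils).
    FLEXIBLE
        Linker/disordered by PAE: non-globular, low-confidence pairwise
        interactions with the rest of the chain.
    LOW_CONFIDENCE
        Region with low (< 70) predicted per-residue confidence (plDDT).
    """

    ASSIGNED = "ASSIGNED"
    UNASSIGNED = "UNASSIGNED"
    PARTIAL = "PARTIAL"
    SIMPLE = "SIMPLE"
    FLEXIBLE = "FLEXIBLE"
    LOW_CONFIDENCE = "LOW_CONFIDENCE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Labels counted as parsed domain regions in proteome summaries.
DOMAIN_LABELS = (
    RegionLabel.ASSIGNED,
    RegionLabel.UNASSIGNED,
    RegionLabel.PARTIAL,
    RegionLabel.SIMPLE,
)


@dataclass(frozen=True)
class ResidueRange:
    """Ordered, non-overlapping 1-based inclusive residue segments."""

    segments: tuple

    def __post_init__(self):
        segs = tuple((int(s), int(e)) for s, e in self.segments)
        if not segs:
            raise ValueError("empty range")
        for s, e in segs:
            if s < 1:
                raise ValueError(f"residue index < 1 in segment {s}-{e}")
            if s > e:
                raise ValueError(f"inverted segment {s}-{e}")
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlap between {s1}-{e1} and {s2}-{e2}")
        object.__setattr__(self, "segments", segs)

    @classmethod
    def single(cls, start: int, end: int) -> "ResidueRange":
        return cls(((start, end),))

    @classmethod
    def from_residues(cls, residues: Iterable[int]) -> "ResidueRange":
        """Build a range from residue indices, merging consecutive runs."""
        idx = sorted(set(int(r) for r in residues))
        if not idx:
            raise ValueError("empty range")
        segs = []
        start = prev = idx[0]
        for r in idx[1:]:
            if r == prev + 1:
                prev = r
            else:
                segs.append((start, prev))
                start = prev = r
        segs.append((start, prev))
        return cls(tuple(segs))

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    def __len__(self) -> int:
        return sum(e - s + 1 for s, e in self.segments)

    def residues(self) -> np.ndarray:
        """All residue indices (1-based) in the range."""
        return np.concatenate([np.arange(s, e + 1) for s, e in self.segments])

    def residue_set(self) -> frozenset:
        return frozenset(int(r) for r in self.residues())

    def to_mask(self, n: int) -> np.ndarray:
        """Boolean mask of length ``n`` (0-based positions)."""
        mask = np.zeros(n, dtype=bool)
        for s, e in self.segments:
            if e > n:
                raise ValueError(f"range {s}-{e} exceeds length {n}")
            mask[s - 1 : e] = True
        return mask

    def jaccard(self, other: "ResidueRange") -> float:
        a, b = self.residue_set(), other.residue_set()
        return len(a & b) / len(a | b)


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite values in {name}")
    return arr


@dataclass
class PredictedModel:
    """One chain of a predicted structure: sequence, C-alpha trace, plDDT, PAE.

    ``pae`` may be None when the model was read from coordinates alone; all
    parsing operations that need pairwise confidence raise in that case.
    """

    model_id: str
    sequence: str
    ca_coords: np.ndarray  # (n, 3) in Angstrom
    plddt: np.ndarray  # (n,) in [0, 100]
    pae: Optional[np.ndarray] = None  # (n, n) in Angstrom, >= 0

    def __post_init__(self):
        self.ca_coords = _as_float_array(self.ca_coords, "ca_coords").reshape(-1, 3)
        self.plddt = _as_float_array(self.plddt, "plddt").ravel()
        n = len(self.sequence)
        if self.ca_coords.shape[0] != n or self.plddt.shape[0] != n:
            raise ValueError(
                "sequence, ca_coords and plddt must have equal length "
                f"(got {n}, {self.ca_coords.shape[0]}, {self.plddt.shape[0]})"
            )
        if np.any(self.plddt < 0) or np.any(self.plddt > 100):
            raise ValueError("plddt values must lie in [0, 100]")
        if self.pae is not None:
            self.pae = _as_float_array(self.pae, "pae")
            if self.pae.shape != (n, n):
                raise ValueError(f"pae must be {n}x{n}, got {self.pae.shape}")
            if np.any(self.pae < 0):
                raise ValueError("pae entries must be >= 0")
            if np.any(np.diagonal(self.pae) > 1.0):
                raise ValueError("pae diagonal must be <= 1.0")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def pae_sym(self) -> np.ndarray:
        """Symmetrized PAE: mean of (i,j) and (j,i)."""
        if self.pae is None:
            raise ValueError("PAE required")
        return 0.5 * (self.pae + self.pae.T)


@dataclass
class HomologyHit:
    """One search hit linking a query range to a reference domain.

    ``source`` distinguishes sequence-profile search output from structure-
    alignment search output; both feed the shared-hit-membership pair features.
    """

    source: str  # "sequence_profile" | "structure_align"
    query_id: str
    query_range: ResidueRange
    ref_domain_id: str
    ref_group_id: str
    confidence: float
    ref_coverage: float
    aligned_pairs: Optional[Sequence] = None

    def __post_init__(self):
        if self.source not in ("sequence_profile", "structure_align"):
            raise ValueError(f"unknown hit source {self.source!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")
        if not 0.0 <= self.ref_coverage <= 1.0:
            raise ValueError("ref_coverage must lie in [0, 1]")


@dataclass(frozen=True)
class ReferenceDomain:
    domain_id: str
    f_group: str
    h_group: str
    x_group: str
    architecture: str
    class5: str
    length: int
    kingdom: str

    def __post_init__(self):
        if self.class5 not in CLASS5:
            raise ValueError(f"class5 must be one of {CLASS5}, got {self.class5!r}")


@dataclass
class ReferenceCatalog:
    """Flat catalog of reference domains with their hierarchy placement."""

    domains: list

    def __post_init__(self):
        ids = [d.domain_id for d in self.domains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate domain_id in catalog")

    @property
    def h_groups(self) -> list:
        seen, out = set(), []
        for d in self.domains:
            if d.h_group not in seen:
                seen.add(d.h_group)
                out.append(d.h_group)
        return out

    def members(self, h_group: str) -> list:
        return [d for d in self.domains if d.h_group == h_group]

    def group_meta(self) -> dict:
        """h_group -> (class5, architecture); groups are homogeneous by construction."""
        meta = {}
        for d in self.domains:
            meta.setdefault(d.h_group, (d.class5, d.architecture))
        return meta


@dataclass
class Thresholds:
    """Tunable cutoffs for parsing and classification.

    plddt_min
        Per-residue confidence below which a region is low-confidence (0-100).
    sse_min_for_globular
        Minimum number of secondary structure elements for a globular domain;
        candidates with fewer are "simple topology".
    segment_len
        Length of the residue segments clustered into domains.
    pair_prob_cut
        Average-linkage threshold on the same-domain pair probability.
    min_domain_len
        Candidates shorter than this are merged into a neighbor or dropped.
    conf_min, cov_assign, cov_partial
        Hit confidence / reference-coverage cutoffs for assigned vs partial.
    flex_partner_pae, flex_min_partners, flex_seq_sep
        A residue is flexible when it has fewer than ``flex_min_partners``
        sequence-distant partners (|i-j| > flex_seq_sep) with symmetrized
        PAE below ``flex_partner_pae`` Angstrom.
    alpha
        Significance level for enrichment testing (before Bonferroni).
    """

    plddt_min: float = 70.0
    sse_min_for_globular: int = 3
    segment_len: int = 5
    pair_prob_cut: float = 0.5
    min_domain_len: int = 25
    conf_min: float = 0.8
    cov_assign: float = 0.7
    cov_partial: float = 0.5
    flex_partner_pae: float = 10.0
    flex_min_partners: int = 5
    flex_seq_sep: int = 10
    alpha: float = 0.05

    def __post_init__(self):
        for name in ("pair_prob_cut", "conf_min", "cov_assign", "cov_partial", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.plddt_min <= 100.0:
            raise ValueError("plddt_min must lie in [0, 100]")
        for name in ("sse_min_for_globular", "segment_len", "min_domain_len",
                     "flex_min_partners", "flex_seq_sep"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "Thresholds":
        return cls(**d)

    def with_overrides(self, **kw) -> "Thresholds":
        return replace(self, **kw)


@dataclass(frozen=True)
class Segment:
    """One contiguous 3-7 residue block of a non-flexible run."""

    index: int
    start: int
    end: int

    def __post_init__(self):
        if not 3 <= self.end - self.start + 1 <= 7:
            raise ValueError("segment length must be 3-7 residues")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def residues(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)

    @property
    def range(self) -> ResidueRange:
        return ResidueRange.single(self.start, self.end)


@dataclass(frozen=True)
class PairFeatures:
    """Per-residue-pair features feeding the same-domain probability model."""

    d_ca: float
    pae_sym: float
    n_shared_seq: int
    n_shared_str: int

    def __post_init__(self):
        if self.d_ca < 0 or self.pae_sym < 0:
            raise ValueError("distances must be >= 0")
        if self.n_shared_seq < 0 or self.n_shared_str < 0:
            raise ValueError("shared-hit counts must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.d_ca, self.pae_sym, self.n_shared_seq, self.n_shared_str], dtype=float
        )


@dataclass
class DomainCandidate:
    """A parsed putative domain prior to categorization."""

    range: ResidueRange
    segment_ids: list = field(default_factory=list)
    mean_plddt: float = 0.0
    n_sse: int = 0
    hits: list = field(default_factory=list)
    score: Optional[float] = None

    def __len__(self) -> int:
        return len(self.range)


@dataclass
class ClassifiedRegion:
    model_id: str
    range: ResidueRange
    label: RegionLabel
    h_group: Optional[str] = None
    score: Optional[float] = None
    mean_plddt: float = 0.0
    n_sse: int = 0

    def __post_init__(self):
        self.label = RegionLabel(self.label)
        has_group = self.h_group is not None
        if has_group != (self.label in (RegionLabel.ASSIGNED, RegionLabel.PARTIAL)):
            raise ValueError("h_group present iff label is ASSIGNED or PARTIAL")


@dataclass
class ProteomeSummary:
    proteome_id: str
    counts: dict  # RegionLabel -> residue count
    fractions: dict  # RegionLabel -> fraction of residues
    n_models: int
    n_domains: int

    @property
    def total_residues(self) -> int:
        return sum(self.counts.values())


@dataclass
class GroundTruth:
    """Per-residue true category labels plus the true domain partition."""

    model_id: str
    labels: list  # length-n list of RegionLabel
    true_partition: list  # [(ResidueRange, true_group_id)]

    def __post_init__(self):
        self.labels = [RegionLabel(l) for l in self.labels]
        n = len(self.labels)
        covered = np.zeros(n, dtype=int)
        for rng, _ in self.true_partition:
            covered += rng.to_mask(n)
        if np.any(covered > 1):
            raise ValueError("true partition ranges overlap")

    @property
    def n_residues(self) -> int:
        return len(self.labels)

    def label_array(self) -> np.ndarray:
        return np.array([l.value for l in self.labels])


@dataclass
class SeqRecord:
    """A sequence with the metadata the representative-priority policy uses."""

    id: str
    sequence: str
    is_previous_rep: bool = False
    is_manual: bool = False
    is_provisional_manual: bool = False
    method: str = "other"  # xray | em | nmr | other
    resolution: Optional[float] = None
    release_date: Optional[str] = None  # ISO yyyy-mm-dd

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        if not self.sequence.isupper() or not self.sequence.isalpha():
            raise ValueError("sequence must be uppercase amino-acid letters")


@dataclass(frozen=True)
class ClusterParams:
    identity: float
    coverage: float
    coverage_mode: str = "local_query"  # local_query | bidirectional
    word_size: int = 4

    def __post_init__(self):
        if not 0.0 < self.identity <= 1.0 or not 0.0 < self.coverage <= 1.0:
            raise ValueError("identity and coverage must lie in (0, 1]")
        if self.word_size < 2:
            raise ValueError("word_size must be >= 2")
        if self.coverage_mode not in ("local_query", "bidirectional"):
            raise ValueError(f"unknown coverage_mode {self.coverage_mode!r}")


@dataclass
class Cluster:
    representative_id: str
    member_ids: list
    identities: dict = field(default_factory=dict)  # member -> identity vs rep
    coverages: dict = field(default_factory=dict)  # member -> (cov_member, cov_rep)

    def __post_init__(self):
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member of its cluster")


@dataclass(frozen=True)
class AnnotationInterval:
    protein_id: str
    source_db: str
    entry_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"inverted annotation interval {self.start}-{self.end}")


@dataclass
class ObsoleteMapping:
    """obsolete_id -> current_id (or None) with per-record ambiguity flags."""

    mapping: dict
    ambiguous: set = field(default_factory=set)
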