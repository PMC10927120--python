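"""Synthetic predicted-structure fixtures with known ground truth.

Emulates the statistical structure the downstream analysis assumes: multi-block
chains with ideal secondary-structure geometry for ordered blocks, self-avoiding
random coils for disordered blocks, block-structured PAE (low within a globular
block, high across blocks, very high for non-globular residues), bimodal plDDT,
mock reference catalogs, and homology-hit tables whose confidence/coverage are
consistent with the per-block ground truth by construction.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .types import (
    GroundTruth,
    HomologyHit,
    PredictedModel,
    ReferenceCatalog,
    ReferenceDomain,
    RegionLabel,
    ResidueRange,
    SeqRecord,
    CLASS5,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: PAE payload ceiling in the AFDB JSON dialect.
PAE_MAX = 31.75
PAE_MIN = 0.2

BLOCK_KINDS = ("domain", "linker", "disordered_tail", "simple_helix")
GEOMETRIES = ("helix_bundle", "sheet_sandwich", "mixed")
SCENARIOS = ("assigned", "unassigned", "partial")

_KIND_LABEL = {
    "simple_helix": RegionLabel.SIMPLE,
    "linker": RegionLabel.FLEXIBLE,
    "disordered_tail": RegionLabel.LOW_CONFIDENCE,
}
_SCENARIO_LABEL = {
    "assigned": RegionLabel.ASSIGNED,
    "unassigned": RegionLabel.UNASSIGNED,
    "partial": RegionLabel.PARTIAL,
}


@dataclass(frozen=True)
class Block:
    """One chain block: a domain, a linker, a disordered tail or a lone helix."""

    kind: str
    length: int
    group_id: Optional[str] = None
    geometry: str = "helix_bundle"
    scenario: str = "assigned"

    def __post_init__(self):
        if self.kind not in BLOCK_KINDS:
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("block length must be >= 1")
        if self.kind == "domain":
            if self.group_id is None:
                raise ValueError("domain blocks must carry a true_group_id")
            if self.geometry not in GEOMETRIES:
                raise ValueError(f"unknown geometry {self.geometry!r}")
            if self.scenario not in SCENARIOS:
                raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic chain.

    Distribution parameters are (mean, sd) pairs. Defaults place within-domain
    PAE (~4 A) and across-domain PAE (~20 A) far apart, with non-globular
    residues near the payload ceiling, and plDDT ~90 for ordered vs ~50 for
    disordered residues.
    """

    blocks: List[Block]
    pae_within: Tuple[float, float] = (4.0, 1.0)
    pae_between: Tuple[float, float] = (20.0, 3.0)
    pae_disorder: Tuple[float, float] = (28.0, 2.0)
    plddt_ordered: Tuple[float, float] = (90.0, 5.0)
    plddt_disordered: Tuple[float, float] = (50.0, 10.0)
    seed: int = 0
    model_id: str = "synthetic"

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("spec must contain at least one block")
        for pair in (self.pae_within, self.pae_between, self.pae_disorder,
                     self.plddt_ordered, self.plddt_disordered):
            if pair[0] < 0:
                raise ValueError("distribution means must be >= 0")


# ---------------------------------------------------------------------------
# ideal geometry builders (local frames)


def helix_coords(n: int, rise: float = 1.5, radius: float = 2.3,
                 twist_deg: float = 100.0) -> np.ndarray:
    """Ideal alpha-helix C-alpha trace along +z."""
    t = np.deg2rad(twist_deg) * np.arange(n)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), rise * np.arange(n)])


def strand_coords(n: int, rise: float = 3.3, amplitude: float = 0.94) -> np.ndarray:
    """Ideal beta-strand zigzag along +z (pleat in y)."""
    i = np.arange(n)
    return np.column_stack([np.zeros(n), amplitude * (-1.0) ** i, rise * i])


def _place(local: np.ndarray, origin: np.ndarray, flip_z: bool) -> np.ndarray:
    out = local.copy()
    if flip_z:
        out[:, 2] = out[:, 2].max() - out[:, 2]
    return out + origin


def _interp_loop(n: int, a: np.ndarray, b: np.ndarray, rng) -> np.ndarray:
    """n loop residues between anchors a and b with small jitter."""
    frac = np.linspace(0, 1, n + 2)[1:-1, None]
    pts = a + frac * (b - a)
    return pts + rng.normal(0.0, 0.3, size=pts.shape)


def _sse_layout(length: int, sse_len: int, loop_len: int, min_sse: int = 3):
    """Split a block length into alternating SSE/loop element lengths."""
    unit = sse_len + loop_len
    n_sse = max(min_sse, (length + loop_len) // unit)
    loop_total = loop_len * (n_sse - 1)
    sse_total = length - loop_total
    base, extra = divmod(sse_total, n_sse)
    if base < 6:
        raise ValueError(f"block of {length} residues too short for {n_sse} SSEs")
    lens = [base + (1 if i < extra else 0) for i in range(n_sse)]
    return lens, loop_len


def _domain_block_coords(length: int, geometry: str, rng) -> np.ndarray:
    """Compact multi-SSE domain coordinates in a local frame."""
    coords: list = []
    if geometry == "helix_bundle":
        lens, loop_len = _sse_layout(length, 14, 4)
        spacing, maker = 6.0, helix_coords
    elif geometry == "sheet_sandwich":
        lens, loop_len = _sse_layout(length, 8, 3)
        spacing, maker = 4.8, strand_coords
    elif geometry == "mixed":
        return _mixed_block_coords(length, rng)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    for k, ln in enumerate(lens):
        origin = np.array([k * spacing, 0.0, 0.0])
        sse = _place(maker(ln), origin, flip_z=(k % 2 == 1))
        if coords and loop_len:
            coords.append(_interp_loop(loop_len, coords[-1][-1], sse[0], rng))
        coords.append(sse)
    return np.vstack(coords)


def _mixed_block_coords(length: int, rng) -> np.ndarray:
    """Alternating helix/strand elements; any remainder trails as coil."""
    elements = []  # (maker, length)
    budget, use_helix, n_sse = length, True, 0
    while True:
        need = 12 if use_helix else 7
        # stop once at least three SSEs are in and the rest is too short
        if budget < need + 3 and n_sse >= 3:
            break
        if budget < need:
            break
        elements.append((helix_coords if use_helix else strand_coords, need))
        budget -= need
        n_sse += 1
        if budget >= 3:
            elements.append((None, 3))  # loop
            budget -= 3
        use_helix = not use_helix
    if n_sse < 3:
        raise ValueError(f"block of {length} residues too short for mixed geometry")
    coords: list = []
    k = 0
    for maker, ln in elements:
        if maker is None:
            coords.append(_interp_loop(ln, coords[-1][-1],
                                       np.array([(k) * 5.5, 0.0, 0.0]), rng))
            continue
        sse = _place(maker(ln), np.array([k * 5.5, 0.0, 0.0]), flip_z=(k % 2 == 1))
        coords.append(sse)
        k += 1
    if budget > 0:  # trailing coil: 3.8 A steps, outside both SSE windows
        last = coords[-1][-1]
        tail = last + np.outer(np.arange(1, budget + 1), np.array([0.0, 3.8, 0.0]))
        coords.append(tail)
    return np.vstack(coords)


def _coil_coords(length: int, start: np.ndarray, rng,
                 step: float = 3.8, clash: float = 3.0) -> np.ndarray:
    """Self-avoiding random walk (coil) from ``start``."""
    pts = [np.asarray(start, dtype=float)]
    for _ in range(length - 1):
        prev = pts[-1]
        for _attempt in range(40):
            v = rng.normal(size=3)
            v *= step / np.linalg.norm(v)
            cand = prev + v
            d = np.linalg.norm(np.array(pts) - cand, axis=1)
            if len(d) < 2 or np.min(d[:-1]) >= clash:
                break
        pts.append(cand)
    return np.array(pts[:length]) if length > 1 else np.array(pts)


# ---------------------------------------------------------------------------
# model generation


def generate_model(spec: SyntheticSpec) -> Tuple[PredictedModel, GroundTruth]:
    """Build one synthetic chain plus its per-residue ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = sum(b.length for b in spec.blocks)

    # block bookkeeping: globular blocks get a distinct id, others -1
    block_of = np.empty(n, dtype=int)
    globular = np.zeros(n, dtype=bool)
    labels: List[RegionLabel] = []
    partition = []
    coords = np.empty((n, 3))

    pos = 0
    cursor = 0.0  # x offset where the next ordered block starts
    chain_end = np.zeros(3)
    for bi, blk in enumerate(spec.blocks):
        sl = slice(pos, pos + blk.length)
        block_of[sl] = bi
        if blk.kind == "domain":
            local = _domain_block_coords(blk.length, blk.geometry, rng)
            local[:, 0] += cursor - local[:, 0].min()
            coords[sl] = local
            globular[sl] = True
            labels.extend([_SCENARIO_LABEL[blk.scenario]] * blk.length)
            partition.append(
                (ResidueRange.single(pos + 1, pos + blk.length), blk.group_id)
            )
        elif blk.kind == "simple_helix":
            local = helix_coords(blk.length)
            local[:, 0] += cursor - local[:, 0].min()
            coords[sl] = local
            globular[sl] = True
            labels.extend([RegionLabel.SIMPLE] * blk.length)
        else:  # linker / disordered_tail: coil from the current chain end
            start = chain_end + np.array([3.8, 0.0, 0.0]) if pos else np.zeros(3)
            local = _coil_coords(blk.length, start, rng)
            coords[sl] = local
            labels.extend([_KIND_LABEL[blk.kind]] * blk.length)
        cursor = max(cursor, coords[sl][:, 0].max()) + 25.0
        chain_end = coords[sl][-1]
        pos += blk.length

    # plDDT: ordered for domains/helices/linkers, disordered for tails
    low_conf = np.array([lab is RegionLabel.LOW_CONFIDENCE for lab in labels])
    mu_o, sd_o = spec.plddt_ordered
    mu_d, sd_d = spec.plddt_disordered
    plddt = np.where(
        low_conf,
        rng.normal(mu_d, sd_d, size=n),
        rng.normal(mu_o, sd_o, size=n),
    )
    plddt = np.round(np.clip(plddt, 0.0, 100.0), 2)

    # PAE: within-globular-block / across-blocks / either-non-globular
    pae = rng.normal(*spec.pae_between, size=(n, n))
    same = (block_of[:, None] == block_of[None, :]) & globular[:, None] & globular[None, :]
    pae[same] = rng.normal(*spec.pae_within, size=int(same.sum()))
    nonglob = ~globular
    dis = nonglob[:, None] | nonglob[None, :]
    pae[dis] = rng.normal(*spec.pae_disorder, size=int(dis.sum()))
    pae = np.clip(pae, PAE_MIN, PAE_MAX)
    np.fill_diagonal(pae, PAE_MIN)
    pae = np.round(pae, 2)

    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=n))
    model = PredictedModel(
        model_id=spec.model_id,
        sequence=sequence,
        ca_coords=np.round(coords, 3),
        plddt=plddt,
        pae=pae,
    )
    truth = GroundTruth(model_id=spec.model_id, labels=labels, true_partition=partition)
    return model, truth


# ---------------------------------------------------------------------------
# reference catalog and hit tables


def make_reference_catalog(n_groups: int, seed: int) -> ReferenceCatalog:
    """Mock reference set: homologous groups in five classes, two kingdoms."""
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    rng = np.random.default_rng(seed)
    archs = {
        "all-α": "α-bundle", "all-β": "β-sandwich", "α/β": "α/β-barrel",
        "α+β": "α+β-plait", "few-SSE": "few-SSE",
    }
    domains = []
    for g in range(n_groups):
        class5 = CLASS5[g % len(CLASS5)]
        kingdom = ("eukaryote", "bacteria")[g % 2]
        n_members = int(rng.integers(1, 6))
        for k in range(n_members):
            domains.append(ReferenceDomain(
                domain_id=f"d{g:04d}.{k}",
                f_group=f"F{g:04d}.{k}",
                h_group=f"H{g:04d}",
                x_group=f"X{g // 2:04d}",
                architecture=archs[class5],
                class5=class5,
                length=int(rng.integers(40, 301)),
                kingdom=kingdom,
            ))
    return ReferenceCatalog(domains)


def generate_hits(
    truth: GroundTruth,
    catalog: ReferenceCatalog,
    conf: Tuple[float, float] = (0.92, 0.04),
    ref_cov: Tuple[float, float] = (0.85, 0.05),
    partial_cov: Tuple[float, float] = (0.3, 0.05),
    decoy_rate: float = 0.0,
    seed: int = 0,
) -> List[HomologyHit]:
    """Emit hits consistent with the ground truth.

    Each ASSIGNED domain gets one sequence-profile and one structure-alignment
    hit to its true group; PARTIAL domains get low-reference-coverage hits;
    UNASSIGNED domains get none. Decoy hits to random wrong groups are added
    per domain with probability ``decoy_rate``.
    """
    rng = np.random.default_rng(seed)
    groups = catalog.h_groups
    members = {g: [d.domain_id for d in catalog.members(g)] for g in groups}
    hits: List[HomologyHit] = []
    for rrange, group in truth.true_partition:
        if group not in members:
            raise ValueError(f"unknown group id {group!r}")
        block_labels = {truth.labels[i - 1] for i in rrange.residues()}
        label = next(iter(block_labels))
        if label is RegionLabel.UNASSIGNED:
            continue
        cov_mu, cov_sd = partial_cov if label is RegionLabel.PARTIAL else ref_cov
        for source in ("sequence_profile", "structure_align"):
            c = float(np.clip(rng.normal(*conf), 0.0, 1.0))
            v = float(np.clip(rng.normal(cov_mu, cov_sd), 0.01, 1.0))
            hits.append(HomologyHit(
                source=source,
                query_id=truth.model_id,
                query_range=rrange,
                ref_domain_id=str(rng.choice(members[group])),
                ref_group_id=group,
                confidence=round(c, 4),
                ref_coverage=round(v, 4),
            ))
        if decoy_rate > 0 and rng.random() < decoy_rate:
            wrong = [g for g in groups if g != group]
            if wrong:
                g = str(rng.choice(wrong))
                hits.append(HomologyHit(
                    source=str(rng.choice(["sequence_profile", "structure_align"])),
                    query_id=truth.model_id,
                    query_range=rrange,
                    ref_domain_id=str(rng.choice(members[g])),
                    ref_group_id=g,
                    confidence=round(float(rng.uniform(0.1, 0.5)), 4),
                    ref_coverage=round(float(rng.uniform(0.3, 0.9)), 4),
                ))
    return hits


# ---------------------------------------------------------------------------
# whole synthetic proteomes

#: Default per-residue category mix: the per-residue category percentages the
#: analysis reports on real whole proteomes (66/4/1/4/12/12 for assigned/
#: unassigned/partial/simple/flexible/low-confidence), renormalized to sum to 1.
DEFAULT_MIX = {
    "assigned": 66 / 99,
    "unassigned": 4 / 99,
    "partial": 1 / 99,
    "simple": 4 / 99,
    "flexible": 12 / 99,
    "low_confidence": 12 / 99,
}

#: Block length per category (residues): domains 60, lone helices 30,
#: linkers 15, disordered tails 20 — typical scales for each region type.
CATEGORY_BLOCK_LEN = {
    "assigned": 60,
    "unassigned": 60,
    "partial": 60,
    "simple": 30,
    "flexible": 15,
    "low_confidence": 20,
}

_CATEGORY_TRUTH = {
    "assigned": RegionLabel.ASSIGNED,
    "unassigned": RegionLabel.UNASSIGNED,
    "partial": RegionLabel.PARTIAL,
    "simple": RegionLabel.SIMPLE,
    "flexible": RegionLabel.FLEXIBLE,
    "low_confidence": RegionLabel.LOW_CONFIDENCE,
}


@dataclass
class ProteomeBundle:
    models: list
    truths: list
    hits: list
    catalog: ReferenceCatalog
    expected_fractions: dict  # realized ground-truth residue fractions


def generate_proteome(
    n_models: int,
    mix: Optional[dict] = None,
    seed: int = 0,
    n_groups: int = 20,
    blocks_per_model: int = 8,
    decoy_rate: float = 0.1,
) -> ProteomeBundle:
    """Draw a synthetic proteome whose residue-category fractions follow ``mix``.

    Block categories are drawn with probability proportional to
    ``mix[c] / block_length[c]`` so that the expected per-residue fraction of
    category ``c`` equals ``mix[c]``.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    mix = dict(DEFAULT_MIX if mix is None else mix)
    unknown = set(mix) - set(_CATEGORY_TRUTH)
    if unknown:
        raise ValueError(f"unknown mix categories: {sorted(unknown)}")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"mix weights must sum to 1, got {total}")

    rng = np.random.default_rng(seed)
    cats = sorted(mix)
    p = np.array([mix[c] / CATEGORY_BLOCK_LEN[c] for c in cats])
    p /= p.sum()

    catalog = make_reference_catalog(n_groups, int(rng.integers(2**31)))
    groups = catalog.h_groups

    models, truths, all_hits = [], [], []
    label_counts: dict = {lab: 0 for lab in RegionLabel}
    for mi in range(n_models):
        blocks = []
        for _, cat in zip(range(blocks_per_model), rng.choice(cats, size=blocks_per_model, p=p)):
            length = CATEGORY_BLOCK_LEN[cat]
            if cat in ("assigned", "unassigned", "partial"):
                blocks.append(Block(
                    kind="domain",
                    length=length,
                    group_id=str(rng.choice(groups)),
                    geometry=GEOMETRIES[int(rng.integers(len(GEOMETRIES)))],
                    scenario=cat,
                ))
            elif cat == "simple":
                blocks.append(Block(kind="simple_helix", length=length))
            elif cat == "flexible":
                blocks.append(Block(kind="linker", length=length))
            else:
                blocks.append(Block(kind="disordered_tail", length=length))
        spec = SyntheticSpec(
            blocks=blocks,
            seed=int(rng.integers(2**31)),
            model_id=f"SYN{mi:04d}",
        )
        model, truth = generate_model(spec)
        hits = generate_hits(
            truth, catalog, decoy_rate=decoy_rate, seed=int(rng.integers(2**31))
        )
        models.append(model)
        truths.append(truth)
        all_hits.extend(hits)
        for lab in truth.labels:
            label_counts[lab] += 1

    total_res = sum(label_counts.values())
    fractions = {lab.value: c / total_res for lab, c in label_counts.items()}
    return ProteomeBundle(models, truths, all_hits, catalog, fractions)


# ---------------------------------------------------------------------------
# sequence families for clustering fixtures


def make_families(
    n_families: int = 10,
    members_per_family: int = 10,
    length_range: Tuple[int, int] = (80, 150),
    mutation_rate: float = 0.05,
    seed: int = 0,
) -> List[SeqRecord]:
    """Sequence families: random roots, members with point substitutions.

    Intra-family identity is ~(1 - mutation_rate)^2-ish (>0.9 by default);
    inter-family sequences are unrelated random strings.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    records = []
    for f in range(n_families):
        length = int(rng.integers(*length_range))
        root = rng.choice(aa, size=length)
        for m in range(members_per_family):
            seq = root.copy()
            mut = rng.random(length) < mutation_rate
            if m > 0 and mut.any():
                seq[mut] = rng.choice(aa, size=int(mut.sum()))
            records.append(SeqRecord(id=f"fam{f:02d}_m{m:02d}", sequence="".join(seq)))
    return records
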