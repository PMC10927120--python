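"""Readers and writers for external formats.

Covers coordinate files (mmCIF/PDB with plDDT in the B-factor column, the
AFDB convention), PAE JSON payloads, range strings, hit tables, reference
catalogs, per-residue truth tables and classified-region tables. All tables
are plain TSV; floats are written at 4 decimals so diffs are stable.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import List, Optional

import gemmi
import numpy as np
import pandas as pd

from .types import (
    AnnotationInterval,
    ClassifiedRegion,
    HomologyHit,
    PredictedModel,
    ReferenceCatalog,
    ReferenceDomain,
    RegionLabel,
    ResidueRange,
)

logger = logging.getLogger("afdomain")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

_RANGE_RE = re.compile(r"^\d+-\d+$")


# ---------------------------------------------------------------------------
# range strings


def parse_range(text: str) -> ResidueRange:
    """Parse a comma-separated "start-end" range string ("1-3,7-9")."""
    tokens = [t.strip() for t in str(text).split(",")]
    segs = []
    for tok in tokens:
        if not _RANGE_RE.match(tok):
            raise ValueError(f"malformed range token {tok!r}")
        s, e = (int(x) for x in tok.split("-"))
        if s > e:
            raise ValueError(f"inverted segment {tok}")
        segs.append((s, e))
    for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
        if s2 <= e1:
            raise ValueError(f"overlap between {s1}-{e1} and {s2}-{e2}")
    return ResidueRange(tuple(segs))


def format_range(r: ResidueRange) -> str:
    return ",".join(f"{s}-{e}" for s, e in r.segments)


# ---------------------------------------------------------------------------
# coordinate models


def read_model(path, chain: Optional[str] = None) -> PredictedModel:
    """Read one chain of an mmCIF/PDB file into a PredictedModel (without PAE).

    plDDT is taken from the B-factor column; one residue per C-alpha atom,
    ordered by author sequence number. Residues lacking a C-alpha are skipped
    with a logged warning. B-factors above 100 mean the file does not follow
    the per-residue-confidence convention and are rejected.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    if chain is None:
        if len(model) == 0:
            raise ValueError(f"no chains in {path}")
        ch = model[0]
    else:
        ch = model.find_chain(chain)
        if ch is None:
            raise KeyError(f"chain not found: {chain!r}")

    entries = []
    n_skipped = 0
    for res in ch:
        ca = None
        for atom in res:
            if atom.name == "CA":
                ca = atom
                break
        if ca is None:
            n_skipped += 1
            continue
        aa = _THREE_TO_ONE.get(res.name, "X")
        entries.append((res.seqid.num, aa, (ca.pos.x, ca.pos.y, ca.pos.z), ca.b_iso))
    if n_skipped:
        logger.warning("%s: skipped %d residues lacking a C-alpha", path.name, n_skipped)
    if not entries:
        raise ValueError(f"no C-alpha atoms in chain of {path}")
    entries.sort(key=lambda t: t[0])
    plddt = np.array([b for _, _, _, b in entries], dtype=float)
    if np.any(plddt > 100.0):
        raise ValueError("B-factors exceed 100: not per-residue confidence (plDDT)")
    return PredictedModel(
        model_id=st.name or path.stem,
        sequence="".join(aa for _, aa, _, _ in entries),
        ca_coords=np.array([xyz for _, _, xyz, _ in entries], dtype=float),
        plddt=plddt,
    )


def write_model(model: PredictedModel, path) -> None:
    """Write a C-alpha-only mmCIF file with plDDT in the B-factor column."""
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model(1)
    ch = gemmi.Chain("A")
    for i, aa in enumerate(model.sequence):
        res = gemmi.Residue()
        res.name = _ONE_TO_THREE.get(aa, "UNK")
        res.seqid = gemmi.SeqId(i + 1, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        x, y, z = model.ca_coords[i]
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        atom.b_iso = float(model.plddt[i])
        atom.occ = 1.0
        res.add_atom(atom)
        ch.add_residue(res)
    gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# PAE JSON (AFDB payload dialect)


def read_pae_json(path) -> np.ndarray:
    """Read an AFDB-style PAE JSON payload into an n x n float matrix.

    Accepts either the AFDB list-of-objects payload with a
    "predicted_aligned_error" key or a bare square matrix. Asymmetry is
    preserved; symmetrization happens only in feature computation.
    """
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, list) and payload and isinstance(payload[0], dict):
        payload = payload[0].get("predicted_aligned_error")
    if payload is None or not isinstance(payload, list):
        raise ValueError("malformed PAE")
    n = len(payload)
    if n == 0 or any(not isinstance(row, list) or len(row) != n for row in payload):
        raise ValueError("malformed PAE")
    mat = np.asarray(payload, dtype=float)
    if np.any(mat < 0) or not np.all(np.isfinite(mat)):
        raise ValueError("malformed PAE")
    return mat


def write_pae_json(pae: np.ndarray, path, max_pae: float = 31.75) -> None:
    pae = np.asarray(pae, dtype=float)
    payload = [{
        "predicted_aligned_error": [[round(float(v), 2) for v in row] for row in pae],
        "max_predicted_aligned_error": max_pae,
    }]
    with open(path, "w") as fh:
        json.dump(payload, fh)


# ---------------------------------------------------------------------------
# TSV tables


def _fmt(v, nd: int = 4) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return ""
    if isinstance(v, float):
        return f"{v:.{nd}f}"
    return str(v)


def write_domain_table(records: List[ClassifiedRegion], path) -> None:
    """Write classified regions as TSV, sorted by (model_id, range start)."""
    rows = sorted(records, key=lambda r: (r.model_id, r.range.start))
    with open(path, "w") as fh:
        fh.write("model_id\trange\tcategory\th_group\tscore\tmean_plddt\tn_sse\n")
        for r in rows:
            fh.write(
                "\t".join([
                    r.model_id,
                    format_range(r.range),
                    r.label.value,
                    r.h_group or "",
                    _fmt(r.score),
                    _fmt(float(r.mean_plddt)),
                    str(int(r.n_sse)),
                ]) + "\n"
            )


def read_domain_table(path) -> List[ClassifiedRegion]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            ClassifiedRegion(
                model_id=row["model_id"],
                range=parse_range(row["range"]),
                label=RegionLabel(row["category"]),
                h_group=row["h_group"] or None,
                score=float(row["score"]) if row["score"] else None,
                mean_plddt=float(row["mean_plddt"]),
                n_sse=int(row["n_sse"]),
            )
        )
    return out


def write_hits(hits: List[HomologyHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("source\tquery_id\tquery_range\tref_domain_id\tref_group_id"
                 "\tconfidence\tref_coverage\n")
        for h in hits:
            fh.write("\t".join([
                h.source, h.query_id, format_range(h.query_range),
                h.ref_domain_id, h.ref_group_id,
                _fmt(float(h.confidence)), _fmt(float(h.ref_coverage)),
            ]) + "\n")


def read_hits(path) -> List[HomologyHit]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        HomologyHit(
            source=row["source"],
            query_id=row["query_id"],
            query_range=parse_range(row["query_range"]),
            ref_domain_id=row["ref_domain_id"],
            ref_group_id=row["ref_group_id"],
            confidence=float(row["confidence"]),
            ref_coverage=float(row["ref_coverage"]),
        )
        for _, row in df.iterrows()
    ]


def write_catalog(catalog: ReferenceCatalog, path) -> None:
    with open(path, "w") as fh:
        fh.write("domain_id\tf_group\th_group\tx_group\tarchitecture\tclass5"
                 "\tlength\tkingdom\n")
        for d in catalog.domains:
            fh.write("\t".join([
                d.domain_id, d.f_group, d.h_group, d.x_group, d.architecture,
                d.class5, str(d.length), d.kingdom,
            ]) + "\n")


def read_catalog(path) -> ReferenceCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return ReferenceCatalog([
        ReferenceDomain(
            domain_id=row["domain_id"], f_group=row["f_group"],
            h_group=row["h_group"], x_group=row["x_group"],
            architecture=row["architecture"], class5=row["class5"],
            length=int(row["length"]), kingdom=row["kingdom"],
        )
        for _, row in df.iterrows()
    ])


def write_truth(truths, path) -> None:
    """Per-residue ground-truth labels as TSV (model_id, position, label)."""
    with open(path, "w") as fh:
        fh.write("model_id\tposition\tlabel\n")
        for t in truths:
            for i, lab in enumerate(t.labels, start=1):
                fh.write(f"{t.model_id}\t{i}\t{lab.value}\n")


def read_annotations(path) -> List[AnnotationInterval]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        AnnotationInterval(
            protein_id=row["protein_id"], entry_id=row["entry_id"],
            source_db=row["source_db"], start=int(row["start"]), end=int(row["end"]),
        )
        for _, row in df.iterrows()
    ]


def write_annotations(annotations: List[AnnotationInterval], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tentry_id\tsource_db\tstart\tend\n")
        for a in annotations:
            fh.write(f"{a.protein_id}\t{a.entry_id}\t{a.source_db}\t{a.start}\t{a.end}\n")


# ---------------------------------------------------------------------------
# FASTA (via Biopython)


def read_fasta(path):
    """Read sequences as a list of (id, sequence) tuples."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path) -> None:
    """Write (id, sequence) tuples or SeqRecord dataclasses as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord as BioSeqRecord
    from Bio import SeqIO

    out = []
    for rec in records:
        if hasattr(rec, "sequence"):
            out.append(BioSeqRecord(Seq(rec.sequence), id=rec.id, description=""))
        else:
            rid, seq = rec
            out.append(BioSeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(out, str(path), "fasta")
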