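"""Template database of protein-peptide complex structures.

Each entry stores the receptor structure, the bound peptide (structure and
one-letter sequence) and the precomputed residue contact map. The database
serializes to a single JSON archive (coordinates rounded to 1e-3 A) and
reloads bit-identically, so a build is reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import config
from .contacts import Contact, ContactClass, ContactMap, detect_contacts
from .structure_io import Residue, Structure, parse_structure

logger = logging.getLogger(__name__)

MIN_PEPTIDE_LEN = 2
MAX_PEPTIDE_LEN = config.MAX_PEPTIDE_LENGTH


@dataclass
class ComplexRecord:
    """One protein-peptide complex: the template unit of the database."""

    id: str
    protein: Structure
    peptide: Structure
    peptide_sequence: str
    contact_map: ContactMap
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        plen = self.peptide.n_residues
        if not (MIN_PEPTIDE_LEN <= plen <= MAX_PEPTIDE_LEN):
            raise ValueError(f"peptide length {plen} outside "
                             f"[{MIN_PEPTIDE_LEN}, {MAX_PEPTIDE_LEN}]")
        if self.protein.n_residues <= plen:
            raise ValueError("protein must be longer than the peptide")


@dataclass
class TemplateDB:
    records: list[ComplexRecord]

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate template ids")
        self.index = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, template_id: str) -> ComplexRecord:
        return self.index[template_id]


def split_complex(s: Structure, peptide_chain_hint: str | None = None,
                  ) -> tuple[Structure, Structure]:
    """Split a complex into (protein, peptide).

    The peptide is the hinted chain if given, otherwise the shortest chain
    with 2-30 residues; the remaining chains form the receptor.
    """
    if len(s.chains) < 2:
        raise ValueError("complex must have at least 2 chains")
    if peptide_chain_hint is not None:
        pep_idx = [i for i, (cid, _) in enumerate(s.chains)
                   if cid == peptide_chain_hint]
        if not pep_idx:
            raise ValueError(f"hinted chain {peptide_chain_hint!r} not found")
        i = pep_idx[0]
    else:
        candidates = [(len(res), i) for i, (_, res) in enumerate(s.chains)
                      if MIN_PEPTIDE_LEN <= len(res) <= MAX_PEPTIDE_LEN]
        if not candidates:
            raise ValueError("no peptide chain (no chain of 2-30 residues)")
        _, i = min(candidates)
    pep_cid, pep_res = s.chains[i]
    protein = Structure([c for k, c in enumerate(s.chains) if k != i],
                        source_id=s.source_id)
    peptide = Structure([(pep_cid, pep_res)], source_id=s.source_id)
    if protein.n_residues == 0:
        raise ValueError("no receptor chains left after peptide split")
    return protein, peptide


def record_from_structure(s: Structure, record_id: str,
                          peptide_chain_hint: str | None = None,
                          metadata: dict | None = None) -> ComplexRecord:
    protein, peptide = split_complex(s, peptide_chain_hint)
    cm = detect_contacts(protein, peptide)
    if len(cm) == 0:
        raise ValueError("complex has no protein-peptide contacts")
    return ComplexRecord(record_id, protein, peptide, peptide.sequence(), cm,
                         metadata or {})


def build_database(pdb_files: list[str | Path],
                   peptide_chain_hint: str | None = None,
                   release_dates: dict[str, str] | None = None) -> TemplateDB:
    """Parse, split and contact-map each complex file into a TemplateDB.

    Files without a peptide chain or without any protein-peptide contact
    are skipped with a warning. ``release_dates`` (id -> ISO date) feeds the
    leave-future-out filtering hook used for benchmark hygiene.
    """
    if not pdb_files:
        raise ValueError("no input files")
    records = []
    for path in pdb_files:
        path = Path(path)
        rid = path.stem
        try:
            s = parse_structure(path.read_text(), source_id=rid)
            meta = {"source_file": str(path)}
            if release_dates and rid in release_dates:
                meta["release_date"] = release_dates[rid]
            records.append(record_from_structure(s, rid, peptide_chain_hint, meta))
        except (ValueError, OSError) as exc:
            logger.warning("skipping %s: %s", path, exc)
    if not records:
        raise ValueError("all input files were rejected")
    return TemplateDB(records)


def filter_by_date(db: TemplateDB, cutoff_date: str) -> TemplateDB:
    """Keep records released strictly before ``cutoff_date`` (ISO strings).

    Records without release metadata are kept.
    """
    kept = [r for r in db.records
            if r.metadata.get("release_date", "") < cutoff_date
            or "release_date" not in r.metadata]
    return TemplateDB(kept)


# ---------------------------------------------------------------------------
# Serialization

def _structure_to_dict(s: Structure) -> dict:
    return {
        "source_id": s.source_id,
        "chains": [
            {
                "chain_id": cid,
                "residues": [
                    {
                        "name": r.name_3letter,
                        "number": r.author_number,
                        "ins_code": r.ins_code,
                        "atoms": r.atom_names,
                        "coords": [[round(float(x), 3) for x in row]
                                   for row in r.coords],
                    }
                    for r in residues
                ],
            }
            for cid, residues in s.chains
        ],
    }


def _structure_from_dict(d: dict) -> Structure:
    from .structure_io import STANDARD_AA_3TO1
    chains = []
    for ch in d["chains"]:
        residues = [
            Residue(r["name"], STANDARD_AA_3TO1.get(r["name"], "X"),
                    ch["chain_id"], r["number"], r["ins_code"],
                    list(r["atoms"]), np.array(r["coords"], dtype=float))
            for r in ch["residues"]
        ]
        chains.append((ch["chain_id"], residues))
    return Structure(chains, source_id=d.get("source_id", ""))


def save_database(db: TemplateDB, path: str | Path) -> None:
    payload = {
        "format": "pepdock-template-db",
        "version": 1,
        "records": [
            {
                "id": r.id,
                "protein": _structure_to_dict(r.protein),
                "peptide": _structure_to_dict(r.peptide),
                "peptide_sequence": r.peptide_sequence,
                "contacts": [
                    [c.protein_index, c.peptide_index, c.contact_class.value,
                     round(c.distance, 6)]
                    for c in r.contact_map
                ],
                "metadata": r.metadata,
            }
            for r in db.records
        ],
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_database(path: str | Path) -> TemplateDB:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "pepdock-template-db":
        raise ValueError("not a pepdock template database archive")
    records = []
    for rd in payload["records"]:
        cm = ContactMap([Contact(int(i), int(j), ContactClass(cls), float(d))
                         for i, j, cls, d in rd["contacts"]])
        records.append(ComplexRecord(
            rd["id"], _structure_from_dict(rd["protein"]),
            _structure_from_dict(rd["peptide"]), rd["peptide_sequence"],
            cm, rd.get("metadata", {})))
    return TemplateDB(records)
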