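"""PDB / FASTA input and output and the internal structure model.

Structures are normalized on parsing: heavy atoms only (hydrogens and
deuteriums dropped), waters and non-amino-acid heteroresidues removed,
alternate locations resolved to the highest-occupancy conformer, and only
the first MODEL of multi-model files read. Nonstandard residues with a
standard parent (MSE, SEP, PTR, ...) are mapped to the parent amino acid;
others are dropped with a warning.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from Bio import SeqIO

logger = logging.getLogger(__name__)

STANDARD_AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in STANDARD_AA_3TO1.items()}
AA_1TO3["X"] = "UNK"

# Nonstandard residues with a conventional parent amino acid.
NONSTANDARD_PARENT = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
    "MLY": "LYS", "M3L": "LYS", "KCX": "LYS", "CME": "CYS",
}
WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

VALID_AA_LETTERS = set(STANDARD_AA_3TO1.values()) | {"X"}


class PDBParseError(ValueError):
    """Raised when a PDB text cannot be interpreted."""


class FastaError(ValueError):
    """Raised for malformed peptide FASTA input."""


@dataclass
class Residue:
    """One amino-acid residue: heavy atoms with unique names.

    ``author_number``/``ins_code`` keep the numbering of the source file so
    reports can refer to residues the way the depositor numbered them.
    """

    name_3letter: str
    aa_1letter: str
    chain_id: str
    author_number: int
    ins_code: str = ""
    atom_names: list[str] = field(default_factory=list)
    coords: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.author_number, self.ins_code)

    def atom_coord(self, name: str) -> np.ndarray | None:
        try:
            return self.coords[self.atom_names.index(name)]
        except ValueError:
            return None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Residue":
        return Residue(
            self.name_3letter, self.aa_1letter, self.chain_id,
            self.author_number, self.ins_code, list(self.atom_names),
            self.coords @ rotation.T + translation,
        )


@dataclass
class Structure:
    """Ordered chains of residues; the in-memory form of a PDB file."""

    chains: list[tuple[str, list[Residue]]]
    source_id: str = ""

    @property
    def residues(self) -> list[Residue]:
        return [r for _, res in self.chains for r in res]

    @property
    def n_residues(self) -> int:
        return sum(len(res) for _, res in self.chains)

    def sequence(self) -> str:
        return "".join(r.aa_1letter for r in self.residues)

    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def ca_coords(self) -> np.ndarray:
        """CA coordinates of residues having a CA atom (one row per residue)."""
        rows = [r.atom_coord("CA") for r in self.residues]
        return np.array([c for c in rows if c is not None], dtype=float)

    def all_coords(self) -> np.ndarray:
        return np.concatenate([r.coords for r in self.residues])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        return Structure(
            [(cid, [r.transformed(rotation, translation) for r in res])
             for cid, res in self.chains],
            self.source_id,
        )


@dataclass
class PeptideSequence:
    sequence: str
    id: str = "peptide"

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise FastaError("empty peptide sequence")
        bad = set(self.sequence) - VALID_AA_LETTERS
        if bad:
            raise FastaError(f"illegal peptide letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


def _check_coordinate_fields(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line) >= 54:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"malformed coordinate field on line {lineno}: {line.rstrip()!r}"
                    )


def parse_structure(pdb_text: str, source_id: str = "") -> Structure:
    """Parse PDB text into a normalized :class:`Structure`.

    Only the first MODEL is read; hydrogens, waters and unmappable
    heteroresidues are dropped; alternate locations are resolved to the
    highest-occupancy conformer (ties resolved by file order, so altloc 'A'
    wins in conventionally ordered files).
    """
    if not any(line.startswith("ATOM") for line in pdb_text.splitlines()):
        raise PDBParseError("no ATOM records found")
    _check_coordinate_fields(pdb_text)
    try:
        pdb_file = pdbio.PDBFile.read(io.StringIO(pdb_text))
        arr = pdb_file.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # pragma: no cover - defensive
        raise PDBParseError(f"PDB parsing failed: {exc}") from exc

    keep = (arr.element != "H") & (arr.element != "D")
    arr = arr[keep]

    chains: list[tuple[str, list[Residue]]] = []
    current: dict[str, list[Residue]] = {}
    order: list[str] = []
    for start in struc.get_residue_starts(arr):
        res_mask = (
            (arr.chain_id == arr.chain_id[start])
            & (arr.res_id == arr.res_id[start])
            & (arr.ins_code == arr.ins_code[start])
            & (arr.res_name == arr.res_name[start])
        )
        sub = arr[res_mask]
        name3 = str(sub.res_name[0])
        if name3 in WATER_NAMES:
            continue
        mapped = NONSTANDARD_PARENT.get(name3, name3)
        if mapped not in STANDARD_AA_3TO1:
            logger.warning("dropping non-amino-acid residue %s %s%s",
                           name3, sub.chain_id[0], sub.res_id[0])
            continue
        if mapped != name3:
            logger.warning("mapping nonstandard residue %s -> %s", name3, mapped)
        # Deduplicate atom names (altloc leftovers); keep first occurrence.
        names, coords, seen = [], [], set()
        for i in range(len(sub)):
            nm = str(sub.atom_name[i])
            if nm in seen:
                continue
            seen.add(nm)
            names.append(nm)
            coords.append(sub.coord[i])
        cid = str(sub.chain_id[0])
        residue = Residue(mapped, STANDARD_AA_3TO1[mapped], cid,
                          int(sub.res_id[0]), str(sub.ins_code[0]),
                          names, np.array(coords))
        if cid not in current:
            current[cid] = []
            order.append(cid)
        current[cid].append(residue)

    chains = [(cid, current[cid]) for cid in order]
    if not chains:
        raise PDBParseError("no amino-acid residues after filtering")
    return Structure(chains, source_id=source_id)


def parse_fasta(fasta_text: str) -> PeptideSequence:
    """Parse a single-record peptide FASTA; uppercases and strips whitespace."""
    if not fasta_text.lstrip().startswith(">"):
        # Accept bare sequence text without a header.
        seq = "".join(fasta_text.split()).upper()
        if not seq:
            raise FastaError("no FASTA record found")
        return PeptideSequence(seq, "peptide")
    records = list(SeqIO.parse(io.StringIO(fasta_text), "fasta"))
    if len(records) == 0:
        raise FastaError("no FASTA record found")
    if len(records) > 1:
        raise FastaError(f"multiple records ({len(records)}) in peptide FASTA")
    rec = records[0]
    seq = "".join(str(rec.seq).split()).upper()
    return PeptideSequence(seq, rec.id or "peptide")


def structure_to_atom_array(s: Structure) -> struc.AtomArray:
    n = sum(len(r.atom_names) for r in s.residues)
    arr = struc.AtomArray(n)
    i = 0
    for cid, residues in s.chains:
        for r in residues:
            for name, xyz in zip(r.atom_names, r.coords):
                arr.chain_id[i] = cid
                arr.res_id[i] = r.author_number
                arr.ins_code[i] = r.ins_code
                arr.res_name[i] = r.name_3letter
                arr.atom_name[i] = name
                arr.element[i] = name[0] if name[0] in "CNOSH" else name[:2]
                arr.coord[i] = xyz
                arr.hetero[i] = False
                i += 1
    return arr


def write_structure(s: Structure, remarks: list[str] | None = None) -> str:
    """Serialize a Structure to PDB text, with optional REMARK lines."""
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(structure_to_atom_array(s))
    body = "\n".join(pdb_file.lines) + "\n"
    header = ""
    if remarks:
        header = "".join(f"REMARK 220 {r}\n" for r in remarks)
    return header + body


def _unused_chain_id(used: set[str]) -> str:
    for cid in "PQRSTUVWXYZABCDEFGHIJKLMNO0123456789":
        if cid not in used:
            return cid
    raise ValueError("no free chain id")


def write_complex(model, remarks: list[str] | None = None) -> str:
    """Write a docked model (protein + peptide) as PDB text.

    Provenance (template id and scores) goes into REMARK 220 records. If the
    peptide chain id collides with a protein chain id the peptide chain is
    renamed to an unused id (logged).
    """
    protein: Structure = model.protein
    peptide: Structure = model.peptide
    used = set(protein.chain_ids())
    pep_chains = []
    for cid, residues in peptide.chains:
        if cid in used:
            new_cid = _unused_chain_id(used)
            logger.warning("peptide chain id %r collides with protein; renamed to %r",
                           cid, new_cid)
            residues = [Residue(r.name_3letter, r.aa_1letter, new_cid,
                                r.author_number, r.ins_code,
                                list(r.atom_names), r.coords.copy())
                        for r in residues]
            cid = new_cid
        used.add(cid)
        pep_chains.append((cid, residues))
    combined = Structure(protein.chains + pep_chains, source_id=protein.source_id)
    all_remarks = [f"TEMPLATE {model.template_id}"]
    if getattr(model, "energy_components", None) is not None:
        clash, restraint, total = model.energy_components
        all_remarks.append(
            f"ENERGY CLASH {clash:.4f} RESTRAINT {restraint:.4f} TOTAL {total:.4f}")
    if remarks:
        all_remarks.extend(remarks)
    return write_structure(combined, all_remarks)
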