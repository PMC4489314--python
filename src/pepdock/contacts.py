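"""Residue-residue contact detection and binding-site utilities.

A protein-peptide residue pair is in contact when at least one heavy-atom
pair is within a class-dependent cutoff: 5.0 A for hydrophobic pairs,
6.0 A for ionic (acidic-basic) pairs, and 4.5 A for all other pairs. The
hydrophobic/ionic criterion follows the PepBind convention; the generic
class lets polar pairs contribute interaction pairs and restraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial.distance import cdist

from . import config
from .structure_io import Residue, Structure


class ResidueClass(str, Enum):
    HYDROPHOBIC = "hydrophobic"
    ACIDIC = "acidic"
    BASIC = "basic"
    OTHER = "other"


class ContactClass(str, Enum):
    HYDROPHOBIC = "hydrophobic"
    IONIC = "ionic"
    GENERIC = "generic"


@dataclass(frozen=True)
class Contact:
    protein_index: int
    peptide_index: int
    contact_class: ContactClass
    distance: float


@dataclass
class ContactMap:
    """Set of protein-peptide residue contacts, indexed by residue position.

    Indices are 0-based positions into the flattened residue lists of the
    protein and peptide structures the map was computed from.
    """

    contacts: list[Contact] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self):
        return iter(self.contacts)

    def pairs(self) -> set[tuple[int, int]]:
        return {(c.protein_index, c.peptide_index) for c in self.contacts}

    def to_tsv(self, protein: Structure | None = None) -> str:
        lines = ["protein_chain\tprotein_resnum\tpeptide_resnum\tclass\tdistance"]
        residues = protein.residues if protein is not None else None
        for c in sorted(self.contacts, key=lambda c: (c.protein_index, c.peptide_index)):
            if residues is not None:
                r = residues[c.protein_index]
                chain, num = r.chain_id, r.author_number
            else:
                chain, num = "", c.protein_index
            lines.append(f"{chain}\t{num}\t{c.peptide_index}\t"
                         f"{c.contact_class.value}\t{c.distance:.3f}")
        return "\n".join(lines) + "\n"


def residue_class(aa: str) -> ResidueClass:
    """Classify a one-letter amino-acid code; 'X' and unknowns are OTHER."""
    if aa in config.HYDROPHOBIC_SET:
        return ResidueClass.HYDROPHOBIC
    if aa in config.ACIDIC_SET:
        return ResidueClass.ACIDIC
    if aa in config.BASIC_SET:
        return ResidueClass.BASIC
    return ResidueClass.OTHER


def min_heavy_atom_distance(res_a: Residue, res_b: Residue) -> float:
    """Minimum Euclidean distance over all heavy-atom pairs of two residues."""
    if len(res_a.coords) == 0 or len(res_b.coords) == 0:
        raise ValueError("residue has no atoms")
    return float(cdist(res_a.coords, res_b.coords).min())


def _classify_pair(class_p: ResidueClass, class_q: ResidueClass,
                   dist: float, cfg: config.ContactConfig) -> ContactClass | None:
    # Priority: hydrophobic > ionic > generic; classes mutually exclusive.
    if (class_p is ResidueClass.HYDROPHOBIC and class_q is ResidueClass.HYDROPHOBIC
            and dist <= cfg.hydrophobic_cutoff):
        return ContactClass.HYDROPHOBIC
    ionic = ({class_p, class_q} == {ResidueClass.ACIDIC, ResidueClass.BASIC})
    if ionic and dist <= cfg.ionic_cutoff:
        return ContactClass.IONIC
    if dist <= cfg.generic_cutoff:
        return ContactClass.GENERIC
    return None


def detect_contacts(protein: Structure, peptide: Structure,
                    cfg: config.ContactConfig | None = None) -> ContactMap:
    """All protein-peptide residue contacts under the class-dependent cutoffs."""
    cfg = cfg or config.ContactConfig()
    prot_res = protein.residues
    pep_res = peptide.residues
    if not prot_res or not pep_res:
        return ContactMap([])

    prot_coords = np.concatenate([r.coords for r in prot_res])
    pep_coords = np.concatenate([r.coords for r in pep_res])
    prot_owner = np.repeat(np.arange(len(prot_res)),
                           [len(r.coords) for r in prot_res])
    pep_owner = np.repeat(np.arange(len(pep_res)),
                          [len(r.coords) for r in pep_res])

    max_cut = max(cfg.hydrophobic_cutoff, cfg.ionic_cutoff, cfg.generic_cutoff)
    dmat = cdist(prot_coords, pep_coords)
    # Residue-pair minimum distance via grouped reduction.
    close = np.argwhere(dmat <= max_cut)
    min_dist: dict[tuple[int, int], float] = {}
    for ai, bi in close:
        key = (int(prot_owner[ai]), int(pep_owner[bi]))
        d = dmat[ai, bi]
        if d < min_dist.get(key, np.inf):
            min_dist[key] = float(d)

    prot_cls = [residue_class(r.aa_1letter) for r in prot_res]
    pep_cls = [residue_class(r.aa_1letter) for r in pep_res]
    contacts = []
    for (i, j), d in min_dist.items():
        cc = _classify_pair(prot_cls[i], pep_cls[j], d, cfg)
        if cc is not None:
            contacts.append(Contact(i, j, cc, d))
    contacts.sort(key=lambda c: (c.protein_index, c.peptide_index))
    return ContactMap(contacts)


def binding_site(cm: ContactMap) -> set[int]:
    """Protein residue indices appearing in at least one contact pair."""
    return {c.protein_index for c in cm.contacts}


def binding_site_recovery(predicted: set[int], native: set[int]) -> float:
    """Fraction of native binding-site residues found in the prediction."""
    if not native:
        raise ValueError("native binding site is empty")
    return len(predicted & native) / len(native)
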