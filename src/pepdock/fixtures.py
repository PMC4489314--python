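"""Deterministic synthetic protein-peptide complexes for tests and demos.

Each fixture is a receptor chain plus a short extended peptide placed so
that a requested number of hydrophobic, ionic and generic residue
contacts — and no others — are formed. The receptor combines a scaffold
(two antiparallel helices for ``helix_groove``, a three-strand sheet for
``strand_pair``, a seeded random coil for ``decoy_fold``) kept clear of
the peptide, with one pocket residue per requested contact placed under
the corresponding peptide position at a class-appropriate distance
(hydrophobic 4.7 A, ionic 5.5 A, generic 4.2 A). Contact positions are
spaced three peptide residues apart so neighbouring pairs stay outside
every cutoff; the finished complex is verified against the contact
detector and construction fails loudly if the requested map is not
realized exactly.

These fixtures emulate the residue-contact geometry of real complexes,
not their packing, secondary-structure context or side-chain detail.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .contacts import ContactClass, detect_contacts, min_heavy_atom_distance
from .geometry import EXTENDED_PHI_PSI, HELIX_PHI_PSI, build_chain, rotation_about_axis
from .structure_io import Residue, Structure
from .template_db import ComplexRecord

FIXTURE_KINDS = ("helix_groove", "strand_pair", "decoy_fold")

_CLASS_TARGET_DIST = {
    ContactClass.HYDROPHOBIC: 4.7,
    ContactClass.IONIC: 5.5,
    ContactClass.GENERIC: 4.2,
}
_PEPTIDE_LETTERS = {
    ContactClass.HYDROPHOBIC: "LIVF",
    ContactClass.IONIC: "KR",
    ContactClass.GENERIC: "ST",
}
_POCKET_LETTERS = {
    ContactClass.HYDROPHOBIC: "LIVM",
    ContactClass.IONIC: "DE",
    ContactClass.GENERIC: "SN",
}
_NEUTRAL_LETTERS = "GSTNQ"  # never hydrophobic or charged
_SPACING = 3  # peptide positions between consecutive engineered contacts


class FixtureError(ValueError):
    """Raised when a requested contact layout cannot be realized."""


def _pocket_direction(peptide: Structure, j: int) -> np.ndarray:
    """Unit vector along which peptide residue j's side chain points,
    orthogonalized against the local chain tangent."""
    residues = peptide.residues
    r = residues[j]
    cb, ca = r.atom_coord("CB"), r.atom_coord("CA")
    d = cb - ca
    t = (residues[min(j + 1, len(residues) - 1)].atom_coord("CA")
         - residues[max(j - 1, 0)].atom_coord("CA"))
    t = t / np.linalg.norm(t)
    d = d - (d @ t) * t
    return d / np.linalg.norm(d)


def _place_pocket_residue(letter: str, peptide: Structure, j: int,
                          target_dist: float) -> Residue:
    """Place one receptor residue off peptide residue j, side chains facing,
    so that the pair's minimum heavy-atom distance equals ``target_dist``.

    The pocket residue approaches along the direction the peptide side
    chain points, which keeps it clear of the flanking peptide residues.
    """
    from scipy.spatial.transform import Rotation

    d = _pocket_direction(peptide, j)
    seg = build_chain(letter, EXTENDED_PHI_PSI, chain_id="A")
    res = seg.residues[0]
    cb = res.atom_coord("CB")
    body = np.mean([res.atom_coord(nm) for nm in ("N", "CA", "C", "O")], axis=0)
    rot, _ = Rotation.align_vectors((body - cb)[None, :], d[None, :])
    coords = (res.coords - cb) @ rot.as_matrix().T  # CB at origin, body along +d
    anchor = peptide.residues[j].atom_coord("CB")
    pep_res = peptide.residues[j]

    def gap(s: float) -> float:
        moved = Residue(res.name_3letter, res.aa_1letter, "A", 1, "",
                        list(res.atom_names), coords + anchor + s * d)
        return min_heavy_atom_distance(moved, pep_res) - target_dist

    s = brentq(gap, 0.0, 25.0, xtol=1e-9)
    return Residue(res.name_3letter, res.aa_1letter, "A", 1, "",
                   list(res.atom_names), coords + anchor + s * d)


def _scaffold(kind: str, rng: np.random.Generator) -> list[Residue]:
    letters = "ACDEFGHIKLMNPQRSTVWY"

    def random_seq(n):
        return "".join(rng.choice(list(letters)) for _ in range(n))

    chains = []
    if kind == "helix_groove":
        # Seed-dependent lengths and placement so distinct seeds give
        # geometrically distinct receptors, not just relettered copies.
        l1, l2 = int(rng.integers(12, 17)), int(rng.integers(12, 17))
        tilt = float(rng.uniform(-0.25, 0.25))
        h1 = build_chain(random_seq(l1), HELIX_PHI_PSI)
        h2 = build_chain(random_seq(l2), HELIX_PHI_PSI,
                         rotation=rotation_about_axis([0, 0, 1], np.pi + tilt),
                         translation=np.array([22.0 + rng.uniform(-2, 2),
                                               rng.uniform(-2, 2),
                                               9.0 + rng.uniform(-2, 2)]))
        chains = [h1, h2]
    elif kind == "strand_pair":
        for k in range(3):
            chains.append(build_chain(
                random_seq(int(rng.integers(10, 14))), EXTENDED_PHI_PSI,
                translation=np.array([rng.uniform(-1.5, 1.5), 0.0,
                                      4.8 * k + rng.uniform(-0.4, 0.4)])))
    elif kind == "decoy_fold":
        phi_psi = [(float(rng.uniform(-150, -60)), float(rng.uniform(-60, 160)))
                   for _ in range(28)]
        chains = [build_chain(random_seq(28), phi_psi)]
    else:
        raise FixtureError(f"unknown fixture kind {kind!r}")
    return [r for c in chains for r in c.residues]


def generate_fixture(kind: str, seed: int = 0, peptide_len: int = 12,
                     n_hydrophobic: int = 2, n_ionic: int = 1,
                     n_generic: int = 1,
                     record_id: str | None = None) -> ComplexRecord:
    """Build a synthetic complex with an exactly known contact map."""
    rng = np.random.default_rng(seed)
    classes = ([ContactClass.HYDROPHOBIC] * n_hydrophobic
               + [ContactClass.IONIC] * n_ionic
               + [ContactClass.GENERIC] * n_generic)
    if not classes:
        raise FixtureError("at least one contact must be requested")
    positions = [1 + _SPACING * k for k in range(len(classes))]
    if positions[-1] > peptide_len - 2:
        raise FixtureError(
            f"{len(classes)} contacts need a peptide of >= "
            f"{positions[-1] + 2} residues (got {peptide_len})")

    # Peptide sequence: engineered letters at contact positions, neutral
    # (non-hydrophobic, uncharged) letters elsewhere.
    pep_letters = [str(rng.choice(list(_NEUTRAL_LETTERS)))
                   for _ in range(peptide_len)]
    pocket_letters = []
    for pos, cls in zip(positions, classes):
        pep_letters[pos] = str(rng.choice(list(_PEPTIDE_LETTERS[cls])))
        pocket_letters.append(str(rng.choice(list(_POCKET_LETTERS[cls]))))
    peptide = build_chain("".join(pep_letters), EXTENDED_PHI_PSI, chain_id="B")
    pep_res = peptide.residues

    # Receptor: scaffold placed clear of the peptide, then pocket residues.
    scaffold = _scaffold(kind, rng)
    pep_all = np.concatenate([r.coords for r in pep_res])
    shift = 12.0
    while True:
        moved = [Residue(r.name_3letter, r.aa_1letter, "A", r.author_number,
                         r.ins_code, list(r.atom_names),
                         r.coords + np.array([0.0, shift, 0.0]))
                 for r in scaffold]
        min_d = min(np.linalg.norm(
            m.coords[:, None, :] - pep_all[None, :, :], axis=2).min()
            for m in moved)
        if min_d > 7.0:
            scaffold = moved
            break
        shift += 2.0

    pocket = []
    for (pos, cls), letter in zip(zip(positions, classes), pocket_letters):
        pocket.append(_place_pocket_residue(letter, peptide, pos,
                                            _CLASS_TARGET_DIST[cls]))

    receptor_res = []
    for num, r in enumerate(scaffold + pocket, start=1):
        receptor_res.append(Residue(r.name_3letter, r.aa_1letter, "A", num, "",
                                    list(r.atom_names), r.coords))
    receptor = Structure([("A", receptor_res)], source_id=kind)

    cm = detect_contacts(receptor, peptide)
    expected = {
        (len(scaffold) + k, pos, cls)
        for k, (pos, cls) in enumerate(zip(positions, classes))
    }
    got = {(c.protein_index, c.peptide_index, c.contact_class) for c in cm}
    if got != expected:
        raise FixtureError(
            f"contact layout not realized: expected {sorted(expected)}, "
            f"got {sorted(got)}")

    rid = record_id or f"{kind}_{seed}"
    return ComplexRecord(rid, receptor, peptide, peptide.sequence(), cm,
                         {"kind": kind, "seed": seed, "synthetic": True})


def fixture_pdb_text(rec: ComplexRecord) -> str:
    """The fixture complex as PDB text (receptor + peptide chains)."""
    from .structure_io import write_structure
    combined = Structure(rec.protein.chains + rec.peptide.chains,
                         source_id=rec.id)
    return write_structure(combined, remarks=[f"SYNTHETIC FIXTURE {rec.id}"])
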