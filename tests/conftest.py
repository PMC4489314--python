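"""Shared fixtures: synthetic complexes and random-structure helpers."""

from __future__ import annotations

import numpy as np
import pytest

from pepdock.fixtures import generate_fixture
from pepdock.similarity import PeptideAlignment, ScoredTemplate, blosum62
from pepdock.struct_align import StructAlignment
from pepdock.structure_io import AA_1TO3, PeptideSequence, Residue, Structure

AAS = "ARNDCQEGHILKMFPSTWYV"


def random_residue(rng: np.random.Generator, chain_id: str = "A",
                   number: int = 1, n_atoms: int = 4,
                   center: np.ndarray | None = None,
                   spread: float = 1.5) -> Residue:
    aa = str(rng.choice(list(AAS)))
    if center is None:
        center = rng.uniform(-10, 10, 3)
    coords = center + rng.normal(0, spread, (n_atoms, 3))
    names = ["CA"] + [f"C{i}" for i in range(1, n_atoms)]
    return Residue(AA_1TO3[aa], aa, chain_id, number, "", names, coords)


def random_structure(rng: np.random.Generator, n_res: int, chain_id: str = "A",
                     box: float = 15.0) -> Structure:
    residues = [
        random_residue(rng, chain_id, i + 1,
                       n_atoms=int(rng.integers(1, 6)),
                       center=rng.uniform(-box, box, 3))
        for i in range(n_res)
    ]
    return Structure([(chain_id, residues)])


def random_rigid_transform(rng: np.random.Generator):
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t


def identity_scored_template(record, s_inter: float = 10.0) -> ScoredTemplate:
    """ScoredTemplate for a target identical to the template (identity maps)."""
    n_prot = record.protein.n_residues
    n_pep = len(record.peptide_sequence)
    sa = StructAlignment(pairs=[(i, i) for i in range(n_prot)],
                         rotation=np.eye(3), translation=np.zeros(3),
                         tm_score_target=1.0)
    pa = PeptideAlignment(offset=0, pairs=[(j, j) for j in range(n_pep)],
                          score=0.0)
    B = blosum62()
    pair_scores = []
    for c in record.contact_map:
        i, j = c.protein_index, c.peptide_index
        ai = record.protein.residues[i].aa_1letter
        aj = record.peptide_sequence[j]
        pair_scores.append((i, j, max(B(ai, ai) + B(aj, aj), 2 * B(ai, aj))))
    s = float(sum(p[2] for p in pair_scores))
    return ScoredTemplate(
        template_id=record.id, tm_score=1.0, s_inter=s, z_tm=0.0, z_inter=0.0,
        s_complex=0.0, n_template_contacts=len(record.contact_map),
        pair_scores=pair_scores, struct_alignment=sa, peptide_alignment=pa)


@pytest.fixture(scope="session")
def helix_record():
    return generate_fixture("helix_groove", seed=0)


@pytest.fixture(scope="session")
def strand_record():
    return generate_fixture("strand_pair", seed=7)


@pytest.fixture(scope="session")
def decoy_records():
    return [generate_fixture("decoy_fold", seed=100 + i, record_id=f"decoy_{i}")
            for i in range(4)]


@pytest.fixture
def helix_peptide(helix_record):
    return PeptideSequence(helix_record.peptide_sequence)
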