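"""Model building, restraints, energy evaluation and refinement."""

import numpy as np
import pytest

from pepdock.config import ModelingConfig, RefineConfig
from pepdock.modeling import (DockModel, Restraint, build_by_superimposition,
                              derive_restraints, energy, generate_models,
                              refine)
from pepdock.structure_io import PeptideSequence
from pepdock.template_db import TemplateDB

from conftest import identity_scored_template, random_rigid_transform


def _pep_rmsd(a, b):
    A = np.concatenate([r.coords for r in a.residues])
    B = np.concatenate([r.coords for r in b.residues])
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def _backbone_rmsd(a, b):
    def bb(s):
        return np.array([r.atom_coord(nm) for r in s.residues
                         for nm in ("N", "CA", "C", "O")])
    return float(np.sqrt(np.mean(np.sum((bb(a) - bb(b)) ** 2, axis=1))))


@pytest.fixture
def self_model(helix_record, helix_peptide):
    st = identity_scored_template(helix_record)
    return st, build_by_superimposition(helix_record.protein, helix_peptide,
                                        st, helix_record)


def test_build_identity_reproduces_native(helix_record, self_model):
    _, model = self_model
    assert _backbone_rmsd(model.peptide, helix_record.peptide) < 0.01
    assert model.peptide.n_residues == len(helix_record.peptide_sequence)
    assert model.peptide.chains[0][0] not in helix_record.protein.chain_ids()


def test_build_transform_consistency(helix_record, helix_peptide):
    # Template given in a rotated frame: the alignment transform must bring
    # the peptide back to the native location in the target frame.
    from pepdock.struct_align import align_structures
    from conftest import identity_scored_template
    rng = np.random.default_rng(8)
    R, t = random_rigid_transform(rng)
    import copy
    moved = copy.copy(helix_record)
    moved = type(helix_record)(
        helix_record.id, helix_record.protein.transformed(R, t),
        helix_record.peptide.transformed(R, t), helix_record.peptide_sequence,
        helix_record.contact_map, helix_record.metadata)
    st = identity_scored_template(moved)
    sa = align_structures(helix_record.protein, moved.protein)
    st.struct_alignment = sa
    model = build_by_superimposition(helix_record.protein, helix_peptide,
                                     st, moved)
    assert _backbone_rmsd(model.peptide, helix_record.peptide) < 0.01


def test_build_extends_overhang_in_extended_conformation(helix_record):
    target = PeptideSequence(helix_record.peptide_sequence + "GGG")
    st = identity_scored_template(helix_record)
    model = build_by_superimposition(helix_record.protein, target,
                                     st, helix_record)
    assert model.peptide.n_residues == len(target)
    # Overhang residues must not be built into the protein.
    prot = helix_record.protein.all_coords()
    for r in model.peptide.residues[-3:]:
        d = np.linalg.norm(prot[:, None, :] - r.coords[None, :, :], axis=2)
        assert d.min() > 2.0
    # Consecutive CA-CA distances stay near the ideal virtual bond.
    cas = model.peptide.ca_coords()
    steps = np.linalg.norm(np.diff(cas[-4:], axis=0), axis=1)
    assert np.all(steps > 2.5) and np.all(steps < 4.2)


def test_derive_restraints_weight_rule(helix_record, self_model):
    st, model = self_model
    restraints = derive_restraints(st, helix_record, model)
    by_pair = {(r.protein_res, r.peptide_pos): r for r in restraints}
    for i, j, s_ij in st.pair_scores:
        if s_ij > 0:
            r = by_pair[(i, j)]
            assert r.weight == pytest.approx(s_ij * 1.0)
            assert r.flat_width == 1.0
        else:
            assert (i, j) not in by_pair


def test_restraint_weight_monotone_in_similarity():
    r1 = Restraint(0, 0, 5.0, 1.0, weight=max(9, 0) * 1.0)
    r2 = Restraint(0, 0, 5.0, 1.0, weight=max(4, 0) * 1.0)
    assert r1.weight >= r2.weight
    with pytest.raises(ValueError):
        Restraint(0, 0, 5.0, 1.0, weight=-1.0)


def test_energy_zero_for_native_pose(helix_record, self_model):
    st, model = self_model
    restraints = derive_restraints(st, helix_record, model)
    clash, restraint, total = energy(model, restraints)
    assert total == pytest.approx(0.0, abs=1e-12)


def test_energy_restraint_formula(helix_record, self_model):
    st, model = self_model
    # A single synthetic restraint violated by exactly 1 A beyond the flat
    # region with weight 2 contributes 2 * 1^2.
    prot_res = model.protein.residues
    pep_res = model.peptide.residues[0]
    anchor_p = prot_res[0].atom_coord("CB")
    if anchor_p is None:
        anchor_p = prot_res[0].atom_coord("CA")
    anchor_q = pep_res.atom_coord("CB")
    if anchor_q is None:
        anchor_q = pep_res.atom_coord("CA")
    d = float(np.linalg.norm(anchor_p - anchor_q))
    r = Restraint(0, 0, target_distance=d - 2.0, flat_width=1.0, weight=2.0)
    clash, restraint, total = energy(model, [r])
    assert restraint == pytest.approx(2.0, abs=1e-9)
    assert total == pytest.approx(clash + restraint, abs=1e-9)


def test_energy_matches_bruteforce(helix_record, self_model):
    st, model = self_model
    restraints = derive_restraints(st, helix_record, model)
    cfg = ModelingConfig()
    rng = np.random.default_rng(17)
    for _ in range(10):
        shift = rng.normal(0, 1.2, 3)
        pep = model.peptide.transformed(np.eye(3), shift)
        m = DockModel(model.protein, pep, model.template_id)
        got = energy(m, restraints, cfg)
        # Independent evaluation: explicit loops and a hand-built bond walk.
        prot_res = m.protein.residues
        pep_res = m.peptide.residues
        clash = 0.0
        for rp in prot_res:
            for rq in pep_res:
                for a in rp.coords:
                    for b in rq.coords:
                        d = np.linalg.norm(a - b)
                        if d < cfg.d_min:
                            clash += cfg.k_clash * (cfg.d_min - d) ** 2
        # peptide-peptide: bond-graph distances by BFS
        import networkx as nx
        g = nx.Graph()
        labels = []
        for k, r in enumerate(pep_res):
            for nm in r.atom_names:
                labels.append((k, nm))
        for k, r in enumerate(pep_res):
            for a, b in (("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB")):
                if a in r.atom_names and b in r.atom_names:
                    g.add_edge((k, a), (k, b))
            if k + 1 < len(pep_res):
                g.add_edge((k, "C"), (k + 1, "N"))
        sp = dict(nx.all_pairs_shortest_path_length(g))
        flat = {(k, nm): r.coords[r.atom_names.index(nm)]
                for k, r in enumerate(pep_res) for nm in r.atom_names}
        for x in range(len(labels)):
            for y in range(x + 1, len(labels)):
                la, lb = labels[x], labels[y]
                sep = sp.get(la, {}).get(lb, 99)
                if sep < 4:
                    continue
                d = np.linalg.norm(flat[la] - flat[lb])
                if d < cfg.d_min:
                    clash += cfg.k_clash * (cfg.d_min - d) ** 2
        restraint_e = 0.0
        for r in restraints:
            pa = prot_res[r.protein_res]
            qa = pep_res[r.peptide_pos]
            ap = pa.atom_coord("CB") if pa.atom_coord("CB") is not None \
                else pa.atom_coord("CA")
            aq = qa.atom_coord("CB") if qa.atom_coord("CB") is not None \
                else qa.atom_coord("CA")
            excess = max(0.0, abs(np.linalg.norm(ap - aq) - r.target_distance)
                         - r.flat_width)
            restraint_e += r.weight * excess ** 2
        assert got[0] == pytest.approx(clash, abs=1e-9)
        assert got[1] == pytest.approx(restraint_e, abs=1e-9)
        assert got[2] == pytest.approx(clash + restraint_e, abs=1e-9)


def test_energy_rigid_invariance(helix_record, self_model):
    st, model = self_model
    restraints = derive_restraints(st, helix_record, model)
    rng = np.random.default_rng(23)
    pep = model.peptide.transformed(np.eye(3), np.array([1.0, -2.0, 0.5]))
    m = DockModel(model.protein, pep, model.template_id)
    base = energy(m, restraints)
    R, t = random_rigid_transform(rng)
    m2 = DockModel(m.protein.transformed(R, t), pep.transformed(R, t),
                   m.template_id)
    moved = energy(m2, restraints)
    for a, b in zip(base, moved):
        assert a == pytest.approx(b, abs=1e-9)


def test_refine_zero_energy_model_unchanged(helix_record, self_model):
    st, model = self_model
    restraints = derive_restraints(st, helix_record, model)
    refined = refine(model, restraints, seed=3)
    assert refined.energy_components[2] == 0.0
    assert _pep_rmsd(refined.peptide, model.peptide) == pytest.approx(0.0)


def test_refine_never_increases_energy_and_is_deterministic(
        helix_record, self_model):
    st, model = self_model
    restraints = derive_restraints(st, helix_record, model)
    displaced = DockModel(
        model.protein,
        model.peptide.transformed(np.eye(3), np.array([2.0, -1.5, 1.0])),
        model.template_id)
    e0 = energy(displaced, restraints)
    r1 = refine(displaced, restraints, seed=11)
    r2 = refine(displaced, restraints, seed=11)
    assert r1.energy_components[2] <= e0[2]
    assert _pep_rmsd(r1.peptide, r2.peptide) == 0.0
    r3 = refine(displaced, restraints, seed=12)
    assert r3.energy_components[2] <= e0[2]


def test_refinement_funnel(helix_record, self_model):
    st, model = self_model
    restraints = derive_restraints(st, helix_record, model)
    away = model.peptide.all_coords().mean(0) - \
        model.protein.all_coords().mean(0)
    away = 3.0 * away / np.linalg.norm(away)
    displaced = DockModel(model.protein,
                          model.peptide.transformed(np.eye(3), away),
                          model.template_id)
    e0 = energy(displaced, restraints)
    assert e0[2] > 0
    rmsd0 = _pep_rmsd(displaced.peptide, model.peptide)
    wins = 0
    for seed in range(3):
        r = refine(displaced, restraints, seed=seed)
        assert r.energy_components[2] < e0[2]
        if _pep_rmsd(r.peptide, model.peptide) < rmsd0:
            wins += 1
    assert wins >= 2


def test_generate_models_counts_and_determinism(helix_record, helix_peptide,
                                                decoy_records):
    db = TemplateDB([helix_record])
    st = identity_scored_template(helix_record)
    cfg = ModelingConfig(n_build_total=6, n_build_min=3,
                         refine=RefineConfig(n_starts=1, max_iter=30))
    models = generate_models(helix_record.protein, helix_peptide, [st], db,
                             cfg, master_seed=5)
    assert 1 <= len(models) <= 10
    assert all(m.template_id == helix_record.id for m in models)
    energies = [m.total_energy for m in models]
    assert energies == sorted(energies)

    models2 = generate_models(helix_record.protein, helix_peptide, [st], db,
                              cfg, master_seed=5)
    for a, b in zip(models, models2):
        assert _pep_rmsd(a.peptide, b.peptide) == 0.0
        assert a.seed == b.seed


def test_generate_models_one_per_template_when_ten(helix_record,
                                                   helix_peptide):
    db = TemplateDB([helix_record])
    st = identity_scored_template(helix_record)
    cfg = ModelingConfig(n_build_total=10, n_build_min=1,
                         refine=RefineConfig(n_starts=1, max_iter=5))
    # Ten logically distinct template entries backed by the same record.
    selected = [st] * 10
    models = generate_models(helix_record.protein, helix_peptide, selected,
                             db, cfg, master_seed=1)
    assert len(models) == 10
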