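"""Interaction-similarity scoring, peptide alignment and template ranking."""

import numpy as np
import pytest

from pepdock.contacts import Contact, ContactClass, ContactMap
from pepdock.similarity import (ScoredTemplate, align_peptide, blosum62,
                                interaction_similarity, pair_similarity,
                                peptide_position_weight, rank_templates,
                                select_templates, zscores)
from pepdock.structure_io import AA_1TO3, PeptideSequence, Residue, Structure
from pepdock.template_db import ComplexRecord, TemplateDB

from conftest import AAS


def _cm(*pairs):
    return ContactMap([Contact(i, j, cls, 4.0) for i, j, cls in pairs])


def test_blosum62_reference_values():
    B = blosum62()
    assert B("L", "L") == 4 and B("K", "K") == 5 and B("A", "A") == 4
    assert B("L", "K") == -2 and B("C", "C") == 9
    assert B("X", "A") == 0  # unknowns are neutral


def test_peptide_position_weight_counts_hydrophobic_and_ionic_only():
    cm = _cm((0, 2, ContactClass.HYDROPHOBIC),
             (1, 2, ContactClass.HYDROPHOBIC),
             (2, 2, ContactClass.IONIC),
             (3, 2, ContactClass.GENERIC),
             (0, 5, ContactClass.GENERIC))
    assert peptide_position_weight(2, cm) == 4   # 1 + 2 hphob + 1 ionic
    assert peptide_position_weight(5, cm) == 1   # generic only
    assert peptide_position_weight(9, cm) == 1   # no contacts


def test_align_peptide_identity_score():
    pa = align_peptide(PeptideSequence("LKA"), "LKA", ContactMap([]))
    assert pa.offset == 0
    assert pa.pairs == [(0, 0), (1, 1), (2, 2)]
    assert pa.score == 4 + 5 + 4  # B(L,L)+B(K,K)+B(A,A)


def test_align_peptide_finds_embedded_match():
    pa = align_peptide(PeptideSequence("LKA"), "GLKAG", ContactMap([]))
    assert pa.offset == 1
    assert [t for t, _ in pa.pairs] == [0, 1, 2]


def test_align_peptide_weights_bias_the_offset():
    # Template GAGAL: a hot-spot weight at the final L pulls the L of the
    # target there even though an unweighted alignment would tie elsewhere.
    weights = [1, 1, 1, 1, 5]
    pa = align_peptide(PeptideSequence("AAL"), "GAGAL", ContactMap([]),
                       weights=weights)
    assert pa.pairs[-1] == (2, 4)


def test_align_peptide_tie_goes_to_smallest_offset():
    pa = align_peptide(PeptideSequence("AAA"), "AAAA", ContactMap([]))
    assert pa.offset == 0


def test_align_peptide_matches_exhaustive_enumeration():
    B = blosum62()
    rng = np.random.default_rng(21)
    for _ in range(50):
        n, m = int(rng.integers(3, 9)), int(rng.integers(3, 12))
        tgt = "".join(rng.choice(list(AAS), n))
        tpl = "".join(rng.choice(list(AAS), m))
        weights = [int(w) for w in rng.integers(1, 5, m)]
        pa = align_peptide(PeptideSequence(tgt), tpl, ContactMap([]),
                           weights=weights)
        # Independent oracle: enumerate all offsets directly.
        best = None
        min_ov = min(3, n, m)
        for off in range(-(n - min_ov), m - min_ov + 1):
            lo, hi = max(0, off), min(m, off + n)
            if hi - lo < min_ov:
                continue
            sc = 0
            for j in range(lo, hi):
                b = B(tgt[j - off], tpl[j])
                sc += weights[j] * b if b > 0 else b
            if best is None or sc > best[0]:
                best = (sc, off)
        assert pa.score == best[0]
        assert pa.offset == best[1]


def test_pair_similarity_formula():
    assert pair_similarity("L", "K", "L", "K") == 9      # max(4+5, -2-2)
    assert pair_similarity("L", "K", "K", "L") == 9      # swap-tolerant
    assert pair_similarity("A", "A", "A", "A") == 8
    B = blosum62()
    rng = np.random.default_rng(7)
    for _ in range(100):
        i, j, ip, jp = rng.choice(list(AAS), 4)
        assert pair_similarity(i, j, ip, jp) == max(
            B(i, ip) + B(j, jp), B(i, jp) + B(j, ip))


def _tiny_record(prot_seq, pep_seq, contacts, rid="T"):
    """Sequence-only complex record (single CA atoms; geometry irrelevant
    for interaction-similarity scoring)."""
    prot_res = [Residue(AA_1TO3[a], a, "A", i + 1, "", ["CA"],
                        np.array([[3.0 * i, 0, 0]]))
                for i, a in enumerate(prot_seq)]
    pep_res = [Residue(AA_1TO3[a], a, "B", j + 1, "", ["CA"],
                       np.array([[3.0 * j, 4, 0]]))
               for j, a in enumerate(pep_seq)]
    return ComplexRecord(rid, Structure([("A", prot_res)]),
                         Structure([("B", pep_res)]), pep_seq,
                         _cm(*contacts))


def test_interaction_similarity_identity_and_partial_mapping():
    from pepdock.similarity import PeptideAlignment
    from pepdock.struct_align import StructAlignment

    rec = _tiny_record("LASK", "LKA",
                       [(0, 1, ContactClass.HYDROPHOBIC),
                        (3, 0, ContactClass.IONIC),
                        (2, 2, ContactClass.GENERIC)])
    n, m = 4, 3
    sa = StructAlignment([(i, i) for i in range(n)], np.eye(3), np.zeros(3), 1.0)
    pa = PeptideAlignment(0, [(j, j) for j in range(m)], 0.0)
    s, pair_scores, skipped = interaction_similarity(
        rec, sa, pa, rec.protein, PeptideSequence("LKA"))
    assert skipped == 0
    # self-similarity: every pair scores its diagonal maximum
    B = blosum62()
    expected = (B("L", "L") + B("K", "K")) + (B("K", "K") + B("L", "L")) \
        + (B("S", "S") + B("A", "A"))
    assert s == expected

    # Drop peptide position 2 from the alignment: its contact is skipped.
    pa2 = PeptideAlignment(0, [(0, 0), (1, 1)], 0.0)
    s2, _, skipped2 = interaction_similarity(
        rec, sa, pa2, rec.protein, PeptideSequence("LKA"))
    assert skipped2 == 1
    assert s2 == expected - (B("S", "S") + B("A", "A"))


def test_interaction_similarity_matches_bruteforce():
    from pepdock.similarity import PeptideAlignment
    from pepdock.struct_align import StructAlignment
    B = blosum62()
    rng = np.random.default_rng(13)
    for _ in range(100):
        np_, mp_ = int(rng.integers(8, 14)), int(rng.integers(3, 8))
        nt, mt = int(rng.integers(8, 14)), int(rng.integers(3, 8))
        prot = "".join(rng.choice(list(AAS), np_))
        pep = "".join(rng.choice(list(AAS), mp_))
        tgt_prot = "".join(rng.choice(list(AAS), nt))
        tgt_pep = "".join(rng.choice(list(AAS), mt))
        contacts = {(int(rng.integers(np_)), int(rng.integers(mp_)))
                    for _ in range(rng.integers(1, 6))}
        rec = _tiny_record(prot, pep,
                           [(i, j, ContactClass.GENERIC) for i, j in contacts])
        # Random monotone partial mappings.
        prot_pairs = sorted(zip(
            sorted(rng.choice(np_, size=min(np_, nt), replace=False)),
            sorted(rng.choice(nt, size=min(np_, nt), replace=False))))
        prot_pairs = [(int(t), int(p)) for p, t in prot_pairs]
        off = int(rng.integers(-mt + 1, mp_))
        pep_pairs = [(j - off, j) for j in range(max(0, off), min(mp_, off + mt))]
        sa = StructAlignment(prot_pairs, np.eye(3), np.zeros(3), 0.5)
        pa = PeptideAlignment(off, pep_pairs, 0.0) if pep_pairs else None
        if pa is None:
            continue
        tgt_prot_s = Structure([("A", [
            Residue(AA_1TO3[a], a, "A", i + 1, "", ["CA"], np.zeros((1, 3)))
            for i, a in enumerate(tgt_prot)])])
        s, pair_scores, skipped = interaction_similarity(
            rec, sa, pa, tgt_prot_s, PeptideSequence(tgt_pep))
        # Independent brute force, no shared code.
        p_map = {tpl: tgt for tgt, tpl in prot_pairs}
        j_map = {tpl: tgt for tgt, tpl in pep_pairs}
        expected, n_skip = 0, 0
        for (i, j) in contacts:
            if i in p_map and j in j_map:
                a, b = prot[i], pep[j]
                ap, bp = tgt_prot[p_map[i]], tgt_pep[j_map[j]]
                expected += max(B(a, ap) + B(b, bp), B(a, bp) + B(b, ap))
            else:
                n_skip += 1
        assert s == expected
        assert skipped == n_skip


def test_zscores():
    z = zscores([1, 2, 3])
    assert z[0] == pytest.approx(-1.2247, abs=1e-4)
    assert z[1] == 0.0
    assert z[2] == pytest.approx(1.2247, abs=1e-4)
    assert zscores([5, 5, 5]) == [0.0, 0.0, 0.0]
    with pytest.raises(ValueError):
        zscores([1.0])


def test_rank_templates_puts_native_first(helix_record, decoy_records,
                                          helix_peptide):
    db = TemplateDB([helix_record] + decoy_records)
    ranked = rank_templates(db, helix_record.protein, helix_peptide)
    assert ranked[0].template_id == helix_record.id
    assert ranked[0].tm_score == pytest.approx(1.0, abs=1e-6)
    for s in ranked:
        assert s.s_complex == pytest.approx(s.z_tm + s.z_inter, abs=1e-12)
    # Self s_inter equals the diagonal-maximum upper bound.
    B = blosum62()
    bound = sum(
        max(2 * B(helix_record.protein.residues[c.protein_index].aa_1letter,
                  helix_record.protein.residues[c.protein_index].aa_1letter),
            0) / 2
        + B(helix_record.peptide_sequence[c.peptide_index],
            helix_record.peptide_sequence[c.peptide_index])
        for c in helix_record.contact_map)
    assert ranked[0].s_inter == pytest.approx(bound)


def test_rank_templates_two_entry_db(helix_record, decoy_records,
                                     helix_peptide):
    db = TemplateDB([helix_record, decoy_records[0]])
    ranked = rank_templates(db, helix_record.protein, helix_peptide)
    # n=2 population: z-scores are +-1 (or 0 on ties).
    assert ranked[0].z_tm == pytest.approx(1.0)
    assert ranked[1].z_tm == pytest.approx(-1.0)
    assert ranked[0].template_id == helix_record.id


def _fake_scored(template_id, s_complex, tm=0.5):
    return ScoredTemplate(template_id=template_id, tm_score=tm, s_inter=0.0,
                          z_tm=0.0, z_inter=0.0, s_complex=s_complex,
                          n_template_contacts=1, pair_scores=[],
                          struct_alignment=None, peptide_alignment=None)


def test_select_templates_ninety_percent_rule():
    ranked = [_fake_scored(f"t{i}", s)
              for i, s in enumerate([10.0, 9.5, 9.2, 8.9])]
    sel = select_templates(ranked)
    assert [s.template_id for s in sel] == ["t0", "t1", "t2"]


def test_select_templates_caps_at_ten():
    ranked = [_fake_scored(f"t{i:02d}", 4.0) for i in range(15)]
    assert len(select_templates(ranked)) == 10


def test_select_templates_nonpositive_max_keeps_top_one():
    ranked = [_fake_scored("a", -0.5), _fake_scored("b", -1.0)]
    sel = select_templates(ranked)
    assert [s.template_id for s in sel] == ["a"]


def test_s_inter_never_increases_under_dissimilar_mutation():
    # Mutating one aligned target peptide residue to a dissimilar amino
    # acid cannot increase S_Inter (BLOSUM62 diagonal dominance).
    from pepdock.similarity import PeptideAlignment
    from pepdock.struct_align import StructAlignment
    rng = np.random.default_rng(31)
    for _ in range(30):
        m = 5
        pep = "".join(rng.choice(list(AAS), m))
        rec = _tiny_record("LKASDF", pep,
                           [(int(rng.integers(6)), int(rng.integers(m)),
                             ContactClass.GENERIC)])
        sa = StructAlignment([(i, i) for i in range(6)], np.eye(3),
                             np.zeros(3), 1.0)
        pa = PeptideAlignment(0, [(j, j) for j in range(m)], 0.0)
        base, *_ = interaction_similarity(rec, sa, pa, rec.protein,
                                          PeptideSequence(pep))
        pos = int(rng.integers(m))
        mutated = pep[:pos] + ("W" if pep[pos] != "W" else "G") + pep[pos + 1:]
        mut, *_ = interaction_similarity(rec, sa, pa, rec.protein,
                                         PeptideSequence(mutated))
        assert mut <= base
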