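"""Independent brute-force oracles used by the acceptance suite.

Deliberately naive reimplementations (explicit loops, scipy primitives
only) that share no code with the package internals they check.
"""

from __future__ import annotations

import numpy as np

HYDROPHOBIC = set("AVLIMFWP")
ACIDIC = set("DE")
BASIC = set("KRH")


def brute_contacts(protein, peptide) -> set[tuple[int, int, str]]:
    out = set()
    for i, rp in enumerate(protein.residues):
        for j, rq in enumerate(peptide.residues):
            d = min(float(np.linalg.norm(a - b))
                    for a in rp.coords for b in rq.coords)
            p, q = rp.aa_1letter, rq.aa_1letter
            if p in HYDROPHOBIC and q in HYDROPHOBIC and d <= 5.0:
                out.add((i, j, "hydrophobic"))
            elif ((p in ACIDIC and q in BASIC) or
                  (p in BASIC and q in ACIDIC)) and d <= 6.0:
                out.add((i, j, "ionic"))
            elif d <= 4.5:
                out.add((i, j, "generic"))
    return out


def brute_peptide_alignment(tgt: str, tpl: str, weights, B):
    best = None
    min_ov = min(3, len(tgt), len(tpl))
    for off in range(-(len(tgt) - min_ov), len(tpl) - min_ov + 1):
        lo, hi = max(0, off), min(len(tpl), off + len(tgt))
        if hi - lo < min_ov:
            continue
        sc = 0
        for j in range(lo, hi):
            b = B(tgt[j - off], tpl[j])
            sc += weights[j] * b if b > 0 else b
        if best is None or sc > best[0]:
            best = (sc, off)
    return best


def brute_s_inter(contacts, prot_seq, pep_seq, tgt_prot_seq, tgt_pep_seq,
                  prot_map, pep_map, B):
    total, skipped = 0, 0
    for (i, j) in contacts:
        if i in prot_map and j in pep_map:
            a, b = prot_seq[i], pep_seq[j]
            ap, bp = tgt_prot_seq[prot_map[i]], tgt_pep_seq[pep_map[j]]
            total += max(B(a, ap) + B(b, bp), B(a, bp) + B(b, ap))
        else:
            skipped += 1
    return total, skipped


def brute_energy(protein, peptide, restraints, d_min=2.8, k_clash=10.0):
    prot_res = protein.residues
    pep_res = peptide.residues
    clash = 0.0
    for rp in prot_res:
        for rq in pep_res:
            d = np.linalg.norm(rp.coords[:, None, :] - rq.coords[None, :, :],
                               axis=2)
            v = d_min - d[d < d_min]
            clash += k_clash * float(np.sum(v ** 2))
    # peptide-peptide with an explicit bond walk
    import networkx as nx
    g = nx.Graph()
    for k, r in enumerate(pep_res):
        for a, b in (("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB")):
            if a in r.atom_names and b in r.atom_names:
                g.add_edge((k, a), (k, b))
        if k + 1 < len(pep_res):
            g.add_edge((k, "C"), (k + 1, "N"))
    sp = dict(nx.all_pairs_shortest_path_length(g))
    atoms = [(k, nm, r.coords[r.atom_names.index(nm)])
             for k, r in enumerate(pep_res) for nm in r.atom_names]
    for x in range(len(atoms)):
        for y in range(x + 1, len(atoms)):
            ka, na, ca = atoms[x]
            kb, nb, cb = atoms[y]
            if sp.get((ka, na), {}).get((kb, nb), 99) < 4:
                continue
            d = float(np.linalg.norm(ca - cb))
            if d < d_min:
                clash += k_clash * (d_min - d) ** 2
    restraint = 0.0
    for r in restraints:
        pa = prot_res[r.protein_res]
        qa = pep_res[r.peptide_pos]
        ap = pa.atom_coord("CB")
        ap = ap if ap is not None else pa.atom_coord("CA")
        aq = qa.atom_coord("CB")
        aq = aq if aq is not None else qa.atom_coord("CA")
        excess = max(0.0, abs(float(np.linalg.norm(ap - aq)))
                     and abs(float(np.linalg.norm(ap - aq)) - r.target_distance)
                     - r.flat_width)
        restraint += r.weight * excess ** 2
    return clash, restraint, clash + restraint


def brute_kabsch(a: np.ndarray, b: np.ndarray):
    """Classic SVD Kabsch, written out explicitly."""
    ca, cb = a.mean(0), b.mean(0)
    H = (b - cb).T @ (a - ca)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    return R, t


def brute_ligand_rmsd(model_prot, model_pep, nat_prot, nat_pep):
    def bb(s):
        return np.array([r.atom_coord(nm) for r in s.residues
                         for nm in ("N", "CA", "C", "O")])
    R, t = brute_kabsch(bb(nat_prot), bb(model_prot))
    moved = bb(model_pep) @ R.T + t
    return float(np.sqrt(np.mean(np.sum((moved - bb(nat_pep)) ** 2, axis=1))))


def brute_interface_rmsd(model_prot, model_pep, nat_prot, nat_pep,
                         cutoff=10.0):
    def near(ra, others):
        return any(np.linalg.norm(a - b) <= cutoff
                   for a in ra.coords for ro in others for b in ro.coords)
    prot_sel = [i for i, r in enumerate(nat_prot.residues)
                if near(r, nat_pep.residues)]
    pep_sel = [j for j, r in enumerate(nat_pep.residues)
               if near(r, nat_prot.residues)]
    mod, nat = [], []
    for i in prot_sel:
        for nm in ("N", "CA", "C", "O"):
            mod.append(model_prot.residues[i].atom_coord(nm))
            nat.append(nat_prot.residues[i].atom_coord(nm))
    for j in pep_sel:
        for nm in ("N", "CA", "C", "O"):
            mod.append(model_pep.residues[j].atom_coord(nm))
            nat.append(nat_pep.residues[j].atom_coord(nm))
    mod, nat = np.array(mod), np.array(nat)
    R, t = brute_kabsch(nat, mod)
    moved = mod @ R.T + t
    return float(np.sqrt(np.mean(np.sum((moved - nat) ** 2, axis=1))))


def brute_fnat(model_prot, model_pep, nat_prot, nat_pep):
    nat = {(i, j) for i, j, _ in brute_contacts(nat_prot, nat_pep)}
    mod = {(i, j) for i, j, _ in brute_contacts(model_prot, model_pep)}
    return len(nat & mod) / len(nat)
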