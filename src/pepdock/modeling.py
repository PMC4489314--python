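"""Complex model building and simplified flexible refinement.

Models are built by superimposing the template complex onto the target
protein via the structural alignment and threading the target peptide
sequence onto the template peptide backbone. Distance restraints between
interacting protein-peptide pairs, weighted by the interaction pair
similarity S_{i-j}, keep well-conserved interactions in place during
refinement: pairs similar to the template are restrained strongly, while
the rest of the structure is free to relax against the clash term.

The refinement energy is deliberately simple — a soft-sphere clash
penalty plus flat-bottom harmonic restraints — minimized by seeded
stochastic descent over peptide rigid-body and backbone dihedral moves.
The energy interface is isolated so a richer force field can be swapped
in without touching the build or ranking code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import lil_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .config import ModelingConfig, RefineConfig
from .geometry import EXTENDED_PHI_PSI, extend_residue, ideal_cb, prepend_residue
from .similarity import ScoredTemplate
from .structure_io import AA_1TO3, PeptideSequence, Residue, Structure, _unused_chain_id
from .template_db import ComplexRecord


@dataclass
class Restraint:
    """Flat-bottom harmonic distance restraint between anchor atoms.

    Anchors are CB atoms (CA for glycine) of a target protein residue and a
    model peptide residue; ``target_distance`` is the template's anchor-atom
    distance for the underlying contact pair.
    """

    protein_res: int           # index into the target protein residue list
    peptide_pos: int           # 0-based position in the model peptide
    target_distance: float
    flat_width: float
    weight: float

    def __post_init__(self):
        if self.weight < 0 or self.target_distance <= 0:
            raise ValueError("restraint needs weight >= 0 and distance > 0")


@dataclass
class DockModel:
    protein: Structure
    peptide: Structure
    template_id: str
    seed: int = 0
    energy_components: tuple[float, float, float] | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def total_energy(self) -> float:
        return self.energy_components[2] if self.energy_components else float("nan")


def _anchor_coord(res: Residue) -> np.ndarray:
    c = res.atom_coord("CB")
    if c is None:
        c = res.atom_coord("CA")
    if c is None:
        raise ValueError(f"residue {res.key} has neither CB nor CA")
    return c


def build_by_superimposition(target_protein: Structure,
                             target_peptide: PeptideSequence,
                             st: ScoredTemplate,
                             template: ComplexRecord) -> DockModel:
    """Thread the target peptide onto the superimposed template peptide.

    The target protein stays in its input frame; the template peptide is
    carried into that frame by the structural-alignment transform. Aligned
    positions copy the template backbone (N, CA, C, O) with the side chain
    mutated to the target residue (ideal CB; atoms beyond CB omitted in the
    unrefined model); unaligned terminal overhangs are built in extended
    conformation continuing from the nearest aligned residue.
    """
    pa = st.peptide_alignment
    sa = st.struct_alignment
    if not pa.pairs:
        raise ValueError("peptide alignment has no aligned positions")
    R, t = sa.rotation, sa.translation
    tpl_pep = template.peptide.transformed(R, t)
    tpl_res = tpl_pep.residues
    tgt_to_tpl = dict(pa.pairs)
    n = len(target_peptide)
    chain_id = _unused_chain_id(set(target_protein.chain_ids()))

    built: dict[int, Residue] = {}
    for pos, tpl_pos in tgt_to_tpl.items():
        tr = tpl_res[tpl_pos]
        aa = target_peptide.sequence[pos]
        coords, names = [], []
        for nm in ("N", "CA", "C", "O"):
            c = tr.atom_coord(nm)
            if c is None:
                raise ValueError(
                    f"template peptide residue {tr.key} missing backbone atom {nm}")
            names.append(nm)
            coords.append(c)
        if aa != "G":
            names.append("CB")
            coords.append(ideal_cb(coords[0], coords[1], coords[2]))
        built[pos] = Residue(AA_1TO3[aa], aa, chain_id, pos + 1, "",
                             names, np.array(coords))

    phi, psi = EXTENDED_PHI_PSI
    first = min(built)
    last = max(built)
    # C-terminal overhang.
    bb = tuple(built[last].atom_coord(nm) for nm in ("N", "CA", "C"))
    for pos in range(last + 1, n):
        aa = target_peptide.sequence[pos]
        res, bb = extend_residue(*bb, aa, phi, psi, psi, chain_id, pos + 1)
        built[pos] = res
    # N-terminal overhang.
    bb = tuple(built[first].atom_coord(nm) for nm in ("N", "CA", "C"))
    for pos in range(first - 1, -1, -1):
        aa = target_peptide.sequence[pos]
        res, bb = prepend_residue(*bb, aa, phi, psi, chain_id, pos + 1)
        built[pos] = res

    peptide = Structure([(chain_id, [built[p] for p in range(n)])],
                        source_id=f"model:{template.id}")
    return DockModel(
        protein=target_protein, peptide=peptide, template_id=template.id,
        provenance={
            "struct_alignment": sa.to_json_dict(),
            "peptide_offset": pa.offset,
            "aligned_peptide_positions": sorted(tgt_to_tpl),
        })


def derive_restraints(st: ScoredTemplate, template: ComplexRecord,
                      model: DockModel, cfg: ModelingConfig | None = None,
                      ) -> list[Restraint]:
    """One restraint per mapped template contact pair with S_{i-j} > 0.

    The restraint weight is max(S_{i-j}, 0) * w0, so interaction pairs more
    similar to the template are held more strongly.
    """
    cfg = cfg or ModelingConfig()
    tpl_to_tgt_prot = st.struct_alignment.template_to_target()
    tpl_to_tgt_pep = st.peptide_alignment.template_to_target()
    tpl_prot = template.protein.residues
    tpl_pep = template.peptide.residues
    restraints = []
    for i, j, s_ij in st.pair_scores:
        if s_ij <= 0:
            continue
        if i not in tpl_to_tgt_prot or j not in tpl_to_tgt_pep:
            continue
        d = float(np.linalg.norm(_anchor_coord(tpl_prot[i]) - _anchor_coord(tpl_pep[j])))
        if d <= 0:
            continue
        restraints.append(Restraint(
            protein_res=tpl_to_tgt_prot[i], peptide_pos=tpl_to_tgt_pep[j],
            target_distance=d, flat_width=cfg.flat_width,
            weight=s_ij * cfg.w0))
    return restraints


def _peptide_nonbonded_pairs(peptide: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Flat-index pairs of peptide atoms >= 3 bonds apart (the non-bonded set)."""
    residues = peptide.residues
    offsets = np.cumsum([0] + [len(r.atom_names) for r in residues])
    n_atoms = offsets[-1]
    g = lil_matrix((n_atoms, n_atoms))
    intra = [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB")]
    for k, r in enumerate(residues):
        base = offsets[k]
        idx = {nm: base + i for i, nm in enumerate(r.atom_names)}
        for a, b in intra:
            if a in idx and b in idx:
                g[idx[a], idx[b]] = 1
        if k + 1 < len(residues):
            nxt = residues[k + 1]
            jdx = {nm: offsets[k + 1] + i for i, nm in enumerate(nxt.atom_names)}
            if "C" in idx and "N" in jdx:
                g[idx["C"], jdx["N"]] = 1
    sep = shortest_path(g.tocsr(), directed=False, unweighted=True)
    iu, ju = np.triu_indices(n_atoms, k=1)
    # 1-4 pairs are also excluded: O(i)-CA(i+1) across the rigid trans
    # peptide bond sits at 2.7 A in ideal geometry, which would otherwise
    # give every chain an irreducible clash energy.
    keep = ~(sep[iu, ju] < 4)
    return iu[keep], ju[keep]


class _EnergyEvaluator:
    """Precomputed fast energy over a flat peptide coordinate array."""

    def __init__(self, model: DockModel, restraints: list[Restraint],
                 cfg: ModelingConfig):
        self.cfg = cfg
        self.prot_coords = model.protein.all_coords()
        residues = model.peptide.residues
        self.res_slices = []
        start = 0
        names_flat = []
        for r in residues:
            k = len(r.atom_names)
            self.res_slices.append(slice(start, start + k))
            names_flat.extend(r.atom_names)
            start += k
        self.atom_index = {}
        for k, r in enumerate(residues):
            base = self.res_slices[k].start
            for i, nm in enumerate(r.atom_names):
                self.atom_index[(k, nm)] = base + i
        self.pp_i, self.pp_j = _peptide_nonbonded_pairs(model.peptide)
        # Restraint anchors: protein side fixed, peptide side a flat index.
        self.r_prot = np.zeros((len(restraints), 3))
        self.r_pep_idx = np.zeros(len(restraints), dtype=int)
        self.r_d0 = np.zeros(len(restraints))
        self.r_w = np.zeros(len(restraints))
        self.r_flat = np.zeros(len(restraints))
        prot_res = model.protein.residues
        for k, r in enumerate(restraints):
            self.r_prot[k] = _anchor_coord(prot_res[r.protein_res])
            pep_res = residues[r.peptide_pos]
            nm = "CB" if "CB" in pep_res.atom_names else "CA"
            self.r_pep_idx[k] = self.atom_index[(r.peptide_pos, nm)]
            self.r_d0[k] = r.target_distance
            self.r_w[k] = r.weight
            self.r_flat[k] = r.flat_width

    def initial_coords(self, model: DockModel) -> np.ndarray:
        return np.concatenate([r.coords for r in model.peptide.residues])

    def __call__(self, pep: np.ndarray) -> tuple[float, float, float]:
        cfg = self.cfg
        d = cdist(self.prot_coords, pep)
        viol = cfg.d_min - d
        clash = cfg.k_clash * float(np.sum(np.square(viol, where=viol > 0,
                                                     out=np.zeros_like(viol))))
        if len(self.pp_i):
            dpp = np.linalg.norm(pep[self.pp_i] - pep[self.pp_j], axis=1)
            v = cfg.d_min - dpp
            clash += cfg.k_clash * float(np.sum(v[v > 0] ** 2))
        restraint = 0.0
        if len(self.r_w):
            dr = np.linalg.norm(pep[self.r_pep_idx] - self.r_prot, axis=1)
            excess = np.maximum(0.0, np.abs(dr - self.r_d0) - self.r_flat)
            restraint = float(np.sum(self.r_w * excess ** 2))
        return clash, restraint, clash + restraint


def energy(model: DockModel, restraints: list[Restraint],
           cfg: ModelingConfig | None = None) -> tuple[float, float, float]:
    """(clash, restraint, total) energy of a model.

    Clash: soft-sphere k*(d_min - d)^2 over protein-peptide heavy-atom
    pairs and peptide-peptide pairs at least 3 bonds apart. Restraint:
    flat-bottom harmonic w*(max(0, |d - d0| - width))^2 over anchor pairs.
    """
    cfg = cfg or ModelingConfig()
    ev = _EnergyEvaluator(model, restraints, cfg)
    return ev(ev.initial_coords(model))


def _with_peptide_coords(model: DockModel, pep_flat: np.ndarray,
                         ev: _EnergyEvaluator,
                         components: tuple[float, float, float],
                         seed: int) -> DockModel:
    residues = []
    for r, sl in zip(model.peptide.residues, ev.res_slices):
        residues.append(Residue(r.name_3letter, r.aa_1letter, r.chain_id,
                                r.author_number, r.ins_code,
                                list(r.atom_names), pep_flat[sl].copy()))
    peptide = Structure([(model.peptide.chains[0][0], residues)],
                        source_id=model.peptide.source_id)
    return DockModel(model.protein, peptide, model.template_id, seed,
                     components, dict(model.provenance))


def _dihedral_move_sets(model: DockModel, ev: _EnergyEvaluator):
    """(axis atom indices, moved flat indices) for each phi/psi of the peptide."""
    moves = []
    nres = len(model.peptide.residues)
    for k in range(nres):
        downstream = list(range(ev.res_slices[k].stop, ev.res_slices[-1].stop))
        idx = {nm: ev.atom_index.get((k, nm)) for nm in ("N", "CA", "C", "O", "CB")}
        if idx["N"] is not None and idx["CA"] is not None:
            moved = [idx[nm] for nm in ("C", "O", "CB") if idx[nm] is not None]
            moves.append(((idx["N"], idx["CA"]), moved + downstream))
        if idx["CA"] is not None and idx["C"] is not None:
            moved = [idx["O"]] if idx["O"] is not None else []
            moves.append(((idx["CA"], idx["C"]), moved + downstream))
    return moves


def refine(model: DockModel, restraints: list[Restraint],
           cfg: ModelingConfig | None = None,
           seed: int = 0) -> DockModel:
    """Seeded stochastic descent over peptide rigid-body and dihedral moves.

    The protein is held fixed. From ``n_starts`` starting points (the input
    pose plus randomly perturbed copies) random moves are proposed and
    accepted only when they lower the total energy, so the reported total
    can never exceed the input total. Deterministic for a given seed.
    """
    cfg = cfg or ModelingConfig()
    rc: RefineConfig = cfg.refine
    ev = _EnergyEvaluator(model, restraints, cfg)
    x0 = ev.initial_coords(model)
    moves = _dihedral_move_sets(model, ev)
    rng = np.random.default_rng(seed)

    best_x = x0.copy()
    best_e = ev(x0)

    for start in range(rc.n_starts):
        x = x0.copy()
        if start > 0:
            centroid = x.mean(axis=0)
            R = Rotation.from_rotvec(
                rng.normal(0, np.deg2rad(15.0), 3)).as_matrix()
            x = (x - centroid) @ R.T + centroid + rng.normal(0, 1.0, 3)
        e = ev(x)
        if e[2] < best_e[2]:
            best_e, best_x = e, x.copy()
        for it in range(rc.max_iter):
            cool = 1.0 - 0.7 * it / rc.max_iter
            if rng.random() < 0.6:  # rigid-body move
                centroid = x.mean(axis=0)
                R = Rotation.from_rotvec(
                    rng.normal(0, np.deg2rad(rc.rot_step) * cool, 3)).as_matrix()
                trial = (x - centroid) @ R.T + centroid \
                    + rng.normal(0, rc.step * cool, 3)
            else:  # backbone dihedral perturbation
                (a_idx, b_idx), moved = moves[rng.integers(len(moves))]
                if not moved:
                    continue
                axis = x[b_idx] - x[a_idx]
                nrm = np.linalg.norm(axis)
                if nrm < 1e-9:
                    continue
                ang = rng.normal(0, np.deg2rad(rc.dihedral_step) * cool)
                R = Rotation.from_rotvec(axis / nrm * ang).as_matrix()
                trial = x.copy()
                trial[moved] = (trial[moved] - x[b_idx]) @ R.T + x[b_idx]
            e_trial = ev(trial)
            if e_trial[2] < e[2]:
                x, e = trial, e_trial
                if e[2] < best_e[2]:
                    best_e, best_x = e, x.copy()
    return _with_peptide_coords(model, best_x, ev, best_e, seed)


def _build_seed(master_seed: int, template_index: int, build_index: int) -> int:
    """Counter-based per-build seed stream below 2**31."""
    ss = np.random.SeedSequence([master_seed, template_index, build_index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_models(target_protein: Structure, target_peptide: PeptideSequence,
                    selected: list[ScoredTemplate], db,
                    cfg: ModelingConfig | None = None,
                    master_seed: int = 0,
                    n_models: int = 10) -> list[DockModel]:
    """Refined models from the selected templates, best-energy first.

    Per template, ``n_build_total / n_templates`` (at least ``n_build_min``)
    refined builds are generated from distinct seed streams; the best per
    template is kept, and remaining slots up to ``n_models`` are filled with
    the next-best builds across all templates.
    """
    if not selected:
        raise ValueError("no templates selected")
    cfg = cfg or ModelingConfig()
    n_build = max(cfg.n_build_min, cfg.n_build_total // len(selected))

    per_template: list[list[DockModel]] = []
    for t_idx, st in enumerate(selected):
        record = db[st.template_id] if hasattr(db, "__getitem__") else db.index[st.template_id]
        base = build_by_superimposition(target_protein, target_peptide, st, record)
        restraints = derive_restraints(st, record, base, cfg)
        builds = []
        for b in range(n_build):
            seed = _build_seed(master_seed, t_idx, b)
            builds.append(refine(base, restraints, cfg, seed))
        builds.sort(key=lambda m: m.total_energy)
        per_template.append(builds)

    chosen = [builds[0] for builds in per_template]
    extras = [m for builds in per_template for m in builds[1:]]
    extras.sort(key=lambda m: m.total_energy)
    chosen.extend(extras[:max(0, n_models - len(chosen))])
    chosen.sort(key=lambda m: m.total_energy)
    return chosen[:n_models]
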