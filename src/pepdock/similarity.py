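"""Interaction-similarity scoring and template ranking.

The score ranking database complexes for a query is

    S_complex = Z_TM + Z_Inter,

where Z_TM is the database Z-score of the protein TM-score (template
aligned onto the target) and Z_Inter the Z-score of the interaction
similarity S_Inter. S_Inter sums, over every protein-peptide residue pair
(i - j) in contact in the template complex, the swap-tolerant BLOSUM62
pair similarity of the template pair and the target pair (i' - j')
aligned to it:

    S_{i-j} = max[ B(i,i') + B(j,j'),  B(i,j') + B(j,i') ].

The peptide is aligned to the template peptide by gapless alignment with
a contact-weighted BLOSUM62 score: positive matrix entries at template
position j are multiplied by (1 + number of hydrophobic or ionic protein
residues contacting j in the template complex), which emphasises hot-spot
positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from . import config
from .contacts import ContactClass, ContactMap, ResidueClass, residue_class
from .struct_align import StructAlignment, align_structures
from .structure_io import PeptideSequence, Structure

logger = logging.getLogger(__name__)

STANDARD_AAS = "ARNDCQEGHILKMFPSTWYV"


class SubstitutionMatrix:
    """20x20 integer substitution table over the standard amino acids.

    Wraps the canonical published BLOSUM62; symmetry and the familiar
    diagonal values are validated at construction. Lookups for 'X' or other
    non-standard letters return 0 (neutral).
    """

    def __init__(self, name: str = "BLOSUM62"):
        mat = substitution_matrices.load(name)
        self._table: dict[tuple[str, str], int] = {}
        for a in STANDARD_AAS:
            for b in STANDARD_AAS:
                self._table[(a, b)] = int(mat[a][b])
        for a in STANDARD_AAS:
            for b in STANDARD_AAS:
                if self._table[(a, b)] != self._table[(b, a)]:
                    raise ValueError("substitution matrix is not symmetric")
        if name == "BLOSUM62":
            if self._table[("C", "C")] != 9 or any(
                    self._table[(a, a)] < 4 for a in STANDARD_AAS):
                raise ValueError("unexpected BLOSUM62 diagonal")

    def __call__(self, a: str, b: str) -> int:
        return self._table.get((a, b), 0)


_DEFAULT_MATRIX: SubstitutionMatrix | None = None


def blosum62() -> SubstitutionMatrix:
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        _DEFAULT_MATRIX = SubstitutionMatrix()
    return _DEFAULT_MATRIX


@dataclass
class PeptideAlignment:
    """Gapless target-onto-template peptide alignment.

    ``offset`` is the position of the target sequence start relative to the
    template peptide start; ``pairs`` holds (target_pos, template_pos) along
    a single diagonal.
    """

    offset: int
    pairs: list[tuple[int, int]]
    score: float

    def template_to_target(self) -> dict[int, int]:
        return {tpl: tgt for tgt, tpl in self.pairs}


@dataclass
class ScoredTemplate:
    template_id: str
    tm_score: float
    s_inter: float
    z_tm: float
    z_inter: float
    s_complex: float
    n_template_contacts: int
    pair_scores: list[tuple[int, int, int]]  # (protein_res, peptide_res, S_ij)
    struct_alignment: StructAlignment
    peptide_alignment: PeptideAlignment
    skipped_pairs: int = 0

    @property
    def s_inter_normalized(self) -> float:
        """S_Inter per template contact pair (the accuracy-model feature)."""
        if self.n_template_contacts == 0:
            return 0.0
        return self.s_inter / self.n_template_contacts


def peptide_position_weight(template_peptide_res: int, cm: ContactMap) -> int:
    """1 + number of hydrophobic/ionic protein residues contacting position j.

    Only hydrophobic and ionic contacts count, and only protein residues
    that are themselves hydrophobic, acidic or basic; generic contacts do
    not contribute.
    """
    partners = {
        c.protein_index for c in cm
        if c.peptide_index == template_peptide_res
        and c.contact_class in (ContactClass.HYDROPHOBIC, ContactClass.IONIC)
    }
    return 1 + len(partners)


def align_peptide(target: PeptideSequence, template_peptide: str,
                  cm: ContactMap, B: SubstitutionMatrix | None = None,
                  weights: list[int] | None = None) -> PeptideAlignment:
    """Best gapless alignment of the target peptide onto the template peptide.

    All offsets with overlap >= min(3, shorter length) are enumerated;
    positive BLOSUM62 entries are multiplied by the template-position
    contact weight; ties go to the smallest offset.
    """
    B = B or blosum62()
    tgt = target.sequence
    tpl = template_peptide
    n, m = len(tgt), len(tpl)
    if n == 0 or m == 0:
        raise ValueError("empty sequence")
    if weights is None:
        weights = [peptide_position_weight(j, cm) for j in range(m)]
    min_overlap = min(3, n, m)

    best: PeptideAlignment | None = None
    for offset in range(-(n - min_overlap), m - min_overlap + 1):
        lo = max(0, offset)
        hi = min(m, offset + n)
        if hi - lo < min_overlap:
            continue
        score = 0.0
        pairs = []
        for j in range(lo, hi):
            t_pos = j - offset
            b = B(tgt[t_pos], tpl[j])
            score += weights[j] * b if b > 0 else b
            pairs.append((t_pos, j))
        if best is None or score > best.score:
            best = PeptideAlignment(offset, pairs, score)
    if best is None:
        raise ValueError("no gapless offset with sufficient overlap")
    return best


def pair_similarity(i: str, j: str, i_prime: str, j_prime: str,
                    B: SubstitutionMatrix | None = None) -> int:
    """Swap-tolerant similarity of template contact pair (i-j) to (i'-j')."""
    B = B or blosum62()
    return max(B(i, i_prime) + B(j, j_prime), B(i, j_prime) + B(j, i_prime))


def interaction_similarity(template, sa: StructAlignment, pa: PeptideAlignment,
                           target_protein: Structure,
                           target_peptide: PeptideSequence,
                           B: SubstitutionMatrix | None = None):
    """S_Inter: summed pair similarity over the template's contact pairs.

    Contact pairs whose protein residue is not structurally aligned or whose
    peptide position falls outside the gapless peptide alignment contribute
    nothing and are counted as skipped.

    ``template`` is a ComplexRecord (protein, peptide sequence, contact map).
    """
    B = B or blosum62()
    tpl_to_tgt_prot = sa.template_to_target()
    tpl_to_tgt_pep = pa.template_to_target()
    tgt_res = target_protein.residues
    tpl_res = template.protein.residues

    s_inter = 0
    pair_scores = []
    skipped = 0
    for c in template.contact_map:
        i, j = c.protein_index, c.peptide_index
        if i not in tpl_to_tgt_prot or j not in tpl_to_tgt_pep:
            skipped += 1
            continue
        aa_i = tpl_res[i].aa_1letter
        aa_j = template.peptide_sequence[j]
        aa_ip = tgt_res[tpl_to_tgt_prot[i]].aa_1letter
        aa_jp = target_peptide.sequence[tpl_to_tgt_pep[j]]
        s = pair_similarity(aa_i, aa_j, aa_ip, aa_jp, B)
        s_inter += s
        pair_scores.append((i, j, s))
    return float(s_inter), pair_scores, skipped


def zscores(values: list[float]) -> list[float]:
    """Population Z-scores; an all-equal list maps to all zeros."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for Z-scores")
    std = v.std()  # population (n-denominator)
    # Values identical to within rounding follow the all-equal convention.
    if std <= 1e-12 * max(1.0, float(np.abs(v).max())):
        return [0.0] * v.size
    return list((v - v.mean()) / std)


def rank_templates(db, target_protein: Structure,
                   target_peptide: PeptideSequence,
                   B: SubstitutionMatrix | None = None) -> list[ScoredTemplate]:
    """Score every database complex against the query and sort by S_complex.

    ``db`` is a TemplateDB or a list of ComplexRecords. With a single-entry
    database Z-scores are degenerate; ranking falls back to raw TM-score
    plus per-contact-normalized S_Inter (logged).
    """
    records = list(db.records) if hasattr(db, "records") else list(db)
    if not records:
        raise ValueError("template database is empty")
    B = B or blosum62()

    rows = []
    for rec in records:
        sa = align_structures(target_protein, rec.protein)
        pa = align_peptide(target_peptide, rec.peptide_sequence, rec.contact_map, B)
        s_inter, pair_scores, skipped = interaction_similarity(
            rec, sa, pa, target_protein, target_peptide, B)
        rows.append((rec, sa, pa, s_inter, pair_scores, skipped))

    tms = [r[1].tm_score_target for r in rows]
    sis = [r[3] for r in rows]
    if len(rows) >= 2:
        z_tm = zscores(tms)
        z_si = zscores(sis)
    else:
        logger.warning("single-entry database: ranking by raw scores, not Z-scores")
        rec = rows[0][0]
        n_c = max(1, len(rec.contact_map))
        z_tm = [tms[0]]
        z_si = [sis[0] / n_c]

    scored = []
    for (rec, sa, pa, s_inter, pair_scores, skipped), zt, zi in zip(rows, z_tm, z_si):
        scored.append(ScoredTemplate(
            template_id=rec.id, tm_score=sa.tm_score_target, s_inter=s_inter,
            z_tm=float(zt), z_inter=float(zi), s_complex=float(zt) + float(zi),
            n_template_contacts=len(rec.contact_map), pair_scores=pair_scores,
            struct_alignment=sa, peptide_alignment=pa, skipped_pairs=skipped))
    scored.sort(key=lambda s: (-s.s_complex, -s.tm_score, s.template_id))
    return scored


def select_templates(ranked: list[ScoredTemplate],
                     max_templates: int = 10,
                     fraction: float = config.SELECTION_FRACTION) -> list[ScoredTemplate]:
    """Keep up to ``max_templates`` entries with S_complex > fraction * max.

    When the maximum S_complex is not positive the 90%-of-maximum rule is
    ill-defined, so only the top-ranked entry is kept.
    """
    if not ranked:
        return []
    smax = ranked[0].s_complex
    if smax <= 0:
        return ranked[:1]
    selected = [s for s in ranked if s.s_complex > fraction * smax]
    return selected[:max_templates]
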