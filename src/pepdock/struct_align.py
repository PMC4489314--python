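"""Rigid superposition and TM-score based protein structure alignment.

``kabsch_superpose`` is the least-squares rigid fit (proper rotations
only). ``tm_score`` implements the length-normalized similarity score

    TM = (1/L_norm) * sum_i 1 / (1 + (d_i/d0)^2),
    d0 = 1.24 * (L_norm - 15)^(1/3) - 1.8   (floored at 0.5 A),

maximized over superpositions by the standard iterative-subset search.
``align_structures`` produces a sequential residue correspondence between
two protein structures by iterating seed superpositions, distance-matrix
dynamic programming, and re-superposition — the scheme popularized by
TM-align. Scores are normalized by the TARGET length so that database
templates are ranked on a common scale for a fixed query.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structure_io import Structure


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class StructAlignment:
    """Sequential residue correspondence target<->template with transform.

    ``rotation``/``translation`` map TEMPLATE coordinates into the target
    frame. ``pairs`` holds (target_index, template_index), strictly
    increasing in both columns.
    """

    pairs: list[tuple[int, int]]
    rotation: np.ndarray
    translation: np.ndarray
    tm_score_target: float
    per_pair_distance: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def aligned_length(self) -> int:
        return len(self.pairs)

    def template_to_target(self) -> dict[int, int]:
        return {tpl: tgt for tgt, tpl in self.pairs}

    def target_to_template(self) -> dict[int, int]:
        return dict(self.pairs)

    def to_json_dict(self) -> dict:
        return {
            "pairs": [list(p) for p in self.pairs],
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "tm_score_target": self.tm_score_target,
        }


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares proper-rotation superposition of B onto A."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be n x 3")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    with warnings.catch_warnings():
        # Near-collinear subsets trigger a scipy degeneracy warning; the
        # returned minimizer is still valid for our purposes.
        warnings.simplefilter("ignore", UserWarning)
        rot, rssd = Rotation.align_vectors(a - cen_a, b - cen_b)
    R = rot.as_matrix()
    t = cen_a - R @ cen_b
    rmsd = float(rssd / np.sqrt(n))
    return SuperpositionResult(R, t, rmsd)


def tm_d0(l_norm: int) -> float:
    """Distance scale of the TM-score for normalization length ``l_norm``."""
    if l_norm <= 21:
        return 0.5
    return max(0.5, 1.24 * (l_norm - 15) ** (1.0 / 3.0) - 1.8)


def _tm_sum(d2: np.ndarray, d0: float) -> float:
    return float(np.sum(1.0 / (1.0 + d2 / (d0 * d0))))


def tm_score(aligned_target: np.ndarray, aligned_template: np.ndarray,
             l_norm: int, return_transform: bool = False):
    """TM-score of an aligned coordinate pair, maximized over superpositions.

    The optimizing transform is searched by the standard scheme: seed
    superpositions on contiguous fragments of several lengths, then
    iteratively re-superpose on the subset of pairs closer than a shrinking
    inclusion cutoff, keeping the best score seen.
    """
    a = np.asarray(aligned_target, float)
    b = np.asarray(aligned_template, float)
    n = a.shape[0]
    if l_norm < n:
        raise ValueError("L_norm must be >= number of aligned pairs")
    if l_norm < 1:
        raise ValueError("L_norm must be >= 1")
    d0 = tm_d0(l_norm)

    best = (-1.0, None)
    frag_lens = {n, max(3, n // 2), max(3, n // 4)}
    starts_of = lambda L: range(0, n - L + 1, max(1, (n - L) // 8 + 1))
    for L in sorted(frag_lens, reverse=True):
        if L > n:
            continue
        for s in starts_of(L):
            idx = np.arange(s, s + L)
            sup = kabsch_superpose(a[idx], b[idx])
            for _ in range(20):
                moved = sup.apply(b)
                d2 = np.sum((moved - a) ** 2, axis=1)
                score = _tm_sum(d2, d0) / l_norm
                if score > best[0]:
                    best = (score, sup)
                # Re-superpose on pairs within an inclusion cutoff.
                for cut in (d0 + 1.5, d0 + 0.5, d0):
                    sel = d2 <= cut * cut
                    if sel.sum() >= 3:
                        break
                else:
                    break
                new_sup = kabsch_superpose(a[sel], b[sel])
                if np.allclose(new_sup.rotation, sup.rotation, atol=1e-10) and \
                   np.allclose(new_sup.translation, sup.translation, atol=1e-10):
                    break
                sup = new_sup
    score, sup = best
    if return_transform:
        return score, sup
    return score


def _tm_from_pairs(a: np.ndarray, b: np.ndarray, l_norm: int,
                   ) -> tuple[float, SuperpositionResult]:
    """Cheap TM-score refinement: full-set superposition followed by
    iterative subset re-superposition (no fragment seeding)."""
    d0 = tm_d0(l_norm)
    sup = kabsch_superpose(a, b)
    best_score = -1.0
    best_sup = sup
    for _ in range(10):
        moved = sup.apply(b)
        d2 = np.sum((moved - a) ** 2, axis=1)
        score = _tm_sum(d2, d0) / l_norm
        if score > best_score:
            best_score, best_sup = score, sup
        for cut in (d0 + 1.5, d0 + 0.5, d0):
            sel = d2 <= cut * cut
            if sel.sum() >= 3:
                break
        else:
            break
        new_sup = kabsch_superpose(a[sel], b[sel])
        if np.allclose(new_sup.rotation, sup.rotation, atol=1e-10) and \
           np.allclose(new_sup.translation, sup.translation, atol=1e-10):
            break
        sup = new_sup
    return best_score, best_sup


try:
    from numba import njit

    @njit(cache=True)
    def _dp_tables(score_mat):  # pragma: no cover - jitted
        n, m = score_mat.shape
        H = np.zeros((n + 1, m + 1))
        ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                diag = H[i - 1, j - 1] + score_mat[i - 1, j - 1]
                up = H[i - 1, j]
                left = H[i, j - 1]
                if diag >= up and diag >= left:
                    H[i, j] = diag
                    ptr[i, j] = 1
                elif up >= left:
                    H[i, j] = up
                    ptr[i, j] = 2
                else:
                    H[i, j] = left
                    ptr[i, j] = 3
        return H, ptr
except ImportError:  # pragma: no cover
    def _dp_tables(score_mat):
        n, m = score_mat.shape
        H = np.zeros((n + 1, m + 1))
        ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                diag = H[i - 1, j - 1] + score_mat[i - 1, j - 1]
                up = H[i - 1, j]
                left = H[i, j - 1]
                if diag >= up and diag >= left:
                    H[i, j] = diag
                    ptr[i, j] = 1
                elif up >= left:
                    H[i, j] = up
                    ptr[i, j] = 2
                else:
                    H[i, j] = left
                    ptr[i, j] = 3
        return H, ptr


def _dp_align(score_mat: np.ndarray) -> list[tuple[int, int]]:
    """Global sequential alignment with zero gap penalty (monotone pairing)."""
    n, m = score_mat.shape
    H, ptr = _dp_tables(np.ascontiguousarray(score_mat))
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        p = ptr[i, j]
        if p == 1:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def _seed_pairings(n: int, m: int) -> list[list[tuple[int, int]]]:
    seeds = []
    # Gapless diagonal offsets, strided to keep the seed count modest.
    min_overlap = max(5, min(n, m) // 2)
    offsets = range(-(m - min_overlap), n - min_overlap + 1)
    stride = max(1, len(offsets) // 40)
    for off in list(offsets)[::stride]:
        pairs = [(i, i - off) for i in range(max(0, off), min(n, m + off))]
        if len(pairs) >= 5:
            seeds.append(pairs)
    # Full-length stretch seed mapping the chains end to end.
    if n >= 5 and m >= 5:
        seeds.append([(i, int(round(i * (m - 1) / (n - 1)))) for i in range(n)])
    return seeds


def align_structures(target: Structure, template: Structure,
                     max_iter: int = 30) -> StructAlignment:
    """Sequential CA-based structure alignment of a template onto a target.

    Iterates superposition -> distance-matrix dynamic programming ->
    re-superposition from multiple seeds and reports the correspondence
    with the best target-normalized TM-score.
    """
    idx_t, ca_t = _ca_with_indices(target)
    idx_p, ca_p = _ca_with_indices(template)
    n, m = len(ca_t), len(ca_p)
    if n < 5 or m < 5:
        raise ValueError("both structures need at least 5 CA atoms")
    d0 = tm_d0(n)

    best_score = -1.0
    best_pairs: list[tuple[int, int]] = []
    best_sup: SuperpositionResult | None = None

    for seed in _seed_pairings(n, m):
        pairs = seed
        prev_pairs: list[tuple[int, int]] = []
        for _ in range(max_iter):
            if len(pairs) < 3:
                break
            ti = np.array([p[0] for p in pairs])
            pi = np.array([p[1] for p in pairs])
            score, sup = _tm_from_pairs(ca_t[ti], ca_p[pi], n)
            if score > best_score:
                best_score, best_pairs, best_sup = score, pairs, sup
            moved = sup.apply(ca_p)
            dmat2 = cdist(ca_t, moved, "sqeuclidean")
            score_mat = 1.0 / (1.0 + dmat2 / (d0 * d0))
            new_pairs = _dp_align(score_mat)
            if new_pairs == pairs or new_pairs == prev_pairs:
                break
            prev_pairs = pairs
            pairs = new_pairs

    # Polish the best correspondence with the thorough fragment-seeded search.
    ti = np.array([p[0] for p in best_pairs])
    pi = np.array([p[1] for p in best_pairs])
    score, sup = tm_score(ca_t[ti], ca_p[pi], n, return_transform=True)
    if score > best_score:
        best_score, best_sup = score, sup

    assert best_sup is not None
    moved = best_sup.apply(ca_p)
    per_pair = np.array([np.linalg.norm(ca_t[i] - moved[j]) for i, j in best_pairs])
    # Map CA-array positions back to residue indices in the structures.
    res_pairs = [(int(idx_t[i]), int(idx_p[j])) for i, j in best_pairs]
    return StructAlignment(res_pairs, best_sup.rotation, best_sup.translation,
                           best_score, per_pair)


def _ca_with_indices(s: Structure) -> tuple[np.ndarray, np.ndarray]:
    idx, coords = [], []
    for i, r in enumerate(s.residues):
        c = r.atom_coord("CA")
        if c is not None:
            idx.append(i)
            coords.append(c)
    return np.array(idx, dtype=int), np.array(coords, dtype=float)
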