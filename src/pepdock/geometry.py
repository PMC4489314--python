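"""Ideal-geometry peptide chain construction (internal helper).

Atoms are placed by the standard internal-coordinate (NeRF) construction
using ideal bond lengths and angles: N-CA 1.458 A, CA-C 1.525 A, C-N
1.329 A, C=O 1.231 A, CA-CB 1.530 A, backbone angles ~111/117/121 deg and
trans peptide bonds. Used for extended-overhang building, ideal CB
placement after side-chain mutation, and the synthetic fixture generator.
"""

from __future__ import annotations

import numpy as np

from .structure_io import AA_1TO3, Residue, Structure

BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530

ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 117.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5

HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-120.0, 120.0)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given positions A-B-C, |CD|, angle(BCD) and dihedral(ABCD)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """CB at ideal tetrahedral geometry from the backbone N, CA, C atoms."""
    return place_atom(n, c, ca, BOND_CA_CB, 110.1, 122.6)


def build_chain(sequence: str, phi_psi: list[tuple[float, float]] | tuple[float, float],
                chain_id: str = "A", start_number: int = 1,
                origin: np.ndarray | None = None,
                rotation: np.ndarray | None = None,
                translation: np.ndarray | None = None) -> Structure:
    """Build a polypeptide with ideal covalent geometry and given phi/psi.

    ``phi_psi`` is either one (phi, psi) pair applied to every residue or a
    per-residue list. CB atoms are added for all residues except glycine.
    An optional rigid transform places the finished chain.
    """
    nres = len(sequence)
    if isinstance(phi_psi, tuple):
        phi_psi = [phi_psi] * nres
    if len(phi_psi) != nres:
        raise ValueError("phi_psi length mismatch")

    # Seed the first residue near the origin.
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    backbone = [(n0, ca0, c0)]
    for i in range(1, nres):
        n_prev, ca_prev, c_prev = backbone[-1]
        psi_prev = phi_psi[i - 1][1]
        phi = phi_psi[i][0]
        n_i = place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = place_atom(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        c_i = place_atom(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        backbone.append((n_i, ca_i, c_i))

    residues = []
    for i, aa in enumerate(sequence):
        n_i, ca_i, c_i = backbone[i]
        if i + 1 < nres:
            n_next = backbone[i + 1][0]
            o_i = place_atom(ca_i, n_next, c_i, BOND_C_O, ANGLE_CA_C_O, 180.0)
        else:
            o_i = place_atom(n_i, ca_i, c_i, BOND_C_O, ANGLE_CA_C_O, phi_psi[i][1])
        names = ["N", "CA", "C", "O"]
        coords = [n_i, ca_i, c_i, o_i]
        if aa != "G":
            names.append("CB")
            coords.append(ideal_cb(n_i, ca_i, c_i))
        residues.append(Residue(AA_1TO3[aa], aa, chain_id, start_number + i,
                                "", names, np.array(coords)))
    s = Structure([(chain_id, residues)])
    if origin is not None:
        translation = np.asarray(origin, float)
    if rotation is not None or translation is not None:
        R = rotation if rotation is not None else np.eye(3)
        t = translation if translation is not None else np.zeros(3)
        s = s.transformed(np.asarray(R, float), np.asarray(t, float))
    return s


def extend_residue(prev_n: np.ndarray, prev_ca: np.ndarray, prev_c: np.ndarray,
                   aa: str, phi: float, psi: float, psi_prev: float,
                   chain_id: str, number: int) -> tuple[Residue, tuple]:
    """Append one residue after a residue with backbone (N, CA, C)."""
    n_i = place_atom(prev_n, prev_ca, prev_c, BOND_C_N, ANGLE_CA_C_N, psi_prev)
    ca_i = place_atom(prev_ca, prev_c, n_i, BOND_N_CA, ANGLE_C_N_CA, 180.0)
    c_i = place_atom(prev_c, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
    o_i = place_atom(n_i, ca_i, c_i, BOND_C_O, ANGLE_CA_C_O, psi)
    names = ["N", "CA", "C", "O"]
    coords = [n_i, ca_i, c_i, o_i]
    if aa != "G":
        names.append("CB")
        coords.append(ideal_cb(n_i, ca_i, c_i))
    res = Residue(AA_1TO3[aa], aa, chain_id, number, "", names, np.array(coords))
    return res, (n_i, ca_i, c_i)


def prepend_residue(next_n: np.ndarray, next_ca: np.ndarray, next_c: np.ndarray,
                    aa: str, phi_next: float, psi: float,
                    chain_id: str, number: int) -> tuple[Residue, tuple]:
    """Prepend one residue before a residue with backbone (N, CA, C).

    Mirror construction of :func:`extend_residue`, walking N-terminally.
    """
    c_i = place_atom(next_c, next_ca, next_n, BOND_C_N, ANGLE_C_N_CA, phi_next)
    ca_i = place_atom(next_ca, next_n, c_i, BOND_CA_C, ANGLE_CA_C_N, 180.0)
    n_i = place_atom(next_n, c_i, ca_i, BOND_N_CA, ANGLE_N_CA_C, psi)
    o_i = place_atom(n_i, ca_i, c_i, BOND_C_O, ANGLE_CA_C_O, psi)
    names = ["N", "CA", "C", "O"]
    coords = [n_i, ca_i, c_i, o_i]
    if aa != "G":
        names.append("CB")
        coords.append(ideal_cb(n_i, ca_i, c_i))
    res = Residue(AA_1TO3[aa], aa, chain_id, number, "", names, np.array(coords))
    return res, (n_i, ca_i, c_i)


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    from scipy.spatial.transform import Rotation
    return Rotation.from_rotvec(axis * angle_rad).as_matrix()
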