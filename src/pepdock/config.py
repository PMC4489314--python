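"""Package-wide tunable parameters.

All distance cutoffs are in angstroms. The contact cutoffs follow the
PepBind convention (hydrophobic pairs within 5.0 A, ionic pairs within
6.0 A); the generic 4.5 A class is this package's addition so that polar
contacts can also seed interaction pairs and restraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field


# Residue classification used by the contact criterion. The hydrophobic /
# acidic / basic memberships are the conventional ones; His is treated as
# basic (protonatable) for the ionic cutoff.
HYDROPHOBIC_SET = frozenset("AVLIMFWP")
ACIDIC_SET = frozenset("DE")
BASIC_SET = frozenset("KRH")


@dataclass
class ContactConfig:
    hydrophobic_cutoff: float = 5.0
    ionic_cutoff: float = 6.0
    generic_cutoff: float = 4.5


@dataclass
class RefineConfig:
    n_starts: int = 2
    max_iter: int = 150
    step: float = 0.4          # rigid translation step scale, A
    rot_step: float = 8.0      # rigid rotation step scale, degrees
    dihedral_step: float = 10.0  # backbone dihedral perturbation, degrees


@dataclass
class ModelingConfig:
    w0: float = 1.0            # restraint weight scale
    flat_width: float = 1.0    # flat-bottom half width, A
    d_min: float = 2.8         # clash onset distance, A
    k_clash: float = 10.0      # clash force constant, per A^2
    n_build_total: int = 50    # builds distributed across templates
    n_build_min: int = 5       # minimum builds per template
    refine: RefineConfig = field(default_factory=RefineConfig)


#: Query size limits enforced by the pipeline (residues).
MAX_PROTEIN_LENGTH = 900
MAX_PEPTIDE_LENGTH = 30

#: Number of models returned by default.
N_OUTPUT_MODELS = 10

#: Template selection keeps entries scoring above this fraction of the maximum.
SELECTION_FRACTION = 0.9
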