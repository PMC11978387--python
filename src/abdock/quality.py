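"""DockQ-style quality scoring of docked poses against a native complex.

A pose is compared with the native structure through three components:

* ``fnat`` — fraction of native cross-interface residue contacts (any
  heavy-atom pair within 5 Å) preserved by the pose;
* ``irms`` — backbone RMSD over the native interface residues (any
  cross-interface heavy-atom pair within 10 Å) after best-fitting the pose
  interface onto the native interface;
* ``lrms`` — ligand (antigen) backbone RMSD after best-fitting the pose on
  the receptor (antibody) backbone.

They combine into DockQ = (fnat + 1/(1+(irms/1.5)^2) + 1/(1+(lrms/8.5)^2))/3
and map to the application-specific quality classes: acceptable at
DockQ >= 0.23 (epitope mapping), medium at >= 0.49 (antibody design) and
high at >= 0.80.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import CorrespondenceError
from .structures import (
    ANTIBODY_ROLES,
    ComplexModel,
    ResidueId,
    region_rmsd,
    superpose,
)

CONTACT_CUTOFF = 5.0
INTERFACE_CUTOFF = 10.0
D1_IRMS = 1.5
D2_LRMS = 8.5

THRESHOLD_ACCEPTABLE = 0.23
THRESHOLD_MEDIUM = 0.49
THRESHOLD_HIGH = 0.80


@dataclass
class PoseQuality:
    """DockQ components and quality class for one pose."""

    fnat: float
    irms: float
    lrms: float
    dockq: float
    quality_class: str

    def to_row(self) -> dict[str, float | str]:
        return {
            "fnat": self.fnat,
            "irms": self.irms,
            "lrms": self.lrms,
            "dockq": self.dockq,
            "quality_class": self.quality_class,
        }


def quality_class(dockq: float) -> str:
    if dockq >= THRESHOLD_HIGH:
        return "high"
    if dockq >= THRESHOLD_MEDIUM:
        return "medium"
    if dockq >= THRESHOLD_ACCEPTABLE:
        return "acceptable"
    return "incorrect"


def _cross_pairs(
    model: ComplexModel, cutoff: float
) -> set[tuple[ResidueId, ResidueId]]:
    ab = model.select_atoms(roles=ANTIBODY_ROLES, atom_subset="heavy")
    ag = model.select_atoms(roles="antigen", atom_subset="heavy")
    if not ab or not ag:
        raise CorrespondenceError("model needs antibody and antigen chains")
    tree = cKDTree(np.array([a.coordinates for a in ag]))
    pairs: set[tuple[ResidueId, ResidueId]] = set()
    for a, hits in zip(
        ab, tree.query_ball_point(np.array([a.coordinates for a in ab]), cutoff)
    ):
        for j in hits:
            pairs.add((a.residue_id, ag[j].residue_id))
    return pairs


def native_contacts(
    native: ComplexModel, cutoff: float = CONTACT_CUTOFF
) -> set[tuple[ResidueId, ResidueId]]:
    """Cross-interface residue pairs with any heavy-atom contact <= cutoff."""
    pairs = _cross_pairs(native, cutoff)
    if not pairs:
        warnings.warn("native complex has no cross-interface contacts")
    return pairs


def dockq_from_components(fnat: float, irms: float, lrms: float) -> float:
    """Closed-form DockQ from its three components."""
    return (
        fnat
        + 1.0 / (1.0 + (irms / D1_IRMS) ** 2)
        + 1.0 / (1.0 + (lrms / D2_LRMS) ** 2)
    ) / 3.0


def dockq_score(pose: ComplexModel, native: ComplexModel) -> PoseQuality:
    """Score a docked pose against the native complex.

    Pose and native must share residue numbering per chain role; a
    mismatch raises :class:`CorrespondenceError`.  Multi-chain antigens are
    treated as a single rigid ligand body.
    """
    native_pairs = native_contacts(native)
    pose_pairs = _cross_pairs(pose, CONTACT_CUTOFF)
    fnat = (
        len(native_pairs & pose_pairs) / len(native_pairs) if native_pairs else 0.0
    )

    iface_pairs = _cross_pairs(native, INTERFACE_CUTOFF)
    iface_res = sorted({r for pair in iface_pairs for r in pair})
    if not iface_res:
        raise CorrespondenceError("native complex has no interface residues")
    _, irms = superpose(pose, native, iface_res, atom_subset="backbone")

    receptor = native.residue_ids(roles=ANTIBODY_ROLES)
    ligand = native.residue_ids(roles="antigen")
    lrms = region_rmsd(pose, native, ligand, receptor, atom_subset="backbone")

    dq = dockq_from_components(fnat, irms, lrms)
    return PoseQuality(
        fnat=fnat, irms=irms, lrms=lrms, dockq=dq, quality_class=quality_class(dq)
    )
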