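"""Structure parsing, chain-role typing, CDR annotation and RMSD diagnostics.

The central container is :class:`ComplexModel`, a flat list of atom records
plus a ``chain_id -> role`` map with roles drawn from ``{"heavy", "light",
"antigen"}``.  Antibody Fv regions are annotated with Chothia-style CDR
windows, and the superposition machinery (closed-form Kabsch fit) supports
the free-/bound-RMSD ensemble diagnostics: framework-fitted RMSD over CDR
loops, averaged pairwise over a free-antibody ensemble or measured against
an antigen-bound reference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .errors import (
    AnnotationError,
    CorrespondenceError,
    DegeneracyError,
    ParseError,
    RoleAssignmentError,
)

#: Residue identity within a model: (chain_id, residue_number, insertion_code).
ResidueId = tuple[str, int, str]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

ROLES = ("heavy", "light", "antigen")
ANTIBODY_ROLES = ("heavy", "light")

#: Chothia CDR windows by chain role (inclusive residue-number ranges).
CHOTHIA_CDR_WINDOWS: dict[str, dict[str, tuple[int, int]]] = {
    "heavy": {"CDR-H1": (26, 32), "CDR-H2": (52, 56), "CDR-H3": (95, 102)},
    "light": {"CDR-L1": (24, 34), "CDR-L2": (50, 56), "CDR-L3": (89, 97)},
}

CDR_SCHEMES = {"chothia": CHOTHIA_CDR_WINDOWS}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a parsed model (author numbering preserved)."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    coordinates: tuple[float, float, float]
    b_factor: float = 0.0

    @property
    def residue_id(self) -> ResidueId:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class ComplexModel:
    """A parsed antibody(-antigen) structure with typed chains."""

    atoms: list[AtomRecord]
    chain_roles: dict[str, str]
    model_id: str = "model"
    source_tool: str | None = None

    def __post_init__(self) -> None:
        missing = {a.chain_id for a in self.atoms} - set(self.chain_roles)
        if missing:
            raise RoleAssignmentError(
                f"atoms reference chains without a role: {sorted(missing)}"
            )
        bad = set(self.chain_roles.values()) - set(ROLES)
        if bad:
            raise RoleAssignmentError(f"unknown chain roles: {sorted(bad)}")
        if not any(r in ANTIBODY_ROLES for r in self.chain_roles.values()):
            raise RoleAssignmentError("model has no antibody (heavy/light) chain")
        for a in self.atoms:
            if not np.all(np.isfinite(a.coordinates)):
                raise ParseError(f"non-finite coordinates on atom {a}")

    # -- selection helpers -------------------------------------------------

    def chains_with_role(self, roles: str | Iterable[str]) -> list[str]:
        if isinstance(roles, str):
            roles = (roles,)
        roles = set(roles)
        return [c for c, r in self.chain_roles.items() if r in roles]

    def residue_ids(self, roles: str | Iterable[str] | None = None) -> list[ResidueId]:
        """Ordered unique residue ids, optionally restricted to chain roles."""
        chains = None if roles is None else set(self.chains_with_role(roles))
        seen: dict[ResidueId, None] = {}
        for a in self.atoms:
            if chains is None or a.chain_id in chains:
                seen.setdefault(a.residue_id, None)
        return list(seen)

    def residue_names(self) -> dict[ResidueId, str]:
        names: dict[ResidueId, str] = {}
        for a in self.atoms:
            names.setdefault(a.residue_id, a.residue_name)
        return names

    def select_atoms(
        self,
        residue_ids: Iterable[ResidueId] | None = None,
        atom_subset: str = "all",
        roles: str | Iterable[str] | None = None,
    ) -> list[AtomRecord]:
        """Atoms filtered by residue set, atom subset and/or chain role.

        ``atom_subset`` is one of ``all`` (every atom), ``heavy`` (drop
        hydrogens) or ``backbone`` (N, CA, C, O).
        """
        rset = None if residue_ids is None else set(residue_ids)
        chains = None if roles is None else set(self.chains_with_role(roles))
        out = []
        for a in self.atoms:
            if rset is not None and a.residue_id not in rset:
                continue
            if chains is not None and a.chain_id not in chains:
                continue
            if atom_subset == "backbone" and a.atom_name not in BACKBONE_ATOMS:
                continue
            if atom_subset == "heavy" and a.element.upper() == "H":
                continue
            out.append(a)
        return out

    def coordinates(self, atoms: Sequence[AtomRecord] | None = None) -> np.ndarray:
        atoms = self.atoms if atoms is None else atoms
        if not atoms:
            return np.empty((0, 3))
        return np.array([a.coordinates for a in atoms], dtype=float)

    def transformed(self, transform: "RigidTransform") -> "ComplexModel":
        coords = transform.apply(self.coordinates())
        atoms = [
            replace(a, coordinates=tuple(xyz)) for a, xyz in zip(self.atoms, coords)
        ]
        return replace(self, atoms=atoms)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform ``x -> x @ R.T + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation)


@dataclass
class CdrAnnotation:
    """Framework/CDR partition of an Fv under a numbering scheme."""

    scheme: str
    regions: dict[str, list[ResidueId]]
    h3_length: int

    def cdr_union(self) -> list[ResidueId]:
        out: list[ResidueId] = []
        for name, res in self.regions.items():
            if name.startswith("CDR"):
                out.extend(res)
        return out


@dataclass
class EnsembleRmsdReport:
    """Free-, bound- and best-bound-RMSD per annotated region (Å)."""

    free_rmsd: dict[str, float]
    bound_rmsd: dict[str, list[float]] = field(default_factory=dict)
    best_bound_rmsd: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Reading / writing structures
# ---------------------------------------------------------------------------

def _roles_from_heuristic(chain_ids: Sequence[str]) -> dict[str, str]:
    roles: dict[str, str] = {}
    for cid in chain_ids:
        if cid.upper() == "H":
            roles[cid] = "heavy"
        elif cid.upper() == "L":
            roles[cid] = "light"
        else:
            roles[cid] = "antigen"
    if not any(r in ANTIBODY_ROLES for r in roles.values()):
        raise RoleAssignmentError(
            "cannot infer chain roles from chain ids "
            f"{list(chain_ids)}; pass chain_roles explicitly"
        )
    return roles


def read_structure(
    path: str | Path,
    format: str = "auto",
    chain_roles: Mapping[str, str] | None = None,
    model_id: str | None = None,
) -> ComplexModel:
    """Read the first model of a PDB or mmCIF file into a :class:`ComplexModel`.

    HETATM records and waters are excluded.  For alternate locations the
    highest-occupancy conformer is kept (first on ties).  Chain roles come
    from ``chain_roles`` or, failing that, from a chain-id heuristic
    (H -> heavy, L -> light, others -> antigen).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format in ("mmcif", "cif"):
            doc = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(doc.sole_block())
        elif format == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ParseError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:  # gemmi raises RuntimeError
        raise ParseError(f"failed to parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ParseError(f"{path} contains no models")
    model = st[0]

    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            if residue.is_water() or residue.het_flag == "H":
                continue
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        insertion_code=(residue.seqid.icode or "").strip(),
                        residue_name=residue.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        coordinates=(atom.pos.x, atom.pos.y, atom.pos.z),
                        b_factor=atom.b_iso,
                    )
                )
    if not atoms:
        raise ParseError(f"{path} contains no polymer ATOM records")
    chain_ids = list(dict.fromkeys(a.chain_id for a in atoms))
    roles = dict(chain_roles) if chain_roles else _roles_from_heuristic(chain_ids)
    return ComplexModel(atoms=atoms, chain_roles=roles, model_id=model_id or path.stem)


def _to_gemmi(model: ComplexModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in model.atoms:
        chain = chains.get(a.chain_id)
        if chain is None:
            chain = gemmi.Chain(a.chain_id)
            chains[a.chain_id] = chain
        if (
            len(chain) == 0
            or chain[-1].seqid.num != a.residue_number
            or (chain[-1].seqid.icode or "").strip() != a.insertion_code
        ):
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
            chain.add_residue(res)
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.coordinates)
        atom.b_iso = a.b_factor
        atom.occ = 1.0
        chain[-1].add_atom(atom)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_pdb(model: ComplexModel, path: str | Path) -> None:
    """Write the model as a PDB file (author numbering preserved)."""
    _to_gemmi(model).write_pdb(str(path))


def write_mmcif(model: ComplexModel, path: str | Path) -> None:
    """Write the model as an mmCIF file."""
    st = _to_gemmi(model)
    st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# CDR annotation
# ---------------------------------------------------------------------------

def annotate_cdrs(model: ComplexModel, scheme: str = "chothia") -> CdrAnnotation:
    """Partition the Fv into framework and CDR regions by numbering windows.

    Residues on antibody chains whose author numbers fall inside the
    scheme's published CDR windows are assigned to that loop; everything
    else on antibody chains is framework (``FR``).  Antigen chains are not
    part of the annotation.
    """
    windows = CDR_SCHEMES.get(scheme)
    if windows is None:
        raise AnnotationError(f"unknown numbering scheme {scheme!r}")
    heavy = model.chains_with_role("heavy")
    if not heavy:
        raise AnnotationError("model has no heavy chain to annotate")

    regions: dict[str, list[ResidueId]] = {"FR": []}
    for role in ANTIBODY_ROLES:
        for name in windows.get(role, {}):
            if model.chains_with_role(role):
                regions[name] = []
    for rid in model.residue_ids(roles=ANTIBODY_ROLES):
        chain_id, num, _ = rid
        role = model.chain_roles[chain_id]
        hit = None
        for name, (lo, hi) in windows.get(role, {}).items():
            if lo <= num <= hi:
                hit = name
                break
        regions[hit if hit else "FR"].append(rid)

    if not regions.get("CDR-H3"):
        span = [r[1] for r in model.residue_ids(roles="heavy")]
        raise AnnotationError(
            "heavy-chain numbering inconsistent with scheme "
            f"{scheme!r}: no residues in the CDR-H3 window "
            f"{windows['heavy']['CDR-H3']} (chain spans {min(span)}-{max(span)})"
        )
    return CdrAnnotation(
        scheme=scheme, regions=regions, h3_length=len(regions["CDR-H3"])
    )


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def _matched_coordinates(
    mobile: ComplexModel,
    reference: ComplexModel,
    residue_ids: Iterable[ResidueId],
    atom_subset: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate arrays for atoms shared by both models over a residue set.

    Correspondence is by (residue id, atom name); a residue or atom present
    on one side only raises :class:`CorrespondenceError`.
    """
    rids = list(residue_ids)
    key = lambda a: (a.residue_id, a.atom_name)  # noqa: E731
    mob = {key(a): a for a in mobile.select_atoms(rids, atom_subset)}
    ref = {key(a): a for a in reference.select_atoms(rids, atom_subset)}
    if set(mob) != set(ref):
        diff = sorted(set(mob) ^ set(ref))[:5]
        raise CorrespondenceError(
            f"selections do not match between models (first mismatches: {diff})"
        )
    if not mob:
        raise CorrespondenceError("selection matched no atoms")
    keys = sorted(mob)
    xm = np.array([mob[k].coordinates for k in keys], dtype=float)
    xr = np.array([ref[k].coordinates for k in keys], dtype=float)
    return xm, xr


def kabsch(mobile_xyz: np.ndarray, reference_xyz: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid fit of one point set onto another.

    Returns the proper rotation (det = +1, reflections guarded) and
    translation minimising the RMSD of ``mobile_xyz`` onto
    ``reference_xyz`` under 1:1 row correspondence.
    """
    if mobile_xyz.shape != reference_xyz.shape or mobile_xyz.shape[0] < 3:
        raise DegeneracyError(
            f"need matched point sets of >= 3 atoms, got {mobile_xyz.shape} "
            f"and {reference_xyz.shape}"
        )
    cm = mobile_xyz.mean(axis=0)
    cr = reference_xyz.mean(axis=0)
    am = mobile_xyz - cm
    ar = reference_xyz - cr
    if np.linalg.matrix_rank(am, tol=1e-8) < 2:
        raise DegeneracyError("fit atoms are collinear")
    h = am.T @ ar
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rotation=rot, translation=cr - rot @ cm)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unfitted) RMSD between two matched coordinate arrays."""
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(
    mobile: ComplexModel,
    reference: ComplexModel,
    fit_selection: Iterable[ResidueId],
    atom_subset: str = "backbone",
) -> tuple[RigidTransform, float]:
    """Best-fit rigid superposition over a residue selection.

    Returns the transform taking ``mobile`` onto ``reference`` and the RMSD
    over the fitted atoms.
    """
    xm, xr = _matched_coordinates(mobile, reference, fit_selection, atom_subset)
    tr = kabsch(xm, xr)
    return tr, rmsd(tr.apply(xm), xr)


def region_rmsd(
    model: ComplexModel,
    reference: ComplexModel,
    measure_region: Iterable[ResidueId],
    fit_region: Iterable[ResidueId],
    atom_subset: str = "backbone",
) -> float:
    """RMSD over ``measure_region`` after best-fitting on ``fit_region``.

    The measured region is NOT refit: the transform obtained on the fit
    region (typically the framework) is applied as-is, so the value reports
    how far the measured region (typically a CDR loop) swings relative to
    the fitted frame.
    """
    tr, _ = superpose(model, reference, fit_region, atom_subset)
    xm, xr = _matched_coordinates(model, reference, measure_region, atom_subset)
    return rmsd(tr.apply(xm), xr)


def ensemble_rmsd_report(
    ensemble: Sequence[ComplexModel],
    annotation: CdrAnnotation,
    bound_reference: ComplexModel | None = None,
    fit_region_name: str = "FR",
    atom_subset: str = "backbone",
) -> EnsembleRmsdReport:
    """Free-/bound-RMSD diagnostics for a free-antibody ensemble.

    ``free_rmsd`` averages the framework-fitted region RMSD over all
    unordered model pairs; ``bound_rmsd`` lists per-model deviations to the
    antigen-bound reference and ``best_bound_rmsd`` their minimum.
    Regions measured are every annotated region plus the pooled ``CDR``
    union.
    """
    if len(ensemble) < 2 and bound_reference is None:
        raise DegeneracyError("free-RMSD needs an ensemble of >= 2 models")
    fit = annotation.regions[fit_region_name]
    measured: dict[str, list[ResidueId]] = {
        name: res for name, res in annotation.regions.items()
    }
    measured["CDR"] = annotation.cdr_union()

    free: dict[str, float] = {}
    if len(ensemble) >= 2:
        for name, region in measured.items():
            vals = [
                region_rmsd(a, b, region, fit, atom_subset)
                for a, b in itertools.combinations(ensemble, 2)
            ]
            free[name] = float(np.mean(vals))

    report = EnsembleRmsdReport(free_rmsd=free)
    if bound_reference is not None:
        for name, region in measured.items():
            vals = [
                region_rmsd(m, bound_reference, region, fit, atom_subset)
                for m in ensemble
            ]
            report.bound_rmsd[name] = vals
            report.best_bound_rmsd[name] = float(min(vals))
    return report
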