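"""Antibody-antigen interface property panel.

Implements the per-complex interface descriptors used to contrast
successfully and unsuccessfully docked systems:

* per-residue solvent-accessible surface areas (SASA) in the complexed and
  uncomplexed states (the latter by rigid separation of the two sides),
  expressed relative to fully-exposed reference areas (rSA);
* residue classification into interior / surface / support / rim / core by
  the rSA transitions on binding;
* summed per-residue stickiness (interface propensity) over those regions;
* global density (GD), an atoms-per-area packing proxy over the interface
  atom cloud; and
* a surface-complementarity (SC) index from opposing surface normals on
  tessellated (dot-surface) interface patches.

SASA uses deterministic Shrake-Rupley sphere sampling with a golden-spiral
point set (probe 1.4 Å, 960 points/atom by default), so repeated runs are
bit-identical.  Reference tables (van der Waals radii, fully-exposed
residue areas, stickiness scale) ship as versioned CSV files under
``abdock/data`` and can be swapped by the caller.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import GeometryError, TableError
from .structures import ANTIBODY_ROLES, AtomRecord, ComplexModel, ResidueId

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_SPHERE_POINTS = 960
#: ΔrSA below this (in % points) counts as "no change on binding"; absorbs
#: quadrature noise without misclassifying genuinely buried residues.
DELTA_RSA_TOLERANCE = 1e-6
RSA_THRESHOLD = 25.0

INTERFACE_CLASSES = ("interior", "surface", "support", "rim", "core")


def _load_table(name: str, key: str, value: str) -> dict[str, float]:
    path = resources.files("abdock.data").joinpath(name)
    with path.open() as handle:
        df = pd.read_csv(handle, comment="#")
    return dict(zip(df[key].astype(str), df[value].astype(float)))


@functools.lru_cache(maxsize=None)
def atomic_radii() -> Mapping[str, float]:
    """Packaged van der Waals radii by element symbol (Å)."""
    return _load_table("atomic_radii.csv", "element", "radius")


@functools.lru_cache(maxsize=None)
def max_sasa_reference() -> Mapping[str, float]:
    """Packaged fully-exposed residue reference areas (Å²)."""
    return _load_table("max_sasa.csv", "residue", "max_sasa")


@functools.lru_cache(maxsize=None)
def stickiness_scale() -> Mapping[str, float]:
    """Packaged per-residue stickiness (interface propensity) scale."""
    return _load_table("stickiness.csv", "residue", "stickiness")


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=8)
def unit_sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral quadrature points on the unit sphere."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radii_for(atoms: Sequence[AtomRecord]) -> np.ndarray:
    table = atomic_radii()
    radii = np.empty(len(atoms))
    for k, a in enumerate(atoms):
        r = table.get(a.element.upper())
        if r is None:
            raise TableError(f"no van der Waals radius for element {a.element!r}")
        radii[k] = r
    return radii


def atom_sasa(
    atoms: Sequence[AtomRecord],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> np.ndarray:
    """Shrake-Rupley accessible surface area per atom (Å²).

    Each atom's solvent-expanded sphere (radius + probe) is sampled at
    ``sphere_points`` fixed quadrature points; a point is accessible when it
    lies outside every other atom's expanded sphere.
    """
    coords = np.array([a.coordinates for a in atoms], dtype=float)
    radii = _radii_for(atoms)
    n = len(atoms)
    if n == 0:
        return np.empty(0)
    expanded = radii + probe_radius
    pts = unit_sphere_points(sphere_points)
    tree = cKDTree(coords)
    reach = 2.0 * expanded.max()
    out = np.empty(n)
    for i in range(n):
        neighbours = [j for j in tree.query_ball_point(coords[i], reach)
                      if j != i and np.linalg.norm(coords[j] - coords[i]) < expanded[i] + expanded[j]]
        sphere = coords[i] + expanded[i] * pts
        if neighbours:
            d2 = ((sphere[:, None, :] - coords[neighbours][None, :, :]) ** 2).sum(-1)
            blocked = (d2 < (expanded[neighbours] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - blocked.mean()
        else:
            frac = 1.0
        out[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    return out


def compute_sasa(
    model: ComplexModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> dict[ResidueId, float]:
    """Per-residue SASA (Å²): sum of the residue's atom areas."""
    areas = atom_sasa(model.atoms, probe_radius, sphere_points)
    per_res: dict[ResidueId, float] = {}
    for a, area in zip(model.atoms, areas):
        per_res[a.residue_id] = per_res.get(a.residue_id, 0.0) + float(area)
    return per_res


def relative_sa(
    sa: Mapping[ResidueId, float],
    residue_names: Mapping[ResidueId, str],
    reference: Mapping[str, float] | None = None,
) -> dict[ResidueId, float]:
    """rSA (%) = 100 * SASA / fully-exposed reference for the residue type.

    Values may exceed 100% for chain termini; they are not clamped.
    """
    ref = max_sasa_reference() if reference is None else reference
    out: dict[ResidueId, float] = {}
    for rid, area in sa.items():
        name = residue_names[rid]
        if name not in ref:
            raise TableError(f"no fully-exposed reference area for {name!r}")
        out[rid] = 100.0 * area / ref[name]
    return out


@dataclass
class SurfaceAreaRecord:
    """Complexed/uncomplexed SASA and rSA for one residue."""

    residue_id: ResidueId
    residue_name: str
    sa_complexed: float
    sa_uncomplexed: float
    rsa_c: float
    rsa_u: float

    @property
    def delta_rsa(self) -> float:
        return self.rsa_u - self.rsa_c


def _side_atoms(model: ComplexModel) -> tuple[list[AtomRecord], list[AtomRecord]]:
    ab = model.select_atoms(roles=ANTIBODY_ROLES)
    ag = model.select_atoms(roles="antigen")
    if not ab or not ag:
        raise GeometryError("complex needs both an antibody and an antigen side")
    return ab, ag


def surface_area_records(
    model: ComplexModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    sphere_points: int = DEFAULT_SPHERE_POINTS,
    reference: Mapping[str, float] | None = None,
) -> list[SurfaceAreaRecord]:
    """Per-residue SA/rSA in the complexed and rigidly-separated states.

    The uncomplexed state keeps each side's coordinates and simply removes
    the other side, so ΔrSA = rSA_u - rSA_c is exactly >= 0.
    """
    ab, ag = _side_atoms(model)
    names = model.residue_names()
    ref = max_sasa_reference() if reference is None else reference

    complexed = atom_sasa(model.atoms, probe_radius, sphere_points)
    sa_c: dict[ResidueId, float] = {}
    for a, area in zip(model.atoms, complexed):
        sa_c[a.residue_id] = sa_c.get(a.residue_id, 0.0) + float(area)
    sa_u: dict[ResidueId, float] = {}
    for side in (ab, ag):
        for a, area in zip(side, atom_sasa(side, probe_radius, sphere_points)):
            sa_u[a.residue_id] = sa_u.get(a.residue_id, 0.0) + float(area)

    records = []
    for rid in model.residue_ids():
        name = names[rid]
        if name not in ref:
            raise TableError(f"no fully-exposed reference area for {name!r}")
        records.append(
            SurfaceAreaRecord(
                residue_id=rid,
                residue_name=name,
                sa_complexed=sa_c[rid],
                sa_uncomplexed=sa_u[rid],
                rsa_c=100.0 * sa_c[rid] / ref[name],
                rsa_u=100.0 * sa_u[rid] / ref[name],
            )
        )
    return records


# ---------------------------------------------------------------------------
# Residue classification and stickiness
# ---------------------------------------------------------------------------

@dataclass
class InterfaceRegions:
    """Interior/surface/support/rim/core assignment per residue."""

    per_residue: dict[ResidueId, str]
    support: list[ResidueId]
    rim: list[ResidueId]
    core: list[ResidueId]

    def interface_residues(self) -> list[ResidueId]:
        return self.support + self.rim + self.core


def classify_residue(rsa_c: float, rsa_u: float, delta_rsa: float) -> str:
    """Classify one residue by its rSA transition on binding.

    interior: rSA_c < 25 and ΔrSA = 0; surface: rSA_c > 25 and ΔrSA = 0;
    support: rSA_c < 25 and ΔrSA > 0; rim: rSA_c > 25 and ΔrSA > 0;
    core: rSA_u > 25, rSA_c < 25 and ΔrSA > 0 (takes precedence over
    support).  Boundary cases at rSA = 25 exactly go to the more exposed
    class (surface/rim).
    """
    if delta_rsa <= DELTA_RSA_TOLERANCE:
        return "interior" if rsa_c < RSA_THRESHOLD else "surface"
    if rsa_c < RSA_THRESHOLD:
        return "core" if rsa_u > RSA_THRESHOLD else "support"
    return "rim"


def classify_residues(records: Sequence[SurfaceAreaRecord]) -> InterfaceRegions:
    """Classify every residue; support/rim/core partition the interface."""
    per_residue: dict[ResidueId, str] = {}
    groups: dict[str, list[ResidueId]] = {"support": [], "rim": [], "core": []}
    for rec in records:
        cls = classify_residue(rec.rsa_c, rec.rsa_u, rec.delta_rsa)
        per_residue[rec.residue_id] = cls
        if cls in groups:
            groups[cls].append(rec.residue_id)
    return InterfaceRegions(per_residue=per_residue, **groups)


def stickiness_sum(
    residue_names: Iterable[str],
    scale: Mapping[str, float] | None = None,
    on_missing: str = "raise",
) -> float:
    """Sum of per-residue stickiness values over a region (with repeats)."""
    scale = stickiness_scale() if scale is None else scale
    total = 0.0
    for name in residue_names:
        if name not in scale:
            if on_missing == "skip":
                warnings.warn(f"no stickiness value for {name!r}; skipped")
                continue
            raise TableError(f"no stickiness value for residue type {name!r}")
        total += scale[name]
    return total


# ---------------------------------------------------------------------------
# Interface atoms, global density, surface complementarity
# ---------------------------------------------------------------------------

def interface_atoms(
    model: ComplexModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    sphere_points: int = DEFAULT_SPHERE_POINTS,
    tolerance: float = 1e-6,
) -> list[int]:
    """Indices of atoms whose accessible area drops on complexation."""
    ab, ag = _side_atoms(model)
    complexed = atom_sasa(model.atoms, probe_radius, sphere_points)
    unbound: dict[int, float] = {}
    index_of = {id(a): i for i, a in enumerate(model.atoms)}
    for side in (ab, ag):
        for a, area in zip(side, atom_sasa(side, probe_radius, sphere_points)):
            unbound[index_of[id(a)]] = float(area)
    return [
        i for i in range(len(model.atoms))
        if unbound[i] - float(complexed[i]) > tolerance
    ]


def global_density(coords: np.ndarray, convention: str = "ellipse-area") -> float:
    """Atoms-per-area packing proxy from the interface atom cloud.

    Principal moments of the centered gyration tensor give equivalent
    uniform-ellipsoid semi-axes a >= b >= c with a_i = sqrt(5 λ_i); the
    default convention divides the atom count by the area of the ellipse
    spanned by the two largest axes, GD = N / (π a b).  The alternative
    ``"ellipsoid-volume"`` convention divides by 4/3 π a b c instead.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise GeometryError("global density needs >= 3 atoms")
    centered = coords - coords.mean(axis=0)
    gyration = centered.T @ centered / len(centered)
    lam = np.sort(np.linalg.eigvalsh(gyration))[::-1]
    if lam[1] <= 1e-12:
        raise GeometryError("interface atoms are collinear")
    a, b = np.sqrt(5.0 * lam[0]), np.sqrt(5.0 * lam[1])
    if convention == "ellipse-area":
        return float(len(coords) / (np.pi * a * b))
    if convention == "ellipsoid-volume":
        c = np.sqrt(5.0 * max(lam[2], 0.0))
        if c <= 1e-12:
            raise GeometryError("planar atom set has no ellipsoid volume")
        return float(len(coords) / (4.0 / 3.0 * np.pi * a * b * c))
    raise ValueError(f"unknown global-density convention {convention!r}")


def _buried_dot_surface(
    atoms: Sequence[AtomRecord],
    keep_idx: Sequence[int],
    partner_coords: np.ndarray,
    partner_radii: np.ndarray,
    probe_radius: float,
    sphere_points: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interface-patch dot-surface (points, outward normals, point areas).

    A point belongs to the patch when it lies on the side's own accessible
    surface (computed in isolation, probe-expanded) but is occluded by the
    partner side's expanded spheres — i.e. the part of the surface buried
    on binding.  Returned point positions sit on the van der Waals sphere
    (the probe-expanded point projected back along its normal), so two
    surfaces in atomic contact are near-coincident rather than separated
    by two probe radii.
    """
    coords = np.array([a.coordinates for a in atoms], dtype=float)
    vdw = _radii_for(atoms)
    radii = vdw + probe_radius
    pradii = partner_radii + probe_radius
    pts = unit_sphere_points(sphere_points)
    tree = cKDTree(coords)
    ptree = cKDTree(partner_coords)
    reach = 2.0 * radii.max()
    preach = float(pradii.max())
    points, normals, areas = [], [], []
    for i in keep_idx:
        neighbours = [j for j in tree.query_ball_point(coords[i], reach) if j != i]
        sphere = coords[i] + radii[i] * pts
        if neighbours:
            d2 = ((sphere[:, None, :] - coords[neighbours][None, :, :]) ** 2).sum(-1)
            ok = ~(d2 < (radii[neighbours] ** 2)[None, :]).any(axis=1)
        else:
            ok = np.ones(len(sphere), dtype=bool)
        if not ok.any():
            continue
        cand = sphere[ok]
        hits = ptree.query_ball_point(cand, preach)
        buried = np.array(
            [
                any(
                    np.linalg.norm(cand[k] - partner_coords[j]) < pradii[j]
                    for j in hit
                )
                for k, hit in enumerate(hits)
            ],
            dtype=bool,
        )
        if buried.any():
            units = pts[ok][buried]
            points.append(coords[i] + vdw[i] * units)
            normals.append(units)
            areas.append(
                np.full(buried.sum(), 4.0 * np.pi * vdw[i] ** 2 / sphere_points)
            )
    if not points:
        return np.empty((0, 3)), np.empty((0, 3)), np.empty(0)
    return np.vstack(points), np.vstack(normals), np.concatenate(areas)


def surface_complementarity(
    model: ComplexModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    sphere_points: int = 240,
    decay_width: float = 1.0,
    interface_tolerance: float = 1e-6,
) -> float:
    """Area-weighted alignment of opposing interface surface normals.

    Each side's accessible dot surface (tessellated at ``sphere_points``
    per atom) is restricted to the binding patch: points on interface
    atoms (ΔSA > 0) that the partner side occludes.  For every surface
    element the nearest element on the opposing patch is found and the
    anti-alignment of their outward normals, -(n_a · n_b), is averaged
    with weights area x exp(-(d / decay_width)^2), so poorly apposed
    surface pairs are distance-penalized.  The index is bounded in
    [-1, 1]; tightly packed, well-apposed interfaces approach 1.
    """
    iface = interface_atoms(model, probe_radius, sphere_points=DEFAULT_SPHERE_POINTS,
                            tolerance=interface_tolerance)
    if not iface:
        raise GeometryError("complex has no interface atoms")
    ab_chains = set(model.chains_with_role(ANTIBODY_ROLES))
    sides = []
    for is_ab in (True, False):
        atoms = [a for a in model.atoms if (a.chain_id in ab_chains) == is_ab]
        partner = [a for a in model.atoms if (a.chain_id in ab_chains) != is_ab]
        local = {id(a): k for k, a in enumerate(atoms)}
        keep = [local[id(model.atoms[i])] for i in iface
                if (model.atoms[i].chain_id in ab_chains) == is_ab]
        if not keep:
            raise GeometryError("one side contributes no interface atoms")
        sides.append(
            _buried_dot_surface(
                atoms,
                keep,
                np.array([a.coordinates for a in partner], dtype=float),
                _radii_for(partner),
                probe_radius,
                sphere_points,
            )
        )
    if any(s[0].shape[0] == 0 for s in sides):
        raise GeometryError("no buried surface patch on one side of the interface")

    num = 0.0
    den = 0.0
    for (pa, na, wa), (pb, nb, _) in ((sides[0], sides[1]), (sides[1], sides[0])):
        tree = cKDTree(pb)
        dist, j = tree.query(pa)
        decay = np.exp(-((dist / decay_width) ** 2))
        w = wa * decay
        num += float((w * -(na * nb[j]).sum(axis=1)).sum())
        den += float(w.sum())
    if den <= 1e-12:
        raise GeometryError("interface surfaces never approach each other")
    return num / den


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

@dataclass
class InterfacePropertyPanel:
    """Per-complex interface descriptors (areas in Å², GD in atoms/Å²)."""

    model_id: str
    sa_total: float
    sa_by_region: dict[str, float]
    stickiness_total: float
    stickiness_by_region: dict[str, float]
    global_density: float
    surface_complementarity: float
    n_interface_residues: int
    n_interface_atoms: int

    def to_row(self) -> dict[str, float | str | int]:
        row: dict[str, float | str | int] = {
            "model_id": self.model_id,
            "sa_total": self.sa_total,
            "stickiness_total": self.stickiness_total,
            "global_density": self.global_density,
            "surface_complementarity": self.surface_complementarity,
            "n_interface_residues": self.n_interface_residues,
            "n_interface_atoms": self.n_interface_atoms,
        }
        for region in ("support", "rim", "core"):
            row[f"sa_{region}"] = self.sa_by_region[region]
            row[f"stickiness_{region}"] = self.stickiness_by_region[region]
        return row


def interface_property_panel(
    model: ComplexModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    sphere_points: int = DEFAULT_SPHERE_POINTS,
    sc_sphere_points: int = 240,
) -> InterfacePropertyPanel:
    """Compute the full interface descriptor panel for one complex.

    Region SA is the buried area (SA_u - SA_c summed over the region's
    residues), so support + rim + core sums to the total interface SA.
    """
    records = surface_area_records(model, probe_radius, sphere_points)
    regions = classify_residues(records)
    by_id = {r.residue_id: r for r in records}
    names = model.residue_names()

    sa_by_region: dict[str, float] = {}
    stick_by_region: dict[str, float] = {}
    for region_name, members in (
        ("support", regions.support),
        ("rim", regions.rim),
        ("core", regions.core),
    ):
        sa_by_region[region_name] = sum(
            by_id[rid].sa_uncomplexed - by_id[rid].sa_complexed for rid in members
        )
        stick_by_region[region_name] = stickiness_sum(names[rid] for rid in members)

    iface_res = regions.interface_residues()
    iface_atoms = interface_atoms(model, probe_radius, sphere_points)
    coords = np.array(
        [model.atoms[i].coordinates for i in iface_atoms], dtype=float
    )
    return InterfacePropertyPanel(
        model_id=model.model_id,
        sa_total=sum(sa_by_region.values()),
        sa_by_region=sa_by_region,
        stickiness_total=stickiness_sum(names[rid] for rid in iface_res),
        stickiness_by_region=stick_by_region,
        global_density=global_density(coords),
        surface_complementarity=surface_complementarity(
            model, probe_radius, sphere_points=sc_sphere_points
        ),
        n_interface_residues=len(iface_res),
        n_interface_atoms=len(iface_atoms),
    )
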