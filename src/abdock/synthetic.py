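"""Deterministic synthetic fixtures: toy complexes, graded decoys and
correlated confidence bundles.

Nothing here downloads or models real proteins.  The generators build
idealised poly-alanine-like chains (3.8 Å CA-CA spacing, pseudo side-chain
CB atoms) with an engineered antibody-antigen contact patch, rigid-body
pose decoys whose true DockQ is computed with the quality module, and
confidence bundles whose metrics are noisy monotone transforms of the true
pose quality with a controllable fidelity rho: rho = 1 gives noiseless
monotone links, rho = 0 quality-independent noise.  Every generator is
bit-reproducible given (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SpecError
from .quality import PoseQuality, dockq_score
from .structures import (
    BACKBONE_ATOMS,
    AtomRecord,
    CdrAnnotation,
    ComplexModel,
    write_pdb,
)

#: Local atom offsets relative to the CA position (Å).  CB is a
#: pseudo-side-chain atom pointing towards the partner chain (+y, +z).
_ATOM_OFFSETS = {
    "N": (-1.2, 0.5, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (1.2, 0.5, 0.0),
    "O": (1.6, 1.6, 0.0),
    "CB": (0.0, 0.8, 1.3),
}
_CA_SPACING = 3.8
_FAR_OFFSET = 24.0


@dataclass(frozen=True)
class ToyComplexSpec:
    """Parameters of a generated toy antibody-antigen complex."""

    n_antibody_residues: int = 20
    n_antigen_residues: int = 18
    interface_size: int = 6
    h3_length: int = 8
    seed: int = 0
    contact_distance: float = 4.5

    def validate(self) -> None:
        if self.interface_size > min(self.n_antibody_residues, self.n_antigen_residues):
            raise SpecError(
                f"interface_size {self.interface_size} exceeds the smaller "
                "chain length"
            )
        if not 0 < self.h3_length <= self.n_antibody_residues:
            raise SpecError(f"h3_length {self.h3_length} infeasible")
        if self.contact_distance <= 2.0:
            raise SpecError("contact_distance must exceed atomic overlap (~2 Å)")


def _chain_atoms(
    chain_id: str,
    n_residues: int,
    y_of: "np.ndarray",
    flip_y: bool,
    jitter: np.ndarray,
) -> list[AtomRecord]:
    atoms = []
    k = 0
    for i in range(n_residues):
        ca = np.array([i * _CA_SPACING, float(y_of[i]), 0.0])
        for name, off in _ATOM_OFFSETS.items():
            off = np.array(off)
            if flip_y:
                off = off * np.array([1.0, -1.0, 1.0])
            xyz = ca + off + jitter[k]
            k += 1
            atoms.append(
                AtomRecord(
                    chain_id=chain_id,
                    residue_number=i + 1,
                    insertion_code="",
                    residue_name="ALA",
                    atom_name=name,
                    element=name[0],
                    coordinates=tuple(xyz),
                    b_factor=0.0,
                )
            )
    return atoms


def make_toy_complex(spec: ToyComplexSpec) -> tuple[ComplexModel, CdrAnnotation]:
    """Build a native toy complex with an engineered contact patch.

    The heavy chain runs along x with its pseudo-side-chains pointing at
    the antigen; the first ``interface_size`` antigen residues are placed
    so their closest heavy atoms sit within ``contact_distance`` of the
    matching antibody residues, and all remaining antigen residues are
    held >= 20 Å away.  The designated H3 window covers the first
    ``h3_length`` heavy-chain residues (which include the contact patch).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_ab, n_ag = spec.n_antibody_residues, spec.n_antigen_residues
    # CB atoms of the two chains face each other 1.6 Å inside the CA-CA gap
    gap = spec.contact_distance - 0.5 + 2 * _ATOM_OFFSETS["CB"][1]
    jitter_ab = rng.normal(0.0, 0.03, size=(n_ab * len(_ATOM_OFFSETS), 3))
    jitter_ag = rng.normal(0.0, 0.03, size=(n_ag * len(_ATOM_OFFSETS), 3))

    y_ab = np.zeros(n_ab)
    y_ag = np.full(n_ag, gap + _FAR_OFFSET)
    y_ag[: spec.interface_size] = gap

    atoms = _chain_atoms("H", n_ab, y_ab, flip_y=False, jitter=jitter_ab)
    atoms += _chain_atoms("A", n_ag, y_ag, flip_y=True, jitter=jitter_ag)
    model = ComplexModel(
        atoms=atoms,
        chain_roles={"H": "heavy", "A": "antigen"},
        model_id=f"toy-{spec.seed}",
        source_tool="synthetic",
    )
    h3 = [("H", i + 1, "") for i in range(spec.h3_length)]
    fr = [("H", i + 1, "") for i in range(spec.h3_length, n_ab)]
    annotation = CdrAnnotation(
        scheme="toy", regions={"FR": fr, "CDR-H3": h3}, h3_length=spec.h3_length
    )
    return model, annotation


# ---------------------------------------------------------------------------
# Pose decoys
# ---------------------------------------------------------------------------

@dataclass
class Decoy:
    """One rigid antigen perturbation of a native complex."""

    model: ComplexModel
    quality: PoseQuality
    rotation_deg: float
    translation_a: float
    pose_id: str

    @property
    def true_dockq(self) -> float:
        return self.quality.dockq


def default_schedule(n: int) -> list[tuple[float, float]]:
    """Graded (rotation deg, translation Å) schedule from native to far-off."""
    if n == 1:
        return [(0.0, 0.0)]
    f = np.linspace(0.0, 1.0, n)
    return [(float(90.0 * fi), float(30.0 * fi**2)) for fi in f]


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def make_pose_decoys(
    native: ComplexModel,
    n_decoys: int | None = None,
    schedule: Sequence[tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[Decoy]:
    """Rigidly perturb the antigen body per schedule and record true DockQ.

    Each decoy rotates the antigen about its own centroid by the scheduled
    angle (random axis, seeded) and translates it along the
    antibody-to-antigen separation direction by the scheduled distance.
    """
    if schedule is None:
        schedule = default_schedule(n_decoys if n_decoys else 10)
    n_decoys = len(schedule) if n_decoys is None else n_decoys
    rng = np.random.default_rng(seed)

    ag_idx = [i for i, a in enumerate(native.atoms) if native.chain_roles[a.chain_id] == "antigen"]
    ab_idx = [i for i in range(len(native.atoms)) if i not in set(ag_idx)]
    coords = native.coordinates()
    centroid_ag = coords[ag_idx].mean(axis=0)
    sep = centroid_ag - coords[ab_idx].mean(axis=0)
    sep = sep / np.linalg.norm(sep)

    decoys = []
    for k in range(n_decoys):
        rot_deg, trans = schedule[k % len(schedule)]
        axis = rng.normal(size=3)
        rot = _rotation_matrix(axis, rot_deg)
        new_coords = coords.copy()
        new_coords[ag_idx] = (
            (coords[ag_idx] - centroid_ag) @ rot.T + centroid_ag + trans * sep
        )
        atoms = [
            replace(a, coordinates=tuple(new_coords[i]))
            for i, a in enumerate(native.atoms)
        ]
        pose_id = f"{native.model_id}-decoy{k:03d}"
        model = replace(native, atoms=atoms, model_id=pose_id)
        decoys.append(
            Decoy(
                model=model,
                quality=dockq_score(model, native),
                rotation_deg=rot_deg,
                translation_a=trans,
                pose_id=pose_id,
            )
        )
    return decoys


# ---------------------------------------------------------------------------
# Confidence bundles
# ---------------------------------------------------------------------------

def make_confidence_bundle(
    true_quality: float,
    fidelity: float,
    seed: int,
    n_antibody: int = 16,
    n_antigen: int = 14,
    engine: str = "zdock",
    pose_id: str = "pose",
):
    """Confidence bundle whose metrics track true DockQ with fidelity rho.

    Each metric is driven by its own effective quality
    ``q_eff = rho * q + (1 - rho) * u`` with an independent uniform draw u,
    so rho = 1 gives deterministic strictly-monotone links and rho = 0
    metrics independent of the true quality.  The PAE probability tensor is
    a discretised Gaussian over 1-Å error bins whose interchain mean error
    decreases with quality, so the derived ipTM is monotone in q_eff.
    Physics scores follow the engine's native orientation (energy-like,
    lower-better, for ProPOSE; higher-better for ZDOCK).
    """
    from .confidence import ConfidenceBundle  # local import avoids cycle

    if not 0.0 <= fidelity <= 1.0:
        raise SpecError(f"fidelity must be in [0, 1], got {fidelity}")
    q = float(np.clip(true_quality, 0.0, 1.0))
    rng = np.random.default_rng(seed)
    n = n_antibody + n_antigen

    def q_eff() -> float:
        return float(np.clip(fidelity * q + (1.0 - fidelity) * rng.uniform(), 0, 1))

    plddt = np.clip(
        40.0 + 55.0 * q_eff() + (1.0 - fidelity) * rng.normal(0.0, 3.0, size=n),
        0.0,
        100.0,
    )
    ptm = float(np.clip(0.15 + 0.80 * q_eff(), 0.0, 1.0))

    centers = np.arange(0.5, 31.0, 1.0)
    target = np.full((n, n), 1.5)
    inter = np.zeros((n, n), dtype=bool)
    inter[:n_antibody, n_antibody:] = True
    inter[n_antibody:, :n_antibody] = True
    target[inter] = 2.0 + 26.0 * (1.0 - q_eff())
    probs = np.exp(-((centers[None, None, :] - target[..., None]) ** 2) / (2 * 2.0**2))
    probs /= probs.sum(axis=2, keepdims=True)

    q_phys = q_eff()
    phys = 20.0 + 60.0 * q_phys
    if engine == "propose":
        phys = -phys  # energy-like: more favorable = more negative

    return ConfidenceBundle(
        plddt=plddt,
        ptm=ptm,
        pae_probs=probs,
        bin_centers=centers,
        chain_partition=np.array([0] * n_antibody + [1] * n_antigen),
        phys_score=float(phys),
        engine=engine,
        pose_id=pose_id,
    )


def write_confidence_json(bundle, path: str | Path) -> None:
    """Write a bundle in the confidence-JSON dialect the readers accept."""
    payload = {
        "plddt": bundle.plddt.tolist(),
        "ptm": bundle.ptm,
        "pae_probs": bundle.pae_probs.tolist(),
        "bin_centers": bundle.bin_centers.tolist(),
        "chain_index": bundle.chain_partition.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# Side-chain perturbation proxy
# ---------------------------------------------------------------------------

def perturb_sidechain_proxy(
    model: ComplexModel, magnitude: float, seed: int = 0
) -> ComplexModel:
    """Jitter pseudo-side-chain atoms at a target RMS displacement (Å).

    Backbone atoms (N, CA, C, O) are untouched; every other atom receives
    an isotropic Gaussian displacement with RMS norm ``magnitude``, capped
    at three times the magnitude.  This stands in for side-chain repacking
    to push a bound structure away from its crystallographic state.
    """
    rng = np.random.default_rng(seed)
    atoms = []
    for a in model.atoms:
        if a.atom_name in BACKBONE_ATOMS or magnitude == 0.0:
            atoms.append(a)
            continue
        d = rng.normal(0.0, magnitude / np.sqrt(3.0), size=3)
        norm = np.linalg.norm(d)
        if norm > 3.0 * magnitude:
            d *= 3.0 * magnitude / norm
        atoms.append(replace(a, coordinates=tuple(np.array(a.coordinates) + d)))
    return replace(model, atoms=atoms)


# ---------------------------------------------------------------------------
# Benchmark-scale fixtures
# ---------------------------------------------------------------------------

def make_certainty_benchmark(
    n_systems: int = 30,
    models_per_system: int = 4,
    rho: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic antibody-model table linking certainty to docking quality.

    Each model has a latent accuracy u ~ N(0, 1); its reported certainty is
    u itself (already on a standardized scale) and its best top-5 DockQ is
    a noisy monotone transform ``0.35 + 0.25 * (rho*u + (1-rho)*eps)``.
    CDR-H3 length is drawn negatively correlated with certainty, mirroring
    the harder-to-model long loops.  Columns: system_id, model_id,
    certainty, best_top5_dockq, h3_length.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_systems):
        for m in range(models_per_system):
            u = rng.normal()
            eps = rng.normal()
            dockq = float(np.clip(0.35 + 0.25 * (rho * u + (1 - rho) * eps), 0.0, 1.0))
            h3 = int(np.clip(round(12 - 2.5 * u + rng.normal(0, 1.5)), 5, 24))
            rows.append(
                {
                    "system_id": f"sys{s:03d}",
                    "model_id": f"sys{s:03d}-m{m}",
                    "certainty": u,
                    "best_top5_dockq": dockq,
                    "h3_length": h3,
                }
            )
    return pd.DataFrame(rows)


def write_fixture_set(
    out_dir: str | Path,
    spec: ToyComplexSpec | None = None,
    n_decoys: int = 10,
    fidelity: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a complete offline fixture set (PDB + JSON + TSV) to a directory.

    Produces the native complex and each decoy as PDB, a confidence JSON
    per decoy, and a physics-score TSV; returns the manifest as a frame
    with pose ids and true DockQ values.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec or ToyComplexSpec(seed=seed)
    native, _ = make_toy_complex(spec)
    write_pdb(native, out / "native.pdb")
    decoys = make_pose_decoys(native, n_decoys=n_decoys, seed=seed)
    rows = []
    for k, d in enumerate(decoys):
        write_pdb(d.model, out / f"{d.pose_id}.pdb")
        bundle = make_confidence_bundle(
            d.true_dockq, fidelity, seed=seed * 10_000 + k, pose_id=d.pose_id
        )
        write_confidence_json(bundle, out / f"{d.pose_id}.json")
        rows.append(
            {
                "pose_id": d.pose_id,
                "engine": bundle.engine,
                "score": bundle.phys_score,
                "true_dockq": d.true_dockq,
            }
        )
    frame = pd.DataFrame(rows)
    frame[["pose_id", "engine", "score"]].to_csv(
        out / "phys_scores.tsv", sep="\t", index=False
    )
    return frame
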