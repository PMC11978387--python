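"""Confidence standardization and composite rescoring of docking poses.

Antibody-model confidences (predicted errors / B-factor-style values) are
standardized into *model certainty* by Z-scoring over the population of all
models from one modeling tool and flipping the sign, so that a smaller
predicted error means a larger certainty.

Docked poses carry a bundle of confidence evidence: a per-residue pLDDT
vector, a pTM scalar, a tensor of aligned-error (PAE) probabilities over
distance-error bins, and a physics docking score.  The interchain TM-style
confidence (ipTM) is computed directly from the PAE probabilities, and the
four standardized components are summed with equal weights into a composite
score used to re-rank the pose population:

    composite = Z_pLDDT + Z_pTM + Z_ipTM + Z_phys

Standardization uses the population convention (divide by n) throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegeneratePopulationError,
    IncompleteEvidenceError,
    MaskError,
    ParseError,
    PopulationError,
)

#: Engines whose native score is better when lower (energy-like).
LOWER_IS_BETTER_ENGINES = {"propose"}


@dataclass
class ConfidenceBundle:
    """Per-pose confidence evidence.

    ``pae_probs`` has shape (n_res, n_res, n_bins) and rows that sum to 1;
    ``chain_partition`` maps each residue index to a chain group (0 for the
    antibody side, 1 for the antigen side) and drives the interchain mask
    for ipTM.
    """

    plddt: np.ndarray
    ptm: float
    pae_probs: np.ndarray
    bin_centers: np.ndarray
    chain_partition: np.ndarray
    phys_score: float
    engine: str = "other"
    pose_id: str = "pose"

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.pae_probs = np.asarray(self.pae_probs, dtype=float)
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.chain_partition = np.asarray(self.chain_partition, dtype=int)
        n = self.plddt.shape[0]
        if self.pae_probs.shape[:2] != (n, n):
            raise ParseError(
                f"pae_probs shape {self.pae_probs.shape} does not match "
                f"{n} residues"
            )
        if self.pae_probs.shape[2] != self.bin_centers.shape[0]:
            raise ParseError("bin_centers length does not match pae_probs bins")
        sums = self.pae_probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ParseError("pae_probs rows do not sum to 1")
        if self.plddt.min() < 0 or self.plddt.max() > 100:
            raise ParseError("pLDDT outside [0, 100]")
        if not 0.0 <= self.ptm <= 1.0:
            raise ParseError("pTM outside [0, 1]")

    @property
    def n_residues(self) -> int:
        return int(self.plddt.shape[0])


@dataclass
class CompositeScore:
    """Equal-weight composite of four standardized confidence components."""

    z_plddt: float
    z_ptm: float
    z_iptm: float
    z_phys: float
    pose_id: str = "pose"
    total: float = field(init=False)

    def __post_init__(self) -> None:
        parts = (self.z_plddt, self.z_ptm, self.z_iptm, self.z_phys)
        if any(p is None or not np.isfinite(p) for p in parts):
            raise IncompleteEvidenceError(
                f"composite for {self.pose_id!r} has a missing or non-finite "
                f"component: {parts}"
            )
        self.total = float(sum(parts))


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def zscore(values: Sequence[float], population: Sequence[float]) -> np.ndarray:
    """Standardize ``values`` against a population (population sd, ddof=0)."""
    pop = np.asarray(population, dtype=float)
    if pop.size < 2:
        raise DegeneratePopulationError(
            f"standardization population needs >= 2 members, got {pop.size}"
        )
    sd = float(pop.std(ddof=0))
    if sd == 0.0:
        raise DegeneratePopulationError("population has zero standard deviation")
    return (np.asarray(values, dtype=float) - pop.mean()) / sd


def model_certainty(
    predicted_errors: Mapping[str, float],
    population: Sequence[float] | None = None,
    population_id: str = "default",
) -> pd.DataFrame:
    """Sign-flipped Z-score of per-model predicted errors.

    The population should pool the predicted errors of every model a single
    modeling tool produced across all antibody-antigen systems; mixing tools
    in one population is rejected by construction (one call = one
    ``population_id``).  Smaller predicted error means larger certainty.
    """
    ids = list(predicted_errors)
    errs = [predicted_errors[k] for k in ids]
    pop = errs if population is None else list(population)
    cert = -zscore(errs, pop)
    return pd.DataFrame(
        {
            "model_id": ids,
            "predicted_error": errs,
            "certainty": cert,
            "population_id": population_id,
        }
    )


# ---------------------------------------------------------------------------
# pTM / ipTM from aligned-error probabilities
# ---------------------------------------------------------------------------

def tm_d0(n_residues: int) -> float:
    """TM-score normalization length d0(N), clamped to >= 1.0 Å."""
    return max(1.24 * max(n_residues - 15, 0) ** (1.0 / 3.0) - 1.8, 1.0)


def ptm_from_probs(bundle: ConfidenceBundle, pair_mask: str = "all") -> float:
    """Expected TM-style score from aligned-error probability bins.

    For each residue i the expected per-pair TM term
    ``sum_k p[i,j,k] / (1 + (e_k/d0)^2)`` is averaged over the residues j
    selected by the mask; the score is the maximum over i (the best aligned
    residue).  ``pair_mask="all"`` gives pTM; ``"interchain"`` restricts j
    to the other chain group and gives ipTM.
    """
    n = bundle.n_residues
    d0 = tm_d0(n)
    tm_per_bin = 1.0 / (1.0 + (bundle.bin_centers / d0) ** 2)
    expected = bundle.pae_probs @ tm_per_bin  # (n, n)
    if pair_mask == "all":
        mask = np.ones((n, n), dtype=bool)
    elif pair_mask == "interchain":
        part = bundle.chain_partition
        mask = part[:, None] != part[None, :]
    else:
        raise MaskError(f"unknown pair mask {pair_mask!r}")
    if not mask.any():
        raise MaskError(f"pair mask {pair_mask!r} selects no residue pairs")
    row_counts = mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        row_means = np.where(
            row_counts > 0, (expected * mask).sum(axis=1) / row_counts, -np.inf
        )
    return float(row_means.max())


def iptm_from_probs(bundle: ConfidenceBundle) -> float:
    """Interchain TM-style confidence (ipTM)."""
    return ptm_from_probs(bundle, pair_mask="interchain")


# ---------------------------------------------------------------------------
# Composite rescoring
# ---------------------------------------------------------------------------

def composite_score(
    z_plddt: float, z_ptm: float, z_iptm: float, z_phys: float, pose_id: str = "pose"
) -> CompositeScore:
    """Unweighted sum of the four standardized components."""
    return CompositeScore(z_plddt, z_ptm, z_iptm, z_phys, pose_id=pose_id)


def _z_or_zero(values: np.ndarray) -> np.ndarray:
    """Population Z-score; a spread-free population maps to all-zero scores."""
    sd = values.std(ddof=0)
    if values.size < 2 or sd == 0.0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def rescore_poses(
    bundles: Sequence[ConfidenceBundle],
    phys_scope: str = "per-engine",
    phys_orientation: Mapping[str, str] | None = None,
) -> list[CompositeScore]:
    """Standardize raw confidence metrics across a pose population and re-rank.

    Each pose's mean pLDDT, pTM, ipTM (from PAE probabilities) and physics
    score are Z-scored over the pose population (the poses of one
    antibody-antigen system).  Physics scores are oriented so that a more
    favorable score gives a positive Z; energy-like engines (lower = better)
    are sign-flipped.  With ``phys_scope="per-engine"`` (default) physics
    scores are standardized within each engine's poses.  Poses are returned
    sorted by descending composite total with the deterministic tie-break
    (total desc, z_ipTM desc, pose_id asc).
    """
    if len(bundles) < 2:
        raise DegeneratePopulationError("rescoring needs a population of >= 2 poses")
    engines = sorted({b.engine for b in bundles})
    if phys_scope not in ("per-engine", "pooled"):
        raise PopulationError(f"unknown phys_scope {phys_scope!r}")
    if phys_scope == "pooled" and len(engines) > 1:
        raise PopulationError(
            "pooled physics-score standardization across engines "
            f"{engines} mixes incompatible score scales; use per-engine"
        )
    orient = {e: ("lower" if e in LOWER_IS_BETTER_ENGINES else "higher") for e in engines}
    if phys_orientation:
        orient.update(phys_orientation)

    mean_plddt = np.array([b.plddt.mean() for b in bundles])
    ptm = np.array([b.ptm for b in bundles])
    iptm = np.array([iptm_from_probs(b) for b in bundles])
    phys = np.array(
        [b.phys_score * (-1.0 if orient[b.engine] == "lower" else 1.0) for b in bundles]
    )

    z_plddt = _z_or_zero(mean_plddt)
    z_ptm = _z_or_zero(ptm)
    z_iptm = _z_or_zero(iptm)
    z_phys = np.empty(len(bundles))
    if phys_scope == "pooled" or len(engines) == 1:
        z_phys[:] = _z_or_zero(phys)
    else:
        for eng in engines:
            idx = np.array([i for i, b in enumerate(bundles) if b.engine == eng])
            z_phys[idx] = _z_or_zero(phys[idx])

    scores = [
        CompositeScore(
            z_plddt=float(z_plddt[i]),
            z_ptm=float(z_ptm[i]),
            z_iptm=float(z_iptm[i]),
            z_phys=float(z_phys[i]),
            pose_id=bundles[i].pose_id,
        )
        for i in range(len(bundles))
    ]
    scores.sort(key=lambda s: (-s.total, -s.z_iptm, s.pose_id))
    return scores


# ---------------------------------------------------------------------------
# I/O: confidence JSON and physics-score TSV
# ---------------------------------------------------------------------------

def read_confidence_json(
    path: str | Path,
    phys_score: float = 0.0,
    engine: str = "other",
    pose_id: str | None = None,
) -> ConfidenceBundle:
    """Read a structure-predictor confidence JSON into a bundle.

    Accepts either binned PAE probabilities (keys ``pae_probs`` +
    ``bin_centers``) or a point-estimate PAE matrix (key ``pae``), which is
    converted to a delta distribution on the nearest bin of a default
    0.5-31.5 Å grid.  Required keys: ``plddt``, ``ptm``, ``chain_index``.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid confidence JSON {path}: {exc}") from exc
    try:
        plddt = np.asarray(payload["plddt"], dtype=float)
        ptm = float(payload["ptm"])
        chain_index = np.asarray(payload["chain_index"], dtype=int)
    except KeyError as exc:
        raise ParseError(f"{path} is missing confidence key {exc}") from exc
    if "pae_probs" in payload:
        probs = np.asarray(payload["pae_probs"], dtype=float)
        centers = np.asarray(payload["bin_centers"], dtype=float)
    elif "pae" in payload:
        pae = np.asarray(payload["pae"], dtype=float)
        centers = np.arange(0.5, 32.0, 1.0)
        idx = np.abs(pae[..., None] - centers).argmin(axis=-1)
        probs = np.zeros(pae.shape + (centers.size,))
        np.put_along_axis(probs, idx[..., None], 1.0, axis=-1)
    else:
        raise ParseError(f"{path} carries neither 'pae_probs' nor 'pae'")
    return ConfidenceBundle(
        plddt=plddt,
        ptm=ptm,
        pae_probs=probs,
        bin_centers=centers,
        chain_partition=chain_index,
        phys_score=phys_score,
        engine=engine,
        pose_id=pose_id or path.stem,
    )


def read_phys_scores(path: str | Path) -> pd.DataFrame:
    """Read physics docking scores as TSV with columns pose_id, engine, score."""
    df = pd.read_csv(path, sep="\t")
    required = {"pose_id", "engine", "score"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path} must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return df


def scores_to_frame(scores: Iterable[CompositeScore]) -> pd.DataFrame:
    """Ranked composite scores as a DataFrame (rank is 1-based)."""
    rows = [
        {
            "rank": i + 1,
            "pose_id": s.pose_id,
            "z_plddt": s.z_plddt,
            "z_ptm": s.z_ptm,
            "z_iptm": s.z_iptm,
            "z_phys": s.z_phys,
            "total": s.total,
        }
        for i, s in enumerate(scores)
    ]
    return pd.DataFrame(rows)


def write_scores(
    scores: Sequence[CompositeScore], path: str | Path, format: str = "tsv"
) -> None:
    """Write ranked scores as TSV or JSON with all four z-components."""
    df = scores_to_frame(scores)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        Path(path).write_text(df.to_json(orient="records", indent=2))
    else:
        raise ValueError(f"unknown format {format!r}")
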