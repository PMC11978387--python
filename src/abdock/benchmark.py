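"""Benchmark evaluation machinery for docking campaigns.

Covers the bookkeeping and statistics of a docking benchmark: enumerating
the full pose manifest (systems x antibody models x engines x poses),
naive (random) and certainty-guided model selection, top-N success rates at
the epitope-mapping (DockQ >= 0.23) and antibody-design (DockQ >= 0.49)
thresholds, bootstrap error bars over antibody models, engine pooling, and
success-vs-failure discriminant statistics over interface properties
(standardized differences with Welch t-tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .confidence import CompositeScore
from .errors import ConfigError

EPITOPE_MAPPING_THRESHOLD = 0.23
ANTIBODY_DESIGN_THRESHOLD = 0.49
MIN_REPRESENTATION = 0.05
BOOTSTRAP_ITERATIONS = 200


# ---------------------------------------------------------------------------
# Manifest enumeration
# ---------------------------------------------------------------------------

@dataclass
class ManifestConfig:
    """Dimensions of a docking campaign.

    ``tools`` maps each antibody-modeling tool to its ensemble size
    (models per system); ``template_free_seeds`` x
    ``template_free_models_per_seed`` is the per-system budget of the
    template-free (end-to-end AI) comparators.
    """

    systems: Sequence[str]
    tools: Mapping[str, int]
    engines: Sequence[str]
    poses_per_engine: int
    template_free_seeds: int = 5
    template_free_models_per_seed: int = 5

    def validate(self) -> None:
        if (
            not self.systems
            or not self.tools
            or not self.engines
            or self.poses_per_engine <= 0
            or any(m <= 0 for m in self.tools.values())
        ):
            raise ConfigError("every manifest dimension must be non-empty/positive")


@dataclass
class RunManifest:
    """Deterministic enumeration of every pose record in a campaign."""

    config: ManifestConfig
    records: pd.DataFrame
    counts: dict[str, int] = field(default_factory=dict)


def enumerate_manifest(config: ManifestConfig) -> RunManifest:
    """Enumerate all pose records and the expected totals.

    The headline totals are ``total_poses`` (systems x total models x
    engines x poses/engine), ``poses_per_ensemble_per_engine`` for each
    (tool, engine) block, and ``template_free_models_per_system``.
    """
    config.validate()
    systems = list(config.systems)
    frames = []
    for tool, n_models in config.tools.items():
        for engine in config.engines:
            idx = pd.MultiIndex.from_product(
                [systems, range(n_models), range(config.poses_per_engine)],
                names=["system_id", "model_index", "pose_index"],
            )
            df = idx.to_frame(index=False)
            df["tool"] = tool
            df["engine"] = engine
            frames.append(df)
    records = pd.concat(frames, ignore_index=True)

    counts: dict[str, int] = {"total_poses": len(records)}
    for tool, n_models in config.tools.items():
        for engine in config.engines:
            counts[f"{tool}:{engine}"] = (
                len(systems) * n_models * config.poses_per_engine
            )
    ensemble_counts = {counts[f"{t}:{e}"] for t in config.tools for e in config.engines}
    if len(ensemble_counts) == 1:
        counts["poses_per_ensemble_per_engine"] = ensemble_counts.pop()
    counts["template_free_models_per_system"] = (
        config.template_free_seeds * config.template_free_models_per_seed
    )
    return RunManifest(config=config, records=records, counts=counts)


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def naive_selection(
    model_ids: Sequence[str], k: int, seed: int = 0
) -> list[str]:
    """Uniform random subset of k models without replacement (seeded)."""
    if not 1 <= k <= len(model_ids):
        raise ConfigError(
            f"cannot select {k} models from an ensemble of {len(model_ids)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(model_ids), size=k, replace=False)
    return [model_ids[i] for i in sorted(idx)]


@dataclass
class CertaintyFilterResult:
    """Outcome of certainty thresholding over antibody models."""

    retained: pd.DataFrame
    systems_total: int
    systems_remaining: int
    mean_h3_length: float
    representation: float
    suppressed: bool


def certainty_filter(
    models: pd.DataFrame,
    threshold: float,
    min_representation: float = MIN_REPRESENTATION,
) -> CertaintyFilterResult:
    """Reject antibody models whose certainty falls below a threshold.

    ``models`` needs columns system_id, model_id, certainty and (optionally)
    h3_length.  Systems losing every model are excluded; results whose
    surviving-system fraction drops below ``min_representation`` are marked
    suppressed (to be hidden in downstream outputs, not erased).
    """
    required = {"system_id", "model_id", "certainty"}
    if not required.issubset(models.columns):
        raise ConfigError(f"models frame needs columns {sorted(required)}")
    total = models["system_id"].nunique()
    retained = models[models["certainty"] >= threshold].reset_index(drop=True)
    remaining = retained["system_id"].nunique()
    representation = remaining / total if total else 0.0
    mean_h3 = (
        float(retained["h3_length"].mean())
        if "h3_length" in models.columns and len(retained)
        else float("nan")
    )
    return CertaintyFilterResult(
        retained=retained,
        systems_total=total,
        systems_remaining=remaining,
        mean_h3_length=mean_h3,
        representation=representation,
        suppressed=representation < min_representation,
    )


# ---------------------------------------------------------------------------
# Success rates
# ---------------------------------------------------------------------------

def topn_success(
    ranked_qualities: Mapping[str, Sequence[float]],
    n: int,
    dockq_threshold: float,
) -> tuple[float, dict[str, bool]]:
    """Per-system top-N success at a DockQ threshold and the overall rate.

    A system succeeds when any of its N best-ranked poses reaches the
    threshold; systems with no poses count as failures.
    """
    indicators: dict[str, bool] = {}
    for system, qualities in ranked_qualities.items():
        if len(qualities) == 0:
            warnings.warn(f"system {system!r} has no ranked poses; counted as failure")
            indicators[system] = False
            continue
        indicators[system] = any(q >= dockq_threshold for q in list(qualities)[:n])
    rate = sum(indicators.values()) / len(indicators) if indicators else 0.0
    return rate, indicators


def pool_engines(
    ranked_per_engine: Mapping[str, Sequence[CompositeScore]],
) -> list[CompositeScore]:
    """Merge per-engine ranked lists into one composite-ordered list.

    Scores must already be standardized within their engine populations;
    duplicates (same pose id) keep their best-scoring occurrence.
    """
    best: dict[str, CompositeScore] = {}
    for scores in ranked_per_engine.values():
        for s in scores:
            cur = best.get(s.pose_id)
            if cur is None or (-s.total, -s.z_iptm) < (-cur.total, -cur.z_iptm):
                best[s.pose_id] = s
    merged = list(best.values())
    merged.sort(key=lambda s: (-s.total, -s.z_iptm, s.pose_id))
    return merged


@dataclass
class BootstrapResult:
    """Bootstrap mean success rate with a percentile interval."""

    mean: float
    lower: float
    upper: float
    rates: np.ndarray


def bootstrap_success(
    indicators: Mapping[str, Sequence[bool]],
    iterations: int = BOOTSTRAP_ITERATIONS,
    seed: int = 0,
    unit: str = "models",
) -> BootstrapResult:
    """Bootstrap the success rate over antibody models (or systems).

    ``indicators`` maps each system to per-model success flags; a system
    succeeds when any of its (resampled) models succeeds.  With
    ``unit="models"`` each system's models are resampled with replacement
    (the default, matching error bars over antibody-model choice); with
    ``unit="systems"`` whole systems are resampled instead.  The interval
    is the 2.5-97.5 percentile of the per-iteration rates.
    """
    systems = list(indicators)
    if len(systems) < 2:
        raise ConfigError("bootstrap needs >= 2 systems")
    flags = {s: np.asarray(indicators[s], dtype=bool) for s in systems}
    if any(f.size == 0 for f in flags.values()):
        raise ConfigError("every system needs >= 1 model indicator")
    rng = np.random.default_rng(seed)
    rates = np.empty(iterations)
    for it in range(iterations):
        if unit == "models":
            succ = [
                flags[s][rng.integers(0, flags[s].size, flags[s].size)].any()
                for s in systems
            ]
        elif unit == "systems":
            chosen = rng.integers(0, len(systems), len(systems))
            succ = [flags[systems[i]].any() for i in chosen]
        else:
            raise ConfigError(f"unknown bootstrap unit {unit!r}")
        rates[it] = np.mean(succ)
    return BootstrapResult(
        mean=float(rates.mean()),
        lower=float(np.percentile(rates, 2.5)),
        upper=float(np.percentile(rates, 97.5)),
        rates=rates,
    )


# ---------------------------------------------------------------------------
# Discriminant statistics
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def discriminant_stats(
    panel: pd.DataFrame,
    success: Mapping[str, bool] | pd.Series,
) -> pd.DataFrame:
    """Success-vs-failure contrasts for each interface property.

    For every numeric column of ``panel`` (rows indexed by system id) the
    standardized difference (mean_success - mean_failure over the Cohen's-d
    pooled sd) and a Welch two-sample t-test p-value are reported, with the
    usual star coding (* p<.05, ** p<.01, *** p<.001).  Positive values
    mean the property is higher among successfully predicted systems.
    Properties with fewer than two systems in either group are skipped.
    """
    labels = pd.Series(success, dtype=bool).reindex(panel.index)
    if labels.isna().any():
        raise ConfigError("success labels missing for some systems in the panel")
    rows = []
    for prop in panel.select_dtypes(include=[np.number]).columns:
        a = panel.loc[labels, prop].dropna()
        b = panel.loc[~labels, prop].dropna()
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"property {prop!r} skipped: a group has < 2 systems")
            continue
        pooled = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (len(a) + len(b) - 2)
        )
        diff = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "property": prop,
                "standardized_difference": float(diff),
                "t_statistic": float(t),
                "p_value": float(p),
                "stars": significance_stars(float(p)),
                "n_success": len(a),
                "n_failure": len(b),
            }
        )
    return pd.DataFrame(rows)
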