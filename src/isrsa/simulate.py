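"""Synthetic cohort and beta-map generator with planted intersubject structure.

Emulates the study design the pipeline targets: ~30 adolescents (plus a
configurable number of motion- and attention-excluded recruits), a 24-item
0-3 trait questionnaire answered by two correlated informants, covariates
(age 10-17, gender, IQ), and per-condition beta volumes on a 3 mm grid for
a blocked fearful-face task with a baseline and three interpretation
contexts ("afraid for you", "afraid of you", "afraid for self").

Beta maps carry *planted* intersubject structure: inside each planted
region, subject i's pattern is a loading on a shared latent spatial
pattern plus independent voxel noise, with the loading chosen so the
expected neural RDM matches one of the intersubject models —

- ``low_alike``:  loading 1 - s_i (low scorers share the pattern)
- ``high_alike``: loading s_i
- ``nn`` (nn_abs / nn_euclid): loadings cos(pi s_i / 2) and sin(pi s_i / 2)
  on two orthogonal patterns, so pattern similarity decays smoothly with
  |s_i - s_j|

where s_i is the subject's max-normalized trait score.  Outside planted
regions the volumes are independent noise.  Everything is deterministic
given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import GridSpec
from .neural import BetaVolumeSet
from .traits import ScoreVector

CONDITIONS = ("baseline", "afraid_for_you", "afraid_of_you", "afraid_for_self")

#: task timing constants of the emulated design
TR_S = 2.5
BASELINE_RUN_S = 180.0          # 3-minute baseline runs
CONTEXT_RUN_S = 253.0           # 4 min 13 s context runs
N_BASELINE_RUNS = 2
N_CONTEXT_RUNS = 4
N_CONTEXTS = 3
PRESENTATIONS_PER_CONTEXT = 2
BLOCK_S = 18.0
FACE_MS = 200
FACE_FIX_MS = 300
CUE_MS = 2000


@dataclass
class PlantedRegion:
    """A contiguous voxel set carrying one model's intersubject structure."""

    voxels: np.ndarray          # (k, 3) int voxel indices
    kind: str                   # low_alike | high_alike | nn
    weight: float = 0.8         # effect weight w in [0, 1]
    name: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=int)
        if not 0.0 <= self.weight <= 1.0:
            raise ConfigError(f"effect weight {self.weight} outside [0, 1]")
        if self.kind not in ("low_alike", "high_alike", "nn"):
            raise ConfigError(f"unknown planted kind {self.kind!r}")


@dataclass
class SimulationConfig:
    """Study conditions for the generator; defaults mirror the target design."""

    n_subjects: int = 30
    n_excluded_motion: int = 4
    n_excluded_attention: int = 3
    n_items: int = 24
    levels: int = 4
    grid_shape: tuple[int, int, int] = (20, 14, 8)   # ~2200-voxel box mask
    voxel_mm: float = 3.0
    planted_regions: list[PlantedRegion] = field(default_factory=list)
    noise_sd: float = 1.0
    trait_spread: float = 1.0
    informant_correlation: float = 0.85
    informant_noise_sd: float = 0.25
    item_bias_sd: float = 0.10
    missing_fraction: float = 0.002
    multi_marked_fraction: float = 0.001
    confound_covariates: bool = False
    conditions: tuple[str, ...] = CONDITIONS
    seed: int = 0

    def __post_init__(self):
        if self.missing_fraction > 0.2:
            raise ConfigError("missing fraction above 0.2 is infeasible for scoring")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ConfigError(f"unknown condition {c!r}")

    @property
    def grid(self) -> GridSpec:
        return GridSpec.isotropic(self.grid_shape, self.voxel_mm)

    @property
    def n_recruited(self) -> int:
        return self.n_subjects + self.n_excluded_motion + self.n_excluded_attention


def default_planted_regions(
    grid_shape: Sequence[int] = (20, 14, 8),
    weight: float = 0.8,
    size: int = 5,
) -> list[PlantedRegion]:
    """Three disjoint, well-separated cubic regions, one per model kind."""
    gx, gy, gz = grid_shape
    if gx < 2 * size + 4 or gy < 2 * size + 4 or gz < size:
        raise ConfigError(f"grid {tuple(grid_shape)} too small for three "
                          f"{size}^3 planted regions")
    z0 = (gz - size) // 2
    corners = [
        (1, 1, z0),
        (gx - size - 1, 1, z0),
        ((gx - size) // 2, gy - size - 1, z0),
    ]
    kinds = ("low_alike", "high_alike", "nn")
    regions = []
    for (x0, y0, zz), kind in zip(corners, kinds):
        xs, ys, zs = np.mgrid[x0:x0 + size, y0:y0 + size, zz:zz + size]
        vox = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
        regions.append(PlantedRegion(voxels=vox, kind=kind, weight=weight,
                                     name=f"{kind}_region"))
    return regions


def task_metadata() -> dict:
    """Timing/bookkeeping manifest of the emulated blocked task."""
    return {
        "tr_s": TR_S,
        "baseline_runs": {
            "n_runs": N_BASELINE_RUNS,
            "duration_s": BASELINE_RUN_S,
            "n_volumes": math.ceil(BASELINE_RUN_S / TR_S),
            "face_blocks": 4,
            "fixation_blocks": 4,
            "block_s": BLOCK_S,
        },
        "context_runs": {
            "n_runs": N_CONTEXT_RUNS,
            "duration_s": CONTEXT_RUN_S,
            "n_volumes": math.ceil(CONTEXT_RUN_S / TR_S),
            "n_contexts": N_CONTEXTS,
            "presentations_per_context": PRESENTATIONS_PER_CONTEXT,
            "contextualized_blocks_per_run": N_CONTEXTS * PRESENTATIONS_PER_CONTEXT,
            "fixation_blocks": N_CONTEXTS * PRESENTATIONS_PER_CONTEXT,
            "block_s": BLOCK_S,
            "cue_ms": CUE_MS,
        },
        "face_ms": FACE_MS,
        "face_fixation_ms": FACE_FIX_MS,
        "conditions": list(CONDITIONS),
    }


def _ordinal_response(p: np.ndarray, levels: int) -> np.ndarray:
    """Map latent propensities in [0, 1]-ish to ordinal 0..levels-1."""
    return np.clip(np.floor(np.clip(p, 0.0, None) * levels), 0, levels - 1).astype(int)


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate the recruited cohort's trait table (long format).

    Returns the table (one row per subject x informant, item cells as
    strings with blanks for missing and ``a|b`` for multi-marked entries)
    and a ground-truth dict with the latent traits and exclusion labels.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_recruited
    sids = [f"sub-{i + 1:02d}" for i in range(n)]
    latent = 0.5 + config.trait_spread * (rng.uniform(0.0, 1.0, size=n) - 0.5)
    item_bias = rng.normal(0.0, config.item_bias_sd, size=config.n_items)
    rho = config.informant_correlation
    shared = rng.normal(0.0, config.informant_noise_sd, size=(n, config.n_items))
    own = rng.normal(0.0, config.informant_noise_sd, size=(2, n, config.n_items))
    responses = {}
    for r, informant in enumerate(("child", "parent")):
        noise = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * own[r]
        prop = latent[:, None] + item_bias[None, :] + noise
        responses[informant] = _ordinal_response(prop, config.levels)

    # covariates; independent of the trait unless confounding is requested
    age = rng.uniform(10.0, 17.0, size=n)
    gender = rng.integers(0, 2, size=n)
    iq = rng.normal(100.0, 15.0, size=n)
    if config.confound_covariates:
        age = age + 3.0 * (latent - 0.5)
        iq = iq - 10.0 * (latent - 0.5)

    # exclusion flags on distinct recruits
    n_excl = config.n_excluded_motion + config.n_excluded_attention
    excl_idx = rng.choice(n, size=n_excl, replace=False)
    motion = np.zeros(n, dtype=bool)
    attention = np.zeros(n, dtype=bool)
    motion[excl_idx[: config.n_excluded_motion]] = True
    attention[excl_idx[config.n_excluded_motion:]] = True

    # injected data quirks exercising the informant-combination rules
    n_cells = 2 * n * config.n_items
    miss = rng.random((2, n, config.n_items)) < config.missing_fraction
    multi = rng.random((2, n, config.n_items)) < config.multi_marked_fraction
    del n_cells

    rows = []
    for r, informant in enumerate(("child", "parent")):
        resp = responses[informant]
        for i in range(n):
            rec = {"subject_id": sids[i], "informant": informant}
            for j in range(config.n_items):
                if miss[r, i, j]:
                    rec[f"item_{j + 1}"] = ""
                elif multi[r, i, j]:
                    v = int(resp[i, j])
                    lo = min(v, config.levels - 2)
                    rec[f"item_{j + 1}"] = f"{lo}|{lo + 1}"
                else:
                    rec[f"item_{j + 1}"] = str(int(resp[i, j]))
            rec.update(age=round(float(age[i]), 2), gender=int(gender[i]),
                       iq=round(float(iq[i]), 1),
                       motion_excluded=bool(motion[i]),
                       attention_excluded=bool(attention[i]))
            rows.append(rec)
    table = pd.DataFrame(rows)
    truth = {
        "subject_ids": sids,
        "latent_trait": latent,
        "motion_excluded": motion,
        "attention_excluded": attention,
    }
    return table, truth


def _loadings(kind: str, s: np.ndarray) -> np.ndarray:
    """Per-subject loadings on the region's shared pattern(s), (n, n_pat)."""
    if kind == "low_alike":
        return (1.0 - s)[:, None]
    if kind == "high_alike":
        return s[:, None]
    # nearest neighbors: unit loadings rotating with s so that the angle
    # between subjects i, j is (pi/2) |s_i - s_j|
    ang = 0.5 * math.pi * s
    return np.column_stack([np.cos(ang), np.sin(ang)])


def generate_betas(
    scores: ScoreVector,
    config: SimulationConfig,
    mask: np.ndarray | None = None,
) -> tuple[dict[str, BetaVolumeSet], np.ndarray, dict]:
    """Simulate beta volumes per condition with the configured planted structure.

    Returns (condition -> BetaVolumeSet, mask, manifest); the manifest
    records ground-truth planted regions and the task metadata.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(scores.subject_order)
    shape = tuple(config.grid_shape)
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    for reg in config.planted_regions:
        if (reg.voxels < 0).any() or (reg.voxels >= np.array(shape)).any():
            raise ConfigError(f"planted region {reg.name!r} outside the grid")
        if not mask[tuple(reg.voxels.T)].all():
            raise ConfigError(f"planted region {reg.name!r} outside the mask")
    flat = {tuple(v) for reg in config.planted_regions for v in reg.voxels}
    if len(flat) < sum(len(r.voxels) for r in config.planted_regions):
        raise ConfigError("planted regions overlap")

    s = scores.normalized
    out: dict[str, BetaVolumeSet] = {}
    for cond in config.conditions:
        data = config.noise_sd * rng.standard_normal((n, *shape))
        for reg in config.planted_regions:
            L = _loadings(reg.kind, s)                       # (n, n_pat)
            G = rng.standard_normal((L.shape[1], len(reg.voxels)))
            signal = reg.weight * (L @ G)                    # (n, k)
            ix, iy, iz = reg.voxels.T
            data[:, ix, iy, iz] += signal
        data[:, ~mask] = np.nan
        out[cond] = BetaVolumeSet(
            data=data, grid=config.grid, condition=cond,
            subject_order=list(scores.subject_order),
        )
    manifest = {
        "planted_regions": [
            {"name": r.name, "kind": r.kind, "weight": r.weight,
             "voxels": r.voxels.tolist()}
            for r in config.planted_regions
        ],
        "n_subjects": n,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
        "conditions": list(config.conditions),
        "task": task_metadata(),
    }
    return out, mask, manifest


def recovery_experiment(
    seed: int,
    weight: float = 0.8,
    B: int = 1000,
    V: int = 100,
    noise_sd: float | None = None,
    condition: str = "afraid_for_you",
) -> dict:
    """Full-pipeline parameter-recovery run on one planted synthetic study.

    Plants one region per model kind (low_alike, high_alike, nn) at the
    given effect weight, runs the searchlight IS-RSA for each of the three
    summary-score models, thresholds each map, and measures how much of
    every planted region is covered by positive extent-surviving clusters.

    Returns a dict with ``coverage[model_kind][region_kind]``,
    ``own_recovered`` (every region covered >= 50% by its own model) and
    ``exclusive`` (own_recovered and no model covers >= 50% of another
    model's region).  Note the three models are mutually rank-correlated
    through the shared score sample, so exclusivity is a much stronger
    demand than own-model recovery.
    """
    from .stats import searchlight_isrsa, threshold_map
    from .neural import build_searchlights
    from .traits import build_model, normalize_scores, score_cohort

    cfg = SimulationConfig(seed=seed, conditions=(condition,))
    if noise_sd is not None:
        cfg.noise_sd = noise_sd
    cfg.planted_regions = default_planted_regions(cfg.grid_shape, weight=weight)
    table, _ = generate_cohort(cfg)
    scored, _ = score_cohort(table)
    scores = normalize_scores(scored["total"].to_numpy(),
                              scored["subject_id"].tolist())
    betas, mask, manifest = generate_betas(scores, cfg)
    lights = build_searchlights(mask, V=V, grid=cfg.grid)
    regions = {r["kind"]: np.asarray(r["voxels"])
               for r in manifest["planted_regions"]}
    plant_of = {"low_alike": "low_alike", "high_alike": "high_alike",
                "nn_abs": "nn"}
    coverage: dict[str, dict[str, float]] = {}
    for kind, plant in plant_of.items():
        model = build_model(scores, kind)
        smap = searchlight_isrsa(betas[condition], model, lights,
                                 B=B, seed=seed + 10_000)
        ct = threshold_map(smap)
        surviving = np.zeros(cfg.grid_shape, dtype=bool)
        for i in range(len(ct.frame)):
            row = ct.frame.iloc[i]
            if row["survives_extent"] and row["sign"] == "positive":
                surviving[tuple(ct.cluster_voxels[i].T)] = True
        coverage[kind] = {rk: float(surviving[tuple(v.T)].mean())
                          for rk, v in regions.items()}
    own = all(coverage[k][p] >= 0.5 for k, p in plant_of.items())
    cross_clean = all(coverage[k][rk] < 0.5
                      for k, p in plant_of.items()
                      for rk in regions if rk != p)
    return {"coverage": coverage, "own_recovered": own,
            "exclusive": own and cross_clean}


def config_dict(config: SimulationConfig) -> dict:
    """JSON-serializable view of a config (for provenance records)."""
    d = asdict(config)
    d["planted_regions"] = [
        {"name": r.name, "kind": r.kind, "weight": r.weight,
         "n_voxels": len(r.voxels)}
        for r in config.planted_regions
    ]
    return d
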