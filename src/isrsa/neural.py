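"""Searchlight geometry and subject x subject neural dissimilarity.

A searchlight is the local neighborhood used for multivoxel pattern
analysis: for every in-mask center voxel we take its V nearest in-mask
voxels by millimeter distance (default V = 100), which realizes a sphere
whose radius grows implicitly and keeps the pattern dimensionality fixed
even near mask edges.  Within a voxel set, the neural representational
dissimilarity matrix (RDM) between subjects is 1 minus the Spearman rank
correlation of their beta patterns, so entries live in [0, 2] with a zero
diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .errors import DegenerateDataError, InputError
from .io import GridSpec


@dataclass
class BetaVolumeSet:
    """Beta volumes for one task condition, subjects stacked on axis 0."""

    data: np.ndarray  # (n_subjects, x, y, z)
    grid: GridSpec
    condition: str
    subject_order: list[str]

    def __post_init__(self):
        if self.data.ndim != 4:
            raise InputError("beta data must be subjects x X x Y x Z")
        if self.data.shape[1:] != tuple(self.grid.shape):
            raise InputError(
                f"beta shape {self.data.shape[1:]} does not match grid "
                f"{self.grid.shape}"
            )
        if self.data.shape[0] != len(self.subject_order):
            raise InputError("subject_order length does not match data")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def patterns(self, voxels: np.ndarray) -> np.ndarray:
        """Extract the (n_subjects, V) pattern matrix for a voxel list."""
        v = np.asarray(voxels)
        return self.data[:, v[:, 0], v[:, 1], v[:, 2]]


@dataclass
class Searchlight:
    """A center voxel and its V member voxels (center included)."""

    center: tuple[int, int, int]
    members: np.ndarray  # (V, 3) int voxel indices


def build_searchlights(
    mask: np.ndarray,
    V: int = 100,
    grid: GridSpec | None = None,
    voxel_size: Sequence[float] = (3.0, 3.0, 3.0),
    radius_cap_mm: float | None = None,
) -> list[Searchlight]:
    """One searchlight per in-mask voxel: the V nearest in-mask voxels.

    Distances are Euclidean in millimeters (anisotropic spacings honored).
    Ties at the cutoff distance are broken by ascending (x, y, z) voxel
    index, making membership fully deterministic.  With ``radius_cap_mm``
    set, centers whose enclosing radius exceeds the cap are skipped
    (truncated-sphere alternative near mask edges).
    """
    mask = np.asarray(mask).astype(bool)
    if grid is not None:
        voxel_size = grid.voxel_size
    coords = np.argwhere(mask)  # lexicographically ascending (x, y, z)
    K = len(coords)
    if K < V:
        raise InputError(f"mask has {K} voxels, fewer than V={V}")
    spacing = np.asarray(voxel_size, dtype=float)
    mm = coords * spacing
    tree = cKDTree(mm)
    # kth-neighbor distance bounds the tie radius for each center
    kth_dist, _ = tree.query(mm, k=V)
    if kth_dist.ndim == 2:
        kth_dist = kth_dist[:, -1]

    out: list[Searchlight] = []
    eps = 1e-9
    for c in range(K):
        cand = tree.query_ball_point(mm[c], kth_dist[c] + eps)
        cand = np.asarray(cand)
        d2 = ((mm[cand] - mm[c]) ** 2).sum(axis=1)
        # primary key squared mm distance, secondary key ascending voxel index
        order = np.lexsort((cand, np.round(d2, 6)))
        members = coords[cand[order[:V]]]
        if radius_cap_mm is not None and np.sqrt(d2[order[V - 1]]) > radius_cap_mm:
            continue
        out.append(Searchlight(center=tuple(int(i) for i in coords[c]), members=members))
    return out


@dataclass
class NeuralRDM:
    """Pairwise 1 - Spearman rho between subjects' multivoxel patterns."""

    matrix: np.ndarray
    condition: str
    voxel_set_id: str
    subject_order: list[str]


def _rank_rows(X: np.ndarray, subject_order: Sequence[str]) -> np.ndarray:
    """Rank each subject's pattern (average ties); error on zero variance."""
    R = rankdata(X, axis=1)
    const = R.std(axis=1) == 0
    if const.any():
        bad = [subject_order[i] for i in np.flatnonzero(const)]
        raise DegenerateDataError(
            f"constant pattern (zero rank variance) for subject(s) {bad}"
        )
    return R

def pattern_rdm(betas: BetaVolumeSet, voxels: np.ndarray,
                voxel_set_id: str = "") -> NeuralRDM:
    """Neural RDM over a voxel list: 1 - Spearman rho for each subject pair."""
    voxels = np.asarray(voxels)
    if betas.n_subjects < 2:
        raise InputError("need at least 2 subjects")
    X = betas.patterns(voxels)
    if X.shape[1] < 3:
        raise InputError("need at least 3 voxels for a rank correlation")
    if not np.isfinite(X).all():
        n_bad = int((~np.isfinite(X)).any(axis=0).sum())
        raise InputError(f"{n_bad} voxel(s) with non-finite betas in voxel set")
    R = _rank_rows(X, betas.subject_order)
    rdm = 1.0 - np.corrcoef(R)
    rdm = (rdm + rdm.T) / 2.0
    np.fill_diagonal(rdm, 0.0)
    return NeuralRDM(
        matrix=rdm,
        condition=betas.condition,
        voxel_set_id=voxel_set_id,
        subject_order=list(betas.subject_order),
    )


def roi_mean(betas: BetaVolumeSet, roi_mask: np.ndarray) -> np.ndarray:
    """Per-subject mean of finite beta values within an ROI mask."""
    roi_mask = np.asarray(roi_mask).astype(bool)
    if roi_mask.shape != tuple(betas.grid.shape):
        raise InputError("ROI mask grid does not match beta grid")
    if not roi_mask.any():
        raise InputError("empty ROI mask")
    X = betas.data[:, roi_mask]
    finite = np.isfinite(X)
    if not finite.any(axis=1).all():
        raise InputError("a subject has no finite voxels in the ROI")
    with np.errstate(invalid="ignore"):
        return np.where(finite, X, 0.0).sum(axis=1) / finite.sum(axis=1)
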