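"""IS-RSA statistics: model-neural correlation, Mantel test, thresholding.

The correspondence between a trait-derived intersubject model and a neural
RDM is the Spearman rank correlation of their strictly-lower triangles
(n(n-1)/2 subject pairs; 435 for n = 30).  Significance comes from a Mantel
permutation test: shuffling subject labels — rows and columns of the model
matrix jointly — and recomputing the correlation builds an empirical null;
the p-value is the fraction of permuted statistics strictly exceeding the
observed one (one-sided; for negative observed correlations the test can
look in the negative direction instead, mirroring how anticorrespondence
clusters are reported).

Because a joint row/column shuffle only permutes which pair each
lower-triangle cell refers to, ranks of the permuted vector are the
permuted ranks.  The permutation loop therefore reduces to gathers and a
matrix-vector product on standardized rank vectors, which is what makes a
whole-brain searchlight pass with B = 1000 permutations cheap.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata, t as t_dist
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, InputError
from .io import GridSpec
from .neural import BetaVolumeSet, Searchlight, _rank_rows
from .traits import IntersubjectModel


# ---------------------------------------------------------------------------
# lower triangle and Spearman machinery

def lower_triangle(matrix: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Strictly-below-diagonal entries in fixed row-major order.

    The ordering is identical for every matrix of the same n, so vectors
    from different matrices are pair-aligned.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InputError("expected a square matrix")
    if not np.allclose(m, m.T, atol=atol, rtol=0):
        raise InputError("matrix is asymmetric beyond tolerance")
    return m[np.tril_indices(m.shape[0], k=-1)]


def _standardized_ranks(x: np.ndarray, what: str) -> np.ndarray:
    """Average-tie ranks, centered and scaled to unit L2 norm."""
    r = rankdata(x)
    c = r - r.mean()
    nrm = math.sqrt(float(c @ c))
    if nrm == 0.0:
        raise DegenerateDataError(f"zero variance in {what}")
    return c / nrm


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average ranks; exactly 1 for tied rank vectors."""
    rx, ry = rankdata(x), rankdata(y)
    if np.array_equal(rx, ry):
        if rx.std() == 0:
            raise DegenerateDataError("zero variance in both vectors")
        return 1.0
    zx = _standardized_ranks(x, "first vector")
    zy = _standardized_ranks(y, "second vector")
    return float(np.clip(zx @ zy, -1.0, 1.0))


def _matrix_of(obj) -> np.ndarray:
    return obj.matrix if hasattr(obj, "matrix") else np.asarray(obj, dtype=float)


def _check_orders(model, neural) -> None:
    mo = getattr(model, "subject_order", None)
    no = getattr(neural, "subject_order", None)
    if mo is not None and no is not None and list(mo) != list(no):
        raise InputError("model and neural RDM subject orders differ")


def isrsa_correlation(model, neural) -> float:
    """Spearman rho between the lower triangles of model and neural RDMs."""
    _check_orders(model, neural)
    a, b = _matrix_of(model), _matrix_of(neural)
    if a.shape != b.shape:
        raise InputError(f"matrix shapes differ: {a.shape} vs {b.shape}")
    return spearman(lower_triangle(a), lower_triangle(b))


# ---------------------------------------------------------------------------
# Mantel permutation test

def _pair_index_matrix(n: int) -> np.ndarray:
    """P[i, j] = position of unordered pair {i, j} in the LT vector."""
    m = n * (n - 1) // 2
    P = np.zeros((n, n), dtype=np.int64)
    rows, cols = np.tril_indices(n, k=-1)
    P[rows, cols] = np.arange(m)
    P[cols, rows] = np.arange(m)
    return P


def make_permutations(n: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """B uniform random permutations of n subject labels, as a (B, n) array."""
    return np.array([rng.permutation(n) for _ in range(B)])


def permuted_rank_gather(perms: np.ndarray, n: int) -> np.ndarray:
    """Map permutations of subject labels to permutations of pair indices.

    Row b gives, for each lower-triangle position (i, j), the position of
    pair {perm_b(i), perm_b(j)} — i.e. where each cell of the label-shuffled
    matrix comes from in the original lower-triangle vector.
    """
    P = _pair_index_matrix(n)
    rows, cols = np.tril_indices(n, k=-1)
    return P[perms[:, rows], perms[:, cols]]


@dataclass
class MantelResult:
    rho: float
    p: float
    B: int
    seed: int | None
    alternative: str


class MantelEngine:
    """Precomputed permutation schedule for one model matrix.

    Shares one schedule across many neural RDMs (e.g. all searchlights of a
    map) so that p-values across centers are comparable, and amortizes the
    standardization of the permuted model ranks.
    """

    def __init__(self, model, B: int = 1000, seed: int | None = None,
                 exhaustive: bool = False, permutations: np.ndarray | None = None):
        _mat = _matrix_of(model)
        self.n = _mat.shape[0]
        self.seed = seed
        v = lower_triangle(_mat)
        self.z_model = _standardized_ranks(v, "model lower triangle")
        if permutations is None:
            if exhaustive:
                permutations = np.array(
                    list(itertools.permutations(range(self.n))), dtype=np.int64
                )
            else:
                rng = np.random.default_rng(seed)
                permutations = make_permutations(self.n, B, rng)
        self.permutations = permutations
        self.B = len(permutations)
        idx = permuted_rank_gather(permutations, self.n)
        # rows are permutations of z_model, already centered/unit-norm
        self.Z = self.z_model[idx]

    def test(self, neural, alternative: str = "greater",
             smoothing: bool = False) -> MantelResult:
        _mat = _matrix_of(neural)
        if _mat.shape[0] != self.n:
            raise InputError("neural RDM size does not match the model")
        z_neural = _standardized_ranks(lower_triangle(_mat),
                                       "neural RDM lower triangle")
        rho = float(np.clip(self.z_model @ z_neural, -1.0, 1.0))
        rho_perm = np.clip(self.Z @ z_neural, -1.0, 1.0)
        side = alternative
        if side == "auto":
            side = "greater" if rho >= 0 else "less"
        if side == "greater":
            count = int((rho_perm > rho).sum())
        elif side == "less":
            count = int((rho_perm < rho).sum())
        else:
            raise InputError(f"unknown alternative {alternative!r}")
        p = (count + 1) / (self.B + 1) if smoothing else count / self.B
        return MantelResult(rho=rho, p=float(p), B=self.B, seed=self.seed,
                            alternative=side)


def mantel_test(model, neural, B: int = 1000, seed: int | None = None,
                alternative: str = "greater", exhaustive: bool = False,
                permutations: np.ndarray | None = None,
                smoothing: bool = False) -> MantelResult:
    """Mantel permutation test of model-neural lower-triangle correlation.

    Subject labels of the model matrix are shuffled jointly over rows and
    columns B times (or exhaustively over all n! permutations); p is the
    fraction of permuted rho strictly beyond the observed one in the tested
    direction.  Deterministic given ``seed``.
    """
    _check_orders(model, neural)
    n = _matrix_of(model).shape[0]
    if n < 4:
        raise InputError("Mantel test needs at least 4 subjects")
    if not exhaustive and permutations is None and B < 1:
        raise InputError("B must be >= 1")
    eng = MantelEngine(model, B=B, seed=seed, exhaustive=exhaustive,
                       permutations=permutations)
    return eng.test(neural, alternative=alternative, smoothing=smoothing)


# ---------------------------------------------------------------------------
# searchlight maps

@dataclass
class SearchlightMap:
    """Per-center rho and permutation p in volume space (NaN = undefined)."""

    rho_volume: np.ndarray
    p_volume: np.ndarray
    grid: GridSpec
    condition: str
    model_kind: str
    B: int = 0
    seed: int | None = None
    failures: dict = field(default_factory=dict)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.p_volume)


def searchlight_isrsa(
    betas: BetaVolumeSet,
    model: IntersubjectModel,
    searchlights: list[Searchlight],
    B: int = 1000,
    seed: int | None = 0,
    alternative: str = "auto",
    shared_schedule: bool = True,
    smoothing: bool = False,
) -> SearchlightMap:
    """Run the Mantel test in every searchlight and map rho/p to centers.

    One permutation schedule (derived from ``seed``) is reused across all
    searchlights by default so the maps are comparable across centers;
    ``shared_schedule=False`` draws an independent schedule per center.
    Searchlights with degenerate data are recorded as undefined with the
    reason, never fatal.
    """
    if list(model.subject_order) != list(betas.subject_order):
        raise InputError("beta set and model subject orders differ")
    shape = tuple(betas.grid.shape)
    rho_vol = np.full(shape, np.nan)
    p_vol = np.full(shape, np.nan)
    failures: dict = {}

    engine = MantelEngine(model, B=B, seed=seed)
    child_seeds = None
    if not shared_schedule:
        child_seeds = np.random.SeedSequence(seed).spawn(len(searchlights))

    R_model = engine  # shared
    for k, sl in enumerate(searchlights):
        if not shared_schedule:
            eng = MantelEngine(
                model, B=B,
                seed=int(child_seeds[k].generate_state(1)[0] % (2**31)),
            )
        else:
            eng = R_model
        try:
            X = betas.patterns(sl.members)
            if not np.isfinite(X).all():
                raise DegenerateDataError("non-finite betas in searchlight")
            R = _rank_rows(X, betas.subject_order)
            rdm = 1.0 - np.corrcoef(R)
            res = eng.test(rdm, alternative=alternative, smoothing=smoothing)
        except DegenerateDataError as exc:
            failures[sl.center] = str(exc)
            continue
        rho_vol[sl.center] = res.rho
        p_vol[sl.center] = res.p
    return SearchlightMap(
        rho_volume=rho_vol, p_volume=p_vol, grid=betas.grid,
        condition=betas.condition, model_kind=model.kind,
        B=engine.B, seed=seed, failures=failures,
    )


# ---------------------------------------------------------------------------
# map thresholding

_STRUCTURES = {6: 1, 18: 2, 26: 3}


@dataclass
class ClusterTable:
    """Thresholded clusters of a searchlight map, in reporting-table form."""

    frame: "pd.DataFrame"  # noqa: F821 (imported lazily below)
    params: dict
    cluster_voxels: list[np.ndarray] = field(default_factory=list)

    def surviving(self, fdr: bool = False):
        f = self.frame
        return f[f["survives_fdr"] if fdr else f["survives_extent"]]


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level q."""
    reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def threshold_map(
    smap: SearchlightMap,
    p_cluster_forming: float = 0.005,
    k_min: int = 10,
    q: float = 0.05,
    connectivity: int = 18,
) -> ClusterTable:
    """Threshold a searchlight map into signed clusters.

    Centers with p below the cluster-forming threshold are binarized and
    split by the sign of rho; connected components (6/18/26 connectivity,
    default 18 = faces + edges) become clusters.  ``survives_extent``
    requires extent >= k_min; ``survives_fdr`` marks clusters containing at
    least one center that passes Benjamini-Hochberg FDR at level q computed
    over all defined centers of the map.
    """
    import pandas as pd

    if connectivity not in _STRUCTURES:
        raise InputError("connectivity must be one of 6, 18, 26")
    defined = smap.defined
    if not defined.any():
        raise InputError("map has no defined centers")
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])

    fdr_pass = np.zeros(smap.p_volume.shape, dtype=bool)
    pv = smap.p_volume[defined]
    fdr_pass[defined] = bh_fdr(pv, q=q)

    supra = defined & (smap.p_volume < p_cluster_forming)
    rows, voxel_sets = [], []
    for sign, sign_name in ((1, "positive"), (-1, "negative")):
        binary = supra & (np.sign(smap.rho_volume) == sign)
        labels, n_lab = ndimage.label(binary, structure=structure)
        for lab in range(1, n_lab + 1):
            vox = np.argwhere(labels == lab)
            rhos = smap.rho_volume[tuple(vox.T)]
            peak_i = int(np.argmax(np.abs(rhos)))
            peak_vox = vox[peak_i]
            peak_mm = smap.grid.voxel_to_mm(peak_vox)[0]
            rows.append({
                "condition": smap.condition,
                "model": smap.model_kind,
                "sign": sign_name,
                "peak_x_mm": float(peak_mm[0]),
                "peak_y_mm": float(peak_mm[1]),
                "peak_z_mm": float(peak_mm[2]),
                "extent": int(len(vox)),
                "peak_rho": float(rhos[peak_i]),
                "peak_p": float(smap.p_volume[tuple(peak_vox)]),
                "survives_extent": bool(len(vox) >= k_min),
                "survives_fdr": bool(fdr_pass[tuple(vox.T)].any()),
            })
            voxel_sets.append(vox)

    frame = pd.DataFrame(
        rows,
        columns=["condition", "model", "sign", "peak_x_mm", "peak_y_mm",
                 "peak_z_mm", "extent", "peak_rho", "peak_p",
                 "survives_extent", "survives_fdr"],
    )
    if len(frame):
        order = frame.sort_values(
            ["sign", "peak_rho"], ascending=[False, False], kind="stable"
        ).index
        voxel_sets = [voxel_sets[i] for i in order]
        frame = frame.loc[order].reset_index(drop=True)
    params = {"p_cluster_forming": p_cluster_forming, "k_min": k_min,
              "q": q, "connectivity": connectivity}
    return ClusterTable(frame=frame, params=params, cluster_voxels=voxel_sets)


def compare_maps(map_a: SearchlightMap, map_b: SearchlightMap) -> float:
    """Voxel-wise Spearman rho between two maps' rho values.

    Centers undefined in either map are listwise excluded; fewer than 3
    overlapping centers is an error.
    """
    if map_a.grid != map_b.grid:
        raise InputError("maps are on different grids")
    both = map_a.defined & map_b.defined
    if both.sum() < 3:
        raise InputError(
            f"only {int(both.sum())} overlapping defined centers (< 3)"
        )
    return spearman(map_a.rho_volume[both], map_b.rho_volume[both])


# ---------------------------------------------------------------------------
# partial rank correlation (ROI analyses)

def partial_spearman(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray
) -> tuple[float, float]:
    """Partial Spearman correlation of x and y controlling for covariates.

    All variables are rank-transformed (average ties); ranked x and y are
    residualized on the ranked covariates plus an intercept by least
    squares, and the product-moment correlation of the residuals is
    returned with a two-sided p from the t approximation on
    n - 2 - n_covariates degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] == x.size and C.shape[1] != x.size:
        pass
    elif C.shape[1] == x.size:
        C = C.T
    k = C.shape[1]
    n = x.size
    if y.size != n or C.shape[0] != n:
        raise InputError("x, y and covariates must share the subject axis")
    if n <= k + 2:
        raise InputError(f"need n > {k + 2} subjects for {k} covariates")
    rx = rankdata(x)
    ry = rankdata(y)
    RC = np.column_stack([np.ones(n)] + [rankdata(C[:, j]) for j in range(k)])
    if np.linalg.matrix_rank(RC) < RC.shape[1]:
        raise InputError("rank-deficient covariate matrix")
    beta_x, *_ = np.linalg.lstsq(RC, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(RC, ry, rcond=None)
    ex = rx - RC @ beta_x
    ey = ry - RC @ beta_y
    denom = math.sqrt(float(ex @ ex) * float(ey @ ey))
    if denom == 0.0:
        raise DegenerateDataError("zero residual variance")
    r = float(np.clip((ex @ ey) / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t_stat = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * float(t_dist.sf(abs(t_stat), df))
    return r, p
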