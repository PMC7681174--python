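"""Readers/writers for the pipeline's on-disk artifacts.

Volumes are NIfTI-1 (via nibabel): beta maps as one 3D file per subject
per condition or as a 4D stack, always accompanied by a JSON manifest that
fixes subject order (filesystem order is never trusted).  Tables are TSV,
configuration YAML/JSON.  All volumes in one analysis must share one grid
exactly; nothing is resampled, because resampling would silently change
searchlight membership.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import InputError

__all__ = [
    "GridSpec",
    "read_beta_set",
    "write_beta_set",
    "read_mask",
    "write_mask",
    "read_subject_table",
    "write_subject_table",
    "write_model_matrix",
    "read_model_matrix",
    "write_searchlight_map",
    "read_searchlight_map",
    "write_cluster_table",
    "load_config",
    "config_hash",
]


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid identity: shape, spacing (mm) and affine orientation."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: tuple  # nested tuple, hashable

    @classmethod
    def from_image(cls, img: nib.spatialimages.SpatialImage) -> "GridSpec":
        shape = tuple(int(s) for s in img.shape[:3])
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        affine = tuple(tuple(float(v) for v in row) for row in img.affine)
        return cls(shape=shape, voxel_size=zooms, affine=affine)

    @classmethod
    def isotropic(cls, shape: Sequence[int], voxel_mm: float = 3.0) -> "GridSpec":
        shape = tuple(int(s) for s in shape)
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        return cls(
            shape=shape,
            voxel_size=(voxel_mm,) * 3,
            affine=tuple(tuple(row) for row in aff),
        )

    @property
    def affine_array(self) -> np.ndarray:
        return np.asarray(self.affine, dtype=float)

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices to millimeter coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (hom @ self.affine_array.T)[:, :3]


def _check_grid(img, grid: GridSpec | None, path) -> GridSpec:
    g = GridSpec.from_image(img)
    if grid is not None and g != grid:
        raise InputError(f"{path}: grid {g.shape}@{g.voxel_size} does not match "
                         f"expected {grid.shape}@{grid.voxel_size}")
    return g


def read_beta_set(
    source: str | Path | Sequence[str | Path],
    subject_order: Sequence[str] | None = None,
    manifest: str | Path | None = None,
    condition: str = "",
):
    """Load beta volumes for one condition into a BetaVolumeSet.

    ``source`` is either a single 4D NIfTI path or a sequence of 3D paths.
    Subject order comes from ``subject_order`` or from a JSON ``manifest``
    with a ``subject_order`` key; for per-subject 3D files the manifest may
    also carry ``files`` mapping order to paths.
    """
    from .neural import BetaVolumeSet

    if manifest is not None:
        meta = json.loads(Path(manifest).read_text())
        subject_order = meta.get("subject_order", subject_order)
        condition = meta.get("condition", condition)
    if subject_order is None:
        raise InputError("subject order must come from a manifest or argument, "
                         "never from filesystem order")
    subject_order = [str(s) for s in subject_order]

    if isinstance(source, (str, Path)):
        img = nib.load(str(source))
        grid = GridSpec.from_image(img)
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise InputError(f"{source}: expected a 4D stack")
        data = np.moveaxis(data, -1, 0)
    else:
        paths = [Path(p) for p in source]
        grid = None
        vols = []
        for p in paths:
            img = nib.load(str(p))
            grid = _check_grid(img, grid, p)
            vols.append(np.asarray(img.dataobj, dtype=float))
        data = np.stack(vols, axis=0)
    if data.shape[0] != len(subject_order):
        raise InputError(
            f"{data.shape[0]} volumes but {len(subject_order)} subjects in manifest"
        )
    return BetaVolumeSet(
        data=data, grid=grid, condition=condition, subject_order=subject_order
    )


def write_beta_set(betas, path: str | Path) -> Path:
    """Write a BetaVolumeSet as a 4D NIfTI plus a JSON sidecar manifest."""
    path = Path(path)
    img = nib.Nifti1Image(
        np.moveaxis(betas.data, 0, -1).astype(np.float64), betas.grid.affine_array
    )
    img.header.set_zooms((*betas.grid.voxel_size, 1.0))
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    sidecar = Path(str(sidecar) + ".json")
    sidecar.write_text(json.dumps(
        {"subject_order": betas.subject_order, "condition": betas.condition},
        indent=2,
    ))
    return sidecar


def read_mask(path: str | Path, grid: GridSpec | None = None) -> np.ndarray:
    """Load a binary mask; any nonzero voxel is inside."""
    img = nib.load(str(path))
    _check_grid(img, grid, path)
    mask = np.asarray(img.dataobj) != 0
    if not mask.any():
        raise InputError(f"{path}: mask is empty")
    return mask


def write_mask(mask: np.ndarray, grid: GridSpec, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), grid.affine_array)
    img.header.set_zooms(grid.voxel_size)
    nib.save(img, str(path))


def read_subject_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    if table.empty:
        raise InputError(f"{path}: empty subject table")
    return table


def write_subject_table(table: pd.DataFrame, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    table.to_csv(path, sep=sep, index=False)


def write_model_matrix(model, path: str | Path, extra: dict | None = None) -> None:
    """Square dissimilarity matrix as TSV with subject ids, plus JSON sidecar."""
    df = pd.DataFrame(model.matrix, index=model.subject_order,
                      columns=model.subject_order)
    df.to_csv(path, sep="\t")
    meta = {"kind": model.kind, "n_subjects": model.n}
    if extra:
        meta.update(extra)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_model_matrix(path: str | Path):
    from .traits import IntersubjectModel

    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = Path(str(path) + ".json")
    kind = json.loads(meta_path.read_text())["kind"] if meta_path.exists() else "unknown"
    return IntersubjectModel(
        kind=kind,
        matrix=df.to_numpy(dtype=float),
        subject_order=[str(s) for s in df.index],
    )


def write_searchlight_map(smap, prefix: str | Path) -> tuple[Path, Path]:
    """Write rho and p volumes (NaN at undefined centers) as NIfTI."""
    prefix = Path(prefix)
    aff = smap.grid.affine_array
    paths = []
    for name, vol in (("rho", smap.rho_volume), ("p", smap.p_volume)):
        p = Path(f"{prefix}_{name}.nii.gz")
        img = nib.Nifti1Image(vol.astype(np.float64), aff)
        img.header.set_zooms(smap.grid.voxel_size)
        nib.save(img, str(p))
        paths.append(p)
    meta = Path(f"{prefix}_map.json")
    meta.write_text(json.dumps(
        {"condition": smap.condition, "model_kind": smap.model_kind,
         "B": smap.B, "seed": smap.seed}, indent=2))
    return tuple(paths)


def read_searchlight_map(prefix: str | Path):
    from .stats import SearchlightMap

    prefix = Path(prefix)
    rho_img = nib.load(f"{prefix}_rho.nii.gz")
    p_img = nib.load(f"{prefix}_p.nii.gz")
    meta = json.loads(Path(f"{prefix}_map.json").read_text())
    return SearchlightMap(
        rho_volume=np.asarray(rho_img.dataobj, dtype=float),
        p_volume=np.asarray(p_img.dataobj, dtype=float),
        grid=GridSpec.from_image(rho_img),
        condition=meta.get("condition", ""),
        model_kind=meta.get("model_kind", ""),
        B=int(meta.get("B", 0)),
        seed=meta.get("seed"),
    )


def write_cluster_table(table, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)
    Path(str(path) + ".json").write_text(json.dumps(table.params, indent=2))


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def config_hash(config: dict) -> str:
    """Stable short hash of a config dict, for provenance records."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
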