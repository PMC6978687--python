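"""Feature-volume ingestion: stacking co-registered NIfTI volumes, grid
resampling, and flattening masked voxels into the analysis table.

A :class:`FeatureVolume` is a 4D stack indexed ``(x, y, z, feature)`` on a
single voxel grid; a :class:`VoxelTable` holds the masked voxels as rows with
their integer grid coordinates retained so results can be scattered back onto
the grid losslessly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "FeatureVolume",
    "LabelVolume",
    "VoxelTable",
    "load_feature_volumes",
    "load_manifest",
    "resample_to_grid",
    "build_voxel_table",
    "scatter_to_grid",
]


def _default_affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class FeatureVolume:
    """A 4D stack of co-registered scalar feature volumes on one grid.

    Parameters
    ----------
    data:
        Array of shape ``(nx, ny, nz, n_features)``.
    spacing:
        Voxel size in mm along each axis.
    feature_names:
        One name per feature channel, in stack order.
    affine:
        4x4 grid-index-to-world transform (NIfTI convention).
    mask:
        Optional boolean inclusion mask on the same grid. Voxels with a
        non-finite value in *any* feature are always excluded regardless.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    feature_names: list[str]
    affine: np.ndarray = None  # type: ignore[assignment]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (x, y, z, feature); got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values; got {self.spacing}")
        self.feature_names = [str(n) for n in self.feature_names]
        if self.data.shape[-1] != len(self.feature_names):
            raise ValueError(
                f"feature axis has length {self.data.shape[-1]} but "
                f"{len(self.feature_names)} feature names were given"
            )
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.grid_shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != grid shape {self.grid_shape}"
                )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_features(self) -> int:
        return self.data.shape[-1]

    def valid_mask(self) -> np.ndarray:
        """Boolean grid of voxels that are finite in every feature and inside
        the inclusion mask (if any)."""
        finite = np.isfinite(self.data).all(axis=-1)
        if self.mask is not None:
            finite &= self.mask
        return finite

    def save(self, out_dir: str | Path, prefix: str = "") -> list[Path]:
        """Write one NIfTI-1 file per feature; returns the written paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, name in enumerate(self.feature_names):
            img = nib.Nifti1Image(self.data[..., i].astype(np.float32), self.affine)
            img.header.set_zooms(self.spacing)
            p = out_dir / f"{prefix}{name}.nii"
            nib.save(img, p)
            paths.append(p)
        return paths


@dataclass
class LabelVolume:
    """3D integer label volume on the reference grid, with a legend mapping
    each label to its meaning. Label 0 is reserved for unmasked voxels."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = None  # type: ignore[assignment]
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label data must be 3D; got shape {self.data.shape}")
        self.data = self.data.astype(np.int32)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        img = nib.Nifti1Image(self.data.astype(np.int16), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, path)
        return path

    @classmethod
    def load(cls, path: str | Path, legend: dict[int, str] | None = None) -> "LabelVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        return cls(
            data=data,
            spacing=tuple(float(z) for z in img.header.get_zooms()[:3]),
            affine=np.asarray(img.affine),
            legend=legend or {},
        )


@dataclass
class VoxelTable:
    """Masked voxels as rows, features as columns.

    ``coords`` keeps the integer grid index of every row so that any per-row
    quantity can be scattered back onto the grid (:func:`scatter_to_grid`).
    """

    coords: np.ndarray
    features: np.ndarray
    feature_names: list[str]
    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.features = np.asarray(self.features, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_rows, 3)")
        if self.features.shape[0] != self.coords.shape[0]:
            raise ValueError("coords and features row counts differ")
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError("feature column count != number of feature names")
        flat = np.ravel_multi_index(self.coords.T, self.grid_shape)
        if len(np.unique(flat)) != len(flat):
            raise ValueError("duplicate voxel coordinates in table")

    @property
    def n_rows(self) -> int:
        return self.coords.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def load_manifest(path: str | Path) -> tuple[list[str], list[Path]]:
    """Read a plain-text manifest: one ``name<TAB or whitespace>path`` per line.

    Lines with a single token are treated as a path whose stem is the name.
    Blank lines and ``#`` comments are skipped.
    """
    names, paths = [], []
    base = Path(path).parent
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) == 1:
            p = Path(parts[0])
            name = p.stem.removesuffix(".nii")
        else:
            name, p = parts[0], Path(parts[1].strip())
        if not p.is_absolute():
            p = base / p
        names.append(name)
        paths.append(p)
    return names, paths


def _nii_stem(path: Path) -> str:
    stem = path.name
    for suffix in (".gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    return stem


def load_feature_volumes(
    paths: Sequence[str | Path],
    mask_path: str | Path | None = None,
    feature_names: Sequence[str] | None = None,
    allow_single: bool = False,
) -> FeatureVolume:
    """Stack co-registered NIfTI-1 feature volumes into a :class:`FeatureVolume`.

    All files must already share one grid (resample upstream with
    :func:`resample_to_grid` if they do not). Fewer than two features is
    rejected as uninformative unless ``allow_single`` is set.
    """
    paths = [Path(p) for p in paths]
    if len(paths) < 2 and not allow_single:
        raise ValueError(
            f"need at least 2 feature volumes (got {len(paths)}); "
            "pass allow_single=True to override"
        )
    if feature_names is None:
        feature_names = [_nii_stem(p) for p in paths]
    elif len(feature_names) != len(paths):
        raise ValueError("feature_names length != number of paths")

    imgs = [nib.load(str(p)) for p in paths]
    shapes = [img.shape[:3] for img in imgs]
    if len(set(shapes)) > 1:
        detail = ", ".join(f"{p.name}: {s}" for p, s in zip(paths, shapes))
        raise ValueError(f"feature volumes are not on one grid after resampling: {detail}")

    data = np.stack([np.asarray(img.get_fdata(), dtype=float) for img in imgs], axis=-1)
    spacing = tuple(float(z) for z in imgs[0].header.get_zooms()[:3])
    affine = np.asarray(imgs[0].affine)

    mask = None
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        if mimg.shape[:3] != shapes[0]:
            raise ValueError(
                f"mask grid {mimg.shape[:3]} does not match feature grid {shapes[0]}"
            )
        mask = np.asanyarray(mimg.dataobj) > 0

    return FeatureVolume(
        data=data,
        spacing=spacing,
        feature_names=list(feature_names),
        affine=affine,
        mask=mask,
    )


def resample_to_grid(
    volume: FeatureVolume | LabelVolume,
    target_spacing: Sequence[float],
) -> FeatureVolume | LabelVolume:
    """Resample onto ``target_spacing``: trilinear for scalar features,
    nearest-neighbour for label volumes. World-space extent is preserved to
    within one voxel."""
    target = tuple(float(s) for s in target_spacing)
    if len(target) != 3 or any(s <= 0 for s in target):
        raise ValueError(f"target_spacing must be 3 strictly positive values; got {target}")

    src = volume.spacing
    factors = np.array([s / t for s, t in zip(src, target)])
    if np.allclose(factors, 1.0, atol=1e-9):
        return dataclasses.replace(volume)

    new_affine = volume.affine.copy()
    new_affine[:3, :3] = volume.affine[:3, :3] / factors[np.newaxis, :]

    if isinstance(volume, LabelVolume):
        out = ndimage.zoom(volume.data, factors, order=0, mode="nearest", grid_mode=True)
        return LabelVolume(
            data=out, spacing=target, affine=new_affine, legend=dict(volume.legend)
        )

    channels = [
        ndimage.zoom(volume.data[..., i], factors, order=1, mode="nearest", grid_mode=True)
        for i in range(volume.n_features)
    ]
    mask = None
    if volume.mask is not None:
        mask = ndimage.zoom(
            volume.mask.astype(np.uint8), factors, order=0, mode="nearest", grid_mode=True
        ).astype(bool)
    return FeatureVolume(
        data=np.stack(channels, axis=-1),
        spacing=target,
        feature_names=list(volume.feature_names),
        affine=new_affine,
        mask=mask,
    )


def build_voxel_table(
    volume: FeatureVolume,
    mask: LabelVolume | np.ndarray | None = None,
) -> VoxelTable:
    """Flatten masked, finite voxels into one row each (x-fastest ordering).

    The mask argument further restricts the volume's own inclusion mask; NaN
    voxels are always excluded.
    """
    keep = volume.valid_mask()
    if mask is not None:
        mdata = mask.data if isinstance(mask, LabelVolume) else np.asarray(mask)
        if mdata.shape != volume.grid_shape:
            raise ValueError(f"mask shape {mdata.shape} != grid shape {volume.grid_shape}")
        keep &= mdata > 0
    if not keep.any():
        raise ValueError("mask selects no voxels")

    # x-fastest (Fortran) row ordering so scatter/gather round-trips are stable
    flat_idx = np.nonzero(keep.reshape(-1, order="F"))[0]
    coords = np.array(np.unravel_index(flat_idx, volume.grid_shape, order="F")).T
    features = volume.data[coords[:, 0], coords[:, 1], coords[:, 2], :]
    return VoxelTable(
        coords=coords,
        features=features,
        feature_names=list(volume.feature_names),
        grid_shape=volume.grid_shape,
        spacing=volume.spacing,
        affine=volume.affine,
    )


def scatter_to_grid(
    table: VoxelTable,
    values: np.ndarray,
    fill: float | int = 0,
    dtype=None,
) -> np.ndarray:
    """Scatter one value per table row back onto the 3D grid (inverse of
    :func:`build_voxel_table` for per-voxel quantities)."""
    values = np.asarray(values)
    if values.shape[0] != table.n_rows:
        raise ValueError("values length != table row count")
    out = np.full(table.grid_shape, fill, dtype=dtype or values.dtype)
    out[table.coords[:, 0], table.coords[:, 1], table.coords[:, 2]] = values
    return out
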