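"""Synthetic multi-feature phantom volumes with ground-truth tissue labels.

The phantom emulates a stack of co-registered scalar feature maps over a
brain-like scene: a healthy background, a tumor region, a thin interface
shell between them, and (optionally) small satellite spots. Each tissue class
has its own per-feature mean and standard deviation; classes may additionally
carry a radial within-class gradient so that tissue is internally
heterogeneous rather than piecewise constant. Interface voxels take the
arithmetic mean of the two adjacent classes' local mean fields plus noise.

Every run is fully determined by ``(spec, spec.seed)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import ndimage

from .volume_stack import FeatureVolume, LabelVolume

__all__ = [
    "Ellipsoid",
    "Box",
    "Background",
    "TissueClass",
    "PhantomSpec",
    "generate_phantom",
    "default_spec",
]

_STRUCT_6CONN = ndimage.generate_binary_structure(3, 1)


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid region in voxel coordinates."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def region_mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
        acc = np.zeros(grid_shape)
        for g, c, r in zip(grids, self.center, self.radii):
            if r <= 0:
                raise ValueError(f"ellipsoid radii must be positive; got {self.radii}")
            acc = acc + ((g - c) / r) ** 2
        return acc <= 1.0

    def reference_center(self) -> tuple[float, float, float]:
        return self.center


@dataclass
class Box:
    """Axis-aligned box region in voxel coordinates."""

    center: tuple[float, float, float]
    half_size: tuple[float, float, float]

    def region_mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
        inside = np.ones(grid_shape, dtype=bool)
        for g, c, h in zip(grids, self.center, self.half_size):
            inside &= np.abs(g - c) <= h
        return inside

    def reference_center(self) -> tuple[float, float, float]:
        return self.center


@dataclass
class Background:
    """Everything not claimed by an explicit geometry."""

    def region_mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        return np.ones(grid_shape, dtype=bool)

    def reference_center(self) -> tuple[float, float, float] | None:
        return None


Geometry = Ellipsoid | Box | Background


@dataclass
class TissueClass:
    """One tissue class: geometry plus per-feature Gaussian parameters.

    ``gradient`` (optional, length n_features) adds ``gradient * (rho - 0.5)``
    to the mean field, where ``rho`` in [0, 1] is the normalized radial
    distance from the class's reference center. This makes the class
    internally heterogeneous along a smooth spatial axis.
    ``make_interface`` marks the class as bounded by an interface shell
    against the background class.
    """

    name: str
    geometry: Geometry
    feature_means: np.ndarray
    feature_sds: np.ndarray
    gradient: np.ndarray | None = None
    make_interface: bool = False

    def __post_init__(self) -> None:
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_sds = np.asarray(self.feature_sds, dtype=float)
        if self.gradient is not None:
            self.gradient = np.asarray(self.gradient, dtype=float)
        if (self.feature_sds < 0).any():
            raise ValueError(f"class {self.name!r}: feature_sds must be non-negative")


@dataclass
class PhantomSpec:
    """Full description of a synthetic phantom; reproducible given its seed."""

    grid_shape: tuple[int, int, int]
    voxel_spacing: tuple[float, float, float]
    n_features: int
    tissue_classes: list[TissueClass]
    interface_width: int = 1
    noise_sd: np.ndarray | float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (self.n_features,)
        ).copy()

    def validate(self) -> None:
        if self.n_features < 2:
            raise ValueError("n_features must be >= 2")
        if any(s < 4 for s in self.grid_shape):
            raise ValueError(f"grid_shape axes must all be >= 4; got {self.grid_shape}")
        if self.interface_width < 0:
            raise ValueError("interface_width must be non-negative")
        if (self.noise_sd < 0).any():
            raise ValueError("noise_sd must be non-negative")
        if not self.tissue_classes:
            raise ValueError("at least one tissue class is required")
        for cls in self.tissue_classes:
            for vec, what in (
                (cls.feature_means, "feature_means"),
                (cls.feature_sds, "feature_sds"),
            ):
                if vec.shape != (self.n_features,):
                    raise ValueError(
                        f"class {cls.name!r}: {what} has length {vec.shape[0]}, "
                        f"expected n_features={self.n_features}"
                    )
            if cls.gradient is not None and cls.gradient.shape != (self.n_features,):
                raise ValueError(
                    f"class {cls.name!r}: gradient has length {cls.gradient.shape[0]}, "
                    f"expected n_features={self.n_features}"
                )
        n_background = sum(
            isinstance(c.geometry, Background) for c in self.tissue_classes
        )
        if n_background > 1:
            raise ValueError("at most one Background class allowed")
        # explicit geometries must be pairwise disjoint
        explicit = [
            c for c in self.tissue_classes if not isinstance(c.geometry, Background)
        ]
        masks = [c.geometry.region_mask(self.grid_shape) for c in explicit]
        for i in range(len(explicit)):
            for j in range(i + 1, len(explicit)):
                if (masks[i] & masks[j]).any():
                    raise ValueError(
                        f"tissue class geometries overlap: "
                        f"{explicit[i].name!r} and {explicit[j].name!r}"
                    )

    # ---- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        def geom_dict(g: Geometry) -> dict:
            d = {"kind": type(g).__name__.lower()}
            d.update(
                {
                    k: list(v) if isinstance(v, (tuple, list)) else v
                    for k, v in dataclasses.asdict(g).items()
                }
            )
            return d

        return {
            "grid_shape": list(self.grid_shape),
            "voxel_spacing": list(self.voxel_spacing),
            "n_features": int(self.n_features),
            "interface_width": int(self.interface_width),
            "noise_sd": np.asarray(self.noise_sd).tolist(),
            "seed": int(self.seed),
            "tissue_classes": [
                {
                    "name": c.name,
                    "geometry": geom_dict(c.geometry),
                    "feature_means": c.feature_means.tolist(),
                    "feature_sds": c.feature_sds.tolist(),
                    "gradient": None if c.gradient is None else c.gradient.tolist(),
                    "make_interface": bool(c.make_interface),
                }
                for c in self.tissue_classes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        def parse_geom(g: dict) -> Geometry:
            kind = g["kind"]
            if kind == "ellipsoid":
                return Ellipsoid(tuple(g["center"]), tuple(g["radii"]))
            if kind == "box":
                return Box(tuple(g["center"]), tuple(g["half_size"]))
            if kind == "background":
                return Background()
            raise ValueError(f"unknown geometry kind {kind!r}")

        classes = [
            TissueClass(
                name=c["name"],
                geometry=parse_geom(c["geometry"]),
                feature_means=np.asarray(c["feature_means"]),
                feature_sds=np.asarray(c["feature_sds"]),
                gradient=None if c.get("gradient") is None else np.asarray(c["gradient"]),
                make_interface=bool(c.get("make_interface", False)),
            )
            for c in d["tissue_classes"]
        ]
        return cls(
            grid_shape=tuple(d["grid_shape"]),
            voxel_spacing=tuple(d["voxel_spacing"]),
            n_features=int(d["n_features"]),
            tissue_classes=classes,
            interface_width=int(d.get("interface_width", 1)),
            noise_sd=np.asarray(d.get("noise_sd", 0.0)),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _radial_coordinate(
    grid_shape: tuple[int, int, int],
    center: Sequence[float],
    scales: Sequence[float] | None = None,
) -> np.ndarray:
    """Anisotropy-aware distance from ``center`` over the whole grid: each
    axis is divided by its scale (e.g. the ellipsoid radii) so level sets
    follow the region's own shape."""
    if scales is None:
        scales = (1.0, 1.0, 1.0)
    grids = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    acc = np.zeros(grid_shape)
    for g, c, s in zip(grids, center, scales):
        acc = acc + ((g - c) / s) ** 2
    return np.sqrt(acc)


def _gradient_scales(geometry: Geometry) -> tuple[float, float, float] | None:
    if isinstance(geometry, Ellipsoid):
        return geometry.radii
    if isinstance(geometry, Box):
        return geometry.half_size
    return None


def _mean_field(
    cls: TissueClass,
    grid_shape: tuple[int, int, int],
    region: np.ndarray,
    fallback_center: Sequence[float],
    fallback_scales: Sequence[float] | None = None,
) -> np.ndarray:
    """Per-voxel mean vector field of a class over the whole grid.

    The field is defined everywhere (it extrapolates smoothly outside the
    class region) so interface voxels can average adjacent class fields at
    their own location.
    """
    n = cls.feature_means.shape[0]
    out = np.broadcast_to(cls.feature_means, grid_shape + (n,)).copy()
    if cls.gradient is None or not np.any(cls.gradient):
        return out
    center = cls.geometry.reference_center()
    scales = _gradient_scales(cls.geometry)
    if center is None:
        center = tuple(fallback_center)
        scales = fallback_scales
    dist = _radial_coordinate(grid_shape, center, scales)
    # rho spans [0, 1] across the class's own region so the gradient acts at
    # full strength at both its inner and outer extremes
    inside = dist[region] if region.any() else dist
    lo, hi = float(inside.min()), float(inside.max())
    if hi - lo <= 0:
        return out
    rho = (dist - lo) / (hi - lo)
    out += (rho - 0.5)[..., np.newaxis] * cls.gradient
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[FeatureVolume, LabelVolume]:
    """Generate the feature stack and its ground-truth label volume.

    Labels are 1-based in tissue-class order; if ``interface_width > 0`` and
    some class has ``make_interface`` set, an extra ``interface`` label is
    appended for the shell between that class and the background. Identical
    ``(spec, seed)`` produces bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    n = spec.n_features

    background_idx = next(
        (
            i
            for i, c in enumerate(spec.tissue_classes)
            if isinstance(c.geometry, Background)
        ),
        None,
    )

    labels = np.zeros(shape, dtype=np.int32)
    if background_idx is not None:
        labels[:] = background_idx + 1
    class_masks: list[np.ndarray] = []
    for i, cls in enumerate(spec.tissue_classes):
        if isinstance(cls.geometry, Background):
            class_masks.append(None)  # type: ignore[arg-type]
            continue
        m = cls.geometry.region_mask(shape)
        class_masks.append(m)
        labels[m] = i + 1
    if background_idx is not None:
        class_masks[background_idx] = labels == background_idx + 1

    legend = {0: "unmasked"}
    for i, cls in enumerate(spec.tissue_classes):
        legend[i + 1] = cls.name

    # interface shell: dilation of each flagged class into the background
    interface_label = 0
    interface_mask = np.zeros(shape, dtype=bool)
    interface_pairs: list[int] = []
    if spec.interface_width > 0 and background_idx is not None:
        for i, cls in enumerate(spec.tissue_classes):
            if not cls.make_interface or isinstance(cls.geometry, Background):
                continue
            shell = (
                ndimage.binary_dilation(
                    class_masks[i], structure=_STRUCT_6CONN, iterations=spec.interface_width
                )
                & ~class_masks[i]
                & (labels == background_idx + 1)
            )
            interface_mask |= shell
            interface_pairs.append(i)
        if interface_mask.any():
            interface_label = len(spec.tissue_classes) + 1
            labels[interface_mask] = interface_label
            legend[interface_label] = "interface"

    # fallback gradient reference: first explicit geometry (its center and
    # shape metric), else the grid center
    fallback_center = tuple((s - 1) / 2 for s in shape)
    fallback_scales: tuple[float, float, float] | None = None
    for cls in spec.tissue_classes:
        c = cls.geometry.reference_center()
        if c is not None:
            fallback_center = c
            fallback_scales = _gradient_scales(cls.geometry)
            break

    data = np.zeros(shape + (n,), dtype=float)
    sd_field = np.zeros(shape + (n,), dtype=float)
    fields: dict[int, np.ndarray] = {}
    for i, cls in enumerate(spec.tissue_classes):
        region = labels == i + 1
        fields[i] = _mean_field(cls, shape, region, fallback_center, fallback_scales)
        data[region] = fields[i][region]
        sd_field[region] = cls.feature_sds

    if interface_label and background_idx is not None:
        bg_cls = spec.tissue_classes[background_idx]
        # mean of the two adjacent classes' local mean fields at the voxel
        acc = np.zeros(shape + (n,), dtype=float)
        sd_acc = np.zeros(n)
        for i in interface_pairs:
            acc += 0.5 * (fields[i] + fields[background_idx]) / len(interface_pairs)
            sd_acc += (
                0.5
                * (spec.tissue_classes[i].feature_sds + bg_cls.feature_sds)
                / len(interface_pairs)
            )
        data[interface_mask] = acc[interface_mask]
        sd_field[interface_mask] = sd_acc

    total_sd = np.sqrt(sd_field**2 + np.asarray(spec.noise_sd) ** 2)
    if np.any(total_sd > 0):
        data = data + rng.standard_normal(shape + (n,)) * total_sd

    feature_names = [f"feature_{i + 1:02d}" for i in range(n)]
    volume = FeatureVolume(
        data=data,
        spacing=spec.voxel_spacing,
        feature_names=feature_names,
    )
    ground_truth = LabelVolume(
        data=labels,
        spacing=spec.voxel_spacing,
        affine=volume.affine,
        legend=legend,
    )
    return volume, ground_truth


def write_phantom(
    spec: PhantomSpec, out_dir: str | Path
) -> tuple[list[Path], Path, Path]:
    """Generate and write a phantom: one NIfTI per feature, the ground-truth
    labels, a manifest, and the spec YAML. Returns (feature paths, label path,
    manifest path)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    volume, truth = generate_phantom(spec)
    feature_paths = volume.save(out_dir)
    label_path = truth.save(out_dir / "ground_truth.nii")
    manifest = out_dir / "manifest.txt"
    manifest.write_text(
        "".join(f"{name}\t{p.name}\n" for name, p in zip(volume.feature_names, feature_paths))
    )
    spec.to_yaml(out_dir / "phantom_spec.yaml")
    return feature_paths, label_path, manifest


def default_spec(
    seed: int = 42,
    grid_shape: tuple[int, int, int] = (64, 64, 8),
    n_features: int = 21,
    noise_sd: float = 0.0,
    satellites: bool = False,
) -> PhantomSpec:
    """The canonical phantom: healthy background + tumor ellipsoid + 1-voxel
    interface shell on a 64x64x8 grid with 21 features.

    The numeric defaults below (baseline levels, tumor contrast, within-class
    gradients, noise) are free parameters of the phantom — they are chosen so
    that healthy and tumor tissue are internally heterogeneous along
    independent feature-space directions while the interface is intermediate,
    and are not derived from any measured data.
    """
    j = np.arange(n_features, dtype=float)
    baseline = 100.0 + 20.0 * np.sin(j)
    # tumor contrast direction: alternating sign, varied magnitude
    contrast = 30.0 * np.where(j % 2 == 0, 1.0, -1.0) * (0.7 + 0.3 * np.cos(j / 2.0))
    # shared within-class axis: the two tissues traverse it in opposite
    # directions so their near-boundary values meet at the interface shell,
    # and the tumor additionally slides toward healthy values at its rim
    shared_axis = 30.0 * np.sin(2.1 * j + 0.5)
    sds = np.full(n_features, 3.0)

    healthy = TissueClass(
        name="healthy",
        geometry=Background(),
        feature_means=baseline,
        feature_sds=sds,
        gradient=shared_axis - 0.3 * contrast,
    )
    tumor = TissueClass(
        name="tumor",
        geometry=Ellipsoid(center=(31.5, 31.5, 3.5), radii=(24.0, 22.0, 12.0)),
        feature_means=baseline + contrast,
        feature_sds=sds,
        gradient=-0.91 * shared_axis - 0.8 * contrast,
        make_interface=True,
    )
    classes = [healthy, tumor]
    if satellites:
        classes.append(
            TissueClass(
                name="satellite",
                geometry=Ellipsoid(center=(10.0, 52.0, 5.0), radii=(2.5, 2.5, 1.2)),
                feature_means=baseline + contrast,
                feature_sds=sds,
            )
        )
    return PhantomSpec(
        grid_shape=grid_shape,
        voxel_spacing=(0.37, 0.37, 5.5),
        n_features=n_features,
        tissue_classes=classes,
        interface_width=1,
        noise_sd=noise_sd,
        seed=seed,
    )
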