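"""Image data model, NIfTI-1 I/O and geometric resampling primitives.

All geometry flows through 4x4 voxel-to-world affines in RAS+ millimetres;
voxel indices are 0-based. Displacement fields follow the pull-back
convention: the field lives on the *output* grid and stores, per voxel, the
world-mm offset added to that voxel's world coordinate to find the sampling
location in the input image. This matches how deformation-field NIfTIs are
commonly consumed by resampling code.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import FormatError, GeometryError

__all__ = [
    "VolumeImage",
    "DynamicSeries",
    "RoiLabelMap",
    "DisplacementField",
    "AffineTransform",
    "Grid",
    "read_nifti",
    "write_nifti",
    "resample",
    "resample_labels",
    "warp",
    "warp_labels",
    "invert_field",
]

_INTERP_ORDER = {"linear": 1, "nearest": 0}

# voxel-centre world coordinates are expensive to rebuild for every warp
_WORLD_COORD_CACHE: dict = {}


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise GeometryError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise GeometryError("affine is singular (non-invertible)")
    return affine


@dataclass
class Grid:
    """A voxel grid: shape plus voxel-to-world affine (no data)."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise GeometryError(f"grid shape must be 3D and positive, got {self.shape}")
        self.affine = _check_affine(self.affine)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm, per axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_geometry(self, other: "Grid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def world_coordinates(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (3, n_voxels).

        The returned array is cached per grid geometry and must be treated
        as read-only.
        """
        key = (self.shape, self.affine.tobytes())
        cached = _WORLD_COORD_CACHE.get(key)
        if cached is None:
            idx = np.indices(self.shape, dtype=np.float64).reshape(3, -1)
            cached = self.affine[:3, :3] @ idx + self.affine[:3, 3:4]
            cached.setflags(write=False)
            if len(_WORLD_COORD_CACHE) >= 8:
                _WORLD_COORD_CACHE.pop(next(iter(_WORLD_COORD_CACHE)))
            _WORLD_COORD_CACHE[key] = cached
        return cached


def grid_of(obj) -> Grid:
    """Extract the :class:`Grid` of any image-like object."""
    if isinstance(obj, Grid):
        return obj
    shape = obj.data.shape[:3] if hasattr(obj, "data") else obj.labels.shape
    return Grid(shape, obj.affine)


@dataclass
class VolumeImage:
    """A 3D scalar volume with voxel-to-world affine.

    ``space_tag`` is a free-text identifier of the coordinate space the
    image lives in (e.g. ``"template"``, ``"anat-native"``, ``"dsc-native"``).
    """

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or any(s < 1 for s in self.data.shape):
            raise GeometryError(
                f"VolumeImage data must be 3D with positive dims, got {self.data.shape}"
            )
        self.affine = _check_affine(self.affine)

    @property
    def grid(self) -> Grid:
        return Grid(self.data.shape, self.affine)


@dataclass
class DynamicSeries:
    """A 4D (x, y, z, t) dynamic signal series with a repetition time."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise GeometryError(f"DynamicSeries data must be 4D, got {self.data.shape}")
        if self.data.shape[3] < 3:
            raise GeometryError("DynamicSeries needs at least 3 timepoints")
        if not self.tr_seconds > 0:
            raise GeometryError("tr_seconds must be positive")
        self.affine = _check_affine(self.affine)

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[3])

    @property
    def grid(self) -> Grid:
        return Grid(self.data.shape[:3], self.affine)


@dataclass
class RoiLabelMap:
    """Integer-labelled volume (0 = background) plus a label->name registry."""

    labels: np.ndarray
    affine: np.ndarray
    registry: Mapping[int, str] = field(default_factory=dict)
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise GeometryError(f"labels must be 3D, got {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise GeometryError("labels must be integer-typed")
        if self.labels.min() < 0:
            raise GeometryError("labels must be non-negative")
        self.affine = _check_affine(self.affine)
        self.registry = {int(k): str(v) for k, v in dict(self.registry).items()}
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.registry)
        if missing:
            raise GeometryError(f"labels {sorted(missing)} missing from registry")

    @property
    def grid(self) -> Grid:
        return Grid(self.labels.shape, self.affine)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class DisplacementField:
    """Voxelwise world-mm displacement vectors on their own grid.

    ``direction_tag`` records which mapping the field implements:
    ``"template->native"`` (warps template-space data onto a native grid) or
    ``"native->template"``.
    """

    offsets: np.ndarray
    affine: np.ndarray
    direction_tag: str = ""

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.ndim != 4 or self.offsets.shape[3] != 3:
            raise GeometryError(
                f"offsets must have shape (x, y, z, 3), got {self.offsets.shape}"
            )
        if not np.all(np.isfinite(self.offsets)):
            raise GeometryError("displacement offsets must be finite")
        self.affine = _check_affine(self.affine)

    @property
    def grid(self) -> Grid:
        return Grid(self.offsets.shape[:3], self.affine)

    @property
    def max_displacement(self) -> float:
        return float(np.sqrt((self.offsets**2).sum(axis=3)).max())


@dataclass
class AffineTransform:
    """A world-to-world affine mapping, stored as a 4x4 matrix."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = _check_affine(self.matrix)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def translation(cls, t) -> "AffineTransform":
        m = np.eye(4)
        m[:3, 3] = np.asarray(t, dtype=float)
        return cls(m)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def apply(self, world: np.ndarray) -> np.ndarray:
        """Apply to world points of shape (3, n)."""
        return self.matrix[:3, :3] @ world + self.matrix[:3, 3:4]

    @property
    def is_rigid(self) -> bool:
        r = self.matrix[:3, :3]
        return bool(
            np.allclose(r.T @ r, np.eye(3), atol=1e-6)
            and np.isclose(abs(np.linalg.det(r)), 1.0, atol=1e-6)
        )

    @property
    def translation_mm(self) -> np.ndarray:
        return self.matrix[:3, 3].copy()


# ---------------------------------------------------------------------------
# NIfTI I/O


def _sidecar(path: Path, kind: str) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            name = name[: -len(suf)]
            break
    return path.with_name(f"{name}.{kind}.json")


def write_nifti(obj, path) -> Path:
    """Write any of the image types to a NIfTI-1 file (plus JSON sidecars).

    Label registries go to ``<stem>.labels.json``; displacement-field
    direction tags go to ``<stem>.field.json``. Scalar data is stored as
    float32, labels as int16/int32.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, RoiLabelMap):
        dtype = np.int16 if obj.labels.max() < 2**15 else np.int32
        img = nib.Nifti1Image(obj.labels.astype(dtype), obj.affine)
        nib.save(img, path)
        _sidecar(path, "labels").write_text(
            json.dumps({str(k): v for k, v in obj.registry.items()}, indent=2)
        )
    elif isinstance(obj, DisplacementField):
        img = nib.Nifti1Image(obj.offsets.astype(np.float32), obj.affine)
        nib.save(img, path)
        _sidecar(path, "field").write_text(
            json.dumps({"direction_tag": obj.direction_tag}, indent=2)
        )
    elif isinstance(obj, DynamicSeries):
        img = nib.Nifti1Image(obj.data.astype(np.float32), obj.affine)
        zooms = nib.affines.voxel_sizes(obj.affine)
        img.header.set_zooms((*zooms, obj.tr_seconds))
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, path)
    elif isinstance(obj, VolumeImage):
        nib.save(nib.Nifti1Image(obj.data.astype(np.float32), obj.affine), path)
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    return path


def read_nifti(path):
    """Read a NIfTI-1 file into the matching in-memory type.

    3D integer volumes load as :class:`RoiLabelMap` (registry from the
    ``.labels.json`` sidecar if present, otherwise auto-named); 4D volumes
    load as :class:`DynamicSeries` unless a ``.field.json`` sidecar marks
    them as a :class:`DisplacementField`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        affine = img.affine
    except Exception as exc:  # nibabel raises a zoo of types on bad headers
        raise FormatError(f"cannot read {path} as NIfTI-1: {exc}") from exc
    if affine is None or abs(np.linalg.det(np.asarray(affine)[:3, :3])) < 1e-12:
        raise GeometryError(f"{path} has a singular affine")

    data = np.squeeze(data) if data.ndim > 4 else data
    if data.ndim == 4:
        fs = _sidecar(path, "field")
        if data.shape[3] == 3 and fs.exists():
            tag = json.loads(fs.read_text()).get("direction_tag", "")
            return DisplacementField(data.astype(float), affine, direction_tag=tag)
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr <= 0:
            raise FormatError(f"{path} is 4D but has no positive TR in its header")
        return DynamicSeries(data, affine, tr_seconds=tr)
    if data.ndim != 3:
        raise FormatError(f"{path}: unsupported dimensionality {data.ndim}")
    if np.issubdtype(data.dtype, np.integer):
        ls = _sidecar(path, "labels")
        if ls.exists():
            registry = {int(k): v for k, v in json.loads(ls.read_text()).items()}
        else:
            registry = {int(v): f"label_{int(v)}" for v in np.unique(data) if v != 0}
        return RoiLabelMap(data, affine, registry=registry)
    return VolumeImage(data, affine)


# ---------------------------------------------------------------------------
# Resampling


def _sample_at_world(
    data: np.ndarray,
    affine: np.ndarray,
    world: np.ndarray,
    interpolation: str,
    fill_value: float,
) -> np.ndarray:
    """Sample ``data`` (on ``affine``'s grid) at world points (3, n)."""
    if interpolation not in _INTERP_ORDER:
        raise ValueError(f"interpolation must be one of {list(_INTERP_ORDER)}")
    inv = np.linalg.inv(affine)
    vox = inv[:3, :3] @ world + inv[:3, 3:4]
    return ndimage.map_coordinates(
        np.asarray(data, dtype=np.float32),
        vox,
        order=_INTERP_ORDER[interpolation],
        mode="constant",
        cval=fill_value,
        prefilter=False,
    )


def resample(
    image: VolumeImage,
    target: Grid | VolumeImage,
    transform: AffineTransform | None = None,
    interpolation: str = "linear",
    fill_value: float = 0.0,
    space_tag: str | None = None,
) -> VolumeImage:
    """Resample ``image`` onto ``target``'s grid through an affine transform.

    ``transform`` maps input-image world coordinates to output world
    coordinates; each output voxel samples the input at
    ``transform⁻¹(world)`` (pull-back). ``None`` means identity.
    Out-of-field samples get ``fill_value`` (never an exception).
    """
    tgt = grid_of(target)
    world = tgt.world_coordinates()
    if transform is not None:
        world = transform.inverse().apply(world)
    out = _sample_at_world(image.data, image.affine, world, interpolation, fill_value)
    return VolumeImage(
        out.reshape(tgt.shape),
        tgt.affine,
        space_tag=image.space_tag if space_tag is None else space_tag,
    )


def warp(
    image: VolumeImage,
    fld: DisplacementField,
    interpolation: str = "linear",
    fill_value: float = 0.0,
    space_tag: str | None = None,
) -> VolumeImage:
    """Warp ``image`` through a displacement field (pull-back).

    The output lives on the field's grid; the output voxel at world ``x``
    samples the input at ``x + offset(x)``.
    """
    g = fld.grid
    world = g.world_coordinates() + fld.offsets.reshape(-1, 3).T
    out = _sample_at_world(image.data, image.affine, world, interpolation, fill_value)
    return VolumeImage(
        out.reshape(g.shape),
        g.affine,
        space_tag=image.space_tag if space_tag is None else space_tag,
    )


def _combine_label_weights(
    label_ids: list[int], weights: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Resolve per-label interpolated weights into a single label volume.

    Winner is the highest weight; ties go to the lowest label id (labels are
    passed in ascending order and argmax returns the first maximum). Voxels
    whose best weight is below ``threshold`` stay background.
    """
    best = np.argmax(weights, axis=0)
    best_w = np.take_along_axis(weights, best[None], axis=0)[0]
    ids = np.asarray(label_ids, dtype=np.int32)
    out = np.where(best_w >= threshold, ids[best], 0)
    return out.astype(np.int32)


def _transform_labels(rois: RoiLabelMap, warp_one, out_grid: Grid) -> RoiLabelMap:
    label_ids = sorted(int(v) for v in np.unique(rois.labels) if v != 0)
    if not label_ids:
        return RoiLabelMap(
            np.zeros(out_grid.shape, dtype=np.int32),
            out_grid.affine,
            registry=rois.registry,
            space_tag=rois.space_tag,
        )
    weights = np.empty((len(label_ids),) + out_grid.shape, dtype=np.float32)
    for i, lab in enumerate(label_ids):
        indicator = (rois.labels == lab).astype(np.float32)
        weights[i] = warp_one(indicator)
    labels = _combine_label_weights(label_ids, weights)
    vol_in = int((rois.labels > 0).sum()) * rois.grid.voxel_volume
    vol_out = int((labels > 0).sum()) * out_grid.voxel_volume
    if vol_out < 0.9 * vol_in:
        warnings.warn(
            f"label transform lost {vol_in - vol_out:.0f} mm^3 of foreground "
            f"({int((rois.labels > 0).sum())} -> {int((labels > 0).sum())} voxels; "
            "field-of-view truncation likely)",
            stacklevel=3,
        )
    return RoiLabelMap(
        labels, out_grid.affine, registry=rois.registry, space_tag=rois.space_tag
    )


def warp_labels(rois: RoiLabelMap, fld: DisplacementField) -> RoiLabelMap:
    """Warp a label map through a displacement field.

    Each label's binary indicator is warped with linear interpolation and
    re-binarised at 0.5; competing claims go to the highest interpolated
    weight, ties to the lowest label id. The label registry is conserved.
    """
    g = fld.grid

    def warp_one(indicator: np.ndarray) -> np.ndarray:
        return warp(
            VolumeImage(indicator, rois.affine), fld, interpolation="linear"
        ).data

    return _transform_labels(rois, warp_one, g)


def resample_labels(
    rois: RoiLabelMap,
    target: Grid | VolumeImage,
    transform: AffineTransform | None = None,
) -> RoiLabelMap:
    """Affine analogue of :func:`warp_labels` (indicator + 0.5 threshold)."""
    tgt = grid_of(target)

    def warp_one(indicator: np.ndarray) -> np.ndarray:
        return resample(
            VolumeImage(indicator, rois.affine), tgt, transform, "linear"
        ).data

    return _transform_labels(rois, warp_one, tgt)


def invert_field(
    fld: DisplacementField, n_iterations: int = 25, tag: str = ""
) -> DisplacementField:
    """Numerically invert a displacement field by fixed-point iteration.

    Solves ``o_inv(x) = -o(x + o_inv(x))`` on the same grid. Converges for
    smooth fields whose displacement gradients stay below 1 (i.e. fields
    that are diffeomorphic in the first place).
    """
    g = fld.grid
    world = g.world_coordinates()
    inv_off = np.zeros_like(fld.offsets)
    for _ in range(n_iterations):
        pts = world + inv_off.reshape(-1, 3).T
        sampled = np.stack(
            [
                _sample_at_world(fld.offsets[..., c], fld.affine, pts, "linear", 0.0)
                for c in range(3)
            ],
            axis=-1,
        )
        inv_off = -sampled.reshape(inv_off.shape)
    return DisplacementField(inv_off, g.affine, direction_tag=tag)


def compose_displacement(
    first: DisplacementField, second: DisplacementField
) -> np.ndarray:
    """Residual offsets of applying ``second`` after ``first`` (same grid).

    Returns the per-voxel world-mm vector ``first(x) + second(x + first(x)) ``
    relative to ``x``; for a field and its inverse this is the round-trip
    residual displacement.
    """
    if not first.grid.same_geometry(second.grid):
        raise GeometryError("fields must share a grid for composition")
    world = first.grid.world_coordinates()
    pts = world + first.offsets.reshape(-1, 3).T
    sampled = np.stack(
        [
            _sample_at_world(second.offsets[..., c], second.affine, pts, "linear", 0.0)
            for c in range(3)
        ],
        axis=0,
    )
    residual = first.offsets.reshape(-1, 3).T + sampled
    return residual.T.reshape(first.offsets.shape)
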