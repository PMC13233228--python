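"""The reverse-transformation (arT) pipeline.

Generic atlas-space ROIs are brought into each subject's native space so
that quantitative perfusion maps can be read where they were measured,
without resampling the measured values:

1. rigid co-registration of the DSC mean image to the anatomical reference,
2. inverse (template->native) warping of the generic ROI label map,
3. tissue-probability filtering (keep voxels whose GM+WM probability —
   plus CSF for the two hemisphere ROIs — exceeds 10%),
4. projection of the filtered ROIs onto the DSC grid.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .errors import DirectionError, GeometryError, RegistrationError
from .imagecore import (
    AffineTransform,
    DisplacementField,
    Grid,
    RoiLabelMap,
    VolumeImage,
    grid_of,
    resample_labels,
    warp_labels,
)
from .perfmaps import compute_mean_tdc
from .phantom import HEMISPHERE_LABELS

__all__ = [
    "ArtConfig",
    "ArtResult",
    "coregister_affine",
    "reverse_transform_rois",
    "filter_rois",
    "to_dsc_grid",
    "run_art",
]

log = logging.getLogger(__name__)


@dataclass
class ArtConfig:
    """Tunable parameters of the arT pipeline.

    ``tissue_threshold`` is the probability above which (strictly) a voxel
    survives filtering; ``hemisphere_labels`` are the labels whose filter
    sum additionally includes CSF. ``None`` infers them from registry names
    containing "hemisphere".
    """

    tissue_threshold: float = 0.10
    hemisphere_labels: frozenset[int] | None = None
    registration_metric: str = "mutual-information"  # or "mean-squares"
    max_iterations: int = 200
    convergence_min_step_mm: float = 0.01
    multiresolution_shrink: tuple[int, ...] = (4, 2, 1)
    multiresolution_smoothing: tuple[float, ...] = (2.0, 1.0, 0.0)
    sampling_fraction: float = 0.25
    outlier_removed_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.tissue_threshold < 1.0:
            raise ValueError("tissue_threshold must lie strictly in (0, 1)")
        if self.registration_metric not in ("mean-squares", "mutual-information"):
            raise ValueError(f"unknown metric {self.registration_metric!r}")
        if self.hemisphere_labels is not None:
            self.hemisphere_labels = frozenset(
                int(v) for v in self.hemisphere_labels
            )

    def hemisphere_labels_for(self, rois: RoiLabelMap) -> frozenset[int]:
        if self.hemisphere_labels is not None:
            extra = self.hemisphere_labels - set(rois.registry)
            if extra:
                raise GeometryError(
                    f"hemisphere labels {sorted(extra)} not in the ROI registry"
                )
            return self.hemisphere_labels
        inferred = frozenset(
            lab for lab, name in rois.registry.items() if "hemisphere" in name.lower()
        )
        return inferred if inferred else frozenset(HEMISPHERE_LABELS & set(rois.registry))


@dataclass
class ArtResult:
    """Output of one arT run: native generic ROIs plus accounting."""

    rois_generic_native: RoiLabelMap  # on the DSC grid
    coreg: AffineTransform  # DSC world -> anatomical world
    filter_report: dict[int, dict]
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Co-registration (SimpleITK behind the module surface)

_RAS2LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


def _to_sitk(img: VolumeImage) -> sitk.Image:
    """nibabel-style (i,j,k)+RAS affine -> SimpleITK image (LPS world)."""
    data = np.ascontiguousarray(np.transpose(img.data, (2, 1, 0)), dtype=np.float32)
    out = sitk.GetImageFromArray(data)
    aff = _RAS2LPS @ img.affine
    m = aff[:3, :3]
    spacing = np.sqrt((m**2).sum(axis=0))
    direction = m / spacing[None, :]
    out.SetSpacing(tuple(spacing))
    out.SetDirection(tuple(direction.ravel()))
    out.SetOrigin(tuple(aff[:3, 3]))
    return out


def _euler_to_matrix(tx: sitk.Euler3DTransform) -> np.ndarray:
    r = np.asarray(tx.GetMatrix()).reshape(3, 3)
    c = np.asarray(tx.GetCenter())
    t = np.asarray(tx.GetTranslation())
    m = np.eye(4)
    m[:3, :3] = r
    m[:3, 3] = c + t - r @ c
    return m


def _world_bounds(grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    idx = np.array(
        [[i, j, k] for i in (0, grid.shape[0] - 1)
         for j in (0, grid.shape[1] - 1)
         for k in (0, grid.shape[2] - 1)],
        dtype=float,
    ).T
    world = grid.affine[:3, :3] @ idx + grid.affine[:3, 3:4]
    return world.min(axis=1), world.max(axis=1)


def coregister_affine(
    moving: VolumeImage, fixed: VolumeImage, config: ArtConfig | None = None
) -> AffineTransform:
    """Rigidly co-register ``moving`` to ``fixed``.

    Returns the world-to-world transform mapping moving-space coordinates
    into fixed-space coordinates (RAS mm). Initialisation is at
    centre-of-mass alignment, optimisation is a multiresolution regular-step
    gradient descent, and sampling is regular (deterministic).
    """
    config = config or ArtConfig()
    mlo, mhi = _world_bounds(moving.grid)
    flo, fhi = _world_bounds(fixed.grid)
    if np.any(mhi < flo) or np.any(fhi < mlo):
        raise RegistrationError("moving and fixed fields of view do not overlap")

    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)
    reg = sitk.ImageRegistrationMethod()
    if config.registration_metric == "mean-squares":
        reg.SetMetricAsMeanSquares()
    else:
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    # fixed seed: regular sampling still jitters its phase per level
    reg.SetMetricSamplingPercentage(config.sampling_fraction, seed=12345)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=config.convergence_min_step_mm,
        numberOfIterations=config.max_iterations,
        relaxationFactor=0.5,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(config.multiresolution_shrink))
    reg.SetSmoothingSigmasPerLevel(list(config.multiresolution_smoothing))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    initial = sitk.CenteredTransformInitializer(
        f_img,
        m_img,
        sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.MOMENTS,
    )
    reg.SetInitialTransform(initial, inPlace=True)
    final = reg.Execute(f_img, m_img)
    stop = reg.GetOptimizerStopConditionDescription()
    if "maximum number of iterations" in stop.lower():
        raise RegistrationError(
            f"registration did not converge within {config.max_iterations} "
            f"iterations (final metric {reg.GetMetricValue():.6g}; {stop})"
        )
    # `final` maps fixed physical points to moving physical points (LPS);
    # invert and convert back to RAS to get moving-world -> fixed-world.
    m_lps = np.linalg.inv(_euler_to_matrix(sitk.Euler3DTransform(final)))
    return AffineTransform(_RAS2LPS @ m_lps @ _RAS2LPS)


# ---------------------------------------------------------------------------
# ROI transformation and filtering


def reverse_transform_rois(
    rois_template: RoiLabelMap,
    field_inverse: DisplacementField,
    anat_grid: Grid | VolumeImage,
) -> RoiLabelMap:
    """Warp generic template-space ROIs backwards into native space.

    ``field_inverse`` must carry the ``template->native`` direction tag
    (the inverse of the spatial normalisation) and live on the anatomical
    native grid; silently wrong-way warps are refused.
    """
    tag = field_inverse.direction_tag.replace("→", "->")
    if tag != "template->native":
        raise DirectionError(
            "reverse transformation needs a template->native field, got "
            f"direction_tag={field_inverse.direction_tag!r}"
        )
    grid = grid_of(anat_grid)
    if not field_inverse.grid.same_geometry(grid):
        raise GeometryError(
            "displacement field is not defined on the anatomical grid; "
            "resample the field first"
        )
    out = warp_labels(rois_template, field_inverse)
    out.space_tag = "anat-native"
    return out


def filter_rois(
    rois: RoiLabelMap,
    tpm_gm: VolumeImage,
    tpm_wm: VolumeImage,
    tpm_csf: VolumeImage,
    config: ArtConfig | None = None,
) -> tuple[RoiLabelMap, dict[int, dict]]:
    """Keep only ROI voxels with sufficient tissue probability.

    Non-hemisphere labels keep voxels with ``p_GM + p_WM`` strictly above
    the threshold; hemisphere labels add ``p_CSF`` to the sum (ventricular
    and sulcal CSF legitimately belongs to a whole-hemisphere ROI). Returns
    the filtered map plus a per-label report of voxel counts.
    """
    config = config or ArtConfig()
    grid = rois.grid
    for name, m in (("gm", tpm_gm), ("wm", tpm_wm), ("csf", tpm_csf)):
        if not m.grid.same_geometry(grid):
            raise GeometryError(f"tissue map {name!r} is not on the ROI grid")
    hemi = config.hemisphere_labels_for(rois)
    p_tissue = tpm_gm.data.astype(np.float64) + tpm_wm.data.astype(np.float64)
    p_hemi = p_tissue + tpm_csf.data.astype(np.float64)
    out = np.zeros_like(rois.labels)
    report: dict[int, dict] = {}
    for lab in sorted(set(np.unique(rois.labels)) - {0}):
        lab = int(lab)
        m = rois.labels == lab
        keep = m & ((p_hemi if lab in hemi else p_tissue) > config.tissue_threshold)
        out[keep] = lab
        before, after = int(m.sum()), int(keep.sum())
        report[lab] = {
            "name": rois.registry.get(lab, str(lab)),
            "csf_included": lab in hemi,
            "voxels_before": before,
            "voxels_after": after,
            "voxels_removed": before - after,
            "removed_fraction": (before - after) / before if before else 0.0,
        }
    filtered = RoiLabelMap(
        out, rois.affine, registry=rois.registry, space_tag=rois.space_tag
    )
    return filtered, report


def to_dsc_grid(
    rois_native_anat: RoiLabelMap,
    coreg: AffineTransform,
    dsc_grid: Grid | VolumeImage,
) -> RoiLabelMap:
    """Project native anatomical-grid ROIs onto the DSC grid.

    ``coreg`` maps DSC world coordinates to anatomical world coordinates;
    labels are resampled through its inverse with indicator interpolation
    and a 0.5 threshold.
    """
    out = resample_labels(rois_native_anat, grid_of(dsc_grid), coreg.inverse())
    out.space_tag = "dsc-native"
    return out


# ---------------------------------------------------------------------------
# End-to-end


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_art(subject, rois_template: RoiLabelMap, config: ArtConfig | None = None) -> ArtResult:
    """Run the full arT pipeline for one subject.

    ``subject`` is any object with ``dsc``, ``anat``, ``tpm_gm``,
    ``tpm_wm``, ``tpm_csf`` and ``field_template_to_native`` attributes
    (e.g. a phantom :class:`~artroi.phantom.SubjectBundle`). Stages run in
    acquisition order: co-registration of the DSC mean image to the
    anatomy, reverse ROI transformation, tissue filtering in native
    anatomical space, projection to the DSC grid.
    """
    config = config or ArtConfig()
    stage = "coregister"
    try:
        mean_tdc = compute_mean_tdc(subject.dsc)
        # Estimate with the DSC mean as the metric's sampling domain (its
        # field of view is brain-only, which anchors the metric far better
        # than the air-dominated anatomical grid), then invert so the
        # stored transform maps DSC world -> anatomical world.
        coreg = coregister_affine(subject.anat, mean_tdc, config).inverse()
        log.info("coregistration translation: %s mm", coreg.translation_mm.round(3))

        stage = "reverse_transform"
        rois_native = reverse_transform_rois(
            rois_template, subject.field_template_to_native, subject.anat.grid
        )

        stage = "filter"
        rois_filtered, report = filter_rois(
            rois_native, subject.tpm_gm, subject.tpm_wm, subject.tpm_csf, config
        )
        for lab, entry in report.items():
            entry["outlier"] = entry["removed_fraction"] > config.outlier_removed_fraction
            if entry["outlier"]:
                log.warning(
                    "ROI %s lost %.1f%% of its voxels in tissue filtering",
                    entry["name"],
                    100 * entry["removed_fraction"],
                )

        stage = "to_dsc_grid"
        rois_dsc = to_dsc_grid(rois_filtered, coreg, subject.dsc.grid)
        for lab, entry in report.items():
            entry["voxels_dsc"] = int((rois_dsc.labels == lab).sum())
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    provenance = {
        "config": {
            "tissue_threshold": config.tissue_threshold,
            "registration_metric": config.registration_metric,
            "max_iterations": config.max_iterations,
        },
        "input_hashes": {
            "dsc": _hash_array(subject.dsc.data),
            "anat": _hash_array(subject.anat.data),
            "rois_template": _hash_array(rois_template.labels),
            "field": _hash_array(subject.field_template_to_native.offsets),
        },
    }
    return ArtResult(
        rois_generic_native=rois_dsc,
        coreg=coreg,
        filter_report=report,
        provenance=provenance,
    )
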