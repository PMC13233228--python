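"""Synthetic brain phantom: template, subjects, tissue maps, deformations, DSC.

The generator emulates the structure of a DSC perfusion-MRI study cohort:
a 1 mm isotropic template with seven labelled structures (left/right basal
ganglia, pons, left/right cerebellum, left/right cerebral hemispheres),
per-subject smooth invertible deformations between template and native
space, analytic GM/WM/CSF tissue-probability maps, and a 4D DSC series on a
coarse perfusion grid (default 1.154 x 1.154 x 6 mm, 20 slices, 81
timepoints at TR = 0.689 s) whose first-pass bolus is a gamma-variate
signal drop with tissue-specific baseline, amplitude and time-to-peak.

Because every curve parameter is known analytically, per-ROI ground-truth
stdTTP and CBV values are recorded alongside each subject, and the whole
pipeline can be validated by parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import PhantomSpecError
from .imagecore import (
    AffineTransform,
    DisplacementField,
    DynamicSeries,
    Grid,
    RoiLabelMap,
    VolumeImage,
    read_nifti,
    resample,
    resample_labels,
    warp,
    warp_labels,
    write_nifti,
)

__all__ = [
    "ROI_REGISTRY",
    "HEMISPHERE_LABELS",
    "TissueCurve",
    "PhantomSpec",
    "TemplateAssets",
    "SubjectBundle",
    "make_template",
    "make_template_assets",
    "make_subject",
    "make_cohort",
    "write_subject",
    "read_subject",
]

ROI_REGISTRY: dict[int, str] = {
    1: "right_basal_ganglia",
    2: "left_basal_ganglia",
    3: "pons",
    4: "right_cerebellum",
    5: "left_cerebellum",
    6: "right_hemisphere",
    7: "left_hemisphere",
}

#: Labels for which CSF is included in the tissue-probability filter sum.
HEMISPHERE_LABELS: frozenset[int] = frozenset({6, 7})

# World-mm geometry of the phantom head (RAS+, origin mid-brain).
_BRAIN = ((0.0, 0.0, 2.0), (38.0, 44.0, 36.0))
_VENTRICLE = {+1: ((7.0, 4.0, 8.0), (3.0, 11.0, 5.0)),
              -1: ((-7.0, 4.0, 8.0), (3.0, 11.0, 5.0))}
_BASAL_GANGLIA = {+1: ((17.0, 4.0, 2.0), (6.0, 9.0, 6.5)),
                  -1: ((-17.0, 4.0, 2.0), (6.0, 9.0, 6.5))}
_PONS = ((0.0, -6.0, -22.0), (7.0, 8.0, 8.5))
_CEREBELLUM = {+1: ((13.0, -26.0, -18.0), (12.0, 13.0, 11.0)),
               -1: ((-13.0, -26.0, -18.0), (12.0, 13.0, 11.0))}
_HEMI_ELLIPSOID = ((0.0, 0.0, 8.0), (37.0, 42.0, 30.0))
_HEMI_Z_CUT = -4.0       # hemispheres live above this plane
_HEMI_X_GAP = 1.5        # half-width of the interhemispheric gap
_CSF_RIM_MM = 2.0        # outer CSF shell thickness
_GM_SHELL_MM = 5.0       # cortical GM reaches this deep


@dataclass
class TissueCurve:
    """Gamma-variate bolus parameters of one tissue class.

    ``s0`` is the pre-bolus baseline signal (a.u.), ``amplitude`` the peak
    fractional signal drop, ``time_to_peak_s`` the interval from bolus
    arrival to the dip peak, and ``alpha`` the gamma shape (larger = narrower
    first pass).
    """

    s0: float
    amplitude: float
    time_to_peak_s: float
    alpha: float = 3.0


def _default_tissue_params() -> dict[str, TissueCurve]:
    return {
        "gm": TissueCurve(s0=1000.0, amplitude=0.35, time_to_peak_s=5.0),
        "wm": TissueCurve(s0=800.0, amplitude=0.20, time_to_peak_s=6.5),
        "csf": TissueCurve(s0=1200.0, amplitude=0.10, time_to_peak_s=8.0),
    }


@dataclass
class PhantomSpec:
    """All knobs of the phantom generator; defaults are the study conditions.

    The template grid is 1 mm isotropic and the DSC grid matches the
    acquisition geometry of a clinical first-pass protocol (20 slices of
    1.154 x 1.154 x 6 mm, 81 timepoints at TR = 0.689 s). The deformation
    amplitude is kept below half the smoothing scale so the generated
    fields are invertible by construction (and verified numerically).
    """

    seed: int = 0
    shape_template: tuple[int, int, int] = (96, 112, 96)
    spacing_template: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shape_dsc: tuple[int, int, int] = (88, 88, 20)
    spacing_dsc: tuple[float, float, float] = (1.154, 1.154, 6.0)
    n_timepoints: int = 81
    tr_seconds: float = 0.689
    deformation_amplitude_mm: float = 4.0
    deformation_smoothing_mm: float = 10.0
    rater_jitter_inplane_mm: float = 1.0
    rater_jitter_z_mm: float = 2.0
    rater_jitter_smoothing_mm: float = 10.0
    coreg_shift_mm: float = 3.0
    noise_sd: float = 10.0
    artifact_csf_flow: bool = False
    bolus_arrival_s: float = 14.0
    delay_gradient_s: float = 1.5
    air_s0: float = 15.0
    tissue_params: dict[str, TissueCurve] = field(
        default_factory=_default_tissue_params
    )

    def __post_init__(self) -> None:
        for name in ("shape_template", "shape_dsc"):
            shp = tuple(int(v) for v in getattr(self, name))
            if len(shp) != 3 or any(s < 4 for s in shp):
                raise PhantomSpecError(f"{name} must be 3 positive ints, got {shp}")
            setattr(self, name, shp)
        for name in ("spacing_template", "spacing_dsc"):
            sp = tuple(float(v) for v in getattr(self, name))
            if any(v <= 0 for v in sp):
                raise PhantomSpecError(f"{name} must be positive, got {sp}")
            setattr(self, name, sp)
        if self.n_timepoints < 3:
            raise PhantomSpecError("n_timepoints must be >= 3")
        if self.tr_seconds <= 0:
            raise PhantomSpecError("tr_seconds must be positive")
        if (
            self.deformation_amplitude_mm < 0
            or self.rater_jitter_inplane_mm < 0
            or self.rater_jitter_z_mm < 0
        ):
            raise PhantomSpecError("deformation amplitudes must be >= 0")
        if self.deformation_amplitude_mm > 0.5 * self.deformation_smoothing_mm:
            raise PhantomSpecError(
                "deformation amplitude must stay below half the smoothing scale "
                f"({self.deformation_amplitude_mm} > "
                f"{0.5 * self.deformation_smoothing_mm}) to guarantee invertibility"
            )
        if isinstance(self.tissue_params, dict):
            self.tissue_params = {
                k: v if isinstance(v, TissueCurve) else TissueCurve(**v)
                for k, v in self.tissue_params.items()
            }
        missing = {"gm", "wm", "csf"} - set(self.tissue_params)
        if missing:
            raise PhantomSpecError(f"tissue_params missing classes: {sorted(missing)}")

    @property
    def grid_template(self) -> Grid:
        return _centered_grid(self.shape_template, self.spacing_template)

    @property
    def grid_dsc(self) -> Grid:
        return _centered_grid(self.shape_dsc, self.spacing_dsc)

    def subject_seed(self, index: int) -> int:
        """Per-subject seed: master seed plus subject index."""
        return int(self.seed) + int(index)


def _centered_grid(shape, spacing) -> Grid:
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = -np.asarray(spacing) * (np.asarray(shape) - 1) / 2.0
    return Grid(tuple(shape), affine)


@dataclass
class TemplateAssets:
    """Template-space anatomy, ROI labels and tissue-probability maps."""

    anat: VolumeImage
    rois: RoiLabelMap
    tpm_gm: VolumeImage
    tpm_wm: VolumeImage
    tpm_csf: VolumeImage


@dataclass
class SubjectBundle:
    """One synthetic subject with its ground truth.

    ``truth`` maps ROI names to the analytic per-ROI mean stdTTP (s) and
    CBV (a.u., normalised like the pipeline output) derived from the
    generating curve parameters; ``stdttp_true``/``cbv_true`` are the
    corresponding noise-free maps on the DSC grid.
    """

    index: int
    anat: VolumeImage
    tpm_gm: VolumeImage
    tpm_wm: VolumeImage
    tpm_csf: VolumeImage
    rois_truth_native: RoiLabelMap
    rois_truth_dsc: RoiLabelMap
    dsc: DynamicSeries
    field_template_to_native: DisplacementField
    coreg_true: AffineTransform
    truth: dict[str, dict[str, float]]
    stdttp_true: VolumeImage | None = None
    cbv_true: VolumeImage | None = None


# ---------------------------------------------------------------------------
# Template construction


def _ellipsoid(world: np.ndarray, center, semi) -> np.ndarray:
    c = np.asarray(center, dtype=float)[:, None]
    s = np.asarray(semi, dtype=float)[:, None]
    return (((world - c) / s) ** 2).sum(axis=0) <= 1.0


def _check_containment(grid: Grid) -> None:
    corners = grid.affine[:3, :3] @ np.array(
        [[0, 0, 0], [s - 1 for s in grid.shape]], dtype=float
    ).T + grid.affine[:3, 3:4]
    lo, hi = corners.min(axis=1), corners.max(axis=1)
    c, s = (np.asarray(v) for v in _BRAIN)
    if np.any(c - s < lo) or np.any(c + s > hi):
        raise PhantomSpecError(
            f"template grid world bounds [{lo}, {hi}] do not contain the "
            f"phantom head (extent [{c - s}, {c + s}])"
        )


def _structure_masks(grid: Grid) -> dict:
    """Boolean structure masks evaluated on a grid from world-mm geometry."""
    world = grid.world_coordinates()
    brain = _ellipsoid(world, *_BRAIN)
    masks = {"brain": brain}
    masks["ventricles"] = (
        _ellipsoid(world, *_VENTRICLE[+1]) | _ellipsoid(world, *_VENTRICLE[-1])
    ) & brain
    bg_r = _ellipsoid(world, *_BASAL_GANGLIA[+1]) & brain
    bg_l = _ellipsoid(world, *_BASAL_GANGLIA[-1]) & brain
    pons = _ellipsoid(world, *_PONS) & brain
    cb_r = _ellipsoid(world, *_CEREBELLUM[+1]) & brain
    cb_l = _ellipsoid(world, *_CEREBELLUM[-1]) & brain
    hemi = _ellipsoid(world, *_HEMI_ELLIPSOID) & brain & (world[2] > _HEMI_Z_CUT)
    hemi &= ~(bg_r | bg_l | pons | cb_r | cb_l)
    masks.update(
        {
            1: bg_r,
            2: bg_l,
            3: pons,
            4: cb_r & ~pons,
            5: cb_l & ~pons,
            6: hemi & (world[0] > _HEMI_X_GAP),
            7: hemi & (world[0] < -_HEMI_X_GAP),
        }
    )
    shape = grid.shape
    return {k: v.reshape(shape) for k, v in masks.items()}


def _tissue_maps(grid: Grid, masks: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """GM/WM/CSF probabilities from structure geometry.

    Hard masks (CSF rim + ventricles, cortical GM shell + deep GM
    structures + cerebellum, WM core) are blurred with a 1 mm Gaussian so
    borders carry realistic partial volume, then renormalised to sum <= 1.
    """
    spacing = grid.spacing
    depth = ndimage.distance_transform_edt(masks["brain"], sampling=spacing)
    csf0 = ((depth > 0) & (depth <= _CSF_RIM_MM)) | masks["ventricles"]
    gm_core = masks[1] | masks[2] | masks[4] | masks[5]
    gm0 = (((depth > _CSF_RIM_MM) & (depth <= _GM_SHELL_MM)) | gm_core) & ~csf0
    wm0 = (depth > _CSF_RIM_MM) & ~csf0 & ~gm0
    sigma = 1.0 / spacing  # 1 mm blur in voxels
    maps = []
    for m in (gm0, wm0, csf0):
        maps.append(ndimage.gaussian_filter(m.astype(np.float32), sigma=sigma))
    gm, wm, csf = (np.clip(m, 0.0, 1.0) for m in maps)
    total = gm + wm + csf
    scale = np.where(total > 1.0, 1.0 / np.maximum(total, 1e-9), 1.0)
    return gm * scale, wm * scale, csf * scale


def make_template_assets(spec: PhantomSpec) -> TemplateAssets:
    """Build the template anatomy, ROI label map and tissue maps."""
    grid = spec.grid_template
    _check_containment(grid)
    masks = _structure_masks(grid)
    labels = np.zeros(grid.shape, dtype=np.int32)
    for lab in sorted(ROI_REGISTRY):  # later assignments never overwrite
        labels[(labels == 0) & masks[lab]] = lab
    present = set(np.unique(labels)) - {0}
    if present != set(ROI_REGISTRY):
        raise PhantomSpecError(
            f"template grid too small: only labels {sorted(present)} realised"
        )
    gm, wm, csf = _tissue_maps(grid, masks)
    anat = (1.0 * gm + 0.7 * wm + 0.3 * csf).astype(np.float32)
    aff = grid.affine
    return TemplateAssets(
        anat=VolumeImage(anat, aff, space_tag="template"),
        rois=RoiLabelMap(labels, aff, registry=ROI_REGISTRY, space_tag="template"),
        tpm_gm=VolumeImage(gm, aff, space_tag="template"),
        tpm_wm=VolumeImage(wm, aff, space_tag="template"),
        tpm_csf=VolumeImage(csf, aff, space_tag="template"),
    )


def make_template(spec: PhantomSpec) -> tuple[VolumeImage, RoiLabelMap]:
    """Template anatomy and the seven-ROI generic label map."""
    assets = make_template_assets(spec)
    return assets.anat, assets.rois


# ---------------------------------------------------------------------------
# Deformations


def _smooth_random_field(
    rng: np.random.Generator,
    grid: Grid,
    amplitude_mm: float,
    smoothing_mm: float,
    direction_tag: str,
) -> DisplacementField:
    """Gaussian-smoothed random vector field scaled to a peak amplitude."""
    if amplitude_mm <= 0:
        return DisplacementField(
            np.zeros(grid.shape + (3,)), grid.affine, direction_tag=direction_tag
        )
    v = rng.standard_normal(size=grid.shape + (3,)).astype(np.float32)
    sigma = smoothing_mm / grid.spacing
    for c in range(3):
        v[..., c] = ndimage.gaussian_filter(v[..., c], sigma=sigma)
    mag = np.sqrt((v.astype(np.float64) ** 2).sum(axis=3)).max()
    v = v * (amplitude_mm / max(mag, 1e-12))
    return DisplacementField(
        v.astype(np.float64), grid.affine, direction_tag=direction_tag
    )


def _rater_jitter_field(
    rng: np.random.Generator, grid: Grid, spec: "PhantomSpec"
) -> DisplacementField | None:
    """Anisotropic boundary-jitter field emulating manual segmentation.

    Native reference ROIs are drawn by raters on the coarse, low-contrast
    perfusion grid, so their boundary uncertainty lives in DSC-voxel units:
    roughly one in-plane voxel, and a sizeable fraction of the 6 mm slice
    thickness through-plane. The field is smooth (10 mm correlation) and
    scaled per axis to the requested root-mean-square displacement. It is a
    disagreement model, not an anatomical deformation, so it is not forced
    to be diffeomorphic.
    """
    if spec.rater_jitter_inplane_mm <= 0 and spec.rater_jitter_z_mm <= 0:
        return None
    v = rng.standard_normal(size=grid.shape + (3,)).astype(np.float32)
    sigma = spec.rater_jitter_smoothing_mm / grid.spacing
    amps = (
        spec.rater_jitter_inplane_mm,
        spec.rater_jitter_inplane_mm,
        spec.rater_jitter_z_mm,
    )
    for c in range(3):
        v[..., c] = ndimage.gaussian_filter(v[..., c], sigma=sigma)
        rms = float(np.sqrt((v[..., c].astype(np.float64) ** 2).mean()))
        v[..., c] *= amps[c] / max(rms, 1e-12)
    return DisplacementField(
        v.astype(np.float64), grid.affine, direction_tag="native->native"
    )


def _count_folds(fld: DisplacementField) -> int:
    """Voxels where the Jacobian determinant of x + o(x) is non-positive."""
    spacing = fld.grid.spacing
    jac = np.empty(fld.offsets.shape[:3] + (3, 3))
    for c in range(3):
        grads = np.gradient(fld.offsets[..., c], *spacing)
        for a in range(3):
            jac[..., c, a] = grads[a]
    jac += np.eye(3)
    det = np.linalg.det(jac)
    return int((det <= 0).sum())


# ---------------------------------------------------------------------------
# DSC signal synthesis


def _gamma_variate(t: np.ndarray, t0: np.ndarray, tp: np.ndarray, alpha: np.ndarray):
    """Unit-peak gamma-variate: g(t0 + tp) = 1, zero before arrival t0."""
    u = np.clip((t - t0) / np.maximum(tp, 1e-3), 0.0, None)
    return (u**alpha) * np.exp(alpha * (1.0 - u))


def _mixed_voxel_params(spec: PhantomSpec, pg, pw, pc):
    """Probability-weighted per-voxel curve parameters on the DSC grid."""
    tp_par = spec.tissue_params
    p = np.stack([pg, pw, pc]).astype(np.float64)
    ptot = p.sum(axis=0)
    wnorm = p / np.maximum(ptot, 1e-6)
    s0 = sum(p[i] * tp_par[k].s0 for i, k in enumerate(("gm", "wm", "csf")))
    s0 = s0 + (1.0 - np.clip(ptot, 0, 1)) * spec.air_s0
    amp = sum(p[i] * tp_par[k].amplitude for i, k in enumerate(("gm", "wm", "csf")))
    tpk = sum(
        wnorm[i] * tp_par[k].time_to_peak_s for i, k in enumerate(("gm", "wm", "csf"))
    )
    alpha = sum(wnorm[i] * tp_par[k].alpha for i, k in enumerate(("gm", "wm", "csf")))
    # air voxels (ptot ~ 0) have amp 0; give them harmless curve parameters
    tpk = np.where(ptot > 1e-6, tpk, 1.0)
    alpha = np.where(ptot > 1e-6, alpha, 1.0)
    return s0, np.clip(amp, 0.0, 0.95), tpk, alpha, ptot


def _bolus_delay_s(spec: PhantomSpec, y_world: np.ndarray) -> np.ndarray:
    """Smooth anterior-posterior arrival-delay gradient across the brain."""
    _, semi = _BRAIN
    frac = np.clip((y_world + semi[1]) / (2.0 * semi[1]), 0.0, 1.0)
    return spec.delay_gradient_s * frac


def _slice_referenced(ttp: np.ndarray, valid: np.ndarray, quantile: float = 5.0):
    """Reference absolute peak times to a per-slice low quantile (truth side)."""
    out = np.full(ttp.shape, np.nan)
    for k in range(ttp.shape[2]):
        v = valid[:, :, k]
        if not v.any():
            continue
        offset = np.percentile(ttp[:, :, k][v], quantile)
        out[:, :, k][v] = np.maximum(ttp[:, :, k][v] - offset, 0.0)
    return out


# ---------------------------------------------------------------------------
# Subject construction


def make_subject(
    spec: PhantomSpec,
    template: TemplateAssets | tuple | None = None,
    index: int = 0,
) -> SubjectBundle:
    """Generate one synthetic subject from the spec (seed = master + index).

    Draws a smooth invertible template->native deformation, warps template
    anatomy/tissues/ROIs into native space, applies independent smooth
    boundary jitter to the truth ROIs (emulating manual-rater variability),
    simulates the DSC first pass on the perfusion grid through a known rigid
    DSC->anatomy offset, and records analytic per-ROI ground truth.
    """
    if template is None:
        template = make_template_assets(spec)
    elif isinstance(template, tuple):
        anat_t, rois_t = template
        assets = make_template_assets(spec)
        template = TemplateAssets(
            anat=anat_t,
            rois=rois_t,
            tpm_gm=assets.tpm_gm,
            tpm_wm=assets.tpm_wm,
            tpm_csf=assets.tpm_csf,
        )
    rng = np.random.default_rng(spec.subject_seed(index))

    native_grid = spec.grid_template  # native anat grid mirrors the template grid
    fld = _smooth_random_field(
        rng,
        native_grid,
        spec.deformation_amplitude_mm,
        spec.deformation_smoothing_mm,
        direction_tag="template->native",
    )
    folds = _count_folds(fld) if spec.deformation_amplitude_mm > 0 else 0
    if folds:
        raise PhantomSpecError(
            f"requested deformation is not invertible: {folds} folded voxels"
        )

    anat = warp(template.anat, fld, space_tag="anat-native")
    tpms = [
        warp(m, fld, space_tag="anat-native")
        for m in (template.tpm_gm, template.tpm_wm, template.tpm_csf)
    ]
    gm, wm, csf = (np.clip(m.data, 0.0, 1.0) for m in tpms)
    total = gm + wm + csf
    scale = np.where(total > 1.0, 1.0 / np.maximum(total, 1e-9), 1.0)
    gm, wm, csf = gm * scale, wm * scale, csf * scale

    rois_truth = warp_labels(template.rois, fld)
    rois_truth.space_tag = "anat-native"

    if spec.artifact_csf_flow:
        gm, wm, csf = _inject_csf_artifact(native_grid, gm, wm, csf)

    # Known rigid DSC->anatomy alignment (what co-registration must recover).
    if spec.coreg_shift_mm > 0:
        t_true = rng.uniform(-spec.coreg_shift_mm, spec.coreg_shift_mm, size=3)
    else:
        t_true = np.zeros(3)
    coreg_true = AffineTransform.translation(t_true)

    dsc_grid = spec.grid_dsc
    aff = native_grid.affine
    to_dsc = coreg_true.inverse()  # anat world -> dsc world
    pg, pw, pc = (
        np.clip(
            resample(VolumeImage(m, aff), dsc_grid, to_dsc, "linear").data, 0.0, 1.0
        )
        for m in (gm, wm, csf)
    )
    rois_truth_dsc = resample_labels(rois_truth, dsc_grid, to_dsc)
    jitter = _rater_jitter_field(rng, dsc_grid, spec)
    if jitter is not None:
        rois_truth_dsc = warp_labels(rois_truth_dsc, jitter)
    rois_truth_dsc.space_tag = "dsc-native"

    s0, amp, tpk, alpha, ptot = _mixed_voxel_params(spec, pg, pw, pc)
    y_anat = dsc_grid.world_coordinates()[1].reshape(dsc_grid.shape) + t_true[1]
    t0 = spec.bolus_arrival_s + _bolus_delay_s(spec, y_anat)

    t = (np.arange(spec.n_timepoints) * spec.tr_seconds).astype(np.float32)
    dip = amp.astype(np.float32)[..., None] * _gamma_variate(
        t[None, None, None, :],
        t0.astype(np.float32)[..., None],
        tpk.astype(np.float32)[..., None],
        alpha.astype(np.float32)[..., None],
    )
    signal = (s0[..., None] * (1.0 - dip)).astype(np.float32)
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape).astype(
            np.float32
        )
    signal = np.clip(signal, 0.0, None)
    dsc = DynamicSeries(
        signal, dsc_grid.affine, tr_seconds=spec.tr_seconds, space_tag="dsc-native"
    )

    # Analytic ground truth on the DSC grid (noise-free).
    valid = (ptot > 0.5) & (amp > 0.01)
    ttp_true = np.where(valid, t0 + tpk, np.nan)
    stdttp_true = _slice_referenced(ttp_true, valid)
    cbv_raw = np.trapezoid(-np.log1p(-np.clip(dip, 0.0, 0.999)), dx=spec.tr_seconds,
                           axis=3)
    norm = 1000.0 / max(float(cbv_raw[valid].mean()), 1e-12)
    cbv_true = np.where(valid, cbv_raw * norm, np.nan)

    truth: dict[str, dict[str, float]] = {}
    for lab, name in ROI_REGISTRY.items():
        m = (rois_truth_dsc.labels == lab) & valid
        if m.any():
            truth[name] = {
                "stdttp_s": float(np.nanmean(stdttp_true[m])),
                "cbv_au": float(np.nanmean(cbv_true[m])),
                "ttp_abs_s": float(np.nanmean(ttp_true[m])),
            }

    return SubjectBundle(
        index=index,
        anat=anat,
        tpm_gm=VolumeImage(gm, aff, space_tag="anat-native"),
        tpm_wm=VolumeImage(wm, aff, space_tag="anat-native"),
        tpm_csf=VolumeImage(csf, aff, space_tag="anat-native"),
        rois_truth_native=rois_truth,
        rois_truth_dsc=rois_truth_dsc,
        dsc=dsc,
        field_template_to_native=fld,
        coreg_true=coreg_true,
        truth=truth,
        stdttp_true=VolumeImage(stdttp_true, dsc_grid.affine, "dsc-native"),
        cbv_true=VolumeImage(cbv_true, dsc_grid.affine, "dsc-native"),
    )


def _inject_csf_artifact(grid: Grid, gm, wm, csf, radius_mm: float = 9.0):
    """Corrupt the tissue maps in a contiguous patch near the right
    ventricle/basal-ganglia region, emulating a CSF-flow artifact of
    spatial normalisation: GM/WM probability collapses, CSF inflates."""
    center = np.asarray(_BASAL_GANGLIA[+1][0])
    world = grid.world_coordinates()
    patch = (
        (((world - center[:, None]) ** 2).sum(axis=0) <= radius_mm**2)
        .reshape(grid.shape)
        .astype(np.float32)
    )
    patch = np.clip(ndimage.gaussian_filter(patch, sigma=1.0 / grid.spacing), 0, 1)
    gm = gm * (1.0 - patch)
    wm = wm * (1.0 - patch)
    csf = np.clip(np.maximum(csf, patch * (gm + wm + csf + patch > 0.2)), 0.0, 1.0)
    return gm, wm, csf


def make_cohort(
    spec: PhantomSpec, n_subjects: int = 36, template: TemplateAssets | None = None
):
    """Generate ``n_subjects`` independent subjects (lazily, as a list).

    Subjects are reproducible in isolation: subject ``i`` uses seed
    ``spec.seed + i`` regardless of cohort size.
    """
    if n_subjects < 1:
        raise PhantomSpecError("n_subjects must be >= 1")
    if template is None:
        template = make_template_assets(spec)
    return [make_subject(spec, template, index=i) for i in range(n_subjects)]


# ---------------------------------------------------------------------------
# On-disk layout (one folder per subject)


def write_subject(bundle: SubjectBundle, out_dir) -> Path:
    """Write a subject folder of NIfTI files plus ``truth.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_nifti(bundle.anat, out / "anat.nii.gz")
    write_nifti(bundle.tpm_gm, out / "tpm_gm.nii.gz")
    write_nifti(bundle.tpm_wm, out / "tpm_wm.nii.gz")
    write_nifti(bundle.tpm_csf, out / "tpm_csf.nii.gz")
    write_nifti(bundle.rois_truth_native, out / "rois_truth_native.nii.gz")
    write_nifti(bundle.rois_truth_dsc, out / "rois_truth_dsc.nii.gz")
    write_nifti(bundle.dsc, out / "dsc.nii.gz")
    write_nifti(bundle.field_template_to_native, out / "field_template_to_native.nii.gz")
    (out / "truth.json").write_text(
        json.dumps(
            {
                "index": bundle.index,
                "coreg_true_matrix": bundle.coreg_true.matrix.tolist(),
                "truth": bundle.truth,
            },
            indent=2,
        )
    )
    return out


def read_subject(subject_dir) -> SubjectBundle:
    """Load a subject folder written by :func:`write_subject`."""
    d = Path(subject_dir)
    meta = json.loads((d / "truth.json").read_text())
    return SubjectBundle(
        index=int(meta["index"]),
        anat=read_nifti(d / "anat.nii.gz"),
        tpm_gm=read_nifti(d / "tpm_gm.nii.gz"),
        tpm_wm=read_nifti(d / "tpm_wm.nii.gz"),
        tpm_csf=read_nifti(d / "tpm_csf.nii.gz"),
        rois_truth_native=read_nifti(d / "rois_truth_native.nii.gz"),
        rois_truth_dsc=read_nifti(d / "rois_truth_dsc.nii.gz"),
        dsc=read_nifti(d / "dsc.nii.gz"),
        field_template_to_native=read_nifti(d / "field_template_to_native.nii.gz"),
        coreg_true=AffineTransform(np.asarray(meta["coreg_true_matrix"])),
        truth=meta["truth"],
    )
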