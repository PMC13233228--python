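"""DSC perfusion parameter maps: mean-TDC, absolute TTP, stdTTP and CBV.

The first-pass bolus of a dynamic susceptibility contrast (DSC) series is a
transient signal *drop*. Per slice, an event window is detected on the
slice-mean drop curve; within that window, absolute time-to-peak (TTP) is
the time of the deepest drop, stdTTP references TTP to a slice-specific
"earliest regular arrival" offset (a low quantile of in-mask TTP), and CBV
integrates the concentration proxy -ln(S/S0) over the window, normalised so
the whole-brain in-mask mean is 1000 a.u.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import EventError, GeometryError
from .imagecore import DynamicSeries, VolumeImage

__all__ = [
    "PerfusionMaps",
    "brain_mask_from_mean",
    "detect_event",
    "compute_ttp",
    "compute_stdttp",
    "compute_cbv",
    "compute_mean_tdc",
    "compute_maps",
]

log = logging.getLogger(__name__)

#: Fraction of the peak drop that still counts as "inside the event".
EVENT_DROP_FRACTION = 0.10
#: Default slice-offset quantile for stdTTP (percent).
STDTTP_OFFSET_QUANTILE = 5.0
#: CBV normalisation target for the whole-brain in-mask mean (a.u.).
CBV_BRAIN_MEAN = 1000.0


@dataclass
class PerfusionMaps:
    """All parameter maps derived from one DSC series."""

    mean_tdc: VolumeImage
    ttp_abs: VolumeImage
    stdttp: VolumeImage
    cbv: VolumeImage
    brain_mask: VolumeImage
    event_window: dict[int, tuple[int, int]]  # slice -> (t_start, t_end), end-exclusive


def compute_mean_tdc(dsc: DynamicSeries) -> VolumeImage:
    """Voxelwise time-average of the series (the anatomical 'mean image')."""
    return VolumeImage(
        dsc.data.mean(axis=3).astype(np.float32), dsc.affine, space_tag=dsc.space_tag
    )


def brain_mask_from_mean(mean_tdc: VolumeImage) -> VolumeImage:
    """Otsu threshold on the mean image, keeping the largest component."""
    data = np.asarray(mean_tdc.data, dtype=np.float64)
    thr = threshold_otsu(data)
    mask = data > thr
    labelled, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labelled, index=np.arange(1, n + 1))
        mask = labelled == (1 + int(np.argmax(sizes)))
    return VolumeImage(
        mask.astype(np.uint8), mean_tdc.affine, space_tag=mean_tdc.space_tag
    )


def _baseline_length(n_timepoints: int) -> int:
    # pre-bolus baseline estimate: the first eighth of the series
    return max(3, n_timepoints // 8)


def detect_event(
    dsc: DynamicSeries, brain_mask: VolumeImage
) -> dict[int, tuple[int, int]]:
    """Per-slice first-pass event windows from the slice-mean drop curve.

    The drop curve is ``baseline - mean_signal(t)`` with the baseline taken
    from the earliest timepoints. The window is the contiguous run around
    the peak drop where the drop exceeds 10% of its peak, extended outward
    to the nearest baseline crossings. A slice whose mask is empty is
    skipped; a slice with no detectable drop raises :class:`EventError`.
    """
    if dsc.n_timepoints < 3:
        raise EventError("need at least 3 timepoints to detect an event")
    mask = brain_mask.data.astype(bool)
    if mask.shape != dsc.data.shape[:3]:
        raise GeometryError("brain mask grid does not match the DSC grid")
    n_t = dsc.n_timepoints
    n_base = _baseline_length(n_t)
    windows: dict[int, tuple[int, int]] = {}
    for k in range(dsc.data.shape[2]):
        m = mask[:, :, k]
        if not m.any():
            continue
        curve = dsc.data[:, :, k][m].mean(axis=0).astype(np.float64)
        baseline = curve[:n_base].mean()
        drop = baseline - curve
        peak = int(np.argmax(drop))
        peak_drop = drop[peak]
        noise_scale = max(np.abs(drop[:n_base]).max(), 1e-12)
        if peak_drop <= 3.0 * noise_scale or peak_drop <= 0:
            raise EventError(
                f"no detectable first-pass drop in slice {k} "
                f"(peak drop {peak_drop:.3g}, baseline noise {noise_scale:.3g})"
            )
        thr = EVENT_DROP_FRACTION * peak_drop
        lo = peak
        while lo > 0 and drop[lo - 1] > thr:
            lo -= 1
        hi = peak
        while hi < n_t - 1 and drop[hi + 1] > thr:
            hi += 1
        while lo > 0 and drop[lo - 1] > 0:
            lo -= 1
        while hi < n_t - 1 and drop[hi + 1] > 0:
            hi += 1
        windows[k] = (lo, hi + 1)
    if not windows:
        raise EventError("brain mask is empty in every slice")
    return windows


def compute_ttp(
    dsc: DynamicSeries,
    event_window: dict[int, tuple[int, int]],
    brain_mask: VolumeImage,
) -> VolumeImage:
    """Absolute TTP (seconds): time of the deepest drop in the slice window.

    TTP is ``tr_seconds`` times the absolute time index of the voxel's
    maximal signal drop inside its slice's event window; ties break to the
    earliest index. Voxels outside the mask (or in slices without a window)
    are NaN.
    """
    mask = brain_mask.data.astype(bool)
    n_base = _baseline_length(dsc.n_timepoints)
    out = np.full(dsc.data.shape[:3], np.nan, dtype=np.float64)
    for k, (lo, hi) in event_window.items():
        if not (0 <= lo < hi <= dsc.n_timepoints):
            raise EventError(f"invalid event window {(lo, hi)} for slice {k}")
        m = mask[:, :, k]
        if not m.any():
            continue
        sig = dsc.data[:, :, k][m].astype(np.float64)
        s0 = sig[:, :n_base].mean(axis=1, keepdims=True)
        drop = s0 - sig[:, lo:hi]
        idx = lo + np.argmax(drop, axis=1)  # argmax -> earliest on ties
        out[:, :, k][m] = idx * dsc.tr_seconds
    return VolumeImage(out, dsc.affine, space_tag=dsc.space_tag)


def compute_stdttp(
    ttp_abs: VolumeImage,
    brain_mask: VolumeImage,
    offset_quantile: float = STDTTP_OFFSET_QUANTILE,
) -> VolumeImage:
    """Slice-referenced (standardised) TTP.

    Per slice, the offset is a low quantile (default 5th percentile) of
    in-mask TTP — a robust estimate of the earliest regular bolus arrival
    in that slice; stdTTP = max(TTP - offset, 0). Slices with an empty mask
    stay NaN and are logged.
    """
    mask = brain_mask.data.astype(bool)
    out = np.full(ttp_abs.data.shape, np.nan)
    for k in range(ttp_abs.data.shape[2]):
        m = mask[:, :, k] & np.isfinite(ttp_abs.data[:, :, k])
        if not m.any():
            log.info("stdTTP: slice %d has no masked voxels, skipped", k)
            continue
        vals = ttp_abs.data[:, :, k][m]
        offset = np.percentile(vals, offset_quantile)
        out[:, :, k][m] = np.maximum(vals - offset, 0.0)
    return VolumeImage(out, ttp_abs.affine, space_tag=ttp_abs.space_tag)


def compute_cbv(
    dsc: DynamicSeries,
    event_window: dict[int, tuple[int, int]],
    brain_mask: VolumeImage,
    brain_mean_target: float = CBV_BRAIN_MEAN,
) -> VolumeImage:
    """CBV: integral of -ln(S/S0) over the slice event window, normalised.

    S0 is the pre-window baseline mean per voxel. Voxels with non-positive
    signal inside the window become NaN (counted and logged). After
    integration the map is scaled so the whole-brain in-mask mean equals
    ``brain_mean_target`` (default 1000 a.u.).
    """
    mask = brain_mask.data.astype(bool)
    out = np.full(dsc.data.shape[:3], np.nan, dtype=np.float64)
    n_bad = 0
    for k, (lo, hi) in event_window.items():
        m = mask[:, :, k]
        if not m.any():
            continue
        sig = dsc.data[:, :, k][m].astype(np.float64)
        n_base = lo if lo >= 3 else _baseline_length(dsc.n_timepoints)
        s0 = sig[:, :n_base].mean(axis=1)
        window = sig[:, lo:hi]
        bad = (window <= 0).any(axis=1) | (s0 <= 0)
        n_bad += int(bad.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            conc = -np.log(window / s0[:, None])
        integral = np.trapezoid(conc, dx=dsc.tr_seconds, axis=1)
        integral[bad] = np.nan
        out[:, :, k][m] = integral
    if n_bad:
        log.info("CBV: %d voxels had non-positive signal and were set NaN", n_bad)
    finite = mask & np.isfinite(out)
    mean = float(out[finite].mean()) if finite.any() else 0.0
    if mean > 0:
        out = out * (brain_mean_target / mean)
    return VolumeImage(out, dsc.affine, space_tag=dsc.space_tag)


def compute_maps(
    dsc: DynamicSeries, brain_mask: VolumeImage | None = None
) -> PerfusionMaps:
    """Run the full map computation for one DSC series."""
    mean_tdc = compute_mean_tdc(dsc)
    if brain_mask is None:
        brain_mask = brain_mask_from_mean(mean_tdc)
    windows = detect_event(dsc, brain_mask)
    ttp = compute_ttp(dsc, windows, brain_mask)
    stdttp = compute_stdttp(ttp, brain_mask)
    cbv = compute_cbv(dsc, windows, brain_mask)
    return PerfusionMaps(
        mean_tdc=mean_tdc,
        ttp_abs=ttp,
        stdttp=stdttp,
        cbv=cbv,
        brain_mask=brain_mask,
        event_window=windows,
    )
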