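"""Spatial-overlap and functional-agreement statistics.

Spatial side: ROI volumes, signed volume error VE = (V_nat - V_gen) /
(0.5 (V_nat + V_gen)), Sørensen-Dice index, and the surface-to-volume
ratio from exposed voxel faces. Functional side: paired comparison of
ROI-mean parameter values via bias, percentile limits of agreement, a
normal-theory CI95 of the bias, Pearson/Spearman correlation, Lin's
concordance correlation coefficient, and the NRMSE of the linear fit
normalised by the mean of the native (reference) values. Cohort summaries
are median ± MAD per ROI plus pooled rows, with the SDI-versus-volume and
SDI-versus-SVR regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError
from .imagecore import RoiLabelMap
from .perfmaps import PerfusionMaps

__all__ = [
    "SpatialOverlapResult",
    "AgreementStats",
    "CohortSummary",
    "volume_error",
    "dice",
    "surface_to_volume",
    "concordance",
    "bland_altman",
    "fit_and_nrmse",
    "evaluate_pair",
    "summarize_cohort",
    "mad",
]


@dataclass
class SpatialOverlapResult:
    """Spatial comparison of one native/generic ROI pair."""

    roi_name: str
    v_native_mm3: float
    v_generic_mm3: float
    ve: float  # signed, dimensionless (fraction of the mean volume)
    svr_per_mm: float  # of the native (reference) ROI
    sdi: float


@dataclass
class AgreementStats:
    """Paired agreement between generic and native ROI-mean values.

    Sign convention: differences are generic - native throughout.
    """

    n: int
    bias: float
    ci95_bias: tuple[float, float]
    loa: tuple[float, float]  # 2.5th / 97.5th percentile of differences
    pcc: float
    srcc: float
    ccc: float
    slope: float
    intercept: float
    nrmse: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci95_bias"] = list(self.ci95_bias)
        d["loa"] = list(self.loa)
        return d


def mad(x) -> float:
    """Median absolute deviation (raw, unscaled)."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


def volume_error(v_native: float, v_generic: float) -> float:
    """Signed volume error, normalised by the mean of the two volumes."""
    if v_native + v_generic <= 0:
        raise UndefinedStatisticError("volume error undefined for two empty ROIs")
    return (v_native - v_generic) / (0.5 * (v_native + v_generic))


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Sørensen-Dice index 2|A∩B| / (|A| + |B|) of two binary masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise UndefinedStatisticError("masks must share a grid")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise UndefinedStatisticError("Dice undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / (na + nb)


def surface_to_volume(mask: np.ndarray, spacing) -> float:
    """Surface-to-volume ratio (1/mm) from exposed voxel faces.

    The surface is the summed area of faces between mask and background
    (including the array boundary); each face's area comes from the two
    in-plane spacings of its orientation.
    """
    m = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    if m.ndim != 3 or spacing.shape != (3,):
        raise UndefinedStatisticError("mask must be 3D with a 3-vector spacing")
    if not m.any():
        raise UndefinedStatisticError("SVR undefined for an empty mask")
    padded = np.pad(m, 1).astype(np.int8)
    surface = 0.0
    for axis in range(3):
        faces = int(np.abs(np.diff(padded, axis=axis)).sum())
        others = [spacing[a] for a in range(3) if a != axis]
        surface += faces * others[0] * others[1]
    volume = float(m.sum()) * float(np.prod(spacing))
    return surface / volume


def _paired(x, y, n_min: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UndefinedStatisticError("x and y must be 1D paired arrays")
    if x.size < n_min:
        raise UndefinedStatisticError(f"need at least {n_min} pairs, got {x.size}")
    return x, y


def concordance(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    x, y = _paired(x, y)
    mx, my = x.mean(), y.mean()
    vx, vy = np.mean((x - mx) ** 2), np.mean((y - my) ** 2)
    cov = np.mean((x - mx) * (y - my))
    denom = vx + vy + (mx - my) ** 2
    if denom <= 0:
        raise UndefinedStatisticError("CCC undefined: both variances and bias are zero")
    return float(2.0 * cov / denom)


def bland_altman(x, y):
    """Bias, CI95 of the bias and percentile limits of agreement.

    Differences are ``y - x``. The bias CI is normal-theory
    (bias ± 1.96·sd/√n, sd with n-1 denominator; degenerate sd gives a
    zero-width interval); the LOA are the 2.5th and 97.5th percentiles of
    the differences with linear-interpolation quantiles.
    """
    x, y = _paired(x, y)
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = 1.96 * sd / np.sqrt(d.size)
    ci = (bias - half, bias + half)
    loa = tuple(float(v) for v in np.percentile(d, [2.5, 97.5], method="linear"))
    return bias, ci, loa


def fit_and_nrmse(x, y):
    """OLS fit of y on x plus NRMSE, PCC and SRCC.

    NRMSE is the root-mean-square of (fitted - native) over the mean of the
    native values, with x taken as the native reference.
    """
    x, y = _paired(x, y)
    if np.isclose(x.var(), 0.0):
        raise UndefinedStatisticError("regression undefined: zero variance in x")
    res = stats.linregress(x, y)
    fit = res.slope * x + res.intercept
    mean_x = x.mean()
    if np.isclose(mean_x, 0.0):
        raise UndefinedStatisticError("NRMSE undefined: reference mean is zero")
    nrmse = float(np.sqrt(np.mean((fit - x) ** 2)) / mean_x)
    pcc = float(res.rvalue)
    srcc = float(stats.spearmanr(x, y).statistic)
    return float(res.slope), float(res.intercept), nrmse, pcc, srcc


def pooled_agreement(x_native, y_generic) -> AgreementStats:
    """All paired agreement statistics for one parameter."""
    x, y = _paired(x_native, y_generic)
    bias, ci, loa = bland_altman(x, y)
    slope, intercept, nrmse, pcc, srcc = fit_and_nrmse(x, y)
    return AgreementStats(
        n=int(x.size),
        bias=bias,
        ci95_bias=ci,
        loa=loa,
        pcc=pcc,
        srcc=srcc,
        ccc=concordance(x, y),
        slope=slope,
        intercept=intercept,
        nrmse=nrmse,
    )


# ---------------------------------------------------------------------------
# Pair evaluation and cohort summaries


def _roi_mean(map_data: np.ndarray, mask: np.ndarray) -> float:
    vals = map_data[mask]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def evaluate_pair(
    rois_truth: RoiLabelMap,
    rois_art: RoiLabelMap,
    maps: PerfusionMaps,
    subject: int | str | None = None,
) -> list[dict]:
    """Per-ROI spatial and functional comparison on the DSC grid.

    For every label in the truth registry, computes the spatial overlap
    (volumes, VE, SDI, native-ROI SVR) and the mean stdTTP/CBV inside the
    native (truth) and generic (arT) masks. A label empty in either map is
    recorded with ``missing=True`` rather than raised.
    """
    if not rois_truth.grid.same_geometry(rois_art.grid):
        raise UndefinedStatisticError("truth and arT label maps must share a grid")
    grid = rois_truth.grid
    vv = grid.voxel_volume
    spacing = grid.spacing
    records = []
    for lab, name in sorted(rois_truth.registry.items()):
        m_nat = rois_truth.labels == lab
        m_gen = rois_art.labels == lab
        rec: dict = {"subject": subject, "roi": name, "label": lab}
        if not m_nat.any() or not m_gen.any():
            rec.update({"missing": True})
            records.append(rec)
            continue
        v_nat, v_gen = float(m_nat.sum()) * vv, float(m_gen.sum()) * vv
        rec.update(
            {
                "missing": False,
                "v_native_mm3": v_nat,
                "v_generic_mm3": v_gen,
                "v_mean_mm3": 0.5 * (v_nat + v_gen),
                "ve": volume_error(v_nat, v_gen),
                "sdi": dice(m_nat, m_gen),
                "svr_per_mm": surface_to_volume(m_nat, spacing),
                "stdttp_nat_s": _roi_mean(maps.stdttp.data, m_nat),
                "stdttp_gen_s": _roi_mean(maps.stdttp.data, m_gen),
                "cbv_nat_au": _roi_mean(maps.cbv.data, m_nat),
                "cbv_gen_au": _roi_mean(maps.cbv.data, m_gen),
            }
        )
        records.append(rec)
    return records


@dataclass
class CohortSummary:
    """Cohort-level tables and pooled agreement statistics.

    ``spatial``/``stdttp``/``cbv`` are per-ROI median ± MAD tables (with a
    pooled row); ``agreement_stdttp``/``agreement_cbv`` pool all ROI pairs;
    ``regressions`` holds the SDI-vs-volume (Spearman, on log volume) and
    SDI-vs-SVR (Pearson, linear) relationships.
    """

    spatial: pd.DataFrame
    stdttp: pd.DataFrame
    cbv: pd.DataFrame
    agreement_stdttp: AgreementStats
    agreement_cbv: AgreementStats
    regressions: dict
    n_pairs: int


def _med_mad(group: pd.Series) -> tuple[float, float]:
    return float(group.median()), mad(group)


def _roi_table(df: pd.DataFrame, columns: dict[str, str]) -> pd.DataFrame:
    """Per-ROI (and pooled) median ± MAD table for the requested columns."""
    rows = []
    roi_order = list(dict.fromkeys(df["roi"]))
    for roi in roi_order + ["total"]:
        sub = df if roi == "total" else df[df["roi"] == roi]
        row: dict = {"roi": roi, "n": int(len(sub))}
        for col, out_name in columns.items():
            med, md = _med_mad(sub[col])
            row[f"{out_name}_median"] = med
            row[f"{out_name}_mad"] = md
        rows.append(row)
    return pd.DataFrame(rows)


def _per_roi_correlations(df: pd.DataFrame, nat: str, gen: str) -> pd.DataFrame:
    rows = []
    for roi in list(dict.fromkeys(df["roi"])) + ["total"]:
        sub = df if roi == "total" else df[df["roi"] == roi]
        if len(sub) >= 3 and sub[nat].var() > 0:
            pcc = float(stats.pearsonr(sub[nat], sub[gen]).statistic)
            ccc = concordance(sub[nat].to_numpy(), sub[gen].to_numpy())
        else:
            pcc = ccc = float("nan")
        rows.append({"roi": roi, "pcc": pcc, "ccc": ccc})
    return pd.DataFrame(rows)


def summarize_cohort(records) -> CohortSummary:
    """Aggregate per-ROI pair records into cohort tables and pooled stats."""
    df = pd.DataFrame(records)
    if df.empty:
        raise UndefinedStatisticError("no records to summarise")
    if "missing" in df.columns:
        df = df[~df["missing"].astype(bool)].copy()
    if df.empty:
        raise UndefinedStatisticError("all records are missing ROIs")
    df["ve_pct"] = 100.0 * df["ve"]
    df["bias_stdttp_s"] = df["stdttp_gen_s"] - df["stdttp_nat_s"]
    df["bias_cbv_au"] = df["cbv_gen_au"] - df["cbv_nat_au"]

    spatial = _roi_table(
        df,
        {
            "v_mean_mm3": "v_mean_mm3",
            "svr_per_mm": "svr_per_mm",
            "ve_pct": "ve_pct",
            "sdi": "sdi",
        },
    )
    stdttp = _roi_table(
        df,
        {"stdttp_nat_s": "nat_s", "stdttp_gen_s": "gen_s", "bias_stdttp_s": "bias_s"},
    ).merge(_per_roi_correlations(df, "stdttp_nat_s", "stdttp_gen_s"), on="roi")
    cbv = _roi_table(
        df, {"cbv_nat_au": "nat_au", "cbv_gen_au": "gen_au", "bias_cbv_au": "bias_au"}
    ).merge(_per_roi_correlations(df, "cbv_nat_au", "cbv_gen_au"), on="roi")

    agree_ttp = pooled_agreement(df["stdttp_nat_s"], df["stdttp_gen_s"])
    agree_cbv = pooled_agreement(df["cbv_nat_au"], df["cbv_gen_au"])

    nan = float("nan")
    if len(df) >= 3 and df["svr_per_mm"].var() > 0 and df["v_mean_mm3"].var() > 0:
        log_v = np.log10(df["v_mean_mm3"])
        svr_fit = stats.linregress(df["svr_per_mm"], df["sdi"])
        regressions = {
            "srcc_sdi_volume": float(stats.spearmanr(df["sdi"], log_v).statistic),
            "pcc_sdi_svr": float(
                stats.pearsonr(df["sdi"], df["svr_per_mm"]).statistic
            ),
            "sdi_vs_svr_slope": float(svr_fit.slope),
            "sdi_vs_svr_intercept": float(svr_fit.intercept),
        }
    else:  # degenerate cohort (single ROI shape): regressions undefined
        regressions = {
            "srcc_sdi_volume": nan,
            "pcc_sdi_svr": nan,
            "sdi_vs_svr_slope": nan,
            "sdi_vs_svr_intercept": nan,
        }
    return CohortSummary(
        spatial=spatial,
        stdttp=stdttp,
        cbv=cbv,
        agreement_stdttp=agree_ttp,
        agreement_cbv=agree_cbv,
        regressions=regressions,
        n_pairs=int(len(df)),
    )
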