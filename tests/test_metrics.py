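"""Overlap and agreement statistics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from artroi.errors import UndefinedStatisticError
from artroi.imagecore import RoiLabelMap, VolumeImage
from artroi.metrics import (
    bland_altman,
    concordance,
    dice,
    evaluate_pair,
    fit_and_nrmse,
    mad,
    summarize_cohort,
    surface_to_volume,
    volume_error,
)
from artroi.perfmaps import PerfusionMaps


# --- brute-force reference implementations (kept deliberately naive) -------


def dice_brute(a, b):
    inter = sum(1 for x, y in zip(a.ravel(), b.ravel()) if x and y)
    return 2.0 * inter / (int(a.sum()) + int(b.sum()))


def ccc_brute(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    vx = sum((v - mx) ** 2 for v in x) / n
    vy = sum((v - my) ** 2 for v in y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * cov / (vx + vy + (mx - my) ** 2)


def nrmse_brute(x, y):
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    rss = sum((slope * a + intercept - a) ** 2 for a in x) / n
    return (rss**0.5) / (sx / n)


class TestFormulaOracles:
    def test_dice_matches_brute_force(self, rng):
        for _ in range(50):
            a = rng.random((6, 6, 6)) > 0.5
            b = rng.random((6, 6, 6)) > 0.5
            assert dice(a, b) == pytest.approx(dice_brute(a, b), rel=1e-12)

    def test_concordance_matches_brute_force(self, rng):
        for _ in range(50):
            x = rng.normal(size=20)
            y = 0.5 * x + rng.normal(size=20)
            assert concordance(x, y) == pytest.approx(
                ccc_brute(list(x), list(y)), rel=1e-10
            )

    def test_nrmse_matches_brute_force(self, rng):
        for _ in range(50):
            x = rng.normal(loc=5.0, size=25)
            y = 1.2 * x + rng.normal(size=25)
            _, _, nrmse, _, _ = fit_and_nrmse(x, y)
            assert nrmse == pytest.approx(nrmse_brute(list(x), list(y)), rel=1e-9)

    def test_bland_altman_matches_direct_computation(self, rng):
        for _ in range(50):
            x = rng.normal(size=30)
            y = x + rng.normal(scale=0.3, size=30)
            bias, ci, loa = bland_altman(x, y)
            d = y - x
            assert bias == pytest.approx(d.mean(), rel=1e-12, abs=1e-14)
            half = 1.96 * d.std(ddof=1) / np.sqrt(30)
            assert ci == pytest.approx((d.mean() - half, d.mean() + half), rel=1e-10)
            assert loa == pytest.approx(
                tuple(np.percentile(d, [2.5, 97.5])), rel=1e-10
            )


class TestAnalyticIdentities:
    def test_dice_of_identical_and_disjoint_masks(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        a[:2] = True
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0
        b = np.zeros_like(a)
        b[1:3] = True  # |A|=|B|=32, overlap 16
        assert dice(a, b) == pytest.approx(0.5)
        with pytest.raises(UndefinedStatisticError):
            dice(np.zeros_like(a), np.zeros_like(a))

    def test_volume_error_identities(self):
        assert volume_error(5.0, 5.0) == 0.0
        assert volume_error(10.0, 12.5) == pytest.approx(-0.2222, abs=5e-5)
        assert volume_error(12.5, 10.0) == pytest.approx(0.2222, abs=5e-5)
        with pytest.raises(UndefinedStatisticError):
            volume_error(0.0, 0.0)

    def test_ccc_location_shift_penalty(self, rng):
        x = rng.normal(size=50)
        assert concordance(x, x) == pytest.approx(1.0)
        shifted = concordance(x, x + 1.0)
        assert shifted < 1.0
        assert np.corrcoef(x, x + 1.0)[0, 1] == pytest.approx(1.0)

    def test_nrmse_zero_for_identity(self, rng):
        x = rng.normal(loc=3.0, size=20)
        slope, intercept, nrmse, pcc, _ = fit_and_nrmse(x, x)
        assert (slope, intercept) == pytest.approx((1.0, 0.0), abs=1e-10)
        assert nrmse == pytest.approx(0.0, abs=1e-12)
        assert pcc == pytest.approx(1.0)

    def test_nrmse_formula_for_proportional_data(self, rng):
        x = np.abs(rng.normal(loc=4.0, size=30)) + 1.0
        _, _, nrmse, pcc, _ = fit_and_nrmse(x, 2 * x)
        # fit is exact (y = 2x), so fitted-vs-native error is x itself
        assert pcc == pytest.approx(1.0)
        assert nrmse == pytest.approx(np.sqrt(np.mean(x**2)) / x.mean(), rel=1e-10)

    def test_svr_of_cubes(self):
        for side in (10, 60):
            mask = np.zeros((side + 2,) * 3, dtype=bool)
            mask[1:-1, 1:-1, 1:-1] = True
            assert surface_to_volume(mask, (1.0, 1.0, 1.0)) == pytest.approx(
                6.0 / side
            )

    def test_mad_example(self):
        assert np.median([1, 2, 9]) == 2
        assert mad([1, 2, 9]) == 1.0


class TestSurfaceEstimator:
    def test_face_count_agrees_with_marching_cubes_on_blob(self, rng):
        from scipy import ndimage
        from skimage.measure import marching_cubes, mesh_surface_area

        blob = ndimage.gaussian_filter(rng.random((24, 24, 24)), 3.0)
        mask = blob > np.percentile(blob, 70)
        svr = surface_to_volume(mask, (1.0, 1.0, 1.0))
        verts, faces, _, _ = marching_cubes(np.pad(mask, 1).astype(float), 0.5)
        area = mesh_surface_area(verts, faces)
        svr_mc = area / mask.sum()
        assert abs(svr - svr_mc) / svr_mc < 0.55  # face counting overestimates

    def test_svr_decreases_with_object_size(self):
        svrs = []
        for side in (6, 10, 16, 24):
            mask = np.zeros((side + 2,) * 3, dtype=bool)
            mask[1:-1, 1:-1, 1:-1] = True
            svrs.append(surface_to_volume(mask, (1.0, 1.0, 1.0)))
        assert all(a > b for a, b in zip(svrs, svrs[1:]))


class TestProperties:
    @settings(deadline=None, max_examples=60)
    @given(
        v1=st.floats(0.01, 1e6),
        v2=st.floats(0.01, 1e6),
    )
    def test_volume_error_antisymmetric_and_bounded(self, v1, v2):
        ve = volume_error(v1, v2)
        assert volume_error(v2, v1) == pytest.approx(-ve, rel=1e-9)
        assert abs(ve) <= 2.0

    @settings(deadline=None, max_examples=60)
    @given(st.data())
    def test_ccc_never_exceeds_pcc_in_magnitude(self, data):
        n = data.draw(st.integers(5, 40))
        x = np.asarray(
            data.draw(
                st.lists(
                    st.floats(-100, 100), min_size=n, max_size=n
                )
            )
        )
        y = np.asarray(
            data.draw(
                st.lists(
                    st.floats(-100, 100), min_size=n, max_size=n
                )
            )
        )
        if x.var() < 1e-9 or y.var() < 1e-9:
            return
        pcc = np.corrcoef(x, y)[0, 1]
        assert abs(concordance(x, y)) <= abs(pcc) + 1e-9

    @settings(deadline=None, max_examples=60)
    @given(seed=st.integers(0, 10_000))
    def test_srcc_invariant_under_monotone_transforms(self, seed):
        from scipy import stats

        r = np.random.default_rng(seed)
        x = r.normal(size=25)
        y = x + r.normal(scale=0.5, size=25)
        base = stats.spearmanr(x, y).statistic
        trans = stats.spearmanr(np.exp(x), y**3).statistic
        assert trans == pytest.approx(base, abs=1e-12)


class TestBlandAltman:
    def test_identical_methods(self, rng):
        x = rng.normal(size=20)
        bias, ci, loa = bland_altman(x, x.copy())
        assert bias == 0.0
        assert ci == (0.0, 0.0)
        assert loa == (0.0, 0.0)

    def test_constant_offset(self, rng):
        x = rng.normal(size=10)
        bias, ci, loa = bland_altman(x, x + 0.5)
        assert bias == pytest.approx(0.5)
        assert loa == pytest.approx((0.5, 0.5))
        assert ci[0] > 0.0  # degenerate sd: CI collapses onto the bias

    def test_loa_match_normal_quantiles_at_large_n(self):
        r = np.random.default_rng(11)
        x = np.zeros(1000)
        y = r.standard_normal(1000)
        _, _, loa = bland_altman(x, y)
        # quantile standard error at n=1000 is ~0.085; allow 4 sigma
        assert loa[0] == pytest.approx(-1.96, abs=0.35)
        assert loa[1] == pytest.approx(1.96, abs=0.35)

    def test_loa_cover_about_95_percent(self):
        r = np.random.default_rng(5)
        d = r.standard_normal(2000)
        _, _, loa = bland_altman(np.zeros(2000), d)
        frac = np.mean((d >= loa[0]) & (d <= loa[1]))
        assert abs(frac - 0.95) < 0.02


def _toy_maps(shape, affine):
    const = VolumeImage(np.full(shape, 2.0), affine)
    return PerfusionMaps(
        mean_tdc=const,
        ttp_abs=const,
        stdttp=VolumeImage(np.linspace(0, 3, np.prod(shape)).reshape(shape), affine),
        cbv=VolumeImage(np.linspace(500, 1500, np.prod(shape)).reshape(shape), affine),
        brain_mask=VolumeImage(np.ones(shape, dtype=np.uint8), affine),
        event_window={k: (10, 50) for k in range(shape[2])},
    )


class TestEvaluatePair:
    affine = np.diag([2.0, 2.0, 6.0, 1.0])

    def _rois(self, shape=(10, 10, 6)):
        labels = np.zeros(shape, dtype=np.int32)
        labels[2:5, 2:5, 1:3] = 1
        labels[6:9, 6:9, 3:5] = 2
        return RoiLabelMap(labels, self.affine, registry={1: "small", 2: "other"})

    def test_identical_maps_give_perfect_overlap(self):
        rois = self._rois()
        maps = _toy_maps(rois.labels.shape, self.affine)
        records = evaluate_pair(rois, rois, maps)
        for rec in records:
            assert rec["sdi"] == 1.0
            assert rec["ve"] == 0.0
            assert rec["stdttp_gen_s"] == rec["stdttp_nat_s"]
        # volumes in mm^3 account for the anisotropic voxel
        assert records[0]["v_native_mm3"] == pytest.approx(3 * 3 * 2 * 24.0)

    def test_missing_label_is_recorded_not_fatal(self):
        rois = self._rois()
        other = RoiLabelMap(
            np.where(rois.labels == 2, 0, rois.labels),
            self.affine,
            registry=rois.registry,
        )
        maps = _toy_maps(rois.labels.shape, self.affine)
        records = evaluate_pair(rois, other, maps)
        by_name = {r["roi"]: r for r in records}
        assert by_name["other"]["missing"] is True
        assert by_name["small"]["missing"] is False

    def test_grid_mismatch_rejected(self):
        rois = self._rois()
        moved = RoiLabelMap(rois.labels, np.eye(4), registry=rois.registry)
        maps = _toy_maps(rois.labels.shape, self.affine)
        with pytest.raises(UndefinedStatisticError):
            evaluate_pair(rois, moved, maps)


class TestSummarize:
    def _record(self, roi="r1", subject=0, sdi=0.9, **kw):
        rec = dict(
            subject=subject,
            roi=roi,
            label=1,
            missing=False,
            v_native_mm3=100.0,
            v_generic_mm3=110.0,
            v_mean_mm3=105.0,
            ve=volume_error(100.0, 110.0),
            sdi=sdi,
            svr_per_mm=0.5,
            stdttp_nat_s=1.5,
            stdttp_gen_s=1.4,
            cbv_nat_au=900.0,
            cbv_gen_au=905.0,
        )
        rec.update(kw)
        return rec

    def test_single_record_summary_is_the_record(self):
        with pytest.raises(UndefinedStatisticError):
            summarize_cohort([])
        # one record per ROI x 3 subjects so pooled stats are defined
        records = [
            self._record(
                subject=s,
                sdi=0.8 + 0.05 * s,
                stdttp_nat_s=1.0 + 0.1 * s,
                cbv_nat_au=900.0 + 10 * s,
                cbv_gen_au=905.0 + 9 * s,
            )
            for s in range(3)
        ]
        summary = summarize_cohort(records)
        assert summary.n_pairs == 3
        row = summary.spatial[summary.spatial["roi"] == "r1"].iloc[0]
        assert row["sdi_median"] == pytest.approx(0.85)
        assert row["sdi_mad"] == pytest.approx(0.05)

    def test_mad_zero_for_identical_spatial_records(self):
        records = [
            self._record(
                subject=s,
                stdttp_nat_s=1.0 + 0.05 * s,
                cbv_nat_au=900.0 + 5 * s,
            )
            for s in range(4)
        ]
        summary = summarize_cohort(records)
        assert summary.spatial.iloc[0]["sdi_mad"] == 0.0
        assert summary.spatial.iloc[0]["svr_per_mm_mad"] == 0.0
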