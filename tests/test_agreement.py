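"""Agreement statistics: t-test, Bland-Altman with proportional bias,
ICC(2,1) against an independent ANOVA oracle, boundary values, the
discrepancy correlation, subtraction SNR, and group comparison tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from imatq import (AM, BFL, VL, BoundaryValueResult, Image2D, PhantomSpec,
                   bland_altman, boundary_value, compare_groups, corner_rois,
                   discrepancy_analysis, icc_2_1, make_boundary_record,
                   make_phantom, quantify_dixon, quantify_t1w,
                   snr_subtraction, threshold_trials, unpaired_t_test)


def anova_icc_oracle(x: np.ndarray) -> float:
    """ICC(2,1) from explicitly looped ANOVA sums of squares."""
    n, k = x.shape
    grand = x.mean()
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_err = sum((x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
                 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestTTest:
    def test_identical_samples(self):
        res = unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)
        assert res.df == 4

    def test_clear_shift_is_significant(self):
        res = unpaired_t_test([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res.p < 0.05

    def test_swap_negates_t_preserves_p(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        a, b = unpaired_t_test(x, y), unpaired_t_test(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_welch_flag_changes_df(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0, 5, 6)
        assert unpaired_t_test(x, y, welch=True).df != 14

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            unpaired_t_test([2.0, 2.0], [2.0, 2.0])


class TestBlandAltman:
    def test_perfect_agreement(self):
        res = bland_altman(t1w=[10.0, 20.0, 30.0], dixon=[10.0, 20.0, 30.0])
        assert res.mean_diff == 0.0
        assert res.loa_low == res.loa_high == 0.0
        assert math.isnan(res.proportional_bias_r)
        assert not res.proportional_bias

    def test_hand_computed_example(self):
        # pairs (T1W, 2PD): differences d = 2PD - T1W = (2, -2, -6)
        res = bland_altman(t1w=[10.0, 20.0, 30.0], dixon=[12.0, 18.0, 24.0])
        assert res.mean_diff == pytest.approx(-2.0)
        assert res.sd_diff == pytest.approx(4.0)
        assert res.loa_low == pytest.approx(-2.0 - 1.96 * 4.0)
        assert res.loa_high == pytest.approx(-2.0 + 1.96 * 4.0)

    def test_linear_pairs_give_unit_proportional_bias(self):
        dixon = np.linspace(5.0, 30.0, 20)
        t1w = 2.0 * dixon   # d = -dixon, mean = 1.5 dixon -> r = -1
        res = bland_altman(t1w=t1w, dixon=dixon)
        assert res.proportional_bias_r == pytest.approx(-1.0)
        assert res.proportional_bias_p < 1e-10
        assert res.proportional_bias

    def test_direction_flag_flips_sign(self):
        t1w, dixon = [10.0, 20.0, 30.0], [12.0, 18.0, 24.0]
        a = bland_altman(t1w=t1w, dixon=dixon)
        b = bland_altman(t1w=t1w, dixon=dixon, direction="t1w-dixon")
        assert a.mean_diff == pytest.approx(-b.mean_diff)

    def test_loa_coverage_on_gaussian_differences(self, rng):
        base = rng.uniform(5, 35, 20000)
        d = rng.normal(1.0, 2.0, base.size)
        res = bland_altman(t1w=base, dixon=base + d)
        inside = np.mean((d >= res.loa_low) & (d <= res.loa_high))
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(t1w=[1.0, 2.0], dixon=[1.0, 2.0])


class TestICC:
    def test_identical_columns_give_exactly_one(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0], [9.0, 9.0]])
        assert icc_2_1(x).value == 1.0

    def test_session_offset_penalized(self):
        base = np.array([1.0, 1.1, 0.9, 1.05])
        x = np.stack([base, base + 10.0], axis=1)
        assert icc_2_1(x).value < 0.1

    def test_toy_matrix_matches_anova_oracle(self):
        x = np.array([[9.0, 2.0], [4.0, 6.0], [8.0, 7.0], [1.0, 3.0]])
        res = icc_2_1(x)
        assert res.value == pytest.approx(anova_icc_oracle(x), abs=1e-12)
        assert res.n_subjects == 4 and res.k_sessions == 2

    def test_matches_pingouin_on_random_matrix(self, rng):
        import pingouin as pg
        x = rng.normal(10, 3, (8, 3))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 3),
            "rater": np.tile(np.arange(3), 8),
            "score": x.ravel(),
        })
        icc_pg = pg.intraclass_corr(df, targets="subject", raters="rater",
                                    ratings="score")
        ref = float(icc_pg.loc[icc_pg["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_2_1(x).value == pytest.approx(ref, abs=1e-9)

    def test_pipeline_repeats_are_reproducible(self):
        """Repeated T1W runs with fresh ROI placements on low-noise
        phantoms agree almost perfectly (between-subject spread dominates)."""
        ratings = []
        for i, p in enumerate([0.05, 0.12, 0.2, 0.28, 0.35]):
            ph = make_phantom(PhantomSpec(
                noise_sd=2.0, bias_amplitude=0.0, partial_volume_width=0.0,
                fat_fractions={VL: p, AM: 0.1, BFL: 0.1}, rng_seed=50 + i))
            sessions = []
            for s in (1, 2):
                thr = threshold_trials(ph.t1w, ph.labels,
                                       np.random.default_rng(100 * i + s))
                q = quantify_t1w(ph.t1w, ph.labels.region(VL), thr.mean)
                sessions.append(q.intramat_percent)
            ratings.append(sessions)
        assert icc_2_1(np.array(ratings)).value > 0.9

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_2_1(np.full((4, 2), 3.0))


class TestBoundaryValue:
    def _image(self, values):
        arr = np.asarray(values, float)
        side = int(np.ceil(np.sqrt(arr.size)))
        data = np.zeros(side * side)
        data[:arr.size] = arr
        mask = np.zeros(side * side, bool)
        mask[:arr.size] = True
        return Image2D(data.reshape(side, side), 1.0), mask.reshape(side, side)

    def test_target_zero_returns_max(self):
        img, mask = self._image([3.0, 9.0, 4.0, 7.0])
        assert boundary_value(img, mask, 0.0) == 9.0

    def test_exact_quantile_on_1_to_100(self):
        img, mask = self._image(np.arange(1.0, 101.0))
        t = boundary_value(img, mask, 20.0)
        assert t == 80.0
        assert np.count_nonzero(img.data[mask] > t) == 20

    def test_non_increasing_in_target(self, rng):
        img, mask = self._image(rng.normal(100, 20, 400))
        targets = np.linspace(0, 100, 21)
        vals = [boundary_value(img, mask, t) for t in targets]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    @given(st.integers(0, 1000))
    def test_round_trip_within_one_pixel_quantum(self, case):
        rng = np.random.default_rng(case)
        n = int(rng.integers(20, 500))
        img, mask = self._image(rng.normal(150, 30, n))
        target = float(rng.uniform(0, 100))
        t = boundary_value(img, mask, target)
        achieved = quantify_t1w(img, mask, t).intramat_percent
        assert target - 100.0 / n - 1e-9 <= achieved <= target + 1e-9

    def test_empty_mask_rejected(self):
        img = Image2D(np.zeros((4, 4)), 1.0)
        with pytest.raises(ValueError):
            boundary_value(img, np.zeros((4, 4), bool), 10.0)


class TestDiscrepancy:
    def _records(self, di, dm):
        return [BoundaryValueResult(i, "m", 0.0, 0.0, x, y)
                for i, (x, y) in enumerate(zip(di, dm))]

    def test_constructed_negative_correlation(self, rng):
        di = np.linspace(2, 40, 15)
        dm = -0.3 * di + rng.normal(0, 0.5, 15)
        r, p = discrepancy_analysis(self._records(di, dm))
        assert r < -0.8 and p < 0.01

    def test_negating_intensity_negates_r(self, rng):
        di = rng.uniform(0, 20, 10)
        dm = rng.normal(0, 3, 10)
        r1, _ = discrepancy_analysis(self._records(di, dm))
        r2, _ = discrepancy_analysis(self._records(-di, dm))
        assert r1 == pytest.approx(-r2)

    def test_constant_intensity_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            discrepancy_analysis(self._records([5.0] * 5, [1, 2, 3, 4, 5]))

    def test_record_sign_convention(self, clean_phantom, rng):
        """Lowering the threshold below the boundary inflates the T1W
        percent: delta_intensity > 0 pairs with delta_intramat < 0."""
        ph = clean_phantom
        mask = ph.labels.region(BFL)
        dq = quantify_dixon(ph.water, ph.fat, mask)
        bv = boundary_value(ph.t1w, mask, dq.intramat_percent)
        low_threshold = bv - 60.0
        tq = quantify_t1w(ph.t1w, mask, low_threshold)
        rec = make_boundary_record("s", "BF-L", ph.t1w, mask, low_threshold,
                                   tq.intramat_percent, dq.intramat_percent)
        assert rec.delta_intensity > 0
        assert rec.delta_intramat < 0


class TestSNR:
    def test_identical_images_give_sentinel(self):
        img = Image2D(np.random.default_rng(0).normal(100, 5, (64, 64)), 1.0)
        res = snr_subtraction(img, img, corner_rois(img.shape, 16))
        assert all(math.isinf(r.snr) for r in res)

    def test_converges_to_mu_over_sigma(self, rng):
        mu, sigma = 120.0, 6.0
        a = Image2D(rng.normal(mu, sigma, (220, 220)), 1.0)
        b = Image2D(rng.normal(mu, sigma, (220, 220)), 1.0)
        res = snr_subtraction(a, b, corner_rois((220, 220), 100))
        for r in res:
            assert r.snr == pytest.approx(mu / sigma, rel=0.05)

    def test_scale_invariance_of_snr(self, rng):
        a = Image2D(rng.normal(80, 4, (64, 64)), 1.0)
        b = Image2D(rng.normal(80, 4, (64, 64)), 1.0)
        rois = corner_rois((64, 64), 16)
        r1 = snr_subtraction(a, b, rois)
        r2 = snr_subtraction(Image2D(a.data * 5, 1.0),
                             Image2D(b.data * 5, 1.0), rois)
        for x, y in zip(r1, r2):
            assert y.signal_mean == pytest.approx(5 * x.signal_mean)
            assert y.snr == pytest.approx(x.snr)

    def test_roi_outside_bounds_rejected(self):
        img = Image2D(np.zeros((32, 32)), 1.0)
        with pytest.raises(ValueError, match="bounds"):
            snr_subtraction(img, img, [(30, 30, 16)])


class TestCompareGroups:
    def _frame(self, young, old):
        rows = []
        for g, vals in (("younger", young), ("older", old)):
            for m in ("VL", "AM", "BF-L"):
                for meth in ("T1W", "2PD"):
                    for i, v in enumerate(vals):
                        rows.append({"group": g, "muscle": m, "method": meth,
                                     "subject": f"{g}{i}",
                                     "intramat_percent": v})
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        vals = [8.0, 10.0, 12.0, 14.0]
        table = compare_groups(self._frame(vals, vals))
        assert len(table) == 6  # muscles x methods
        assert np.allclose(table["p"], 1.0)
        assert not table["significant"].any()

    def test_doubled_fat_cohort_separates(self):
        """Phantom cohorts with doubled infiltration in the older group
        differ significantly in the expected direction for every muscle."""
        rng = np.random.default_rng(8)
        rows = []
        for g, lo, hi in (("younger", 0.06, 0.10), ("older", 0.12, 0.20)):
            for i in range(10):
                fr = {m: float(rng.uniform(lo, hi)) for m in (VL, AM, BFL)}
                ph = make_phantom(PhantomSpec(
                    partial_volume_width=0.0, bias_amplitude=0.0,
                    fat_fractions=fr, rng_seed=int(rng.integers(2**31))))
                for m, name in ((VL, "VL"), (AM, "AM"), (BFL, "BF-L")):
                    q = quantify_dixon(ph.water, ph.fat, ph.labels.region(m))
                    rows.append({"group": g, "muscle": name, "method": "2PD",
                                 "subject": f"{g}{i}",
                                 "intramat_percent": q.intramat_percent})
        table = compare_groups(pd.DataFrame(rows))
        assert table["significant"].all()
        assert (table["older_mean"] > table["younger_mean"]).all()
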