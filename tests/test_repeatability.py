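"""Agreement statistics: Bland-Altman, ICC(3,1), CV, and report assembly."""

import numpy as np
import pytest

from octaquant.reference import BLAND_ALTMAN_TABLE, CONSISTENT_ROWS
from octaquant.repeatability import (
    PairedMeasurements,
    activity_correlation,
    bland_altman,
    coefficient_of_variation,
    cr_over_mean,
    icc_3_1,
    repeatability_report,
)
from octaquant.synthetic import simulate_paired_measurements


def pairs_from(m1, m2):
    m1, m2 = np.asarray(m1, float), np.asarray(m2, float)
    return PairedMeasurements([f"S{i}" for i in range(m1.size)], m1, m2)


def anova_icc_oracle(m1, m2):
    """From-scratch two-way ANOVA ICC(3,1), computed cell by cell."""
    data = [[a, b] for a, b in zip(m1, m2)]
    n, k = len(data), 2
    grand = sum(sum(row) for row in data) / (n * k)
    subj_means = [sum(row) / k for row in data]
    rater_means = [sum(row[j] for row in data) / n for j in range(k)]
    ss_total = sum((x - grand) ** 2 for row in data for x in row)
    ss_subj = k * sum((m - grand) ** 2 for m in subj_means)
    ss_rater = n * sum((m - grand) ** 2 for m in rater_means)
    ss_err = ss_total - ss_subj - ss_rater
    bms = ss_subj / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    return (bms - ems) / (bms + (k - 1) * ems)


class TestBlandAltman:
    def test_identical_pairs(self):
        p = pairs_from([1, 2, 3], [1, 2, 3])
        r = bland_altman(p)
        assert r.bias == 0 and r.cr == 0
        assert r.degenerate_p and r.p_value == 1.0

    def test_hand_computed_sample_sd(self):
        # differences -1, +1, -1, +1: sample SD = sqrt(4/3)
        p = pairs_from([0, 2, 0, 2], [1, 1, 1, 1])
        r = bland_altman(p)
        assert r.bias == 0
        assert r.sd_diff == pytest.approx(np.sqrt(4 / 3))
        assert r.cr == pytest.approx(1.96 * np.sqrt(4 / 3))
        assert r.cr == pytest.approx(2.263, abs=5e-4)

    def test_loa_identity(self):
        rng = np.random.default_rng(0)
        p = pairs_from(rng.normal(5, 1, 30), rng.normal(5, 1, 30))
        r = bland_altman(p)
        assert r.loa_upper - r.loa_lower == pytest.approx(2 * r.cr, rel=1e-12)
        assert r.loa_lower == pytest.approx(r.bias - r.cr)

    def test_published_dcp_vessel_row_consistency(self):
        # printed upper limit of agreement minus printed bias equals printed CR
        row = BLAND_ALTMAN_TABLE["dcp_vd"]
        assert row["loa_upper"] - row["bias"] == pytest.approx(row["cr"], abs=5e-4)

    def test_n_below_three_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(pairs_from([1, 2], [1, 2]))


class TestCrOverMean:
    @pytest.mark.parametrize("key", CONSISTENT_ROWS)
    def test_published_ratios_reproduced(self, key):
        row = BLAND_ALTMAN_TABLE[key]
        assert cr_over_mean(row["cr"], row["mean"]) == pytest.approx(
            row["cr_over_mean"], abs=5e-4)

    def test_zero_cr(self):
        assert cr_over_mean(0.0, 3.0) == 0.0

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            cr_over_mean(1.0, 0.0)


class TestICC:
    def test_perfect_agreement(self):
        r = icc_3_1(pairs_from([1, 2, 3, 4], [1, 2, 3, 4]))
        assert r.icc == pytest.approx(1.0)

    def test_constant_offset_ignored_by_consistency_model(self):
        r = icc_3_1(pairs_from([1, 2, 3, 4], [1.5, 2.5, 3.5, 4.5]))
        assert r.icc == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 25))
        m1 = rng.normal(10, 2, n)
        m2 = m1 + rng.normal(0, 1, n)
        r = icc_3_1(pairs_from(m1, m2))
        assert r.icc == pytest.approx(anova_icc_oracle(m1, m2), rel=1e-9)
        assert r.ci_lower <= r.icc <= r.ci_upper

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(42)
        m1 = rng.normal(10, 2, 15)
        m2 = m1 + rng.normal(0, 0.8, 15)
        r = icc_3_1(pairs_from(m1, m2))
        df = pd.DataFrame({
            "t": np.repeat(np.arange(15), 2),
            "r": np.tile([1, 2], 15),
            "y": np.column_stack([m1, m2]).ravel(),
        })
        row = pg.intraclass_corr(df, targets="t", raters="r", ratings="y").iloc[2]
        assert r.icc == pytest.approx(float(row["ICC"]), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_3_1(pairs_from([1, 1, 1], [1, 1, 1]))


class TestCV:
    def test_identical_pairs_zero(self):
        assert coefficient_of_variation(pairs_from([1, 2, 3], [1, 2, 3])).cv_percent == 0

    def test_hand_computed_duplicate_formula(self):
        # every subject measured 9 then 11: d = 2, within-person variance
        # d²/2 = 2, within-SD = sqrt(2), grand mean 10 -> CV = 14.14%
        r = coefficient_of_variation(pairs_from([9] * 5, [11] * 5))
        assert r.within_sd == pytest.approx(np.sqrt(2.0))
        assert r.cv_percent == pytest.approx(100 * np.sqrt(2.0) / 10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        m1, m2 = rng.uniform(5, 10, 20), rng.uniform(5, 10, 20)
        a = coefficient_of_variation(pairs_from(m1, m2)).cv_percent
        b = coefficient_of_variation(pairs_from(2 * m1, 2 * m2)).cv_percent
        assert a == pytest.approx(b, rel=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation(pairs_from([-1, -2, -3], [-1, -2, -3]))


class TestActivityCorrelation:
    def test_perfect_correlation(self):
        d = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        r, p = activity_correlation(d, d)
        assert r == pytest.approx(1.0)

    def test_constant_activity_rejected(self):
        with pytest.raises(ValueError):
            activity_correlation(np.array([1.0, 2.0, 3.0]), np.zeros(3))

    def test_zero_covariance(self):
        d = np.array([1.0, 2.0, 3.0])
        a = np.array([1.0, -1.0, 1.0])
        r, _ = activity_correlation(d, a)
        assert r == pytest.approx(0.0, abs=1e-12)


class TestReport:
    def test_empty_report(self):
        rep = repeatability_report({})
        assert rep.to_frame().empty

    def test_simulation_recovery_icc(self):
        pairs, true_icc = simulate_paired_measurements(200, 10, 1.0, 0.5, seed=5)
        assert true_icc == pytest.approx(0.8)
        rep = repeatability_report({"idx": pairs})
        est = rep.indices["idx"]["icc"].icc
        assert est == pytest.approx(0.8, abs=0.05)

    def test_duplicate_scan_cohort_all_zero(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 3, 20)
        pairs = pairs_from(vals, vals)
        rep = repeatability_report({"idx": pairs})
        assert rep.indices["idx"]["bland_altman"].cr == 0.0
        assert rep.indices["idx"]["cv"].cv_percent == 0.0

    def test_manual_faz_jitter_gives_nonzero_cr(self):
        """Simulated operator tracings of one FAZ vary; automated repeats do not."""
        from octaquant.synthetic import jittered_faz_polygon
        from octaquant.vessel_metrics import FazDelineation, faz_area

        mm_per_px = 3.0 / 256
        areas = {1: [], 2: []}
        for i in range(10):
            for attempt in (1, 2):
                poly = jittered_faz_polygon(0.41, (128, 128), mm_per_px,
                                            seed=100 * attempt + i)
                d = FazDelineation("manual_polygon", polygon=poly)
                areas[attempt].append(
                    faz_area(np.zeros((256, 256), bool), d, mm_per_px))
        pairs = pairs_from(areas[1], areas[2])
        r = bland_altman(pairs)
        assert r.cr > 0
        # tracings stay close to the true area on average
        assert np.mean(areas[1] + areas[2]) == pytest.approx(0.41, rel=0.05)

    def test_cr_recovery(self):
        rng = np.random.default_rng(3)
        sigma = 0.3
        true_vals = rng.normal(10, 1, 500)
        m1 = true_vals + rng.normal(0, sigma / np.sqrt(2), 500)
        m2 = true_vals + rng.normal(0, sigma / np.sqrt(2), 500)
        r = bland_altman(pairs_from(m1, m2))
        assert r.cr == pytest.approx(1.96 * sigma, rel=0.05)
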