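import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from quantafm.afm_io import PipelineConfig, QuantRecord
from quantafm.quantify import (
    compare_classes,
    correct_arm_length,
    dunn_posthoc,
    filter_valid,
    median_ci,
    nm_per_bp,
    normalize_angle,
    sa_ratio,
    summarize_class,
    wrapping_length,
)


class TestCalibration:
    def test_free_dna_calibration(self):
        # mean contour of the 464 bp fragment reproduces canonical B-DNA rise
        assert round(nm_per_bp(158.2, 464), 2) == 0.34

    def test_longer_fragment_same_rise(self):
        assert round(nm_per_bp(203.66, 599), 2) == 0.34

    def test_identity(self):
        assert nm_per_bp(1.0, 1) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            nm_per_bp(0.0, 464)


class TestArmCorrection:
    @pytest.mark.parametrize("arm,radius,expected", [
        (42.4, 10.7, 47.6),   # tip-broadened radius ~2x the known 5.5 nm
        (44.9, 10.6, 50.0),
        (10.0, 5.5, 10.0),    # zero correction at the known radius
    ])
    def test_correction_arithmetic(self, arm, radius, expected):
        assert correct_arm_length(arm, radius) == pytest.approx(expected)

    def test_small_radius_gives_negative_correction(self):
        assert correct_arm_length(10.0, 4.5) == pytest.approx(9.0)


class TestWrappingLength:
    @pytest.mark.parametrize("s,l,expected_bp", [
        (47.6, 55.1, 163),  # wt +H1
        (52.4, 64.7, 121),  # mut
    ])
    def test_reported_class_means(self, s, l, expected_bp):
        assert round(wrapping_length(s, l, 158.2, 0.34)) == expected_bp

    def test_arms_equal_fragment_gives_zero(self):
        assert wrapping_length(80.0, 78.2, 158.2, 0.34) == pytest.approx(0.0)

    def test_full_chain_from_class_means(self):
        """Arm correction + wrapping conversion reproduces reported means."""
        table = {  # (radius, short, long) -> published mean l_w
            (10.7, 42.4, 49.9): 163,
            (10.6, 47.3, 59.6): 121,
            (10.2, 43.8, 56.3): 143,
        }
        for (r, s, l), lw in table.items():
            sc, lc = correct_arm_length(s, r), correct_arm_length(l, r)
            assert round(wrapping_length(sc, lc, 158.2, 0.34)) == lw
        # wt row: mean-of-means differs from per-object averaging by <= 1 bp
        sc, lc = correct_arm_length(44.9, 10.6), correct_arm_length(53.6, 10.6)
        assert abs(wrapping_length(sc, lc, 158.2, 0.34) - 145) <= 1.5


class TestSaRatio:
    def test_equal_arms_central(self):
        assert sa_ratio(10.0, 10.0) == 0.5

    @pytest.mark.parametrize("s,l,expected", [
        (153, 164, 0.483),  # 464 bp design overhangs
        (183, 269, 0.405),  # 599 bp design overhangs
    ])
    def test_design_ratios(self, s, l, expected):
        assert round(sa_ratio(s, l), 3) == expected

    def test_swaps_misordered_arms(self):
        assert sa_ratio(164, 153) == sa_ratio(153, 164)

    @settings(derandomize=True, max_examples=50)
    @given(s=st.floats(1.0, 100.0), l=st.floats(1.0, 100.0),
           c=st.floats(0.01, 100.0))
    def test_scale_invariance(self, s, l, c):
        assert sa_ratio(c * s, c * l) == pytest.approx(sa_ratio(s, l), rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(s=st.floats(0.1, 500.0), l=st.floats(0.1, 500.0))
    def test_range_invariant(self, s, l):
        assert 0.0 < sa_ratio(s, l) <= 0.5


class TestNormalizeAngle:
    @pytest.mark.parametrize("theta,flag,expected", [
        (70.0, True, 110.0),
        (70.0, False, 70.0),
        (90.0, True, 90.0),
    ])
    def test_inversion(self, theta, flag, expected):
        assert normalize_angle(theta, flag) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            normalize_angle(200.0, False)


def _nuc_record(short, long_, flags=(), sa=None, **kw):
    sa = sa if sa is not None else short / (short + long_)
    return QuantRecord("img", 1, "nucleosome", short_arm_nm=short,
                       long_arm_nm=long_, short_arm_corr_nm=short,
                       long_arm_corr_nm=long_, sa_ratio_c=sa,
                       qc_flags=tuple(flags), **kw)


class TestFilterValid:
    def test_arm_sum_window(self, cfg):
        keep = _nuc_record(45.0, 55.0)          # sum 100, inside [65, 155]
        drop = _nuc_record(75.0, 85.0)          # sum 160, outside
        out = filter_valid([keep, drop], cfg)
        assert out == [keep]

    def test_abnormal_flags_dropped(self, cfg):
        bad = _nuc_record(45.0, 55.0, flags=("branched",))
        assert filter_valid([bad], cfg) == []

    def test_positioning_cut_only_for_positioning(self, cfg):
        rec = _nuc_record(20.0, 80.0)  # sa 0.2 < 0.3
        assert filter_valid([rec], cfg) == [rec]
        assert filter_valid([rec], cfg, for_positioning=True) == []

    def test_clean_record_kept_everywhere(self, cfg):
        rec = _nuc_record(45.0, 55.0)
        assert filter_valid([rec], cfg) == [rec]
        assert filter_valid([rec], cfg, for_positioning=True) == [rec]


class TestSummarizeClass:
    def _records(self, values):
        return [QuantRecord("i", k, "nucleosome", theta_deg=v,
                            short_arm_nm=40.0, long_arm_nm=50.0,
                            lw_bp=150.0, sa_ratio_c=0.45)
                for k, v in enumerate(values)]

    def test_basic_moments(self):
        s = summarize_class(self._records([1.0, 2.0, 3.0]), "demo")
        row = s.stats.loc["theta_deg"]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)   # n-1 denominator
        assert row["median"] == pytest.approx(2.0)

    def test_sampling_distribution_of_mean(self):
        rng = np.random.default_rng(444)
        values = rng.normal(74.2, 39.6, 444)
        values = np.clip(values, 0, 180)
        s = summarize_class(self._records(values), "wt")
        tol = 3 * 39.6 / np.sqrt(444)
        assert abs(s.stats.loc["theta_deg", "mean"] - 74.2) < tol + 1.0

    def test_histograms_are_probabilities(self):
        rng = np.random.default_rng(7)
        s = summarize_class(self._records(rng.uniform(0, 180, 200)), "h")
        for key, (probs, edges) in s.histograms.items():
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_theta_180_lands_in_last_bin(self):
        s = summarize_class(self._records([180.0] * 5), "edge")
        probs, edges = s.histograms["theta_deg"]
        assert probs[-1] == pytest.approx(1.0)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            summarize_class(self._records([1.0]), "x")

    def test_median_ci_covers_median(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 300)
        lo, hi = median_ci(x)
        assert lo <= np.median(x) <= hi
        # CI shrinks with n
        lo2, hi2 = median_ci(rng.normal(0, 1, 3000))
        assert (hi2 - lo2) < (hi - lo)


def dunn_oracle(groups):
    """Independent recomputation of Dunn z statistics from definitions."""
    all_vals = np.concatenate(groups)
    n = len(all_vals)
    order = np.argsort(all_vals, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    sorted_vals = all_vals[order]
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    ties = {}
    for v in sorted_vals:
        ties[v] = ties.get(v, 0) + 1
    tie_sum = sum(t**3 - t for t in ties.values())
    var = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    means = [ranks[bounds[i]: bounds[i + 1]].mean() for i in range(len(groups))]
    k = len(groups)
    m = k * (k - 1) / 2
    p = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        z = (means[i] - means[j]) / np.sqrt(var * (1 / sizes[i] + 1 / sizes[j]))
        p[i, j] = p[j, i] = min(2 * (1 - stats.norm.cdf(abs(z))) * m, 1.0)
    return p


class TestCompareClasses:
    def test_identical_groups_not_significant(self):
        g = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.5, 2.2, 8.1])
        report = compare_classes([g, g.copy()])
        assert report.p_value > 0.99

    def test_large_shift_detected_nonparametric(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        # force the nonparametric branch with a heavy-tailed contamination
        a[:10] += rng.standard_cauchy(10) * 10
        report = compare_classes([a, b])
        assert report.branch == "mann-whitney"
        assert report.p_value < 0.05

    def test_normal_groups_use_t_test(self):
        rng = np.random.default_rng(4)
        report = compare_classes([rng.normal(0, 1, 50), rng.normal(0, 1, 50)])
        assert report.branch == "t-test"

    def test_four_groups_nonnormal_use_kruskal_dunn(self):
        rng = np.random.default_rng(5)
        groups = [np.exp(rng.normal(0, 1, 60)) for _ in range(4)]
        report = compare_classes(groups)
        assert report.branch == "kruskal-wallis+dunn"
        assert report.posthoc.shape == (4, 4)

    def test_constant_group_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compare_classes([np.ones(5), np.array([1.0, 2.0, 3.0, 4.0, 5.0])])

    def test_dunn_matches_independent_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            groups = [rng.normal(rng.uniform(-1, 1), 1, rng.integers(8, 30))
                      for _ in range(rng.integers(3, 5))]
            np.testing.assert_allclose(dunn_posthoc(groups), dunn_oracle(groups),
                                       atol=1e-6)

    def test_dunn_handles_ties(self):
        rng = np.random.default_rng(11)
        groups = [rng.integers(0, 5, 25).astype(float) for _ in range(3)]
        np.testing.assert_allclose(dunn_posthoc(groups), dunn_oracle(groups),
                                   atol=1e-6)

    def test_kruskal_wallis_type_i_error_calibrated(self):
        """Null rejection rate of the KW branch stays near the nominal 5%."""
        rng = np.random.default_rng(2718)
        rejections = 0
        reps = 200
        for _ in range(reps):
            groups = [np.exp(rng.normal(0, 1, 25)) for _ in range(4)]
            stat, p = stats.kruskal(*groups)
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) <= 0.02


class TestReconstructionIdentity:
    def test_lw_recomputable_from_stored_fields(self, cfg):
        from quantafm.quantify import quantify_record

        rec = QuantRecord("i", 1, "nucleosome", radius_nm=10.7, theta_deg=80.0,
                          short_arm_nm=42.4, long_arm_nm=49.9)
        rec = quantify_record(rec, cfg)
        lw = wrapping_length(rec.short_arm_corr_nm, rec.long_arm_corr_nm,
                             cfg.free_dna_mean_nm, cfg.nm_per_bp)
        assert rec.lw_bp == lw
        assert rec.sa_ratio_c == sa_ratio(rec.short_arm_corr_nm,
                                          rec.long_arm_corr_nm)
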