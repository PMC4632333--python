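import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as spstats

from tremorflux import (
    CohortSubject,
    ConfusionCounts,
    DelayPair,
    LengthError,
    ParameterError,
    classify,
    confusion_metrics,
    delay_embed,
    delay_sweep,
    ellipse_area,
    fluctuation_ratio,
    generate_cohort,
    CohortSpec,
    separation_distance,
    subject_features,
    temporal_fluctuation,
    two_sample_t,
)

from .conftest import make_recording, sine

CHI2_95_2DOF = spstats.chi2.ppf(0.95, df=2)


class TestDelayPair:
    def test_defaults(self):
        assert (DelayPair().d1, DelayPair().d2) == (5, 20)

    @pytest.mark.parametrize("d1,d2", [(0, 5), (5, 5), (20, 5), (-1, 3)])
    def test_invalid_orderings_rejected(self, d1, d2):
        with pytest.raises(ParameterError):
            DelayPair(d1, d2)


class TestDelayEmbed:
    def test_constant_signal_gives_origin_points(self):
        cloud = delay_embed(np.full(50, 7.0), DelayPair(3, 10))
        assert len(cloud) == 40
        np.testing.assert_array_equal(cloud.points, np.zeros((40, 2)))

    def test_linear_ramp(self):
        cloud = delay_embed(np.arange(6.0), DelayPair(1, 2))
        assert len(cloud) == 4
        np.testing.assert_array_equal(cloud.points, np.tile([1.0, 2.0], (4, 1)))

    def test_point_count_at_default_lags(self):
        cloud = delay_embed(np.random.default_rng(0).standard_normal(1250))
        assert len(cloud) == 1230

    def test_point_formula(self):
        s = np.array([0.0, 1.0, 4.0, 9.0, 16.0, 25.0])
        cloud = delay_embed(s, DelayPair(1, 3))
        np.testing.assert_array_equal(cloud.points[0], [s[1] - s[0], s[3] - s[0]])
        np.testing.assert_array_equal(cloud.points[2], [s[3] - s[2], s[5] - s[2]])

    def test_signal_too_short(self):
        with pytest.raises(LengthError):
            delay_embed(np.zeros(20), DelayPair(5, 20))

    @given(
        n=st.integers(2, 500),
        d1=st.integers(1, 100),
        gap=st.integers(1, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_length_contract(self, n, d1, gap):
        d2 = d1 + gap
        signal = np.linspace(0, 1, n)
        if n <= d2:
            with pytest.raises(LengthError):
                delay_embed(signal, DelayPair(d1, d2))
        else:
            assert len(delay_embed(signal, DelayPair(d1, d2))) == n - d2


class TestEllipseArea:
    def test_identical_points_degenerate(self):
        summary = ellipse_area(np.ones((10, 2)))
        assert summary.area == 0.0
        assert summary.degenerate

    def test_gaussian_cloud_matches_closed_form(self):
        rng = np.random.default_rng(11)
        pts = rng.standard_normal((100_000, 2))
        summary = ellipse_area(pts)
        assert summary.area == pytest.approx(math.pi * CHI2_95_2DOF, rel=0.02)

    def test_gaussian_coverage_fraction(self):
        rng = np.random.default_rng(12)
        pts = rng.standard_normal((100_000, 2))
        summary = ellipse_area(pts)
        centered = pts - summary.center
        inv = np.linalg.inv(summary.covariance)
        mahal2 = np.einsum("ij,jk,ik->i", centered, inv, centered)
        inside = np.mean(mahal2 <= CHI2_95_2DOF)
        assert inside == pytest.approx(0.95, abs=0.01)

    @pytest.mark.parametrize("c", [0.5, 3.0, 100.0])
    def test_quadratic_scaling(self, c):
        rng = np.random.default_rng(13)
        pts = rng.standard_normal((500, 2)) @ np.array([[2.0, 0.3], [0.0, 0.7]])
        base = ellipse_area(pts).area
        assert ellipse_area(c * pts).area == pytest.approx(c**2 * base, rel=1e-9)

    def test_closed_form_identity(self):
        rng = np.random.default_rng(14)
        pts = rng.standard_normal((400, 2))
        summary = ellipse_area(pts, coverage=0.8)
        q = spstats.chi2.ppf(0.8, df=2)
        expected = math.pi * q * math.sqrt(np.linalg.det(np.cov(pts, rowvar=False)))
        assert summary.area == pytest.approx(expected, rel=1e-12)

    def test_too_few_points(self):
        with pytest.raises(LengthError):
            ellipse_area(np.zeros((2, 2)))

    def test_bad_coverage(self):
        with pytest.raises(ParameterError):
            ellipse_area(np.zeros((10, 2)), coverage=1.0)


class TestTemporalFluctuation:
    def test_zero_recording_gives_zero(self):
        assert temporal_fluctuation(make_recording(np.zeros(1250))) == 0.0

    def test_quadratic_amplitude_scaling(self):
        rec = make_recording(sine(5.0) + 0.01 * np.random.default_rng(15).standard_normal(1250))
        doubled = rec.with_samples(2 * rec.samples)
        tf1 = temporal_fluctuation(rec)
        tf2 = temporal_fluctuation(doubled)
        assert tf1 > 0
        assert tf2 == pytest.approx(4 * tf1, rel=1e-9)

    def test_amplitude_ratio_10_gives_tf_ratio_100(self):
        high = make_recording(sine(5.0, amplitude=10.0))
        low = make_recording(sine(5.0, amplitude=1.0))
        ratio = temporal_fluctuation(high) / temporal_fluctuation(low)
        assert ratio == pytest.approx(100.0, rel=1e-6)

    def test_deterministic(self):
        rec = make_recording(sine(5.0) + 0.01 * np.random.default_rng(16).standard_normal(1250))
        assert temporal_fluctuation(rec) == temporal_fluctuation(rec)

    def test_nonnegative(self):
        rng = np.random.default_rng(17)
        rec = make_recording(rng.standard_normal(1250))
        assert temporal_fluctuation(rec) >= 0


class TestFluctuationRatio:
    def test_one_percent_is_the_threshold(self):
        assert fluctuation_ratio(0.01 * 7.3, 7.3) == pytest.approx(0.0, abs=1e-12)

    def test_equal_tf_gives_two(self):
        assert fluctuation_ratio(5.0, 5.0) == pytest.approx(2.0)

    def test_tenth_gives_one(self):
        assert fluctuation_ratio(0.5, 5.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("base", [2.0, math.e, 10.0])
    def test_threshold_invariant_to_log_base(self, base):
        assert fluctuation_ratio(0.01 * 3.0, 3.0, base=base) == pytest.approx(0.0, abs=1e-12)
        assert fluctuation_ratio(0.02 * 3.0, 3.0, base=base) > 0
        assert fluctuation_ratio(0.005 * 3.0, 3.0, base=base) < 0

    def test_rescaling_invariance(self):
        rf1 = fluctuation_ratio(0.37, 4.2)
        rf2 = fluctuation_ratio(0.37 * 1e6, 4.2 * 1e6)
        assert rf1 == pytest.approx(rf2, rel=1e-12)

    @pytest.mark.parametrize("rest,kin", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_nonpositive_tf_rejected(self, rest, kin):
        with pytest.raises(ParameterError):
            fluctuation_ratio(rest, kin)


class TestClassify:
    @pytest.mark.parametrize("rf", [0.7298, 0.0679, 0.2788])
    def test_positive_ratios_are_pd(self, rf):
        assert classify(rf) == "PD"

    @pytest.mark.parametrize("rf", [-3.1430, -1.8253])
    def test_negative_ratios_are_et(self, rf):
        assert classify(rf) == "ET"

    def test_zero_is_indeterminate(self):
        assert classify(0.0) == "indeterminate"

    def test_non_finite_rejected(self):
        with pytest.raises(ParameterError):
            classify(float("nan"))


class TestConfusionMetrics:
    def test_perfect_discrimination(self):
        metrics = confusion_metrics(ConfusionCounts(tp=3, tn=2, fp=0, fn=0))
        assert (metrics.sensitivity, metrics.specificity, metrics.accuracy) == (100, 100, 100)

    def test_all_wrong(self):
        metrics = confusion_metrics(ConfusionCounts(tp=0, tn=0, fp=1, fn=1))
        assert (metrics.sensitivity, metrics.specificity, metrics.accuracy) == (0, 0, 0)

    def test_even_split(self):
        metrics = confusion_metrics(ConfusionCounts(tp=1, tn=1, fp=1, fn=1))
        assert (metrics.sensitivity, metrics.specificity, metrics.accuracy) == (50, 50, 50)

    def test_undefined_metrics_are_none(self):
        metrics = confusion_metrics(ConfusionCounts())
        assert metrics.sensitivity is None
        assert metrics.specificity is None
        assert metrics.accuracy is None

    def test_tn_only_accuracy_variant(self):
        counts = ConfusionCounts(tp=3, tn=2, fp=0, fn=0)
        assert confusion_metrics(counts, tn_only_accuracy=True).accuracy == pytest.approx(40.0)

    def test_from_labels_counts_indeterminate_as_error(self):
        counts = ConfusionCounts.from_labels(
            ["PD", "PD", "ET", "ET"], ["PD", "indeterminate", "ET", "indeterminate"]
        )
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (1, 1, 1, 1)

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            ConfusionCounts(tp=-1)


class TestTwoSampleT:
    def test_identical_groups_give_p_one(self):
        assert two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_large_shift_gives_tiny_p(self):
        assert two_sample_t([1.0, 2.0, 3.0], [101.0, 102.0, 103.0]) < 1e-6

    def test_matches_hand_computed_pooled_t(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 9.0])
        # closed-form pooled-variance Student t, computed independently
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        t_stat = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        df = len(a) + len(b) - 2
        expected = 2 * spstats.t.sf(abs(t_stat), df)
        assert two_sample_t(a, b) == pytest.approx(expected, abs=1e-10)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(18)
        ps = [
            two_sample_t(rng.standard_normal(20), rng.standard_normal(20))
            for _ in range(1000)
        ]
        ks = spstats.kstest(ps, "uniform")
        assert ks.pvalue > 0.001

    def test_degenerate_variance_gives_nan(self):
        assert math.isnan(two_sample_t([1.0, 1.0], [1.0, 1.0]))

    def test_tiny_groups_rejected(self):
        with pytest.raises(ParameterError):
            two_sample_t([1.0], [1.0, 2.0])


class TestSeparationDistance:
    def test_separated_groups(self):
        assert separation_distance([1.0, 2.0], [-1.0, -2.0]) == 2.0

    def test_touching_groups(self):
        assert separation_distance([0.5], [0.5]) == 0.0

    def test_overlap_is_negative(self):
        assert separation_distance([-1.0, 3.0], [0.0]) == -1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            separation_distance([], [1.0])


class TestSubjectFeatures:
    def test_missing_kinetic_task_is_indeterminate(self):
        rec = make_recording(sine(5.0), task="resting")
        feats = subject_features("s1", {"resting": rec})
        assert feats.rf is None
        assert feats.predicted_label == "indeterminate"

    def test_zero_tf_is_indeterminate(self):
        feats = subject_features(
            "s1",
            {
                "resting": make_recording(np.zeros(1250), task="resting"),
                "kinetic": make_recording(sine(5.0), task="kinetic"),
            },
        )
        assert feats.rf is None
        assert feats.predicted_label == "indeterminate"

    def test_rest_dominant_subject_is_pd(self):
        feats = subject_features(
            "s1",
            {
                "resting": make_recording(sine(4.5, amplitude=1.0), task="resting"),
                "kinetic": make_recording(sine(6.5, amplitude=0.1), task="kinetic"),
            },
        )
        assert feats.rf is not None and feats.rf > 0
        assert feats.predicted_label == "PD"


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(CohortSpec(n_pd=3, n_et=3, seed=9))


class TestDelaySweep:
    def test_separated_cohort_has_positive_margin(self, small_cohort):
        result = delay_sweep(small_cohort, lag_grid=[(5, 20)], axes=["x"])
        row = result.rows[0]
        assert row.separation > 0
        assert len(row.rf_pd) == 3 and len(row.rf_et) == 3

    def test_grid_size(self, small_cohort):
        result = delay_sweep(small_cohort)
        assert len(result.rows) == 8 * 3
        combos = {(r.d1, r.d2, r.axis) for r in result.rows}
        assert len(combos) == 24

    def test_single_subject_groups_flag_p_undefined(self):
        cohort = generate_cohort(CohortSpec(n_pd=1, n_et=1, seed=10))
        result = delay_sweep(cohort, lag_grid=[(5, 20)], axes=["x"])
        row = result.rows[0]
        assert math.isnan(row.p_value)
        assert math.isfinite(row.separation)

    def test_identical_groups_overlap(self):
        cohort = generate_cohort(CohortSpec(n_pd=3, n_et=0, seed=11))
        mirrored = [
            CohortSubject(subject_id=f"et{i}", label="ET", recordings=s.recordings)
            for i, s in enumerate(cohort)
        ]
        result = delay_sweep(list(cohort) + mirrored, lag_grid=[(5, 20)], axes=["x"])
        row = result.rows[0]
        assert row.separation <= 0
        assert row.p_value == pytest.approx(1.0)
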