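"""Delay-difference embedding, confidence-ellipse area, and the
resting/kinetic fluctuation ratio classifier.

The core statistic chain:

1. ``delay_embed`` maps a filtered 1-D signal s to the 2-D cloud
   ``(s[n + d1] - s[n], s[n + d2] - s[n])`` for two sample lags d1 < d2.
2. ``ellipse_area`` summarizes the cloud by its Gaussian 95% confidence
   ellipse; the area (pi * chi2_quantile * sqrt(det covariance)) is the
   temporal fluctuation TF, in squared signal units.
3. ``fluctuation_ratio`` compares tasks: RF = log10(100 * TF_rest / TF_kin).
   RF > 0 -> PD-like (rest-dominant tremor), RF < 0 -> ET-like.

Cohort-level helpers sweep lag pairs and axes, run pooled-variance
two-sample t-tests on the per-group RF lists, and report the separation
margin min(RF_PD) - max(RF_ET).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as spstats

from .errors import LengthError, ParameterError
from .preprocessing import FilterSpec, bandpass
from .recording import TremorRecording, validate_axis

logger = logging.getLogger(__name__)

LABEL_PD = "PD"
LABEL_ET = "ET"
LABEL_INDETERMINATE = "indeterminate"

#: Lag grid used for the cohort sweep (samples at 125 /s).
DEFAULT_LAG_GRID = (
    (5, 10),
    (5, 20),
    (10, 20),
    (10, 30),
    (15, 30),
    (15, 40),
    (20, 30),
    (20, 40),
)


@dataclass(frozen=True)
class DelayPair:
    """The two sample lags of the difference embedding, ``0 < d1 < d2``."""

    d1: int = 5
    d2: int = 20

    def __post_init__(self) -> None:
        if not (isinstance(self.d1, (int, np.integer)) and isinstance(self.d2, (int, np.integer))):
            raise ParameterError("lags must be integers (samples)")
        if not 0 < self.d1 < self.d2:
            raise ParameterError(f"lags must satisfy 0 < d1 < d2, got ({self.d1}, {self.d2})")


@dataclass(frozen=True)
class EmbeddedCloud:
    """The 2-D point set produced by the two-delay difference map."""

    points: np.ndarray = field(repr=False)  # (N - d2, 2)
    lags: DelayPair = DelayPair()

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class EllipseSummary:
    """Center, covariance, and area of a Gaussian confidence ellipse.

    ``area`` is the temporal fluctuation TF (squared signal units);
    ``degenerate`` is set when every point of the cloud coincides.
    """

    center: np.ndarray
    covariance: np.ndarray
    coverage: float
    area: float
    degenerate: bool = False


def delay_embed(signal: np.ndarray, lags: DelayPair = DelayPair()) -> EmbeddedCloud:
    """Two-delay difference embedding; exactly ``len(signal) - d2`` points.

    Point k is ``(s[k + d1] - s[k], s[k + d2] - s[k])`` for
    ``k = 0 .. N - d2 - 1``.
    """
    s = np.asarray(signal, dtype=float)
    if s.ndim != 1:
        raise ParameterError(f"signal must be 1-D, got shape {s.shape}")
    n = len(s)
    if n <= lags.d2:
        raise LengthError(f"signal length {n} must exceed d2 = {lags.d2}")
    m = n - lags.d2
    x = s[lags.d1 : lags.d1 + m] - s[:m]
    y = s[lags.d2 : lags.d2 + m] - s[:m]
    return EmbeddedCloud(points=np.column_stack([x, y]), lags=lags)


def ellipse_area(
    cloud: EmbeddedCloud | np.ndarray, coverage: float = 0.95
) -> EllipseSummary:
    """Gaussian confidence ellipse of a 2-D point cloud.

    area = pi * q * sqrt(det(sample covariance)), with q the chi-square
    (2 d.o.f.) quantile at ``coverage`` (~5.9915 at 0.95) and the sample
    covariance using the n-1 denominator. A cloud of identical points is
    not an error: it yields area 0 with the ``degenerate`` flag set.
    """
    points = cloud.points if isinstance(cloud, EmbeddedCloud) else np.asarray(cloud, float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ParameterError(f"cloud must be an (M, 2) array, got shape {points.shape}")
    if points.shape[0] < 3:
        raise LengthError(f"need at least 3 points for an ellipse, got {points.shape[0]}")
    if not 0 < coverage < 1:
        raise ParameterError(f"coverage must be in (0, 1), got {coverage}")
    if not np.all(np.isfinite(points)):
        raise ParameterError("cloud contains non-finite values")

    center = points.mean(axis=0)
    covariance = np.cov(points, rowvar=False, ddof=1)
    det = float(np.linalg.det(covariance))
    det = max(det, 0.0)  # guard tiny negative round-off
    q = float(spstats.chi2.ppf(coverage, df=2))
    area = math.pi * q * math.sqrt(det)
    degenerate = bool(np.all(points == points[0]))
    return EllipseSummary(
        center=center,
        covariance=covariance,
        coverage=coverage,
        area=area,
        degenerate=degenerate,
    )


def temporal_fluctuation(
    recording: TremorRecording,
    axis: str = "x",
    lags: DelayPair = DelayPair(),
    filter_spec: FilterSpec = FilterSpec(),
    coverage: float = 0.95,
) -> float:
    """TF of one recording: filter -> select axis -> embed -> ellipse area."""
    validate_axis(axis)
    filtered = bandpass(recording.channel(axis), recording.sampling_rate, filter_spec)
    cloud = delay_embed(filtered, lags)
    return ellipse_area(cloud, coverage).area


def fluctuation_ratio(tf_resting: float, tf_kinetic: float, base: float = 10.0) -> float:
    """RF = log_base(100 * TF_resting / TF_kinetic); both TF must be > 0.

    RF = 0 exactly when resting fluctuation is 1% of kinetic fluctuation,
    for any logarithm base.
    """
    if not (tf_resting > 0 and tf_kinetic > 0):
        raise ParameterError(
            f"both temporal fluctuations must be positive, got "
            f"resting={tf_resting}, kinetic={tf_kinetic}"
        )
    if not base > 1:
        raise ParameterError(f"log base must exceed 1, got {base}")
    return math.log(100.0 * tf_resting / tf_kinetic, base)


def classify(rf: float, threshold: float = 0.0) -> str:
    """Threshold rule: PD if rf > threshold, ET if below, indeterminate at it."""
    if not math.isfinite(rf):
        raise ParameterError(f"fluctuation ratio must be finite, got {rf}")
    if rf > threshold:
        return LABEL_PD
    if rf < threshold:
        return LABEL_ET
    return LABEL_INDETERMINATE


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with PD as the positive case."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")

    @classmethod
    def from_labels(
        cls, true_labels: Sequence[str], predicted_labels: Sequence[str]
    ) -> "ConfusionCounts":
        """Count outcomes; an indeterminate prediction counts as an error."""
        if len(true_labels) != len(predicted_labels):
            raise ParameterError("label lists must have equal length")
        tp = tn = fp = fn = 0
        for truth, pred in zip(true_labels, predicted_labels):
            if truth == LABEL_PD:
                if pred == LABEL_PD:
                    tp += 1
                else:
                    fn += 1
            elif truth == LABEL_ET:
                if pred == LABEL_ET:
                    tn += 1
                else:
                    fp += 1
            else:
                raise ParameterError(f"true label must be PD or ET, got {truth!r}")
        return cls(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass(frozen=True)
class PerformanceMetrics:
    """Percent metrics; a field is None when its denominator is zero."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None


def confusion_metrics(
    counts: ConfusionCounts, tn_only_accuracy: bool = False
) -> PerformanceMetrics:
    """Sensitivity, specificity, accuracy in percent.

    ``tn_only_accuracy`` switches the accuracy numerator from TP + TN to
    TN alone (a non-standard variant kept behind this flag).
    """
    total = counts.tp + counts.tn + counts.fp + counts.fn

    def ratio(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    numerator = counts.tn if tn_only_accuracy else counts.tp + counts.tn
    return PerformanceMetrics(
        sensitivity=ratio(counts.tp, counts.tp + counts.fn),
        specificity=ratio(counts.tn, counts.tn + counts.fp),
        accuracy=ratio(numerator, total),
    )


def two_sample_t(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided pooled-variance (equal-variance) Student t-test p-value.

    Returns NaN when the pooled variance is zero (test undefined).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs at least 2 values")
    with warnings.catch_warnings():
        # degenerate (near-constant) input produces NaN plus a RuntimeWarning;
        # NaN is the documented "test undefined" flag, the warning is noise
        warnings.simplefilter("ignore", RuntimeWarning)
        result = spstats.ttest_ind(a, b, equal_var=True)
    return float(result.pvalue)


def separation_distance(rf_pd: Sequence[float], rf_et: Sequence[float]) -> float:
    """Margin min(RF_PD) - max(RF_ET); positive means threshold-separable."""
    if len(rf_pd) == 0 or len(rf_et) == 0:
        raise ParameterError("both groups must be nonempty")
    return float(min(rf_pd) - max(rf_et))


@dataclass(frozen=True)
class SubjectFeatures:
    """Per-subject TF per task, fluctuation ratio, and predicted label."""

    subject_id: str
    axis: str
    tf_by_task: Mapping[str, float]
    rf: float | None
    predicted_label: str


def subject_features(
    subject_id: str,
    recordings: Mapping[str, TremorRecording],
    axis: str = "x",
    lags: DelayPair = DelayPair(),
    filter_spec: FilterSpec = FilterSpec(),
    coverage: float = 0.95,
    log_base: float = 10.0,
) -> SubjectFeatures:
    """Compute TF for every provided task and the resting/kinetic RF.

    RF is undefined (subject indeterminate) when either required task is
    missing or either TF is nonpositive; no epsilon flooring is applied.
    """
    tf_by_task = {
        task: temporal_fluctuation(rec, axis=axis, lags=lags, filter_spec=filter_spec, coverage=coverage)
        for task, rec in recordings.items()
    }
    rf: float | None = None
    tf_rest = tf_by_task.get("resting")
    tf_kin = tf_by_task.get("kinetic")
    if tf_rest is not None and tf_kin is not None and tf_rest > 0 and tf_kin > 0:
        rf = fluctuation_ratio(tf_rest, tf_kin, base=log_base)
    predicted = classify(rf) if rf is not None else LABEL_INDETERMINATE
    return SubjectFeatures(
        subject_id=subject_id,
        axis=axis,
        tf_by_task=tf_by_task,
        rf=rf,
        predicted_label=predicted,
    )


@dataclass(frozen=True)
class CohortSubject:
    """One subject's true label and task recordings."""

    subject_id: str
    label: str
    recordings: Mapping[str, TremorRecording]


@dataclass(frozen=True)
class SweepRow:
    """Cohort statistics for one (lag pair, axis) combination."""

    d1: int
    d2: int
    axis: str
    rf_pd: tuple[float, ...]
    rf_et: tuple[float, ...]
    p_value: float
    separation: float
    n_excluded: int


@dataclass(frozen=True)
class CohortResult:
    rows: tuple[SweepRow, ...]


def delay_sweep(
    cohort: Sequence[CohortSubject],
    lag_grid: Iterable[tuple[int, int]] = DEFAULT_LAG_GRID,
    axes: Sequence[str] = ("x", "y", "z"),
    filter_spec: FilterSpec = FilterSpec(),
    coverage: float = 0.95,
    log_base: float = 10.0,
) -> CohortResult:
    """RF group statistics over a grid of lag pairs and axes.

    For each combination: the per-group RF lists, the pooled-variance
    t-test p-value (NaN when undefined), and the separation margin.
    Subjects whose RF is undefined are excluded with a logged count.
    """
    rows = []
    for d1, d2 in lag_grid:
        lags = DelayPair(d1, d2)
        for axis in axes:
            rf_pd: list[float] = []
            rf_et: list[float] = []
            n_excluded = 0
            for subject in cohort:
                feats = subject_features(
                    subject.subject_id,
                    subject.recordings,
                    axis=axis,
                    lags=lags,
                    filter_spec=filter_spec,
                    coverage=coverage,
                    log_base=log_base,
                )
                if feats.rf is None:
                    n_excluded += 1
                    continue
                (rf_pd if subject.label == LABEL_PD else rf_et).append(feats.rf)
            if n_excluded:
                logger.warning(
                    "lags (%d, %d) axis %s: excluded %d subject(s) with undefined RF",
                    d1, d2, axis, n_excluded,
                )
            if len(rf_pd) >= 2 and len(rf_et) >= 2:
                p_value = two_sample_t(rf_pd, rf_et)
            else:
                p_value = float("nan")
            if rf_pd and rf_et:
                separation = separation_distance(rf_pd, rf_et)
            else:
                separation = float("nan")
            rows.append(
                SweepRow(
                    d1=d1,
                    d2=d2,
                    axis=axis,
                    rf_pd=tuple(rf_pd),
                    rf_et=tuple(rf_et),
                    p_value=p_value,
                    separation=separation,
                    n_excluded=n_excluded,
                )
            )
    return CohortResult(rows=tuple(rows))


def evaluate_cohort(
    cohort: Sequence[CohortSubject],
    axis: str = "x",
    lags: DelayPair = DelayPair(),
    filter_spec: FilterSpec = FilterSpec(),
    coverage: float = 0.95,
    log_base: float = 10.0,
    tn_only_accuracy: bool = False,
) -> tuple[ConfusionCounts, PerformanceMetrics]:
    """Classify every subject and score against the true labels."""
    truths = []
    preds = []
    for subject in cohort:
        feats = subject_features(
            subject.subject_id,
            subject.recordings,
            axis=axis,
            lags=lags,
            filter_spec=filter_spec,
            coverage=coverage,
            log_base=log_base,
        )
        truths.append(subject.label)
        preds.append(feats.predicted_label)
    counts = ConfusionCounts.from_labels(truths, preds)
    return counts, confusion_metrics(counts, tn_only_accuracy=tn_only_accuracy)
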