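"""Per-tumor pharmacodynamic response labelling and baseline-threshold
predictors.

Each tumor-visit is summarized by the median parameter value over its
VOI. A change from baseline beyond the repeatability coefficient in the
pharmacologically expected direction — a fall for ADC and T1, a rise for
iAUC, ktrans, ve, vp — marks the tumor a pharmacodynamic responder (P),
otherwise a non-responder (N). Baseline-value threshold rules predicting
P/N are learned by exhaustive cut-point search maximizing balanced
accuracy, with McNemar's exact test for significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .core import PARAMETER_DIRECTION, ParameterMap
from .repeatability import RcSpec

MIN_VALID_VOXELS = 5  # tumor-visits with fewer valid voxels are excluded upstream


@dataclass
class TumorMeasurement:
    subject_id: str
    tumor_id: str
    visit: str
    parameter: str
    median_value: float
    n_valid_voxels: int


@dataclass
class ResponseLabel:
    subject_id: str
    tumor_id: str
    visit: str
    parameter: str
    change: float  # parameter units (absolute RC) or fraction of baseline
    label: str  # "P" | "N"
    direction: str  # "decrease" | "increase"


@dataclass
class ThresholdRule:
    parameter: str
    threshold: float
    predict_p_side: str  # "below" | "above"
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    p_value: float

    def predict(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.predict_p_side == "below":
            return values < self.threshold
        return values > self.threshold


def summarize_voi(pmap: ParameterMap, mask: np.ndarray, subject_id: str = "",
                  tumor_id: str = "", visit: str = "") -> TumorMeasurement:
    """Median of the map's valid voxels inside the VOI mask."""
    vals = pmap.masked_values(mask)
    if vals.size == 0:
        raise ValueError(
            f"no valid voxels in VOI for {pmap.name} "
            f"({subject_id}/{tumor_id}/{visit})"
        )
    return TumorMeasurement(subject_id, tumor_id, visit, pmap.name,
                            float(np.median(vals)), int(vals.size))


def label_response(
    baseline: TumorMeasurement,
    followup: TumorMeasurement,
    rc: RcSpec,
    direction: str | None = None,
) -> ResponseLabel:
    """Directional responder call of a follow-up change against the RC.

    Absolute mode compares followup - baseline with the RC bounds in
    parameter units; relative modes compare the fractional change
    (followup - baseline)/baseline, the only defensible anchor for a
    literature percentage RC. A decrease-direction parameter responds
    when the change falls below the lower bound, an increase-direction
    parameter when it exceeds the upper bound.
    """
    if (baseline.subject_id, baseline.tumor_id, baseline.parameter) != (
        followup.subject_id, followup.tumor_id, followup.parameter
    ):
        raise ValueError("baseline and follow-up refer to different measurements")
    if direction is None:
        direction = PARAMETER_DIRECTION[baseline.parameter]
    if direction not in {"decrease", "increase"}:
        raise ValueError(f"unknown direction {direction!r}")

    if rc.is_relative:
        if baseline.median_value == 0:
            raise ValueError("relative RC undefined for zero baseline")
        change = (followup.median_value - baseline.median_value) / baseline.median_value
    else:
        change = followup.median_value - baseline.median_value

    if direction == "decrease":
        is_p = change < rc.lower
    else:
        is_p = change > rc.upper
    return ResponseLabel(baseline.subject_id, baseline.tumor_id, followup.visit,
                         baseline.parameter, float(change),
                         "P" if is_p else "N", direction)


def _as_bool(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "US":
        return arr == "P"
    return arr.astype(bool)


def classification_metrics(predicted, truth) -> tuple[float, float, float]:
    """(sensitivity, specificity, balanced accuracy) of P/N predictions.

    sensitivity = |predicted-P and true-P| / |true-P|; specificity the
    analogue on N; balanced accuracy their mean. Undefined (error) when
    either class is absent from the truth.
    """
    pred = _as_bool(predicted)
    true = _as_bool(truth)
    if pred.shape != true.shape:
        raise ValueError("predicted and true label vectors differ in length")
    n_p = int(true.sum())
    n_n = int((~true).sum())
    if n_p == 0 or n_n == 0:
        raise ValueError("balanced accuracy undefined: a class is absent")
    sens = float((pred & true).sum() / n_p)
    spec = float((~pred & ~true).sum() / n_n)
    return sens, spec, (sens + spec) / 2.0


def mcnemar_test(predicted, truth) -> float:
    """Exact two-sided McNemar test on paired binary outcomes.

    Discordant counts b (predicted P, true N) and c (predicted N,
    true P) follow Binomial(b+c, 1/2) under the null;
    p = min(1, 2*P(X <= min(b, c))). b + c = 0 gives p = 1 by
    convention.
    """
    pred = _as_bool(predicted)
    true = _as_bool(truth)
    if pred.shape != true.shape:
        raise ValueError("predicted and true label vectors differ in length")
    b = int((pred & ~true).sum())
    c = int((~pred & true).sum())
    n = b + c
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * binom.cdf(min(b, c), n, 0.5)))


def optimize_threshold(baseline_values, labels, predict_p_side: str) -> ThresholdRule:
    """Exhaustive cut-point search maximizing balanced accuracy.

    Candidate thresholds are the midpoints between consecutive sorted
    distinct baseline values plus one candidate beyond each extreme.
    Ties are broken toward higher specificity, then smaller absolute
    threshold. The returned rule carries McNemar's exact p-value of its
    own predictions against the labels.
    """
    if predict_p_side not in {"below", "above"}:
        raise ValueError("predict_p_side must be 'below' or 'above'")
    values = np.asarray(baseline_values, dtype=float)
    true = _as_bool(labels)
    if values.shape != true.shape:
        raise ValueError("values and labels differ in length")
    distinct = np.unique(values)
    if distinct.size < 2:
        raise ValueError("all baseline values identical: no threshold exists")
    span = distinct[-1] - distinct[0]
    candidates = np.concatenate([
        [distinct[0] - 0.5 * span],
        (distinct[:-1] + distinct[1:]) / 2.0,
        [distinct[-1] + 0.5 * span],
    ])

    best = None
    for thr in candidates:
        pred = values < thr if predict_p_side == "below" else values > thr
        sens, spec, ba = classification_metrics(pred, true)
        key = (ba, spec, -abs(thr))
        if best is None or key > best[0]:
            best = (key, thr, sens, spec, ba)
    _, thr, sens, spec, ba = best
    pred = values < thr if predict_p_side == "below" else values > thr
    return ThresholdRule(
        parameter="", threshold=float(thr), predict_p_side=predict_p_side,
        sensitivity=sens, specificity=spec, balanced_accuracy=ba,
        p_value=mcnemar_test(pred, true),
    )
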