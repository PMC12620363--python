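"""Directed threshold classifiers (DTCs) and ordinal classifier cascades.

A DTC is a one-dimensional binary classifier with a single cut point and
a fixed orientation: values at or above the cut belong to the right-hand
class.  Cascades chain DTCs over a class sequence with strictly increasing
cut points, which partitions the axis into contiguous decision intervals.
Fitting tolerates a per-class misclassification budget ``theta`` (the
complement of the minimal class-wise sensitivity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

_DEGENERATE_RTOL = 1e-12


@dataclass(frozen=True)
class ThresholdInterval:
    """Feasible threshold region ``(lower, upper]`` with point estimate.

    The point is the margin midpoint of the region; when the region is
    degenerate at floating-point tolerance the upper bound (the only value
    guaranteed inside the half-open region) is used instead.
    """

    lower: float
    upper: float
    point: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"empty interval ({self.lower}, {self.upper}]")
        if not self.lower < self.point <= self.upper:
            raise ValueError("point outside interval")

    @classmethod
    def from_bounds(cls, lower: float, upper: float) -> "ThresholdInterval":
        point = 0.5 * (lower + upper)
        if not lower < point <= upper:
            point = upper
        return cls(lower=float(lower), upper=float(upper), point=float(point))

    def intersect(self, other: "ThresholdInterval",
                  rtol: float = 1e-9) -> Optional["ThresholdInterval"]:
        lo = max(self.lower, other.lower)
        up = min(self.upper, other.upper)
        scale = max(1.0, abs(lo), abs(up))
        if up - lo <= rtol * scale:
            return None
        return ThresholdInterval.from_bounds(lo, up)

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class DirectedThresholdClassifier:
    """Binary threshold rule: ``x >= point -> right_label`` else ``left_label``."""

    left_label: str
    right_label: str
    interval: ThresholdInterval
    left_sens: float
    right_sens: float

    def classify(self, x: float) -> str:
        return self.right_label if x >= self.interval.point else self.left_label


@dataclass(frozen=True)
class Cascade:
    """A class sequence with one DTC per adjacent pair.

    ``sensitivity_items`` is a sorted tuple of ``(label, sensitivity)``
    pairs (kept as a tuple so cascades are hashable).
    """

    order: tuple
    classifiers: tuple
    sensitivity_items: tuple

    def __post_init__(self):
        if len(self.order) < 2 or len(self.classifiers) != len(self.order) - 1:
            raise ValueError("cascade needs k classes and k-1 classifiers")
        for i, c in enumerate(self.classifiers):
            if c.left_label != self.order[i] or c.right_label != self.order[i + 1]:
                raise ValueError("classifier labels do not match the order")
        pts = self.points
        if any(pts[i] >= pts[i + 1] for i in range(len(pts) - 1)):
            raise ValueError("threshold points must be strictly increasing")

    @property
    def points(self) -> tuple:
        return tuple(c.interval.point for c in self.classifiers)

    @property
    def sensitivities(self) -> Mapping[str, float]:
        return dict(self.sensitivity_items)

    @property
    def min_sensitivity(self) -> float:
        return min(s for _, s in self.sensitivity_items)


@dataclass(frozen=True)
class RejectedCascade:
    """Marker for a rejected candidate order; position indexes the first
    failing adjacent pair (threshold fit) or class (sensitivity)."""

    order: tuple
    position: int
    reason: str

    def __bool__(self):
        return False


def fit_dtc(
    left_values: Sequence[float],
    right_values: Sequence[float],
    theta: float,
    left_label: str = "left",
    right_label: str = "right",
) -> Optional[DirectedThresholdClassifier]:
    """Fit the maximal feasible threshold region under the budget ``theta``.

    A threshold ``t`` is feasible when at most ``floor(theta*n_left)`` left
    values are ``>= t`` and at most ``floor(theta*n_right)`` right values are
    ``< t``.  The feasible set is the half-open interval whose bounds are the
    corresponding order statistics; the returned point is its midpoint (the
    1-D hard-margin solution on the trimmed samples).  Returns ``None`` when
    no feasible threshold exists.
    """
    left = np.sort(np.asarray(left_values, dtype=float))
    right = np.sort(np.asarray(right_values, dtype=float))
    if left.size == 0 or right.size == 0:
        raise ValueError("both classes need at least one value")
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must lie in [0, 0.5]")
    k_left = math.floor(theta * left.size)
    k_right = math.floor(theta * right.size)
    lower = left[left.size - 1 - k_left]
    upper = right[k_right]
    if not lower < upper:
        return None
    interval = ThresholdInterval.from_bounds(lower, upper)
    left_sens = float(np.mean(left < interval.point))
    right_sens = float(np.mean(right >= interval.point))
    return DirectedThresholdClassifier(
        left_label=str(left_label),
        right_label=str(right_label),
        interval=interval,
        left_sens=left_sens,
        right_sens=right_sens,
    )


class DTCCache:
    """Memoizes per-ordered-pair DTC fits for reuse across candidate orders."""

    def __init__(self, projected, theta: float):
        self.projected = projected
        self.theta = float(theta)
        self._fits: dict = {}
        self.n_fits = 0

    def get(self, left_label: str, right_label: str):
        key = (left_label, right_label)
        if key not in self._fits:
            self._fits[key] = fit_dtc(
                self.projected.class_values(left_label),
                self.projected.class_values(right_label),
                self.theta,
                left_label,
                right_label,
            )
            self.n_fits += 1
        return self._fits[key]


def fit_cascade(projected, order: Sequence[str], theta: float,
                cache: DTCCache | None = None):
    """Fit a cascade for a candidate order; reject at the first failure.

    Rejection happens at the first adjacent pair without a feasible
    threshold, at the first threshold breaking strict monotonicity, or at
    the first class whose cascade sensitivity falls below ``1 - theta``.
    """
    order = tuple(str(l) for l in order)
    if len(order) < 2:
        raise ValueError("an order needs at least two classes")
    known = set(projected.labels)
    for l in order:
        if l not in known:
            raise ValueError(f"unknown label {l!r}")
    if len(set(order)) != len(order):
        raise ValueError("repeated label in order")
    if cache is not None and (cache.projected is not projected
                              or cache.theta != theta):
        raise ValueError("cache was built for a different projection/theta")

    classifiers = []
    for i in range(len(order) - 1):
        a, b = order[i], order[i + 1]
        if cache is not None:
            dtc = cache.get(a, b)
        else:
            dtc = fit_dtc(projected.class_values(a), projected.class_values(b),
                          theta, a, b)
        if dtc is None:
            return RejectedCascade(order, i, f"no feasible threshold for ({a},{b})")
        if classifiers and dtc.interval.point <= classifiers[-1].interval.point:
            return RejectedCascade(order, i, "threshold monotonicity violated")
        classifiers.append(dtc)

    cascade = Cascade(
        order=order,
        classifiers=tuple(classifiers),
        sensitivity_items=tuple(
            sorted(_sensitivities(order, classifiers, projected).items())
        ),
    )
    for pos, label in enumerate(order):
        if cascade.sensitivities[label] < 1.0 - theta - 1e-12:
            return RejectedCascade(
                order, pos,
                f"class {label!r} sensitivity "
                f"{cascade.sensitivities[label]:.4f} < {1.0 - theta:.4f}",
            )
    return cascade


def cascade_predict(cascade: Cascade, x: float) -> str:
    """Sequential prediction: walk the classifiers; the first left-hand
    prediction is final, otherwise the last label wins."""
    for c in cascade.classifiers:
        if c.classify(x) == c.left_label:
            return c.left_label
    return cascade.order[-1]


def cascade_predict_interval(cascade: Cascade, xs) -> np.ndarray:
    """Closed form of :func:`cascade_predict` for monotone thresholds:
    look up the decision interval containing each value."""
    xs = np.asarray(xs, dtype=float)
    pts = np.asarray(cascade.points)
    idx = np.searchsorted(pts, xs, side="right")
    labels = np.asarray(cascade.order, dtype=object)
    return labels[idx]


def _sensitivities(order, classifiers, projected) -> dict:
    pts = np.asarray([c.interval.point for c in classifiers])
    labels = np.asarray(order, dtype=object)
    out = {}
    for i, label in enumerate(order):
        vals = projected.class_values(label)
        pred = labels[np.searchsorted(pts, vals, side="right")]
        out[label] = float(np.mean(pred == label))
    return out


def classwise_sensitivity(cascade: Cascade, projected) -> dict:
    """Fraction of each cascade class's samples assigned their true label;
    samples of classes outside the order are ignored."""
    missing = [l for l in cascade.order if l not in set(projected.labels)]
    if missing:
        raise ValueError(f"labels absent from projection: {missing}")
    return _sensitivities(cascade.order, cascade.classifiers, projected)
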