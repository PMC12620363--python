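"""One-dimensional supervised projections via max-margin linear models.

A projection is trained on exactly two classes (the *projection pair*) and
then applied to every sample: all points are mapped onto the unit normal of
the pair's separating hyperplane.  Orientation is fixed so that the second
pair class lies to the right (larger projected mean), which makes the
mirror relation between ``(a, b)`` and ``(b, a)`` exact and testable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr
from sklearn.svm import SVC

from .datasets_io import LabeledDataset

logger = logging.getLogger("ordmine")

#: Fixed soft-margin constant.  Large enough for hard-margin behaviour on
#: separable pairs after standardization, small enough to keep the solver
#: fast on fully overlapping pairs.
SVM_C = 100.0


@dataclass(eq=False)
class ProjectedDataset:
    """Per-sample coordinates on a projection axis plus provenance."""

    sample_ids: tuple
    values: np.ndarray
    y: np.ndarray
    labels: tuple
    pair: tuple
    direction_norm: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        if self.values.shape[0] != self.y.shape[0]:
            raise ValueError("values and labels disagree in length")
        if self.direction_norm <= 0:
            raise ValueError("direction_norm must be positive")

    def class_values(self, label: str) -> np.ndarray:
        if label not in self.labels:
            raise ValueError(f"unknown label {label!r}")
        return self.values[self.y == label]


def fit_projection(dataset: LabeledDataset, pair) -> ProjectedDataset:
    """Project all samples onto the max-margin normal of a class pair.

    The linear model is trained on the pair's samples only, after
    standardizing features with the pair's statistics (applied to every
    sample).  A warning is logged when the pair is not separable at
    resubstitution (training error > 0).
    """
    a, b = (str(pair[0]), str(pair[1]))
    if a == b:
        raise ValueError("projection pair labels must differ")
    for l in (a, b):
        if l not in dataset.labels:
            raise ValueError(f"unknown label {l!r}")

    mask = np.isin(dataset.y, [a, b])
    Xp, yp = dataset.X[mask], dataset.y[mask]
    mu = Xp.mean(axis=0)
    sd = np.maximum(Xp.std(axis=0), 1e-12)
    clf = SVC(kernel="linear", C=SVM_C)
    clf.fit((Xp - mu) / sd, yp.astype(str))
    if clf.score((Xp - mu) / sd, yp.astype(str)) < 1.0:
        logger.warning("projection pair (%s, %s) is not separable at "
                       "resubstitution", a, b)

    w = clf.coef_[0].astype(float)
    norm = float(np.linalg.norm(w))
    if norm == 0.0:
        raise ValueError(f"degenerate separating direction for pair ({a}, {b})")
    values = ((dataset.X - mu) / sd) @ (w / norm)
    if values[dataset.y == b].mean() < values[dataset.y == a].mean():
        values = -values
    return ProjectedDataset(
        sample_ids=dataset.sample_ids,
        values=values,
        y=dataset.y.copy(),
        labels=dataset.labels,
        pair=(a, b),
        direction_norm=norm,
    )


def reverse_projection_property(dataset: LabeledDataset, pair) -> bool:
    """Check that swapping the projection pair exactly reverses rank order."""
    fwd = fit_projection(dataset, pair)
    rev = fit_projection(dataset, (pair[1], pair[0]))
    rho = spearmanr(fwd.values, rev.values).statistic
    return bool(np.isclose(rho, -1.0))


def class_centroids(dataset: LabeledDataset) -> dict:
    return {l: dataset.class_matrix(l).mean(axis=0) for l in dataset.labels}


def select_projection_pairs(dataset: LabeledDataset, strategy: str = "all",
                            explicit=None) -> list:
    """Choose ordered projection pairs.

    ``all``: every unordered pair, oriented by the dataset's label order.
    ``most_distant``: the single pair with maximal Euclidean distance
    between class centroids in feature space.
    ``explicit``: validated pass-through of user pairs.
    """
    if len(dataset.labels) < 2:
        raise ValueError("need at least two classes")
    if strategy == "all":
        return list(itertools.combinations(dataset.labels, 2))
    if strategy == "most_distant":
        cent = class_centroids(dataset)
        best, best_d = None, -1.0
        for a, b in itertools.combinations(dataset.labels, 2):
            d = float(np.linalg.norm(cent[a] - cent[b]))
            if d > best_d:
                best, best_d = (a, b), d
        return [best]
    if strategy == "explicit":
        if not explicit:
            raise ValueError("explicit strategy needs a pair list")
        pairs = []
        for a, b in explicit:
            a, b = str(a), str(b)
            for l in (a, b):
                if l not in dataset.labels:
                    raise ValueError(f"unknown label {l!r} in explicit pair list")
            if a == b:
                raise ValueError("pair labels must differ")
            pairs.append((a, b))
        return pairs
    raise ValueError(f"unknown strategy {strategy!r}")
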