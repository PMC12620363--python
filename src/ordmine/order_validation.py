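"""Independent total-order detection via monotone separability matrices.

For every class pair a separability score is computed (resubstitution
accuracy of a linear max-margin classifier, or a bounded multidimensional
discriminant ratio).  A total ordinal structure exists exactly when some
arrangement of the symmetric score matrix makes every row non-increasing
toward the (zero) diagonal from both sides; each structure is found
together with its reverse.  Used to cross-check suborders found by the
cascade screening on the corresponding data subsets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import List

import numpy as np
from sklearn.svm import SVC

from .datasets_io import LabeledDataset

logger = logging.getLogger("ordmine")

TIE_TOL = 1e-12
_BRUTE_FORCE_MAX = 8


@dataclass(eq=False)
class SeparabilityMatrix:
    """Symmetric pairwise class-separability scores with zero diagonal."""

    labels: tuple
    a: np.ndarray

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        n = len(self.labels)
        if self.a.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.a, self.a.T):
            raise ValueError("separability matrix must be symmetric")
        if not np.allclose(np.diag(self.a), 0.0):
            raise ValueError("diagonal must be zero")

    def reordered(self, order) -> np.ndarray:
        idx = [self.labels.index(l) for l in order]
        return self.a[np.ix_(idx, idx)]


def _pair_accuracy(Xi: np.ndarray, Xj: np.ndarray) -> float:
    X = np.vstack([Xi, Xj])
    y = np.array([0] * len(Xi) + [1] * len(Xj))
    mu = X.mean(axis=0)
    sd = np.maximum(X.std(axis=0), 1e-12)
    clf = SVC(kernel="linear", C=100.0)
    Z = (X - mu) / sd
    clf.fit(Z, y)
    return float(clf.score(Z, y))


def _pair_fisher(Xi: np.ndarray, Xj: np.ndarray, li: str, lj: str) -> float:
    mu_i, mu_j = Xi.mean(axis=0), Xj.mean(axis=0)
    for label, X in ((li, Xi), (lj, Xj)):
        if float(X.var(axis=0).sum()) == 0.0:
            raise ValueError(f"class {label!r} has zero within-class variance")
    scatter = float(Xi.var(axis=0).sum() + Xj.var(axis=0).sum())
    ratio = float(np.sum((mu_i - mu_j) ** 2)) / scatter
    return ratio / (1.0 + ratio)  # monotone map of the ratio into [0, 1)


def build_separability_matrix(dataset: LabeledDataset,
                              score: str = "accuracy") -> SeparabilityMatrix:
    """One pairwise fit per unordered class pair, filled symmetrically."""
    labels = dataset.labels
    n = len(labels)
    a = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        Xi, Xj = dataset.class_matrix(labels[i]), dataset.class_matrix(labels[j])
        if score == "accuracy":
            a[i, j] = _pair_accuracy(Xi, Xj)
        elif score == "fisher":
            if len(Xi) < 2 or len(Xj) < 2:
                raise ValueError("fisher score needs >= 2 samples per class")
            a[i, j] = _pair_fisher(Xi, Xj, labels[i], labels[j])
        else:
            raise ValueError(f"unknown score {score!r}")
        a[j, i] = a[i, j]
    return SeparabilityMatrix(labels=labels, a=a)


def is_monotone_arrangement(M: SeparabilityMatrix, order,
                            tol: float = TIE_TOL) -> bool:
    """Every row non-increasing toward the diagonal from both sides."""
    B = M.reordered(order)
    n = B.shape[0]
    for i in range(n):
        for j in range(i - 1):
            if B[i, j] < B[i, j + 1] - tol:
                return False
        for j in range(i + 1, n - 1):
            if B[i, j] > B[i, j + 1] + tol:
                return False
    return True


def _brute_force(M: SeparabilityMatrix, tol: float) -> List[tuple]:
    return [perm for perm in itertools.permutations(M.labels)
            if is_monotone_arrangement(M, perm, tol)]


def detect_total_order(M: SeparabilityMatrix, tol: float = TIE_TOL) -> List[tuple]:
    """All label arrangements under which the matrix is monotone.

    Candidates are generated by seriation: if an admissible arrangement
    starts with class ``e``, sorting the other classes by their score
    against ``e`` recovers it (up to ties).  Ties among sort keys trigger
    the exhaustive fallback for small label sets.  The result is closed
    under reversal; an empty list means no total ordinal structure.
    """
    labels = M.labels
    n = len(labels)
    if n < 2:
        return []
    found = set()
    ambiguous = False
    for e in range(n):
        keys = M.a[e]
        others = sorted((k for k in range(n) if k != e),
                        key=lambda k: (keys[k], labels[k]))
        vals = [keys[k] for k in others]
        if any(abs(vals[i] - vals[i + 1]) <= tol for i in range(len(vals) - 1)):
            ambiguous = True
        order = tuple(labels[k] for k in [e] + others)
        if is_monotone_arrangement(M, order, tol):
            found.add(order)
    if ambiguous:
        if n > _BRUTE_FORCE_MAX:
            logger.warning(
                "tied separability scores with %d classes: seriation may be "
                "incomplete (exhaustive fallback capped at %d)", n,
                _BRUTE_FORCE_MAX,
            )
        else:
            found = set(_brute_force(M, tol))
    return sorted(found)


@dataclass(frozen=True)
class ValidationRecord:
    sequence: tuple
    status: str  # confirmed | contradicted | undetected
    orderings: tuple


def cross_validate_substructures(dataset: LabeledDataset, suborders,
                                 score: str = "accuracy") -> List[ValidationRecord]:
    """Re-test each longest suborder with the monotone-matrix detector.

    The dataset is restricted to the suborder's classes; *confirmed* means
    the detector admits the sequence (or its reverse), *contradicted* means
    it admits only other arrangements, *undetected* means it finds none.
    """
    subs = sorted({tuple(s.sequence) for s in suborders})
    if not subs:
        return []
    longest = max(len(s) for s in subs)
    records = []
    for seq in subs:
        if len(seq) != longest:
            continue
        restricted = dataset.subset(sorted(seq))
        M = build_separability_matrix(restricted, score=score)
        orderings = detect_total_order(M)
        if seq in orderings or seq[::-1] in orderings:
            status = "confirmed"
        elif orderings:
            status = "contradicted"
        else:
            status = "undetected"
        records.append(ValidationRecord(sequence=seq, status=status,
                                        orderings=tuple(orderings)))
    return records
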