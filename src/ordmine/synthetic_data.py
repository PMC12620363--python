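"""Synthetic labeled datasets with known ordinal (sub)structure.

Classes are uniform draws from fixed intervals on a single structure axis
(feature 0) plus uniform-noise dimensions.  Because intervals either
overlap or are separated by a gap, the ground-truth suborders are exactly
the maximal chains of pairwise-disjoint intervals and are independent of
the per-class sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .datasets_io import LabeledDataset

#: Feature-0 intervals of the ten-class branching benchmark: two parallel
#: ordinal chains (l0..l5 and l6..l9) where l6 spans l0+l1, l7/l8 coincide
#: with l2/l3, and l9 spans l4+l5.
TEN_CLASS_INTERVALS: Dict[str, Tuple[float, float]] = {
    "l0": (0.0, 1.0),
    "l1": (1.5, 2.5),
    "l2": (3.0, 4.0),
    "l3": (4.5, 5.5),
    "l4": (6.0, 7.0),
    "l5": (7.5, 8.5),
    "l6": (0.2, 2.3),
    "l7": (3.0, 4.0),
    "l8": (4.5, 5.5),
    "l9": (6.2, 8.3),
}


@dataclass
class BranchingSpec:
    """Layout of a branching benchmark on the structure axis."""

    class_intervals: Dict[str, Tuple[float, float]]
    n_per_class: int = 100
    noise_dims: int = 1
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.noise_dims < 1:
            raise ValueError("noise_dims must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        for label, (lo, hi) in self.class_intervals.items():
            if not lo < hi:
                raise ValueError(f"class {label!r} interval must satisfy low < high")


def interval_ground_truth(intervals: Dict[str, Tuple[float, float]]) -> List[Tuple[str, ...]]:
    """Brute-force oracle: all maximal chains of pairwise-disjoint intervals.

    A sequence is a chain when every consecutive (hence every) pair of
    intervals is separated left-to-right; it is maximal when no further
    class can be inserted anywhere.  Single classes count only when no
    pair containing them is separable.
    """
    labels = sorted(intervals, key=lambda l: (intervals[l][0], intervals[l][1], l))

    def disjoint(a: str, b: str) -> bool:
        return intervals[a][1] <= intervals[b][0]

    chains: List[Tuple[str, ...]] = []

    def grow(chain: Tuple[str, ...]):
        chains.append(chain)
        for lab in labels:
            if lab in chain:
                continue
            if disjoint(chain[-1], lab):
                grow(chain + (lab,))

    for lab in labels:
        grow((lab,))

    chain_set = set(chains)

    def extensible(chain: Tuple[str, ...]) -> bool:
        for lab in labels:
            if lab in chain:
                continue
            for pos in range(len(chain) + 1):
                cand = chain[:pos] + (lab,) + chain[pos:]
                ok = all(disjoint(cand[i], cand[i + 1]) for i in range(len(cand) - 1))
                if ok:
                    return True
        return False

    maximal = sorted(c for c in chain_set if not extensible(c))
    return maximal


def make_branching(spec: BranchingSpec) -> Tuple[LabeledDataset, List[Tuple[str, ...]]]:
    """Sample a branching dataset and its brute-force ground truth."""
    rng = np.random.default_rng(spec.seed)
    labels = tuple(spec.class_intervals)
    ids, rows, y = [], [], []
    for label in labels:
        lo, hi = spec.class_intervals[label]
        f0 = rng.uniform(lo, hi, spec.n_per_class)
        noise = rng.uniform(0.0, spec.noise_scale, (spec.n_per_class, spec.noise_dims))
        rows.append(np.column_stack([f0, noise]))
        y += [label] * spec.n_per_class
        ids += [f"{label}_s{i:04d}" for i in range(spec.n_per_class)]
    dataset = LabeledDataset(
        sample_ids=tuple(ids),
        X=np.vstack(rows),
        y=np.asarray(y, dtype=object),
        labels=labels,
    )
    return dataset, interval_ground_truth(spec.class_intervals)


def make_ten_class_fixture(n_per_class: int = 100, seed: int = 0
                        ) -> Tuple[LabeledDataset, List[Tuple[str, ...]]]:
    """The ten-class two-feature branching benchmark.

    Structure on feature 0: l0 < l1 < {l2 || l7} < {l3 || l8} < l4 < l5 with
    strict gaps between consecutive groups; l6 overlaps l0 and l1, l9
    overlaps l4 and l5; feature 1 is pure noise.  The returned ground truth
    contains every maximal chain: 4 of length six, 8 of length five (the
    length-six chains with (l0,l1) replaced by l6 and/or (l4,l5) by l9) and
    4 of length four (both ends replaced).
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    spec = BranchingSpec(
        class_intervals=dict(TEN_CLASS_INTERVALS),
        n_per_class=n_per_class,
        noise_dims=1,
        noise_scale=1.0,
        seed=seed,
    )
    return make_branching(spec)
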