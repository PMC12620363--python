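import math

import numpy as np
import pytest

from ordmine import (
    ThresholdInterval,
    aggregate_alternatives,
    fit_projection,
    screen_suborders,
    suborder_is_path,
    thresholds_equivalent,
)
from ordmine.alternatives import LEFT_SHARED, RIGHT_SHARED

from conftest import make_interval_dataset, tiny_dataset


def _exact_projection(values_by_label, pair):
    """1-feature dataset whose projection preserves the stated values as an
    affine map — used where tests need exact interval endpoints."""
    ds = tiny_dataset(values_by_label)
    return ds, fit_projection(ds, pair)


def _projected_raw(values_by_label, pair=None):
    """Bypass the SVM: wrap explicit 1-D values as a projection."""
    from ordmine import ProjectedDataset
    labels = tuple(values_by_label)
    vals = np.concatenate([np.asarray(v, float) for v in values_by_label.values()])
    y = np.concatenate([[l] * len(v) for l, v in values_by_label.items()])
    ids = tuple(f"s{i}" for i in range(len(vals)))
    return ProjectedDataset(sample_ids=ids, values=vals,
                            y=np.asarray(y, dtype=object), labels=labels,
                            pair=pair or (labels[0], labels[-1]),
                            direction_norm=1.0)


def test_left_shared_region_exact():
    projected = _projected_raw({
        "ll": [0.0, 0.5, 1.0],
        "la": [2.0, 3.5, 5.0],
        "lb": [2.0, 2.5, 3.0],
    })
    dummy = ThresholdInterval.from_bounds(1.0, 2.0)
    shared = thresholds_equivalent(dummy, dummy, ("la", "lb", "ll", LEFT_SHARED),
                                   projected, theta=0.0)
    assert shared is not None
    assert shared.kind == LEFT_SHARED
    assert shared.feasible.lower == pytest.approx(1.0)
    assert shared.feasible.upper == pytest.approx(2.0)


def test_right_shared_region_exact():
    projected = _projected_raw({
        "la": [0.0, 1.0],
        "lb": [0.5, 2.0],
        "lr": [3.0, 4.0],
    })
    dummy = ThresholdInterval.from_bounds(2.0, 3.0)
    shared = thresholds_equivalent(dummy, dummy, ("la", "lb", "lr", RIGHT_SHARED),
                                   projected, theta=0.0)
    assert shared is not None
    assert shared.feasible.lower == pytest.approx(2.0)  # max over both branches
    assert shared.feasible.upper == pytest.approx(3.0)


def test_shared_region_empty_returns_none():
    projected = _projected_raw({
        "ll": [0.0, 1.0],
        "la": [2.0, 3.0],
        "lb": [0.5, 1.5],  # overlaps the anchor
    })
    dummy = ThresholdInterval.from_bounds(1.0, 2.0)
    assert thresholds_equivalent(dummy, dummy, ("la", "lb", "ll", LEFT_SHARED),
                                 projected, theta=0.0) is None


def test_shared_threshold_symmetry():
    projected = _projected_raw({
        "ll": [0.0, 1.0],
        "la": [2.0, 5.0],
        "lb": [2.0, 3.0],
    })
    dummy = ThresholdInterval.from_bounds(1.0, 2.0)
    ab = thresholds_equivalent(dummy, dummy, ("la", "lb", "ll", LEFT_SHARED),
                               projected, theta=0.0)
    ba = thresholds_equivalent(dummy, dummy, ("lb", "la", "ll", LEFT_SHARED),
                               projected, theta=0.0)
    assert ab.feasible == ba.feasible
    assert set(ab.branch_labels) == set(ba.branch_labels)


def test_context_validation():
    projected = _projected_raw({"a": [0.0], "b": [1.0], "c": [2.0]})
    dummy = ThresholdInterval.from_bounds(0.0, 1.0)
    with pytest.raises(ValueError):
        thresholds_equivalent(dummy, dummy, ("a", "a", "b", LEFT_SHARED),
                              projected, 0.0)
    with pytest.raises(ValueError):
        thresholds_equivalent(dummy, dummy, ("a", "b", "zz", LEFT_SHARED),
                              projected, 0.0)
    with pytest.raises(ValueError):
        thresholds_equivalent(dummy, dummy, ("a", "b", "c", "sideways"),
                              projected, 0.0)


def sweep_shared_region(projected, anchor, la, lb, theta, kind):
    """Brute-force oracle: thresholds passing the per-class budget count on
    BOTH anchor->branch transitions."""
    vals = {l: projected.class_values(l) for l in (anchor, la, lb)}
    allv = np.unique(np.concatenate(list(vals.values())))
    cands = list(allv) + [0.5 * (a + b) for a, b in zip(allv, allv[1:])]
    cands += [allv[0] - 1, allv[-1] + 1]

    def ok(t, left, right):
        kl = math.floor(theta * len(vals[left]))
        kr = math.floor(theta * len(vals[right]))
        return (np.sum(vals[left] >= t) <= kl
                and np.sum(vals[right] < t) <= kr)

    if kind == LEFT_SHARED:
        feas = [t for t in cands if ok(t, anchor, la) and ok(t, anchor, lb)]
    else:
        feas = [t for t in cands if ok(t, la, anchor) and ok(t, lb, anchor)]
    return feas


@pytest.mark.parametrize("trial", range(8))
def test_shared_region_matches_sweep_oracle(trial):
    rng = np.random.default_rng(trial)
    theta = 0.2
    projected = _projected_raw({
        "anchor": rng.uniform(0, 3, 10),
        "la": rng.uniform(2, 6, 10),
        "lb": rng.uniform(2, 6, 10),
    })
    dummy = ThresholdInterval.from_bounds(-10.0, 10.0)
    for kind in (LEFT_SHARED, RIGHT_SHARED):
        ctx = ("la", "lb", "anchor", kind)
        shared = thresholds_equivalent(dummy, dummy, ctx, projected, theta)
        feas = sweep_shared_region(projected, "anchor", "la", "lb", theta, kind)
        if shared is None:
            assert not feas
            continue
        assert feas
        for t in feas:
            assert shared.feasible.lower < t <= shared.feasible.upper + 1e-12
        # candidates outside the region are infeasible
        out_low = shared.feasible.lower
        out_high = np.nextafter(shared.feasible.upper, np.inf) + 1e-9
        assert out_low not in feas
        assert out_high not in feas


def test_aggregate_benchmark_layers(projected_05):
    subs = [s for s in screen_suborders(projected_05, min_sens=1.0)
            if len(s.sequence) >= 5]
    assert len(subs) == 12
    graph = aggregate_alternatives(subs, projected_05, theta=0.0)
    assert len(graph.components) == 1
    layers = graph.components[0].layers
    assert layers == [
        [("l0", "l1"), ("l6",)],
        [("l2",), ("l7",)],
        [("l3",), ("l8",)],
        [("l4", "l5"), ("l9",)],
    ]
    for s in subs:
        assert suborder_is_path(graph, s.sequence)


def test_aggregate_parallel_soundness(projected_05):
    subs = [s for s in screen_suborders(projected_05, min_sens=1.0)
            if len(s.sequence) >= 5]
    graph = aggregate_alternatives(subs, projected_05, theta=0.0)
    sequences = [set(s.sequence) for s in subs]
    for layer in graph.components[0].layers:
        for i, u1 in enumerate(layer):
            for u2 in layer[i + 1:]:
                for seq in sequences:
                    assert not (set(u1) <= seq and set(u2) <= seq)


def test_aggregate_single_suborder_path_graph(projected_05):
    subs = [s for s in screen_suborders(projected_05, min_sens=1.0)
            if s.sequence == ("l0", "l1", "l2", "l3", "l4", "l5")]
    graph = aggregate_alternatives(subs, projected_05, theta=0.0)
    assert len(graph.components) == 1
    layers = graph.components[0].layers
    assert layers == [[(f"l{i}",)] for i in range(6)]
    assert suborder_is_path(graph, subs[0].sequence)


def test_aggregate_disjoint_suborders_separate_components():
    ds, _ = make_interval_dataset(
        {"a": (0, 1), "b": (2, 3), "c": (0.2, 2.8), "d": (4, 5), "e": (6, 7)},
        n_per_class=10,
    )
    projected = fit_projection(ds, ("a", "e"))
    subs = {s.sequence: s for s in
            screen_suborders(projected, min_sens=1.0, max_len=2)}
    chosen = [subs[("a", "b")], subs[("d", "e")]]
    graph = aggregate_alternatives(chosen, projected, theta=0.0)
    assert len(graph.components) == 2
    comp_labels = sorted(c.labels for c in graph.components)
    assert comp_labels == [("a", "b"), ("d", "e")]


def test_aggregate_boundary_regions(projected_05):
    subs = [s for s in screen_suborders(projected_05, min_sens=1.0)
            if len(s.sequence) >= 5]
    comp = aggregate_alternatives(subs, projected_05, theta=0.0).components[0]
    assert len(comp.boundaries) == 3
    for region, point in zip(comp.boundaries, comp.boundary_points):
        assert region is not None
        assert region.lower < region.upper
    assert comp.boundary_points == sorted(comp.boundary_points)


def test_aggregate_rejects_mixed_projections(projected_05, ten_class_dataset):
    other = fit_projection(ten_class_dataset, ("l1", "l4"))
    subs = list(screen_suborders(projected_05, min_sens=1.0))[:2]
    with pytest.raises(ValueError):
        aggregate_alternatives(subs, other, theta=0.0)


def test_aggregate_requires_source_orientation(projected_05):
    subs = sorted(screen_suborders(projected_05, min_sens=1.0),
                  key=lambda s: s.sequence)[:2]
    flipped = [type(s)(sequence=s.sequence[::-1], cascade=s.cascade,
                       min_sensitivity=s.min_sensitivity,
                       source_pair=s.source_pair, is_maximal=True)
               for s in subs]
    with pytest.raises(ValueError):
        aggregate_alternatives(flipped, projected_05, theta=0.0)
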