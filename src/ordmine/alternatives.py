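"""Shared-threshold equivalence and aggregation into alternative graphs.

Two suborders are parallel routes of one progression when, at each point
of divergence, their cascade thresholds admit a common feasible region:
a *left-shared* threshold separates both branch classes from a common
left neighbor, a *right-shared* one from a common right neighbor.
Equivalent thresholds are merged by transitive closure; the resulting cut
points layer the classes into groups of interchangeable branch units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .dtc_cascade import ThresholdInterval, fit_dtc
from .projection import ProjectedDataset

logger = logging.getLogger("ordmine")

LEFT_SHARED = "left_shared"
RIGHT_SHARED = "right_shared"


@dataclass(frozen=True)
class SharedThreshold:
    """A common feasible cut region for two branch classes and an anchor."""

    kind: str
    anchor_label: str
    branch_labels: tuple
    feasible: ThresholdInterval


@dataclass(eq=False)
class GraphComponent:
    """One connected group of merged suborders: ordered layers of units."""

    labels: tuple
    layers: List[List[tuple]]
    boundaries: List[Optional[ThresholdInterval]]
    boundary_points: List[float]


@dataclass(eq=False)
class AlternativeGraph:
    """Layered DAG merging suborders; parallel units are alternatives."""

    nodes: tuple
    pair: tuple
    components: List[GraphComponent]
    edges: Dict[Tuple[str, str], ThresholdInterval]
    provenance: List[tuple]


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _transition_region(projected: ProjectedDataset, left: str, right: str,
                       theta: float) -> Optional[ThresholdInterval]:
    dtc = fit_dtc(projected.class_values(left), projected.class_values(right),
                  theta, left, right)
    return None if dtc is None else dtc.interval


def thresholds_equivalent(
    tau_i: ThresholdInterval,
    tau_j: ThresholdInterval,
    context: tuple,
    projected: ProjectedDataset,
    theta: float,
) -> Optional[SharedThreshold]:
    """Test whether two cascade thresholds admit a shared cut region.

    ``context`` is ``(l_a, l_b, anchor_label, kind)`` where ``l_a``/``l_b``
    are the branch classes of the two suborders and ``kind`` says on which
    side the anchor neighbors both branches.  The shared region is the
    intersection of the two anchor-to-branch feasible intervals under the
    misclassification budget ``theta`` (at ``theta = 0`` this is exactly
    the region above all anchor values and at or below the minimum of both
    branch classes, or its mirror image).  Returns ``None`` when empty.
    """
    l_a, l_b, anchor, kind = context
    if kind not in (LEFT_SHARED, RIGHT_SHARED):
        raise ValueError(f"unknown shared-threshold kind {kind!r}")
    if len({l_a, l_b, anchor}) != 3:
        raise ValueError("branch classes and anchor must be three distinct labels")
    for l in (l_a, l_b, anchor):
        if l not in projected.labels:
            raise ValueError(f"unknown label {l!r}")
    if kind == LEFT_SHARED:
        r1 = _transition_region(projected, anchor, l_a, theta)
        r2 = _transition_region(projected, anchor, l_b, theta)
    else:
        r1 = _transition_region(projected, l_a, anchor, theta)
        r2 = _transition_region(projected, l_b, anchor, theta)
    if r1 is None or r2 is None:
        return None
    region = r1.intersect(r2)
    if region is None:
        return None
    return SharedThreshold(
        kind=kind,
        anchor_label=anchor,
        branch_labels=(l_a, l_b),
        feasible=region,
    )


def _check_same_projection(suborders, projected):
    for sub in suborders:
        if tuple(sub.source_pair) != tuple(projected.pair):
            raise ValueError(
                f"suborder {sub.sequence} comes from projection pair "
                f"{sub.source_pair}, expected {projected.pair}"
            )
        if tuple(sub.sequence) != tuple(sub.cascade.order):
            raise ValueError(
                "suborders must be aggregated in their source orientation "
                "(canonicalize after aggregation, not before)"
            )


def aggregate_alternatives(suborders, projected: ProjectedDataset,
                           theta: float = 0.0) -> AlternativeGraph:
    """Merge suborders of one projection into a layered alternative graph.

    Thresholds are declared equivalent pairwise (identical transitions, or
    a non-empty left-/right-shared region) and merged transitively.  A cut
    becomes a layer boundary when no suborder of its component bridges it
    without an equivalent threshold of its own; the classes between
    consecutive boundaries form the parallel branch units of one layer.
    """
    subs = sorted(suborders, key=lambda s: s.sequence)
    if not subs:
        raise ValueError("no suborders to aggregate")
    _check_same_projection(subs, projected)

    # thresholds as (suborder index, position); one per adjacent transition
    items: List[Tuple[int, int]] = []
    transition: Dict[Tuple[int, int], Tuple[str, str]] = {}
    for si, sub in enumerate(subs):
        for pos in range(len(sub.sequence) - 1):
            it = (si, pos)
            items.append(it)
            transition[it] = (sub.sequence[pos], sub.sequence[pos + 1])

    uf = _UnionFind(items)
    sub_uf = _UnionFind(range(len(subs)))
    member_sets = [set(s.sequence) for s in subs]

    for i, it_i in enumerate(items):
        for it_j in items[i + 1:]:
            si, sj = it_i[0], it_j[0]
            (u, v), (u2, v2) = transition[it_i], transition[it_j]
            shared = None
            if (u, v) == (u2, v2):
                shared = True
            elif si != sj and u == u2 and v != v2 \
                    and v not in member_sets[sj] and v2 not in member_sets[si]:
                shared = thresholds_equivalent(
                    subs[si].cascade.classifiers[it_i[1]].interval,
                    subs[sj].cascade.classifiers[it_j[1]].interval,
                    (v, v2, u, LEFT_SHARED), projected, theta)
            elif si != sj and v == v2 and u != u2 \
                    and u not in member_sets[sj] and u2 not in member_sets[si]:
                shared = thresholds_equivalent(
                    subs[si].cascade.classifiers[it_i[1]].interval,
                    subs[sj].cascade.classifiers[it_j[1]].interval,
                    (u, u2, v, RIGHT_SHARED), projected, theta)
            if shared:
                uf.union(it_i, it_j)
                sub_uf.union(si, sj)

    # threshold equivalence classes with mean point and merged region
    cut_members: Dict[Tuple[int, int], List[Tuple[int, int]]] = {}
    for it in items:
        cut_members.setdefault(uf.find(it), []).append(it)

    cuts = {}
    for root, members in cut_members.items():
        points = [subs[si].cascade.classifiers[pos].interval.point
                  for si, pos in members]
        region: Optional[ThresholdInterval] = None
        for trans in sorted({transition[m] for m in members}):
            r = _transition_region(projected, trans[0], trans[1], theta)
            if r is None:
                region = None
                break
            region = r if region is None else region.intersect(r)
            if region is None:
                break
        cuts[root] = {
            "members": members,
            "point": float(np.mean(points)),
            "region": region,
            "subs": {si for si, _ in members},
        }

    # class spans on the projection axis (for bridge detection and layering)
    span = {l: (float(np.min(projected.class_values(l))),
                float(np.max(projected.class_values(l))))
            for l in {c for s in subs for c in s.sequence}}

    components: List[GraphComponent] = []
    comp_roots = sorted({sub_uf.find(si) for si in range(len(subs))})
    for comp_root in comp_roots:
        comp_sub_idx = [si for si in range(len(subs))
                        if sub_uf.find(si) == comp_root]
        comp_cuts = [c for root, c in sorted(cuts.items())
                     if c["subs"] <= set(comp_sub_idx)
                     and c["subs"] & set(comp_sub_idx)]

        def bridged(cut) -> bool:
            # a suborder bridges a cut if one of its classes spans the cut
            # point while the suborder holds no member threshold there
            for si in comp_sub_idx:
                if si in cut["subs"]:
                    continue
                for lbl in subs[si].sequence:
                    lo, hi = span[lbl]
                    if lo < cut["point"] < hi:
                        return True
            return False

        boundaries = sorted((c for c in comp_cuts if not bridged(c)),
                            key=lambda c: c["point"])
        b_points = [c["point"] for c in boundaries]

        n_layers = len(boundaries) + 1
        layer_units: List[List[tuple]] = [[] for _ in range(n_layers)]
        for si in comp_sub_idx:
            seq = subs[si].sequence
            lidx = [int(np.searchsorted(b_points,
                                        float(np.median(projected.class_values(c)))))
                    for c in seq]
            unit = [seq[0]]
            for c, li_prev, li in zip(seq[1:], lidx, lidx[1:]):
                if li == li_prev:
                    unit.append(c)
                else:
                    _add_unit(layer_units[li_prev], tuple(unit))
                    unit = [c]
            _add_unit(layer_units[lidx[-1]], tuple(unit))

        layers = [sorted(units) for units in layer_units if units]
        _warn_on_cooccurrence(layers, [subs[si].sequence for si in comp_sub_idx])
        comp_labels = tuple(sorted({c for si in comp_sub_idx
                                    for c in subs[si].sequence}))
        components.append(GraphComponent(
            labels=comp_labels,
            layers=layers,
            boundaries=[c["region"] for c in boundaries],
            boundary_points=b_points,
        ))

    edges: Dict[Tuple[str, str], ThresholdInterval] = {}
    for sub in subs:
        for pos, c in enumerate(sub.cascade.classifiers):
            edges.setdefault((sub.sequence[pos], sub.sequence[pos + 1]),
                             c.interval)

    return AlternativeGraph(
        nodes=tuple(sorted({c for s in subs for c in s.sequence})),
        pair=tuple(projected.pair),
        components=components,
        edges=edges,
        provenance=[s.sequence for s in subs],
    )


def _add_unit(units: list, unit: tuple):
    if unit not in units:
        units.append(unit)


def _warn_on_cooccurrence(layers, sequences):
    for layer in layers:
        if len(layer) < 2:
            continue
        for seq in sequences:
            present = [u for u in layer if set(u) & set(seq)]
            if len(present) > 1:
                logger.warning(
                    "alternative units %s co-occur in suborder %s", present, seq
                )


def suborder_is_path(graph: AlternativeGraph, sequence) -> bool:
    """Whether a class sequence is a directed path through the graph."""
    seq = tuple(sequence)
    return all((seq[i], seq[i + 1]) in graph.edges for i in range(len(seq) - 1))
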