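"""Enumeration of maximal ordinal suborders on a projected dataset.

Candidate class sequences are grown breadth-first by single-class
insertion, pruning every candidate whose cascade is rejected; adjacent-pair
threshold fits are memoized so each ordered pair is fitted at most once.
An exhaustive permutation search is kept as the reference oracle.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

from .datasets_io import LabeledDataset, RunConfig
from .dtc_cascade import Cascade, DTCCache, fit_cascade
from .projection import ProjectedDataset, fit_projection, select_projection_pairs

logger = logging.getLogger("ordmine")


@dataclass(frozen=True)
class Suborder:
    """An accepted class sequence with its cascade and provenance."""

    sequence: tuple
    cascade: Cascade
    min_sensitivity: float
    source_pair: tuple
    is_maximal: bool
    has_reverse: bool = False


def _accepted_sequences(projected: ProjectedDataset, theta: float,
                        max_len: int, method: str) -> dict:
    """Map accepted sequence -> Cascade, for sequences of length >= 2."""
    labels = [l for l in projected.labels]
    cache = DTCCache(projected, theta)

    def accept(seq):
        res = fit_cascade(projected, seq, theta, cache=cache)
        return res if isinstance(res, Cascade) else None

    accepted: dict = {}
    if method == "exhaustive":
        for k in range(2, max_len + 1):
            for subset in itertools.combinations(labels, k):
                for perm in itertools.permutations(subset):
                    cas = accept(perm)
                    if cas is not None:
                        accepted[perm] = cas
        return accepted

    if method != "incremental":
        raise ValueError(f"unknown screening method {method!r}")

    level = {}
    for a, b in itertools.permutations(labels, 2):
        cas = accept((a, b))
        if cas is not None:
            level[(a, b)] = cas
    accepted.update(level)
    k = 2
    while level and k < max_len:
        candidates = set()
        for seq in level:
            free = [l for l in labels if l not in seq]
            for lab in free:
                for pos in range(len(seq) + 1):
                    candidates.add(seq[:pos] + (lab,) + seq[pos:])
        nxt = {}
        for cand in sorted(candidates):
            cas = accept(cand)
            if cas is not None:
                nxt[cand] = cas
        accepted.update(nxt)
        level = nxt
        k += 1
    return accepted


def _maximal(accepted: dict) -> set:
    """Sequences with no accepted single-class insertion extension."""
    non_max = set()
    for seq in accepted:
        for i in range(len(seq)):
            child = seq[:i] + seq[i + 1:]
            if len(child) >= 2 and child in accepted:
                non_max.add(child)
    return set(accepted) - non_max


def screen_suborders(projected: ProjectedDataset, min_sens: float = 1.0,
                     max_len: int | None = None,
                     method: str = "incremental") -> set:
    """All maximal suborders supported by the projection at the given
    sensitivity floor.

    ``method='exhaustive'`` enumerates every ordered subset and is the
    test oracle; the default incremental search prunes via early cascade
    rejection and reuses pairwise threshold fits.
    """
    if not 0.5 <= min_sens <= 1.0:
        raise ValueError("min_sens must lie in [0.5, 1]")
    theta = 1.0 - min_sens
    if max_len is None:
        max_len = len(projected.labels)
    accepted = _accepted_sequences(projected, theta, max_len, method)
    maximal = _maximal(accepted)
    return {
        Suborder(
            sequence=seq,
            cascade=accepted[seq],
            min_sensitivity=accepted[seq].min_sensitivity,
            source_pair=projected.pair,
            is_maximal=True,
        )
        for seq in maximal
    }


def canonicalize(suborders, report_reversed: bool = False,
                 orient: bool = True) -> set:
    """Resolve mirror-duplicate sequences from opposite projections.

    Of each ``{sequence, reverse(sequence)}`` pair only the
    lexicographically smaller orientation is kept (reversed orders are
    artifacts of mirroring the projection axis), flagged via
    ``has_reverse`` when both orientations were present;
    ``report_reversed=True`` keeps both, tagged as mutual reverses.
    With ``orient=True`` sequences without a mirror partner are also
    rewritten to their canonical orientation, which makes canonical sets
    from opposite projections identical; ``orient=False`` preserves the
    source orientation (required if the result feeds aggregation).
    Cascades always stay as fitted on their source orientation.
    """
    by_key = {}
    for sub in suborders:
        key = min(sub.sequence, sub.sequence[::-1])
        by_key.setdefault(key, []).append(sub)
    out = set()
    for key, subs in sorted(by_key.items()):
        seqs = {s.sequence for s in subs}
        mirrored = len(seqs) > 1
        if report_reversed:
            for s in subs:
                out.add(replace(s, has_reverse=mirrored))
        else:
            keep = min(subs, key=lambda s: s.sequence)
            if orient:
                keep = replace(keep, sequence=key)
            out.add(replace(keep, has_reverse=mirrored))
    return out


def screen_all_pairs(dataset: LabeledDataset, config: RunConfig) -> dict:
    """Run projection + screening for every selected pair."""
    if isinstance(config.projection_pairs, str):
        pairs = select_projection_pairs(dataset, config.projection_pairs)
    else:
        pairs = select_projection_pairs(dataset, "explicit",
                                        explicit=config.projection_pairs)
    results = {}
    for pair in pairs:
        projected = fit_projection(dataset, pair)
        subs = screen_suborders(
            projected,
            min_sens=config.min_sensitivity,
            max_len=config.max_order_length,
        )
        longest = max((len(s.sequence) for s in subs), default=0)
        logger.info("pair (%s, %s): %d maximal suborder(s), longest %d",
                    pair[0], pair[1], len(subs), longest)
        results[pair] = subs
    return results
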