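"""Data model, delimited-text readers/writers and run configuration.

A :class:`LabeledDataset` is the universal input of the pipeline: a real
``N x d`` matrix with one opaque string label per sample.  Matrices are
exchanged as delimited text (TSV or CSV) with sample identifiers in the
header row or column; labels travel in a two-column table
(``sample_id``, ``label``).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ordmine")

SAMPLES_IN_ROWS = "samples_in_rows"
SAMPLES_IN_COLUMNS = "samples_in_columns"


class DatasetError(ValueError):
    """Raised for malformed or inconsistent dataset inputs."""


@dataclass(eq=False)
class LabeledDataset:
    """Samples x features matrix with per-sample class labels.

    Parameters
    ----------
    sample_ids : sequence of str
        One opaque identifier per sample (row of ``X``).
    X : ndarray of shape (N, d)
        Real-valued feature matrix; missing values are rejected.
    y : sequence of str
        Class label per sample; every value must occur in ``labels``.
    labels : sequence of str
        The ordered list of distinct class labels.
    """

    sample_ids: tuple
    X: np.ndarray
    y: np.ndarray
    labels: tuple

    def __post_init__(self):
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        self.labels = tuple(str(l) for l in self.labels)
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray([str(v) for v in self.y], dtype=object)
        if self.X.ndim != 2:
            raise DatasetError("X must be a 2-D matrix")
        n = self.X.shape[0]
        if len(self.sample_ids) != n or len(self.y) != n:
            raise DatasetError(
                f"inconsistent sizes: {len(self.sample_ids)} ids, "
                f"{n} matrix rows, {len(self.y)} labels"
            )
        if len(set(self.sample_ids)) != n:
            raise DatasetError("duplicate sample id")
        if len(set(self.labels)) != len(self.labels):
            raise DatasetError("duplicate class label")
        present = set(self.y)
        unknown = present - set(self.labels)
        if unknown:
            raise DatasetError(f"labels missing from label list: {sorted(unknown)}")
        empty = [l for l in self.labels if l not in present]
        if empty:
            raise DatasetError(f"classes without samples: {empty}")
        if not np.all(np.isfinite(self.X)):
            i, j = np.argwhere(~np.isfinite(self.X))[0]
            raise DatasetError(
                f"missing/non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature column {j}"
            )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_matrix(self, label: str) -> np.ndarray:
        """Rows of ``X`` belonging to one class."""
        if label not in self.labels:
            raise DatasetError(f"unknown label {label!r}")
        return self.X[self.y == label]

    def subset(self, labels: Iterable[str]) -> "LabeledDataset":
        """Restriction to the samples of the given classes (order kept)."""
        labels = [str(l) for l in labels]
        for l in labels:
            if l not in self.labels:
                raise DatasetError(f"unknown label {l!r}")
        mask = np.isin(self.y, labels)
        return LabeledDataset(
            sample_ids=tuple(np.asarray(self.sample_ids, dtype=object)[mask]),
            X=self.X[mask],
            y=self.y[mask],
            labels=tuple(labels),
        )

    def equals(self, other: "LabeledDataset") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.labels == other.labels
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.X, other.X)
        )


@dataclass
class RunConfig:
    """Pipeline-wide settings; ``theta`` is always derived from the
    sensitivity floor (``theta = 1 - min_sensitivity``)."""

    min_sensitivity: float = 1.0
    projection_pairs: object = "all"  # "all" | "most_distant" | list of pairs
    max_order_length: int | None = None
    report_reversed: bool = False
    seed: int = 0
    theta: float = field(init=False)

    def __post_init__(self):
        if not 0.5 <= self.min_sensitivity <= 1.0:
            raise ValueError("min_sensitivity must lie in [0.5, 1]")
        self.theta = 1.0 - self.min_sensitivity


# ---------------------------------------------------------------------------
# delimited-text I/O


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _read_table(path: str) -> pd.DataFrame:
    # C engine + round_trip keeps floats bit-exact across write/read cycles
    return pd.read_csv(path, sep=_sniff_sep(path), index_col=0,
                       float_precision="round_trip")


def read_dataset(
    matrix_path: str,
    labels_path: str,
    orientation: str = SAMPLES_IN_COLUMNS,
) -> LabeledDataset:
    """Read a matrix + label table pair from delimited text.

    Samples present in only one of the two files are dropped with a logged
    warning; zero matched samples or duplicated identifiers are fatal.
    The default orientation follows the GEO series-matrix convention
    (samples in columns).
    """
    if orientation not in (SAMPLES_IN_ROWS, SAMPLES_IN_COLUMNS):
        raise DatasetError(f"unknown orientation {orientation!r}")
    df = _read_table(matrix_path)
    if orientation == SAMPLES_IN_COLUMNS:
        df = df.T
    df.index = df.index.map(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise DatasetError(f"duplicate sample id {dup!r} in matrix")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna().to_numpy()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DatasetError(
            f"non-numeric cell at sample {df.index[i]!r}, "
            f"feature {df.columns[j]!r}: {df.iat[i, j]!r}"
        )

    lab = pd.read_csv(labels_path, sep=None, engine="python")
    if not {"sample_id", "label"} <= set(lab.columns):
        raise DatasetError("label table must have columns 'sample_id' and 'label'")
    lab["sample_id"] = lab["sample_id"].map(str)
    if lab["sample_id"].duplicated().any():
        dup = lab["sample_id"][lab["sample_id"].duplicated()].iloc[0]
        raise DatasetError(f"duplicate sample id {dup!r} in label table")

    matrix_ids = list(df.index)
    label_map = dict(zip(lab["sample_id"], lab["label"].map(str)))
    matched = [s for s in matrix_ids if s in label_map]
    dropped_m = [s for s in matrix_ids if s not in label_map]
    dropped_l = [s for s in lab["sample_id"] if s not in set(matrix_ids)]
    if dropped_m:
        logger.warning(
            "dropping %d matrix sample(s) without labels: %s",
            len(dropped_m), dropped_m[:5],
        )
    if dropped_l:
        logger.warning(
            "dropping %d labeled sample(s) absent from matrix: %s",
            len(dropped_l), dropped_l[:5],
        )
    if not matched:
        raise DatasetError("zero samples matched between matrix and label table")

    y = [label_map[s] for s in matched]
    labels = list(dict.fromkeys(label_map[s] for s in lab["sample_id"] if s in set(matched)))
    return LabeledDataset(
        sample_ids=tuple(matched),
        X=numeric.loc[matched].to_numpy(dtype=float),
        y=np.asarray(y, dtype=object),
        labels=tuple(labels),
    )


def write_dataset(
    dataset: LabeledDataset,
    matrix_path: str,
    labels_path: str,
    orientation: str = SAMPLES_IN_COLUMNS,
) -> None:
    """Write a dataset back to delimited text, full float precision."""
    df = pd.DataFrame(
        dataset.X,
        index=list(dataset.sample_ids),
        columns=[f"f{j}" for j in range(dataset.n_features)],
    )
    if orientation == SAMPLES_IN_COLUMNS:
        df = df.T
    df.to_csv(matrix_path, sep="\t", float_format=None)
    pd.DataFrame(
        {"sample_id": list(dataset.sample_ids), "label": list(dataset.y)}
    ).to_csv(labels_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result serialization (suborder report + alternative graph)


def _interval_to_json(iv) -> dict:
    return {"lower": iv.lower, "upper": iv.upper, "point": iv.point}


def suborder_to_json(sub) -> dict:
    return {
        "sequence": list(sub.sequence),
        "source_pair": list(sub.source_pair),
        "min_sensitivity": sub.min_sensitivity,
        "is_maximal": sub.is_maximal,
        "has_reverse": sub.has_reverse,
        "sensitivities": {l: s for l, s in sub.cascade.sensitivity_items},
        "classifiers": [
            {
                "left_label": c.left_label,
                "right_label": c.right_label,
                "left_sens": c.left_sens,
                "right_sens": c.right_sens,
                "interval": _interval_to_json(c.interval),
            }
            for c in sub.cascade.classifiers
        ],
    }


def suborder_from_json(obj) -> "Suborder":
    from .dtc_cascade import Cascade, DirectedThresholdClassifier, ThresholdInterval
    from .screening import Suborder

    classifiers = tuple(
        DirectedThresholdClassifier(
            left_label=c["left_label"],
            right_label=c["right_label"],
            interval=ThresholdInterval(
                lower=c["interval"]["lower"],
                upper=c["interval"]["upper"],
                point=c["interval"]["point"],
            ),
            left_sens=c["left_sens"],
            right_sens=c["right_sens"],
        )
        for c in obj["classifiers"]
    )
    order = tuple(obj["sequence"])
    cascade_order = (classifiers[0].left_label,) + tuple(
        c.right_label for c in classifiers
    )
    cascade = Cascade(
        order=cascade_order,
        classifiers=classifiers,
        sensitivity_items=tuple(sorted(obj["sensitivities"].items())),
    )
    return Suborder(
        sequence=order,
        cascade=cascade,
        min_sensitivity=obj["min_sensitivity"],
        source_pair=tuple(obj["source_pair"]),
        is_maximal=obj["is_maximal"],
        has_reverse=obj.get("has_reverse", False),
    )


def write_suborders(suborders, path: str) -> None:
    records = sorted(
        (suborder_to_json(s) for s in suborders),
        key=lambda r: (tuple(r["source_pair"]), tuple(r["sequence"])),
    )
    with open(path, "w") as fh:
        json.dump({"schema": "ordmine.suborders/1", "suborders": records}, fh,
                  indent=1, sort_keys=True)
        fh.write("\n")


def load_suborders(path: str):
    with open(path) as fh:
        obj = json.load(fh)
    return [suborder_from_json(r) for r in obj["suborders"]]


def graph_to_json(graph) -> dict:
    return {
        "schema": "ordmine.graph/1",
        "nodes": list(graph.nodes),
        "pair": list(graph.pair),
        "components": [
            {
                "layers": [[list(u) for u in layer] for layer in comp.layers],
                "boundaries": [
                    _interval_to_json(b) if b is not None else None
                    for b in comp.boundaries
                ],
            }
            for comp in graph.components
        ],
        "edges": [
            {"from": u, "to": v, "interval": _interval_to_json(iv)}
            for (u, v), iv in sorted(graph.edges.items())
        ],
        "suborders": [list(s) for s in graph.provenance],
    }


def graph_to_dot(graph) -> str:
    """Render the layered alternative graph as Graphviz DOT text.

    Units of the same layer are emitted as one ``rank=same`` group so that
    parallel alternatives line up vertically.
    """
    lines = ["digraph alternatives {", "  rankdir=LR;", "  node [shape=box];"]
    for node in graph.nodes:
        lines.append(f'  "{node}";')
    for (u, v), iv in sorted(graph.edges.items()):
        lines.append(f'  "{u}" -> "{v}" [label="({iv.lower:.6g}, {iv.upper:.6g}]"];')
    for ci, comp in enumerate(graph.components):
        for li, layer in enumerate(comp.layers):
            members = sorted({lbl for unit in layer for lbl in unit})
            quoted = " ".join(f'"{m}";' for m in members)
            lines.append(f"  {{ rank=same; {quoted} }}  /* component {ci} layer {li} */")
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_results(suborders, graph, out_dir: str) -> None:
    """Emit the suborder report plus DOT/JSON renderings of the graph."""
    try:
        os.makedirs(out_dir, exist_ok=True)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise DatasetError(f"cannot create output directory {out_dir!r}: {exc}")
    if not os.access(out_dir, os.W_OK):
        raise DatasetError(f"output directory {out_dir!r} is not writable")
    write_suborders(suborders, os.path.join(out_dir, "suborders.json"))
    if graph is not None:
        with open(os.path.join(out_dir, "graph.json"), "w") as fh:
            json.dump(graph_to_json(graph), fh, indent=1, sort_keys=True)
            fh.write("\n")
        with open(os.path.join(out_dir, "graph.dot"), "w") as fh:
            fh.write(graph_to_dot(graph))
    with open(os.path.join(out_dir, "report.txt"), "w") as fh:
        for s in sorted(suborders, key=lambda s: (s.source_pair, s.sequence)):
            fh.write(
                f"pair={'|'.join(s.source_pair)}\t"
                f"order={' < '.join(s.sequence)}\t"
                f"min_sens={s.min_sensitivity:.6g}\t"
                f"thresholds={[round(c.interval.point, 9) for c in s.cascade.classifiers]}\n"
            )
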