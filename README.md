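# ordmine

Mining total and partial ordinal class structures in labeled molecular
data (bulk or single-cell expression matrices, or any samples × features
table with class labels).

The pipeline:

1. **Projection** — all samples are mapped to one dimension along the
   max-margin normal of a linear SVM trained on a chosen *projection pair*
   of classes (`ordmine.projection`).
2. **Directed threshold classifiers & cascades** — one-dimensional binary
   threshold rules (`x >= τ` → right class) chained over a candidate class
   sequence with strictly increasing cut points; fitting tolerates a
   per-class misclassification budget `θ = 1 − min_sensitivity`
   (`ordmine.dtc_cascade`).
3. **Screening** — breadth-first enumeration of all maximal suborders
   (class sequences whose cascade keeps every class-wise sensitivity at or
   above the floor), with early rejection, memoized pairwise fits and
   canonicalization of mirror-image duplicates (`ordmine.screening`).
4. **Alternatives** — suborders sharing left-/right-shared threshold
   regions are merged into a layered alternative-progression graph whose
   parallel units are interchangeable branches (`ordmine.alternatives`).
5. **Validation** — an independent total-order detector based on pairwise
   separability matrices with row-monotonicity toward the diagonal
   cross-checks the longest suborders (`ordmine.order_validation`).

A synthetic generator (`ordmine.synthetic_data`) produces branching
benchmarks with brute-force ground truth, including the ten-class
two-feature fixture with two parallel ordinal chains used throughout the
test suite.

## CLI

```sh
# synthetic benchmark (matrix.tsv, labels.tsv, ground_truth.json)
ordmine simulate --out sim/ --n-per-class 100 --seed 1

# full pipeline on the most distant class pair
ordmine run --matrix sim/matrix.tsv --labels sim/labels.tsv \
    --pairs most_distant --out results/

# step by step
ordmine project --matrix sim/matrix.tsv --labels sim/labels.tsv \
    --pair l0,l5 --out proj/
ordmine screen  --matrix sim/matrix.tsv --labels sim/labels.tsv \
    --pair l0,l5 --min-sensitivity 1.0 --out scr/
ordmine aggregate --suborders scr/suborders.json \
    --projected proj/projected_l0_l5.tsv --out agg/
ordmine validate --matrix sim/matrix.tsv --labels sim/labels.tsv \
    --suborders scr/suborders.json --score fisher --out val/
```

Matrices are delimited text (TSV or CSV) with sample identifiers in the
header row or column (`--orientation`, default `samples_in_columns`,
matching the GEO series-matrix convention); labels are a two-column table
(`sample_id`, `label`). Use `--orientation samples_in_rows` for matrices
with one sample per row; `ordmine simulate` writes the default
samples-in-columns layout.

Outputs: `suborders.json` (documented schema `ordmine.suborders/1`,
round-trips exactly), `graph.json` + `graph.dot` (layered alternative
graph; parallel units share a `rank=same` group), `report.txt`,
`ordmine.log`.

## Library example

```python
from ordmine import (make_ten_class_fixture, fit_projection,
                     screen_suborders, aggregate_alternatives)

dataset, truth = make_ten_class_fixture(n_per_class=100, seed=1)
projected = fit_projection(dataset, ("l0", "l5"))
suborders = screen_suborders(projected, min_sens=1.0)
graph = aggregate_alternatives(
    [s for s in suborders if len(s.sequence) >= 5], projected, theta=0.0)
for layer in graph.components[0].layers:
    print(layer)
```
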