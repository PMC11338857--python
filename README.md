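# topoqspr

Degree-based topological indices and QSPR regression for drug-repurposing
descriptor screening.

QSPR (quantitative structure–property relationship) modelling correlates
numerical descriptors of molecular structure with physicochemical properties.
This package targets the descriptor family computable from nothing but a
molecule's hydrogen-suppressed graph *G(V, E)* — heavy atoms as vertices,
covalent bonds as edges, bond order ignored — and a study set of fifteen
approved non-oncology drugs screened for repurposing potential (thalidomide,
aspirin, valproic acid, celecoxib, metformin, simvastatin, …).

Six indices are implemented, each a function of the edge partition (edge
counts per unordered endpoint-degree pair) or the degree spectrum:

* **ABC−R** = Σ_{st∈E} (√(d_s+d_t−2) − 1)/√(d_s d_t) — atom-bond-connectivity
  minus Randić;
* **GA** = Σ 2√(d_s d_t)/(d_s+d_t) — geometric over arithmetic mean of
  endpoint degrees;
* **SDD** = Σ (d_s²+d_t²)/(d_s d_t) — symmetric division degree;
* **EΠ₁** = Π_{v∈V} e^(d_v²) and **EΠ₂** = Π_{st∈E} e^(d_s d_t) —
  multiplicative exponential Zagreb indices, carried as their exact integer
  logarithms (values reach 10¹¹⁴);
* **GAΠ** — multiplicative GA, in the class-wise operational form that the
  published tables use, with the literal per-edge product as a named variant.

Each index is then related to six properties (melting and boiling point,
water solubility, density, vapour pressure, molecular weight) by ordinary
least squares under three families — P = A + bTI, P = A + bTI + cTI², and
P = A + b ln TI — with the conventional report per fit: A, b, c, r, r², F and
its p-value. Designs made meaningless by the exponential indices'
magnitudes raise a degenerate-fit diagnostic instead of printing zeros.
The packaged dataset ships the published per-drug index table verbatim
together with an errata layer documenting its internally inconsistent cells.

## Worked example

Thalidomide's fixture graph has 19 heavy atoms and 21 bonds:

```python
from topoqspr import dataset, indices, qspr
from topoqspr.molgraph import edge_partition

rec = dataset.load_builtin_drugs()[0]          # Thalidomide
print(edge_partition(rec.graph))
# {(1, 3): 4, (2, 2): 4, (2, 3): 6, (3, 3): 7}

for name, v in indices.compute_all(rec.graph).items():
    print(name, v.rendered(6) if name in ("EPi1", "EPi2") else round(v.linear_value, 4))
# ABC-R  5.9115
# GA     20.3429
# EPi1   1.46766E45
# EPi2   1.43021E55
# GAPi   570.213
# SDD    48.3333
```

Four edges join a degree-1 to a degree-3 atom, four join 2–2, six join 2–3
and seven join 3–3; the four additive/multiplicative index values above
follow from those frequencies alone, and the exponential indices from the
integer sums Σd² = 104 and Σd_s d_t = 127.

Fitting molecular weight on the SDD column of the published table:

```python
res = qspr.fit_all("published").result("SDD", "MW", "linear")
print(res.row())
# {'N': 15, 'A': 25.43, 'b': 4.962, 'c': '', 'r': 0.979, 'r2': 0.958, 'F': 299.562, 'P': 0.0}
```

i.e. MW ≈ 25.43 + 4.962·SDD explains 95.8 % of the molecular-weight variance
across the fifteen drugs, with an overall F(1, 13) near 300 — molecular
weight is by far the best-modelled property; melting point, density and
vapour pressure correlate only weakly with every index.

## Command line

```sh
topoqspr indices drug1.edges drug2.edges -o out/   # descriptor CSV
topoqspr fit --index-csv x.csv --property-csv y.csv \
         --index-col SDD --property-col MW --family linear -o out/
topoqspr reproduce -o out/                          # full study regeneration
topoqspr simulate --seed 7 -o out/                  # synthetic data + ground truth
```

`reproduce` regenerates the computed index table, the per-index regression
tables, the published-vs-computed discrepancy report and an anchor summary;
it exits nonzero if any printed anchor value is not met, listing the deltas
(one printed intercept is known not to be recoverable from the printed
inputs — see `docs/methods.md`).

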