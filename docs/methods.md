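# Methods

## The model

`topoqspr` implements a quantitative structure–property relationship (QSPR)
workflow built on degree-based topological indices of hydrogen-suppressed
molecular graphs. A molecule is reduced to the simple graph *G(V, E)* of its
heavy atoms: hydrogens are dropped, bond order is ignored (a double bond is
one edge), and the degree of a vertex counts its distinct heavy-atom
neighbours. Every index depends on the graph only through two summaries — the
degree spectrum (vertex counts per degree) and the edge partition (edge counts
per unordered endpoint-degree pair (d_s, d_t)) — so all evaluation is
class-wise over the partition, with brute-force per-edge evaluation retained
as a test oracle.

The six indices, for an edge {s, t} with endpoint degrees d_s, d_t:

| index | per-edge / per-vertex term | aggregate |
|-------|---------------------------|-----------|
| ABC−R | (√(d_s+d_t−2) − 1)/√(d_s d_t) | edge sum |
| GA    | 2√(d_s d_t)/(d_s+d_t) | edge sum |
| SDD   | (d_s²+d_t²)/(d_s d_t) | edge sum |
| EΠ₁   | e^(d²) per vertex | product |
| EΠ₂   | e^(d_s d_t) per edge | product |
| GAΠ   | 2√(d_s d_t)/(d_s+d_t) | product (see below) |

EΠ₁ and EΠ₂ reach 10¹¹⁴ on the study molecules, far past any meaningful
floating-point product, so they are carried as their natural logarithms —
exact integers, ln EΠ₁ = Σ d² and ln EΠ₂ = Σ d_s d_t, computed in integer
arithmetic — and rendered as mantissa × 10^exponent on demand. Linear-scale
values are materialised only below ln ≈ 700 (the float64 overflow boundary).

### The two GAΠ readings

The defining formula for GAΠ is a per-edge product of terms in (0, 1], which
is therefore itself at most 1. The published computations instead multiply,
over *distinct* partition classes, frequency × GA-term — for thalidomide
3.4641 × 4 × 5.8788 × 7 = 570.213. Both are implemented; `ga_pi_classwise` is
the default because only it reproduces the published values, and
`ga_pi_edgewise` is the literal variant. The published arithmetic evaluates
each class factor to four decimal places before multiplying; with that
convention (`factor_decimals=4`, the default) the computed GAΠ column matches
the published one digit-for-digit in 10 of 15 rows and to ≤5×10⁻⁴ relative in
all verifiable rows. `factor_decimals=None` gives the full-precision product
(570.211 for thalidomide).

## The packaged dataset and its errata layer

Fifteen repurposing-candidate drugs are shipped as plain-text edge lists with
JSON sidecars, together with their six physicochemical properties
(MP, BP in °C; WS in mg/mL; D in g/cm³; VP in mmHg; MW in g/mol — used
verbatim, including a physically implausible WS for methotrexate) and the
published per-drug index table.

The published table contains internal inconsistencies, so fixtures were
frozen in two steps. For nine drugs the standard 2D structure reproduces the
row's trustworthy cells (ABC−R and SDD, cross-checked against GA and the
exponential cells) and the fixture is that structure, transcribed via its
SMILES (kept in the sidecar for documentation). For six drugs
(wortmannin, minocycline, thiocolchicoside, noscapine, vesnarinone,
simvastatin) no standard structure matches the published row; however, the
exponential cells of those rows equal e^integer exactly, fixing Σ d² and
Σ d_s d_t, and an exact integer search over edge partitions (on the lattice
of Σ d_s d_t and 12·SDD, filtered by realizability and the remaining cells)
yields a *unique* partition per drug consistent with the full row. The
fixture is then a connected graph realising that partition (joint-degree
construction plus degree-preserving rewiring), shipped with `.synthetic.` in
its file name and flagged `reconstructed-from-published-partition` in the
sidecar. These graphs reproduce the published descriptor row; they are not
claimed to be the drug's chemical structure.

Cells that still fail verification are flagged in an errata layer with the
row-consistent value and a note; notable entries are thalidomide's GA
(printed 2.3429 vs the worked example's 20.3429), celecoxib's ABC−R (printed
9.2836; every other cell of the row matches the standard structure, whose
ABC−R is 8.5637) and noscapine's SDD (printed 70.75; the row-consistent value
is 75.75, a digit slip). A discrepancy report classifies every cell as
`match` (≤5×10⁻⁴ relative, log-scale for the exponential indices),
`rounding` (≤5×10⁻³) or `erratum`.

## Regression

Each property is regressed on each index under three families,
P = A + b·TI, P = A + b·TI + c·TI², and P = A + b·ln TI, by ordinary least
squares (statsmodels behind the module surface; a normal-equations solve
serves as the test oracle). Reported statistics are the correlation r (signed
by the slope for single-predictor families; the non-negative multiple
correlation for the quadratic), r², the overall F with (k, n−k−1) degrees of
freedom (k = 1 or 2), and the upper-tail F p-value. Printed-style tables
round to 3 decimals, so p prints as 0.000 below 0.0005; full-precision JSON
is emitted alongside. No multiple-testing correction is applied — the study
design fits 108 models and reports each marginally; the tables should be read
accordingly.

Designs are screened by a 2-norm condition number with a documented limit of
1e12: ample for every legitimate design here (the worst, quadratic in GAΠ,
sits near 1e8) and categorically failed by linear/quadratic designs in the
exponential indices (condition ≥1e30, or non-finite squares). Such fits raise
a degenerate-fit error carrying the diagnostic rather than printing zero
coefficients; the published all-zero/r = 1.000 quadratic block for EΠ₂ is
deliberately not reproduced. Logarithmic models for the exponential indices
regress on the exact integer ln values instead.

Regressions can be fed three input variants: `computed` (from the fixture
graphs), `published` (the printed table verbatim) and
`published_with_corrections` (errata cells replaced). The reproduction
default is `published`, because the printed regression rows are recovered
from the printed columns (including their erroneous cells) and not from the
corrected ones — e.g. the MW-on-ABC−R F statistic is 249.3 with the printed
column (printed: 249.667) but 271.3 with the corrected celecoxib value.
Residual deviations of ~0.04 in intercepts (e.g. 50.645 vs the printed
50.608) persist under every plausible input variant and are treated as an
irreducible provenance gap of the printed rows; slopes, r, r² and F reproduce
at printed precision. Printed BP rows fail a through-the-means audit at ~2%
and are reported but not used as anchors.

## Synthetic data

The generator emulates only the statistical structure the regression stage
assumes. Graphs: a uniform random labelled tree (Prüfer sequence, rejected
until the degree cap holds) plus random extra edges subject to max degree 4 —
connected, simple, valence-capped, deterministic per seed. It does not
emulate chemistry: no element types, ring statistics or valence-per-element
rules, so passing tests demonstrate correctness of the graph→index→fit
pipeline, not chemical realism. Properties: P = family(A, b, c)(TI) + ε with
ε ~ N(0, σ²). Defaults mirror the packaged study — 15 molecules, 9–39
vertices (the fixture range), descriptor values spanning the observed ABC−R
range, and the molecular-weight model's coefficients (A = 50.608, b = 38.815)
with σ = 30 g/mol, the residual scale of that fit. σ = 0 must recover
coefficients to 1e−9; at study noise the slope estimator is unbiased within
Monte-Carlo error over 1000 seeded replicates.

## Numerical choices and limitations

* Edge classes are unordered (min, max) pairs; all index terms are symmetric.
* Disconnected input is rejected by default (`allow_disconnected=True` exists
  for deliberate use); self-loops and duplicate edges are always errors.
* ABC−R can be negative on degree-1–degree-1 edges (K₂ gives −1), so it
  bypasses the log-domain carrier.
* The condition limit (1e12) and the match/rounding thresholds (5×10⁻⁴ /
  5×10⁻³ relative) are the only free tolerances; both are far from every
  decision boundary they guard.
* The six reconstructed fixtures realise a degree partition, not a chemical
  structure; any analysis that depends on more than degree information would
  need true structures.
* Properties and published cells are transcribed table values; no external
  database is consulted at runtime.
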