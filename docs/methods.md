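# Methods

This note documents the models implemented in `zefmea`, the defaults and
why they were chosen, the numerical choices, and what the bundled case
study and synthetic generator do and do not exercise.

## Fuzzy algebra

All quantities are triangular fuzzy numbers (TFNs) `(l, m, u)` with
`l ≤ m ≤ u`. Addition, nonnegative scalar multiplication, and
multiplication/division of nonnegative operands preserve the ordering;
subtraction uses the interval-widening rule `(l1-u2, m1-m2, u1-l2)`, which
is always order-preserving for valid inputs. Multiplication and division
are defined componentwise and restricted to nonnegative (resp. strictly
positive) operands: every scale in the package is nonnegative, and the only
signed quantities (MABAC distances and scores) are produced exclusively by
subtraction and addition. Degenerate TFNs (`l = m = u`) reduce every
operation to crisp arithmetic, which is exploited by the crisp-limit test
oracles.

Two defuzzifiers are exposed:

* **GMIR** `(l + 4m + u)/6` — used for crisp reliability values and for the
  weight-normalisation constraint in the BWM program;
* **centroid** `(l + m + u)/3` — the default for final scores, because it
  reproduces the defuzzified score columns of the case study's reference
  rankings to ±0.01, whereas GMIR deviates by up to ~0.02 there. Both are
  available via configuration.

## Linguistic scales

Three built-in scales (also shipped as `data/scales.yaml`; custom scales
load from YAML/JSON):

| scale | terms | values |
|---|---|---|
| importance | EI, WI, FI, I, VI, AI | (1,1,1) … (4.5,5,5.5), each with a consistency index 3.00 … 9.35 |
| reliability | VL, L, M, H, VH | (0,0,0.3), (0.1,0.3,0.5), (0.3,0.5,0.7), (0.5,0.7,0.9), (0.7,1,1) |
| rating | VL, L, ML, M, MH, H, VH | (0,1,2), (1,2,3), (2,3.5,5), (4,5,6), (5,6.5,8), (7,8,9), (8,9,10) |

The rating scale is reverse-engineered: the case-study source never prints
it. Dividing the published converted matrix cells by the recomputed
`sqrt(b*)` recovers these triples exactly (e.g. the A12/TM3 severity cell
`(0.00, 0.76, 1.52) / 0.760 = (0, 1, 2)`), so the scale above ships as the
default and is configurable like any other.

## ZE conversion chain

`b = gmir(B)`; `R = (Y-N)/(n-θ)` (undefined and rejected when every voter
is neutral); `b* = b(1+R)` for `R<0`, `b` for `R=0`, `1-(1-b)(1-R)` for
`R>0`; converted rating `A* = sqrt(b*)·A`. The square-root discount is the
standard Z-number-to-fuzzy conversion; it is confirmed against the
published converted matrix, and makes `gmir(A*) = sqrt(b*)·gmir(A)` exactly
(scaling commutes with defuzzification). The adjustment map is continuous
at `R = 0`, monotone nondecreasing in `R`, and keeps `b*` in [0, 1].

One vote triple applies to an expert's whole (S, O, D) row for a failure
mode — the panel votes on the overall assessment, not per criterion — but
the conversion API accepts per-cell votes for generality. The plain
Z-variant runs the same chain with `b* = b` (consensus treated as neutral).

### Case-study errata

The bundled fixture stores its source tables verbatim and corrects two
misprints on load (`zefmea.fmea.VOTE_ERRATA`, `RELIABILITY_TERM_ERRATA`):

* the A30/TM2 vote triple is printed (5, 4, 1), which sums to 10 rather
  than the panel size 12 and contradicts its own printed consensus ratio
  −0.11; the corrected triple (4, 5, 3) satisfies both constraints and
  matches the other two experts' rows;
* two judgment cells carry reliability terms ("ML", "MH") that are not on
  the five-term reliability scale; both are mapped to "M", the value their
  published converted cells correspond to.

### Known reproduction limit

Recomputing the full converted matrix from the raw judgments reproduces the
published cells exactly for VL-reliability rows and to ≤2% for M/VH rows,
but deviates systematically (up to ~8%) for L- and some H-reliability
cells: the published values imply crisp reliabilities of 0.35 (L), 0.5165
(M), ~0.73 (H) and ~0.96 (VH), which match no standard defuzzification of
the stated reliability TFNs (GMIR, centroid and possibilistic mean all give
0.3 / 0.5 / 0.7 / 0.95). A handful of published cells are additionally
inconsistent with their own stated rating terms. The package keeps the
principled GMIR contract rather than fitting unexplained constants; the
corresponding full-matrix test documents the discrepancy by failing, and
the downstream pipeline is unaffected because the published *aggregated*
initial matrix is the input of record for ranking.

## Fuzzy BWM

Decision variables are `(l_j, m_j, u_j)` per criterion plus the scalar
objective `ξ`. Constraints: componentwise `|w̃_B ⊘ w̃_j − ã_Bj| ≤ ξ` and
`|w̃_j ⊘ w̃_W − ã_jW| ≤ ξ` with fuzzy division `(l_B/u_j, m_B/m_j, u_B/l_j)`
(absolute values linearised into paired inequalities), `Σ_j gmir(w̃_j) = 1`,
`l_j ≤ m_j ≤ u_j`, `l_j ≥ 10⁻⁶` (the floor prevents division blow-up). The
program is nonconvex and solved by SLSQP from 32 seeded multistarts
(uniform start plus Dirichlet draws), keeping the best feasible incumbent
with constraint violation below 10⁻⁸; objective ties break towards the
lexicographically smallest weight vector so repeated runs with the same
seed are bit-identical. The best-vs-worst term for `CR = ξ*/CI` is read
from the BO vector's entry at the worst criterion.

Validation intentionally does **not** force the best-vs-worst comparison to
be the maximal term: internally inconsistent panels (the case study's TM1
gives best-vs-worst = WI while an OW entry reaches FI) are retained and
surfaced through a large CR instead. Two of the three case-study panels are
inconsistent in this sense (CR 0.38 and 0.46); their defuzzified weight
*orderings* nevertheless match the published per-expert weights (TM1:
D>S>O, TM2: S>O>D, TM3: O>D>S), which — together with sum-to-one and the
crisp closed-form oracle — is the acceptance contract for this module. The
published weight *cells* are not desk-reproducible: they depend on an
unstated solver and an unstated reliability treatment of the comparisons.
When reliability/vote annotations for comparisons are supplied, an optional
pre-step scales each comparison TFN by `sqrt(b*)` exactly as in the rating
conversion; the bundled comparisons carry no annotations and are treated as
fully reliable.

Experts are aggregated by the componentwise arithmetic mean of their fuzzy
weights, renormalised so the GMIRs sum to one.

## Fuzzy MABAC

* **Normalization** is columnwise min–max on each component:
  `(x − x⁻)/(x⁺ − x⁻)` with `x⁻` the column minimum of lower bounds and
  `x⁺` the maximum of upper bounds (flipped for cost criteria; all three
  FMEA criteria are benefit-type — higher S/O/D means higher risk). This is
  the default because it reproduces the case study's published normalized
  matrix to two decimals; the divide-by-column-max variant sometimes quoted
  for MABAC is available behind `method="max-divide"` for fidelity
  experiments but does not reproduce it. Constant columns normalize to zero
  with a warning.
* **Weighting** uses the standard MABAC shift constant 1:
  `ṽ = w̃ (1 + ñ)`, keeping cells strictly positive so the geometric-mean
  border is well defined.
* **Border approximation area**: componentwise geometric mean over
  alternatives, per criterion.
* **Distances** use fuzzy subtraction; **scores** are fuzzy row sums,
  defuzzified (centroid default) and ranked descending. Ties break by the
  larger modal value of the fuzzy score, then input order — deterministic
  and documented.

Within the reference tables, the published weighted and distance matrices
are *not* reproduction targets: their printed triples are internally
non-monotone (e.g. a "(0.41, 0.11, 0.41)" row), indicating column
scrambling in the source. The reproduction anchors are the normalized
matrix, the defuzzified score columns and the final rank order. Note the
aggregated initial matrix of record is itself not derivable from the
published per-expert converted matrices by arithmetic-mean aggregation (its
provenance is unstated in the source), so matrix assembly is validated on
synthetic data and the bundled matrix is used as given.

With the bundled matrix and mean-aggregated weights the pipeline places A2
first and A12 last, matching the published extremes; 24 of 30 ranks are
identical to the published final ranking and the rest are adjacent swaps
within printed rounding (Spearman ρ = 0.999). The two extreme positions are
robust to weight perturbation: resampling the weight vector from a
Dirichlet centred on the mean weights (concentration 50, i.e. roughly ±0.06
standard deviation per weight) leaves A2 at rank 1 and A12 at rank 30 in
100/100 seeded draws.

## Synthetic generator

`generate_synthetic_panel` draws seeded categorical rating/reliability
terms per (alternative, expert, criterion) and multinomial vote triples per
(alternative, expert) row summing to the panel size, with four profiles:
`uniform`, `dominant-alternative` (one alternative drawn from the top of
the rating scale, the rest from the bottom), and `consensus-high` /
`consensus-low` (agreement probabilities 0.8/0.1/0.1 vs 0.25/0.25/0.5).
All-neutral vote triples are redrawn since their consensus ratio is
undefined. The generator emulates the *structure* of an elicitation session
— it does not emulate correlated experts, criterion-dependent voting, or
systematic rater bias, so passing tests demonstrate pipeline correctness
and dominance/consensus behaviour, not calibration against real panels.

## Numerical choices

* TFN ordering is validated with a 10⁻¹² absolute slack; solver outputs are
  componentwise-sorted before constructing weight TFNs to absorb
  ≤10⁻⁸-level SLSQP noise.
* Published two-decimal tables are compared at ±0.01 absolute (the printed
  precision); converted-matrix comparisons use 2% relative with a 0.01
  absolute floor for components printed as 0.00. Up to 0.006 of the
  normalized-matrix deviation stems from the source normalizing *unrounded*
  inputs while the shipped matrix is the printed two-decimal one.
* Full precision everywhere in computation; rounding is presentation-only.
* The classical RPN baseline takes separately elicited integer 1–10 scores;
  a convenience linguistic-term-to-integer map exists (`RPN_TERM_MAP`) but
  is never applied automatically, since no principled mapping from fuzzy
  ratings to RPN integers exists.
* Case-study problem sizes are used as-is everywhere (30 alternatives, 3
  criteria, 3 experts, panel of 12); test oracles use 5×3 crisp instances
  (100 draws) and a 10³-resolution grid search for the crisp BWM optimum.

## Limitations

* Trapezoidal/Gaussian fuzzy numbers, α-cut interval arithmetic and type-2
  fuzzy sets are out of scope; so are other MCDM rankers (TOPSIS, VIKOR,
  EDAS) and group-consensus BWM variants beyond mean aggregation.
* Probabilistic Z-number semantics are not modelled; the reliability
  component enters only through the crisp `sqrt(b*)` discount.
* The BWM program is nonconvex; the multistart SLSQP contract is "best
  feasible incumbent", not a global-optimality certificate. Seeds make it
  reproducible, not provably optimal.
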