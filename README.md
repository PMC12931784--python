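# zefmea

Fuzzy ZE-number FMEA risk assessment: expert-panel failure-mode ranking for
process risk analysis, with a worked case study on medicinal plant
extraction.

## The problem

Failure Mode and Effects Analysis (FMEA) scores every potential process
failure on Severity (S), Occurrence (O) and Detection (D). The classical
risk priority number `RPN = S x O x D` treats the three criteria as equally
important, assumes crisp integer scores, and takes every expert's word at
face value. `zefmea` implements a richer pipeline for panels of experts who
rate failure modes *linguistically* and whose judgments carry *uncertainty*
(fuzziness), *self-declared reliability* and *group consensus*:

1. **Triangular fuzzy numbers (TFNs).** Every linguistic term maps to a
   triple `(l, m, u)`; arithmetic follows the standard componentwise rules,
   with subtraction widening the interval: `A - B = (l1-u2, m1-m2, u1-l2)`.
2. **Z- and ZE-numbers.** A Z-number `Z = (A, B)` pairs a fuzzy rating `A`
   with a fuzzy reliability `B`. A ZE-number `((A, B), E)` adds a panel vote
   `E = (Y, N, θ)` (agree / disagree / neutral out of `n` voters). The
   conversion to a plain TFN is

       b  = (l + 4m + u)/6 of B          (graded mean integration)
       R  = (Y - N) / (n - θ)            (consensus ratio, in [-1, 1])
       b* = b(1+R)          if R < 0
            b               if R = 0
            1 - (1-b)(1-R)  if R > 0
       A* = sqrt(b*) · A

3. **Fuzzy Best–Worst Method (BWM).** Each expert names a best and worst
   criterion and compares them to the rest linguistically; fuzzy weights
   `w̃_j` minimise the largest deviation `ξ` between weight ratios and the
   stated comparisons, subject to `Σ_j gmir(w̃_j) = 1`. The consistency
   ratio `CR = ξ*/CI` (CI from the importance scale) flags unreliable
   panels; `CR < 0.1` is acceptable.
4. **Fuzzy MABAC ranking.** The assembled decision matrix is min–max
   normalized per column, weighted as `ṽ_ij = w̃_j (1 + ñ_ij)`, compared to
   the border approximation area `g̃_j = (Π_i ṽ_ij)^{1/m}` (componentwise
   geometric mean), and each alternative's fuzzy distances are summed and
   defuzzified by the centroid `(l + m + u)/3`. Rank 1 = most critical.

## Worked example

The bundled case study covers 30 failure modes of a medicinal plant
extraction process (sample handling, extraction method, instrumentation,
analytical method, operator, biological/environmental), judged by three
decision-makers with a 12-member consensus panel:

```python
from zefmea import load_case_study, run_ze_pipeline

case = load_case_study()
result = run_ze_pipeline(case.initial_matrix, case.mean_weights())
print(result.to_frame().sort_values("rank").head(3))
```

Running `python examples/04_case_ranking.py` prints:

```
Top 5 risks (largest distance above the border approximation area):
  rank  1  A2   score=+0.353  Inappropriate sample preparation techniques
  rank  2  A10  score=+0.309  Incompatibility between the extraction method and target met
  rank  3  A9   score=+0.304  Inefficient extraction technique (solid-liquid extraction, l
...
  rank 30  A12  score=-0.303  Inaccurate or malfunctioning equipment
```

A positive score means the failure mode sits above the border approximation
area (critical); negative means below. Sample preparation, method/metabolite
incompatibility and inefficient extraction technique head the list, while
equipment malfunction (A12) — weakly rated and weakly trusted by the
panel — lands last.

The other scripts in `examples/` each demonstrate one capability: fuzzy
arithmetic (`01`), the ZE conversion chain (`02`), BWM weight solving and
aggregation (`03`), and synthetic panel generation with Z-vs-ZE comparison
(`05`).

## Command line

```
ze-fmea run --fixture case --out report/          # bundled case study
ze-fmea run --judgments j.csv --votes v.csv --comparisons c.csv --variant ze
ze-fmea synth --alternatives 30 --experts 3 --panel 12 --seed 7
ze-fmea weights --comparisons c.csv
```

Every run writes a `manifest.json` (config, seed, package version, input
checksums) alongside the ranking.

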