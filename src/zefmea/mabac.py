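"""Fuzzy MABAC ranking (Multi-Attributive Border Approximation area Comparison).

The pipeline takes an alternatives x criteria matrix of TFN cells through
five stages:

1. *assemble* — componentwise mean across expert matrices;
2. *normalize* — columnwise min–max scaling of every component into [0, 1]
   (cost criteria are flipped); the historical divide-by-column-max variant
   is available as ``method="max-divide"``;
3. *weight* — ``v_ij = w_j * (1 + n_ij)`` with the standard MABAC shift
   constant 1, keeping every cell strictly positive;
4. *border approximation area* — per criterion, the componentwise geometric
   mean of the weighted column; *distances* ``q_ij = v_ij - g_j`` with fuzzy
   subtraction;
5. *score* — fuzzy row sums of the distances, defuzzified (centroid by
   default) and ranked in descending order; rank 1 is the most critical
   alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .fuzzy import TriangularFuzzyNumber, defuzzify

__all__ = [
    "DecisionMatrix",
    "BorderApproximationArea",
    "RankingResult",
    "assemble_matrix",
    "normalize",
    "weight_matrix",
    "compute_baa",
    "compute_distances",
    "score_and_rank",
    "run_pipeline",
]

Stage = Literal["initial", "normalized", "weighted", "distance"]


@dataclass(frozen=True)
class DecisionMatrix:
    """Alternatives x criteria grid of TFNs at a named pipeline stage.

    ``values`` has shape ``(n_alternatives, n_criteria, 3)`` with the last
    axis holding ``(l, m, u)``.
    """

    alternatives: tuple[str, ...]
    criteria: tuple[str, ...]
    values: np.ndarray
    stage: Stage = "initial"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        expected = (len(self.alternatives), len(self.criteria), 3)
        if v.shape != expected:
            raise ValueError(f"values shape {v.shape} != {expected}")
        if np.isnan(v).any():
            raise ValueError("decision matrix contains missing cells")
        if not ((v[..., 0] <= v[..., 1] + 1e-12) & (v[..., 1] <= v[..., 2] + 1e-12)).all():
            bad = np.argwhere(~((v[..., 0] <= v[..., 1]) & (v[..., 1] <= v[..., 2])))[0]
            a, c = self.alternatives[bad[0]], self.criteria[bad[1]]
            raise ValueError(f"cell ({a}, {c}) is not a valid TFN: {tuple(v[bad[0], bad[1]])}")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_cells(
        cls,
        cells: Mapping[tuple[str, str], TriangularFuzzyNumber],
        alternatives: Sequence[str],
        criteria: Sequence[str],
        stage: Stage = "initial",
    ) -> "DecisionMatrix":
        v = np.empty((len(alternatives), len(criteria), 3))
        v.fill(np.nan)
        for (a, c), t in cells.items():
            v[list(alternatives).index(a), list(criteria).index(c)] = t.as_tuple()
        return cls(tuple(alternatives), tuple(criteria), v, stage)

    def cell(self, alternative: str, criterion: str) -> TriangularFuzzyNumber:
        i = self.alternatives.index(alternative)
        j = self.criteria.index(criterion)
        return TriangularFuzzyNumber(*self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns alternative, criterion, l, m, u."""
        rows = [
            (a, c, *self.values[i, j])
            for i, a in enumerate(self.alternatives)
            for j, c in enumerate(self.criteria)
        ]
        return pd.DataFrame(rows, columns=["alternative", "criterion", "l", "m", "u"])


@dataclass(frozen=True)
class BorderApproximationArea:
    """Per-criterion border TFN ``g_j`` (componentwise geometric column mean)."""

    criteria: tuple[str, ...]
    values: np.ndarray  # shape (n_criteria, 3)

    def __getitem__(self, criterion: str) -> TriangularFuzzyNumber:
        return TriangularFuzzyNumber(*self.values[self.criteria.index(criterion)])


@dataclass(frozen=True)
class RankingResult:
    """Per-alternative fuzzy total distance, defuzzified score and rank (1 = top)."""

    alternatives: tuple[str, ...]
    fuzzy_scores: tuple[TriangularFuzzyNumber, ...]
    scores: tuple[float, ...]
    ranks: tuple[int, ...]

    def rank_of(self, alternative: str) -> int:
        return self.ranks[self.alternatives.index(alternative)]

    def ordered(self) -> list[str]:
        """Alternatives from rank 1 downwards."""
        return [a for _, a in sorted(zip(self.ranks, self.alternatives))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alternative": self.alternatives,
                "S_l": [t.l for t in self.fuzzy_scores],
                "S_m": [t.m for t in self.fuzzy_scores],
                "S_u": [t.u for t in self.fuzzy_scores],
                "score": self.scores,
                "rank": self.ranks,
            }
        )


def _require_stage(dm: DecisionMatrix, stage: Stage) -> None:
    if dm.stage != stage:
        raise ValueError(f"expected a {stage!r}-stage matrix, got {dm.stage!r}")


def assemble_matrix(per_expert: Sequence[DecisionMatrix]) -> DecisionMatrix:
    """Componentwise arithmetic mean across expert matrices (stage: initial)."""
    if not per_expert:
        raise ValueError("need at least one expert matrix")
    first = per_expert[0]
    for dm in per_expert[1:]:
        if dm.alternatives != first.alternatives or dm.criteria != first.criteria:
            raise ValueError("expert matrices must share alternatives and criteria")
    mean = np.mean([dm.values for dm in per_expert], axis=0)
    return DecisionMatrix(first.alternatives, first.criteria, mean, "initial")


def normalize(
    dm: DecisionMatrix,
    directions: Mapping[str, str] | None = None,
    method: Literal["minmax", "max-divide"] = "minmax",
) -> DecisionMatrix:
    """Columnwise normalization of the initial matrix.

    ``minmax`` maps each component through ``(x - x-) / (x+ - x-)`` where
    ``x-`` is the column minimum of lower bounds and ``x+`` the column
    maximum of upper bounds (flipped for cost criteria).  ``max-divide``
    divides by the column maximum of upper bounds instead.
    """
    _require_stage(dm, "initial")
    directions = directions or {}
    out = np.empty_like(dm.values)
    for j, c in enumerate(dm.criteria):
        col = dm.values[:, j, :]
        lo, hi = col[:, 0].min(), col[:, 2].max()
        sense = directions.get(c, "benefit")
        if sense not in ("benefit", "cost"):
            raise ValueError(f"criterion direction must be benefit or cost, got {sense!r}")
        if method == "minmax":
            if hi == lo:
                warnings.warn(f"constant column {c!r}; normalized to 0", stacklevel=2)
                out[:, j, :] = 0.0
                continue
            if sense == "benefit":
                out[:, j, :] = (col - lo) / (hi - lo)
            else:
                # decreasing transform: the new lower bound comes from u, etc.
                out[:, j, :] = ((col - hi) / (lo - hi))[:, ::-1].copy()
        elif method == "max-divide":
            if hi == 0:
                warnings.warn(f"all-zero column {c!r}; normalized to 0", stacklevel=2)
                out[:, j, :] = 0.0
                continue
            if sense == "cost":
                raise ValueError("max-divide normalization supports benefit criteria only")
            out[:, j, :] = col / hi
        else:
            raise ValueError(f"unknown normalization method {method!r}")
    return DecisionMatrix(dm.alternatives, dm.criteria, out, "normalized")


def weight_matrix(
    dm: DecisionMatrix,
    weights: Mapping[str, TriangularFuzzyNumber],
    shift: float = 1.0,
) -> DecisionMatrix:
    """Weighted matrix ``v_ij = w_j * (shift + n_ij)`` (stage: weighted)."""
    _require_stage(dm, "normalized")
    out = np.empty_like(dm.values)
    for j, c in enumerate(dm.criteria):
        try:
            w = weights[c]
        except KeyError:
            raise KeyError(f"no weight supplied for criterion {c!r}") from None
        if w.l <= 0:
            raise ValueError(f"weight for {c!r} must be strictly positive, got {w}")
        out[:, j, :] = np.asarray(w.as_tuple()) * (shift + dm.values[:, j, :])
    return DecisionMatrix(dm.alternatives, dm.criteria, out, "weighted")


def compute_baa(dm: DecisionMatrix) -> BorderApproximationArea:
    """Border approximation area: componentwise geometric mean per criterion."""
    _require_stage(dm, "weighted")
    if (dm.values <= 0).any():
        raise ValueError("border approximation area requires strictly positive cells")
    g = np.exp(np.log(dm.values).mean(axis=0))
    return BorderApproximationArea(dm.criteria, g)


def compute_distances(dm: DecisionMatrix, baa: BorderApproximationArea) -> DecisionMatrix:
    """Signed fuzzy distances ``q_ij = v_ij - g_j`` (fuzzy subtraction)."""
    _require_stage(dm, "weighted")
    if baa.criteria != dm.criteria:
        raise ValueError("border approximation area criteria mismatch")
    g = baa.values  # (n_crit, 3)
    q = np.empty_like(dm.values)
    q[..., 0] = dm.values[..., 0] - g[None, :, 2]
    q[..., 1] = dm.values[..., 1] - g[None, :, 1]
    q[..., 2] = dm.values[..., 2] - g[None, :, 0]
    return DecisionMatrix(dm.alternatives, dm.criteria, q, "distance")


def score_and_rank(dm: DecisionMatrix, defuzzifier: str = "centroid") -> RankingResult:
    """Fuzzy row sums of distances, defuzzified and ranked descending.

    Ties in the defuzzified score are broken by the larger modal value of
    the fuzzy score, then by input order.
    """
    _require_stage(dm, "distance")
    s = dm.values.sum(axis=1)  # (n_alt, 3)
    fuzzy = tuple(TriangularFuzzyNumber(*row) for row in s)
    scores = tuple(defuzzify(t, defuzzifier) for t in fuzzy)
    order = sorted(
        range(len(scores)), key=lambda i: (-scores[i], -fuzzy[i].m, i)
    )
    ranks = [0] * len(scores)
    for pos, i in enumerate(order):
        ranks[i] = pos + 1
    return RankingResult(dm.alternatives, fuzzy, scores, tuple(ranks))


def run_pipeline(
    initial: DecisionMatrix,
    weights: Mapping[str, TriangularFuzzyNumber],
    *,
    directions: Mapping[str, str] | None = None,
    normalization: Literal["minmax", "max-divide"] = "minmax",
    defuzzifier: str = "centroid",
    collect: dict | None = None,
) -> RankingResult:
    """Run normalize -> weight -> BAA -> distances -> score on an initial matrix.

    If ``collect`` is a dict, the intermediate matrices are stored in it under
    the keys ``normalized``, ``weighted``, ``baa`` and ``distance`` for audit.
    """
    norm = normalize(initial, directions, normalization)
    weighted = weight_matrix(norm, weights)
    baa = compute_baa(weighted)
    dist = compute_distances(weighted, baa)
    if collect is not None:
        collect.update(normalized=norm, weighted=weighted, baa=baa, distance=dist)
    return score_and_rank(dist, defuzzifier)
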