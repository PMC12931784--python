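"""Fuzzy Best–Worst Method (BWM) criteria weighting.

Each expert names a best and a worst criterion and gives two linguistic
comparison vectors: best-to-others (BO) and others-to-worst (OW).  The
fuzzy weights ``w_j = (l_j, m_j, u_j)`` are found by minimising the largest
componentwise deviation ``xi`` between the fuzzy weight ratios and the
stated comparison TFNs:

    min xi  s.t.  | w_B / w_j - a_Bj | <= xi   componentwise, all j
                  | w_j / w_W - a_jW | <= xi   componentwise, all j
                  sum_j gmir(w_j) = 1,  l_j <= m_j <= u_j,  l_j >= eps

with fuzzy division ``w_B / w_j = (l_B/u_j, m_B/m_j, u_B/l_j)``.  The
program is nonconvex; it is solved by SLSQP from a seeded set of
Dirichlet-perturbed multistarts, keeping the best feasible incumbent.
The consistency ratio ``CR = xi* / CI(a_BW)`` (CI read off the importance
scale for the best-vs-worst term) flags unreliable comparison sets;
``CR < 0.1`` is conventionally acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .fuzzy import LinguisticScale, TriangularFuzzyNumber

__all__ = [
    "ComparisonVector",
    "WeightSolution",
    "BWMSolverError",
    "validate_comparisons",
    "solve_fuzzy_bwm",
    "consistency_ratio",
    "aggregate_expert_weights",
    "CR_ACCEPTABLE_THRESHOLD",
]

CR_ACCEPTABLE_THRESHOLD = 0.1
_EPS = 1e-6


@dataclass(frozen=True)
class ComparisonVector:
    """One expert's BWM input: best/worst criteria and BO/OW linguistic vectors."""

    criteria: tuple[str, ...]
    best: str
    worst: str
    best_to_others: Mapping[str, str]
    others_to_worst: Mapping[str, str]
    expert: str = ""


@dataclass(frozen=True)
class WeightSolution:
    """Fuzzy weights with the optimal consistency objective ``xi*`` and CR."""

    weights: Mapping[str, TriangularFuzzyNumber]
    xi_star: float
    cr: float

    @property
    def acceptable(self) -> bool:
        return self.cr < CR_ACCEPTABLE_THRESHOLD

    def defuzzified(self) -> dict[str, float]:
        return {c: w.gmir() for c, w in self.weights.items()}


class BWMSolverError(RuntimeError):
    """Raised when no feasible solution is found; carries the best incumbent."""

    def __init__(self, message: str, incumbent: WeightSolution | None = None):
        super().__init__(message)
        self.incumbent = incumbent


def validate_comparisons(
    cv: ComparisonVector, importance_scale: LinguisticScale
) -> ComparisonVector:
    """Check the structural invariants of a comparison vector.

    Internal inconsistency between the BO and OW vectors (for instance a
    best-vs-worst term weaker than some other entry) is *not* rejected:
    panels are kept as given and judged through the consistency ratio.
    """
    crits = set(cv.criteria)
    if len(crits) != len(cv.criteria):
        raise ValueError(f"duplicate criteria in {cv.criteria}")
    if cv.best == cv.worst:
        raise ValueError(f"best and worst criterion coincide ({cv.best!r})")
    for name, c in (("best", cv.best), ("worst", cv.worst)):
        if c not in crits:
            raise ValueError(f"{name} criterion {c!r} not among criteria {cv.criteria}")
    for label, vec in (("best_to_others", cv.best_to_others),
                       ("others_to_worst", cv.others_to_worst)):
        missing = crits - set(vec)
        if missing:
            raise ValueError(f"{label} vector missing criteria: {sorted(missing)}")
        for c, term in vec.items():
            importance_scale.lookup(term)  # raises UnknownTermError
    unit = TriangularFuzzyNumber(1.0, 1.0, 1.0)
    if importance_scale.lookup(cv.best_to_others[cv.best]) != unit:
        raise ValueError("best-to-best comparison must be the unit term (EI)")
    if importance_scale.lookup(cv.others_to_worst[cv.worst]) != unit:
        raise ValueError("worst-to-worst comparison must be the unit term (EI)")
    return cv


def _pack_constraints(n: int, B: int, W: int, bo: np.ndarray, ow: np.ndarray):
    """Vector inequality function for SLSQP: all entries must be >= 0."""

    def ineqs(x: np.ndarray) -> np.ndarray:
        w = x[: 3 * n].reshape(n, 3)
        k = x[-1]
        out = []
        for j in range(n):
            if j != B:
                d = (w[B, 0] / w[j, 2] - bo[j, 0],
                     w[B, 1] / w[j, 1] - bo[j, 1],
                     w[B, 2] / w[j, 0] - bo[j, 2])
                out.extend((k - d[0], k + d[0], k - d[1], k + d[1], k - d[2], k + d[2]))
            if j != W:
                d = (w[j, 0] / w[W, 2] - ow[j, 0],
                     w[j, 1] / w[W, 1] - ow[j, 1],
                     w[j, 2] / w[W, 0] - ow[j, 2])
                out.extend((k - d[0], k + d[0], k - d[1], k + d[1], k - d[2], k + d[2]))
            out.extend((w[j, 1] - w[j, 0], w[j, 2] - w[j, 1]))
        return np.asarray(out)

    return ineqs


def solve_fuzzy_bwm(
    cv: ComparisonVector,
    importance_scale: LinguisticScale,
    *,
    n_starts: int = 32,
    seed: int = 0,
    feas_tol: float = 1e-8,
) -> WeightSolution:
    """Solve the fuzzy BWM program for one comparison vector.

    Returns the best feasible incumbent over ``n_starts`` seeded multistarts;
    ties in the objective are broken towards the lexicographically smallest
    ``(l, m, u)`` weight vector in criterion order, for reproducibility.
    """
    validate_comparisons(cv, importance_scale)
    crits = list(cv.criteria)
    n = len(crits)
    B, W = crits.index(cv.best), crits.index(cv.worst)
    bo = np.array([importance_scale.lookup(cv.best_to_others[c]).as_tuple() for c in crits])
    ow = np.array([importance_scale.lookup(cv.others_to_worst[c]).as_tuple() for c in crits])

    ineqs = _pack_constraints(n, B, W, bo, ow)
    gvec = np.array([1.0, 4.0, 1.0]) / 6.0

    def gmir_sum_minus_one(x: np.ndarray) -> float:
        return float((x[: 3 * n].reshape(n, 3) @ gvec).sum() - 1.0)

    constraints = [
        {"type": "eq", "fun": gmir_sum_minus_one},
        {"type": "ineq", "fun": ineqs},
    ]
    bounds = [(_EPS, None)] * (3 * n) + [(0.0, None)]

    rng = np.random.default_rng(seed)
    best_x: np.ndarray | None = None
    best_k = np.inf
    for s in range(n_starts):
        w0 = np.full(n, 1.0 / n) if s == 0 else rng.dirichlet(np.ones(n))
        x0 = np.concatenate([np.repeat(w0, 3), [1.0]])
        res = minimize(
            lambda x: x[-1],
            x0,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        x = res.x
        if (
            res.success
            and ineqs(x).min() > -feas_tol
            and abs(gmir_sum_minus_one(x)) < feas_tol
        ):
            k = x[-1]
            if k < best_k - 1e-10:
                best_k, best_x = k, x.copy()
            elif abs(k - best_k) <= 1e-10 and best_x is not None:
                if tuple(x[: 3 * n]) < tuple(best_x[: 3 * n]):
                    best_x = x.copy()

    if best_x is None:
        raise BWMSolverError(
            f"fuzzy BWM solver found no feasible solution in {n_starts} starts"
        )

    w = best_x[: 3 * n].reshape(n, 3)
    # clamp numerically-inverted orderings from the solver (within feas_tol)
    w = np.sort(w, axis=1)
    weights = {c: TriangularFuzzyNumber(*w[j]) for j, c in enumerate(crits)}
    xi_star = max(float(best_k), 0.0)
    sol = WeightSolution(weights=weights, xi_star=xi_star, cr=float("nan"))
    cr = consistency_ratio(sol, cv, importance_scale)
    return WeightSolution(weights=weights, xi_star=xi_star, cr=cr)


def consistency_ratio(
    sol: WeightSolution, cv: ComparisonVector, importance_scale: LinguisticScale
) -> float:
    """``CR = xi* / CI`` with CI taken for the best-vs-worst comparison term.

    The best-vs-worst term is read from the BO vector's entry at the worst
    criterion.
    """
    a_bw = cv.best_to_others[cv.worst]
    ci = importance_scale.consistency_index(a_bw)
    return sol.xi_star / ci


def aggregate_expert_weights(
    solutions: Sequence[WeightSolution | Mapping[str, TriangularFuzzyNumber]],
) -> dict[str, TriangularFuzzyNumber]:
    """Componentwise mean of per-expert fuzzy weights, renormalised to sum-1 GMIR."""
    if not solutions:
        raise ValueError("need at least one weight solution to aggregate")
    maps = [s.weights if isinstance(s, WeightSolution) else s for s in solutions]
    crits = list(maps[0])
    for m in maps[1:]:
        if set(m) != set(crits):
            raise ValueError(f"criteria mismatch between weight sets: {sorted(m)} vs {crits}")
    k = len(maps)
    mean = {
        c: TriangularFuzzyNumber(
            sum(m[c].l for m in maps) / k,
            sum(m[c].m for m in maps) / k,
            sum(m[c].u for m in maps) / k,
        )
        for c in crits
    }
    total = sum(w.gmir() for w in mean.values())
    return {c: w.scale(1.0 / total) for c, w in mean.items()}
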