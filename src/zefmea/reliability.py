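"""Z-number and ZE-number engine.

A Z-number pairs a fuzzy restriction *A* (here: a linguistic rating resolved
to a TFN) with a fuzzy reliability *B* describing how much the assessor
trusts that restriction.  A ZE-number additionally attaches an
evaluation-counting component *E* — a panel vote ``(Y, N, theta)`` of
agreeing, disagreeing and neutral experts — which adjusts the reliability
towards the group consensus.

The conversion chain implemented here turns a ZE-judgment into a plain TFN:

1. ``b = gmir(B)`` — crisp reliability of the individual assessor;
2. ``R = (Y - N) / (n - theta)`` — signed consensus ratio in ``[-1, 1]``;
3. ``b* = b(1+R)`` if ``R < 0``, ``b`` if ``R = 0``, ``1 - (1-b)(1-R)`` if
   ``R > 0`` — consensus-adjusted reliability;
4. ``A* = sqrt(b*) * A`` — the reliability-discounted rating TFN, which is
   what enters the decision matrices downstream.

The plain Z-number route is the same chain with step 2-3 skipped
(``b* = b``), i.e. consensus treated as neutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .fuzzy import LinguisticScale, TriangularFuzzyNumber

__all__ = [
    "ZJudgment",
    "VoteRecord",
    "ZEJudgment",
    "crisp_reliability",
    "consensus_ratio",
    "adjust_reliability",
    "z_to_fuzzy",
    "ze_convert",
    "z_convert",
]


@dataclass(frozen=True)
class ZJudgment:
    """One expert's (rating term, reliability term) pair."""

    rating_term: str
    reliability_term: str


@dataclass(frozen=True)
class VoteRecord:
    """Panel vote ``(Y agree, N disagree, theta neutral)`` out of ``n`` voters."""

    agree: int
    disagree: int
    neutral: int
    panel_size: int

    def __post_init__(self) -> None:
        if min(self.agree, self.disagree, self.neutral) < 0 or self.panel_size <= 0:
            raise ValueError(f"vote counts must be nonnegative with panel_size > 0: {self}")
        if self.agree + self.disagree + self.neutral != self.panel_size:
            raise ValueError(
                f"votes must sum to the panel size: "
                f"{self.agree}+{self.disagree}+{self.neutral} != {self.panel_size}"
            )


@dataclass(frozen=True)
class ZEJudgment:
    """A Z-judgment together with the panel vote that adjusts its reliability."""

    judgment: ZJudgment
    vote: VoteRecord


def crisp_reliability(reliability_tfn: TriangularFuzzyNumber) -> float:
    """Crisp reliability ``b`` of a reliability TFN, via graded mean integration.

    The TFN must live on the unit interval.
    """
    if reliability_tfn.l < -1e-12 or reliability_tfn.u > 1.0 + 1e-12:
        raise ValueError(f"reliability TFN must have support within [0, 1]: {reliability_tfn}")
    return reliability_tfn.gmir()


def consensus_ratio(vote: VoteRecord) -> float:
    """Signed consensus ratio ``R = (Y - N) / (n - theta)`` in ``[-1, 1]``."""
    denom = vote.panel_size - vote.neutral
    if denom <= 0:
        raise ValueError(
            "consensus ratio undefined: every panellist was neutral "
            f"(theta = n = {vote.panel_size})"
        )
    return (vote.agree - vote.disagree) / denom


def adjust_reliability(b: float, R: float) -> float:
    """Consensus-adjusted reliability ``b*``.

    Disagreement shrinks reliability multiplicatively, agreement pulls it
    towards 1; the map is continuous at ``R = 0`` and keeps ``b*`` in [0, 1].
    """
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"reliability b must be in [0, 1], got {b}")
    if not -1.0 <= R <= 1.0:
        raise ValueError(f"consensus ratio R must be in [-1, 1], got {R}")
    if R < 0:
        return b * (1.0 + R)
    if R > 0:
        return 1.0 - (1.0 - b) * (1.0 - R)
    return b


def z_to_fuzzy(rating_tfn: TriangularFuzzyNumber, alpha: float) -> TriangularFuzzyNumber:
    """Fold a crisp reliability ``alpha`` into the rating TFN as ``sqrt(alpha) * A``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return rating_tfn.scale(math.sqrt(alpha))


def ze_convert(
    je: ZEJudgment,
    rating_scale: LinguisticScale,
    reliability_scale: LinguisticScale,
) -> TriangularFuzzyNumber:
    """Convert a ZE-judgment into its consensus- and reliability-weighted TFN."""
    a = rating_scale.lookup(je.judgment.rating_term)
    b = crisp_reliability(reliability_scale.lookup(je.judgment.reliability_term))
    r = consensus_ratio(je.vote)
    return z_to_fuzzy(a, adjust_reliability(b, r))


def z_convert(
    j: ZJudgment,
    rating_scale: LinguisticScale,
    reliability_scale: LinguisticScale,
) -> TriangularFuzzyNumber:
    """Convert a plain Z-judgment (no consensus adjustment, ``b* = b``)."""
    a = rating_scale.lookup(j.rating_term)
    b = crisp_reliability(reliability_scale.lookup(j.reliability_term))
    return z_to_fuzzy(a, b)
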