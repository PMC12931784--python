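"""FMEA orchestration: failure-mode catalog, case study, runners, synthesis.

The package ships a complete worked case study — risk assessment of a
medicinal plant extraction process — as plain-CSV data: 30 failure modes in
six categories, three decision-makers rating each mode on Severity,
Occurrence and Detection with linguistic (rating, reliability) pairs, a
12-member panel vote per decision-maker row, per-expert Best–Worst
comparison vectors, per-expert fuzzy criterion weights, and the aggregated
initial decision matrix of record together with the published reference
rankings used by the test-suite.

Two published misprints in the case-study source are corrected on load and
recorded in :data:`VOTE_ERRATA` / :data:`RELIABILITY_TERM_ERRATA`; the CSV
files themselves store the source verbatim.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .bwm import ComparisonVector, aggregate_expert_weights
from .fuzzy import (
    LinguisticScale,
    TriangularFuzzyNumber,
    rating_scale,
    reliability_scale,
)
from .mabac import DecisionMatrix, RankingResult, run_pipeline
from .reliability import VoteRecord, ZEJudgment, ZJudgment, z_convert, ze_convert

__all__ = [
    "FailureMode",
    "PanelSession",
    "CaseStudy",
    "FixtureIntegrityError",
    "classical_rpn",
    "load_case_study",
    "session_to_matrices",
    "run_ze_pipeline",
    "run_z_pipeline",
    "generate_synthetic_panel",
    "compare_rankings",
    "RPN_TERM_MAP",
    "VOTE_ERRATA",
    "RELIABILITY_TERM_ERRATA",
]

CRITERIA = ("S", "O", "D")

# source misprints, corrected on load (see docs/methods.md, "Case-study errata"):
# - A30/TM2 vote triple is printed (5, 4, 1), which sums to 10 rather than the
#   panel size 12 and contradicts the printed consensus ratio -0.11; the
#   corrected triple (4, 5, 3) satisfies both.
VOTE_ERRATA: dict[tuple[str, str], tuple[int, int, int]] = {("A30", "TM2"): (4, 5, 3)}
# - two judgment cells carry reliability terms that are not on the 5-term
#   reliability scale; both are mapped to "M", the term their published
#   converted values correspond to.
RELIABILITY_TERM_ERRATA: dict[str, str] = {"ML": "M", "MH": "M"}


@dataclass(frozen=True)
class FailureMode:
    """One catalogued failure mode of the extraction process."""

    id: str
    category: str
    description: str


@dataclass(frozen=True)
class PanelSession:
    """A complete elicitation session: judgments, votes and BWM comparisons."""

    failure_modes: tuple[FailureMode, ...]
    criteria: tuple[str, ...]
    experts: tuple[str, ...]
    judgments: Mapping[tuple[str, str, str], ZJudgment]  # (alt, expert, criterion)
    votes: Mapping[tuple[str, str], VoteRecord]  # (alt, expert): one vote per row
    comparisons: Mapping[str, ComparisonVector] = field(default_factory=dict)
    panel_size: int = 12

    def __post_init__(self) -> None:
        for fm in self.failure_modes:
            for e in self.experts:
                if (fm.id, e) not in self.votes:
                    raise ValueError(f"missing vote for ({fm.id}, {e})")
                for c in self.criteria:
                    if (fm.id, e, c) not in self.judgments:
                        raise ValueError(f"missing judgment for ({fm.id}, {e}, {c})")

    @property
    def alternatives(self) -> tuple[str, ...]:
        return tuple(fm.id for fm in self.failure_modes)


@dataclass(frozen=True)
class CaseStudy:
    """The bundled case study with its reference tables."""

    session: PanelSession
    initial_matrix: DecisionMatrix
    expert_weights: Mapping[str, Mapping[str, TriangularFuzzyNumber]]
    printed_R: Mapping[tuple[str, str], float]
    ze_matrix_printed: Mapping[str, DecisionMatrix]  # per expert
    normalized_printed: DecisionMatrix
    ranking_printed: Mapping[str, pd.DataFrame]  # variant "z" / "ze"

    def mean_weights(self) -> dict[str, TriangularFuzzyNumber]:
        """Componentwise mean of the per-expert weights, GMIR-renormalised."""
        return aggregate_expert_weights(list(self.expert_weights.values()))


class FixtureIntegrityError(RuntimeError):
    """Bundled case-study data failed its checksum manifest."""


def classical_rpn(severity: int, occurrence: int, detection: int) -> int:
    """Classical risk priority number ``S x O x D`` on integer 1-10 scores."""
    for name, v in (("severity", severity), ("occurrence", occurrence), ("detection", detection)):
        if not (isinstance(v, (int, np.integer)) and 1 <= v <= 10):
            raise ValueError(f"{name} must be an integer in 1..10, got {v!r}")
    return int(severity) * int(occurrence) * int(detection)


#: optional convenience map from rating-scale terms to RPN-style integers
#: (modal values of the rating TFNs, rounded).  Not applied automatically:
#: the classical RPN operates on separately elicited integer scores.
RPN_TERM_MAP: dict[str, int] = {"VL": 1, "L": 2, "ML": 4, "M": 5, "MH": 7, "H": 8, "VH": 9}


# ---------------------------------------------------------------------------
# bundled case study
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("zefmea.data").joinpath(name)


def _read_csv(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p)


def _verify_manifest() -> None:
    manifest = _data_path("MANIFEST.sha256").read_text()
    for line in manifest.strip().splitlines():
        digest, name = line.split()
        actual = hashlib.sha256(_data_path(name).read_bytes()).hexdigest()
        if actual != digest:
            raise FixtureIntegrityError(f"checksum mismatch for bundled file {name}")


def _matrix_from_long(df: pd.DataFrame, alternatives, criteria, stage="initial") -> DecisionMatrix:
    v = np.full((len(alternatives), len(criteria), 3), np.nan)
    ai = {a: i for i, a in enumerate(alternatives)}
    ci = {c: j for j, c in enumerate(criteria)}
    for r in df.itertuples(index=False):
        v[ai[r.alternative], ci[r.criterion]] = (r.l, r.m, r.u)
    return DecisionMatrix(tuple(alternatives), tuple(criteria), v, stage)


def load_case_study(verify: bool = True) -> CaseStudy:
    """Load the bundled medicinal-plant-extraction case study.

    ``verify=True`` (default) checks every bundled CSV against its SHA-256
    manifest and raises :class:`FixtureIntegrityError` on mismatch.
    """
    if verify:
        _verify_manifest()

    fm_df = _read_csv("failure_modes.csv")
    failure_modes = tuple(
        FailureMode(r.id, r.category, r.description) for r in fm_df.itertuples(index=False)
    )
    alternatives = [fm.id for fm in failure_modes]
    experts = ("TM1", "TM2", "TM3")

    votes_df = _read_csv("votes.csv")
    votes: dict[tuple[str, str], VoteRecord] = {}
    printed_R: dict[tuple[str, str], float] = {}
    for r in votes_df.itertuples(index=False):
        key = (r.alternative, r.expert)
        y, n, th = VOTE_ERRATA.get(key, (r.Y, r.N, r.theta))
        votes[key] = VoteRecord(int(y), int(n), int(th), int(r.n))
        printed_R[key] = float(r.R_printed)

    jd_df = _read_csv("judgments.csv")
    judgments = {
        (r.alternative, r.expert, r.criterion): ZJudgment(
            r.rating_term,
            RELIABILITY_TERM_ERRATA.get(r.reliability_term, r.reliability_term),
        )
        for r in jd_df.itertuples(index=False)
    }

    comp_df = _read_csv("comparisons.csv")
    comparisons: dict[str, ComparisonVector] = {}
    for expert, grp in comp_df.groupby("expert", sort=False):
        comparisons[expert] = ComparisonVector(
            criteria=CRITERIA,
            best=grp.best.iloc[0],
            worst=grp.worst.iloc[0],
            best_to_others=dict(zip(grp.criterion, grp.bo_term)),
            others_to_worst=dict(zip(grp.criterion, grp.ow_term)),
            expert=expert,
        )

    session = PanelSession(
        failure_modes=failure_modes,
        criteria=CRITERIA,
        experts=experts,
        judgments=judgments,
        votes=votes,
        comparisons=comparisons,
        panel_size=12,
    )

    w_df = _read_csv("ze_bwm_weights.csv")
    expert_weights = {
        e: {
            r.criterion: TriangularFuzzyNumber(r.l, r.m, r.u)
            for r in grp.itertuples(index=False)
        }
        for e, grp in w_df.groupby("expert", sort=False)
    }

    initial = _matrix_from_long(_read_csv("initial_matrix.csv"), alternatives, CRITERIA)

    ze_df = _read_csv("ze_matrix_printed.csv")
    ze_printed = {
        e: _matrix_from_long(grp, alternatives, CRITERIA)
        for e, grp in ze_df.groupby("expert", sort=False)
    }
    normalized_printed = _matrix_from_long(
        _read_csv("normalized_printed.csv"), alternatives, CRITERIA, stage="normalized"
    )
    ranking_printed = {
        variant: _read_csv(f"ranking_printed_{variant}.csv") for variant in ("z", "ze")
    }

    return CaseStudy(
        session=session,
        initial_matrix=initial,
        expert_weights=expert_weights,
        printed_R=printed_R,
        ze_matrix_printed=ze_printed,
        normalized_printed=normalized_printed,
        ranking_printed=ranking_printed,
    )


# ---------------------------------------------------------------------------
# pipeline runners
# ---------------------------------------------------------------------------

def session_to_matrices(
    session: PanelSession,
    variant: Literal["ze", "z"] = "ze",
    rating: LinguisticScale | None = None,
    reliability: LinguisticScale | None = None,
) -> dict[str, DecisionMatrix]:
    """Convert a session's judgments into one TFN decision matrix per expert."""
    rating = rating or rating_scale()
    reliability = reliability or reliability_scale()
    alts = session.alternatives
    out: dict[str, DecisionMatrix] = {}
    for e in session.experts:
        v = np.empty((len(alts), len(session.criteria), 3))
        for i, a in enumerate(alts):
            for j, c in enumerate(session.criteria):
                zj = session.judgments[(a, e, c)]
                if variant == "ze":
                    t = ze_convert(
                        ZEJudgment(zj, session.votes[(a, e)]), rating, reliability
                    )
                elif variant == "z":
                    t = z_convert(zj, rating, reliability)
                else:
                    raise ValueError(f"variant must be 'ze' or 'z', got {variant!r}")
                v[i, j] = t.as_tuple()
        out[e] = DecisionMatrix(tuple(alts), tuple(session.criteria), v, "initial")
    return out


def run_ze_pipeline(
    initial: DecisionMatrix,
    weights: Mapping[str, TriangularFuzzyNumber],
    *,
    defuzzifier: str = "centroid",
    normalization: str = "minmax",
    collect: dict | None = None,
) -> RankingResult:
    """Rank an assembled ZE decision matrix through the fuzzy MABAC stages."""
    return run_pipeline(
        initial,
        weights,
        normalization=normalization,  # type: ignore[arg-type]
        defuzzifier=defuzzifier,
        collect=collect,
    )


def run_z_pipeline(
    initial: DecisionMatrix,
    weights: Mapping[str, TriangularFuzzyNumber],
    **kwargs,
) -> RankingResult:
    """Rank a Z-number decision matrix; weights must be supplied explicitly."""
    if not weights:
        raise ValueError("the Z pipeline requires explicit criterion weights")
    return run_ze_pipeline(initial, weights, **kwargs)


def compare_rankings(r1: RankingResult, r2: RankingResult) -> float:
    """Spearman rank correlation between two rankings of the same alternatives."""
    if set(r1.alternatives) != set(r2.alternatives):
        raise ValueError("rankings cover different alternative sets")
    order = list(r1.alternatives)
    x = [r1.rank_of(a) for a in order]
    y = [r2.rank_of(a) for a in order]
    return float(spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# synthetic panels
# ---------------------------------------------------------------------------

_PROFILES = ("uniform", "dominant-alternative", "consensus-high", "consensus-low")


def generate_synthetic_panel(
    n_alternatives: int = 30,
    n_experts: int = 3,
    panel_size: int = 12,
    seed: int = 0,
    profile: str = "uniform",
) -> PanelSession:
    """Draw a seeded synthetic elicitation session.

    Profiles
    --------
    ``uniform``
        Ratings and reliabilities drawn uniformly over their scales; votes
        multinomial with balanced agreement.
    ``dominant-alternative``
        The first alternative receives stochastically larger ratings
        (H/VH-heavy) while all others are drawn from the low end.
    ``consensus-high`` / ``consensus-low``
        Vote triples drawn with agreement probability 0.8 / mostly-neutral
        split 0.25/0.25/0.5, giving clearly separated |R| distributions.
    """
    if profile not in _PROFILES:
        raise ValueError(f"invalid profile {profile!r}; choose from {_PROFILES}")
    if min(n_alternatives, n_experts, panel_size) <= 0:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    rating_terms = list(rating_scale().terms)
    rel_terms = list(reliability_scale().terms)
    alts = [f"A{i + 1}" for i in range(n_alternatives)]
    experts = [f"TM{i + 1}" for i in range(n_experts)]

    if profile == "consensus-high":
        p_vote = (0.8, 0.1, 0.1)
    elif profile == "consensus-low":
        p_vote = (0.25, 0.25, 0.5)
    else:
        p_vote = (0.4, 0.4, 0.2)

    low_terms, high_terms = rating_terms[:3], rating_terms[-2:]

    failure_modes = tuple(
        FailureMode(a, "synthetic", f"synthetic failure mode {a}") for a in alts
    )
    judgments: dict[tuple[str, str, str], ZJudgment] = {}
    votes: dict[tuple[str, str], VoteRecord] = {}
    for a in alts:
        for e in experts:
            y, n, th = rng.multinomial(panel_size, p_vote)
            while th == panel_size:  # all-neutral panels have no defined consensus
                y, n, th = rng.multinomial(panel_size, p_vote)
            votes[(a, e)] = VoteRecord(int(y), int(n), int(th), panel_size)
            for c in CRITERIA:
                if profile == "dominant-alternative":
                    pool = high_terms if a == alts[0] else low_terms
                else:
                    pool = rating_terms
                judgments[(a, e, c)] = ZJudgment(
                    str(rng.choice(pool)), str(rng.choice(rel_terms))
                )
    return PanelSession(
        failure_modes=failure_modes,
        criteria=CRITERIA,
        experts=tuple(experts),
        judgments=judgments,
        votes=votes,
        panel_size=panel_size,
    )
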