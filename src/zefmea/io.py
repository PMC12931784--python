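"""Readers and writers for judgment, vote, comparison, matrix and ranking files.

All files are UTF-8 CSV with ``.`` decimals (JSON mirrors the same field
names).  Readers validate eagerly and raise :class:`InputValidationError`
carrying an itemised list of (row number, reason) problems rather than
failing on the first bad row.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .bwm import ComparisonVector
from .fuzzy import LinguisticScale, TriangularFuzzyNumber
from .mabac import DecisionMatrix, RankingResult
from .reliability import VoteRecord, ZJudgment

__all__ = [
    "InputValidationError",
    "RunConfig",
    "read_judgments",
    "read_votes",
    "read_comparisons",
    "read_matrix",
    "read_matrix_wide",
    "write_matrix",
    "write_ranking",
    "read_ranking",
    "write_manifest",
]


class InputValidationError(ValueError):
    """Input file failed validation; ``problems`` lists (row, reason) pairs."""

    def __init__(self, path, problems: list[tuple[int, str]]):
        self.problems = problems
        lines = "; ".join(f"row {r}: {msg}" for r, msg in problems[:20])
        more = "" if len(problems) <= 20 else f" (+{len(problems) - 20} more)"
        super().__init__(f"{path}: {lines}{more}")


class RunConfig(BaseModel):
    """Configuration of a ranking run; every enumeration is a closed set."""

    variant: Literal["ze", "z"] = "ze"
    defuzzifier: Literal["centroid", "gmir"] = "centroid"
    normalization: Literal["minmax", "max-divide"] = "minmax"
    solver_starts: int = Field(default=32, ge=1)
    seed: int = 0
    solver_tolerance: float = Field(default=1e-8, gt=0)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputValidationError(path, [(0, f"missing columns {missing}")])


def read_judgments(
    path,
    rating: LinguisticScale,
    reliability: LinguisticScale,
) -> dict[tuple[str, str, str], ZJudgment]:
    """Read ``alternative,expert,criterion,rating_term,reliability_term`` rows."""
    df = pd.read_csv(path)
    _require_columns(df, ["alternative", "expert", "criterion", "rating_term", "reliability_term"], path)
    problems: list[tuple[int, str]] = []
    out: dict[tuple[str, str, str], ZJudgment] = {}
    for i, r in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        key = (str(r.alternative), str(r.expert), str(r.criterion))
        if key in out:
            problems.append((i, f"duplicate judgment key {key}"))
            continue
        if r.rating_term not in rating:
            problems.append((i, f"unknown rating term {r.rating_term!r}"))
            continue
        if r.reliability_term not in reliability:
            problems.append((i, f"unknown reliability term {r.reliability_term!r}"))
            continue
        out[key] = ZJudgment(str(r.rating_term), str(r.reliability_term))
    if problems:
        raise InputValidationError(path, problems)
    return out


def read_votes(path) -> dict[tuple[str, str], VoteRecord]:
    """Read ``alternative,expert,Y,N,theta,n`` rows into vote records."""
    df = pd.read_csv(path)
    _require_columns(df, ["alternative", "expert", "Y", "N", "theta", "n"], path)
    problems: list[tuple[int, str]] = []
    out: dict[tuple[str, str], VoteRecord] = {}
    for i, r in enumerate(df.itertuples(index=False), start=2):
        key = (str(r.alternative), str(r.expert))
        if key in out:
            problems.append((i, f"duplicate vote key {key}"))
            continue
        try:
            out[key] = VoteRecord(int(r.Y), int(r.N), int(r.theta), int(r.n))
        except (ValueError, TypeError) as exc:
            problems.append((i, str(exc)))
    if problems:
        raise InputValidationError(path, problems)
    return out


def read_comparisons(path, importance: LinguisticScale) -> dict[str, ComparisonVector]:
    """Read ``expert,best,worst,criterion,bo_term,ow_term`` rows, one vector per expert."""
    df = pd.read_csv(path)
    _require_columns(df, ["expert", "best", "worst", "criterion", "bo_term", "ow_term"], path)
    problems: list[tuple[int, str]] = []
    for i, r in enumerate(df.itertuples(index=False), start=2):
        for term in (r.bo_term, r.ow_term):
            if term not in importance:
                problems.append((i, f"unknown importance term {term!r}"))
    if problems:
        raise InputValidationError(path, problems)
    out: dict[str, ComparisonVector] = {}
    for expert, grp in df.groupby("expert", sort=False):
        out[str(expert)] = ComparisonVector(
            criteria=tuple(grp.criterion),
            best=str(grp.best.iloc[0]),
            worst=str(grp.worst.iloc[0]),
            best_to_others=dict(zip(grp.criterion, grp.bo_term)),
            others_to_worst=dict(zip(grp.criterion, grp.ow_term)),
            expert=str(expert),
        )
    return out


def read_matrix(path, stage: str = "initial") -> DecisionMatrix:
    """Read a long-format matrix CSV: ``alternative,criterion,l,m,u``."""
    df = pd.read_csv(path)
    _require_columns(df, ["alternative", "criterion", "l", "m", "u"], path)
    alts = list(dict.fromkeys(df.alternative))
    crits = list(dict.fromkeys(df.criterion))
    v = np.full((len(alts), len(crits), 3), np.nan)
    for r in df.itertuples(index=False):
        v[alts.index(r.alternative), crits.index(r.criterion)] = (r.l, r.m, r.u)
    try:
        return DecisionMatrix(tuple(alts), tuple(crits), v, stage)  # type: ignore[arg-type]
    except ValueError as exc:
        raise InputValidationError(path, [(0, str(exc))]) from exc


def read_matrix_wide(path, criteria=("S", "O", "D"), stage: str = "initial") -> DecisionMatrix:
    """Read a wide-format matrix: one row per alternative, three numbers per criterion.

    Accepts either explicit headers (``S_l,S_m,S_u,...``) or a headerless
    layout of ``alternative`` followed by ``3 * len(criteria)`` numbers,
    matching how such matrices are usually tabulated.
    """
    df = pd.read_csv(path)
    expected = [f"{c}_{x}" for c in criteria for x in ("l", "m", "u")]
    if not set(expected) <= set(df.columns):
        df = pd.read_csv(path, header=None)
        if df.shape[1] != 1 + 3 * len(criteria):
            raise InputValidationError(
                path, [(0, f"expected columns {['alternative'] + expected} or "
                           f"{1 + 3 * len(criteria)} headerless columns")])
        df.columns = ["alternative"] + expected
    alts = [str(a) for a in df.alternative]
    v = df[expected].to_numpy(float).reshape(len(alts), len(criteria), 3)
    return DecisionMatrix(tuple(alts), tuple(criteria), v, stage)  # type: ignore[arg-type]


def write_matrix(dm: DecisionMatrix, path) -> None:
    dm.to_frame().to_csv(path, index=False)


def write_ranking(result: RankingResult, path, format: str | None = None) -> None:
    """Write a ranking as CSV or JSON (full precision; no display rounding)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "csv")
    df = result.to_frame()
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=2))
    else:
        raise ValueError(f"unknown ranking format {fmt!r}")


def read_ranking(path) -> RankingResult:
    path = Path(path)
    if path.suffix == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    fuzzy = tuple(TriangularFuzzyNumber(r.S_l, r.S_m, r.S_u) for r in df.itertuples(index=False))
    return RankingResult(
        alternatives=tuple(str(a) for a in df.alternative),
        fuzzy_scores=fuzzy,
        scores=tuple(float(s) for s in df.score),
        ranks=tuple(int(r) for r in df["rank"]),
    )


def write_manifest(out_dir, config: RunConfig, inputs: Mapping[str, Path] | None = None) -> Path:
    """Write a reproducibility manifest (config, seed, version, input checksums)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "zefmea",
        "version": __version__,
        "config": config.model_dump(),
        "inputs": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in (inputs or {}).items()
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
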