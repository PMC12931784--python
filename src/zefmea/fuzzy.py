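"""Triangular fuzzy numbers, linguistic scales and defuzzification.

A triangular fuzzy number (TFN) is an ordered triple ``(l, m, u)`` with
``l <= m <= u``: the support is ``[l, u]`` and the membership function rises
linearly from 0 at ``l`` to 1 at the modal value ``m``, then falls linearly
back to 0 at ``u``.  All quantities flowing through this package — linguistic
ratings, criterion weights, decision-matrix cells and aggregate scores — are
TFNs; a degenerate TFN with ``l == m == u`` behaves exactly like the crisp
real number ``m``.

Arithmetic follows the standard extension-principle rules for TFNs:

* addition and subtraction are always closed (subtraction widens the
  interval: ``a - b = (l1 - u2, m1 - m2, u1 - l2)``);
* multiplication and division are componentwise and are only defined here
  for nonnegative (resp. strictly positive) operands, which is the regime
  every scale in this package lives in.

Two defuzzifiers are provided: the graded mean integration representation
``(l + 4m + u) / 6`` and the centroid ``(l + m + u) / 3``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "TriangularFuzzyNumber",
    "TFN",
    "defuzzify_gmir",
    "defuzzify_centroid",
    "defuzzify",
    "LinguisticScale",
    "UnknownTermError",
    "importance_scale",
    "reliability_scale",
    "rating_scale",
]

_ORD_TOL = 1e-12


@dataclass(frozen=True, order=False)
class TriangularFuzzyNumber:
    """Ordered triple ``(l, m, u)`` with ``l <= m <= u``."""

    l: float
    m: float
    u: float

    def __post_init__(self) -> None:
        if not (self.l <= self.m + _ORD_TOL and self.m <= self.u + _ORD_TOL):
            raise ValueError(
                f"invalid TFN ({self.l}, {self.m}, {self.u}): requires l <= m <= u"
            )

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other: "TriangularFuzzyNumber") -> "TriangularFuzzyNumber":
        return TriangularFuzzyNumber(self.l + other.l, self.m + other.m, self.u + other.u)

    def __sub__(self, other: "TriangularFuzzyNumber") -> "TriangularFuzzyNumber":
        # interval-widening rule; always yields a valid TFN for valid inputs
        return TriangularFuzzyNumber(self.l - other.u, self.m - other.m, self.u - other.l)

    def __mul__(self, other):
        if isinstance(other, TriangularFuzzyNumber):
            if self.l < 0 or other.l < 0:
                raise ValueError(
                    "TFN product is only defined for nonnegative operands "
                    f"(got {self} * {other})"
                )
            return TriangularFuzzyNumber(self.l * other.l, self.m * other.m, self.u * other.u)
        return self.scale(float(other))

    __rmul__ = __mul__

    def __truediv__(self, other: "TriangularFuzzyNumber") -> "TriangularFuzzyNumber":
        if not isinstance(other, TriangularFuzzyNumber):
            return self.scale(1.0 / float(other))
        if other.l <= 0:
            raise ZeroDivisionError(
                f"TFN division requires a strictly positive divisor (got {other})"
            )
        return TriangularFuzzyNumber(self.l / other.u, self.m / other.m, self.u / other.l)

    def scale(self, lam: float) -> "TriangularFuzzyNumber":
        """Scalar multiple ``lam * (l, m, u)``; ``lam`` must be nonnegative."""
        if lam < 0:
            raise ValueError(f"scalar multiplier must be nonnegative, got {lam}")
        return TriangularFuzzyNumber(lam * self.l, lam * self.m, lam * self.u)

    # -- membership / defuzzification --------------------------------------

    def membership(self, x: float) -> float:
        """Piecewise-linear membership degree of ``x`` in ``[0, 1]``."""
        if x < self.l or x > self.u:
            return 0.0
        if x == self.m:
            return 1.0
        if x < self.m:
            return (x - self.l) / (self.m - self.l)
        return (self.u - x) / (self.u - self.m)

    def gmir(self) -> float:
        """Graded mean integration representation ``(l + 4m + u) / 6``."""
        return (self.l + 4.0 * self.m + self.u) / 6.0

    def centroid(self) -> float:
        """Centroid defuzzification ``(l + m + u) / 3``."""
        return (self.l + self.m + self.u) / 3.0

    # -- misc ---------------------------------------------------------------

    @property
    def is_degenerate(self) -> bool:
        return self.l == self.m == self.u

    @classmethod
    def crisp(cls, x: float) -> "TriangularFuzzyNumber":
        return cls(x, x, x)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.l, self.m, self.u)

    def almost_equal(self, other: "TriangularFuzzyNumber", tol: float = 1e-9) -> bool:
        return all(
            math.isclose(a, b, rel_tol=0.0, abs_tol=tol)
            for a, b in zip(self.as_tuple(), other.as_tuple())
        )

    def __repr__(self) -> str:  # compact, matches the field's (l,m,u) notation
        return f"TFN({self.l:g}, {self.m:g}, {self.u:g})"


TFN = TriangularFuzzyNumber


def defuzzify_gmir(a: TriangularFuzzyNumber) -> float:
    return a.gmir()


def defuzzify_centroid(a: TriangularFuzzyNumber) -> float:
    return a.centroid()


_DEFUZZIFIERS = {"gmir": defuzzify_gmir, "centroid": defuzzify_centroid}


def defuzzify(a: TriangularFuzzyNumber, method: str = "centroid") -> float:
    """Defuzzify ``a`` by the named method (``"centroid"`` or ``"gmir"``)."""
    try:
        return _DEFUZZIFIERS[method](a)
    except KeyError:
        raise ValueError(
            f"unknown defuzzifier {method!r}; expected one of {sorted(_DEFUZZIFIERS)}"
        ) from None


class UnknownTermError(KeyError):
    """A linguistic term that does not exist on the scale it was looked up on."""


@dataclass(frozen=True)
class LinguisticScale:
    """Ordered map from linguistic term labels to TFNs.

    ``ci`` optionally attaches a consistency index to each term (only the
    importance scale used by the Best–Worst Method carries one).
    """

    name: str
    entries: Mapping[str, TriangularFuzzyNumber]
    ci: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ValueError(f"scale {self.name!r} has no terms")

    def lookup(self, term: str) -> TriangularFuzzyNumber:
        try:
            return self.entries[term]
        except KeyError:
            raise UnknownTermError(
                f"term {term!r} is not on scale {self.name!r}; "
                f"known terms: {', '.join(self.entries)}"
            ) from None

    def consistency_index(self, term: str) -> float:
        if term not in self.entries:
            raise UnknownTermError(
                f"term {term!r} is not on scale {self.name!r}"
            )
        if term not in self.ci:
            raise KeyError(f"term {term!r} on scale {self.name!r} carries no consistency index")
        return self.ci[term]

    def __contains__(self, term: str) -> bool:
        return term in self.entries

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.entries)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dict(cls, spec: Mapping) -> "LinguisticScale":
        """Build a scale from ``{name, terms: [{label, l, m, u, ci?}, ...]}``."""
        entries: dict[str, TriangularFuzzyNumber] = {}
        ci: dict[str, float] = {}
        for t in spec["terms"]:
            label = t["label"]
            if label in entries:
                raise ValueError(f"duplicate term {label!r} in scale {spec['name']!r}")
            entries[label] = TriangularFuzzyNumber(float(t["l"]), float(t["m"]), float(t["u"]))
            if "ci" in t and t["ci"] is not None:
                ci[label] = float(t["ci"])
        return cls(name=spec["name"], entries=entries, ci=ci)

    @classmethod
    def from_file(cls, path: str | Path) -> "LinguisticScale":
        """Load a scale from a YAML or JSON file with the ``from_dict`` schema."""
        path = Path(path)
        text = path.read_text()
        spec = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(spec)


def _scale(name: str, rows: Iterable[tuple], with_ci: bool = False) -> LinguisticScale:
    entries, ci = {}, {}
    for row in rows:
        if with_ci:
            label, l, m, u, c = row
            ci[label] = c
        else:
            label, l, m, u = row
        entries[label] = TriangularFuzzyNumber(l, m, u)
    return LinguisticScale(name=name, entries=entries, ci=ci)


def importance_scale() -> LinguisticScale:
    """Six-term importance scale for pairwise comparisons, with consistency indices."""
    return _scale(
        "importance",
        [
            ("EI", 1.0, 1.0, 1.0, 3.00),
            ("WI", 2.0 / 3.0, 1.0, 1.5, 3.80),
            ("FI", 1.5, 2.0, 2.5, 5.29),
            ("I", 2.5, 3.0, 3.5, 6.69),
            ("VI", 3.5, 4.0, 4.5, 8.04),
            ("AI", 4.5, 5.0, 5.5, 9.35),
        ],
        with_ci=True,
    )


def reliability_scale() -> LinguisticScale:
    """Five-term reliability scale on [0, 1]."""
    return _scale(
        "reliability",
        [
            ("VL", 0.0, 0.0, 0.3),
            ("L", 0.1, 0.3, 0.5),
            ("M", 0.3, 0.5, 0.7),
            ("H", 0.5, 0.7, 0.9),
            ("VH", 0.7, 1.0, 1.0),
        ],
    )


def rating_scale() -> LinguisticScale:
    """Seven-term severity/occurrence/detection rating scale on the 0-10 range."""
    return _scale(
        "rating",
        [
            ("VL", 0.0, 1.0, 2.0),
            ("L", 1.0, 2.0, 3.0),
            ("ML", 2.0, 3.5, 5.0),
            ("M", 4.0, 5.0, 6.0),
            ("MH", 5.0, 6.5, 8.0),
            ("H", 7.0, 8.0, 9.0),
            ("VH", 8.0, 9.0, 10.0),
        ],
    )
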