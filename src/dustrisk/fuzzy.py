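"""Triangular fuzzy numbers, α-cut interval arithmetic, and risk-level classification.

A triangular fuzzy number (TFN) models an uncertain non-negative quantity by
its minimum, most-expected, and maximum values ``(a1, a2, a3)`` with a
piecewise-linear membership function peaking at ``a2``.  All arithmetic is
performed on α-cuts: the closed interval of values whose membership degree is
at least α.  Cutting at the confidence level α (conventionally 0.9) and
propagating the resulting intervals through the exposure equations yields
fuzzy risk intervals, which are finally classified against an ordered scheme
of carcinogenic-risk levels (I, negligible, below 1e-6, up to V, very high,
1e-4 and above) by overlap membership and the maximum-membership principle.

The interval product and quotient formulas used here are the endpoint
formulas valid for non-negative operands only; operands are validated rather
than generalising to signed interval arithmetic, because every physical
quantity in this model (concentration, intake, body weight, risk) is
non-negative.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

logger = logging.getLogger(__name__)

__all__ = [
    "TriangularFuzzyNumber",
    "AlphaCutInterval",
    "RiskLevel",
    "RiskLevelScheme",
    "DEFAULT_RISK_SCHEME",
    "DEFAULT_ALPHA",
    "make_tfn",
    "tfn_from_samples",
    "membership",
    "alpha_cut",
    "interval_binary",
    "interval_add",
    "interval_mul",
    "interval_div",
    "interval_scale",
    "classify_interval",
    "assign_level",
]

#: Conventional confidence level for α-cuts.
DEFAULT_ALPHA = 0.9

_ALPHA_MATCH_TOL = 1e-12


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """A non-negative triangular fuzzy number ``(a1, a2, a3)``.

    ``a1`` is the minimum value, ``a2`` the most-expected value, ``a3`` the
    maximum.  A degenerate TFN with ``a1 == a2 == a3`` represents a crisp
    (non-fuzzy) value.
    """

    a1: float
    a2: float
    a3: float

    def __post_init__(self) -> None:
        for name, v in (("a1", self.a1), ("a2", self.a2), ("a3", self.a3)):
            if not math.isfinite(v):
                raise ValueError(f"TFN component {name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(
                    f"TFN components must be non-negative, got {name} = {v}"
                )
        if self.a1 > self.a2:
            raise ValueError(f"TFN ordering violated: a1 > a2 ({self.a1} > {self.a2})")
        if self.a2 > self.a3:
            raise ValueError(f"TFN ordering violated: a2 > a3 ({self.a2} > {self.a3})")

    @property
    def is_crisp(self) -> bool:
        return self.a1 == self.a2 == self.a3

    def membership(self, x: float) -> float:
        return membership(self, x)

    def cut(self, alpha: float) -> "AlphaCutInterval":
        return alpha_cut(self, alpha)

    @classmethod
    def crisp(cls, value: float) -> "TriangularFuzzyNumber":
        """Degenerate TFN representing a crisp value."""
        return cls(value, value, value)


@dataclass(frozen=True)
class AlphaCutInterval:
    """Closed interval ``[lo, hi]`` cut from a fuzzy number at confidence α."""

    lo: float
    hi: float
    alpha: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"interval endpoints out of order: [{self.lo}, {self.hi}]")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def contains(self, x: float) -> bool:
        return self.lo <= x <= self.hi


@dataclass(frozen=True)
class RiskLevel:
    """One risk class: half-open interval ``[lower, upper)`` with a label."""

    label: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(
                f"risk level {self.label!r}: lower bound {self.lower} must be "
                f"below upper bound {self.upper}"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x: float) -> bool:
        return self.lower <= x < self.upper


@dataclass(frozen=True)
class RiskLevelScheme:
    """Ordered, contiguous, disjoint risk classes from least to most severe."""

    levels: Tuple[RiskLevel, ...]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("risk level scheme must contain at least one level")
        labels = [lv.label for lv in self.levels]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate risk level labels: {labels}")
        for a, b in zip(self.levels, self.levels[1:]):
            if a.upper != b.lower:
                raise ValueError(
                    f"risk levels {a.label!r} and {b.label!r} are not contiguous: "
                    f"{a.upper} != {b.lower}"
                )

    @property
    def labels(self) -> List[str]:
        return [lv.label for lv in self.levels]

    @property
    def top(self) -> float:
        return self.levels[-1].upper

    def level_of(self, x: float) -> RiskLevel:
        """The level containing *x* (the last level also claims its upper bound)."""
        for lv in self.levels:
            if lv.contains(x):
                return lv
        if x >= self.top:
            return self.levels[-1]
        return self.levels[0]

    def severity(self, label: str) -> int:
        return self.labels.index(label)


#: Carcinogenic-risk classes I–V: negligible (< 1e-6) through very high (>= 1e-4).
DEFAULT_RISK_SCHEME = RiskLevelScheme(
    levels=(
        RiskLevel("I", -math.inf, 1.0e-6),
        RiskLevel("II", 1.0e-6, 1.0e-5),
        RiskLevel("III", 1.0e-5, 5.0e-5),
        RiskLevel("IV", 5.0e-5, 1.0e-4),
        RiskLevel("V", 1.0e-4, 1.0),
    )
)

#: Membership degrees keyed by risk-level label, in scheme (severity) order.
MembershipVector = Dict[str, float]


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def make_tfn(a1: float, a2: float, a3: float) -> TriangularFuzzyNumber:
    """Validated TFN from minimum, most-expected, and maximum values."""
    return TriangularFuzzyNumber(float(a1), float(a2), float(a3))


def tfn_from_samples(
    values: Sequence[float], center_rule: str = "mean"
) -> TriangularFuzzyNumber:
    """Build a TFN from observed values: support = [min, max], mode = centre.

    The most-expected value ``a2`` is the mean (default) or median of the
    sample, clamped into the support.  A single observation yields a crisp
    TFN.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("cannot build a TFN from an empty sample")
    for v in vals:
        if v < 0:
            raise ValueError(f"TFN samples must be non-negative, got {v}")
    if center_rule == "mean":
        center = sum(vals) / len(vals)
    elif center_rule == "median":
        center = statistics.median(vals)
    else:
        raise ValueError(f"unknown center_rule {center_rule!r}; use 'mean' or 'median'")
    lo, hi = min(vals), max(vals)
    center = min(max(center, lo), hi)
    return TriangularFuzzyNumber(lo, center, hi)


# ---------------------------------------------------------------------------
# Membership and α-cuts
# ---------------------------------------------------------------------------

def membership(tfn: TriangularFuzzyNumber, x: float) -> float:
    """Piecewise-linear membership degree of *x* in *tfn*, in [0, 1].

    Degenerate segments (zero width) carry membership 1 at the point itself.
    """
    a1, a2, a3 = tfn.a1, tfn.a2, tfn.a3
    if x < a1 or x > a3:
        return 0.0
    if x == a2:
        return 1.0
    if x < a2:
        # a1 < x < a2 implies a2 > a1
        return (x - a1) / (a2 - a1)
    # a2 < x <= a3 implies a3 > a2
    return (a3 - x) / (a3 - a2)


def alpha_cut(tfn: TriangularFuzzyNumber, alpha: float) -> AlphaCutInterval:
    """α-cut ``[(a2−a1)α+a1, −(a3−a2)α+a3]``: the values with membership ≥ α."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if alpha == 0.0:
        return AlphaCutInterval(tfn.a1, tfn.a3, 0.0)
    if alpha == 1.0:
        return AlphaCutInterval(tfn.a2, tfn.a2, 1.0)
    lo = (tfn.a2 - tfn.a1) * alpha + tfn.a1
    hi = -(tfn.a3 - tfn.a2) * alpha + tfn.a3
    if lo > hi:
        # rounding noise at a near-degenerate cut; mathematically lo <= hi
        lo = hi = 0.5 * (lo + hi)
    return AlphaCutInterval(lo, hi, alpha)


# ---------------------------------------------------------------------------
# Interval algebra (non-negative operands)
# ---------------------------------------------------------------------------

def _check_same_alpha(a: AlphaCutInterval, b: AlphaCutInterval) -> float:
    if abs(a.alpha - b.alpha) > _ALPHA_MATCH_TOL:
        raise ValueError(
            f"mismatched confidence levels: alpha={a.alpha} vs alpha={b.alpha}"
        )
    return a.alpha


def interval_add(a: AlphaCutInterval, b: AlphaCutInterval) -> AlphaCutInterval:
    alpha = _check_same_alpha(a, b)
    return AlphaCutInterval(a.lo + b.lo, a.hi + b.hi, alpha)


def interval_mul(a: AlphaCutInterval, b: AlphaCutInterval) -> AlphaCutInterval:
    alpha = _check_same_alpha(a, b)
    if a.lo < 0 or b.lo < 0:
        raise ValueError(
            "interval product requires non-negative operands; "
            f"got [{a.lo}, {a.hi}] and [{b.lo}, {b.hi}]"
        )
    return AlphaCutInterval(a.lo * b.lo, a.hi * b.hi, alpha)


def interval_div(a: AlphaCutInterval, b: AlphaCutInterval) -> AlphaCutInterval:
    alpha = _check_same_alpha(a, b)
    if a.lo < 0:
        raise ValueError(
            f"interval quotient requires a non-negative numerator; got [{a.lo}, {a.hi}]"
        )
    if b.lo <= 0:
        raise ValueError(
            f"interval quotient requires a strictly positive denominator; "
            f"got [{b.lo}, {b.hi}]"
        )
    return AlphaCutInterval(a.lo / b.hi, a.hi / b.lo, alpha)


_BINARY_OPS = {"add": interval_add, "mul": interval_mul, "div": interval_div}


def interval_binary(
    op: str, a: AlphaCutInterval, b: AlphaCutInterval
) -> AlphaCutInterval:
    """Dispatch ``add``/``mul``/``div`` on two α-cut intervals of equal α."""
    try:
        fn = _BINARY_OPS[op]
    except KeyError:
        raise ValueError(f"unknown interval operation {op!r}") from None
    return fn(a, b)


def interval_scale(k: float, a: AlphaCutInterval) -> AlphaCutInterval:
    """Scale an interval by a non-negative crisp factor."""
    if k < 0:
        raise ValueError(f"scale factor must be non-negative, got {k}")
    return AlphaCutInterval(k * a.lo, k * a.hi, a.alpha)


# ---------------------------------------------------------------------------
# Risk-level classification
# ---------------------------------------------------------------------------

def classify_interval(
    interval: AlphaCutInterval,
    scheme: RiskLevelScheme = DEFAULT_RISK_SCHEME,
    normalization: str = "computed_interval",
) -> MembershipVector:
    """Membership degrees of a risk interval in each level of *scheme*.

    Each level receives ``len(interval ∩ level) / D``.  Under the default
    ``computed_interval`` normalisation D is the width of the classified
    interval, so degrees sum to 1 whenever the interval has positive width
    and lies inside the scheme's coverage.  Under ``level_interval`` D is the
    width of the level, an alternative normalisation in which degrees need
    not sum to 1; for the open-ended lowest class the width is measured from
    zero, since risk quantities are non-negative.

    A zero-width (point) interval gets membership 1 for the level containing
    the point.  Values at or above the scheme's top bound are clamped into
    the most severe level with a logged warning.
    """
    if normalization not in ("computed_interval", "level_interval"):
        raise ValueError(
            f"unknown normalization {normalization!r}; "
            "use 'computed_interval' or 'level_interval'"
        )
    lo, hi = interval.lo, interval.hi
    top = scheme.top
    if hi > top:
        logger.warning(
            "risk interval [%g, %g] exceeds the scheme's top bound %g; "
            "clamping into the most severe level %r",
            lo, hi, top, scheme.levels[-1].label,
        )
        hi = min(hi, top)
        lo = min(lo, top)

    mv: MembershipVector = {lv.label: 0.0 for lv in scheme.levels}
    if hi == lo:
        mv[scheme.level_of(lo).label] = 1.0
        return mv

    width = hi - lo
    for lv in scheme.levels:
        overlap = min(hi, lv.upper) - max(lo, lv.lower)
        if overlap <= 0:
            continue
        if normalization == "computed_interval":
            mv[lv.label] = overlap / width
        else:
            # risk quantities are non-negative, so an open lower end
            # contributes no width below zero
            eff_width = lv.upper - max(lv.lower, 0.0)
            mv[lv.label] = overlap / eff_width
    return mv


def assign_level(mv: Mapping[str, float]) -> str:
    """Label with the maximum membership degree (maximum-membership principle).

    Ties are broken toward the more severe level — the later entry in the
    vector's (scheme) order — which is conservative for health protection.
    """
    if not mv:
        raise ValueError("cannot assign a level from an empty membership vector")
    best_label = None
    best_degree = 0.0
    for label, degree in mv.items():
        if degree >= best_degree and degree > 0.0:
            best_label, best_degree = label, degree
    if best_label is None:
        raise ValueError("cannot assign a level: all membership degrees are zero")
    return best_label
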