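"""Focal-group marker screen and its binomial chance model.

Given a binary gene-family matrix and a focal subset of strains (here,
fructophilic lactic acid bacteria within a family-wide panel), a family is

* **specific** when it is conserved in more than ``q_high`` of the focal
  strains but less than ``q_low`` of the remaining strains, and
* **missing** when it is conserved in less than ``q_low`` of the focal
  strains but more than ``q_high`` of the remaining strains.

The strict fractions convert to integer cutoffs as ``floor(q_high*n)+1``
(minimum count for "more than") and ``ceil(q_low*n)-1`` (maximum count
for "less than"); at the canonical panel shape (10 focal, 164 others,
80%/20%) these are >= 9 of 10, <= 1 of 10, >= 132 of 164 and <= 32 of 164.

The chance model asks how often independent random loss would fabricate a
hit.  If each of the ``n`` strains loses a family independently with
probability ``x``, the probability that the family passes the "missing"
screen by chance is the product of two binomial tail sums,

    f(x) = [ sum_{k<=k_focal} C(n_f,k) (1-x)^k x^(n_f-k) ]
           * [ sum_{k<=k_other} C(n_o,k) x^k (1-x)^(n_o-k) ],

whose single sharp peak over x in (0,1) bounds the per-family false-hit
probability; multiplied by the pan-genome size it bounds the expected
number of chance hits at the least favourable loss rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import PresenceMatrix

__all__ = [
    "ScreenThresholds",
    "ScreenResult",
    "ChanceModel",
    "make_thresholds",
    "screen",
    "chance_probability",
    "find_peak",
    "expected_chance_hits",
]

# guard against binary representation of q*n straddling an integer
_EPS = 1e-9


@dataclass(frozen=True)
class ScreenThresholds:
    """Integer conservation cutoffs for the specific/missing screen."""

    n_focal: int
    n_other: int
    q_high: float
    q_low: float
    k_focal_high: int
    k_focal_low: int
    k_other_high: int
    k_other_low: int

    def __post_init__(self) -> None:
        for n, lo, hi in (
            (self.n_focal, self.k_focal_low, self.k_focal_high),
            (self.n_other, self.k_other_low, self.k_other_high),
        ):
            if not (0 <= lo < hi <= n):
                raise ValidationError(
                    f"inconsistent cutoffs low={lo}, high={hi} for n={n}"
                )


def make_thresholds(
    n_focal: int, n_other: int, q_high: float = 0.8, q_low: float = 0.2
) -> ScreenThresholds:
    """Convert strict conservation fractions to integer cutoffs.

    "Conserved in more than ``q_high``" means a count of at least
    ``floor(q_high*n) + 1``; "conserved in less than ``q_low``" means at
    most ``ceil(q_low*n) - 1``.
    """
    if n_focal < 1 or n_other < 1:
        raise ValidationError("n_focal and n_other must be >= 1")
    if not (0 < q_low < q_high < 1):
        raise ValidationError(f"need 0 < q_low < q_high < 1, got {q_low}, {q_high}")

    def high(n: int) -> int:
        return int(math.floor(q_high * n + _EPS)) + 1

    def low(n: int) -> int:
        return int(math.ceil(q_low * n - _EPS)) - 1

    return ScreenThresholds(
        n_focal=n_focal,
        n_other=n_other,
        q_high=q_high,
        q_low=q_low,
        k_focal_high=high(n_focal),
        k_focal_low=low(n_focal),
        k_other_high=high(n_other),
        k_other_low=low(n_other),
    )


@dataclass
class ScreenResult:
    """Per-family conservation counts and screen category.

    ``table`` has one row per family with columns ``focal_count``,
    ``other_count`` and ``category`` in {specific, missing, neither}.
    """

    table: pd.DataFrame
    thresholds: ScreenThresholds

    @property
    def specific(self) -> list[str]:
        return list(self.table.index[self.table["category"] == "specific"])

    @property
    def missing(self) -> list[str]:
        return list(self.table.index[self.table["category"] == "missing"])


def screen(
    presence: PresenceMatrix,
    focal: Iterable[str],
    thresholds: ScreenThresholds | None = None,
) -> ScreenResult:
    """Classify every family as specific, missing, or neither.

    ``focal`` must be a non-empty strict subset of the matrix strains.
    If ``thresholds`` is omitted, the default 80%/20% rule is applied at
    the observed group sizes.
    """
    focal = list(dict.fromkeys(focal))
    strains = presence.strains
    missing_strains = set(focal) - set(strains)
    if missing_strains:
        raise ValidationError(
            f"focal strains absent from matrix: {sorted(missing_strains)}"
        )
    if not focal or len(focal) == len(strains):
        raise ValidationError("focal set must be a non-empty strict subset of strains")
    other = [s for s in strains if s not in set(focal)]
    if thresholds is None:
        thresholds = make_thresholds(len(focal), len(other))
    if thresholds.n_focal != len(focal) or thresholds.n_other != len(other):
        raise ValidationError(
            "threshold group sizes do not match the matrix/focal split"
        )
    vals = presence.values
    focal_count = vals[focal].sum(axis=1)
    other_count = vals[other].sum(axis=1)
    is_specific = (focal_count >= thresholds.k_focal_high) & (
        other_count <= thresholds.k_other_low
    )
    is_missing = (focal_count <= thresholds.k_focal_low) & (
        other_count >= thresholds.k_other_high
    )
    category = np.where(is_specific, "specific", np.where(is_missing, "missing", "neither"))
    table = pd.DataFrame(
        {
            "focal_count": focal_count.astype(int),
            "other_count": other_count.astype(int),
            "category": category,
        },
        index=vals.index,
    )
    return ScreenResult(table=table, thresholds=thresholds)


@dataclass(frozen=True)
class ChanceModel:
    """Binomial null for chance hits under independent per-strain loss.

    ``k_focal`` caps the number of focal strains that may retain the
    family; ``k_other`` caps the number of other strains that may lose it.
    Defaults are the canonical 10/164 panel with the <=1 / <=32 caps.
    """

    n_focal: int = 10
    n_other: int = 164
    k_focal: int = 1
    k_other: int = 32

    def __post_init__(self) -> None:
        if not (0 <= self.k_focal <= self.n_focal):
            raise ValidationError("k_focal must lie in [0, n_focal]")
        if not (0 <= self.k_other <= self.n_other):
            raise ValidationError("k_other must lie in [0, n_other]")


def _log_binom_cdf_terms(n: int, k_max: int, log_p: float, log_q: float) -> float:
    """sum_{k=0}^{k_max} C(n,k) p^k q^(n-k) via log-space terms.

    Terms are exponentiated individually and accumulated with Neumaier
    compensated summation, keeping the relative error near machine
    precision even when the terms span many orders of magnitude.
    """
    total = 0.0
    comp = 0.0
    for k in range(k_max + 1):
        log_term = (
            math.lgamma(n + 1)
            - math.lgamma(k + 1)
            - math.lgamma(n - k + 1)
            + k * log_p
            + (n - k) * log_q
        )
        term = math.exp(log_term)
        t = total + term
        if abs(total) >= abs(term):
            comp += (total - t) + term
        else:
            comp += (term - t) + total
        total = t
    return total + comp


def retained_factor(x: float, model: ChanceModel) -> float:
    """P(at most ``k_focal`` of the focal strains retain the family)."""
    if x == 0.0:
        return 0.0 if model.k_focal < model.n_focal else 1.0
    if x == 1.0:
        return 1.0
    # retained count k ~ Binomial(n_focal, 1 - x)
    return _log_binom_cdf_terms(
        model.n_focal, model.k_focal, math.log1p(-x), math.log(x)
    )


def lost_factor(x: float, model: ChanceModel) -> float:
    """P(at most ``k_other`` of the other strains lose the family)."""
    if x == 1.0:
        return 0.0 if model.k_other < model.n_other else 1.0
    if x == 0.0:
        return 1.0
    # lost count k ~ Binomial(n_other, x)
    return _log_binom_cdf_terms(
        model.n_other, model.k_other, math.log(x), math.log1p(-x)
    )


def chance_probability(x: float, model: ChanceModel | None = None) -> float:
    """f(x): probability that random loss at rate ``x`` fabricates a hit.

    Product of the focal retained-count tail and the other-group
    lost-count tail; vanishes at both endpoints for the canonical caps.
    """
    if model is None:
        model = ChanceModel()
    if not (0.0 <= x <= 1.0):
        raise ValidationError(f"loss probability x must lie in [0, 1], got {x}")
    return retained_factor(x, model) * lost_factor(x, model)


def find_peak(
    model: ChanceModel | None = None, grid_step: float = 1e-4
) -> tuple[float, float]:
    """Locate the single sharp peak of f on [0, 1].

    A dense grid scan brackets the maximum, then golden-section search
    refines the argmax to |dx| < 1e-8.
    """
    if model is None:
        model = ChanceModel()
    xs = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    fs = np.array([chance_probability(float(x), model) for x in xs])
    i = int(np.argmax(fs))
    lo = xs[max(i - 1, 0)]
    hi = xs[min(i + 1, len(xs) - 1)]
    inv_phi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = float(lo), float(hi)
    c = b - inv_phi * (b - a)
    d = a + inv_phi * (b - a)
    fc = chance_probability(c, model)
    fd = chance_probability(d, model)
    while b - a > 1e-8:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - inv_phi * (b - a)
            fc = chance_probability(c, model)
        else:
            a, c, fc = c, d, fd
            d = a + inv_phi * (b - a)
            fd = chance_probability(d, model)
    x_peak = (a + b) / 2.0
    return x_peak, chance_probability(x_peak, model)


def expected_chance_hits(f_peak: float, n_families: int) -> float:
    """Upper-envelope expected number of chance hits in a pan-genome.

    Evaluates ``f_peak * n_families``: the expected hit count if every
    family were lost independently at the least favourable rate.  An
    observed hit count far above this bound is evidence of selection
    rather than chance.
    """
    if n_families < 1:
        raise ValidationError("n_families must be >= 1")
    if f_peak < 0:
        raise ValidationError("f_peak must be >= 0")
    return f_peak * n_families
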