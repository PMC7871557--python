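"""Per-class ordinary least squares of gene count on genome size.

Across a family of bacterial genomes, the number of genes in a functional
class tends to rise approximately linearly with genome size.  The slope of
that line (genes per Mbp) measures how strongly the class participates in
genome expansion and reduction; ranking classes by slope identifies the
functions that shrink fastest in reduced genomes (carbohydrate transport
and metabolism, class G, is the canonical leader in Lactobacillaceae).

Given a fitted line, the *deduced* count for a strain is the line's
prediction at its genome size, and the *shortfall* is the observed count
expressed as an integer percentage of the deduced count.  A focal strain
sitting far below the family-wide line is the regression-level signature
of class-specific reductive evolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateDesignError, ValidationError
from .io_formats import ClassCountTable, GenomeRecord

__all__ = [
    "RegressionFit",
    "ShortfallReport",
    "fit_class_regression",
    "fit_all_classes",
    "rank_classes",
    "deduce_count",
    "shortfall",
    "round_half_away",
]


@dataclass(frozen=True)
class RegressionFit:
    """One class's count-versus-size line.

    ``slope`` is in genes per Mbp, ``intercept`` in genes, ``r2`` is the
    coefficient of determination and ``n`` the number of strains fitted.
    ``degenerate`` flags classes with zero genes in every strain, which
    are reported with a zero line rather than omitted.
    """

    class_code: str
    slope: float
    intercept: float
    r2: float
    n: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("a regression fit needs n >= 2 strains")
        if not math.isfinite(self.slope):
            raise ValidationError("slope must be finite")
        if not (-1e-12 <= self.r2 <= 1 + 1e-12):
            raise ValidationError(f"r2 out of [0, 1]: {self.r2}")


@dataclass(frozen=True)
class ShortfallReport:
    """Observed count against the deduced (line-predicted) count."""

    strain_id: str
    class_code: str
    observed: int
    deduced: float
    percent: int


def round_half_away(value: float) -> int:
    """Round to the nearest integer with halves away from zero."""
    return int(math.floor(value + 0.5)) if value >= 0 else -int(math.floor(-value + 0.5))


def fit_class_regression(
    metadata: Sequence[GenomeRecord],
    class_counts: ClassCountTable,
    class_code: str,
) -> RegressionFit:
    """Fit count = slope * genome_size + intercept for one class by OLS.

    Genome size (Mbp) is the predictor and the class gene count the
    response.  Sums are evaluated with numpy's pairwise summation in the
    metadata's strain order, so the fit is bit-for-bit reproducible for a
    given input order.  All-identical sizes raise
    :class:`DegenerateDesignError`; an all-zero class is returned as a
    flagged zero line.
    """
    if class_code not in class_counts.counts.columns:
        raise ValidationError(f"unknown class code {class_code!r}")
    ids = [r.strain_id for r in metadata]
    if len(ids) < 2:
        raise ValidationError("need at least 2 strains to fit a regression")
    try:
        y = class_counts.counts.loc[ids, class_code].to_numpy(dtype=np.float64)
    except KeyError as exc:
        raise ValidationError(f"metadata strain missing from count table: {exc}") from exc
    x = np.array([r.genome_size_mbp for r in metadata], dtype=np.float64)

    sxx = float(np.sum((x - np.mean(x)) ** 2))
    if sxx == 0.0:
        raise DegenerateDesignError("all genome sizes identical; slope undefined")
    if not np.any(y):
        return RegressionFit(class_code, 0.0, 0.0, 0.0, len(ids), degenerate=True)

    sxy = float(np.sum((x - np.mean(x)) * (y - np.mean(y))))
    slope = sxy / sxx
    intercept = float(np.mean(y)) - slope * float(np.mean(x))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        # flat response: the zero-slope line explains nothing and misses nothing
        return RegressionFit(class_code, 0.0, float(np.mean(y)), 0.0, len(ids))
    resid = y - (slope * x + intercept)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    return RegressionFit(class_code, slope, intercept, r2, len(ids))


def fit_all_classes(
    metadata: Sequence[GenomeRecord], class_counts: ClassCountTable
) -> list[RegressionFit]:
    """Fit every class in the count table, in column order."""
    return [
        fit_class_regression(metadata, class_counts, code)
        for code in class_counts.classes
    ]


def rank_classes(fits: Sequence[RegressionFit]) -> list[tuple[str, float]]:
    """Order classes by descending slope; ties break alphabetically."""
    if not fits:
        raise ValidationError("rank_classes needs at least one fit")
    return [
        (f.class_code, f.slope)
        for f in sorted(fits, key=lambda f: (-f.slope, f.class_code))
    ]


def deduce_count(fit: RegressionFit, genome_size_mbp: float) -> float:
    """Predicted (deduced) gene count at a genome size, unrounded."""
    if not genome_size_mbp > 0:
        raise ValidationError("genome_size_mbp must be > 0")
    return fit.slope * genome_size_mbp + fit.intercept


def shortfall(
    observed: int,
    deduced: float,
    strain_id: str = "",
    class_code: str = "",
) -> ShortfallReport:
    """Observed count as an integer percentage of the deduced count.

    The percentage is computed from the *unrounded* deduced value and then
    rounded half-away-from-zero; deduced counts themselves are displayed
    rounded but never fed back rounded into the ratio.
    """
    if not deduced > 0:
        raise ValidationError(f"deduced count must be > 0, got {deduced}")
    if observed < 0:
        raise ValidationError("observed count must be >= 0")
    percent = round_half_away(100.0 * observed / deduced)
    return ShortfallReport(
        strain_id=strain_id,
        class_code=class_code,
        observed=observed,
        deduced=deduced,
        percent=percent,
    )
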