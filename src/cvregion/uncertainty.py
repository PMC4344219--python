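"""Margin-of-error algebra for survey estimates.

The American Community Survey (and comparable surveys) publish each estimate
with a margin of error (MOE), the half-width of a 90% confidence interval, so

    SE = MOE / 1.645        and        CV = SE / estimate.

Region-level standard errors follow the US Census Bureau aggregation rules:
counts add with root-sum-of-squares standard errors; derived proportions and
ratios combine numerator and denominator uncertainty through the standard
approximation formulas.  All functions here operate on plain numbers or on
:class:`UncertainValue` pairs; nothing is survey-format specific.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

#: z-score of the 90% confidence level used for published ACS margins of error.
Z90 = 1.645


@dataclass(frozen=True)
class UncertainValue:
    """An estimate together with its standard error (same units)."""

    estimate: float
    se: float

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError(f"standard error must be nonnegative, got {self.se}")

    @property
    def moe(self) -> float:
        """90%-level margin of error, ``1.645 * se``."""
        return Z90 * self.se

    @classmethod
    def from_moe(cls, estimate: float, moe: float) -> "UncertainValue":
        return cls(estimate, moe_to_se(moe))


@dataclass
class FallbackLog:
    """Counts derived-proportion computations that fell back to the ratio form.

    The proportion standard-error formula has a negative radicand whenever the
    denominator is relatively noisier than the numerator; standard guidance is
    to switch to the (conservative) ratio form in that case.  Every switch is
    recorded here so a run can report how often it happened.
    """

    count: int = 0
    variables: list[str] = field(default_factory=list)

    def record(self, label: str = "") -> None:
        self.count += 1
        if label:
            self.variables.append(label)


def moe_to_se(moe: float) -> float:
    """Convert a 90%-level margin of error to a standard error."""
    if moe < 0:
        raise ValueError(f"margin of error must be nonnegative, got {moe}")
    return moe / Z90


def se_to_moe(se: float) -> float:
    """Convert a standard error to a 90%-level margin of error."""
    if se < 0:
        raise ValueError(f"standard error must be nonnegative, got {se}")
    return se * Z90


def cv(estimate: float, moe: float) -> float:
    """Coefficient of variation, ``moe / (1.645 * estimate)``.

    A zero estimate with a zero MOE is treated as perfectly known (CV 0); a
    zero estimate with positive MOE returns ``inf`` so that constraint checks
    fail loudly instead of silently passing.
    """
    if moe < 0:
        raise ValueError(f"margin of error must be nonnegative, got {moe}")
    if estimate < 0:
        raise ValueError(f"estimate must be nonnegative for a CV, got {estimate}")
    if estimate == 0:
        return 0.0 if moe == 0 else math.inf
    return moe / (Z90 * estimate)


def aggregate_count(values: Sequence[UncertainValue] | Iterable[UncertainValue]) -> UncertainValue:
    """Sum count estimates; standard errors add in quadrature."""
    values = list(values)
    if not values:
        raise ValueError("cannot aggregate an empty collection of values")
    est = sum(v.estimate for v in values)
    se = math.sqrt(sum(v.se * v.se for v in values))
    return UncertainValue(est, se)


def derived_se(
    num: UncertainValue,
    den: UncertainValue,
    kind: Literal["proportion", "mean"],
    fallback: FallbackLog | None = None,
    label: str = "",
) -> UncertainValue:
    """Estimate and SE of a derived proportion or mean (ratio).

    ``kind="proportion"`` assumes the numerator counts a subset of the
    denominator (e.g. people in poverty / all people), which induces negative
    covariance and a minus sign under the radical:

        se = sqrt(se_num^2 - p^2 * se_den^2) / den

    If the radicand is negative the ratio form (plus sign) is used instead and
    the event is recorded in *fallback*.  ``kind="mean"`` is the ratio of two
    non-nested quantities (e.g. aggregate income / persons):

        se = sqrt(se_num^2 + p^2 * se_den^2) / den
    """
    if den.estimate <= 0:
        raise ValueError(
            f"denominator estimate must be positive, got {den.estimate} "
            "(zero-denominator areas should be filtered during preprocessing)"
        )
    if kind not in ("proportion", "mean"):
        raise ValueError(f"kind must be 'proportion' or 'mean', got {kind!r}")
    p = num.estimate / den.estimate
    if kind == "proportion":
        radicand = num.se**2 - p * p * den.se**2
        if radicand < 0:
            radicand = num.se**2 + p * p * den.se**2
            if fallback is not None:
                fallback.record(label)
    else:
        radicand = num.se**2 + p * p * den.se**2
    return UncertainValue(p, math.sqrt(radicand) / den.estimate)


def interval(value: UncertainValue, nonnegative: bool = False) -> tuple[float, float]:
    """90% confidence interval; the lower bound is clipped at 0 when the
    quantity cannot be negative (counts, proportions)."""
    lower = value.estimate - Z90 * value.se
    upper = value.estimate + Z90 * value.se
    if nonnegative:
        lower = max(lower, 0.0)
    return lower, upper


def region_cv_table(region, table, specs, fallback: FallbackLog | None = None):
    """Aggregate a set of areas and return per-variable (estimate, se, cv).

    Counts are summed with root-sum-of-squares SEs; proportions and means are
    re-derived from the aggregated numerator and denominator.  Returns a dict
    ``{variable name: UncertainValue-with-cv}`` represented as
    ``{name: (estimate, se, cv)}``.

    This is the plain row-by-row reference path; the optimizer keeps running
    sums internally but must agree with this function exactly.
    """
    region = list(region)
    if not region:
        raise ValueError("region must contain at least one area")
    out: dict[str, tuple[float, float, float]] = {}
    for spec in specs:
        nums = [
            UncertainValue.from_moe(
                float(table.df.at[a, spec.num_est]), float(table.df.at[a, spec.num_moe])
            )
            for a in region
        ]
        agg_num = aggregate_count(nums)
        if spec.kind == "count":
            val = agg_num
        else:
            dens = [
                UncertainValue.from_moe(
                    float(table.df.at[a, spec.den_est]), float(table.df.at[a, spec.den_moe])
                )
                for a in region
            ]
            agg_den = aggregate_count(dens)
            if agg_den.estimate <= 0:
                out[spec.name] = (math.nan, math.nan, math.inf)
                continue
            val = derived_se(agg_num, agg_den, spec.kind, fallback, spec.name)
        out[spec.name] = (val.estimate, val.se, cv(val.estimate, val.moe))
    return out
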