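"""Occupational-epidemiology support computations.

Exact-Poisson power for detecting a relative risk against an expected
count, standardized mortality ratios with exact (Garwood) confidence
intervals, the referent-deficit inflation of internally referenced
relative risks, and the excess-cancer projection used as a reality check
of a unit risk against an observed cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CohortStratum",
    "RiskProjection",
    "ReferentRow",
    "poisson_exact_power",
    "poisson_critical_count",
    "smr_exact_ci",
    "referent_inflation",
    "excess_cases",
    "whole_cases",
]


@dataclass(frozen=True)
class CohortStratum:
    """Observed and expected deaths for one exposure stratum."""

    label: str
    observed: int
    expected: float

    def __post_init__(self) -> None:
        if self.observed < 0:
            raise ValueError("observed must be >= 0")
        if self.expected <= 0:
            raise ValueError("expected must be > 0")

    @property
    def smr(self) -> float:
        return self.observed / self.expected

    @classmethod
    def from_rate(
        cls, label: str, observed: int, person_years: float, reference_rate: float
    ) -> "CohortStratum":
        """Build from person-years and a reference rate (per person-year)."""
        return cls(label, observed, person_years * reference_rate)


@dataclass(frozen=True)
class RiskProjection:
    """Excess cancers implied by a unit risk over an exposed population."""

    iur: float  # per µg/m³
    lifetime_conc: float  # µg/m³
    n_exposed: int
    excess_cases: float


def poisson_critical_count(expected: float, alpha: float) -> int:
    """Smallest k with P(X >= k | expected) <= alpha under the null Poisson."""
    if expected <= 0:
        raise ValueError("expected must be > 0")
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    # P(X >= k) = sf(k - 1); isf gives the smallest k with sf(k) <= alpha.
    k = int(stats.poisson.isf(alpha, expected)) + 1
    while k > 0 and stats.poisson.sf(k - 2, expected) <= alpha:
        k -= 1
    return k


def poisson_exact_power(expected: float, rr: float, alpha: float = 0.05) -> float:
    """Exact one-sided Poisson power to detect a true relative risk ``rr``.

    The critical count k* is the smallest count significant at level
    ``alpha`` under the null (mean = expected); power is the probability of
    reaching k* when the true mean is rr * expected.  Tail sums are exact —
    no normal approximation.
    """
    if rr < 1:
        raise ValueError("rr must be >= 1")
    k_star = poisson_critical_count(expected, alpha)
    return float(stats.poisson.sf(k_star - 1, rr * expected))


def smr_exact_ci(
    observed: int, expected: float, level: float = 0.95
) -> tuple[float, float, float]:
    """SMR with exact (Garwood) confidence limits.

    Limits are gamma quantiles of the observed count: lower
    q_gamma(alpha/2; O)/E (0 when O = 0), upper q_gamma(1 - alpha/2; O+1)/E
    — equivalently chi-square limits.
    """
    if expected <= 0:
        raise ValueError("expected must be > 0")
    if observed < 0:
        raise ValueError("observed must be >= 0")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    smr = observed / expected
    lower = 0.0 if observed == 0 else float(stats.gamma.ppf(alpha / 2, observed)) / expected
    upper = float(stats.gamma.ppf(1.0 - alpha / 2, observed + 1)) / expected
    return smr, lower, upper


@dataclass(frozen=True)
class ReferentRow:
    label: str
    smr: float
    implied_rr: float
    internal_rr: float | None = None


def referent_inflation(
    strata: list[CohortStratum], internal_rrs: list[float] | None = None
) -> tuple[float, list[ReferentRow]]:
    """Implied relative risks when SMRs are re-expressed against the first
    stratum as internal referent.

    A deficit in the referent (SMR < 1) inflates every internally
    referenced RR by the factor 1 / SMR_ref; the rows expose
    SMR_i / SMR_ref next to any user-supplied internal RRs for comparison.
    Returns (inflation factor, rows).
    """
    if not strata:
        raise ValueError("strata must be nonempty")
    smr_ref = strata[0].smr
    if smr_ref == 0:
        raise ValueError("referent stratum has SMR = 0")
    if internal_rrs is not None and len(internal_rrs) != len(strata):
        raise ValueError("internal_rrs must align with strata")
    rows = [
        ReferentRow(
            label=s.label,
            smr=s.smr,
            implied_rr=s.smr / smr_ref,
            internal_rr=None if internal_rrs is None else internal_rrs[i],
        )
        for i, s in enumerate(strata)
    ]
    return 1.0 / smr_ref, rows


def excess_cases(iur: float, lifetime_conc: float, n_exposed: int) -> RiskProjection:
    """Excess cancers = unit risk x lifetime concentration x exposed workers.

    The product is kept at full precision; round only at display.
    """
    if iur < 0 or lifetime_conc < 0 or n_exposed < 0:
        raise ValueError("all inputs must be >= 0")
    return RiskProjection(
        iur=iur,
        lifetime_conc=lifetime_conc,
        n_exposed=n_exposed,
        excess_cases=iur * lifetime_conc * n_exposed,
    )


def whole_cases(excess: float) -> int:
    """Display convention for projected case counts: round up to the next
    whole case (conservative, as risk projections conventionally are)."""
    import math

    if excess < 0:
        raise ValueError("excess must be >= 0")
    return math.ceil(excess - 1e-9)
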