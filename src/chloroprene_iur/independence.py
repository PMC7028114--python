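"""Tetrachoric correlation between tumor sites from 2x2 co-occurrence tables.

A tetrachoric correlation models two dichotomous outcomes (tumor at site A
yes/no, tumor at site B yes/no) as thresholded coordinates of a latent
bivariate normal with correlation rho.  The thresholds are fixed at the
standard-normal quantiles of the empirical marginals (the usual two-step
estimator) and rho maximizes the orthant (multinomial cell) likelihood.
A likelihood-ratio chi-square with one degree of freedom tests rho = 0.

Used here to probe the assumption — implicit in summing tumor-site
potencies into a composite unit risk — that tumor occurrences at
different sites are statistically independent.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .bioassay import TumorPairMarginals

__all__ = [
    "FourfoldTable",
    "TetrachoricResult",
    "TetrachoricMethod",
    "reconstruct_fourfold",
    "orthant_probabilities",
    "tetrachoric_loglik",
    "tetrachoric_mle",
    "tetrachoric_grid",
    "independence_screen",
    "ScreenRow",
    "RHO_BOUND",
    "POSITIVE_CORRELATION_FLAG",
]

#: rho estimates are clipped to +/- this bound; hitting it flags a boundary table.
RHO_BOUND = 0.999

#: Correlations above this are flagged as discernable positive correlation.
POSITIVE_CORRELATION_FLAG = 0.25


class TetrachoricMethod(str, enum.Enum):
    ML = "ml"
    GRID = "grid"


@dataclass(frozen=True)
class FourfoldTable:
    """2x2 co-occurrence counts (both, first only, second only, neither)."""

    n_both: int
    n_first_only: int
    n_second_only: int
    n_neither: int

    def __post_init__(self) -> None:
        cells = (self.n_both, self.n_first_only, self.n_second_only, self.n_neither)
        if any(c < 0 for c in cells):
            raise ValueError("cell counts must be >= 0")
        if sum(cells) == 0:
            raise ValueError("table total must be > 0")

    @property
    def total(self) -> int:
        return self.n_both + self.n_first_only + self.n_second_only + self.n_neither

    @property
    def margin_first(self) -> int:
        return self.n_both + self.n_first_only

    @property
    def margin_second(self) -> int:
        return self.n_both + self.n_second_only

    def swapped(self) -> "FourfoldTable":
        """Exchange the two variables."""
        return FourfoldTable(
            self.n_both, self.n_second_only, self.n_first_only, self.n_neither
        )

    def first_flipped(self) -> "FourfoldTable":
        """Flip the coding (positive <-> negative) of the first variable."""
        return FourfoldTable(
            self.n_second_only, self.n_neither, self.n_both, self.n_first_only
        )


@dataclass(frozen=True)
class TetrachoricResult:
    rho: float
    tau1: float
    tau2: float
    p_value: float
    method: TetrachoricMethod
    boundary: bool = False


def reconstruct_fourfold(
    n_total: int, m_first: int, m_second: int, n_both: int
) -> FourfoldTable:
    """Rebuild the 2x2 table from the two marginals and the joint count."""
    if n_both > min(m_first, m_second):
        raise ValueError(
            f"joint count {n_both} exceeds a marginal (first={m_first}, "
            f"second={m_second})"
        )
    n_neither = n_total - m_first - m_second + n_both
    if n_neither < 0:
        raise ValueError(
            f"infeasible marginals: first={m_first}, second={m_second}, "
            f"both={n_both} overflow total={n_total}"
        )
    return FourfoldTable(
        n_both=n_both,
        n_first_only=m_first - n_both,
        n_second_only=m_second - n_both,
        n_neither=n_neither,
    )


def _thresholds(table: FourfoldTable) -> tuple[float, float]:
    n = table.total
    p1 = table.margin_first / n
    p2 = table.margin_second / n
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        raise ValueError("a zero marginal leaves a latent threshold undefined")
    # Latent coordinate above the threshold marks a positive outcome.
    return float(stats.norm.ppf(1.0 - p1)), float(stats.norm.ppf(1.0 - p2))


def orthant_probabilities(
    rho: float, tau1: float, tau2: float
) -> tuple[float, float, float, float]:
    """Cell probabilities (both, first only, second only, neither).

    Computed from the bivariate-normal CDF at the thresholds; the four
    values sum to 1 for any (rho, tau1, tau2).
    """
    cov = [[1.0, rho], [rho, 1.0]]
    p00 = float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([tau1, tau2]))
    phi1 = float(stats.norm.cdf(tau1))
    phi2 = float(stats.norm.cdf(tau2))
    p_first_only = phi2 - p00
    p_second_only = phi1 - p00
    p_both = 1.0 - phi1 - phi2 + p00
    return (p_both, p_first_only, p_second_only, p00)


def tetrachoric_loglik(rho: float, table: FourfoldTable) -> float:
    """Orthant log-likelihood at fixed marginal thresholds."""
    tau1, tau2 = _thresholds(table)
    probs = orthant_probabilities(rho, tau1, tau2)
    counts = (table.n_both, table.n_first_only, table.n_second_only, table.n_neither)
    ll = 0.0
    for n, p in zip(counts, probs):
        if n > 0:
            if p <= 0:
                return -np.inf
            ll += n * math.log(p)
    return ll


def _finish(table: FourfoldTable, rho: float, method: TetrachoricMethod) -> TetrachoricResult:
    tau1, tau2 = _thresholds(table)
    boundary = abs(rho) >= RHO_BOUND - 1e-9
    lr = 2.0 * (tetrachoric_loglik(rho, table) - tetrachoric_loglik(0.0, table))
    p_value = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return TetrachoricResult(
        rho=float(np.clip(rho, -RHO_BOUND, RHO_BOUND)),
        tau1=tau1,
        tau2=tau2,
        p_value=p_value,
        method=method,
        boundary=boundary,
    )


def tetrachoric_mle(table: FourfoldTable) -> TetrachoricResult:
    """Maximum-likelihood tetrachoric correlation with fixed thresholds."""
    res = optimize.minimize_scalar(
        lambda rho: -tetrachoric_loglik(rho, table),
        bounds=(-RHO_BOUND, RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-7},
    )
    return _finish(table, float(res.x), TetrachoricMethod.ML)


def tetrachoric_grid(table: FourfoldTable, step: float = 1e-4) -> TetrachoricResult:
    """Brute-force grid search over rho; the independent oracle for the MLE."""
    grid = np.arange(-RHO_BOUND, RHO_BOUND + step / 2, step)
    lls = np.array([tetrachoric_loglik(r, table) for r in grid])
    return _finish(table, float(grid[int(np.argmax(lls))]), TetrachoricMethod.GRID)


@dataclass(frozen=True)
class ScreenRow:
    label: str
    result: TetrachoricResult | None
    positive_correlation: bool
    significant: bool
    error: str | None = None


def independence_screen(
    pairs: list[tuple[str, FourfoldTable]],
    alpha: float = 0.05,
    rho_flag: float = POSITIVE_CORRELATION_FLAG,
) -> list[ScreenRow]:
    """Estimate rho for each labelled table, flagging discernable positive
    correlations (rho > ``rho_flag``) and significant ones (p < ``alpha``).

    Per-pair failures (e.g. a zero marginal) are reported in the row and do
    not stop the screen.
    """
    if not pairs:
        raise ValueError("pairs must be nonempty")
    rows: list[ScreenRow] = []
    for label, table in pairs:
        try:
            result = tetrachoric_mle(table)
        except ValueError as exc:
            rows.append(ScreenRow(label, None, False, False, error=str(exc)))
            continue
        rows.append(
            ScreenRow(
                label=label,
                result=result,
                positive_correlation=result.rho > rho_flag,
                significant=result.p_value < alpha,
            )
        )
    return rows


def pairs_from_marginals(
    marginals: list[TumorPairMarginals],
) -> list[tuple[str, FourfoldTable]]:
    """Reconstruct (tumor type, lung) fourfold tables from marginal counts."""
    return [
        (
            m.label,
            reconstruct_fourfold(m.n_total, m.n_with_type, m.n_with_lung, m.n_both),
        )
        for m in marginals
    ]
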