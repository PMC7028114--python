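"""Synthetic bioassay and tumor-pair generators.

These generators produce data with exactly the statistical structure the
analysis modules assume, so parameter recovery and interval coverage can
be tested end to end without any external data:

* individual-animal time-to-tumor records drawn from a known multistage
  Weibull onset truth, with dose-accelerated Weibull mortality truncated
  at terminal sacrifice (tumor onset and death are independent given dose
  — the incidental-context assumption that the tumor does not cause
  death); and
* correlated binary tumor-pair tables drawn from a latent bivariate
  normal dichotomized at prevalence quantiles — the generative model the
  tetrachoric estimator assumes.

The default design emulates the NTP-style 4-group x 50-animal 2-year
study at the chloroprene fixture's internal doses, with an onset truth
calibrated so group prevalences at terminal sacrifice roughly mimic the
female-mouse lung-tumor counts 4/28/34/42 of 50.  That truth is a test
fixture of this package, not a published estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bioassay import DEFAULT_TERMINAL_WEEKS, AnimalRecord, TumorContext
from .independence import FourfoldTable
from .msw import MSWParams, cumulative_probability

__all__ = [
    "BioassayDesign",
    "default_ntp_design",
    "DEFAULT_TRUTH",
    "simulate_bioassay",
    "simulate_tumor_pair",
]

#: Onset truth for the default design (per-week^c units, c = 3): terminal
#: prevalences at internal doses 0/0.74/1.19/1.58 are roughly
#: 0.08/0.56/0.73/0.83.
DEFAULT_TRUTH = MSWParams(b=(7.4e-8, 8.0e-7, 1.0e-7), c=3.0)


@dataclass(frozen=True)
class BioassayDesign:
    """A dose-group layout plus the generating onset and mortality truths.

    ``mortality`` holds one (scale weeks, shape) Weibull death-time pair per
    group; draws beyond ``terminal_time`` become terminal sacrifices.
    """

    groups: tuple[tuple[float, float, int], ...]  # (external ppm, internal dose, n)
    terminal_time: float = DEFAULT_TERMINAL_WEEKS
    mortality: tuple[tuple[float, float], ...] = ()
    truth: MSWParams = DEFAULT_TRUTH
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("design needs at least one group")
        if any(n <= 0 for _, _, n in self.groups):
            raise ValueError("each group needs n > 0")
        if self.terminal_time <= 0:
            raise ValueError("terminal_time must be > 0")
        if len(self.mortality) != len(self.groups):
            raise ValueError("need one (scale, shape) mortality pair per group")
        if any(scale <= 0 or shape <= 0 for scale, shape in self.mortality):
            raise ValueError("Weibull mortality parameters must be > 0")


def default_ntp_design(seed: int = 0, n_per_group: int = 50) -> BioassayDesign:
    """4-group chronic design at the fixture doses with dose-accelerated
    mortality (higher dose groups die earlier, mimicking reduced survival
    of exposed animals)."""
    return BioassayDesign(
        groups=(
            (0.0, 0.0, n_per_group),
            (12.8, 0.74, n_per_group),
            (32.0, 1.19, n_per_group),
            (80.0, 1.58, n_per_group),
        ),
        mortality=((130.0, 5.0), (120.0, 5.0), (110.0, 5.0), (95.0, 5.0)),
        seed=seed,
    )


def simulate_bioassay(design: BioassayDesign) -> list[AnimalRecord]:
    """Draw one bioassay: latent onset times by inverse-CDF sampling from the
    multistage Weibull truth, death times from per-group Weibulls truncated
    at terminal sacrifice; an animal bears the tumor iff onset preceded
    death.  Deterministic for a given design seed."""
    rng = np.random.default_rng(design.seed)
    truth = design.truth
    records: list[AnimalRecord] = []
    for gi, ((conc, dose, n), (scale, shape)) in enumerate(
        zip(design.groups, design.mortality)
    ):
        g = float(truth.dose_polynomial(dose))
        death = np.minimum(scale * rng.weibull(shape, size=n), design.terminal_time)
        death = np.maximum(death, 1.0)  # deaths in week 0 recorded as week 1
        u = rng.uniform(size=n)
        if g > 0:
            # Invert P(T_on <= t) = 1 - exp(-g t^c); u beyond the terminal-
            # time mass means onset never happens within any finite horizon.
            onset = (-np.log1p(-u) / g) ** (1.0 / truth.c) + truth.t0
        else:
            onset = np.full(n, np.inf)
        tumor = onset <= death
        for ai in range(n):
            records.append(
                AnimalRecord(
                    animal_id=f"g{gi}a{ai + 1:03d}",
                    group_label=f"{conc:g}ppm",
                    external_conc=conc,
                    internal_dose=dose,
                    death_time=float(death[ai]),
                    tumor_present=bool(tumor[ai]),
                    context=TumorContext.INCIDENTAL,
                )
            )
    return records


def simulate_tumor_pair(
    rho: float, prevalence1: float, prevalence2: float, n: int, seed: int = 0
) -> FourfoldTable:
    """Draw a 2x2 tumor co-occurrence table from a latent bivariate normal.

    ``n`` animals receive latent site scores with correlation ``rho``; a
    site is tumor-positive when its score exceeds the (1 - prevalence)
    normal quantile.
    """
    if not -1 < rho < 1:
        raise ValueError("|rho| must be < 1")
    for p in (prevalence1, prevalence2):
        if not 0 < p < 1:
            raise ValueError("prevalences must lie in (0, 1)")
    from scipy import stats

    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    pos1 = z[:, 0] > stats.norm.ppf(1.0 - prevalence1)
    pos2 = z[:, 1] > stats.norm.ppf(1.0 - prevalence2)
    return FourfoldTable(
        n_both=int(np.sum(pos1 & pos2)),
        n_first_only=int(np.sum(pos1 & ~pos2)),
        n_second_only=int(np.sum(~pos1 & pos2)),
        n_neither=int(np.sum(~pos1 & ~pos2)),
    )
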