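"""Multistage Weibull time-to-tumor model.

The cumulative probability that an animal at dose ``d`` has developed the
tumor by study time ``t`` is

    P(d, t) = 1 - exp[-(b0 + b1*d + ... + bk*d^k) * (t - t0)^c]

with stage coefficients ``b_i >= 0``, Weibull time power ``c > 0`` and
latency ``t0`` (fixed at 0 throughout this work).  Animals contribute to
the likelihood according to their tumor context: *incidental* tumors (the
tumor did not cause death) contribute the onset prevalence ``P(d, t)`` at
the death time, tumor-free animals ``1 - P(d, t)``, and *fatal* tumors the
onset density ``dP/dt`` — the density branch is kept for generality; the
chloroprene lung tumors are all modelled as incidental.

Extra risk at dose ``d`` and reference time ``t*`` is
``(P(d,t*) - P(0,t*)) / (1 - P(0,t*))``; the benchmark dose (BMD) is the
dose whose extra risk equals the benchmark response (BMR), and the BMDL is
the one-sided profile-likelihood lower confidence bound on the BMD.

Numerically the fit works on time rescaled to the unit interval
(``u = t / t_ref``) so the products ``b_i * t^c`` stay O(1) even for large
Weibull powers; coefficients are converted back to per-week^c units on
output.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .bioassay import DEFAULT_TERMINAL_WEEKS, AnimalRecord, TumorContext

__all__ = [
    "MSWParams",
    "FitResult",
    "BMDResult",
    "UnknownPolicy",
    "cumulative_probability",
    "log_likelihood",
    "fit",
    "extra_risk",
    "bmd",
    "bmdl_profile",
]

#: Convergence tolerance on the log-likelihood.
LOGLIK_TOL = 1e-8

#: Default bounds on the Weibull power c.  The lower bound of 1 enforces a
#: nondecreasing hazard (common benchmark-dose practice); pass
#: ``c_bounds=(1e-6, 18.0)`` to relax to c > 0.
DEFAULT_C_BOUNDS = (1.0, 18.0)


class UnknownPolicy(str, enum.Enum):
    """How animals with unknown tumor context enter the likelihood."""

    EXCLUDE = "exclude"
    AS_INCIDENTAL = "as_incidental"


@dataclass(frozen=True)
class MSWParams:
    """Multistage Weibull coefficients in per-week^c units."""

    b: tuple[float, ...]  # b0..bk, each >= 0
    c: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if len(self.b) < 2:
            raise ValueError("need at least b0 and b1 (degree k >= 1)")
        if any(bi < 0 for bi in self.b):
            raise ValueError("all stage coefficients b_i must be >= 0")
        if self.c <= 0:
            raise ValueError("Weibull power c must be > 0")
        if self.t0 < 0:
            raise ValueError("latency t0 must be >= 0")

    @property
    def k(self) -> int:
        """Polynomial degree."""
        return len(self.b) - 1

    def dose_polynomial(self, d: float | np.ndarray) -> float | np.ndarray:
        """g(d) = b0 + b1 d + ... + bk d^k."""
        return np.polynomial.polynomial.polyval(d, self.b)


@dataclass(frozen=True)
class FitResult:
    params: MSWParams
    loglik: float
    converged: bool
    n_starts: int
    records_used: int


@dataclass(frozen=True)
class BMDResult:
    """Benchmark dose and its profile-likelihood lower bound."""

    bmr: float
    t_star: float
    bmd: float
    bmdl: float
    conf_level: float

    def __post_init__(self) -> None:
        if not 0 < self.bmr < 1:
            raise ValueError("bmr must lie in (0, 1)")
        if not 0 < self.bmdl <= self.bmd * (1 + 1e-9):
            raise ValueError("require 0 < bmdl <= bmd")


def cumulative_probability(
    params: MSWParams, d: float | np.ndarray, t: float | np.ndarray
) -> float | np.ndarray:
    """Cumulative tumor-onset probability P(d, t)."""
    d = np.asarray(d, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    if np.any(t <= params.t0):
        raise ValueError(f"time must exceed the latency t0 = {params.t0}")
    g = params.dose_polynomial(d)
    out = -np.expm1(-g * (t - params.t0) ** params.c)
    return float(out) if out.ndim == 0 else out


def _resolve_records(
    records: list[AnimalRecord], unknown_policy: UnknownPolicy | str
) -> list[AnimalRecord]:
    policy = UnknownPolicy(unknown_policy)
    if policy is UnknownPolicy.EXCLUDE:
        kept = [r for r in records if r.context is not TumorContext.UNKNOWN]
        if records and not kept:
            raise ValueError("all records have unknown context under policy=exclude")
        return kept
    return records


def log_likelihood(
    params: MSWParams,
    records: list[AnimalRecord],
    unknown_policy: UnknownPolicy | str = UnknownPolicy.AS_INCIDENTAL,
) -> float:
    """Sum of per-animal log-likelihood contributions.

    Incidental (and, under ``as_incidental``, unknown) contexts contribute
    ``log P(d, t)`` for tumor-bearing animals and ``log(1 - P(d, t))``
    otherwise; fatal contexts contribute the log onset density.
    """
    if not records:
        raise ValueError("records must be nonempty")
    kept = _resolve_records(records, unknown_policy)
    d = np.array([r.internal_dose for r in kept])
    t = np.array([r.death_time for r in kept])
    tumor = np.array([r.tumor_present for r in kept])
    fatal = np.array([r.context is TumorContext.FATAL for r in kept])
    g = np.asarray(params.dose_polynomial(d), dtype=float)
    x = g * (t - params.t0) ** params.c

    ll = np.empty(len(kept))
    inc_tumor = tumor & ~fatal
    no_tumor = ~tumor
    with np.errstate(divide="ignore"):
        ll[inc_tumor] = np.log(-np.expm1(-x[inc_tumor]))
        ll[no_tumor] = -x[no_tumor]
        if fatal.any():
            tf = t[fatal] - params.t0
            ll[fatal] = (
                np.log(g[fatal])
                + math.log(params.c)
                + (params.c - 1.0) * np.log(tf)
                - x[fatal]
            )
    return float(ll.sum())


# ---------------------------------------------------------------------------
# Fitting (scaled-time internal representation)
# ---------------------------------------------------------------------------


class _Data:
    """Vectorized record arrays on the rescaled time axis u = t / t_ref."""

    def __init__(self, records: list[AnimalRecord], t_ref: float):
        if any(r.context is TumorContext.FATAL for r in records):
            raise NotImplementedError(
                "fitting with fatal-context records is not supported; "
                "the likelihood itself is (see log_likelihood)"
            )
        self.t_ref = t_ref
        self.d = np.array([r.internal_dose for r in records])
        self.u = np.array([r.death_time for r in records]) / t_ref
        self.tumor = np.array([r.tumor_present for r in records])
        self.n = len(records)

    def loglik(self, bs: np.ndarray, c: float) -> float:
        """Log-likelihood at scaled coefficients bs_i = b_i * t_ref^c."""
        g = np.polynomial.polynomial.polyval(self.d, bs)
        x = g * self.u**c
        xt = x[self.tumor]
        with np.errstate(divide="ignore"):
            ll_t = np.log(-np.expm1(-np.maximum(xt, 1e-300))).sum()
        return float(ll_t - x[~self.tumor].sum())


def _initial_scaled_coefficients(data: _Data, k: int) -> np.ndarray:
    """Crude method-of-moments start from per-group terminal prevalences."""
    doses = np.unique(data.d)
    g_emp = []
    for dose in doses:
        sel = data.d == dose
        p = np.clip(data.tumor[sel].mean(), 0.02, 0.95)
        g_emp.append(-math.log1p(-p))
    g_emp = np.array(g_emp)
    b = np.zeros(k + 1)
    b[0] = max(g_emp[doses == 0].mean() if (doses == 0).any() else g_emp.min(), 1e-4)
    dmax = doses.max()
    if dmax > 0:
        slope = max((g_emp.max() - b[0]) / dmax, 1e-4)
        b[1] = slope
        for i in range(2, k + 1):
            b[i] = slope / (10.0 * dmax ** (i - 1))
    return b


def fit(
    records: list[AnimalRecord],
    k: int = 2,
    unknown_policy: UnknownPolicy | str = UnknownPolicy.AS_INCIDENTAL,
    n_starts: int = 20,
    seed: int = 0,
    c_bounds: tuple[float, float] = DEFAULT_C_BOUNDS,
) -> FitResult:
    """Constrained maximum-likelihood fit of the degree-``k`` model.

    Multi-start L-BFGS-B over (b0..bk, c) with b_i >= 0 and c within
    ``c_bounds``; starts are seeded perturbations of a moment-based
    initial point, so the fit is deterministic for a given seed.
    """
    if k < 1:
        raise ValueError("degree k must be >= 1")
    kept = _resolve_records(records, unknown_policy)
    if len({r.internal_dose for r in kept}) < 2:
        raise ValueError("records must span at least 2 dose levels")
    kept = sorted(kept, key=lambda r: (r.internal_dose, r.death_time, r.animal_id))
    t_ref = max(r.death_time for r in kept)
    data = _Data(kept, t_ref)

    b_init = _initial_scaled_coefficients(data, k)
    rng = np.random.default_rng(seed)

    def objective(x: np.ndarray) -> float:
        return -data.loglik(x[:-1], x[-1])

    bounds = [(0.0, None)] * (k + 1) + [c_bounds]
    best_x, best_ll, converged = None, -np.inf, False
    c_lo, c_hi = c_bounds
    for start in range(max(n_starts, 1)):
        if start == 0:
            x0 = np.append(b_init, np.clip(3.0, c_lo, c_hi))
        else:
            scale = np.exp(rng.uniform(np.log(0.2), np.log(5.0), size=k + 1))
            c0 = rng.uniform(c_lo, min(c_hi, 12.0))
            x0 = np.append(b_init * scale, c0)
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": LOGLIK_TOL, "gtol": 1e-10, "maxiter": 2000},
        )
        if -res.fun > best_ll + 0.0:
            best_ll = -res.fun
            best_x = res.x
            converged = bool(res.success) or converged
    assert best_x is not None

    bs, c = best_x[:-1], best_x[-1]
    b_ext = tuple(float(bi) / t_ref**c for bi in bs)
    params = MSWParams(b=b_ext, c=float(c))
    return FitResult(
        params=params,
        loglik=float(best_ll),
        converged=converged,
        n_starts=max(n_starts, 1),
        records_used=len(kept),
    )


# ---------------------------------------------------------------------------
# Extra risk, BMD, profile BMDL
# ---------------------------------------------------------------------------


def extra_risk(params: MSWParams, d: float, t_star: float) -> float:
    """Extra risk (P(d,t*) - P(0,t*)) / (1 - P(0,t*)) at the reference time."""
    if t_star <= params.t0:
        raise ValueError("t_star must exceed the latency t0")
    p0 = cumulative_probability(params, 0.0, t_star)
    if p0 >= 1.0:
        raise ValueError("degenerate background: P(0, t*) = 1")
    pd_ = cumulative_probability(params, d, t_star)
    return float((pd_ - p0) / (1.0 - p0))


def _dose_term(params: MSWParams, d: float) -> float:
    """q(d) = sum_{i>=1} b_i d^i (the background-free dose polynomial)."""
    return float(np.polynomial.polynomial.polyval(d, (0.0,) + params.b[1:]))


def bmd(params: MSWParams, bmr: float, t_star: float) -> float:
    """Dose at which the extra risk equals ``bmr`` at time ``t_star``.

    Solved from q(d) * (t* - t0)^c = -ln(1 - bmr) by bracketing + Brent
    root-finding to 1e-8 relative tolerance.
    """
    if not 0 < bmr < 1:
        raise ValueError("bmr must lie in (0, 1)")
    if t_star <= params.t0:
        raise ValueError("t_star must exceed the latency t0")
    if all(bi == 0 for bi in params.b[1:]):
        raise ValueError("no positive dose coefficient: extra risk is flat in dose")
    target = -math.log1p(-bmr) / (t_star - params.t0) ** params.c

    def f(d: float) -> float:
        return _dose_term(params, d) - target

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("failed to bracket the benchmark dose")
    return float(optimize.brentq(f, 0.0, hi, rtol=1e-8, xtol=1e-300))


def _profile_loglik(
    data: _Data,
    k: int,
    bmd_value: float,
    bmr: float,
    u_star: float,
    c_bounds: tuple[float, float],
    x0: np.ndarray | None,
) -> tuple[float, np.ndarray]:
    """Maximum log-likelihood subject to BMD(params) = ``bmd_value``.

    The constraint sum_{i>=1} bs_i D^i = -ln(1-bmr)/u*^c is eliminated by
    reparameterization: for k=1, bs1 is determined by (c, D); for k=2 the
    free parameter f in [0, 1] splits the constraint mass between bs1 and
    bs2.  Free parameters are (bs0, [f], c).
    """
    if k > 2:
        raise NotImplementedError("profile BMDL implemented for degree k <= 2")
    A0 = -math.log1p(-bmr)

    def constraint_mass(c: float) -> float:
        return A0 / u_star**c

    if k == 1:

        def unpack(x: np.ndarray) -> tuple[np.ndarray, float]:
            bs0, c = x
            a = constraint_mass(c)
            return np.array([bs0, a / bmd_value]), c

        bounds = [(0.0, None), c_bounds]
        starts = [np.array([0.1, 3.0]), np.array([0.02, 1.5]), np.array([0.5, 6.0])]
    else:

        def unpack(x: np.ndarray) -> tuple[np.ndarray, float]:
            bs0, frac, c = x
            a = constraint_mass(c)
            bs2 = frac * a / bmd_value**2
            bs1 = (1.0 - frac) * a / bmd_value
            return np.array([bs0, bs1, bs2]), c

        bounds = [(0.0, None), (0.0, 1.0), c_bounds]
        starts = [
            np.array([0.1, 0.0, 3.0]),
            np.array([0.1, 0.9, 3.0]),
            np.array([0.02, 0.5, 1.5]),
        ]
    if x0 is not None:
        starts = [x0] + starts

    def objective(x: np.ndarray) -> float:
        bs, c = unpack(x)
        return -data.loglik(bs, c)

    best_ll, best_x = -np.inf, None
    for x0_i in starts:
        res = optimize.minimize(
            objective, x0_i, method="L-BFGS-B", bounds=bounds,
            options={"ftol": LOGLIK_TOL, "maxiter": 1000},
        )
        if -res.fun > best_ll:
            best_ll, best_x = -res.fun, res.x
    assert best_x is not None
    return best_ll, best_x


def bmdl_profile(
    records: list[AnimalRecord],
    fit_result: FitResult,
    bmr: float = 0.01,
    t_star: float = DEFAULT_TERMINAL_WEEKS,
    conf_level: float = 0.95,
    unknown_policy: UnknownPolicy | str = UnknownPolicy.AS_INCIDENTAL,
    c_bounds: tuple[float, float] = DEFAULT_C_BOUNDS,
) -> BMDResult:
    """Profile-likelihood BMDL at a one-sided confidence level.

    The BMDL is the smallest dose D for which the log-likelihood maximized
    subject to BMD = D stays within chi2_1(1 - 2(1 - conf_level))/2 of the
    unconstrained maximum (1.352877 for one-sided 95%), found by Brent
    search on D with inner constrained refits.
    """
    if not fit_result.converged:
        raise ValueError("fit did not converge; BMDL profile requires a converged fit")
    kept = _resolve_records(records, unknown_policy)
    kept = sorted(kept, key=lambda r: (r.internal_dose, r.death_time, r.animal_id))
    t_ref = max(r.death_time for r in kept)
    data = _Data(kept, t_ref)
    u_star = t_star / t_ref
    k = fit_result.params.k

    bmd_hat = bmd(fit_result.params, bmr, t_star)
    drop = stats.chi2.ppf(1.0 - 2.0 * (1.0 - conf_level), df=1) / 2.0

    ll_at_hat, warm = _profile_loglik(data, k, bmd_hat, bmr, u_star, c_bounds, None)
    ll_max = max(fit_result.loglik, ll_at_hat)
    target = ll_max - drop

    warm_cache = {"x": warm}

    def deficit(D: float) -> float:
        ll, x = _profile_loglik(data, k, D, bmr, u_star, c_bounds, warm_cache["x"])
        warm_cache["x"] = x
        return ll - target

    lo = bmd_hat
    f_lo = deficit(lo)
    for _ in range(60):
        lo *= 0.5
        f_lo = deficit(lo)
        if f_lo < 0:
            break
    else:
        raise RuntimeError("could not bracket the BMDL below the BMD")
    bmdl = float(optimize.brentq(deficit, lo, bmd_hat, rtol=1e-5))
    return BMDResult(bmr=bmr, t_star=t_star, bmd=bmd_hat, bmdl=min(bmdl, bmd_hat),
                     conf_level=conf_level)
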