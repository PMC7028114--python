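import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chloroprene_iur import msw
from chloroprene_iur.bioassay import TumorContext
from chloroprene_iur.msw import (
    MSWParams,
    UnknownPolicy,
    bmd,
    bmdl_profile,
    cumulative_probability,
    extra_risk,
    fit,
    log_likelihood,
)
from chloroprene_iur.simulate import default_ntp_design, simulate_bioassay

from conftest import make_record


class TestCumulativeProbability:
    def test_closed_form_values(self):
        p = cumulative_probability(MSWParams(b=(0.0, 0.001), c=1.0), 1.0, 100.0)
        assert p == pytest.approx(1 - math.exp(-0.1), rel=1e-12)
        p2 = cumulative_probability(MSWParams(b=(0.002, 0.001), c=2.0), 2.0, 10.0)
        assert p2 == pytest.approx(1 - math.exp(-0.4), rel=1e-12)

    def test_zero_dose_with_zero_background_is_zero(self):
        params = MSWParams(b=(0.0, 5.0), c=2.0)
        for t in (1.0, 50.0, 104.0):
            assert cumulative_probability(params, 0.0, t) == 0.0

    def test_time_at_or_below_latency_is_domain_error(self):
        params = MSWParams(b=(0.1, 0.1), c=1.0, t0=10.0)
        with pytest.raises(ValueError, match="latency"):
            cumulative_probability(params, 1.0, 10.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        b0=st.floats(0, 0.01),
        b1=st.floats(0, 0.01),
        c=st.floats(0.5, 6),
        d=st.floats(0, 5),
        t=st.floats(1, 104),
    )
    def test_bounded_and_monotone(self, b0, b1, c, d, t):
        params = MSWParams(b=(b0, b1), c=c)
        p = cumulative_probability(params, d, t)
        assert 0.0 <= p <= 1.0
        assert cumulative_probability(params, d + 1.0, t) >= p - 1e-12
        assert cumulative_probability(params, d, t + 1.0) >= p - 1e-12


class TestLogLikelihood:
    def test_tumor_free_animal_under_zero_params_contributes_zero(self):
        params = MSWParams(b=(0.0, 0.0), c=1.0)
        rec = make_record(tumor=False)
        assert log_likelihood(params, [rec]) == 0.0

    def test_two_animal_closed_form(self):
        # One tumor-bearing, one tumor-free animal at d=1, t=100 under a
        # one-stage model: log P + log(1 - P) with P = 1 - e^(-0.1).
        params = MSWParams(b=(0.0, 0.001), c=1.0)
        recs = [
            make_record(animal_id="t", dose=1.0, time=100.0, tumor=True),
            make_record(animal_id="n", dose=1.0, time=100.0, tumor=False),
        ]
        p = 1 - math.exp(-0.1)
        expected = math.log(p) + math.log(1 - p)
        assert log_likelihood(params, recs) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-2.4521, abs=1e-4)

    def test_contributions_are_additive(self):
        params = MSWParams(b=(0.001, 0.002), c=1.5)
        recs = [
            make_record(animal_id=f"a{i}", dose=d, time=t, tumor=y)
            for i, (d, t, y) in enumerate(
                [(0.0, 90.0, False), (1.0, 100.0, True), (2.0, 80.0, True)]
            )
        ]
        total = log_likelihood(params, recs)
        parts = sum(log_likelihood(params, [r]) for r in recs)
        assert total == pytest.approx(parts, rel=1e-12)

    def test_unknown_policy_exclude_drops_only_unknowns(self):
        params = MSWParams(b=(0.001, 0.002), c=1.5)
        known = [
            make_record(animal_id="a", dose=1.0, time=100.0, tumor=True),
            make_record(animal_id="b", dose=0.0, time=104.0, tumor=False),
        ]
        unknown = make_record(
            animal_id="u", dose=1.0, time=93.0, tumor=True, context=TumorContext.UNKNOWN
        )
        ll_known = log_likelihood(params, known)
        assert log_likelihood(params, known + [unknown], UnknownPolicy.EXCLUDE) == (
            pytest.approx(ll_known, rel=1e-12)
        )
        # as_incidental adds the unknown animal's incidental term
        ll_with = log_likelihood(params, known + [unknown], UnknownPolicy.AS_INCIDENTAL)
        p = cumulative_probability(params, 1.0, 93.0)
        assert ll_with == pytest.approx(ll_known + math.log(p), rel=1e-12)

    def test_all_unknown_with_exclude_policy_errors(self):
        params = MSWParams(b=(0.001, 0.002), c=1.5)
        recs = [
            make_record(animal_id="u", tumor=True, context=TumorContext.UNKNOWN)
        ]
        with pytest.raises(ValueError, match="unknown"):
            log_likelihood(params, recs, UnknownPolicy.EXCLUDE)


class TestFit:
    def test_all_tumor_free_data_hits_zero_boundary(self):
        recs = [
            make_record(animal_id=f"a{i}", dose=d, time=104.0, tumor=False)
            for i, d in enumerate([0.0] * 10 + [1.0] * 10)
        ]
        result = fit(recs, k=1, n_starts=5, seed=0)
        assert result.loglik == pytest.approx(0.0, abs=1e-6)
        assert all(b < 1e-6 for b in result.params.b)

    def test_fit_invariant_to_record_order(self, toy_records):
        rng = np.random.default_rng(0)
        shuffled = list(toy_records)
        rng.shuffle(shuffled)
        a = fit(toy_records, k=1, n_starts=5, seed=3)
        b = fit(shuffled, k=1, n_starts=5, seed=3)
        assert a.loglik == b.loglik
        assert a.params == b.params

    def test_fitted_loglik_dominates_refit_from_returned_params(self, toy_records):
        result = fit(toy_records, k=1, n_starts=5, seed=3)
        # perturbing the solution never improves the likelihood beyond tol
        best = result.loglik
        for eps in (0.9, 1.1):
            b = tuple(bi * eps for bi in result.params.b)
            ll = log_likelihood(MSWParams(b=b, c=result.params.c), toy_records)
            assert ll <= best + 1e-6

    def test_single_dose_level_rejected(self):
        recs = [
            make_record(animal_id=f"a{i}", dose=1.0, tumor=i % 2 == 0)
            for i in range(6)
        ]
        with pytest.raises(ValueError, match="dose levels"):
            fit(recs, k=1)


class TestExtraRisk:
    def test_direct_arithmetic(self):
        # Pi = 0.5, Po = 0.2 -> (0.5 - 0.2)/(1 - 0.2) = 0.375, built from a
        # one-stage model chosen to hit those cumulative probabilities.
        t = 104.0
        b0 = -math.log(0.8) / t
        b1 = (-math.log(0.5) / t) - b0
        params = MSWParams(b=(b0, b1), c=1.0)
        assert cumulative_probability(params, 0.0, t) == pytest.approx(0.2)
        assert cumulative_probability(params, 1.0, t) == pytest.approx(0.5)
        assert extra_risk(params, 1.0, t) == pytest.approx(0.375, rel=1e-10)

    def test_zero_at_zero_dose(self):
        params = MSWParams(b=(0.001, 0.002), c=2.0)
        assert extra_risk(params, 0.0, 104.0) == 0.0

    def test_matches_background_free_closed_form_on_grid(self):
        # (P(d,t*) - P(0,t*)) / (1 - P(0,t*)) == 1 - exp(-(b1 d + b2 d^2) t*^c)
        for b0 in (0.0, 1e-7, 1e-6):
            for b1, b2 in [(1e-6, 0.0), (5e-7, 2e-7), (0.0, 1e-6)]:
                for c in (1.0, 1.7, 3.0):
                    params = MSWParams(b=(b0, b1, b2), c=c)
                    for d in (0.1, 0.74, 1.58, 3.0):
                        analytic = -math.expm1(-(b1 * d + b2 * d * d) * 104.0**c)
                        assert extra_risk(params, d, 104.0) == pytest.approx(
                            analytic, rel=1e-9, abs=1e-15
                        )


class TestBMD:
    def test_one_stage_closed_form(self):
        params = MSWParams(b=(0.005, 0.001), c=1.0)
        expected = -math.log(0.99) / (0.001 * 104.0)
        assert bmd(params, 0.01, 104.0) == pytest.approx(expected, rel=1e-8)
        assert expected == pytest.approx(0.09664, abs=5e-6)

    def test_doubling_slope_halves_bmd(self):
        a = bmd(MSWParams(b=(0.001, 0.001), c=2.0), 0.01, 104.0)
        b = bmd(MSWParams(b=(0.001, 0.002), c=2.0), 0.01, 104.0)
        assert a == pytest.approx(2 * b, rel=1e-7)

    def test_independent_of_background(self):
        for b0 in (0.0, 1e-4, 1e-2):
            params = MSWParams(b=(b0, 2e-4, 1e-4), c=2.0)
            ref = bmd(MSWParams(b=(0.0, 2e-4, 1e-4), c=2.0), 0.01, 104.0)
            assert bmd(params, 0.01, 104.0) == pytest.approx(ref, rel=1e-9)

    def test_flat_dose_response_has_no_root(self):
        with pytest.raises(ValueError, match="dose coefficient"):
            bmd(MSWParams(b=(0.001, 0.0), c=1.0), 0.01, 104.0)


class TestProfileBMDL:
    def test_bmdl_below_bmd_on_simulated_data(self, simulated_bioassay):
        result = fit(simulated_bioassay, k=2, n_starts=10, seed=0)
        out = bmdl_profile(simulated_bioassay, result, bmr=0.01, t_star=104.0)
        assert 0 < out.bmdl <= out.bmd

    def test_unknown_animal_policy_changes_bmdl_reportably(self, simulated_bioassay):
        # recode one tumor-bearing animal as unknown context; both policies
        # must run and give close but distinct BMDLs
        records = list(simulated_bioassay)
        idx = next(i for i, r in enumerate(records) if r.tumor_present)
        import dataclasses

        records[idx] = dataclasses.replace(records[idx], context=TumorContext.UNKNOWN)
        outs = {}
        for policy in UnknownPolicy:
            f = fit(records, k=2, unknown_policy=policy, n_starts=10, seed=0)
            outs[policy] = bmdl_profile(
                records, f, bmr=0.01, t_star=104.0, unknown_policy=policy
            )
        a = outs[UnknownPolicy.AS_INCIDENTAL].bmdl
        b = outs[UnknownPolicy.EXCLUDE].bmdl
        assert a > 0 and b > 0
        assert a != b
        assert abs(a - b) / a < 0.15  # one animal cannot move the BMDL much

    def test_profile_agrees_with_grid_oracle_one_stage(self):
        # Independent oracle: profile log-likelihood by brute-force grid over
        # (b0, c) with b1 eliminated by the BMD constraint, then the BMDL by
        # interpolating the likelihood-drop crossing on a dose grid.
        records = simulate_bioassay(default_ntp_design(seed=5))
        f = fit(records, k=1, n_starts=10, seed=0)
        out = bmdl_profile(records, f, bmr=0.01, t_star=104.0, conf_level=0.95)

        d = np.array([r.internal_dose for r in records])
        t = np.array([r.death_time for r in records])
        tumor = np.array([r.tumor_present for r in records])
        bmr, t_star = 0.01, 104.0
        target_drop = 1.352877  # chi2_1(0.90)/2

        def grid_profile(D):
            # grid over the *scaled* background bs0 = b0 * t*^c so resolution
            # is comparable across c; b1 is eliminated by the constraint
            # b1 * D * t*^c = -ln(1 - bmr)
            bs0 = np.linspace(0.0, 0.4, 241)
            c = np.linspace(1.0, 8.0, 241)
            BS0, C = np.meshgrid(bs0, c, indexing="ij")
            A = -np.log1p(-bmr)
            u = (t / t_star)[None, None, :]
            x = (BS0[..., None] + A * d[None, None, :] / D) * u ** C[..., None]
            with np.errstate(divide="ignore"):
                ll = np.where(tumor, np.log(-np.expm1(-np.maximum(x, 1e-300))), -x)
            return ll.sum(axis=-1).max()

        ll_max = max(f.loglik, grid_profile(out.bmd))
        Ds = np.linspace(0.55 * out.bmd, out.bmd, 25)
        profile = np.array([grid_profile(D) for D in Ds])
        deficit = profile - (ll_max - target_drop)
        assert deficit[0] < 0 < deficit[-1]
        i = int(np.argmax(deficit > 0))
        # linear interpolation of the crossing
        x0, x1 = Ds[i - 1], Ds[i]
        y0, y1 = deficit[i - 1], deficit[i]
        bmdl_grid = x0 - y0 * (x1 - x0) / (y1 - y0)
        assert out.bmdl == pytest.approx(bmdl_grid, rel=0.01)


def test_fit_refuses_fatal_records():
    recs = [
        make_record(animal_id="f", dose=1.0, tumor=True, context=TumorContext.FATAL),
        make_record(animal_id="n", dose=0.0, tumor=False),
    ]
    with pytest.raises(NotImplementedError):
        fit(recs, k=1, n_starts=1)
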