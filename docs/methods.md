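# Methods

## Time-to-tumor model

The multistage Weibull cumulative onset probability is

P(d, t) = 1 − exp[−(b₀ + b₁d + … + b_k dᵏ)(t − t₀)ᶜ],  bᵢ ≥ 0.

Animals enter the likelihood by tumor context. All chloroprene lung tumors
are treated as incidental — the tumor is observed at death but did not
cause it — so a tumor-bearing animal contributes log P(d, t) at its death
time and a tumor-free animal log(1 − P(d, t)). The fatal-context density
contribution, log[g(d)·c·(t−t₀)^(c−1)] − g(d)(t−t₀)ᶜ, is implemented in the
likelihood for generality but the fitter refuses fatal records, since no
bundled dataset exercises that branch and an untested code path in an
optimizer is worse than an explicit refusal.

Assumptions worth stating plainly:

- **Internal dose is the correct dose metric.** The PBPK outputs
  (0.74/1.19/1.58 µmole/g-lung/day for 12.8/32/80 ppm in the female mouse;
  0.0106 per ppm continuous in the human) are consumed as constants. The
  PBPK models themselves are out of scope.
- **Onset and death are independent given dose** (the incidental
  assumption). This is also exactly what the synthetic generator simulates.
- **Latency t₀ = 0**; the time unit is study weeks with terminal sacrifice
  at 104 weeks (2-year study). The BMD reference time t\* defaults to 104
  weeks. The reference time is an assumption, not a data quantity: extra
  risk at a different t\* gives a different BMD scale.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| k | 2 | polynomial degree ("2-stage"); selectable 1–4, profile BMDL supports k ≤ 2 |
| BMR | 0.01 | benchmark extra risk |
| t\* | 104 weeks | reference time for extra risk |
| c bounds | [1, 18] | lower bound 1 enforces a nondecreasing hazard; a flag (`--relax-c`) allows c > 0 |
| confidence | 0.95 one-sided | BMDL level, χ²₁ drop 1.352877 |
| unknown policy | `as_incidental` | unknown-context animals kept as incidental; `exclude` drops them — the pipeline always reports both branches |

## Numerical choices

- **Scaling.** The optimizer works on time rescaled to u = t/t_ref
  (t_ref = latest death time), so the products bᵢ·tᶜ stay O(1) for any c up
  to 18; coefficients convert back to per-weekᶜ units on output. Without
  this, external-unit coefficients range over ~40 orders of magnitude as c
  varies and L-BFGS-B stalls.
- **Multi-start.** 20 seeded starts around a moment-based initial point
  (group prevalences at terminal time → crude g(d) values). Convergence
  tolerance 1e-8 on the log-likelihood. Fitting is deterministic given the
  seed and invariant to record order (records are sorted internally).
- **BMD.** Solved from q(d)·t\*ᶜ = −ln(1−BMR) by bracketing plus Brent root
  finding at 1e-8 relative tolerance; q(d) = Σ_{i≥1} bᵢdⁱ, so the BMD is
  independent of the background b₀.
- **Profile BMDL.** The BMD constraint is eliminated by reparameterization:
  for k = 1, b₁ is determined by (c, D); for k = 2 a fraction f ∈ [0,1]
  splits the constraint mass −ln(1−BMR)/t\*ᶜ between b₁ and b₂, keeping
  every inner iterate exactly on the constraint with bounds-only
  optimization (no penalty tuning). The outer search brackets downward from
  the BMD and Brent-solves the likelihood-drop crossing at 1e-5 relative
  tolerance, warm-starting each inner refit from the previous one.
- **Tetrachoric.** Thresholds are fixed at the empirical marginal normal
  quantiles (two-step estimator) rather than jointly estimated — standard
  for 2×2 data, and with both margins near 1/2 in the bioassay tables the
  difference is negligible. The orthant likelihood uses the bivariate
  normal CDF; ρ is maximized by bounded scalar search on [−0.999, 0.999],
  estimates at the bound are clipped and flagged. p-values are
  likelihood-ratio χ²₁ against ρ = 0.
- **Exact Poisson power.** The critical count k\* is the smallest count with
  null tail probability ≤ α; power is the exact tail at mean RR·E. No
  normal approximation anywhere; scipy's survival functions are stable to
  E = 10⁴ and beyond.
- **SMR limits** are the exact Garwood gamma/χ² quantile limits; the lower
  limit is 0 when no events are observed.
- **Display rounding.** Stored values are full precision. The unit-risk
  summary chain rounds at each step (ppm to 3 s.f., µg/m³ to the nearest
  integer, per-ppm to 3 s.f., per-µg/m³ to 2 s.f.), which is how published
  summary rows are constructed. Projected excess-case counts are displayed
  rounded **up** to the next whole case — the conservative convention for
  risk projections; concentrations use nearest-integer display.

## Synthetic data: what it emulates, what it does not

`simulate_bioassay` draws latent onset times by inverse-CDF sampling from a
known multistage Weibull truth and death times from per-group Weibull
distributions truncated at terminal sacrifice; an animal bears the tumor
iff onset preceded death. Dose groups, group sizes and internal doses
follow the NTP-style 4 × 50 design at 0/0.74/1.19/1.58 µmole/g-lung/day,
with mortality scale decreasing with dose (130 → 95 weeks at shape 5) to
emulate the reduced survival of exposed animals. The default truth
(b = (7.4e-8, 8.0e-7, 1.0e-7) per weekᶜ, c = 3) was calibrated once so the
terminal-time group prevalences roughly mimic the observed 4/28/34/42 of
50; it is a fixture of this package, not a published estimate.

The generator does **not** emulate: fatal tumors or cause-of-death
attribution, interval-censored necropsy schedules, litter or cage effects,
multiple tumor types per animal in the bioassay stream (the tumor-pair
generator is separate), or PBPK dose uncertainty. Passing recovery and
coverage tests therefore show the estimators are correct *under the model's
own assumptions*; they cannot show the incidental-context assumption holds
in any real bioassay.

`simulate_tumor_pair` draws dichotomized bivariate-normal pairs — exactly
the tetrachoric generative model — so its recovery test checks estimator
consistency, not the latent-normality assumption itself.

## Study sizes used in the statistical checks

Interval coverage of the profile BMDL is assessed over 100 replicates of a
4 × 200 one-stage design (one-stage truth and one-stage fit; the coverage
property is degree-generic and the one-stage profile keeps the replicated
study compact). Tetrachoric recovery uses 500 replicates at n = 200,
ρ = 0.3. The false-flag rate of the independence screen is checked at 200
null tables of n = 200.

## Design choices that were genuinely open

- **Unknown-context animals** are treated as incidental when included,
  because every tumor in the modelled endpoint is incidental; exclusion is
  the other documented branch and both are always reported.
- **t\* = 104 weeks** (study end) for extra risk: the natural choice when
  the bioassay defines the observable lifetime, and configurable.
- **c ≥ 1 by default**: a decreasing hazard for tumor onset is biologically
  implausible in a chronic bioassay and invites boundary pathologies at
  c → 0; the relaxation flag exists for sensitivity analysis.
- **Reality-check inputs**: where a published summary concentration
  (1423 µg/m³ at the mean cumulative exposure) disagrees with recomputing
  its own adjustment formula (1484 µg/m³), the pipeline reports projections
  under both, labelled `mean_printed` and `mean_recomputed`.

## Known limitations

- Profile BMDL is implemented for k ≤ 2 (the headline analysis is k = 2);
  higher degrees fit but have no profile bound.
- The likelihood-ratio p-value for ρ is asymptotic; with cells of ~3–5
  animals (forestomach, Zymbal gland) it is qualitative, and boundary
  estimates (clipped at 0.999) should be read as "near-complete nesting of
  one tumor type in the other", not as precise correlations.
- The SMR/power machinery takes expected counts as given; no person-year
  computation from work histories is provided.
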