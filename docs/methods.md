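# Methods

This note records the model conventions, parameter choices and numerical
decisions behind `radetriment`, and what the synthetic-registry tests do
and do not demonstrate about real data.

## The model

For each organ/tissue *T* the detriment is

    D_T = R_T · (k_T + (1 − k_T) · q_T) · L_rel,T = R_T · d_T

with the nominal risk coefficient `R_T` (cases per 10,000 persons per Sv)
taken as a fixed ICRP 103 constant. The radiation-independent severity
`d_T` is assembled from three registry-derived factors, evaluated
independently for each calendar year (period analysis):

1. **Rates.** The age-specific rate in group *i* is `r_i = n_i / (N_i·Δt)`
   with `Δt = 1 a` fixed. The cumulative rate `P = Σ r_i·ΔA` is a direct
   age standardization with equal group weights; the survival-weighted
   variant `P_S = Σ r_i·ΔA·S_i` weights each group by the probability of
   being alive there.

2. **Survival.** `S_i = Π_{k≤i} exp(−ΔA·r_k,all)` — the
   piecewise-exponential period survival implied by the same year's
   all-cause mortality. Remaining life expectancy at group *i* is
   `a_i = (Σ_{k=i..m} S_k·ΔA) / S_i`.

3. **Lethality.** `k_T = ᴹP_S,T / ᴵP_S,T`, mortality over incidence on the
   common survival-weighted standard, with the same year's `S_i` in both
   numerator and denominator. The all-sites lethality is the ratio of the
   summed weighted rates, which equals the site formula applied to summed
   counts.

4. **Life lost.** The survival-weighted mean age at death
   `ᴹA_T = Σ r_i·S_i·Ā_i / Σ r_i·S_i` is mapped to its age group; the
   absolute life lost `L_T` is `a_i` at that group; `L_rel,T = n·L_T/ΣL_T`
   over the *n* computed sites, so the cross-site mean is 1.

5. **Quality of life.** `q_T = q_min + k_T·(1 − q_min)` with floors
   `q_min = 0` (skin), `0.2` (thyroid), `0.1` (all other sites).

Two rows — gonads (heritable effects; R=20, k=0.80, q=0.82, L_rel=1.32,
D=25.4) and the "other solid cancers" remainder (R=144, k=0.49, q=0.54,
L_rel=1.03, D=113.5) — are package constants taken verbatim from ICRP 103
and held constant in time; they never enter the `L_rel` average. The total
detriment sums all 14 rows.

## Conventions and open choices

- **Age grid.** Default 18 contiguous 5-year groups, lower bounds
  0, 5, …, 85, with an open 85+ top group. The open group needs a nominal
  midpoint for mean-age arithmetic; it is fixed at 87.5 a (configurable).
  This is a bounded proxy for an unbounded class; results at the very top
  of the age range inherit its arbitrariness.
- **Survival-index convention.** The survival product runs through group
  *i* itself, so `S_i` is survival through the *end* of group *i*; the
  life-expectancy sum then uses these values unchanged. This is the
  literal actuarial reading of the defining product. The conventional
  life-table alternative — survival to the *start* of group *i* — is
  available as `survival_convention="start"` and propagates consistently;
  it raises all weights (the first group gets weight 1) and slightly
  raises weighted rates. The default is tagged on the curve object, never
  silent.
- **Mean-age → group mapping.** Half-open intervals `[lower, lower+ΔA)`;
  ages at or above the top lower bound map to the top group. No
  interpolation of `a_i` by default (group-level approximation); linear
  interpolation is available behind a flag.
- **`n` in the life-lost average.** The unweighted mean over the sites
  with a *computed* `L_T` (the 12 non-fixed sites when the full catalogue
  is used). A mortality-weighted average is defensible but the plain sum
  in the defining relation implies the unweighted form; implemented as
  such.
- **k > 1.** Standardized mortality exceeding incidence is a data anomaly
  (registration artefacts, coding changes). Policy `clamp` (default)
  clamps to 1 with a logged warning and keeps the raw ratio alongside for
  diagnostics; policy `error` fails the year instead.
- **Zero incidence.** Lethality is undefined; the site/year fails loudly
  and the detriment for that year is not produced. No carry-forward.
- **Zero or negative population** in any needed cell is a construction
  error, never imputed.
- **q source.** The pipeline computes `q` from `k`. The worked-example
  reproduction instead evaluates with the tabulated 2-decimal `q` values
  ("printed" mode), because the reference table's detriments round from
  tabulated q (breast: computed-q gives 42.1 against the printed 41.7).
- **Rounding** happens only at reporting (1 dp for detriments, 2 dp for
  factors); all internal arithmetic is full double precision, and tests
  compare with explicit tolerances, never rounded equality.
- **Trend analysis** treats years independently: no smoothing, and a year
  that fails leaves a gap rather than an interpolated value. Percent
  decline is `100·(v(y0) − v(y1))/v(y0)`. The incidence proxy for sites
  without usable incidence registration fits an unweighted OLS line per
  observation zone, averages the zone lines with equal weight (no
  population weighting is attempted), extrapolates to the target years,
  and adds a companion type via a constant proportional factor (default
  1, i.e. the companion doubles the fitted rate).

## Synthetic registries

The generator emulates the structure the analysis assumes:

- all-cause hazard `μ(A) = μ₀·exp(b·A)` with defaults `μ₀ = 8·10⁻⁵ a⁻¹`,
  `b = 0.084 a⁻¹` — a Gompertz adult-mortality curve giving ≈10⁻³ at age
  30 and ≈0.12 at 87.5, human-like in magnitude;
- site incidence `r(A) = level·exp(s·(A − 70))` with `s = 0.06 a⁻¹` by
  default and site-specific levels of 10⁻⁵–10⁻² at age 70, loosely
  matching the rank order of real site frequencies;
- site mortality = `ρ_T ×` incidence per age group, so the true lethality
  `ρ_T` is exactly identifiable (proportional series cancel the survival
  weights); an optional mortality age shift breaks the proportionality to
  exercise the weighting;
- linear start→end multipliers per quantity for secular trends;
- `expected_value` mode emits `N_i·r_i` directly (real-valued,
  seed-independent) — the infinite-population limit; `poisson` mode draws
  integer counts with those means from per-(year, site, kind) substreams
  derived from one global seed, so draws are reproducible and adding a
  site leaves the others' counts untouched.

The study scenario (`lethality_decline_scenario`) spans 1980–2012 on the
default grid with the 12 computed sites, true lethalities set to the
bundled USA-2012 reference values, and site mortality rates scaled
linearly from 1.0 to 0.7 while incidence and all-cause mortality stay
constant. In expected-value mode the overall lethality then declines by
exactly 30% while the total detriment declines by ~13% — the structural
attenuation that is the model's key qualitative behaviour.

**What this does not show.** Synthetic registries have constant
populations per age group, stationary age shapes, no competing-risks
coherence between all-cause and site-specific deaths (sites are modelled
marginally), no registration artefacts, and noise that is exactly Poisson.
Passing tests therefore demonstrate the *arithmetic* of the pipeline and
its statistical recovery properties, not the faithfulness of any national
trend; reproducing published country curves (e.g. 2012 overall lethality
near 0.38–0.46, total detriment of order 470–630·10⁻⁴ Sv⁻¹) requires the
real registry extracts and is an integration exercise for users who hold
that data.

## Numerical and testing choices

- Survival/ life-expectancy closed forms under constant hazard (geometric
  series) agree with the generic implementation to 1e−12 relative; these
  serve as independent oracles in the tests.
- The `L_rel` normalization is pinned by a final exact rescale so
  `Σ L_rel = n` holds to 1e−12 regardless of summation order.
- The non-lethal severity part `Δd(k) = (1−k)(q_min + k(1−q_min))` has its
  analytic maximum at `k* = (1−2q_min)/(2(1−q_min))`; the tests verify the
  formula against a 10⁶-point grid search.
- Monte-Carlo recovery uses one year, 10⁶ persons per age group and 200
  replicate seeds — large enough that the ratio-estimator bias (order
  1/counts) is far below the Monte-Carlo standard error being tested
  against, and small enough to run in seconds.
- Counts are stored as floats so expected-value data flows through the
  same code path as integer registry counts; validation enforces
  non-negativity and finiteness.

## Known limitations

- Period (not cohort) life tables; no actuarial graduation or smoothing;
  no confidence intervals on rates or on the derived factors.
- Lethality is the rate-ratio (mortality/incidence) operationalization; it
  approximates, but is not identical to, survival-cohort lethality
  estimates derived from follow-up data.
- Whole-population quantities only; no sex-specific or working-age
  detriments, and `R_T` is never re-derived from dose-response data.
- The open-top midpoint and the survival-index convention are conventions,
  not estimates; sensitivity to both is easy to probe via the exposed
  switches but is not folded into any reported uncertainty.
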