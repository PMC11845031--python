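# Methods

## The quantities being estimated

For a population observed through one calendar year *a*, every
combination of integer age *x*, age quarter *r* and calendar (season)
quarter *s* defines a quarter cell of the Lexis plane.  The package
computes, per cell, the death count `D_x^{s,r}` and the person-years of
exposure `L_x^{s,r}`, and from them the crude central rates

    m_x   = D_x / L_x                 (annual; cell sums over r, s)
    m_x^{s,r} = D_x^{s,r} / L_x^{s,r} (quarterly)

so the annual rate is by construction the exposure-weighted mean of the
sixteen quarterly rates of the same age.  Seasonal-ageing indexes
γ_rs(x) summarise the stable multiplicative deviation of quarterly
rates around the annual rate and let that structure be transferred onto
a reference annual life table, yielding four quarterly life tables
indexed by the season of birth.

## Time, ages and the subjective year length

Timestamps are civil Gregorian dates at second resolution; a day is
exactly 86 400 s and leap seconds are ignored.  Sub-second resolution
and time zones are out of scope.

The season coordinate of an instant is elapsed days since Jan 1
divided by the calendar year's length (365 or 366).  Exact ages default
to the *subjective* (pair-dependent) year length: with `f_a` the
fraction of calendar year *a* enclosed between birth and event and
`l_a` that year's length,

    l(b,e) = Σ l_a f_a / Σ f_a ,   age = d(t_b, t_e) / l(b,e) = Σ f_a .

The second equality is an algebraic identity (the elapsed days
`d = Σ l_a f_a` cancel), which the implementation uses in closed form:
`age = (year_e − year_b) + coord_time(t_e) − coord_time(t_b)`.  The
weighted-mean construction is retained as an independent oracle in the
test suite and in the acceptance script.  Consequences worth noting:

* within any calendar year, age and calendar time advance at the same
  rate, so lifelines have exactly unit slope on the quarter grid;
* same-calendar-moment anniversaries give whole-number ages unless the
  birth year is a leap year;
* the degenerate pair t_b = t_e has age 0, and `pair_year_length`
  falls back to the birth year's calendar length (the ratio is 0/0).

The constant-year option divides elapsed days by exactly 365.25 (the
conventional mean Gregorian year; the orbital year is a fraction of a
day shorter, but event dates are recorded in calendar days, so the
calendar mean is the operative constant).

Dates without a time of day are resolved either uniformly at random
within the day (the default, which avoids the systematic placement bias
a fixed convention would introduce at quarter boundaries) or at a fixed
time, noon by default.  All randomisation flows through one explicit
`numpy` Generator in record order; there is no hidden global state.

## Quarter-cell geometry

Quarter membership uses the floor formulas `r = ⌊4·coord_age⌋ + 1`,
`s = ⌊4·coord_time⌋ + 1` with lower-closed/upper-open intervals, so
every event belongs to exactly one cell; an exact-integer age rolls the
integer age forward with r = 1, and coord_time can never reach 1.0 (an
event at 24:00 Dec 31 is the next year's 00:00 Jan 1).

Exposure is computed by one traversal primitive: a lifeline segment is
split at every crossing of an age or time multiple of 1/4 and the
pieces are attributed to cells, the cell of each piece being evaluated
at its midpoint (which sidesteps boundary rounding).  Pieces shorter
than 1e-12 years (boundary touches) are dropped; output grids are
always completed with explicit zero cells up to the maximum age
attained.  The unified splitting replaces a case-by-case enumeration of
event positions; its equivalence to direct numerical integration of the
lifeline (step 1e-6 years) is part of the acceptance suite.  For
full-year lifelines the traversal reduces to the closed-form
eight-cell alternation (`r0/4 − c` vs `c − (r0−1)/4`), which is also
implemented vectorised and cross-checked against the generic primitive.

Stocks counted at 00:00 Jan 1 (`forward`) accumulate a full year ahead;
stocks counted at 24:00 Dec 31 (`backward`) accumulate the year behind.
One deliberate convention: lifelines are never extended before birth.
A person born within the year — a newborn in a year-end stock, or a
newborn death passed to the outs accumulator — contributes from the
birth instant, not from Jan 1.  With this convention the two
combinations

    forward : L = L(P) + L(I) − L(E) − L(D) + L(B)
    backward: L = L(P) − L(I) + L(E) + L(D)

agree cell by cell on a closed population even in the presence of
in-year births, which is why the backward formula needs no newborn
term.  Component grids of different maximum age are zero-padded to the
common maximum before combining; negative resulting cells indicate
inconsistent inputs and are reported as a warning, not an error.

## The January-1 registration artifact

Registries frequently record an unknown immigrant birth date as Jan 1,
producing an artificial spike.  `distribute_excess` corrects a year
when the target-day count c exceeds the mean daily count over the
year's *other* days (ȳ; excluding the target day so the spike does not
inflate its own baseline) by more than `maximum_excess` percent
(default 50).  A uniformly chosen subsample of size `c − round(ȳ)`
gets new dates uniform over the year's other days, which reduces the
target day to the rounded daily mean — the full surge is removed, not
just the above-threshold part (the milder alternative is not clearly
superior and this one restores a flat profile).  When event dates are
supplied, redraws enforce birth ≤ event with a 1000-attempt cap, after
which the birth is clamped to the event date and logged.

## SAI estimation

With yearly crude-rate tables for years a_1…a_T (at least two), the
model is `log(m_x,a^{s,r} / m_x,a) = log γ_rs(x) + noise`.  Estimation
proceeds in three steps:

1. **Raw fit.**  The least-squares solution for a per-cell intercept is
   the mean over years of the log rate ratios.  Year-cells with zero or
   undefined quarterly (or annual) rate are excluded — their log does
   not exist; a cell with no valid year at all is imputed γ = 1 and
   flagged.
2. **Adjustment.**  Per age, indexes are rescaled so their
   exposure-weighted mean over the sixteen cells is exactly 1, with
   weights pooled over the input years.  This restores the identity
   that annual rates are exposure-weighted means of quarterly rates.
3. **Smoothing.**  A centered geometric moving average across ages
   within each (r, s) (arithmetic on the log scale; window truncated at
   the age-range ends; default width 5 ages, width 1 disables it),
   followed by re-adjustment.  The smoother is deliberately simple and
   configurable; heavier graduation can be applied downstream.

`margins=True` repeats the identical procedure on rates aggregated over
the season axis (γ by age quarter) and over the age-quarter axis (γ by
season).

## Life-table assembly

The reference annual table supplies `m_x`, or `q_x` converted through
the standard identity `m = q / (1 − (1 − a)q)` with a_x defaulting to
0.5.  Quarterly rates are `m̃_rs(x) = m_x γ_rs(x)` and quarterly
probabilities `q̃ = m̃ / (4 + m̃/2)`, which assumes the dying contribute
half a quarter of exposure; `q̃ < 1` holds for every `m̃ < 8` per
person-year and larger rates (far outside the demographic range) are
clamped with a warning.  The table for birth season s0 takes, in age
quarter r, the cell with season `mod4̄(s0 + r − 1)` — an individual
born in season s0 reaches age quarter r exactly r−1 seasons later — so
each (r, s) pair is used exactly once per age in each of the four
tables, and the output is the ten-column layout (age, quarter, four m
columns and four q columns by season of birth).

## The synthetic generator

`quarterlife.synthetic` emulates one calendar year of event
registration under the exact model the estimators assume: hazards are
piecewise constant over quarter cells at `m_x · γ_rs(x)`, so death
times along each lifeline are drawn by inverting the cumulative hazard
over the eight traversed cells against a unit-exponential variate.
Stock birth instants are uniform within the appropriate birth year
(placing year-start ages in the scheduled integer-age band), newborn
births and migrations are uniform within the year, and emigration
competes with death as a constant-intensity risk.  Everything derives
from one seeded generator; identical seeds give byte-identical bundles.

Default study conditions: ages 75–84 with 20 000 persons per age
(200 000 in total), a Gompertz-type schedule `m_x = 0.15·e^{0.08(x−75)}`
— death-rate levels typical of ages where seasonal mortality is
strong and cell counts are large enough for quarterly estimation — and
the seasonal pattern winter 1.2 / summer 0.8 / shoulder seasons 1.0
(mean one per age).  These sizes give roughly 3 000–6 000 deaths per
age-year, i.e. an expected per-cell sampling error of log γ of about
4–5% over two years, so the 5%-mean-recovery check has genuine power
without being a coin flip.

What the generator does *not* emulate — and therefore what passing
tests do not establish about real data: within-cell hazard variation
(real mortality varies continuously with age and date), reporting and
coverage errors other than the Jan-1 spike, cohort effects across
years, dependence between migration and mortality, and heaping of event
dates.  The generator validates the accounting and estimation
machinery, not the demographic realism of any particular population.

## Numerical conventions

* Quarter-boundary splitting uses a 1e-9 guard when locating the next
  boundary and midpoint evaluation for cell membership; traversal times
  sum to the segment length to better than 1e-9 years.
* Exposure grids and rate tables are complete by construction
  (16·(A+1) ordered rows); serialization keeps 15 significant digits
  and round-trips exactly at double precision.
* Rates of cells with zero exposure are NaN, and deaths in such cells
  raise a warning; they are excluded from SAI fitting.
* Counts stay integer-typed through grid completion; exposures are
  float throughout.

## Known limitations

* The backward stock accumulator assumes members of a year-end stock
  were present (or newborn) throughout the year; populations assembled
  from inconsistent stock and flow files will surface as negative cells
  in `combine_exposures` rather than being silently clipped.
* SAI estimation assumes the index structure is stable across the input
  years; trends in seasonality bias the pooled estimate.
* Shortcut estimators for settings without full microdata (stock-only
  approximations) are not implemented; the full-data path is the scope
  of this package.
* The age-graduation smoother is a geometric moving average, not a
  penalised spline; users needing actuarial-grade graduation should
  smooth the assembled rates externally (the window parameter exists to
  ease such alignment).
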