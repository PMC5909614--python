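# Methods

This note records the modelling choices, defaults and numerical details
behind `phenoscan`, and what the synthetic-data results do and do not
establish.

## Phenology model

The anthesis-date model develops in whole days after sowing, driven by
two daily inputs derived from weather and geometry:

* **Thermal time.** `ΔGDD = max(0, min((Tmax+Tmin)/2, Topt) − Tbase)`,
  with defaults Tbase = 8 °C, Topt = 34 °C. The response is a function of
  the daily mean only; no sub-daily interpolation is applied. The
  cardinal temperatures are configurable, and the batch kernel accepts
  per-cultivar values for six-parameter scans.
* **Photoperiod.** Day length from the closed-form hour-angle solution
  `cos ω = (sin(−d) − sin φ sin δ)/(cos φ cos δ)` at depression d = 6°
  (civil twilight), with declination from the annual sinusoid
  `δ = −23.45°·cos(2π(doy+10)/365)` and the cosine argument clamped to
  [−1, 1] so polar day/night return 24 h/0 h. The sinusoid is accurate
  to a few minutes of day length; the tests bound the error against a
  numerical solar-elevation sweep at 0.1 h over latitudes 0–42.73°.

Stages:

1. **Emergence** occurs once cumulative GDD from sowing reaches a fixed
   lag (default 45 GDD, configurable). Emergence is deliberately not
   genotype-specific: the panel being emulated recorded no emergence
   data, so it cannot distinguish lines.
2. **Juvenile phase** ends on the first day cumulative GDD since
   emergence reaches P1.
3. **Photoperiod-sensitive phase** accumulates a daily rate
   `1/(4 + P2·max(0, DL − P2O))`, evaluated at each day's own
   photoperiod, and ends (tassel initiation) when the sum reaches 1.
   The sum is compared against `1 − 1e-9`: the slack absorbs float
   accumulation (e.g. six additions of 1/6) and is far below one day's
   smallest possible increment. A `stage2_mode="fixed"` variant computes
   the duration once from the day length at end of the juvenile phase,
   for sensitivity analysis.
4. **Leaf expansion.** `SUMDTT` is thermal time from emergence through
   tassel initiation (a `sumdtt_origin="juvenile_end"` variant resets at
   the end of Stage 1 instead — the descriptions of this detail in the
   literature are ambiguous, so both readings are available and the
   default is recorded in every output). `TOLN = SUMDTT/(0.5·PHINT) + 5`;
   anthesis is the first day cumulative GDD since tassel initiation
   reaches `(TOLN + 0.5)·PHINT − SUMDTT`.

All boundaries are "first day the threshold is met" — integer days, no
interpolation. A simulation that exhausts the weather horizon (default
250 days) returns a failure sentinel ("did not flower") rather than
raising; downstream, such rows are ineligible for a line's scoring
rather than penalised, since no principled penalty date exists.

The batch kernel (`simulate_anthesis_batch`) vectorises the same
recurrences over parameter sets via cumulative sums and searchsorted;
tests assert cell-for-cell equality with the scalar path and with an
independent day-by-day trace.

## Sobol database

Parameter sets come from an unscrambled Sobol sequence (scipy's
direction numbers, skip configurable, order recorded) scaled into the
box and rounded per-axis to the grid anchored at each axis minimum
(P1 step 0.01, P2O 0.01, P2 0.0001, PHINT 0.001 — giving 30001, 401,
20001 and 45001 distinct values respectively). Generation order is the
scan order that defines first-best-found estimates, so the database
records everything needed to rebuild itself bit-identically (box, n,
skip, phenology config, content hash). The desk-scale default is
2^16 sets; the method scales to tens of millions by sharding, but
nothing in the analysis depends on the count.

Storage is parquet (one column per GSP; one int32 column per site-year;
failure sentinel −1) plus JSON metadata with a schema version and a
SHA-256 content hash, verified on load.

## Inversion

Scoring uses the exact integer sum of squared day differences; RMSE is
derived from it only for reporting. Tie detection compares integer SSEs,
never floats. The first-best-found convention (update only on strictly
smaller SSE) makes the reported estimate the earliest minimal row in
generation order, and the tie count the number of later rows attaining
the same minimum.

The continuous cross-check uses differential evolution (rand/1/bin,
population 60 = 15 per dimension, F = 0.7, CR = 0.9, up to 500
generations, seeded) on the same objective over extended bounds.
Candidates that fail to flower receive a large finite penalty. The
hyperparameters are unexceptional defaults for a 4-D box-constrained
search; the sphere-function self-test and the zero-noise recovery test
calibrate the configuration.

## Expressivity

"Nearest achievable tuple" uses per-line RMSE, which for a fixed subset
is order-equivalent to Euclidean distance; distance ties are broken by
first-witness generation order, making classification deterministic and
consistent with the database scan (asserted by a cross-module test).
The 2-D frontier is reported as the achievable set's cells in the
integer date lattice; higher-dimensional subsets report membership and
distance only.

## Stability analysis

Estimates enter the stability table only from tie-free searches, and
subsets keeping fewer than `min_lines` lines (default 100) are dropped;
both filters are recorded in the dataset provenance.

The crossed random-effects model is fit by maximum likelihood (not
REML — the compared models differ in their random structure). The
fitter profiles the grand mean by GLS and evaluates the likelihood via
the Woodbury identity on the line/subset indicator blocks: since the
line block of `A = I + G^{1/2}Z'Z G^{1/2}/σ²` is diagonal, its Schur
complement reduces each evaluation to one Cholesky of size
`n_subsets × n_subsets`. Optimisation is L-BFGS-B over the three
variances (bounded below by zero; residual variance floored at 1e-10)
from four fixed starts including the boundary `σ²_e = 0`, so the full
fit can never fall below the reduced one. Agreement with statsmodels
MixedLM (ML) is asserted to 1e-4 on reference panels, and to 1e-8
against the closed-form eigendecomposition likelihood on balanced
panels.

The LRT for `σ²_e = 0` is a boundary test. Two reference nulls are
provided: `half_df` (central χ² with 0.5 degrees of freedom — the
convention the emulated analysis stated) and `mixture`
(0.5·χ²₀ + 0.5·χ²₁, the standard boundary result; p = 0.5·P(χ²₁ > LRT),
equal to 0.5 at LRT = 0). The choice is recorded in output. The
calibration suites use `mixture`, which is the variant with a
well-defined size. P-values below floating-point range are reported in
log10 via the Chernoff bound
`ln P(χ²_k > x) ≤ (k/2)·ln(x/k) + (k − x)/2`, tagged in the output
(`p_method` suffix `:chernoff`); the bound is only an order-of-magnitude
statement, and no attempt is made to reproduce any particular published
exponent convention.

Descriptors: `IoV = 100·σ_e/μ` and
`var_pct_subset = 100·σ²_e/(σ²_e + σ²_l + σ²_ε)`;
`AIC = −2ℓ + 2k`, `BIC = −2ℓ + k·ln N` with k = 4 (full: μ and three
variances) or 3 (reduced).

## Synthetic panel

The generator emulates the *structure* of a large multi-environment
maize trial, not its climate or genetics:

* Eleven site-years at the emulated study's latitudes and sowing dates
  (18.00–42.73 °N, DOY 120–314), with weather
  `Tmax = mean + amplitude·cos(2π(doy − 200)/365) + N(0, 2°C)`,
  `Tmin = Tmax − 10 + N(0, 2°C)` clipped to `Tmax ≥ Tmin`; annual mean
  and amplitude scale linearly with latitude (warmer, flatter seasons
  toward the tropics). Two calendar years are generated so November
  sowings wrap the year end.
* Lines drawn uniformly and independently per axis inside the scanned
  box, or snapped to database rows for closed-loop experiments.
* Observations are model output plus rounded Gaussian noise (default
  sd 1.5 days — anthesis is scored in whole days), floored at day 1,
  with independent missingness (default 15%) and structural missingness
  where a line fails to flower.
* Defaults (600 lines, 11 site-years) keep a full pipeline run in the
  minutes range on one CPU.

Because observations come from the same model family the inversion
assumes, passing closed-loop tests demonstrates the correctness of the
machinery — exact recovery, tie accounting, frontier geometry, test
calibration — not the realism of the phenology model for field data.
In particular the synthetic panel contains no genotype structure, no
G×E beyond what the model itself generates, and no observer effects;
absolute tie counts and inexpressible fractions depend on database
resolution and noise settings and are not field predictions.

## Problem sizes and determinism

Default experiment sizes (2^16-set database; 600-line panels; 200
null and 100 power replicates at 200 lines × 50 subsets for LRT
calibration) were chosen as the smallest designs at which the studied
phenomena are unambiguous. Every stochastic component takes an explicit
seed; per-site and per-stage streams are spawned from a master seed, so
panels, databases and whole pipeline runs are bit-reproducible, and the
run manifest records seeds, configuration and content hashes.

## Known limitations

* The phenology model covers anthesis only — no silking, maturity,
  water or nitrogen stress; emergence is a fixed thermal lag.
* The daily-mean thermal-time response is a simplification of sub-daily
  interpolation schemes used by some implementations.
* The declination sinusoid and the clamped hour-angle formula ignore
  atmospheric refraction beyond the fixed twilight depression.
* The half-df reference for the boundary LRT is provided for
  comparability but is not a calibrated size-α test; the mixture null
  is the defensible default for inference.
* The stability fitter assumes the two crossed effects are the only
  structure; no spatial or temporal correlation is modelled.
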