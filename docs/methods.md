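# Methods

This note documents the models, estimators and design choices behind
`hotspot_assembly`, and what the synthetic-data experiments do and do not
demonstrate.

## The measurement model

**Chemotactic index.** A chemotaxis assay recovers cells from microfluidic
wells loaded either with a metabolite or with filtered seawater (the
random-motility control). The chemotactic index is the per-replicate ratio

    I_C = cells(metabolite well) / cells(control well),

with I_C = 1 meaning indifference, > 1 attraction, < 1 repulsion. Attraction
is called by a two-sided one-sample t-test of the replicate ratios against 1
at α = 0.05, reported as attraction only when the mean exceeds 1. The test
runs on raw ratios by default; a log-ratio variant is available
(`compute_ic(..., log_scale=True)`) since the sampling scale is not uniquely
determined by the ratio definition. A metabolite count of 0 with a positive
control count is a valid repulsion-side value (I_C = 0); a zero control
count makes the ratio undefined and is an error naming the replicate.

**Growth rate.** The maximum specific growth rate μ (h⁻¹) is the steepest
slope of ln OD600 over a sliding window of `window_points` consecutive
readings (default 5, ≈ 5 h at hourly sampling). A window qualifies as "the
linear portion" when its R² ≥ `fit_r2_min` (default 0.95); the replicate
estimate is the maximum slope among qualifying windows. If no window
qualifies, the best-R² window is reported with a quality flag instead of an
exception. Significant growth requires (i) a two-sided t-test of the
replicate μ values against 0 at α, (ii) a positive mean, and (iii) the
quality flag: maximum-slope selection over noise-only windows is positively
biased, so without (iii) a flat noisy curve would regularly be called
growth. Curves are assumed blank-corrected; `blank="first"` subtracts each
well's first reading instead. Note that first-point subtraction removes the
inoculum signal too and steepens early log-slopes, which is why it is not
the default. Points at or below the blank are excluded from the log
transform rather than clamped.

## The null model of hotspot community assembly

The null hypothesis is that each strain in a mixture behaves exactly as it
does in isolation. For a pair at inoculum fractions f = (f_A, f_B) with
control-well entry coefficients r (equal by default; solo control counts
can be supplied as estimates):

* **Chemotaxis phase.** Entry weights w_i = f_i r_i / Σ f_j r_j. The pooled
  index of the mixture is the weighted mean Σ w_i I_i and the metabolite-well
  composition is share_i = w_i I_i / Σ w_j I_j. Under the Poisson well-entry
  model (cells enter wells as independent Poisson processes with rate ∝
  background × entry coefficient × index) these formulas are exact
  expectations, which is what makes the zero-noise self-consistency checks
  exact.
* **Growth phase.** Each strain grows exponentially and independently at its
  solo rate for T = 24 h: n_i(T) = n_i(0) e^{μ_i T}, fractions renormalized.
  There is no carrying capacity in the null projection — it is deliberately
  a null of independent growth; negative point estimates of μ are clamped
  to 0 (the rate is non-negative by definition).

**Deviation statistic.** At each stage the deviation between predicted and
observed compositions is D = 100·max_i |f_pred,i − f_obs,i| percentage
points (for two strains both coordinates give the same value). D > 10 pp
flags an inter-species interaction. The 10 pp threshold is conservative
*when the predicted final composition is away from the knife edge*: the
post-growth deviation responds to growth-rate estimation error Δμ roughly as
f(1−f)·T·Δμ·100, so at T = 24 h and mid-range fractions (f ≈ 0.5) even a
Δμ of 0.02 h⁻¹ produces ≈ 12 pp. The default synthetic conditions encode a
clear competitive hierarchy (μ = 0.25 vs 0.14 h⁻¹), under which a 1000-seed
null calibration measures P(D > 10) ≈ 1%. Near-equal growth rates make the
rule anti-conservative at realistic OD noise — a genuine property of the
statistic that users should keep in mind when interpreting borderline
daggers. The same saturation effect means a growth boost of the *dominant*
strain is nearly undetectable by D (the composition is already ≈ 1/0),
while any interaction that changes the outcome is highly visible.

**Member-level indices.** Within a mixture, each strain's index is inferred
by splitting the pooled well counts by the sequenced well compositions:
I_i = (fm_i·M)/(fc_i·C) where fm/fc are the strain's fractions in the
metabolite and control wells. This satisfies Σ fc_i·I_i = M/C exactly
(tested to 1e-12). Interaction directions per strain — detrimental (−),
neutral (0), beneficial (+) — come from a two-sided Welch test of the
replicate member indices against the solo replicate ratios at α (one-way
ANOVA available as the alternative); outcome labels are canonicalized worse
symbol first (−/0, −/−, −/+, 0/+).

## Monte Carlo uncertainty propagation

Per draw (default 10 000): solo indices and growth rates are sampled from
the Student-t-scaled sampling distributions of their replicate means
(rejection-truncated at 0), or by nonparametric bootstrap of the replicates
(`mode="bootstrap"`); the initial composition is drawn from
Dirichlet(initial read counts + 1), a minimal posterior acknowledging
finite read depth. The trajectory is then evaluated in closed form
(vectorized, growth in log space to avoid overflow from t tails). Tracked
quantities: the pooled index and the focal strain's fraction at each stage,
as empirical CDFs with central 95% intervals. Empirical two-sided p-values
are p = 2·min(F(x), 1−F(x)), floored at 1/draws so they are never exactly 0.

The predicted-vs-observed test for the pooled index places the mean
observed ratio in the MC predictive. A 400-seed null run measured a type-I
rate of 0.055 at nominal α = 0.05: the heavy t₂ tails of the n = 3 sampling
distributions compensate the unmodelled observation noise almost exactly.
An explicitly widened posterior-predictive variant
(`include_observation_noise=True`) is available and is strictly
conservative (measured 0.002–0.018).

## Amplicon calibration

Each library is normalized to a fixed total (10⁶ reads) and per-strain
ordinary least squares of normalized reads on known mock cell counts gives
a calibration line; inversion (with clamping at 0 near the detection limit)
converts sample reads to cell abundances. The intercept is fitted rather
than forced through the origin (`through_origin=True` available). 16S
copy-number and amplification biases are absorbed into the per-strain
slopes, exactly what a mock-community design measures. The synthetic mock
design assigns each strain a shuffled log-spaced ladder of cell counts
(10⁴–10⁶) and rescales every mock to a common total: with unequal totals,
per-library normalization would destroy the reads~cells linearity the
calibration relies on, so equal-total mixing is treated as part of the
design (mocks mixed at matched optical density are consistent with this).

## The synthetic-data generator

The generator emulates the post-processing inputs of the study design:

* Well counts: per-strain Poisson around the entry-model expectations
  (control ≈ 1000 cells at the defaults: background 10⁶ cells/ml, entry
  coefficient 10⁻³ per hour, 1 h incubation).
* Amplicon reads: multinomial at fixed depth (default 50 000 reads, a
  typical per-sample amplicon depth) from within-sample cell fractions;
  optional Dirichlet-multinomial overdispersion for robustness checks.
* OD curves: logistic with lag (default 3 h), inoculum OD 0.01, carrying
  OD 0.5, plus Gaussian noise σ = 0.002 OD units (typical plate-reader
  precision), truncated at 0.
* Interactions: multiplicative modifiers α (on I_C) and γ (on μ) applied
  only when a partner is present; 1.0 everywhere is the null. Multiplicative
  rather than additive because both quantities are ratio/rate scaled.
* Unequal inoculum (focal strain 60/40 overrepresented) emulates clumping
  at inoculation; clumps are not modelled physically.

Zero-noise mode replaces every draw by its expectation, reproducing all
closed forms to ≤ 1e-12; fixed seeds give bit-identical outputs. The
zero-noise self-consistency fixtures additionally lift the carrying
capacity (pure exponential curves): with a finite K even a noiseless
logistic has window slopes strictly below μ, so "deviation exactly 0" holds
only in the exponential regime — the regime the null projection assumes.

What passing these tests does **not** show about real data: the generator
has no cross-feeding dynamics, no spatial structure in the wells, no
chimeras/contamination in sequencing, no diauxie or death phase in growth,
and its read noise is at most mildly overdispersed. Conclusions about
detection power and calibration transfer to real experiments only insofar
as those features are second-order.

## Problem sizes and numerical choices

Calibration experiments in the test suite use 1000 seeded null pipelines
(conservativeness and type-I rates), 200-seed power runs per injected
effect, 100-seed parameter-recovery and calibration-linearity runs, and
20 random parameter sets against a 10⁶-agent Bernoulli/branching oracle —
sizes at which Monte Carlo error is far below every asserted margin while
the whole suite runs in about a minute. Ties and degenerate cases: zero
replicate variance short-circuits t-tests (p = 0 or 1 by exact comparison);
an MC draw with both indices 0 falls back to the entry weights (no
chemotactic tilt); empirical p-values are floored at 1/draws; estimate
tables round-trip through CSV at full precision (%.17g with round-trip
float parsing).
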