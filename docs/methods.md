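# Methods

## The paradigm

A participant glimpses a shape drawn from a circular space of 360 morphs
(one per integer degree; angular distance tracks visual similarity) and
then *bets* on what they saw: six successive placements of a Gaussian
bump (sd 4°) on the wheel. The first bet is twice as tall as the rest.
The bumps sum into a per-trial **uncertainty profile** — effectively a
drawn probability distribution over shape space — and the trial is
scored by the profile's height at the true shape:

    points = 500 × height(target),   maximum 200 per trial.

Stacking all six bets on one spot is discouraged by a diminishing-returns
penalty. With `y` the running profile and `b` the new bet location, the
component about to be added is scaled by a factor read at `b`:

    y' = y + G_b · m · (1 − y(b)^0.4)

where `G_b` is the unit Gaussian component at `b`, `m` its height
multiplier (2 for bet 1, 1 after), and 0.4 the penalty exponent. The
factor is a scalar evaluated at the integer bin nearest `b` and applied
to the whole component, clamped to [0, 1] so mass can never be removed;
profile heights consequently approach but never reach 1.

The paradigm is a probability-elicitation device: if perception hands
the decision system a full posterior rather than a point estimate, the
drawn profiles should carry trial-specific probabilistic structure, and
the package's analyses are built to detect exactly that.

## Scoring normalization

The unscaled component's peak height is a free constant. Two
normalizations are provided:

- **fixed** (default): `standard_peak = 0.1`, the peak of a unit-area
  Gaussian with sd 4° (≈ 0.0997) rounded to one digit. Bet 1 then peaks
  at a round 0.2 (100 points on its own) and six stacked bets score
  ≈ 199.2 — the advertised 200-point maximum up to rounding.
- **calibrated**: the component height (≈ 0.1006) is solved numerically
  from the scalar stacking recursion `y₁ = 2H`,
  `yₖ₊₁ = yₖ + H(1 − yₖ^0.4)` so the six-bet stack scores exactly 200.

Profiles are evaluated on the 360-bin integer grid (bin *i* covers
[i − ½, i + ½)); bet centers remain continuous. Components are wrapped
(summed over ±2 revolutions); at sd 4° the wrap mass is far below
floating-point resolution, so wrapping matters only for much wider
components.

## Circular conventions

Everything at the interface is in degrees. Positions live in [0, 360)
(360 maps to 0); signed errors live in (−180, 180] with positive =
clockwise, and the antipodal tie resolves to +180. Cumulative bet
averages are unweighted circular (vector-resultant) means; a resultant
below 10⁻⁹ of the total weight raises an explicit "undefined mean" error
rather than returning an arbitrary direction — trials tripping it are
excluded from the bet-order analysis with a warning. The expected
absolute error of a uniformly random response is 90°, the chance
baseline used throughout.

## Simulated observers

The synthetic-data generator produces cohorts (default 40 participants ×
150 trials, matching the study design it emulates) under three
generative accounts. Per trial, the internal center is
`m = target + ε`, `ε` wrapped-normal with participant-level
`encoding_sd`, and an internal width `w` is drawn (normal with mean
`internal_sd_mean`, sd `internal_sd_spread`, floored at 5% of the mean).

- **sampling** — every bet is an independent draw from the internal
  distribution (center `m`, width `w`), plus motor/decay noise of sd
  `bet_noise_growth × (k − 1)` for bet `k`. Averaging independent draws
  pulls the running mean toward the target, so the cumulative error can
  fall *below* the first bet's error — the signature of reportable
  probabilistic structure.
- **discrete** — bet 1 is placed exactly at `m`; bets 2–6 scatter
  symmetrically about `m` with width `w` independent of `ε`. Symmetric
  scatter about a point estimate can only dilute it: the cumulative
  error never improves on bet 1 in expectation.
- **discrete_confidence** — as discrete, but `w` is a convex combination
  (weight `confidence_coupling`) of the random width and a term
  proportional to `|ε|`: a point estimate plus a calibrated sense of
  confidence, still without access to a distribution.

Asymmetry (`skew ≠ 0`) is a two-component zero-mean mixture: offsets
`+skew·w` (weight ¼) and `−skew·w/3` (weight ¾), component width
`w/(1 + |skew|/2)` so the offsets, not the tails, carry the asymmetry;
`skew = 0` reduces exactly to a single wrapped normal. A von Mises
noise switch is available for robustness checks.

Defaults (`encoding_sd` 12°, `internal_sd_mean` 10°, growth 2°/bet,
heterogeneity ranges of roughly ±30% across participants) place mean
first-bet error in the mid-teens of degrees — the regime typical of
brief shape presentations. They are configuration values, not fitted
estimates.

Each bet is independently replaced by a uniform mis-click with
probability `lapse_rate` (default 0.5%). With `undo_enabled`, the first
mis-click of a trial is noticed with probability 0.67 — which puts the
per-trial undo rate near the ~2% seen empirically — recorded as an undo
event, and replaced by a fresh draw. Undone bets therefore sit at the
90° chance level while their replacements look like ordinary responses.

Reproducibility: one seed per dataset, with an independent spawned
substream per participant, so enlarging a cohort never perturbs
existing participants.

## Analyses

`BettingGameModel(dataset).fit()` computes four families per participant
and aggregates:

1. **Spread–error coupling.** Pearson correlation (linear, on the two
   nonnegative quantities) between |bet-1 error| and a per-trial spread
   measure — median absolute adjacent-bet distance by default, or the
   sd/IQR of the drawn profile. Per-participant r values are
   Fisher-transformed and the z's tested against zero (one-sample t,
   95% CI). Participants with zero variance in either variable are
   excluded with a warning. No multiple-testing correction is applied to
   the per-participant p-values; the count of significant positive
   correlations is reported alongside.

2. **Profile vs first-bet-error distribution.** Each trial's six-bet
   profile is rebuilt, circle-shifted to put the target at 0, and
   averaged across trials. The across-trial distribution of signed
   first-bet errors is compared with this average by a two-sample KS
   test, where the profile side enters as a deterministic inverse-CDF
   pseudo-sample at quantiles (i − ½)/n (no added randomness); a
   one-sample variant against the profile's continuous CDF is available
   behind a flag. The **flipped** control mirrors the averaged profile
   about the aligned target before comparison (mirroring each trial
   about its first bet is provided as an option). KS p-values use the
   asymptotic two-sample null.

   *Independence split.* The first bet is itself part of the drawn
   profile, so comparing both sides on the same trials couples their
   finite-sample noise: the unflipped D is biased low and a flip
   "effect" appears even for perfectly symmetric observers (paired
   t ≈ 4.7 at 40×150 in simulation). By default the error sample is
   taken from even-indexed trials and the profile from odd-indexed
   trials, restoring the independence the KS null assumes;
   `holdout=False` reproduces the same-trials comparison.

3. **Bet-order error curves.** Mean |error| of each individual bet, and
   of the running circular mean of bets 1..k, per participant; each
   curve goes into a classical one-way repeated-measures ANOVA over bet
   order (df (5, 5(n−1)) for 6 bets, no sphericity correction). Effect
   size is reported as η² = SS_effect/(SS_effect + SS_error), with the
   total-SS variant attached since conventions differ.

4. **Undo diagnostics.** Usage rate, error of undone vs replacement
   bets, and the distribution of undos over bet indices.

All group tests are two-sided.

## What the simulations show — and what they cannot

On seeded synthetic cohorts the analysis battery separates the accounts
as designed: only the sampling observer produces a cumulative bet-6
error significantly below bet-1 error, while its individual-bet errors
rise with bet order; both discrete accounts leave the cumulative curve
at or above bet 1; confidence coupling (and width variability alone)
produces a positive group mean z; pronounced skew makes the flipped KS
D significantly exceed the unflipped D, and symmetric observers show no
flip effect. Two findings from building the battery are worth flagging:

- *Mis-clicks mimic confidence coupling.* A lapsed first bet inflates
  both the first-bet error and the trial's bet spread, so even the
  fixed-spread discrete observer acquires a small positive mean z
  (≈ +0.01 to +0.04 at a 0.5% lapse rate). The discrimination cohorts
  are therefore simulated lapse-free, and real-data spread–error
  correlations should be read net of this contamination channel.
- *The flip control has limited power for mild asymmetry.* At 40×150,
  detecting the flip effect reliably requires pronounced skew (the
  mixture at `skew = 2.5`); weak asymmetry goes undetected.

The generator emulates the trial schema and the statistical structure
the analyses consume — not stimulus rendering, retention intervals,
motor kinematics, sequential dependencies between trials, or strategic
behavior. Passing fingerprints on synthetic cohorts validates the
pipeline's logic and power at this design size; it does not by itself
certify conclusions about any real dataset.

## Numerical choices

- Degenerate circular means raise; they are never silently imputed.
- The penalty gain factor is clamped to [0, 1]; profiles are
  monotonically non-decreasing under added bets.
- Profile spread: sd is the discrete standard deviation of the
  normalized profile over (−180, 180]; IQR interpolates linearly within
  one-degree bins (a single sd-4° component gives sd ≈ 4.0° and
  IQR ≈ 5.4° ≈ 1.349 σ).
- Calibration of the component height is a bracketed root solve on the
  scalar recursion (Brent, xtol 10⁻¹⁴).
- Angles serialize at 3 decimals; the read→write→read cycle is an exact
  fixed point and repeated writes are byte-identical.

## Problem sizes

Unit tests run cohorts of 3–10 participants × 20–150 trials; the
end-to-end discrimination battery uses four cohorts at the full design
size of 40 × 150 (seed 1234), which completes in seconds. Chance-level
checks use 10⁶ uniform draws.
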