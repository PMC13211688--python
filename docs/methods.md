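# Methods

This note documents the models, numerical choices and limitations of
`ecotransfer` at the level a user needs to judge what the outputs mean.

## Data model and censoring

A cohort is two tables: animals (id, ISO sampling date, WGS84 coordinates,
region, age in years, sex, optional body mass kg and length cm) and long-form
measurements (animal, tissue from the closed seven-tissue vocabulary —
muscle, heart, spleen, lungs, liver, kidney, bone —, analyte, value, unit,
dry/wet basis, censored flag, optional relative uncertainty). A value
reported only as "below the decision threshold" is stored as the threshold
with `censored=True`: the file keeps one numeric column and every downstream
stage decides explicitly what to do with censored rows. The default policy is
complete-case (censored rows counted, never substituted); `half_lod`
substitutes half the threshold and exists as a sensitivity switch, not a
recommendation — with per-tissue n of 5–10, any substitution rule visibly
moves tail statistics. Units are carried as strings and checked for
consistency within an analyte; they are never converted silently (the only
automatic alignment is µg/kg ↔ mg/kg where a soil or threshold table is
explicitly being compared against tissue values).

## Physical corrections

Decay correction uses A(t) = A₀·2^(−Δt/T½) with Δt in years of exactly
365.25 days; the sub-0.1 % deviation from calendar arithmetic is far below
the measurement uncertainty of γ-spectrometric activities and keeps the
operation exactly invertible (the round trip is the identity to machine
precision, which is tested). Half-lives: Cs-137 30.0 y, Pb-210 22.2 y; K-40
is carried with its physical half-life (1.25·10⁹ y), making its correction a
no-op on sampling timescales.

Dry→wet conversion multiplies by f = 1 − moisture. Defaults: muscle 0.25,
heart 0.24, lungs 0.23, liver 0.30 (from measured moisture of those
tissues); **spleen 0.23 and kidney 0.25 are configuration placeholders**, not
measured values — no moisture is available for those tissues and users with
their own measurements should override them. Bone uses a fixed 0.8 dry/wet
mass ratio in place of a measured moisture. Censored thresholds convert like
values, flag preserved: basis conversion is bookkeeping, not inference.

## Summaries and distribution

Per analyte × tissue cell: AM, sample SD (n−1), GM = exp(mean log), median
(midpoint rule for even n), min–max, all over detected values, with the
censored count reported alongside. GM ≤ AM is a tested invariant.

Relative tissue distribution is the mean over animals of the *per-animal*
percent (tissue value / same animal's muscle value × 100), not the ratio of
tissue means: the per-animal ratios are what the paired sign-flip comparison
between two analytes' distributions needs, and they are scale-free per
animal. Animals without a detected muscle value are dropped with a warning.

Inter-tissue association uses tie-aware Spearman rank correlation
(scipy, average ranks), pairwise-complete; entries with fewer than three
complete pairs are reported missing (NaN), never as zero. No significance
testing is attached to these matrices — they are descriptive.

The body condition index regresses body mass (response) on body length over
a reference population by OLS and reports the mass residual. The regression
direction follows the residual-index convention (condition = mass relative
to that predicted for the animal's length); animals missing either biometric
get a missing BCI.

## Permutation inference

Three tests share one design: two-sided p-values on |statistic|, exact
enumeration whenever the null set fits (2ⁿ sign patterns up to 2²⁰; n!
orderings or C(n, n_a) label assignments up to 10⁶), otherwise seeded Monte
Carlo with the add-one correction p = (k+1)/(B+1) and B = 10,000 by default.
Exhaustive p-values are exact rationals and include the identity
arrangement; ties between permuted and observed |statistic| count toward the
numerator (conservative), implemented with a 10⁻¹² relative tolerance so
exact ties survive floating point. Statistics: mean paired difference
(sign-flip), Pearson r (correlation test), mean difference (two-group test).
Type-I calibration at α = 0.05 over 200 null replicates is part of the test
suite for all three.

## Robust Bayesian correlation

Pairs (xᵢ, yᵢ) within one tissue follow a bivariate Student-t with location
μ, scale matrix Σ = diag(σ)·[[1, ρ], [ρ, 1]]·diag(σ) and degrees of freedom
ν. Priors: ρ ~ Uniform(−1,1); ν−1 ~ Exponential(mean 29); μⱼ ~
Normal(x̄ⱼ, 2.5·SDⱼ); σⱼ ~ HalfNormal(2.5·SDⱼ), with the sample moments taken
over the pairs actually fitted (detected, listwise-complete). The t tails
let the model estimate how much weight outlying animals deserve instead of
forcing an include/exclude decision; outlying individuals are always
retained.

The sampler is adaptive random-walk Metropolis on transformed parameters
(raw μ, log σ, atanh ρ, log(ν−1)), with the log-Jacobian added so the chain
targets the stated priors. Each sweep updates the six coordinates one at a
time (proposal scales adapted toward 44 % acceptance in 25-iteration windows
during tuning only, with 10 % of proposals at 5× scale to cross low-density
valleys) and then makes two joint proposals from a multivariate normal whose
covariance is the empirical covariance of the second half of tuning, scaled
by 2.38/√6. Everything adapted is frozen when tuning ends, so the returned
draws come from a valid Markov chain. Chain c is seeded `seed + c`. Defaults:
4 chains × 2000 draws after 1000 tuning steps.

Diagnostics are computed on the returned draws: split-R̂ (Gelman–Rubin on
half-chains) and ESS per chain via Geyer's initial-positive-sequence
truncation of the autocorrelation, summed over chains; constant chains
return NaN ESS as a documented sentinel. The adequacy bar is R̂ < 1.01 and
ESS > 400 on *all six* parameters. The 95 % interval is the highest density
interval (shortest window over sorted draws), not equal-tailed, which
matters for the skewed ρ posteriors that small n produces.

Practical behaviour, as exercised by the test suite: at n = 200 the sampler
meets the adequacy bar at default settings and recovers a true ρ = 0.8
within ±0.1; over 50 seeded replicates at n = 50 the 95 % HDI covers the
true ρ at its nominal rate (≥ 43/50 required). At n = 5–7 with values
spanning several orders of magnitude, the *nuisance* parameters (μ, σ, ν)
can mix slowly — the posterior develops near-disconnected regimes trading σ
against ν — while the ρ margin typically remains well mixed. The
diagnostics exist precisely to flag this: when R̂ exceeds the bar, rerun
with more tuning and draws (the README example uses 4000/8000 for such a
case) rather than trusting the summary.

## Concentration ratios

CR_wo-soil = c_wo (wet mass) / c_soil (dry mass), dimensionless. One proxy
tissue represents the whole organism per analyte: muscle for Cs-137, Ca, Cd,
Cu; bone for Mn and Pb; liver for Zn. Soft-tissue proxies convert dry→wet
with the tissue factor; bone Mn uses the 0.8 dry/wet ratio; Pb and Pb-210
from bone use the dedicated bone-to-whole-organism factor 0.16, which
already embeds the 0.8 ratio (so it is applied instead of it, not on top).
Radionuclide soil entries are decay-corrected from their own reference date
to each animal's sampling date *before* averaging across entries, because
literature entries refer to different dates; stable-element entries pass
through unchanged. Per-animal CRs are computed first and then summarised
(AM ± SD, GM, range) — summaries of ratios, not ratios of summaries.

The shipped soil table is **synthetic**: the two Cs-137 entries use
literature activity values (109 and 141 Bq/kg dm) with placeholder reference
dates (mid-years of plausible survey windows, 2013-07-01 and 2015-07-01),
and the remaining rows are invented, order-of-magnitude-plausible values.
Any quantitative CR work must supply a real site-specific table; the
placeholder dates shift the Cs-137 denominator by roughly 2 % per year of
error (half-life 30 y), which is small but not nil.

## Threshold screening

Literature thresholds (toxic levels, adequate bands, high levels) are a
packaged, editable CSV in mg/kg; entries published on a wet-mass basis carry
a wet-to-dry factor and are multiplied by it before comparison against
dry-basis measurements. Observed detected ranges are flagged
below / within / spans / exceeds; band entries use interval logic, single
thresholds a one-sided comparison. µg/kg measurements are rescaled to mg/kg
for the comparison.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the study's conditions: cohorts of 10 animals (7 is typical for radionuclide
subsets) across seven tissues; lognormal levels with tissue-specific medians
of the magnitude reported for temperate-forest wolf tissues (e.g. muscle
Cs-137 median 6.49 Bq/kg dm); equicorrelation 0.7 between tissues on the log
scale; radionuclide/stable-analogue pairs drawn as a multivariate Student-t
(ν = 5) whose per-tissue bivariate margins have correlation 0.8 — the
correlated-normal-over-√(χ²_ν/ν) construction, one mixing draw per animal;
one outlier animal (index 3) whose caesium-family values are multiplied by
5, mirroring a biologically plausible high individual retained in all
analyses; and thresholding-based censoring (default: radiolead below
9 Bq/kg). Log-scale SDs (1.6 for Cs-137, 1.3 for Cs, 0.6 for Pb-210, 1.0 for
Pb, 0.9 for Cd) were chosen once for realistic skew and test power — no
per-tissue variance components are published to fit against.

Randomness uses one root seed with named substreams (animals, levels,
censoring), so adding a stage cannot perturb earlier draws, and identical
parameters and seed give a bit-identical dataset.

What the generator does *not* emulate: spatial structure of deposition,
diet/trophic-transfer mechanisms, age- or sex-dependent accumulation,
measurement uncertainty, or correlated censoring. Tests passing on synthetic
cohorts therefore demonstrate the statistical machinery is correct under the
assumed structure, not that real tissue data satisfy that structure.

## Numerical conventions

- Exact binary arithmetic is exploited where it exists: one half-life halves
  an activity exactly (2⁻¹), and exhaustive permutation p-values are exact
  rationals.
- Degenerate inputs fail loudly before computation: zero-variance data for
  the correlation model, constant reference lengths for the BCI fit,
  all-censored cells for summaries, non-positive-definite correlation
  matrices for the generator.
- Missing is distinguished from zero throughout (NaN Spearman entries,
  `None` biometrics, omitted CR rows with a warning).
- Pipeline outputs are deterministic given the config: every CSV carries a
  `# seed=` header and reruns are byte-identical.

## Design choices where the design was open

- Relative distribution aggregates per-animal ratios rather than ratio of
  means (pairing is required by the sign-flip comparison; both views can be
  derived from the stored per-animal percents).
- BCI regresses mass on length, not the reverse (residual-index convention).
- Exhaustive permutation enumeration is preferred whenever feasible even
  though B = 10,000 Monte Carlo is the conventional default; the result
  object records which method produced the p-value.
- The sampler is random-walk Metropolis rather than gradient-based: six
  parameters, a cheap likelihood, and no autodiff dependency; the R̂/ESS bar
  defines adequacy regardless of sampler brand.
- Spleen/kidney moisture defaults and the soil reference dates are declared
  placeholders rather than silently invented numbers.

## Known limitations

- Left-censoring is handled by exclusion (or half-threshold substitution),
  not by likelihood-based censored models; with heavier censoring than a few
  rows per cell, summaries become biased high.
- The robust-correlation nuisance parameters mix slowly on very dispersed
  small samples (see above); budget longer chains there.
- CR results inherit every approximation of the proxy-tissue convention; the
  whole-organism value is a single-tissue surrogate, not a body-burden
  integral.
- The BCI is only as good as its reference regression; no reference
  population ships with the package.
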