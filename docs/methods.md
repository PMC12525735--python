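# Methods

## Model

Caloric intake from breast milk per kg of infant body weight is modelled
per age stratum as

    per_feed = V · (D/100) / W      [kcal/kg/feed]
    per_day  = F · per_feed         [kcal/kg/day]

with F the daily feeding frequency (feeds/day), V the volume ingested
per feed (mL), D the milk caloric density (kcal/dL; ÷100 converts to
kcal/mL) and W the infant weight (kg). Milk mass and volume are treated
as equivalent (milk density ≈ 1.03 g/mL is not corrected for). The four
variables are sampled **independently**: no correlation structure is
imposed, although an inverse frequency–volume relationship has been
reported observationally; modelling it would require a joint
distribution the available evidence does not constrain, and the
independent model already reproduces the reference summary table. This
is the main structural assumption and the first candidate for
refinement.

Age is stratified into 0–1, 1–3, 3–6, 6–9, 9–12, 12–18 and 18–24
completed months (half-open intervals, so strata are contiguous and
non-overlapping). Each stratum is simulated with a single flat loop of
5000 iterations (35,000 total at defaults); no nested
uncertainty/variability structure is used, as the reference results are
reproducible without one.

## Input distributions

Families were chosen to match what each variable's evidence supports:

* **F ~ triangular(a, m, b)** — only a plausible range and modal value
  are available from feeding-frequency studies. Sampling uses the
  inverse-CDF transform (deterministic in the underlying uniform
  stream; no rejection step).
* **V ~ Beta-PERT(a, m, b; λ=4)** — captures asymmetry and damps
  outliers relative to a triangular with the same support. Implemented
  as the standard construction: a Beta(α₁, α₂) variate rescaled to
  [a, b] with α₁ = 1 + λ(m−a)/(b−a), α₂ = 1 + λ(b−m)/(b−a); mean
  (a + λm + b)/(λ+2), variance (μ−a)(b−μ)/(λ+3). λ = 4 is the
  conventional weight used by spreadsheet risk-analysis tools and is
  exposed as a field so variants are testable; with it, the PERT mean
  (a + 4m + b)/6 ties the density inputs exactly to their pooled means.
* **D ~ normal(μ, σ) or PERT** — decided by the heterogeneity of the
  pooled evidence (below). Normal density draws are not truncated; a
  guard resamples the practically impossible non-positive draw (at the
  default μ/σ the event has probability below 10⁻⁶⁰⁰⁰) and logs a
  warning, so meaningless negative calories can never enter the
  equations without distorting the distribution measurably.
* **W ~ uniform(a, b)** — bounds are the reference median (P50)
  weight-for-age of girls (lower) and boys (upper); a flat distribution
  encodes indifference within that biologically plausible band.

The shipped default configuration hard-codes the published per-group
parameters, including which groups use a normal versus a PERT density;
these defaults are authoritative over the I² rule below. `make-config`
emits them as editable YAML for scenario analyses (preterm growth,
maternal malnutrition, alternative growth references).

## Meta-analysis stage

Study-level density measurements (mean, SD, n per study) are pooled per
age group with inverse-variance weighting under a random-effects model.
Within-study SE is sd/√n. The between-study variance τ² uses the
DerSimonian–Laird moment estimator — the canonical random-effects
inverse-variance method and the default of common online calculators —
computed from Cochran's Q; I² = max(0, (Q−(k−1))/Q)·100. Alternative τ²
estimators (REML, Paule–Mandel) would be drop-in replacements but are
not provided. A single-study group is passed through as its own pooled
estimate with Q = τ² = I² = 0 rather than erroring, because two strata
rest on one usable study. z = 1.96 (95% CI) throughout, configurable.

Conversion to a model input: I² < 75% (the conventional "high
heterogeneity" cut-off; values at the threshold take the PERT branch)
gives normal(pooled mean, σ) with σ back-computed from the CI
half-width, σ = (CI_high − CI_low)/(2·1.96); otherwise PERT(CI_low,
pooled mean, CI_high). Back-computing σ from the rounded, published CI
rather than carrying the pooled SE forward reproduces the published
input parameters exactly (0.76 and 0.79 kcal/dL for the two
homogeneous strata).

## Randomness and determinism

One master seed governs everything. Each (age group, variable) pair
draws from an independent generator keyed on the master seed plus CRC32
hashes of the group and variable labels (via numpy's `SeedSequence`),
so per-group results are bit-identical regardless of which groups are
run or in what order, and identical seeds give byte-identical output
files end-to-end. The CLI default seed is 20250930 and is always logged.

## Summaries and convergence

Summaries use the sample mean, SD with the n−1 denominator, and
quantiles by linear interpolation between order statistics (numpy's
default, equal to the inclusive spreadsheet percentile rule). The
convention is fixed because exact regression tests need one; at n = 5000
the alternatives differ by well under 0.1%. Quartiles define the
scenario bands: value ≤ Q1 is LCI, value ≥ Q3 is HCI, MCI between —
boundary assignment to the outer bands is a documented convention, and
MCI (Q2) is read as the empirical median of the draws. Full precision is
retained internally; 2-decimal rounding is presentation-only.

Convergence is monitored by running means and quartiles at periodic
checkpoints; a run is declared stable when the maximal relative span of
each statistic over the trailing 20% of checkpoints is ≤ 0.5%. All
default groups satisfy this at 5000 iterations; runs of a few hundred
iterations are flagged.

## Synthetic study generator

`synth_studies` draws k study means from N(true_mean, τ² + sd²/n) with
the reported SD held at the nominal within-study value, emulating a
literature of equally sized, equally precise studies with optional real
between-study heterogeneity. It supports parameter-recovery tests
(unbiasedness at τ = 0, detection of large τ through I²). It does not
emulate unequal study sizes, rounding of published values, selective
reporting or non-normal effect distributions — so passing tests show
the estimator is implemented correctly, not that it is robust to those
real-data features.

## Verification

Three independent oracles check the pipeline: (i) closed-form moments
of every distribution family against large-sample empirical moments;
(ii) an analytic expected-intake formula, E[per_day] =
E[F]·E[V]·(E[D]/100)·E[1/W] with E[1/W] = ln(b/a)/(b−a) for uniform
weight, against simulated means at n = 10⁶; (iii) a pure-Python
brute-force DerSimonian–Laird implementation (and R's `metafor`,
method "DL") against the vectorised pooling on randomised fixtures.
The acceptance script re-simulates at the reference size of 5000
iterations per group.

## Known limitations

* Independence of F, V, D, W (see above).
* Inputs describe healthy, full-term infants from mostly high- and
  middle-income settings; exclusively literature-derived ranges for V
  and F rather than pooled estimates.
* No complementary-food energy, no comparison against energy-requirement
  references, no growth-curve interpolation within a stratum.
* Bit-level agreement with spreadsheet risk-analysis engines is not
  claimable: their PERT λ and sampling algorithms are unpublished; only
  distributional agreement is tested.
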