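# Methods

## Scope

`oscillometry` implements a within-breath forced-oscillation (FOT) analysis
chain for induced-bronchoconstriction studies, together with a virtual-lung
simulator that serves as its ground truth. The chain is: breath
segmentation → least-squares impedance estimation at the stimulation
frequencies → artifact rejection → temporal-variability indices →
post-deep-inspiration (DI) renarrowing kinetics → dose–response
interpolation → cohort-level symptom–mechanics screening and forward
stepwise regression.

## The virtual lung

A single-compartment respiratory system with prescribed flow. Flow is the
sum of a tidal sinusoid (tidal volume `VT`, breathing frequency `BF`), an
optional DI excursion (a raised-cosine volume bump of `di_volume` litres
over `di_duration` seconds), and small sinusoidal oscillations at the
stimulation frequencies. Pressure follows from

    P(t) = R(t)·V'(t) + E·V(t) + I·V''(t)

with instantaneous resistance

    R(t) = R0 · (1 + x(t)) · (1 − vol_gain·V_slow(t)) · g_DI(t).

* `x(t)` is a stationary Ornstein–Uhlenbeck process (exact AR(1)
  discretization, stationary initial state) with SD `tone_sd/R0` and
  correlation time `tone_tau` — stochastic airway tone. The literature
  asserts that short-term variability of tone exists without prescribing
  its law; an OU process is the simplest stationary, mean-reverting,
  continuously varying choice, and its stationary quartile spread
  (IQR = 1.349·SD) gives a closed-form recovery target.
* `vol_gain` is the fractional bronchodilation per litre of lung inflation,
  applied to the oscillation-free (tidal + DI) volume.
* `g_DI(t)` ramps from 1 to `1 − di_drop` during the DI, then the
  resistance recovers linearly at `renarrow_slope` (cmH2O·s/L per minute),
  saturating at the pre-DI level. Linear recovery matches the
  linear-regression readout used downstream and is approximately what
  constricted airways show over the first two post-DI minutes.

Why flow-driven: prescribing flow makes the true impedance
Z(f) = R + j(2πf·I − E/(2πf)) analytically known, so every estimator has an
exact oracle. Oscillatory *flow* amplitudes are scaled by 1/|Z(f)| so the
oscillatory *pressure* is ≈ `osc_amp` at each frequency, as delivered by a
pressure-controlled loudspeaker.

Defaults (changeable per run): R0 = 2.5 cmH2O·s/L, E = 35 cmH2O/L
(dynamic elastance at 5 Hz giving X5 ≈ −0.8 cmH2O·s/L and a resonance near
12 Hz, typical of mild asthma — quasi-static elastance would be lower),
I = 0.01 cmH2O·s²/L, VT = 1.1 L, BF = 14/min, 5/11/19 Hz at ~2 cmH2O,
200 Hz sampling, 7-minute recording with the DI at the end of the 5th
minute. The DI depth/duration are not standardized in the source protocol;
the defaults (2 L excursion over 4 s, roughly 90% TLC at the peak) are
configurable and never asserted by tests.

Volume is the cumulative trapezoid of flow (so the stored traces satisfy
the volume/flow consistency invariant to machine precision); the inertance
term uses the analytic flow derivative. The residual O((ω/fs)²) trapezoid
attenuation of the elastance term biases X5 by < 1e-3 cmH2O·s/L at 200 Hz,
well inside every stated tolerance.

## Impedance estimation

Within an analysis window, pressure and flow are each regressed on
{sin, cos} pairs at all stimulation frequencies plus a trend basis, and
Z(f) is the ratio of the complex coefficients. In-regression detrending was
chosen over pre-filtering to avoid phase distortion at 5 Hz. The trend
basis is a cubic Legendre polynomial plus low-frequency harmonics of the
half-window fundamental (capped below half the lowest stimulation
frequency): over a full breath a cubic alone cannot absorb a complete
breathing cycle, while the harmonic set contains the tidal component
exactly, leaving the tones unbiased (the clean-signal recovery error is at
the 1e-10 level). On trend-free windows holding an integer number of cycles
the estimator agrees with the DFT-bin ratio to better than 1e-9 relative —
the independent oracle used in the tests.

Breaths are delimited at upward zero crossings of the flow low-passed at
2 Hz (4th-order Butterworth, zero-phase); crossings closer than 1 s are
merged, and a trailing segment is kept when at least half the median breath
length. Inspiratory-phase estimates use the onset-to-expiration window;
whole-breath estimates the full breath. Windows shorter than two cycles of
5 Hz (0.4 s) are unidentifiable and flagged invalid, as are fits whose
oscillatory flow amplitude falls below 0.01 L/s (SNR guard).

Within-breath reactance series for the artifact criterion use sliding
0.4 s windows with a 0.25 s hop (0.4 s = the minimum identifiable window at
5 Hz) and a quadratic local trend. 11 Hz is stimulated and fitted but not
propagated into the reported metrics, which use 5 and 19 Hz only.

## Breath quality control

Three criteria, all configurable, defaults as printed in the source
methodology: tidal volume outside (0.1, 2.0) L; flow-distortion index
(RMS of the unexplained flow around the fitted sine, over the RMS of the
fitted sine) above 0.2; within-breath minimum-to-mean reactance ratio above
3.5. Bounds are strict, so threshold-exact breaths pass. The reactance
ratio uses whole-breath sub-windows (inspiratory-only is a configuration
switch). The DI breath is a maneuver, not tidal breathing: it keeps its QC
verdict but is excluded from ventilation and variability summaries.
Ventilation is VT = mean tidal volume, BF = 60 / mean breath duration
(so VE = VT·BF holds exactly).

## Derived indices

* **Variability**: interquartile ranges of Gaussian-KDE density estimates
  (Silverman bandwidth; quantiles from the integrated CDF on a 2048-point
  grid) of the pre-DI inspiratory R5, R5−19 and X5 series. A plain sample
  IQR is available as a switch. KDE smoothing widens the IQR by roughly
  √(1 + h²/σ²) (~5% at 70 breaths), far inside the recovery tolerance.
* **DI kinetics**: per-breath (whole-breath mean) R5 and X5 after the DI
  regressed on time from `t0`, the moment the DI ended. `t0` defaults to
  the instant volume first returns to the pre-DI end-expiratory level
  after the DI peak (`volume_return`); `di_end_event` and `full_inflation`
  are alternatives. Each series is truncated at the first breath that
  reaches its pre-DI reference (median of accepted pre-DI breaths; median
  for robustness to outliers), or at 120 s. "Reached" means within one
  pre-DI SD of the reference (or 2% of the observed drop): without a
  tolerance, a recovery saturating exactly at the pre-DI plateau would
  asymptote strictly below the median and censored, partially recovered
  breaths would flatten the fitted slope. Fits use ≥ 2 points (flagged
  unreliable below 3); with fewer, the intercept falls back to the
  first-breath value. Intercepts are evaluated at t = 0 and slopes are per
  minute. In the simulator only resistance responds to the DI, so the
  reactance fit typically terminates at the first breath — its intercept
  then reports that breath's value.
* **Dose–response**: provocative doses (PD15/PD25) by linear interpolation
  of the FEV1 fall against log2(dose), consistent with doubling-dose
  challenge design; unbracketed targets are errors, not extrapolations.
* **Classification**: obstruction bands are open intervals as printed —
  (10, 20)% mild, (20, 30)% moderate; exactly 20% is unclassified, ≤ 10%
  baseline-range, ≥ 30% beyond the studied range.

## Cohort generator and symptom statistics

`simulate_cohort` draws one row per subject per level (baseline / mild
≈15% FEV1 fall / moderate ≈25% fall). Strictly positive indices (flows,
volumes, resistances, IQRs) have lognormal baselines with moments anchored
to published mild-asthma challenge cohorts and respond multiplicatively
(`value = base · fold^(1 + cv·z)`), which keeps them positive without
censoring; signed indices (reactances and their kinetics) respond
additively. Each variable's standardized response `z` combines a
per-subject latent severity factor (default 60% shared variance — induced
changes in different indices are strongly mutually correlated in real
challenge data) with variable-specific variation.

Borg descriptor scores are clipped (0–10) linear functions of the
*standardized measured change* of the configured predictor plus Gaussian
noise, so a planted effect with slope b and noise SD s has population
r² = b²/(b² + s²) exactly; dyspnea is always the sum of the four
descriptors. Scores stay continuous (no half-point rounding) — the less
lossy choice for recovery experiments. Variables named in the effect map
respond idiosyncratically (severity loading zero): a descriptor-specific
mechanism is by construction the component of the mechanics response that
global obstruction severity does not explain. This is what makes planted
associations separable from the shared bronchoconstrictor response.

The association analysis offers each variable's change on an absolute and
a percent basis. The percent basis is only formed when the baseline is
one-signed and bounded away from zero (minimum |baseline| above 10% of the
median |baseline|) — otherwise Δ/baseline is dominated by near-zero
denominators and carries no information. The univariate Pearson screen
retains columns with two-sided p < 0.05 (n ≥ 10 required), keeping only
the smaller-p basis when both pass for one variable. Forward stepwise
selection adds, at each step, the candidate with the smallest per-term
p-value while it is below `alpha_enter` = 0.05 (entry-only; candidates
with |r| > 0.999 to the selected set are skipped as collinear), and the
final OLS refit reports coefficients, r² and the overall F-test p.
Holm–Šidák step-down adjustment (closed form, monotone-enforced) is
provided for families of p-values.

## What the simulator does and does not emulate

It reproduces: tidal breathing with realistic VT/BF, multi-sine
oscillations at target pressure amplitude, stationary stochastic tone,
volume-dependent bronchodilation, DI renarrowing with configurable
kinetics, and cohort-level association structure with planted effect
sizes. It does not reproduce: upper-airway shunt, glottis closure and
expiratory flow limitation (the QC criteria are exercised with constructed
artifacts instead), nonlinear or frequency-dependent tissue mechanics
(R5−19 is zero by construction unless resistance varies), DI-induced
reactance responses, breath-to-breath timing variability, or measurement
noise from real transducers. Passing recovery tests therefore demonstrates
correctness of the estimation chain under the stated model, not field
performance on hardware recordings.

## Problem sizes and numerical choices

Validation studies (also what `scripts/acceptance.py` reruns) use: a 60 s
noise-free recording for impedance recovery; 100 random integer-cycle
windows for the DFT oracle; 20 seeds × two tone levels of 5-minute
recordings for variability recovery; 20 seeds × three renarrowing slopes
(DI at 60 s, ~2 minutes of recovery) for kinetics recovery; and 60 planted
plus 40 null cohorts of 64 subjects for the selection study (the full test
suite runs 200/100). The DI-kinetics study carries a small stochastic tone
(tone_sd = 0.1 cmH2O·s/L) so per-seed estimates vary realistically.

Known limitations: the null-cohort empty-model rate of the screen sits
near 0.95^k for k effective candidate variables — with ~11 candidates at
per-test α = 0.05 it is ~0.55–0.65, an irreducible property of an
unadjusted screen, not an implementation artifact. The xmin reactance
ratio is numerically unstable when mean X ≈ 0 (e.g. near resonance); it is
intended for clearly negative reactance, and undefined ratios mark the
breath unevaluable rather than producing spurious rejections.
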