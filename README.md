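# oscillometry

Within-breath forced-oscillation analysis of respiratory mechanics, for
researchers studying induced bronchoconstriction (e.g. methacholine
challenge) in asthma. The package covers the full analysis chain used in
within-breath FOT studies — and ships a virtual-lung simulator with known
ground truth so every estimator can be validated by parameter recovery.

## What it computes

During the forced oscillation technique, small pressure oscillations
(here 5/11/19 Hz, ~2 cmH2O) are superimposed on tidal breathing and the
respiratory input impedance Z(f) = R(f) + jX(f) is estimated continuously.
Within each breath, pressure and flow are regressed on sin/cos pairs at the
stimulation frequencies plus a low-order trend basis, and

    Z(f) = C_P(f) / C_F(f)

is the ratio of the complex coefficients. From the per-breath estimates the
package derives:

* **R5, X5, R19, R5−19** per breath (inspiratory phase and whole breath);
  R5−19 indexes serial/parallel ventilation heterogeneity.
* **Artifact rejection**: breaths are discarded when tidal volume is
  outside (0.1, 2.0) L, when the flow-distortion index exceeds 0.2, or when
  the within-breath minimum-to-mean reactance ratio exceeds 3.5; ventilation
  (VT, BF, VE) is summarized over accepted breaths.
* **Temporal variability of airway tone**: interquartile ranges of kernel
  density estimates of the pre-deep-inspiration R5, R5−19 and X5 series
  (R5_IQR, R5−19_IQR, X5_IQR).
* **Deep-inspiration renarrowing kinetics**: post-DI R5 and X5 regressed
  on time until the pre-DI level is reached; the intercept at the moment
  the DI ended (R5-int, X5-int) measures the bronchodilator effect of lung
  inflation, the slope (R5-slope, X5-slope, per minute) the velocity of
  airway renarrowing.
* **Dose–response**: PD15/PD25 by log2-linear interpolation of FEV1 fall
  against dose; obstruction-level classification (mild: >10–<20% fall,
  moderate: >20–<30%); the M40m/M40p maximal-to-partial flow ratio.
* **Symptom–mechanics statistics**: per-subject changes at each
  obstruction level screened by Pearson correlation against Borg
  descriptor scores (chest tightness, inspiratory effort, unrewarded
  inspiration, expiratory difficulty, and dyspnea as their sum), followed
  by forward stepwise OLS selection; Holm–Šidák adjustment for p-value
  families.

The simulator (`oscillometry.synthlung`) drives a single-compartment lung
P = R(t)·V' + E·V + I·V'' with prescribed flow, Ornstein–Uhlenbeck airway
tone, volume-dependent bronchodilation and linear post-DI renarrowing, plus
a cohort generator with planted symptom–mechanics associations. See
`docs/methods.md` for the model and every numerical choice.

## Worked example

```python
from oscillometry import MechConfig, simulate_subject_protocol
from oscillometry.pipeline import analyze_subject

cfg = MechConfig(tone_sd=0.2, di_time=300.0, duration=420.0)
sig = simulate_subject_protocol(cfg, seed=42)   # 7 min, DI at 5 min
res, breaths = analyze_subject(sig)

c, v, var, di = res["counts"], res["ventilation"], res["variability"], res["di"]
print(f"breaths: {c['n_breaths']} ({c['n_accepted']} accepted)")
print(f"VT = {v.vt:.2f} L   BF = {v.bf:.1f} /min   VE = {v.ve:.1f} L/min")
print(f"R5_IQR = {var.r5_iqr:.3f}   R5-19_IQR = {var.r5_19_iqr:.3f}   "
      f"X5_IQR = {var.x5_iqr:.3f}  (cmH2O s/L)")
print(f"DI: t0 = {di.t0:.1f} s  R5_int = {di.r5_int:.2f}  "
      f"R5_slope = {di.r5_slope:.2f} /min  (n = {di.n_r})")
```

prints

```
breaths: 98 (97 accepted)
VT = 1.10 L   BF = 14.0 /min   VE = 15.4 L/min
R5_IQR = 0.371   R5-19_IQR = 0.009   X5_IQR = 0.006  (cmH2O s/L)
DI: t0 = 303.8 s  R5_int = 1.63  R5_slope = 1.23 /min  (n = 6)
```

Reading this: 98 breaths were segmented and one (the DI maneuver itself)
excluded; ventilation matches the configured tidal pattern. The tone
fluctuation (SD 0.2 cmH2O·s/L) appears almost entirely in R5_IQR
(≈ 1.349 × 0.2 × the small breath-averaging shrinkage), while R5−19 and X5
barely vary — in this model only resistance fluctuates. After the DI the
resistance restarts at R5-int = 1.63 (the configured 30% drop from
R0 = 2.5, i.e. ≈1.75, within estimation noise) and renarrows at
1.23 cmH2O·s/L/min against a configured 1.0 (six breaths enter the fit).

A command-line interface mirrors the library: `oscillometry simulate`,
`oscillometry analyze`, `oscillometry cohort-stats`, and `oscillometry all`
(YAML config; all stages seeded and byte-reproducible). Signals are plain
CSV (`t,flow,pressure,volume` + JSON events sidecar), per-breath tables are
TSV, results are JSON.

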