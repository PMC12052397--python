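# lpbtflim

Pile-up-corrected TCSPC-FLIM, in silico: a Monte Carlo simulator of
time-correlated single photon counting with threshold-based detection, the
**laser-period blind-time (LPBT)** pile-up correction, a PT3/TTTR event
codec, and fluorescence-lifetime estimators (Poisson-MLE exponential
fitting and the method of moments).

## Why

Fluorescence lifetime imaging (FLIM) by TCSPC is traditionally limited to
detection rates of ~5% of the laser repetition rate: at higher rates the
analog pulses from the detector overlap and several photons yield a single
threshold crossing ("pile-up"), which distorts the measured decay and
biases the fitted lifetime.  The LPBT correction deletes every detected
event arriving within exactly one excitation period `T` of the previous
accepted event.  Because the blind window matches the excitation period,
acquisition re-arms at the same phase relative to the laser, so photons are
removed uniformly over relative time: the decay *shape* is preserved while
the rate is capped at exactly `1/T` (80 Mcps at 80 MHz).  This package
reproduces the correction's validation entirely in software — no hardware,
no external data — for anyone building or evaluating photon-counting
electronics, or studying pile-up and dead-time statistics.

The measured decay is modeled as the exponential `exp(-t/τ)` convolved with
a Gaussian instrument response and wrapped around the period (incomplete
decay at 80 MHz): for `u = (t − shift) mod T`,

    Σ_{m≥0} exp(−(u + mT)/τ) = exp(−u/τ) / (1 − e^(−T/τ)),

fitted by maximizing the Poisson likelihood of the 256-bin counts
(48.8 ps bins).  Biexponential decays are fitted globally (shared τ₁, τ₂,
per-pixel amplitudes) and summarized by τ_I = (β₁τ₁² + β₂τ₂²)/(β₁τ₁ + β₂τ₂)
and τ_A = β₁τ₁ + β₂τ₂.  The fit-free method of moments is
τ_MOM = Σ t·I(t)/Σ I(t) − t₀ with t₀ calibrated at low count rate.

## Worked example

Simulate a 1 ns decay at 80 Mcps incident (one photon per pulse on
average), emulate threshold detection with a realistic 0.7 ns FWHM
hybrid-detector pulse at 3/4-peak threshold, and fit with and without the
correction:

```
$ lpbtflim simulate --lifetime-ns 1.0 --rate-cps 8e7 --photons 100000 \
      --seed 1 --detect --out raw.pt3
wrote 78806 events to raw.pt3
$ lpbtflim lpbt --in raw.pt3 --out corrected.pt3
kept 48962/78806 events (0.621)
$ lpbtflim fit --in corrected.pt3
tau = 1.0171 ns  (shift 0.020 ns, loglik -596.6, N 48962)
$ lpbtflim fit --in raw.pt3
tau = 1.0634 ns  (shift 12.500 ns, loglik -924.5, N 78806)
```

Pile-up merges 21% of the true photons into shared crossings and biases the
uncorrected fit by +6.3%; after the blind-time filter (which keeps 62% of
detections, capping the output near the repetition rate) the fit lands
within 1.7% of the 1 ns ground truth.  The same pipeline is available as a
library:

```python
from lpbtflim import (SimConfig, SPRModel, generate_ground_truth,
                      detect_crossings, lpbt_filter_stream,
                      histogram_decay, IRFHistogram, fit_monoexp_mle)

truth = generate_ground_truth(SimConfig(lifetime=1.0, target_rate=8e7,
                                        max_photons=100_000, seed=1))
detected = detect_crossings(truth, SPRModel.hpd())
kept = lpbt_filter_stream(detected)
hist = histogram_decay(kept.rel_time, 256, truth.laser.period)
irf = IRFHistogram.gaussian(2.0, 0.2, truth.laser.period, 256)
print(fit_monoexp_mle(hist, irf).tau)
```

`lpbtflim experiments fig2c --out results/` runs the full lifetime ×
count-rate error grid and reports the worst-case corrected error;
`experiments fig2b` sweeps the detector pulse width.

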