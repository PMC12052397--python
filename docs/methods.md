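# Methods

## Problem and model

Time-correlated single photon counting (TCSPC) builds a histogram of photon
delays relative to a pulsed excitation laser; the fluorescence lifetime is
estimated from that histogram.  With threshold-based timing electronics the
analog pulses from the detector overlap at high count rates, so several
photons can produce a single threshold crossing ("pile-up"), distorting the
decay.  The laser-period blind time (LPBT) correction discards every
detected event that falls within exactly one excitation period of the
previous *accepted* event.  Because the blind window is an integer number of
periods, acquisition re-enables at the same phase relative to the laser:
removal is uniform over relative time, the decay shape is preserved, and the
sustained output rate is capped at exactly `1 / blind_time` (the repetition
rate for a one-period window).

This package implements the complete in-silico validation of that idea:
a Monte Carlo simulator of the TCSPC collection process, the blind-time
filter, a PT3-format TTTR event codec, and the lifetime estimators used to
quantify accuracy.

## Simulator (`sim_core`)

An ensemble of `n_molecules` (default 1000) emitters is driven by an 80 MHz
laser.  Each molecule emits at most one photon per excitation cycle with
probability `p = target_rate / (rep_rate * n_molecules)`; multi-photon
cycles arise from the ensemble.  Emission cycles are sampled through
geometric inter-emission gaps, so cost scales with the photon yield, not the
cycle count.  Each photon's delay is drawn from the exponentially modified
Gaussian (EMG): `Normal(irf_center, sigma) + Exponential(lifetime)`, with
`sigma = irf_fwhm / 2.3548` and a 200 ps FWHM default.  Draws beyond one
period are re-anchored to later cycles (the physical origin of incomplete
decay); draws before `t = 0` of the first cycle are dropped.  Per-molecule
RNG streams are spawned deterministically from the root seed, so changing
the molecule count does not perturb other molecules' draws, and the whole
stream is bit-reproducible.

Per-point simulated photon counts are held constant across rates (the
acquisition window stretches at low rates), so estimator noise is uniform
over a rate sweep and any residual trend is bias.

### Threshold detection

Every true photon deposits one single-photon response (SPR) pulse on a
common voltage trace; the detected stream is the sequence of upward
crossings of `threshold_fraction * peak_height` (default 3/4).  Detection is
event-driven: the scanner walks only the union of pulse supports, evaluates
the trace on a fine grid (1/16 of the pulse sigma for the Gaussian shape,
1/4 of the rise sigma for tabulated shapes), and refines each bracketed
upward crossing by bisection to sub-femtosecond precision.  A literal
sampled-trace detector (1 ps grid) is retained as a test oracle; the two
agree to < 0.01 ps on randomized streams.

Three pulse-shape families are provided:

* `gaussian` — symmetric Gaussian, FWHM 0.7 ns default.  Used for the
  pulse-width sweep, where the FWHM is the independent variable.
* `hpd` — a fast Gaussian rise (`rise_sigma = 0.1` ns, 10–90% rise
  ≈ 0.26 ns) convolved with an exponential fall whose constant is solved so
  the pulse has the requested FWHM (0.673 ns fall constant at 0.7 ns FWHM).
  This is a synthetic stand-in for the measured single-photon response of a
  hybrid photodetector, whose pulses rise much faster than they fall.  It is
  the default for the validation grid.
* `table` — any measured shape supplied as `(times, values)` arrays.

The pulse shape matters: with a symmetric Gaussian, merged photon bursts
cross threshold early on the slow summed leading edge, producing an early
shoulder on the corrected decay that inflates fitted lifetimes by several
percent at 80 Mcps (and > 10% at tau = 0.25 ns).  With the fast-rise `hpd`
shape the same experiment stays within ~2%.  This is why the pulse-width
sweep reports rapidly growing distortion for wide Gaussians while the
realistic-detector grid meets the 3% specification.

Optional log-normal pulse-height variability (`height_cv`) reproduces the
sub-merging-window inter-photon gaps seen on real detectors; it is off by
default, matching a fixed predetermined SPR.  Detector afterpulsing, dark
counts, TDC quantization jitter, and excitation saturation are not modeled.

## Blind-time filter (`lpbt`)

Non-paralyzable streaming semantics: the first event is kept and each later
event is kept iff it is at least `blind_time` after the last *kept* event.
Non-paralyzable behavior is the only choice that guarantees the
`1 / blind_time` rate ceiling; a paralyzable flag exists for sensitivity
analysis.  The window is anchored at the threshold-crossing time.  Filtering
is idempotent and the output never contains a gap below the blind time
(property-tested).

Photon-loss accounting: for a homogeneous Poisson input the kept fraction is
the classical non-paralyzable dead-time result `1 / (1 + lambda T)`.  TCSPC
photons are *not* homogeneous — they cluster inside the decay window — so a
Monte Carlo mode (filter a simulated stream and count) is authoritative; the
two agree as `lambda T -> 0` and the 80 Mcps Monte Carlo value is pinned as
a regression constant (0.50008 at tau = 1 ns, seed 0, 1e5 photons).

## PT3 event records (`tttr_io`)

Headerless 32-bit little-endian records: channel (4 bits), relative time in
TDC units (12 bits, 3.26 ps default resolution), cycle counter (16 bits)
with channel-15 overflow specials every 65536 cycles.  Scan markers are
channel-15 records with bit 0 = frame, 1 = line start, 2 = line stop,
3 = pixel clock (the marker-bit mapping is this package's convention).
Metadata (resolution, repetition rate, simulation config) travels in a JSON
sidecar; a fixed-length foreign header can be skipped on read.  A marker
coinciding exactly with a photon is encoded first, because markers gate
pixel assignment and ordering must be deterministic.  The codec is
bit-idempotent: `encode(decode(encode(s))) == encode(s)`.

FLIM image assembly bins photons into per-pixel 256-bin decays using the
pixel clock with half-open `[clock, next boundary)` windows (edge photons go
to the later pixel).  Photons before the first frame marker or ahead of a
frame's first pixel clock are tallied as discards, so photons are conserved
exactly.

## Lifetime estimators (`lifetime`)

**Decay model.**  Under periodic excitation the tails of all preceding
pulses sum to a geometric factor: for `u = (t - shift) mod T`,
`sum_m exp(-(u + mT)/tau) = exp(-u/tau) / (1 - exp(-T/tau))`.  For a
Gaussian IRF the per-bin integrals of the wrapped EMG are computed exactly
(via the EMG CDF); for a measured 256-bin IRF histogram the periodic kernel
is circularly convolved with the IRF on an 8x finer grid (cumulative-mass
interpolation) and re-binned.  The exact path is bias-free by construction;
the histogram path carries the irreducible discretization of its input and
recovers lifetimes to ~1% at tau = 0.25 ns, better at longer lifetimes.

**Mono-exponential MLE.**  Poisson likelihood of the 256-bin counts under
`N * [(1 - f) q(tau, shift) + f / n_bins]`, with the total amplitude fixed
at the observed count (its exact MLE when the shape is normalized).  The
optimizer is Nelder-Mead over `(log tau, shift)` (plus a logit background
fraction when enabled) with an explicit initial simplex — a zero shift
start would otherwise make the simplex degenerate along the shift
coordinate.  Derivative-free optimization was chosen over a gradient-based
hybrid because the search space is two- or three-dimensional, the likelihood
is smooth but cheap, and the circular-shift seam makes analytic gradients
error-prone.  Convergence `xatol = 1e-9`; tau bounded to `[1 ps, 3T]`.  The
IRF position is always free, absorbing optical-path and threshold-crossing
offsets.  The background term is flat (period-invariant), i.e. the
incomplete-decay correction is not applied to it.

**Global biexponential fit.**  Shared `(tau1, tau2, shift)` in an outer
Nelder-Mead; per-pixel non-negative component amplitudes solved inside by
multiplicative EM updates (the Richardson-Lucy / KL iteration), which are
monotone in the Poisson likelihood — variable projection.  Because the
likelihood has an equal-lifetimes ridge, the auto-initialized fit starts
from three spreads around the pooled mono-exponential estimate and keeps the
best optimum; convergence to `tau1 ~ tau2` is flagged `effectively_mono`,
not raised.  Amplitudes scale area-normalized shapes, so component photon
counts are proportional to `beta_i * tau_i`; the fractional initial
intensities are recovered as `beta_i ∝ a_i / tau_i` before computing the
intensity- and amplitude-weighted means
`tau_I = (b1 t1^2 + b2 t2^2)/(b1 t1 + b2 t2)` and `tau_A = b1 t1 + b2 t2`.
`tau1 <= tau2` is the canonical ordering.

**Method of moments.**  `tau_MOM = sum(t I(t)) / sum(I(t)) - t0` with
bin-center times.  `t0` is either the IRF center of mass or, because
incomplete decay biases the center of mass at 80 MHz, calibrated as
`raw_MOM - fitted_tau` at a count rate low enough that pile-up is
negligible (1 Mcps in the sweeps), making the calibrated MOM match the fit
at low rate by construction.

**Diagnostics.**  Inter-photon-gap histograms (the low-gap edge reveals the
merging window; zero mass below the blind time after filtering) and the
two-pulse timing error `e = |mean(t2) - mean(t1) - dt|`.

## Validation experiments (`experiments`)

`run_rate_sweep` executes simulate → detect → (optionally) filter →
histogram → estimate over a grid of lifetimes {0.25, 1, 2, 4} ns and rates
{1, 2, 5, 10, 20, 40, 80} Mcps (logarithmic 1→80, chosen to contain the
40 Mcps point used by the short-lifetime analysis).  Rates are the
*incident* target rates handed to the simulator (one photon per pulse on
average at 80 Mcps); the detected pre-correction rate is recorded alongside.
MOM estimates are calibrated per (lifetime, correction, replicate) series
against the fitted lifetime at the lowest rate.  The default pulse is the
`hpd` shape; `run_fwhm_sweep` varies Gaussian pulse widths at tau = 1 ns and
80 Mcps and reports a reduced chi-square distortion of the corrected decay
against the ground-truth shape (aligned by the constant crossing offset),
which sits at the Poisson noise floor for narrow pulses and grows with
width.

Problem sizes: unit tests use 2e3–1e5 photons per stream; the grid tests and
the acceptance script use 1e5 simulated photons per grid point (the
full-scale study uses 1e6; the truncation count is a parameter and the
errors measured are rate-driven biases, insensitive to the photon budget
beyond its Monte Carlo noise of ~0.45% per point).  The acceptance script
averages three replicate estimates per grid point.

## Known limitations

* The `hpd` pulse is a two-parameter idealization of a real measured SPR;
  absolute residual-bias numbers at the harshest corner (0.25 ns at
  80 Mcps) depend on the exact pulse shape at threshold.
* The histogram-IRF model path is limited by the 48.8 ps bin width of its
  input; sub-bin IRF structure is invisible to it.
* No detector afterpulsing, dark counts, dead time distinct from the pulse
  width, TDC bin quantization (3.26 ps available in the codec but not
  injected into simulated times), or laser-trigger jitter.
* The paralyzable filter mode is provided for sensitivity analysis only; no
  accuracy claims are made for it.
* Restricted mean lifetimes and phasor analysis are out of scope.
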