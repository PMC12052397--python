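"""Fluorescence lifetime estimators and photon-stream diagnostics.

Decay model
-----------
Under pulsed excitation with period ``T`` the measured decay is the true
exponential convolved with the instrument response function (IRF), *wrapped*
around the period because fluorescence excited by earlier pulses has not
fully decayed at 80 MHz ("incomplete decay").  Summing the exponential tails
of all preceding cycles gives a closed form: for ``u = (t - shift) mod T``,

    sum_{m>=0} exp(-(u + m T)/tau)  =  exp(-u/tau) / (1 - exp(-T/tau)),

which is then circularly convolved with the binned IRF.  Mono- and
biexponential models are fitted by maximizing the Poisson log-likelihood of
the binned counts; the IRF temporal position is a free parameter to absorb
optical-path and trigger offsets.

The fit-free method of moments (center of mass) estimates the lifetime as
the count-weighted mean delay minus a reference time ``t0``, taken either as
the IRF center of mass or calibrated against a fitted lifetime at low count
rate where pile-up is negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import exponnorm, norm

from .sim_core import FWHM_TO_SIGMA

__all__ = [
    "DecayHistogram",
    "IRFHistogram",
    "MonoFitResult",
    "BiexpFitResult",
    "MOMResult",
    "TimingErrorResult",
    "FitConvergenceError",
    "histogram_decay",
    "periodic_decay_model",
    "fit_monoexp_mle",
    "fit_biexp_global",
    "intensity_weighted_lifetime",
    "amplitude_weighted_lifetime",
    "mom_lifetime",
    "calibrate_mom_t0",
    "interphoton_histogram",
    "timing_error",
]


# ---------------------------------------------------------------------------
# histogram containers
# ---------------------------------------------------------------------------


@dataclass
class DecayHistogram:
    """Binned fluorescence decay I(t) over one excitation period."""

    counts: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bin_width(self) -> float:
        return self.period / self.n_bins

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class IRFHistogram(DecayHistogram):
    """Binned instrument response IRF(t); real-valued counts allowed.

    An IRF built by :meth:`gaussian` additionally remembers its analytic
    (center, fwhm) parameters, letting the decay model evaluate exact bin
    integrals instead of a discrete convolution.
    """

    analytic_center: float | None = None
    analytic_fwhm: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if np.all(self.counts <= 0):
            raise ValueError("IRF must have at least one positive bin")

    @property
    def center_of_mass(self) -> float:
        return float(np.sum(self.bin_centers * self.counts) / np.sum(self.counts))

    @classmethod
    def gaussian(
        cls, center: float, fwhm: float, period: float, n_bins: int = 256
    ) -> "IRFHistogram":
        """Gaussian IRF binned by exact per-bin integrals, wrapped periodically."""
        sigma = max(fwhm / FWHM_TO_SIGMA, 1e-6)
        edges = np.linspace(0.0, period, n_bins + 1)
        counts = np.zeros(n_bins)
        for wrap in (-period, 0.0, period):
            cdf = norm.cdf(edges, loc=center + wrap, scale=sigma)
            counts += np.diff(cdf)
        return cls(counts, period, analytic_center=center, analytic_fwhm=fwhm)


def histogram_decay(
    rel_times: np.ndarray, n_bins: int = 256, period: float = 12.5
) -> DecayHistogram:
    """Histogram photon relative times into ``n_bins`` equal bins over one
    period (half-open bins, so ``sum(counts)`` equals the photon count)."""
    rel_times = np.asarray(rel_times, dtype=np.float64)
    if len(rel_times) and (rel_times.min() < 0.0 or rel_times.max() >= period):
        raise ValueError("relative times must lie in [0, period)")
    idx = np.minimum((rel_times / (period / n_bins)).astype(np.int64), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return DecayHistogram(counts, period)


# ---------------------------------------------------------------------------
# periodic decay model and Poisson MLE fits
# ---------------------------------------------------------------------------


def _periodic_exp_kernel(
    tau: float, period: float, n_bins: int, shift: float
) -> np.ndarray:
    """exp(-u/tau) / (1 - exp(-T/tau)) at bin centers, u = (t - shift) mod T."""
    t = (np.arange(n_bins) + 0.5) * (period / n_bins)
    u = np.mod(t - shift, period)
    return np.exp(-u / tau) / -np.expm1(-period / tau)


def _circular_convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.real(np.fft.ifft(np.fft.fft(a) * np.fft.fft(b)))


def _gaussian_irf_model(
    tau: float,
    center: float,
    fwhm: float,
    period: float,
    n_bins: int,
    shift: float,
) -> np.ndarray:
    """Exact bin integrals of the periodically wrapped EMG.

    The decay excited by pulse ``-m`` contributes the EMG density evaluated
    ``m`` periods later; summing those wraps gives the incomplete-decay model
    without any grid discretization.
    """
    sigma = max(fwhm / FWHM_TO_SIGMA, 1e-6)
    K = tau / sigma
    edges = np.linspace(0.0, period, n_bins + 1)
    loc = center + shift
    n_wrap = int(math.ceil(30.0 * tau / period)) + 2
    q = np.zeros(n_bins)
    for m in range(-1, n_wrap):
        q += np.diff(exponnorm.cdf(edges + m * period, K, loc=loc, scale=sigma))
    return q


def periodic_decay_model(
    tau: float,
    irf: IRFHistogram,
    shift: float = 0.0,
    n_bins: int | None = None,
    oversample: int = 8,
) -> np.ndarray:
    """Normalized model decay shape under periodic excitation.

    The exponential decay is convolved with the IRF and wrapped around the
    excitation period (incomplete decay).  For an IRF carrying analytic
    Gaussian parameters the per-bin integrals are computed exactly; for a
    general measured IRF histogram the periodic exponential kernel
    (geometric tail factor) is circularly convolved with the IRF on an
    ``oversample``-times finer grid and re-binned, which keeps the
    discretization bias on the fitted lifetime well below statistical noise.

    Returns a probability vector over the bins (sums to 1).
    """
    n_bins = n_bins or irf.n_bins
    if n_bins != irf.n_bins:
        raise ValueError("IRF and decay binning must match")
    if irf.analytic_fwhm is not None and irf.analytic_center is not None:
        q = _gaussian_irf_model(
            tau, irf.analytic_center, irf.analytic_fwhm, irf.period, n_bins, shift
        )
    else:
        m = n_bins * oversample
        # refine the binned IRF by linear interpolation of its cumulative mass
        coarse_edges = np.linspace(0.0, irf.period, n_bins + 1)
        cum = np.concatenate([[0.0], np.cumsum(irf.counts, dtype=np.float64)])
        fine_edges = np.linspace(0.0, irf.period, m + 1)
        p_irf = np.diff(np.interp(fine_edges, coarse_edges, cum))
        p_irf /= p_irf.sum()
        kern = _periodic_exp_kernel(tau, irf.period, m, shift)
        q = _circular_convolve(p_irf, kern).reshape(n_bins, oversample).sum(axis=1)
    q = np.maximum(q, 1e-300)
    return q / q.sum()


class FitConvergenceError(RuntimeError):
    """Optimizer exhausted its budget; carries the best-so-far result."""

    def __init__(self, message: str, result=None, diagnostics=None):
        super().__init__(message)
        self.result = result
        self.diagnostics = diagnostics


@dataclass
class MonoFitResult:
    """Maximum-likelihood monoexponential fit."""

    tau: float
    irf_shift: float
    background: float
    loglik: float
    n_photons: float
    converged: bool = True


@dataclass
class BiexpFitResult:
    """Biexponential fit with canonical ordering tau1 <= tau2 and
    beta1 + beta2 = 1; tau_I and tau_A are the intensity- and
    amplitude-weighted mean lifetimes."""

    tau1: float
    tau2: float
    beta1: float
    beta2: float
    tau_I: float
    tau_A: float
    irf_shift: float
    background: float
    loglik: float
    effectively_mono: bool = False


def _poisson_nll(counts: np.ndarray, model: np.ndarray) -> float:
    model = np.maximum(model, 1e-300)
    return float(np.sum(model - counts * np.log(model)))


def poisson_loglik(counts: np.ndarray, model: np.ndarray) -> float:
    """Full Poisson log-likelihood including the factorial normalization."""
    model = np.maximum(model, 1e-300)
    return float(np.sum(counts * np.log(model) - model - gammaln(counts + 1.0)))


def _initial_tau(hist: DecayHistogram, irf: IRFHistogram) -> float:
    guess = (
        np.sum(hist.bin_centers * hist.counts) / hist.total - irf.center_of_mass
    )
    return float(np.clip(guess, 0.05, 0.8 * hist.period))


def fit_monoexp_mle(
    hist: DecayHistogram,
    irf: IRFHistogram,
    *,
    fit_background: bool = False,
    min_photons: int = 1000,
    tau_init: float | None = None,
    shift_init: float = 0.0,
    maxiter: int = 4000,
) -> MonoFitResult:
    """Fit ``counts ~ Poisson(N * [(1-f) q(tau, shift) + f/n_bins])``.

    ``q`` is the normalized periodic-convolution shape; the total amplitude
    is fixed at the observed photon count (its exact Poisson-MLE value when
    the shape is normalized), so the optimizer works on (log tau, shift) and
    optionally a flat background fraction ``f``.
    """
    N = hist.total
    if N < min_photons:
        raise ValueError(
            f"histogram holds {N:.0f} photons; at least {min_photons} required"
        )
    if hist.n_bins != irf.n_bins:
        raise ValueError("decay and IRF must share binning")
    counts = hist.counts.astype(np.float64)
    n_bins = hist.n_bins
    period = hist.period
    tau0 = tau_init if tau_init is not None else _initial_tau(hist, irf)
    tau_lo, tau_hi = 1e-3, 3.0 * period

    def unpack(x):
        tau = float(np.clip(np.exp(x[0]), tau_lo, tau_hi))
        shift = float(x[1])
        f = 1.0 / (1.0 + math.exp(-x[2])) if fit_background else 0.0
        return tau, shift, f

    def nll(x):
        tau, shift, f = unpack(x)
        q = periodic_decay_model(tau, irf, shift, n_bins)
        model = N * ((1.0 - f) * q + f / n_bins)
        return _poisson_nll(counts, model)

    x0 = [math.log(tau0), shift_init] + ([-4.0] if fit_background else [0.0])
    # explicit initial simplex: a zero shift start would otherwise give a
    # nearly degenerate simplex along the shift coordinate
    steps = [0.15, 0.1, 0.5]

    def simplex(x):
        pts = [list(x)]
        for i in range(len(x)):
            p = list(x)
            p[i] += steps[i]
            pts.append(p)
        return np.array(pts)

    if not fit_background:
        # freeze the background coordinate by optimizing only the first two
        def nll2(x2):
            return nll([x2[0], x2[1], 0.0])

        res = minimize(
            nll2,
            [x0[0], x0[1]],
            method="Nelder-Mead",
            options={
                "xatol": 1e-9,
                "fatol": 1e-10,
                "maxiter": maxiter,
                "maxfev": maxiter,
                "initial_simplex": simplex(x0[:2]),
            },
        )
        xfull = [res.x[0], res.x[1], 0.0]
    else:
        res = minimize(
            nll,
            x0,
            method="Nelder-Mead",
            options={
                "xatol": 1e-9,
                "fatol": 1e-10,
                "maxiter": maxiter,
                "maxfev": maxiter,
                "initial_simplex": simplex(x0),
            },
        )
        xfull = list(res.x)

    tau, shift, f = unpack(xfull)
    q = periodic_decay_model(tau, irf, shift, n_bins)
    model = N * ((1.0 - f) * q + f / n_bins)
    result = MonoFitResult(
        tau=tau,
        irf_shift=shift % period,
        background=f * N / n_bins,
        loglik=poisson_loglik(counts, model),
        n_photons=N,
        converged=bool(res.success),
    )
    if not res.success:
        raise FitConvergenceError(
            f"monoexponential fit did not converge in {maxiter} iterations",
            result=result,
            diagnostics={"scipy_message": res.message, "nfev": res.nfev},
        )
    return result


# ---------------------------------------------------------------------------
# biexponential global fit
# ---------------------------------------------------------------------------


def intensity_weighted_lifetime(tau1, tau2, beta1, beta2) -> float:
    """tau_I = (b1 t1^2 + b2 t2^2) / (b1 t1 + b2 t2)."""
    return (beta1 * tau1**2 + beta2 * tau2**2) / (beta1 * tau1 + beta2 * tau2)


def amplitude_weighted_lifetime(tau1, tau2, beta1, beta2) -> float:
    """tau_A = b1 t1 + b2 t2 (with b1 + b2 = 1)."""
    return (beta1 * tau1 + beta2 * tau2) / (beta1 + beta2)


def _fit_amplitudes(counts, q1, q2, n_bins, fit_background,
                    max_iter=5000, tol=1e-12):
    """Per-histogram Poisson MLE over non-negative component amplitudes.

    Multiplicative EM updates (the Richardson-Lucy / KL-NMF iteration
    ``a_k <- a_k * sum_i q_ki c_i / m_i`` for unit-sum component shapes):
    monotone in the likelihood and non-negative by construction.  A flat
    background is just a third component with shape ``1/n_bins``.
    """
    comps = [q1, q2] + ([np.full(n_bins, 1.0 / n_bins)] if fit_background else [])
    Q = np.vstack(comps)
    N = max(counts.sum(), 1.0)
    a = np.full(len(comps), N / len(comps))
    for _ in range(max_iter):
        m = np.maximum(a @ Q, 1e-300)
        a_new = a * (Q @ (counts / m))
        if np.max(np.abs(a_new - a)) <= tol * N:
            a = a_new
            break
        a = a_new
    m = np.maximum(a @ Q, 1e-300)
    return a, _poisson_nll(counts, m)


def fit_biexp_global(
    hists,
    irf: IRFHistogram,
    *,
    fit_background: bool = False,
    tau_init: tuple[float, float] | None = None,
    shift_init: float = 0.0,
    maxiter: int = 2000,
):
    """Global biexponential fit: one (tau1, tau2, shift) shared by all
    histograms, per-histogram amplitudes (variable projection).

    Returns ``(results, (tau1, tau2))`` where ``results`` is one
    :class:`BiexpFitResult` per input histogram.  A single histogram
    degenerates to an ordinary biexponential fit.  Convergence to
    ``tau1 ~ tau2`` is flagged ``effectively_mono`` rather than raised.
    """
    hists = list(hists)
    if not hists:
        raise ValueError("at least one histogram required")
    n_bins = hists[0].n_bins
    period = hists[0].period
    for h in hists:
        if h.n_bins != n_bins or h.period != period:
            raise ValueError("all histograms must share binning")
    counts = [h.counts.astype(np.float64) for h in hists]
    tau_lo, tau_hi = 1e-3, 3.0 * period
    if tau_init is None:
        # bracket the pooled single-exponential estimate; the biexponential
        # likelihood has an equal-lifetimes ridge, so try several spreads
        # around it and keep the best optimum
        pooled = DecayHistogram(np.sum(counts, axis=0), period)
        mono = fit_monoexp_mle(pooled, irf, min_photons=1, shift_init=shift_init)
        m = mono.tau
        starts = [(m / 3.0, 2.5 * m), (m / 8.0, 1.5 * m), (0.7 * m, 5.0 * m)]
        shift_init = mono.irf_shift if mono.irf_shift < period / 2 else mono.irf_shift - period
    else:
        starts = [tuple(tau_init)]

    def shapes(x):
        t1 = float(np.clip(np.exp(x[0]), tau_lo, tau_hi))
        t2 = float(np.clip(np.exp(x[1]), tau_lo, tau_hi))
        shift = float(x[2])
        q1 = periodic_decay_model(t1, irf, shift, n_bins)
        q2 = periodic_decay_model(t2, irf, shift, n_bins)
        return t1, t2, shift, q1, q2

    def nll_total(x):
        _, _, _, q1, q2 = shapes(x)
        total = 0.0
        for c in counts:
            _, fval = _fit_amplitudes(c, q1, q2, n_bins, fit_background)
            total += fval
        return total

    res = None
    for t1_0, t2_0 in starts:
        x0 = np.array([math.log(t1_0), math.log(t2_0), shift_init])
        init_simplex = np.vstack(
            [x0, x0 + [0.2, 0, 0], x0 + [0, 0.2, 0], x0 + [0, 0, 0.1]]
        )
        cand = minimize(
            nll_total,
            x0,
            method="Nelder-Mead",
            options={
                "xatol": 1e-7,
                "fatol": 1e-9,
                "maxiter": maxiter,
                "maxfev": maxiter,
                "initial_simplex": init_simplex,
            },
        )
        if res is None or cand.fun < res.fun:
            res = cand
    t1, t2, shift, q1, q2 = shapes(res.x)
    if t1 > t2:  # canonical ordering resolves label switching
        t1, t2, q1, q2 = t2, t1, q2, q1
    effectively_mono = abs(t2 - t1) < 1e-3 * max(t1, t2)

    results = []
    for c in counts:
        a, _ = _fit_amplitudes(c, q1, q2, n_bins, fit_background)
        a1, a2 = float(a[0]), float(a[1])
        bg = float(a[2]) / n_bins if fit_background else 0.0
        # a_i scale *area-normalized* shapes, so a_i is the component photon
        # count, proportional to beta_i * tau_i; the fractional initial
        # intensities beta_i therefore weight by 1/tau_i
        w1, w2 = a1 / t1, a2 / t2
        b1 = w1 / (w1 + w2) if (w1 + w2) > 0 else 0.5
        b2 = 1.0 - b1
        model = a1 * q1 + a2 * q2 + bg
        results.append(
            BiexpFitResult(
                tau1=t1,
                tau2=t2,
                beta1=b1,
                beta2=b2,
                tau_I=intensity_weighted_lifetime(t1, t2, b1, b2),
                tau_A=amplitude_weighted_lifetime(t1, t2, b1, b2),
                irf_shift=shift % period,
                background=bg,
                loglik=poisson_loglik(c, model),
                effectively_mono=effectively_mono,
            )
        )
    return results, (t1, t2)


# ---------------------------------------------------------------------------
# method of moments
# ---------------------------------------------------------------------------


@dataclass
class MOMResult:
    """Center-of-mass lifetime estimate."""

    tau_mom: float
    t0: float
    mode: str = "irf_com"


def mom_lifetime(hist: DecayHistogram, t0: float, mode: str = "irf_com") -> MOMResult:
    """tau_MOM = sum(t I(t)) / sum(I(t)) - t0, with bin-center times.

    Invariant under rescaling of the counts.  Note the estimate carries a
    real truncation bias at finite period (late tail wrapped into early
    bins), which is exactly why low-rate calibration of ``t0`` exists.
    """
    if hist.total <= 0:
        raise ValueError("cannot compute MOM lifetime of an empty histogram")
    com = float(np.sum(hist.bin_centers * hist.counts) / hist.total)
    return MOMResult(tau_mom=com - t0, t0=t0, mode=mode)


def calibrate_mom_t0(
    mode: str,
    irf: IRFHistogram | None = None,
    low_rate_pair: tuple[float, float] | None = None,
) -> float:
    """Reference time t0 for the method of moments.

    ``irf_com`` returns the IRF center of mass.  ``low_rate_calibration``
    takes ``(fitted_tau, uncalibrated_mom)`` measured at a count rate low
    enough that pile-up is negligible and returns their difference, so the
    calibrated MOM matches the fit at low rate by construction.
    """
    if mode == "irf_com":
        if irf is None:
            raise ValueError("irf_com mode requires an IRF histogram")
        return irf.center_of_mass
    if mode == "low_rate_calibration":
        if low_rate_pair is None:
            raise ValueError("low_rate_calibration mode requires (tau, raw_mom)")
        fitted_tau, raw_mom = low_rate_pair
        return raw_mom - fitted_tau
    raise ValueError(f"unknown t0 mode {mode!r}")


# ---------------------------------------------------------------------------
# stream diagnostics
# ---------------------------------------------------------------------------


def interphoton_histogram(
    times: np.ndarray, bin_width: float = 0.05, max_lag: float = 50.0
):
    """Histogram of gaps between consecutive events, up to ``max_lag`` ns.

    The low-gap edge of this histogram reveals the effective merging window
    of the detection chain (pulse width at threshold), and after blind-time
    filtering it is empty below the blind time.

    Returns ``(counts, edges)``.
    """
    times = np.asarray(times, dtype=np.float64)
    if len(times) > 1 and np.any(np.diff(times) < 0):
        raise ValueError("input times must be sorted ascending")
    gaps = np.diff(times)
    edges = np.arange(0.0, max_lag + bin_width, bin_width)
    counts, _ = np.histogram(gaps[gaps < edges[-1]], bins=edges)
    return counts, edges


@dataclass
class TimingErrorResult:
    """Two-pulse timing accuracy: e = |mean(t2) - mean(t1) - dt|."""

    e: float
    mean_t1: float
    mean_t2: float
    delta_t: float


def timing_error(
    rel_times_1: np.ndarray, rel_times_2: np.ndarray, delta_t: float
) -> TimingErrorResult:
    """Timing error of a two-pulse protocol: the absolute deviation of the
    measured group-mean separation from the known separation ``delta_t``."""
    rel_times_1 = np.asarray(rel_times_1, dtype=np.float64)
    rel_times_2 = np.asarray(rel_times_2, dtype=np.float64)
    if len(rel_times_1) == 0 or len(rel_times_2) == 0:
        raise ValueError("both pulse groups must be non-empty")
    m1 = float(rel_times_1.mean())
    m2 = float(rel_times_2.mean())
    return TimingErrorResult(
        e=abs(m2 - m1 - delta_t), mean_t1=m1, mean_t2=m2, delta_t=delta_t
    )
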