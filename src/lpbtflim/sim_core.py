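"""Monte Carlo simulation of TCSPC photon collection with threshold detection.

The simulator produces ground-truth photon arrival streams for an ensemble of
independently emitting molecules under pulsed excitation, then emulates the
analog detection chain: every photon deposits a single-photon response (SPR)
voltage pulse on a common trace, and a photon is *detected* whenever the trace
crosses a fixed threshold upward.  Overlapping pulses produce a single
crossing, which is the physical origin of pile-up at high count rates.

Units: times in nanoseconds, rates in counts per second, unless noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.optimize import brentq
from scipy.special import erfc

__all__ = [
    "LaserConfig",
    "SimConfig",
    "SPRModel",
    "EventStream",
    "sample_relative_time",
    "generate_ground_truth",
    "detect_crossings",
]

#: FWHM of a Gaussian in units of its standard deviation.
FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: SPR pulse support half-width, in units of sigma (Gaussian shape).
#: Contributions beyond 5 sigma (< 4e-6 of the peak) are below any
#: meaningful threshold.
PULSE_SUPPORT_SIGMA = 5.0

#: Tabulated pulse support cut: the template extends until the pulse has
#: fallen below this fraction of its peak.
PULSE_TAIL_CUT = 1e-5


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LaserConfig:
    """Pulsed excitation laser.

    Parameters
    ----------
    rep_rate : float
        Repetition rate in Hz.  Default 80 MHz, the standard rate of
        Ti:Sapphire lasers used in two-photon microscopy.
    """

    rep_rate: float = 8.0e7

    def __post_init__(self) -> None:
        if self.rep_rate <= 0:
            raise ValueError("rep_rate must be positive")

    @property
    def period(self) -> float:
        """Excitation period in ns (12.5 ns at 80 MHz)."""
        return 1.0e9 / self.rep_rate


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated TCSPC acquisition.

    Parameters
    ----------
    lifetime : float
        Monoexponential fluorescence lifetime tau in ns.
    target_rate : float
        Average emission rate summed over all molecules, counts/s.
    n_molecules : int
        Number of independent emitters; each emits at most one photon per
        excitation cycle, so multi-photon cycles arise from the ensemble.
    irf_fwhm : float
        FWHM of the Gaussian instrument response, ns (default 0.2 ns = 200 ps).
    irf_center : float
        Position of the IRF peak within the excitation period, ns.
    max_photons : int
        Keep only the first ``max_photons`` photons of the merged stream, so
        the analyzed signal-to-noise ratio is independent of count rate.
    duration : float or None
        Simulated wall time in seconds.  ``None`` sizes the window so the
        expected photon yield comfortably exceeds ``max_photons``.
    seed : int
        Root seed; per-molecule generators are spawned deterministically from
        it, so changing ``n_molecules`` does not perturb other molecules.
    """

    lifetime: float
    target_rate: float
    n_molecules: int = 1000
    irf_fwhm: float = 0.2
    irf_center: float = 2.0
    max_photons: int = 1_000_000
    duration: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lifetime <= 0:
            raise ValueError("lifetime must be positive")
        if self.irf_fwhm < 0:
            raise ValueError("irf_fwhm must be non-negative")
        if self.target_rate < 0:
            raise ValueError("target_rate must be non-negative")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be at least 1")

    def emission_probability(self, laser: LaserConfig) -> float:
        """Per-molecule per-cycle Bernoulli emission probability."""
        p = self.target_rate / (laser.rep_rate * self.n_molecules)
        if p > 1.0:
            max_rate = laser.rep_rate * self.n_molecules
            raise ValueError(
                f"target_rate {self.target_rate:g} cps exceeds the maximum "
                f"achievable rate {max_rate:g} cps "
                f"({self.n_molecules} molecules x {laser.rep_rate:g} Hz)"
            )
        return p


def _emg_pulse(u: np.ndarray, sigma: float, tau_fall: float) -> np.ndarray:
    """Gaussian-rise / exponential-fall pulse (EMG density, unnormalized)."""
    arg = sigma**2 / (2.0 * tau_fall**2) - u / tau_fall
    return np.exp(np.clip(arg, -700.0, 700.0)) * erfc(
        (sigma / tau_fall - u / sigma) / math.sqrt(2.0)
    )


def _emg_fwhm(sigma: float, tau_fall: float) -> float:
    u = np.linspace(-6.0 * sigma, 12.0 * tau_fall + 6.0 * sigma, 20001)
    v = _emg_pulse(u, sigma, tau_fall)
    half = v >= 0.5 * v.max()
    idx = np.nonzero(half)[0]
    return float(u[idx[-1]] - u[idx[0]])


@dataclass(frozen=True, eq=False)
class SPRModel:
    """Single-photon response of the detector plus analog front end.

    Detection is an upward crossing of ``threshold_fraction * peak_height``
    on the summed voltage trace.  Three pulse-shape families:

    ``"gaussian"``
        Symmetric Gaussian of the given FWHM (analytic detection path).
    ``"hpd"``
        Fast Gaussian rise (``rise_sigma``) convolved with an exponential
        fall whose time constant is solved so the pulse has the given FWHM —
        a synthetic stand-in for the measured single-photon response of a
        hybrid photodetector, whose pulses rise much faster than they fall.
    ``"table"``
        A measured pulse shape supplied as ``(times, values)`` arrays,
        peak-normalized internally.

    ``height_cv`` adds log-normal pulse-height variability (CV of the height
    distribution), which is what lets occasional photon pairs be resolved
    below the nominal merging window on real detectors.
    """

    fwhm: float = 0.7
    peak_height: float = 1.0
    height_cv: float = 0.0
    threshold_fraction: float = 0.75
    shape: str = "gaussian"
    rise_sigma: float = 0.1
    table: tuple | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian", "hpd", "table"):
            raise ValueError(f"unknown SPR shape {self.shape!r}")
        if self.shape != "table" and self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.shape == "hpd" and self.fwhm <= FWHM_TO_SIGMA * self.rise_sigma:
            raise ValueError("hpd shape needs fwhm > 2.355 * rise_sigma")
        if self.shape == "table" and self.table is None:
            raise ValueError("table shape requires the table argument")
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.height_cv < 0:
            raise ValueError("height_cv must be non-negative")

    @classmethod
    def hpd(
        cls,
        fwhm: float = 0.7,
        rise_sigma: float = 0.1,
        threshold_fraction: float = 0.75,
        **kwargs,
    ) -> "SPRModel":
        """Fast-rise, slow-fall pulse emulating a hybrid photodetector SPR."""
        return cls(
            fwhm=fwhm,
            rise_sigma=rise_sigma,
            threshold_fraction=threshold_fraction,
            shape="hpd",
            **kwargs,
        )

    @property
    def sigma(self) -> float:
        """Gaussian-shape standard deviation (FWHM / 2.3548)."""
        return self.fwhm / FWHM_TO_SIGMA

    @property
    def threshold(self) -> float:
        return self.threshold_fraction * self.peak_height

    def fall_time(self) -> float:
        """Exponential fall constant of the hpd shape, solved from the FWHM."""
        if self.shape != "hpd":
            raise ValueError("fall_time is defined for the hpd shape only")
        lo = 0.05 * self.fwhm
        hi = 3.0 * self.fwhm
        return float(
            brentq(lambda tf: _emg_fwhm(self.rise_sigma, tf) - self.fwhm, lo, hi)
        )

    def template(self, dt: float = 0.001) -> tuple[float, float, np.ndarray]:
        """Uniformly sampled peak-normalized pulse: ``(u_start, dt, values)``.

        ``u`` is time relative to the photon arrival anchor.
        """
        if self.shape == "gaussian":
            s = self.sigma
            u = np.arange(-PULSE_SUPPORT_SIGMA * s, PULSE_SUPPORT_SIGMA * s + dt, dt)
            v = np.exp(-(u**2) / (2.0 * s**2))
        elif self.shape == "hpd":
            s = self.rise_sigma
            tf = self.fall_time()
            u_max = tf * math.log(1.0 / PULSE_TAIL_CUT) + PULSE_SUPPORT_SIGMA * s
            u = np.arange(-PULSE_SUPPORT_SIGMA * s, u_max + dt, dt)
            v = _emg_pulse(u, s, tf)
        else:
            ut, vt = self.table
            ut = np.asarray(ut, dtype=np.float64)
            vt = np.asarray(vt, dtype=np.float64)
            u = np.arange(ut[0], ut[-1] + dt, dt)
            v = np.interp(u, ut, vt)
        v = v / v.max() * self.peak_height
        return float(u[0]), dt, v

    def pulse(self, u: np.ndarray) -> np.ndarray:
        """Pulse voltage at times ``u`` relative to the photon arrival."""
        u = np.asarray(u, dtype=np.float64)
        if self.shape == "gaussian":
            return self.peak_height * np.exp(-(u**2) / (2.0 * self.sigma**2))
        u0, du, vals = self.template()
        out = np.interp(u, u0 + du * np.arange(len(vals)), vals, left=0.0, right=0.0)
        return out

    @property
    def crossing_offset(self) -> float:
        """Time by which an isolated pulse's crossing precedes the photon.

        For the Gaussian shape this is analytic:
        ``sigma * sqrt(2 ln(1/threshold_fraction))``.  Other shapes are
        solved numerically on the rising edge of the template.
        """
        if self.shape == "gaussian":
            return self.sigma * math.sqrt(
                2.0 * math.log(1.0 / self.threshold_fraction)
            )
        u0, du, vals = self.template()
        thr = self.threshold
        i = int(np.argmax(vals >= thr))
        if i == 0:
            return -u0
        # linear interpolation between template samples
        frac = (thr - vals[i - 1]) / (vals[i] - vals[i - 1])
        return -(u0 + du * (i - 1 + frac))

    def width_at_threshold(self) -> float:
        """Duration the isolated pulse spends above threshold (ns)."""
        u0, du, vals = self.template()
        above = np.nonzero(vals >= self.threshold)[0]
        return float(du * (above[-1] - above[0])) if len(above) else 0.0

    def sample_heights(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.height_cv == 0.0:
            return np.full(n, self.peak_height)
        # log-normal with mean peak_height and coefficient of variation cv
        s2 = math.log(1.0 + self.height_cv**2)
        mu = math.log(self.peak_height) - 0.5 * s2
        return rng.lognormal(mean=mu, sigma=math.sqrt(s2), size=n)


# ---------------------------------------------------------------------------
# event stream container
# ---------------------------------------------------------------------------


@dataclass
class EventStream:
    """Time-ordered photon events anchored to laser cycles.

    ``cycle`` is the index of the excitation pulse each photon is referenced
    to (the TTTR "absolute time" anchor) and ``rel_time`` the delay from that
    pulse, with ``0 <= rel_time < period``.
    """

    cycle: np.ndarray
    rel_time: np.ndarray
    laser: LaserConfig = field(default_factory=LaserConfig)
    channel: np.ndarray | None = None
    markers: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cycle = np.asarray(self.cycle, dtype=np.int64)
        self.rel_time = np.asarray(self.rel_time, dtype=np.float64)
        if self.cycle.shape != self.rel_time.shape:
            raise ValueError("cycle and rel_time must have the same length")
        if self.channel is None:
            self.channel = np.ones(len(self.cycle), dtype=np.int16)
        else:
            self.channel = np.asarray(self.channel, dtype=np.int16)

    def __len__(self) -> int:
        return len(self.cycle)

    @property
    def abs_time(self) -> np.ndarray:
        """Absolute arrival times in ns."""
        return self.cycle * self.laser.period + self.rel_time

    def is_sorted(self) -> bool:
        t = self.abs_time
        return bool(np.all(np.diff(t) >= 0))

    @classmethod
    def from_abs_times(
        cls,
        times: np.ndarray,
        laser: LaserConfig,
        channel: np.ndarray | None = None,
        markers: list | None = None,
    ) -> "EventStream":
        """Re-anchor absolute times (ns) to (cycle, rel_time) pairs.

        Times that fall before t = 0 (possible for detection offsets or
        Gaussian IRF tails ahead of cycle 0) are dropped.
        """
        times = np.asarray(times, dtype=np.float64)
        keep = times >= 0.0
        times = times[keep]
        cycle = np.floor(times / laser.period).astype(np.int64)
        rel = times - cycle * laser.period
        # guard against floating roundoff putting rel exactly at the period
        bump = rel >= laser.period
        cycle[bump] += 1
        rel[bump] -= laser.period
        rel[rel < 0.0] = 0.0
        if channel is not None:
            channel = np.asarray(channel)[keep]
        return cls(cycle, rel, laser, channel, markers or [])


# ---------------------------------------------------------------------------
# ground-truth photon generation
# ---------------------------------------------------------------------------


def sample_relative_time(
    lifetime: float,
    irf_fwhm: float,
    irf_center: float,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw photon delays from the exponentially modified Gaussian.

    The delay of an emitted photon relative to its excitation pulse is the
    sum of a Gaussian timing jitter (the IRF, ``sigma = fwhm / 2.3548``
    centered on ``irf_center``) and an exponential decay delay with mean
    ``lifetime``.  Draws are *unwrapped*: values below zero or beyond one
    period belong physically to neighboring cycles and are re-anchored by the
    caller.
    """
    if lifetime <= 0:
        raise ValueError("lifetime must be positive")
    if irf_fwhm < 0:
        raise ValueError("irf_fwhm must be non-negative")
    sigma = irf_fwhm / FWHM_TO_SIGMA
    n = 1 if size is None else size
    draws = rng.normal(irf_center, sigma, size=n) if sigma > 0 else np.full(n, float(irf_center))
    draws = draws + rng.exponential(lifetime, size=n)
    return draws[0] if size is None else draws


def _molecule_emission_cycles(
    p: float, n_cycles: int, rng: np.random.Generator
) -> np.ndarray:
    """Cycle indices at which one molecule emits (Bernoulli(p) per cycle).

    Sampled through geometric inter-emission gaps, so the cost is O(number of
    photons) rather than O(number of cycles).
    """
    if p <= 0.0 or n_cycles <= 0:
        return np.empty(0, dtype=np.int64)
    expected = n_cycles * p
    out = []
    pos = -1  # index of last emission
    while True:
        batch = max(16, int(expected + 5.0 * math.sqrt(expected) + 16))
        gaps = rng.geometric(p, size=batch)
        cycles = pos + np.cumsum(gaps)
        if cycles[-1] >= n_cycles - 1:
            out.append(cycles[cycles < n_cycles])
            break
        out.append(cycles)
        pos = int(cycles[-1])
        expected = (n_cycles - 1 - pos) * p
    return np.concatenate(out).astype(np.int64)


def generate_ground_truth(cfg: SimConfig, laser: LaserConfig | None = None) -> EventStream:
    """Simulate the true photon arrival stream of the molecular ensemble.

    Each of ``cfg.n_molecules`` molecules emits at most one photon per
    excitation cycle with probability ``p = target_rate / (rep_rate *
    n_molecules)``; each photon's delay is an EMG draw (exponential decay
    convolved with the Gaussian IRF).  All per-molecule traces are merged,
    time-sorted, and truncated to the first ``max_photons`` events.
    Bit-reproducible for a given seed and configuration.
    """
    laser = laser or LaserConfig()
    p = cfg.emission_probability(laser)
    if cfg.target_rate == 0.0:
        return EventStream(np.empty(0, np.int64), np.empty(0), laser)

    if cfg.duration is not None:
        duration = cfg.duration
    else:
        # enough cycles that the expected yield exceeds max_photons by >5 sd
        n_exp = float(cfg.max_photons)
        duration = (n_exp + 6.0 * math.sqrt(n_exp) + 100.0) / cfg.target_rate
    n_cycles = int(round(duration * laser.rep_rate))

    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_molecules)
    all_abs = []
    for m in range(cfg.n_molecules):
        rng = np.random.default_rng(children[m])
        cycles = _molecule_emission_cycles(p, n_cycles, rng)
        if len(cycles) == 0:
            continue
        rel = sample_relative_time(
            cfg.lifetime, cfg.irf_fwhm, cfg.irf_center, rng, size=len(cycles)
        )
        all_abs.append(cycles * laser.period + rel)

    if not all_abs:
        return EventStream(np.empty(0, np.int64), np.empty(0), laser)
    times = np.concatenate(all_abs)
    times.sort(kind="stable")
    if cfg.max_photons is not None and len(times) > cfg.max_photons:
        times = times[: cfg.max_photons]
    return EventStream.from_abs_times(times, laser)


# ---------------------------------------------------------------------------
# threshold-crossing detection (the pile-up mechanism)
# ---------------------------------------------------------------------------


@njit(cache=False)
def _trace_value(t, h, inv_two_s2, support, x):
    """Voltage trace at time x: sum of Gaussian pulses within +-support."""
    lo = np.searchsorted(t, x - support)
    hi = np.searchsorted(t, x + support)
    v = 0.0
    for k in range(lo, hi):
        d = x - t[k]
        v += h[k] * math.exp(-d * d * inv_two_s2)
    return v


@njit(cache=False)
def _scan_crossings(t, h, sigma, thr, step, out):
    """Event-driven scan for upward threshold crossings (Gaussian pulses).

    Walks the union of pulse supports (clusters of pulses whose supports
    overlap), evaluating the trace on a fine grid and refining each bracketed
    upward crossing by bisection.  Returns the number of crossings written
    to ``out``.
    """
    n = t.shape[0]
    if n == 0:
        return 0
    support = PULSE_SUPPORT_SIGMA * sigma
    inv_two_s2 = 1.0 / (2.0 * sigma * sigma)
    m = 0
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] - t[j] <= 2.0 * support:
            j += 1
        x0 = t[i] - support
        x1 = t[j] + support
        npts = int((x1 - x0) / step) + 2
        prev = _trace_value(t, h, inv_two_s2, support, x0)
        above = prev >= thr
        for k in range(1, npts):
            x = x0 + k * step
            v = _trace_value(t, h, inv_two_s2, support, x)
            if (not above) and v >= thr:
                lo = x - step
                hi = x
                for _ in range(48):
                    mid = 0.5 * (lo + hi)
                    if _trace_value(t, h, inv_two_s2, support, mid) >= thr:
                        hi = mid
                    else:
                        lo = mid
                out[m] = 0.5 * (lo + hi)
                m += 1
                above = True
            elif above and v < thr:
                above = False
        i = j + 1
    return m


@njit(cache=False)
def _trace_value_tab(t, h, u_min, u_max, du, vals, x):
    """Voltage trace at time x for a tabulated pulse (linear interpolation)."""
    lo = np.searchsorted(t, x - u_max)
    hi = np.searchsorted(t, x - u_min)
    v = 0.0
    n_tab = vals.shape[0]
    for k in range(lo, hi):
        idx = (x - t[k] - u_min) / du
        i0 = int(idx)
        if 0 <= i0 < n_tab - 1:
            fr = idx - i0
            v += h[k] * (vals[i0] * (1.0 - fr) + vals[i0 + 1] * fr)
    return v


@njit(cache=False)
def _scan_crossings_tab(t, h, u_min, u_max, du, vals, thr, step, out):
    """Event-driven upward-crossing scan for a tabulated pulse shape."""
    n = t.shape[0]
    if n == 0:
        return 0
    span = u_max - u_min
    m = 0
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] - t[j] <= span:
            j += 1
        x0 = t[i] + u_min
        x1 = t[j] + u_max
        npts = int((x1 - x0) / step) + 2
        prev = _trace_value_tab(t, h, u_min, u_max, du, vals, x0)
        above = prev >= thr
        for k in range(1, npts):
            x = x0 + k * step
            v = _trace_value_tab(t, h, u_min, u_max, du, vals, x)
            if (not above) and v >= thr:
                lo = x - step
                hi = x
                for _ in range(48):
                    mid = 0.5 * (lo + hi)
                    if _trace_value_tab(t, h, u_min, u_max, du, vals, mid) >= thr:
                        hi = mid
                    else:
                        lo = mid
                out[m] = 0.5 * (lo + hi)
                m += 1
                above = True
            elif above and v < thr:
                above = False
        i = j + 1
    return m


def _detect_crossings_sampled(
    times: np.ndarray,
    heights: np.ndarray,
    spr: SPRModel,
    dt: float = 0.001,
) -> np.ndarray:
    """Sampled-trace reference detector (default 1 ps grid).

    Builds the literal voltage trace on a uniform grid and finds upward
    threshold crossings by linear interpolation.  Memory- and time-hungry;
    intended as an oracle for short streams, not for production use.
    """
    if len(times) == 0:
        return np.empty(0)
    u0, du, vals = spr.template(dt=min(dt, 0.001))
    u1 = u0 + du * (len(vals) - 1)
    tmpl_u = u0 + du * np.arange(len(vals))
    grid = np.arange(times.min() + u0, times.max() + u1 + dt, dt)
    v = np.zeros_like(grid)
    for ti, hi in zip(times, heights):
        lo = np.searchsorted(grid, ti + u0)
        hi_i = np.searchsorted(grid, ti + u1)
        v[lo:hi_i] += hi / spr.peak_height * np.interp(
            grid[lo:hi_i] - ti, tmpl_u, vals, left=0.0, right=0.0
        )
    thr = spr.threshold
    up = np.nonzero((v[:-1] < thr) & (v[1:] >= thr))[0]
    frac = (thr - v[up]) / (v[up + 1] - v[up])
    return grid[up] + frac * dt


def detect_crossings(
    truth: EventStream,
    spr: SPRModel,
    laser: LaserConfig | None = None,
    rng: np.random.Generator | None = None,
    method: str = "event",
    sample_dt: float = 0.001,
) -> EventStream:
    """Emulate threshold-based photon tagging on the analog voltage trace.

    Every true photon adds one SPR pulse to the trace; the detected stream is
    the sequence of upward crossings of the detection threshold.  An isolated
    photon is detected at its true time minus ``spr.crossing_offset``;
    overlapping pulses that keep the trace above threshold merge into a
    single detection (pile-up).

    ``method="event"`` is the production event-driven scan (analytic for the
    Gaussian shape, fine-tabulated otherwise); ``method="sampled"`` is the
    brute-force sampled-trace reference.
    """
    laser = laser or truth.laser or LaserConfig()
    if not truth.is_sorted():
        raise ValueError("input stream must be sorted by absolute time")
    times = truth.abs_time
    if len(times) == 0:
        return EventStream(np.empty(0, np.int64), np.empty(0), laser)
    if spr.height_cv > 0.0 and rng is None:
        rng = np.random.default_rng(0)
    heights = spr.sample_heights(len(times), rng) if spr.height_cv > 0 else np.full(
        len(times), spr.peak_height
    )
    if method == "event":
        out = np.empty(len(times), dtype=np.float64)
        if spr.shape == "gaussian":
            m = _scan_crossings(
                times, heights, spr.sigma, spr.threshold, spr.sigma / 16.0, out
            )
        else:
            u0, du, vals = spr.template()
            u1 = u0 + du * (len(vals) - 1)
            # scan step: a quarter of the rising-edge width resolves every
            # excursion above/below threshold the pulse shape can produce
            rise = spr.rise_sigma if spr.shape == "hpd" else spr.width_at_threshold() / 4
            step = max(du, rise / 4.0)
            m = _scan_crossings_tab(
                times, heights, u0, u1, du, vals, spr.threshold, step, out
            )
        crossings = out[:m]
    elif method == "sampled":
        crossings = _detect_crossings_sampled(times, heights, spr, dt=sample_dt)
    else:
        raise ValueError(f"unknown detection method {method!r}")
    return EventStream.from_abs_times(crossings, laser, markers=list(truth.markers))


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Copy of ``cfg`` with a different root seed."""
    return replace(cfg, seed=seed)
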