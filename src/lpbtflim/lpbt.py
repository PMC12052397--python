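"""Laser-period blind-time (LPBT) pile-up correction.

After every accepted photon detection an artificial blind window of exactly
one excitation period is imposed, and any detection inside the window is
discarded.  Because the blind window is an integer number of periods, the
acquisition re-enables at the same phase relative to the laser, so photons
are removed *uniformly over relative time*: the measured decay shape is
preserved while the count rate is reduced.  The window is anchored on
accepted detections only (non-paralyzable semantics), which caps the output
rate at exactly ``1 / blind_time`` — the repetition rate when the blind time
equals one period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .sim_core import EventStream, LaserConfig, SimConfig, generate_ground_truth

__all__ = ["LPBTConfig", "lpbt_filter", "lpbt_filter_stream", "lpbt_keep_fraction"]


@dataclass(frozen=True)
class LPBTConfig:
    """Blind-time filter parameters.

    ``blind_time`` in ns; defaults to one period of an 80 MHz laser.  With
    ``paralyzable=True`` discarded detections also restart the window — a
    sensitivity-analysis mode, not the correction itself.
    """

    blind_time: float = 12.5
    paralyzable: bool = False

    def __post_init__(self) -> None:
        if self.blind_time <= 0:
            raise ValueError("blind_time must be positive")

    @classmethod
    def for_laser(cls, laser: LaserConfig, paralyzable: bool = False) -> "LPBTConfig":
        return cls(blind_time=laser.period, paralyzable=paralyzable)


@njit(cache=False)
def _filter_nonparalyzable(times, blind, keep):
    n_kept = 0
    last = -np.inf
    for i in range(times.shape[0]):
        if times[i] - last >= blind:
            keep[i] = True
            last = times[i]
            n_kept += 1
    return n_kept


@njit(cache=False)
def _filter_paralyzable(times, blind, keep):
    n_kept = 0
    last_arrival = -np.inf
    for i in range(times.shape[0]):
        if times[i] - last_arrival >= blind:
            keep[i] = True
            n_kept += 1
        last_arrival = times[i]
    return n_kept


def lpbt_mask(times: np.ndarray, cfg: LPBTConfig | None = None) -> np.ndarray:
    """Boolean mask of events kept by the blind-time filter.

    ``times`` must be sorted ascending (never silently re-sorted).  The first
    event is always kept; each later event is kept iff its separation from
    the last *kept* event is at least ``blind_time`` (non-paralyzable), in a
    single streaming pass.
    """
    cfg = cfg or LPBTConfig()
    times = np.ascontiguousarray(times, dtype=np.float64)
    if len(times) > 1 and np.any(np.diff(times) < 0):
        raise ValueError("input times must be sorted ascending")
    keep = np.zeros(len(times), dtype=np.bool_)
    if cfg.paralyzable:
        _filter_paralyzable(times, cfg.blind_time, keep)
    else:
        _filter_nonparalyzable(times, cfg.blind_time, keep)
    return keep


def lpbt_filter(times: np.ndarray, cfg: LPBTConfig | None = None) -> np.ndarray:
    """Apply the blind-time filter to sorted absolute times; returns the kept
    subsequence."""
    times = np.asarray(times, dtype=np.float64)
    return times[lpbt_mask(times, cfg)]


def lpbt_filter_stream(stream: EventStream, cfg: LPBTConfig | None = None) -> EventStream:
    """Blind-time filter on an event stream, preserving (cycle, rel_time)."""
    cfg = cfg or LPBTConfig.for_laser(stream.laser)
    keep = lpbt_mask(stream.abs_time, cfg)
    return EventStream(
        stream.cycle[keep],
        stream.rel_time[keep],
        stream.laser,
        stream.channel[keep],
        list(stream.markers),
    )


def lpbt_keep_fraction(
    incident_rate: float,
    blind_time: float = 12.5,
    mode: str = "poisson_approx",
    *,
    lifetime: float = 1.0,
    n_photons: int = 100_000,
    seed: int = 0,
    laser: LaserConfig | None = None,
) -> float:
    """Fraction of incident photons surviving the blind-time filter.

    ``poisson_approx`` is the classical non-paralyzable dead-time result for
    a homogeneous Poisson input, ``1 / (1 + lambda * T)``.  ``monte_carlo``
    filters a simulated TCSPC stream instead; simulated photons cluster
    inside the decay window rather than arriving homogeneously, so the two
    modes agree only as ``lambda * T -> 0`` and the Monte Carlo estimate is
    authoritative.
    """
    if incident_rate < 0:
        raise ValueError("incident_rate must be non-negative")
    if mode == "poisson_approx":
        lam_T = incident_rate * blind_time * 1e-9
        return 1.0 / (1.0 + lam_T)
    if mode == "monte_carlo":
        if incident_rate == 0.0:
            return 1.0
        laser = laser or LaserConfig()
        cfg = SimConfig(
            lifetime=lifetime,
            target_rate=incident_rate,
            max_photons=n_photons,
            seed=seed,
        )
        truth = generate_ground_truth(cfg, laser)
        if len(truth) == 0:
            return 1.0
        kept = lpbt_mask(truth.abs_time, LPBTConfig(blind_time=blind_time))
        return float(kept.sum()) / len(truth)
    raise ValueError(f"unknown mode {mode!r}")
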