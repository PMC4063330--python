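"""Stochastic spike-train simulation and first-crossing interval decoding.

A trial starts at a stimulus (t = 0 by convention of the rate function) and
the simulator draws a non-homogeneous Poisson spike train whose rate follows
a monotone (log-power) curve.  The decoder convolves the train with a boxcar
window of width tau, yielding the running spike count R(t), and reports the
interval estimate t_est as the first time R(t) reaches the threshold R0 —
from above for a decreasing rate, from below for an increasing one.

Spikes are generated as independent per-step Poisson draws with mean
r(t_mid) * dt, which is exact for the inhomogeneous Poisson process at any
rate magnitude (unlike thinning, there is no proposal bound to pick).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError, InsufficientDataError, ParameterError
from .rates import Direction, RateFunction, TabulatedRate, _as_direction

__all__ = [
    "SimConfig",
    "SpikeTrain",
    "Threshold",
    "TrialEnsemble",
    "simulate_spike_train",
    "windowed_counts",
    "first_crossing",
    "expected_counts",
    "run_ensemble",
    "ensemble_stats",
    "default_sim_config",
]

logger = logging.getLogger(__name__)

CENSORED = math.nan  # sentinel for trials that never cross threshold


@dataclass(frozen=True)
class SimConfig:
    """Trial-simulation settings.

    dt is the simulation step (s); the boxcar window tau must contain at
    least ten steps so the windowed count is a smooth function of time.
    """

    t_start: float
    t_end: float
    dt: float = 0.001
    tau: float = 0.1
    seed: int = 0
    n_trials: int = 200

    def __post_init__(self) -> None:
        if not (self.t_start > 0 and self.t_end > self.t_start):
            raise ParameterError("need 0 < t_start < t_end")
        if not self.dt > 0 or self.dt > self.tau / 10.0 + 1e-15:
            raise ParameterError("dt must satisfy 0 < dt <= tau/10")
        if self.tau > self.t_end - self.t_start:
            raise ParameterError("window tau exceeds the trial span")
        if self.n_trials < 1:
            raise ParameterError("n_trials must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round((self.t_end - self.t_start) / self.dt))

    @property
    def step_mids(self) -> np.ndarray:
        return self.t_start + (np.arange(self.n_steps) + 0.5) * self.dt


@dataclass(frozen=True)
class SpikeTrain:
    """One trial's spikes, stored as per-step counts on the SimConfig grid."""

    counts: np.ndarray  # int counts per dt step
    t_start: float
    dt: float

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def spike_times(self) -> np.ndarray:
        """Spike times, each placed at its step midpoint (resolution dt)."""
        mids = self.t_start + (np.arange(self.counts.size) + 0.5) * self.dt
        return np.repeat(mids, self.counts)


@dataclass(frozen=True)
class Threshold:
    """Spike-count threshold R0 with the crossing sense of the rate curve."""

    R0: float
    direction: Direction

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", _as_direction(self.direction))
        if self.R0 < 0:
            raise ParameterError(f"R0 must be >= 0, got {self.R0}")


@dataclass
class TrialEnsemble:
    """Per-trial interval estimates for one target time."""

    t_tar: float
    estimates: np.ndarray  # uncensored t_est values, s
    n_censored: int = 0

    @property
    def n_trials(self) -> int:
        return self.estimates.size + self.n_censored

    @property
    def censored_fraction(self) -> float:
        return self.n_censored / self.n_trials if self.n_trials else 0.0


def default_sim_config(
    rf: RateFunction,
    t_tar: float,
    *,
    dt: float = 0.001,
    seed: int = 0,
    n_trials: int = 200,
    span_factor: float = 2.0,
) -> SimConfig:
    """Trial span bracketing a target for the given rate function.

    The decreasing branch diverges as t -> 0+, so trials start at the later
    of t_tar/span_factor and the rate function's practical floor t_min, and
    end at span_factor * t_tar (capped inside the domain so the full first
    and last windows fit).
    """
    tau = rf.tau
    if rf.direction is Direction.DECREASING:
        t_start = max(t_tar / span_factor, rf.t_min(t_tar)) - tau / 2.0
        t_start = max(t_start, tau / 2.0 * 0.1)
        t_end = min(span_factor * t_tar + tau / 2.0, rf.t0 * (1 - 1e-9))
    else:
        t_start = max(rf.t0 * (1 + 1e-9), t_tar / span_factor - tau / 2.0)
        t_end = span_factor * t_tar + tau / 2.0
    return SimConfig(
        t_start=t_start, t_end=t_end, dt=dt, tau=tau, seed=seed, n_trials=n_trials
    )


def simulate_spike_train(rf, cfg: SimConfig, rng: np.random.Generator) -> SpikeTrain:
    """Draw one inhomogeneous-Poisson trial from the rate curve.

    Per-step counts are Poisson with mean r(t_mid) * dt, independent across
    steps; ``rf`` may be a RateFunction or TabulatedRate (anything callable
    on an array of times that raises DomainError outside its validity).
    """
    mids = cfg.step_mids
    lam = np.asarray(rf(mids), dtype=float) * cfg.dt  # DomainError if outside
    counts = rng.poisson(lam)
    return SpikeTrain(counts=counts, t_start=cfg.t_start, dt=cfg.dt)


def expected_counts(rf, cfg: SimConfig) -> SpikeTrain:
    """Noiseless counterpart of :func:`simulate_spike_train`.

    Returns the per-step expected counts r(t_mid) * dt (real-valued), used
    to check that the decoder is unbiased in the deterministic limit.
    """
    lam = np.asarray(rf(cfg.step_mids), dtype=float) * cfg.dt
    return SpikeTrain(counts=lam, t_start=cfg.t_start, dt=cfg.dt)


def windowed_counts(spikes: SpikeTrain, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Boxcar spike count: at time t, spikes within [t - tau/2, t + tau/2].

    Counts are emitted only where the full window fits inside the trial, so
    the first centre is t_start + tau/2 and the last t_end - tau/2 (partial
    windows would masquerade as early threshold crossings for a decreasing
    rate).  Returns (centres, counts) with the centres spaced dt apart.
    """
    w = int(round(cfg.tau / cfg.dt))
    m = spikes.counts.size
    if w > m:
        raise ParameterError("window tau larger than the simulated span")
    csum = np.concatenate(([0], np.cumsum(spikes.counts)))
    counts = csum[w:] - csum[:-w]  # sliding sums over w consecutive steps
    centres = spikes.t_start + (np.arange(m - w + 1) + w / 2.0) * spikes.dt
    return centres, counts


def first_crossing(
    times: np.ndarray, counts: np.ndarray, thr: Threshold
) -> float:
    """First time the windowed count reaches threshold; NaN if censored.

    Decreasing sense: earliest t with count <= R0 (the falling count dips to
    threshold).  Increasing: earliest t with count >= R0.  A count exactly
    equal to R0 counts as a crossing; non-integer (learned) thresholds are
    compared directly, without rounding.
    """
    if counts.size == 0:
        raise ParameterError("empty count series")
    if thr.direction is Direction.DECREASING:
        hit = counts <= thr.R0
    else:
        hit = counts >= thr.R0
    idx = int(np.argmax(hit))
    if not hit[idx]:
        return CENSORED
    return float(times[idx])


def run_ensemble(
    rf,
    thr: Threshold,
    cfg: SimConfig,
    t_tar: float,
    censor_warn_fraction: float = 0.01,
) -> TrialEnsemble:
    """Simulate -> window -> decode for cfg.n_trials independent trials.

    Trial i uses its own Generator seeded with cfg.seed + i, so ensembles
    are bit-reproducible and individual trials can be replayed in
    isolation.  Censored trials (no crossing before t_end) are counted but
    excluded from the estimate list; a censored fraction above
    ``censor_warn_fraction`` is logged as a warning.
    """
    emit_lo, emit_hi = cfg.t_start + cfg.tau / 2.0, cfg.t_end - cfg.tau / 2.0
    if not (emit_lo <= t_tar <= emit_hi):
        raise ParameterError(
            f"t_tar={t_tar} outside the emitted-count range [{emit_lo}, {emit_hi}]"
        )
    estimates = []
    n_censored = 0
    for i in range(cfg.n_trials):
        rng = np.random.default_rng(cfg.seed + i)
        train = simulate_spike_train(rf, cfg, rng)
        t, c = windowed_counts(train, cfg)
        t_est = first_crossing(t, c, thr)
        if math.isnan(t_est):
            n_censored += 1
        else:
            estimates.append(t_est)
    ens = TrialEnsemble(
        t_tar=t_tar, estimates=np.asarray(estimates, dtype=float), n_censored=n_censored
    )
    if ens.censored_fraction > censor_warn_fraction:
        logger.warning(
            "censored fraction %.3f exceeds %.3f at t_tar=%.3g (R0=%.3g)",
            ens.censored_fraction, censor_warn_fraction, t_tar, thr.R0,
        )
    return ens


def ensemble_stats(ens: TrialEnsemble) -> tuple[float, float, int]:
    """(mean t_est, sample std with ddof=1, n_censored) over uncensored trials."""
    if ens.estimates.size < 2:
        raise InsufficientDataError(
            f"need >= 2 uncensored estimates, have {ens.estimates.size}"
        )
    return (
        float(np.mean(ens.estimates)),
        float(np.std(ens.estimates, ddof=1)),
        ens.n_censored,
    )
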