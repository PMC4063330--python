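"""Error-driven learning of an unbiased decision threshold.

Setting the threshold directly from the rate curve, R0 = tau * r(t_tar),
systematically shortens the decoded intervals: the windowed count is noisy
and, sampled repeatedly on its way down (or up), it first touches the
threshold before its mean does.  The bias is removed by treating R0 as a
learned quantity, nudged after every trial by the signed timing error:

    R0  <-  R0 + s * eta_eff * (t_est - t_tar)

with s = +1 for a decreasing rate (estimates too short -> lower R0 ->
later crossings) and s = -1 for an increasing one.  The raw error is in
seconds while R0 is a count, so the update is scaled by the local slope of
the mean count at the target, eta_eff = eta * |tau * r'(t_tar)|; eta is
then a dimensionless per-trial contraction rate and a single default works
across targets.  The rule's fixed point is exactly the threshold whose mean
decoded estimate equals the target.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DivergenceError, ParameterError
from .rates import Direction, RateFunction
from .simulate import (
    SimConfig,
    Threshold,
    TrialEnsemble,
    ensemble_stats,
    expected_counts,
    first_crossing,
    run_ensemble,
    simulate_spike_train,
    windowed_counts,
)

__all__ = [
    "LearningConfig",
    "LearningTrace",
    "learn_threshold",
    "evaluate_threshold",
    "noiseless_crossing_time",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LearningConfig:
    """Settings for the iterative threshold update.

    eta is dimensionless (fraction of the slope-predicted count correction
    applied per trial); small values average over more trials at the cost
    of slower convergence.  Convergence is declared when the trailing
    ``window`` of per-iteration estimates has mean relative bias <= tol.
    """

    eta: float = 0.01
    n_iterations: int = 1000
    batch: int = 1
    tol: float = 0.01
    window: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.eta > 0:
            raise ParameterError("eta must be > 0")
        if self.n_iterations < 1 or self.batch < 1 or self.window < 1:
            raise ParameterError("n_iterations, batch and window must be >= 1")
        if not self.tol > 0:
            raise ParameterError("tol must be > 0")


@dataclass
class LearningTrace:
    """Per-iteration record of the threshold trajectory."""

    t_tar: float
    R0_path: np.ndarray  # threshold before each update
    t_est_path: np.ndarray  # batch-mean estimate per iteration (NaN if censored)
    R0_final: float  # trailing-window average of the threshold
    converged: bool

    @property
    def n_iterations(self) -> int:
        return self.R0_path.size


def noiseless_crossing_time(rf, thr: Threshold, cfg: SimConfig) -> float:
    """Crossing time of the expected (deterministic) windowed count."""
    train = expected_counts(rf, cfg)
    t, c = windowed_counts(train, cfg)
    return first_crossing(t, c, thr)


def _count_slope(rf, t_tar: float, tau: float) -> float:
    """|d(tau r)/dt| at the target: converts seconds of error into counts."""
    if hasattr(rf, "derivative"):
        g = abs(float(np.asarray(rf.derivative(t_tar)))) * tau
    else:  # pragma: no cover - all shipped rate types have derivatives
        h = 1e-4 * t_tar
        g = abs(float(rf(t_tar + h)) - float(rf(t_tar - h))) / (2 * h) * tau
    if not g > 0:
        raise ParameterError("count slope vanishes at the target time")
    return g


def learn_threshold(
    rf,
    t_tar: float,
    cfg_sim: SimConfig,
    cfg_learn: LearningConfig | None = None,
    noiseless: bool = False,
) -> LearningTrace:
    """Iterate the threshold update until estimates are unbiased at t_tar.

    Starts from the unlearned R0 = tau * r(t_tar).  Each iteration runs
    ``batch`` fresh trials at the current threshold (sub-seeded from
    cfg_learn.seed so the whole trace is reproducible), measures the mean
    estimate, and applies the slope-scaled error update.  With
    ``noiseless=True`` trials are replaced by the expected-count trajectory,
    which makes the fixed point exact and the approach monotone.

    Raises DivergenceError if R0 leaves [0, max expected windowed count].
    """
    cfg_learn = cfg_learn or LearningConfig()
    direction = getattr(rf, "direction", Direction.DECREASING)
    sign = 1.0 if direction is Direction.DECREASING else -1.0
    tau = cfg_sim.tau
    R0 = tau * float(rf(t_tar))
    gain = cfg_learn.eta * _count_slope(rf, t_tar, tau)

    exp_train = expected_counts(rf, cfg_sim)
    _, exp_c = windowed_counts(exp_train, cfg_sim)
    R0_cap = float(exp_c.max()) + 10.0 * math.sqrt(float(exp_c.max()) + 1.0)

    R0_path = np.empty(cfg_learn.n_iterations)
    t_est_path = np.full(cfg_learn.n_iterations, np.nan)
    converged = False
    n_done = cfg_learn.n_iterations
    for k in range(cfg_learn.n_iterations):
        R0_path[k] = R0
        thr = Threshold(R0=max(R0, 0.0), direction=direction)
        if noiseless:
            t_est = noiseless_crossing_time(rf, thr, cfg_sim)
        else:
            ests = []
            for b in range(cfg_learn.batch):
                rng = np.random.default_rng(
                    cfg_learn.seed + k * cfg_learn.batch + b
                )
                train = simulate_spike_train(rf, cfg_sim, rng)
                t, c = windowed_counts(train, cfg_sim)
                te = first_crossing(t, c, thr)
                if not math.isnan(te):
                    ests.append(te)
            t_est = float(np.mean(ests)) if ests else math.nan
        t_est_path[k] = t_est
        if not math.isnan(t_est):
            R0 = R0 + sign * gain * (t_est - t_tar)
        else:
            # censored batch: no crossing means estimates run long; push the
            # threshold toward earlier crossings by a full-span error
            R0 = R0 + sign * gain * (cfg_sim.t_end - t_tar)
        if R0 < 0.0 or R0 > R0_cap:
            raise DivergenceError(
                f"threshold left [0, {R0_cap:.3g}] at iteration {k} (R0={R0:.3g})"
            )
        w = cfg_learn.window
        if k + 1 >= w:
            recent = t_est_path[k + 1 - w : k + 1]
            recent = recent[~np.isnan(recent)]
            if recent.size >= max(2, w // 2):
                rel_bias = abs(float(np.mean(recent)) - t_tar) / t_tar
                if rel_bias <= cfg_learn.tol:
                    converged = True
                    if noiseless:  # deterministic: no need to keep iterating
                        n_done = k + 1
                        break
    w = min(cfg_learn.window, n_done)
    R0_final = float(np.mean(R0_path[n_done - w : n_done]))
    if not converged:
        logger.warning(
            "threshold learning did not meet tol=%.3g at t_tar=%.3g",
            cfg_learn.tol, t_tar,
        )
    return LearningTrace(
        t_tar=t_tar,
        R0_path=R0_path[:n_done],
        t_est_path=t_est_path[:n_done],
        R0_final=R0_final,
        converged=converged,
    )


def evaluate_threshold(
    rf,
    R0: float,
    t_tar: float,
    cfg_sim: SimConfig,
    noiseless: bool = False,
) -> tuple[float, float, float]:
    """Out-of-sample bias check: (bias, relative bias, std of t_est).

    Runs a fresh evaluation ensemble at the given threshold with a seed
    offset from the simulation seed, so learning trials and evaluation
    trials never share a random stream.
    """
    direction = getattr(rf, "direction", Direction.DECREASING)
    thr = Threshold(R0=R0, direction=direction)
    if noiseless:
        t_est = noiseless_crossing_time(rf, thr, cfg_sim)
        bias = t_est - t_tar
        return bias, bias / t_tar, 0.0
    eval_cfg = replace(cfg_sim, seed=cfg_sim.seed + 7_654_321)
    ens = run_ensemble(rf, thr, eval_cfg, t_tar)
    mean, std, _ = ensemble_stats(ens)
    bias = mean - t_tar
    return bias, bias / t_tar, std
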