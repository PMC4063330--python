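"""End-to-end in-silico timing experiments and their summary statistics.

Two canonical experiments ship with the package, both for the decreasing
log-power scenario (Poisson counts, beta = 1, rho = 1/2, tau = 0.1 s,
t0 = 10 s, 200 trials per target by default):

* the *unlearned-threshold* experiment — for each target time, simulate
  trial ensembles with R0 = tau * r(t_tar), compute discrete-approximation
  moments alongside, fit the scalar law (std of the estimate vs. its mean),
  and test distribution collapse with pairwise KS statistics on
  mean-rescaled estimates;
* the *learned-threshold* experiment — the same pipeline after the
  error-driven threshold update removes the estimation bias.

Both write tidy CSV tables plus a JSON manifest (parameters, seed,
versions) so every figure is regenerable from its output directory.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import math
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ParameterError
from .discrete import (
    bin_profile,
    coarse_grained_simulate,
    distribution_moments,
    first_crossing_distribution,
)
from .learning import LearningConfig, evaluate_threshold, learn_threshold
from .rates import Direction, NoiseModel, RateFunction, ScalarLaw, derive_rate_function
from .simulate import (
    SimConfig,
    Threshold,
    TrialEnsemble,
    default_sim_config,
    ensemble_stats,
    run_ensemble,
)

__all__ = [
    "ExperimentSpec",
    "ScalarFit",
    "CollapseReport",
    "ExperimentResult",
    "fit_scalar_law",
    "collapse_test",
    "run_figure2_experiment",
    "run_figure3_experiment",
    "recover_noise_model",
    "discrete_moments_for_target",
]

logger = logging.getLogger(__name__)

# seed spacing between targets: far larger than any per-trial stream length
_TARGET_SEED_STRIDE = 1_000_000


@dataclass(frozen=True)
class ExperimentSpec:
    """Full parameterisation of a timing experiment.

    Defaults reproduce the canonical decreasing scenario: Poisson-like
    counts (beta = 1, rho = 1/2), Weber fraction alpha = 0.05 (within the
    behaviourally observed range), t0 = 10 s, tau = 0.1 s, six log-spaced
    targets between 0.5 and 6 s, 200 trials per target.
    """

    alpha: float = 0.05
    beta: float = 1.0
    rho: float = 0.5
    tau: float = 0.1
    t0: float = 10.0
    direction: Direction = Direction.DECREASING
    targets: tuple[float, ...] = tuple(np.geomspace(0.5, 6.0, 6).round(6))
    n_trials: int = 200
    dt: float = 0.001
    seed: int = 0
    learning: bool = False
    learning_config: LearningConfig | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction(self.direction))
        if len(self.targets) < 1:
            raise ParameterError("need at least one target time")
        if self.n_trials < 1:
            raise ParameterError("n_trials must be >= 1")
        rf = self.rate_function()  # validates alpha/beta/rho/tau/t0
        lo, hi = rf.domain
        for t in self.targets:
            if not (lo < t < hi):
                raise ParameterError(f"target {t} outside rate domain ({lo}, {hi})")

    def rate_function(self) -> RateFunction:
        return derive_rate_function(
            NoiseModel(self.beta, self.rho),
            ScalarLaw.linear(self.alpha),
            tau=self.tau,
            t0=self.t0,
            direction=self.direction,
        )

    def sim_config(self, t_tar: float, k: int) -> SimConfig:
        return default_sim_config(
            self.rate_function(),
            t_tar,
            dt=self.dt,
            seed=self.seed + (k + 1) * _TARGET_SEED_STRIDE,
            n_trials=self.n_trials,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["direction"] = self.direction.value
        d["targets"] = list(self.targets)
        if self.learning_config is not None:
            d["learning_config"] = dataclasses.asdict(self.learning_config)
        return d


@dataclass(frozen=True)
class ScalarFit:
    """OLS fit of estimate std on estimate mean: sigma_T = slope * <t> + b.

    A slope close to the configured Weber fraction with R^2 near 1 is the
    signature of scalar timing.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass
class CollapseReport:
    """Pairwise KS comparison of mean-rescaled estimate distributions."""

    pairs: pd.DataFrame  # columns: t_tar_a, t_tar_b, ks_stat, p_value
    level: float

    @property
    def fraction_nonsignificant(self) -> float:
        return float((self.pairs["p_value"] > self.level).mean())


@dataclass
class ExperimentResult:
    """Bundle returned by the experiment runners."""

    spec: ExperimentSpec
    per_target: pd.DataFrame
    trials: pd.DataFrame
    scalar_fit_sim: ScalarFit
    scalar_fit_discrete: ScalarFit
    collapse: CollapseReport | None
    thresholds: pd.DataFrame | None = None

    def write(self, outdir: str | Path) -> Path:
        """Write manifest + CSV tables; returns the output directory."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "spec": self.spec.to_dict(),
            "package": "scalartime",
            "versions": {
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "scalar_fit_sim": dataclasses.asdict(self.scalar_fit_sim),
            "scalar_fit_discrete": dataclasses.asdict(self.scalar_fit_discrete),
        }
        if self.collapse is not None:
            manifest["collapse_fraction_nonsignificant"] = (
                self.collapse.fraction_nonsignificant
            )
            manifest["collapse_level"] = self.collapse.level
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        self.per_target.to_csv(out / "per_target.csv", index=False)
        self.trials.to_csv(out / "trials.csv", index=False)
        if self.collapse is not None:
            self.collapse.pairs.to_csv(out / "collapse.csv", index=False)
        if self.thresholds is not None:
            self.thresholds.to_csv(out / "thresholds.csv", index=False)
        return out


def fit_scalar_law(points) -> ScalarFit:
    """Least-squares line through (mean t_est, std t_est) pairs.

    ``points`` is an iterable of (mean, std).  Two points always fit
    perfectly (logged as uninformative); identical means are degenerate.
    """
    arr = np.asarray(list(points), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise InsufficientDataError("need at least two (mean, std) points")
    means, stds = arr[:, 0], arr[:, 1]
    if np.ptp(means) == 0:
        raise ParameterError("degenerate input: identical means")
    if arr.shape[0] == 2:
        logger.info("scalar fit with two points is uninformative (R^2 = 1 always)")
    res = stats.linregress(means, stds)
    return ScalarFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=arr.shape[0],
    )


def collapse_test(ensembles: list[TrialEnsemble], level: float = 0.01) -> CollapseReport:
    """All-pairs two-sample KS tests on estimates rescaled by their own mean.

    Under exact scalar timing the rescaled distributions t_est / <t_est>
    coincide across targets, so the tests should be non-significant.  Raw
    p-values are reported without multiplicity correction, plus the
    fraction of non-significant pairs at ``level``.
    """
    if len(ensembles) < 2:
        raise InsufficientDataError("need at least two ensembles")
    for e in ensembles:
        if e.estimates.size < 20:
            raise InsufficientDataError(
                f"ensemble at t_tar={e.t_tar} has {e.estimates.size} < 20 trials"
            )
    rows = []
    for a, b in itertools.combinations(ensembles, 2):
        xa = a.estimates / a.estimates.mean()
        xb = b.estimates / b.estimates.mean()
        ks = stats.ks_2samp(xa, xb)
        rows.append(
            {
                "t_tar_a": a.t_tar,
                "t_tar_b": b.t_tar,
                "ks_stat": float(ks.statistic),
                "p_value": float(ks.pvalue),
            }
        )
    return CollapseReport(pairs=pd.DataFrame(rows), level=level)


def discrete_moments_for_target(
    rf: RateFunction, R0: float, convention: str = "midpoint"
) -> tuple[float, float, float]:
    """Discrete-approximation (mean, std, residual) for one threshold.

    Uses every bin whose midpoint fits inside the rate domain; for the
    decreasing branch the rate reaches zero at t0, so the crossing
    probability approaches one and the residual is negligible by
    construction.
    """
    if rf.direction is Direction.DECREASING:
        j_max = int(math.floor(rf.t0 / rf.tau + 0.5 - 1e-9))
    else:
        raise ParameterError("discrete moments helper covers the decreasing branch")
    prof = bin_profile(rf, j_max)
    dist = first_crossing_distribution(prof, R0)
    return distribution_moments(dist, convention=convention)


def _targets_table(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)


def run_figure2_experiment(spec: ExperimentSpec) -> ExperimentResult:
    """Unlearned-threshold experiment: bias, scaling, and collapse.

    For each target, an ensemble of fine-grained trials is decoded with
    R0 = tau * r(t_tar) and the discrete approximation is evaluated at the
    same threshold; the result carries mean-vs-target and std-vs-mean
    tables from both pipelines, the scalar fits, and the KS collapse
    report.
    """
    rf = spec.rate_function()
    rows, trial_rows, ensembles = [], [], []
    for k, t_tar in enumerate(spec.targets):
        cfg = spec.sim_config(t_tar, k)
        R0 = spec.tau * float(rf(t_tar))
        thr = Threshold(R0=R0, direction=spec.direction)
        ens = run_ensemble(rf, thr, cfg, t_tar)
        mean, std, n_cens = ensemble_stats(ens)
        d_mean, d_std, resid = discrete_moments_for_target(rf, R0)
        rows.append(
            {
                "t_tar": t_tar,
                "R0": R0,
                "mean_test": mean,
                "std_test": std,
                "n": ens.estimates.size,
                "n_censored": n_cens,
                "discrete_mean": d_mean,
                "discrete_std": d_std,
                "discrete_residual": resid,
            }
        )
        for i, te in enumerate(ens.estimates):
            trial_rows.append(
                {"t_tar": t_tar, "trial": i, "t_est": te, "censored": False}
            )
        ensembles.append(ens)
    per_target = _targets_table(rows)
    fit_sim = fit_scalar_law(per_target[["mean_test", "std_test"]].to_numpy())
    fit_disc = fit_scalar_law(per_target[["discrete_mean", "discrete_std"]].to_numpy())
    collapse = collapse_test(ensembles) if len(ensembles) >= 2 else None
    return ExperimentResult(
        spec=spec,
        per_target=per_target,
        trials=pd.DataFrame(trial_rows),
        scalar_fit_sim=fit_sim,
        scalar_fit_discrete=fit_disc,
        collapse=collapse,
    )


def run_figure3_experiment(spec: ExperimentSpec) -> ExperimentResult:
    """Learned-threshold experiment: per-target learning then fresh evaluation.

    Each target's threshold starts at the unlearned tau * r(t_tar), is
    adapted by the error-driven rule, and is evaluated out-of-sample on an
    independent ensemble; the bundle includes the learned thresholds and
    the post-learning scalar fit.
    """
    rf = spec.rate_function()
    cfg_learn_base = spec.learning_config or LearningConfig()
    rows, trial_rows, thr_rows, ensembles = [], [], [], []
    for k, t_tar in enumerate(spec.targets):
        cfg = spec.sim_config(t_tar, k)
        cfg_learn = replace(
            cfg_learn_base, seed=cfg_learn_base.seed + spec.seed + (k + 1) * 31_000_000
        )
        trace = learn_threshold(rf, t_tar, cfg, cfg_learn)
        R0_unlearned = spec.tau * float(rf(t_tar))
        thr = Threshold(R0=trace.R0_final, direction=spec.direction)
        ens = run_ensemble(rf, thr, replace(cfg, seed=cfg.seed + 500_000), t_tar)
        mean, std, n_cens = ensemble_stats(ens)
        d_mean, d_std, resid = discrete_moments_for_target(rf, trace.R0_final)
        rows.append(
            {
                "t_tar": t_tar,
                "R0": trace.R0_final,
                "mean_test": mean,
                "std_test": std,
                "n": ens.estimates.size,
                "n_censored": n_cens,
                "discrete_mean": d_mean,
                "discrete_std": d_std,
                "discrete_residual": resid,
            }
        )
        thr_rows.append(
            {
                "t_tar": t_tar,
                "R0_unlearned": R0_unlearned,
                "R0_learned": trace.R0_final,
                "converged": trace.converged,
                "iterations": trace.n_iterations,
            }
        )
        for i, te in enumerate(ens.estimates):
            trial_rows.append(
                {"t_tar": t_tar, "trial": i, "t_est": te, "censored": False}
            )
        ensembles.append(ens)
    per_target = _targets_table(rows)
    fit_sim = fit_scalar_law(per_target[["mean_test", "std_test"]].to_numpy())
    fit_disc = fit_scalar_law(per_target[["discrete_mean", "discrete_std"]].to_numpy())
    collapse = collapse_test(ensembles) if len(ensembles) >= 2 else None
    return ExperimentResult(
        spec=spec,
        per_target=per_target,
        trials=pd.DataFrame(trial_rows),
        scalar_fit_sim=fit_sim,
        scalar_fit_discrete=fit_disc,
        collapse=collapse,
        thresholds=pd.DataFrame(thr_rows),
    )


def recover_noise_model(
    mean_counts=None,
    n_draws: int = 5000,
    seed: int = 0,
    tau: float = 0.1,
    dt: float = 0.001,
) -> tuple[float, float, pd.DataFrame]:
    """Fit the power-law noise model to simulated windowed spike counts.

    At each mean count level (default: 20 levels log-spaced between 2 and
    200) a constant-rate spike train is generated with the simulator's
    step model — independent Poisson draws of mean r*dt per step — and the
    spikes in one window of width tau are counted, ``n_draws`` times.
    Regressing log sample std on log sample mean across levels recovers the
    noise law sigma_R = beta * R**rho: the slope estimates rho and
    exp(intercept) estimates beta.  For Poisson counts the truth is
    rho = 1/2, beta = 1.

    Returns (beta_hat, rho_hat, table of per-level mean/std).
    """
    if mean_counts is None:
        mean_counts = np.geomspace(2.0, 200.0, 20)
    mean_counts = np.asarray(mean_counts, dtype=float)
    rng = np.random.default_rng(seed)
    w = int(round(tau / dt))
    rows = []
    for mu in mean_counts:
        lam_step = mu / w  # rate * dt for a flat rate of mu / tau
        draws = rng.poisson(lam_step, size=(n_draws, w)).sum(axis=1)
        rows.append(
            {
                "mean_level": mu,
                "sample_mean": float(draws.mean()),
                "sample_std": float(draws.std(ddof=1)),
            }
        )
    tab = pd.DataFrame(rows)
    res = stats.linregress(np.log(tab["sample_mean"]), np.log(tab["sample_std"]))
    rho_hat = float(res.slope)
    beta_hat = float(math.exp(res.intercept))
    return beta_hat, rho_hat, tab
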