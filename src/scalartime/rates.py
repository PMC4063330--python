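"""Firing-rate functions consistent with scalar timing.

The scalar timing law states that the standard deviation of interval
estimates grows linearly with the interval: sigma_t(t) = alpha * t, with
alpha the Weber fraction.  If intervals are decoded from the threshold
crossing of a monotone firing-rate process r(t), a linear error-propagation
argument links the timing error to the spike-count noise sigma_R and the
local slope of the mean windowed count R(t) ~ tau * r(t):

    sigma_t(t) = sigma_R(t) / |tau * r'(t)|

Assuming power-law count noise sigma_R = beta * (tau * r)**rho, the rate
function that yields exactly linear scaling solves

    dr/dt = +/- (beta * tau**(rho-1) / alpha) * r**rho / t

whose closed-form solution is the log-power curve

    r(t) = K * (+/- log(t / t0))**n,
    n = 1 / (1 - rho),       K = (1/tau) * (beta * (1 - rho) / alpha)**n.

The increasing branch is valid for t >= t0, the decreasing branch for
0 < t <= t0, and r(t0) = 0 in both.  rho = 0 gives the logarithmic
(Fechner) form, rho = 1/2 with beta = 1 the Poisson case with n = 2, and
rho = 1 degenerates to a pure power law handled separately.

This module holds the parameter containers, the closed-form derivation,
rate/window-count evaluation, residual checks of the governing ODE, and a
general numerical solver for non-power-law noise or non-linear scaling.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.interpolate import PchipInterpolator

from .errors import (
    DegenerateNoiseError,
    DomainError,
    IntegrationError,
    ParameterError,
)

__all__ = [
    "Direction",
    "NoiseModel",
    "ScalarLaw",
    "RateFunction",
    "TabulatedRate",
    "derive_rate_function",
    "derive_proportional_rate",
    "solve_rate_numeric",
    "ode_residual",
    "ode_residual_tabulated",
]


class Direction(str, enum.Enum):
    """Sense in which the rate function is monotone."""

    INCREASING = "increasing"
    DECREASING = "decreasing"

    @property
    def sign(self) -> int:
        return 1 if self is Direction.INCREASING else -1


def _as_direction(direction: "Direction | str") -> Direction:
    return Direction(direction) if not isinstance(direction, Direction) else direction


@dataclass(frozen=True)
class NoiseModel:
    """Power-law spike-count noise sigma_R = beta * R**rho.

    Parameters
    ----------
    beta : float
        Noise multiplier (dimensionless); beta = 1 with rho = 1/2 is the
        Poisson case.
    rho : float
        Noise exponent in [0, 1].  rho = 0 is count-independent (constant)
        noise; rho = 1 is proportional noise, a degenerate case for which
        the log-power formula does not apply.
    """

    beta: float
    rho: float

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ParameterError(f"beta must be > 0, got {self.beta}")
        if not 0.0 <= self.rho <= 1.0:
            raise ParameterError(f"rho must lie in [0, 1], got {self.rho}")

    @property
    def is_proportional(self) -> bool:
        """True for the degenerate rho = 1 case."""
        return self.rho == 1.0

    def sigma_R(self, mean_count):
        """Count standard deviation at the given mean windowed count."""
        return self.beta * np.asarray(mean_count, dtype=float) ** self.rho


@dataclass(frozen=True)
class ScalarLaw:
    """Timing-error law sigma_t(t), linear by default.

    The linear form sigma_t = alpha * t is the scalar (Weber-like) law;
    a tabulated form supports empirically non-linear scaling, interpolated
    monotonically (PCHIP) between the given (time, sigma) pairs.
    """

    alpha: float | None = None
    times: tuple[float, ...] | None = None
    sigmas: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.alpha is not None:
            if not self.alpha > 0:
                raise ParameterError(f"alpha must be > 0, got {self.alpha}")
            if self.times is not None or self.sigmas is not None:
                raise ParameterError("give either alpha or a table, not both")
        else:
            if self.times is None or self.sigmas is None:
                raise ParameterError("tabulated law needs both times and sigmas")
            t = np.asarray(self.times, float)
            s = np.asarray(self.sigmas, float)
            if t.size != s.size or t.size < 2:
                raise ParameterError("tabulated law needs >= 2 matching pairs")
            if not np.all(np.diff(t) > 0):
                raise ParameterError("tabulated times must be strictly increasing")
            if not np.all(s > 0):
                raise ParameterError("tabulated sigma_t values must be positive")
            object.__setattr__(self, "times", tuple(float(x) for x in t))
            object.__setattr__(self, "sigmas", tuple(float(x) for x in s))

    @property
    def form(self) -> str:
        return "linear" if self.alpha is not None else "tabulated"

    def sigma_t(self, t):
        """Timing-error standard deviation at time(s) t."""
        t = np.asarray(t, dtype=float)
        if self.alpha is not None:
            return self.alpha * t
        interp = PchipInterpolator(np.asarray(self.times), np.asarray(self.sigmas))
        return interp(t)

    @classmethod
    def linear(cls, alpha: float) -> "ScalarLaw":
        return cls(alpha=alpha)

    @classmethod
    def tabulated(cls, times: Sequence[float], sigmas: Sequence[float]) -> "ScalarLaw":
        return cls(times=tuple(times), sigmas=tuple(sigmas))


@dataclass(frozen=True)
class RateFunction:
    """Closed-form log-power rate r(t) = K * (+/- log(t/t0))**n.

    Parameters
    ----------
    K : float
        Rate amplitude, spikes/s.
    n : float
        Log-power exponent (n = 2 for Poisson-like noise).
    t0 : float
        Integration constant, s: the shortest (increasing) or longest
        (decreasing) time representable; r(t0) = 0.
    direction : Direction
        Increasing (valid t >= t0) or decreasing (valid 0 < t <= t0).
    tau : float
        Spike-count window width, s, carried along because K absorbs 1/tau.
    """

    K: float
    n: float
    t0: float
    direction: Direction
    tau: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", _as_direction(self.direction))
        for name in ("K", "n", "t0", "tau"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")

    # -- domain ------------------------------------------------------------

    @property
    def domain(self) -> tuple[float, float]:
        """(t_lo, t_hi) validity interval; one end is t0, the other open."""
        if self.direction is Direction.INCREASING:
            return (self.t0, math.inf)
        return (0.0, self.t0)

    def _check_domain(self, t: np.ndarray) -> None:
        if self.direction is Direction.INCREASING:
            bad = t < self.t0
        else:
            bad = (t <= 0) | (t > self.t0)
        if np.any(bad):
            raise DomainError(
                f"t={np.atleast_1d(t)[np.atleast_1d(bad)][:3]} outside the "
                f"{self.direction.value} domain (t0={self.t0})"
            )

    def t_min(self, t_tar: float, r_max_factor: float = 10.0) -> float:
        """Practical lower time bound for decreasing-branch simulations.

        The decreasing branch blows up as t -> 0+; trials must start
        somewhere.  Returns the time at which the mean windowed count
        equals r_max_factor * tau * r(t_tar), i.e.
        t0 * exp(-(R_max / (K tau))**(1/n)).
        """
        if self.direction is Direction.INCREASING:
            return self.t0
        r_max = r_max_factor * self.tau * self(t_tar)
        return self.t0 * math.exp(-((r_max / (self.K * self.tau)) ** (1.0 / self.n)))

    # -- evaluation ---------------------------------------------------------

    def __call__(self, t):
        """Firing rate in spikes/s; exactly 0 at t = t0."""
        t_arr = np.asarray(t, dtype=float)
        self._check_domain(t_arr)
        logterm = self.direction.sign * np.log(t_arr / self.t0)
        out = self.K * np.where(logterm > 0, logterm, 0.0) ** self.n
        return out if out.ndim else float(out)

    rate = __call__

    def derivative(self, t):
        """Analytic dr/dt (spikes/s^2), differentiating the closed form."""
        t_arr = np.asarray(t, dtype=float)
        self._check_domain(t_arr)
        logterm = self.direction.sign * np.log(t_arr / self.t0)
        out = (
            self.direction.sign
            * self.K
            * self.n
            * np.where(logterm > 0, logterm, 0.0) ** (self.n - 1.0)
            / t_arr
        )
        return out if out.ndim else float(out)

    def mean_window_count(self, t, mode: str = "approx"):
        """Expected spike count in the boxcar window [t - tau/2, t + tau/2].

        mode='approx' returns tau * r(t) (first order in tau); mode='exact'
        integrates r over the window by adaptive quadrature and requires the
        whole window inside the validity region.
        """
        if mode == "approx":
            return self.tau * np.asarray(self(t))[()] if np.ndim(t) else self.tau * self(t)
        if mode != "exact":
            raise ParameterError(f"mode must be 'approx' or 'exact', got {mode!r}")

        def one(tc: float) -> float:
            lo, hi = tc - self.tau / 2.0, tc + self.tau / 2.0
            self._check_domain(np.asarray([lo, hi]))
            val, _ = quad(lambda x: self(x), lo, hi, limit=200)
            return val

        if np.ndim(t):
            return np.array([one(float(tc)) for tc in np.asarray(t, float)])
        return one(float(t))


@dataclass(frozen=True)
class TabulatedRate:
    """A rate function given on a grid, e.g. from the numerical ODE solver.

    Evaluation between grid points uses monotone (PCHIP) interpolation, so
    a monotone table stays monotone.
    """

    times: tuple[float, ...]
    rates: tuple[float, ...]
    direction: Direction

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", _as_direction(self.direction))
        t = np.asarray(self.times, float)
        r = np.asarray(self.rates, float)
        if t.size != r.size or t.size < 2:
            raise ParameterError("times and rates must match and have length >= 2")
        if not np.all(np.diff(t) > 0):
            raise ParameterError("times must be strictly increasing")
        if np.any(r < 0):
            raise ParameterError("rates must be non-negative")
        d = np.diff(r)
        tol = 1e-9 * max(1.0, float(np.max(np.abs(r))))
        ok = np.all(d >= -tol) if self.direction is Direction.INCREASING else np.all(d <= tol)
        if not ok:
            raise ParameterError(f"rates not monotone {self.direction.value}")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "rates", tuple(float(x) for x in r))

    @property
    def domain(self) -> tuple[float, float]:
        return (self.times[0], self.times[-1])

    def _interp(self) -> PchipInterpolator:
        return PchipInterpolator(np.asarray(self.times), np.asarray(self.rates))

    def __call__(self, t):
        t_arr = np.asarray(t, dtype=float)
        lo, hi = self.domain
        if np.any((t_arr < lo - 1e-12) | (t_arr > hi + 1e-12)):
            raise DomainError(f"t outside tabulated range [{lo}, {hi}]")
        out = np.clip(self._interp()(t_arr), 0.0, None)
        return out if out.ndim else float(out)

    rate = __call__

    def derivative(self, t):
        return self._interp().derivative()(np.asarray(t, dtype=float))

    def to_frame(self):
        """Two-column table (time_s, rate_hz) for CSV round-tripping."""
        import pandas as pd

        return pd.DataFrame({"time_s": self.times, "rate_hz": self.rates})

    @classmethod
    def from_frame(cls, df, direction: "Direction | str") -> "TabulatedRate":
        return cls(tuple(df["time_s"]), tuple(df["rate_hz"]), direction)


# ---------------------------------------------------------------------------
# derivations


def derive_rate_function(
    noise: NoiseModel,
    law: ScalarLaw,
    tau: float,
    t0: float,
    direction: "Direction | str" = Direction.DECREASING,
) -> RateFunction:
    """Derive the log-power rate function from noise and scaling parameters.

    Returns r(t) = K (+/- log(t/t0))**n with n = 1/(1 - rho) and
    K = (1/tau) * (beta (1 - rho) / alpha)**n — the unique rate curve for
    which threshold-crossing estimates have sigma_t = alpha * t under the
    power-law noise model (to linear order).

    Raises
    ------
    DegenerateNoiseError
        If rho = 1 (use :func:`derive_proportional_rate`).
    ParameterError
        For non-positive alpha, beta, tau or t0, or a non-linear law.
    """
    if law.form != "linear":
        raise ParameterError("closed form requires the linear scalar law")
    if noise.is_proportional:
        raise DegenerateNoiseError(
            "rho = 1 (proportional noise) has a power-law, not log-power, "
            "solution; use derive_proportional_rate"
        )
    if not tau > 0 or not t0 > 0:
        raise ParameterError("tau and t0 must be > 0")
    n = 1.0 / (1.0 - noise.rho)
    K = (1.0 / tau) * (noise.beta * (1.0 - noise.rho) / law.alpha) ** n
    return RateFunction(K=K, n=n, t0=t0, direction=_as_direction(direction), tau=tau)


def derive_proportional_rate(
    noise: NoiseModel,
    law: ScalarLaw,
    anchor_time: float,
    anchor_rate: float,
    direction: "Direction | str",
    grid: Sequence[float] | None = None,
) -> TabulatedRate:
    """Power-law solution for the degenerate proportional-noise case rho = 1.

    With sigma_R = beta * R the governing equation dr/dt = +/-(beta/alpha) r/t
    integrates to r(t) = r_a * (t / t_a)**(+/- beta/alpha), pinned at an
    anchor point (t_a, r_a) since proportional noise fixes no amplitude.
    """
    if not noise.is_proportional:
        raise ParameterError("derive_proportional_rate requires rho = 1 exactly")
    if law.form != "linear":
        raise ParameterError("closed form requires the linear scalar law")
    if not anchor_time > 0 or not anchor_rate > 0:
        raise ParameterError("anchor_time and anchor_rate must be > 0")
    direction = _as_direction(direction)
    expo = direction.sign * noise.beta / law.alpha
    if grid is None:
        grid = np.geomspace(anchor_time / 4.0, anchor_time * 4.0, 101)
    t = np.asarray(grid, float)
    r = anchor_rate * (t / anchor_time) ** expo
    return TabulatedRate(tuple(t), tuple(r), direction)


# ---------------------------------------------------------------------------
# ODE residuals


def _rhs_closed_form(noise: NoiseModel, law: ScalarLaw, tau: float, direction: Direction):
    """Right-hand side +/- (beta tau**(rho-1) / alpha) r**rho / t."""
    coef = noise.beta * tau ** (noise.rho - 1.0) / law.alpha

    def rhs(t, r):
        return direction.sign * coef * np.maximum(r, 0.0) ** noise.rho / t

    return rhs


def ode_residual(
    rf: RateFunction,
    noise: NoiseModel,
    law: ScalarLaw,
    t,
    relative: bool = True,
) -> float | np.ndarray:
    """Residual of the governing ODE dr/dt = +/- (beta tau**(rho-1)/alpha) r**rho / t.

    The derivative side is the analytic derivative of the closed form (not a
    finite difference), so the residual isolates solution error.  For a rate
    function produced by :func:`derive_rate_function` the residual vanishes
    to floating-point precision.  By default the residual is normalised by
    the magnitude of the two sides.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr == rf.t0):
        raise DomainError("residual undefined at t = t0 (both sides vanish)")
    lhs = rf.derivative(t_arr)
    rhs = _rhs_closed_form(noise, law, rf.tau, rf.direction)(t_arr, np.asarray(rf(t_arr)))
    res = lhs - rhs
    if relative:
        scale = np.maximum(np.abs(lhs), np.abs(rhs))
        res = res / np.where(scale > 0, scale, 1.0)
    return res if np.ndim(res) else float(res)


def ode_residual_tabulated(
    tab: TabulatedRate,
    rhs: Callable[[float, float], float],
    t=None,
    relative: bool = True,
):
    """Residual dr/dt - rhs(t, r) for a tabulated rate, PCHIP derivative."""
    t_arr = np.asarray(tab.times if t is None else t, dtype=float)
    lhs = tab.derivative(t_arr)
    rhs_v = np.asarray([rhs(float(ti), float(ri)) for ti, ri in zip(t_arr, tab(t_arr))])
    res = lhs - rhs_v
    if relative:
        scale = np.maximum(np.abs(lhs), np.abs(rhs_v))
        res = res / np.where(scale > 0, scale, 1.0)
    return res


# ---------------------------------------------------------------------------
# general numerical solver


def solve_rate_numeric(
    sigma_R: Callable[[float], float] | NoiseModel,
    law: ScalarLaw,
    tau: float,
    boundary: tuple[float, float],
    direction: "Direction | str",
    grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> TabulatedRate:
    """Integrate the generalized rate equation dr/dt = +/- sigma_R(tau r) / (tau sigma_t(t)).

    Covers cases with no closed form: arbitrary count-noise maps sigma_R(R)
    (callable of the mean windowed count) and non-linear scaling laws
    sigma_t(t) (tabulated :class:`ScalarLaw`).  Integration starts from the
    boundary condition ``boundary = (t_b, r_b)`` and proceeds to both ends
    of ``grid`` with an adaptive Runge-Kutta stepper (DOP853).

    For power-law noise and a linear law the result reproduces the
    log-power closed form, which the tests use as the oracle.
    """
    direction = _as_direction(direction)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ParameterError("grid must be strictly increasing, length >= 2")
    t_b, r_b = boundary
    if not (grid[0] <= t_b <= grid[-1]):
        raise ParameterError("boundary time must lie inside the grid span")
    if r_b < 0:
        raise ParameterError("boundary rate must be non-negative")
    sig = sigma_R.sigma_R if isinstance(sigma_R, NoiseModel) else sigma_R

    def rhs(t, r):
        rr = max(float(np.atleast_1d(r)[0]), 0.0)
        return [direction.sign * float(sig(tau * rr)) / (tau * float(law.sigma_t(t)))]

    def hit_zero(t, r):
        return r[0]

    hit_zero.terminal = True
    hit_zero.direction = -1

    rates = np.empty_like(grid)
    idx = int(np.searchsorted(grid, t_b))
    for t_end, sel in (
        (grid[-1], slice(idx, None)),
        (grid[0], slice(None, idx)),
    ):
        pts = grid[sel]
        if pts.size == 0:
            continue
        if t_end == t_b:  # degenerate span: only the boundary point itself
            rates[sel] = r_b
            continue
        sol = solve_ivp(
            rhs,
            (t_b, t_end),
            [r_b],
            method="DOP853",
            t_eval=pts if t_end > t_b else pts[::-1],
            rtol=rtol,
            atol=atol,
            events=hit_zero if direction is Direction.DECREASING and t_end > t_b else None,
            dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(f"rate ODE integration failed: {sol.message}")
        if sol.t_events and len(sol.t_events[0]) and sol.t[-1] < t_end:
            raise IntegrationError(
                f"rate crossed zero at t={sol.t_events[0][0]:.6g} before grid end "
                f"{t_end:.6g}; shrink the grid"
            )
        vals = sol.y[0] if t_end > t_b else sol.y[0][::-1]
        rates[sel] = vals
    rates = np.clip(rates, 0.0, None)
    return TabulatedRate(tuple(grid), tuple(rates), direction)
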