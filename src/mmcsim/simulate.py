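"""Time integration, outcome classification, and basin-boundary search.

Trajectories are computed with :func:`scipy.integrate.solve_ivp`.  The
default method is LSODA: the effector equation relaxes at a rate
``p3*T + mu2`` that reaches hundreds per day once the tumor approaches its
carrying capacity, which makes the system stiff on persistence runs and
bogs down purely explicit schemes; LSODA switches automatically and agrees
with the adaptive Runge-Kutta 5(4) scheme (``method="RK45"``) to well
below the solver tolerances.  The drug equation is linear and decoupled,
so every run can be cross-checked against the closed form
``M(t) = m/mu1 + (M0 - m/mu1) * exp(-mu1*t)``.

A run is classified as a *cure* when the final tumor count falls strictly
below a cure threshold (default: one cell), and as *persistence* otherwise.
Because the tumor-free and carrying-capacity states are both attracting for
realistic parameters, the initial tumor count that separates the two
outcomes is a basin boundary; :func:`find_initial_size_threshold` locates
it by bisection on a logarithmic scale.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import _rhs_raw
from .params import ModelParameters

__all__ = [
    "ScenarioConfig",
    "Trajectory",
    "SolverError",
    "integrate",
    "drug_closed_form",
    "classify_outcome",
    "find_initial_size_threshold",
]

CURE = "cure"
PERSISTENCE = "persistence"


class SolverError(RuntimeError):
    """Raised when the ODE solver fails (e.g. step-size underflow)."""


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    """A simulation scenario.

    ``T0`` is the initial tumor cell count; ``M0`` defaults to no residual
    drug and ``E0`` to the homeostatic effector level ``d0/mu2`` (resolved
    against the parameter set at integration time when left as ``None``).
    ``treated=False`` switches the drug source off (``m = 0``) regardless
    of the parameter set.
    """

    T0: float
    M0: float = 0.0
    E0: float | None = None
    treated: bool = True
    horizon: float = 400.0
    cure_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError(f"horizon must be positive, got {self.horizon}")
        if self.cure_threshold < 0:
            raise ValueError(f"cure_threshold must be >= 0, got {self.cure_threshold}")
        for name in ("T0", "M0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.E0 is not None and self.E0 < 0:
            raise ValueError("E0 must be nonnegative")

    def initial_state(self, params: ModelParameters) -> np.ndarray:
        E0 = self.E0 if self.E0 is not None else params.d0 / params.mu2
        return np.array([self.M0, self.T0, E0], dtype=float)


@dataclasses.dataclass
class Trajectory:
    """A solved trajectory: aligned time grid and (M, T, E) samples."""

    t: np.ndarray
    M: np.ndarray
    T: np.ndarray
    E: np.ndarray
    params: ModelParameters
    scenario: ScenarioConfig
    meta: dict = dataclasses.field(default_factory=dict)

    @property
    def final_T(self) -> float:
        return float(self.T[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "M": self.M, "T": self.T, "E": self.E})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def drug_closed_form(t, M0: float, params: ModelParameters) -> np.ndarray:
    """Analytic solution of the drug equation, ``m/mu1 + (M0-m/mu1)e^{-mu1 t}``."""
    mstar = params.m / params.mu1
    return mstar + (M0 - mstar) * np.exp(-params.mu1 * np.asarray(t, dtype=float))


def integrate(
    params: ModelParameters,
    scenario: ScenarioConfig,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-6,
    method: str = "LSODA",
    n_points: int | None = None,
    t_eval: Sequence[float] | None = None,
) -> Trajectory:
    """Integrate the system over ``[0, horizon]``.

    By default the solution is sampled on a uniform daily grid (at least
    200 points); pass ``t_eval`` for an explicit grid or ``n_points`` for a
    uniform grid of that size.
    """
    run_params = params if scenario.treated else params.untreated()
    y0 = scenario.initial_state(run_params)
    if t_eval is None:
        if n_points is None:
            n_points = max(int(scenario.horizon) + 1, 200)
        t_eval = np.linspace(0.0, scenario.horizon, n_points)
    else:
        t_eval = np.asarray(t_eval, dtype=float)

    sol = solve_ivp(
        lambda t, y: _rhs_raw(y[0], y[1], y[2], run_params),
        (0.0, scenario.horizon),
        y0,
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise SolverError(
            f"integration failed: {sol.message}; last state t={sol.t[-1] if len(sol.t) else 0.0}, "
            f"y={sol.y[:, -1] if sol.y.size else y0}"
        )
    return Trajectory(
        t=sol.t,
        M=sol.y[0],
        T=sol.y[1],
        E=sol.y[2],
        params=run_params,
        scenario=scenario,
        meta={"method": method, "rtol": rtol, "atol": atol, "nfev": sol.nfev},
    )


def classify_outcome(traj: Trajectory, cure_threshold: float | None = None) -> str:
    """``"cure"`` iff the final tumor count is strictly below the threshold.

    A final count exactly at the threshold counts as persistence.
    """
    if traj.t.size == 0 or traj.t[-1] < traj.scenario.horizon * (1 - 1e-9):
        raise ValueError("trajectory is incomplete; cannot classify outcome")
    if cure_threshold is None:
        cure_threshold = traj.scenario.cure_threshold
    return CURE if traj.final_T < cure_threshold else PERSISTENCE


def find_initial_size_threshold(
    params: ModelParameters,
    scenario: ScenarioConfig,
    bracket: tuple[float, float],
    rel_tol: float = 0.01,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-6,
) -> float:
    """Initial tumor count separating cure from persistence, by bisection.

    ``scenario`` is used as a template: its ``T0`` is replaced by the probe
    value.  The bracket must straddle the basin boundary (cure at the low
    end, persistence at the high end).  Bisection runs in log10 space until
    the bracket width falls below ``rel_tol`` (relative); the geometric
    midpoint of the final bracket is returned.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if not (0 < lo < hi):
        raise ValueError(f"bracket must satisfy 0 < lo < hi, got {bracket}")

    def outcome(T0: float) -> str:
        sc = dataclasses.replace(scenario, T0=T0)
        traj = integrate(params, sc, rtol=rtol, atol=atol, n_points=2)
        return classify_outcome(traj)

    out_lo, out_hi = outcome(lo), outcome(hi)
    if out_lo == out_hi:
        raise ValueError(
            f"no threshold in bracket: outcome is {out_lo!r} at both endpoints "
            f"({lo:g}, {hi:g}); widen the bracket or extend the horizon"
        )
    if out_lo != CURE:
        raise ValueError("expected cure at the low end of the bracket")

    llo, lhi = np.log10(lo), np.log10(hi)
    tol_log = np.log10(1.0 + rel_tol)
    while lhi - llo > tol_log:
        mid = 0.5 * (llo + lhi)
        if outcome(10.0**mid) == CURE:
            llo = mid
        else:
            lhi = mid
    return float(10.0 ** (0.5 * (llo + lhi)))
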