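"""Right-hand side and Jacobian of the tumor-immune-chemotherapy system.

The dynamics are

    dM/dt = -mu1*M + m
    dT/dt = -T*(p1*M/(M+a) + p2*E) + r*T*(1 - T/k)
    dE/dt = d0 + gamma*p1*T*M/(M+a) - E*(p3*T + mu2)

where M is intravesical MMC [uM], T tumor cells, E effector cells.  The
drug equation is linear and decoupled; the tumor is killed by a saturating
(Michaelis-Menten) drug term and by mass-action effector kill, and grows
logistically; effectors have a constant source, are activated by the
drug-induced apoptosis flux, and are lost to natural death and to
deactivation on tumor contact.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .params import ModelParameters

__all__ = ["SystemState", "logistic_growth", "rhs", "jacobian"]


@dataclasses.dataclass(frozen=True)
class SystemState:
    """State (M, T, E) of the system at time ``t`` [days]."""

    M: float
    T: float
    E: float
    t: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.M, self.T, self.E], dtype=float)


def _coerce_state(state) -> np.ndarray:
    if isinstance(state, SystemState):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
    if y.shape != (3,):
        raise ValueError(f"state must have three components (M, T, E), got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"state contains non-finite values: {y}")
    if np.any(y < 0):
        raise ValueError(f"state components must be nonnegative: {y}")
    return y


def logistic_growth(T: float, params: ModelParameters) -> float:
    """Logistic tumor growth term ``r*T*(1 - T/k)`` [cells/day]."""
    if T < 0:
        raise ValueError(f"tumor cell count must be nonnegative, got {T}")
    return params.r * T * (1.0 - T / params.k)


def rhs(state, params: ModelParameters) -> np.ndarray:
    """Time derivative (dM/dt, dT/dt, dE/dt) at a nonnegative state.

    Units: [uM/day, cells/day, cells/day].  Tumor counts above the
    carrying capacity are mathematically legal but outside the biological
    range of interest; they trigger a warning, never clipping.
    """
    M, T, E = _coerce_state(state)
    if T > params.k:
        warnings.warn(
            f"tumor count T={T:g} exceeds carrying capacity k={params.k:g}; "
            "outside the biological range of interest",
            stacklevel=2,
        )
    return _rhs_raw(M, T, E, params)


def _rhs_raw(M: float, T: float, E: float, params: ModelParameters) -> np.ndarray:
    """Unchecked RHS (used by the integrator, which may probe any state)."""
    p = params
    kill = p.p1 * M / (M + p.a)  # saturating per-cell drug kill rate [1/day]
    dM = -p.mu1 * M + p.m
    dT = -T * (kill + p.p2 * E) + p.r * T * (1.0 - T / p.k)
    dE = p.d0 + p.gamma * kill * T - E * (p.p3 * T + p.mu2)
    return np.array([dM, dT, dE])


def jacobian(state, params: ModelParameters) -> np.ndarray:
    """3x3 Jacobian of the RHS with respect to (M, T, E)."""
    M, T, E = _coerce_state(state)
    p = params
    sat = M / (M + p.a)
    # d/dM of M/(M+a) = a/(M+a)^2
    dsat = p.a / (M + p.a) ** 2
    return np.array(
        [
            [-p.mu1, 0.0, 0.0],
            [
                -p.p1 * T * dsat,
                p.r - 2.0 * p.r * T / p.k - p.p2 * E - p.p1 * sat,
                -p.p2 * T,
            ],
            [
                p.gamma * p.p1 * T * dsat,
                -p.p3 * E + p.gamma * p.p1 * sat,
                -p.p3 * T - p.mu2,
            ],
        ]
    )
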