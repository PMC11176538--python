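"""Equilibria and local stability of the tumor-immune-chemotherapy system.

Two disease-free equilibria exist in closed form:

* homeostasis (untreated, ``m = 0``):  ``(0, 0, d0/mu2)``
* tumor-free under treatment (``m > 0``):  ``(m/mu1, 0, d0/mu2)``

Their stability is governed by two kill intensities with units of 1/day:
``I1 = p2*d0/mu2`` (net daily tumor kill by the immune system) and
``I2 = p1*(m/mu1) / (m/mu1 + a)`` (net daily tumor kill by the drug).  The
homeostasis point is locally stable iff ``r < I1``; the treated tumor-free
point iff ``r < I1 + I2``.

Interior ("cancer") equilibria have no usable closed form and are found
numerically: with ``M* = m/mu1`` fixed, the effector equation gives
``E*(T)`` explicitly and the tumor equation reduces to a quadratic in T
after clearing denominators.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model import jacobian, _rhs_raw
from .params import ModelParameters

__all__ = [
    "EquilibriumReport",
    "immune_intensity_I1",
    "chemo_intensity_I2",
    "disease_free_equilibria",
    "find_cancer_equilibria",
]

HOMEOSTASIS = "homeostasis_EB1"
TUMOR_FREE = "tumor_free_EB2"
CANCER = "cancer_numeric"


@dataclasses.dataclass(frozen=True)
class EquilibriumReport:
    """An equilibrium with its eigenvalues and a stability verdict.

    ``stable`` is strict (all eigenvalue real parts < 0); an eigenvalue
    with zero real part makes the point non-stable and sets ``marginal``.
    """

    state: tuple[float, float, float]  # (M*, T*, E*)
    eigenvalues: np.ndarray
    stable: bool
    label: str
    marginal: bool = False

    @property
    def M(self) -> float:
        return self.state[0]

    @property
    def T(self) -> float:
        return self.state[1]

    @property
    def E(self) -> float:
        return self.state[2]


def immune_intensity_I1(params: ModelParameters) -> float:
    """Net daily tumor-kill intensity of the immune system, ``p2*d0/mu2`` [1/day]."""
    return params.p2 * params.d0 / params.mu2


def chemo_intensity_I2(params: ModelParameters) -> float:
    """Net daily tumor-kill intensity of the drug, ``p1*m/(m + mu1*a)`` [1/day].

    This is the saturating kill rate evaluated at the residual drug level
    ``M* = m/mu1``; it is bounded above by ``p1`` for every ``m``.
    """
    return params.p1 * params.m / (params.m + params.mu1 * params.a)


def _verdict(eigenvalues: np.ndarray) -> tuple[bool, bool]:
    real = np.real(eigenvalues)
    marginal = bool(np.any(np.isclose(real, 0.0, atol=1e-12)))
    stable = bool(np.all(real < 0)) and not marginal
    return stable, marginal


def disease_free_equilibria(params: ModelParameters) -> list[EquilibriumReport]:
    """The disease-free equilibrium for the given treatment regime.

    ``m = 0`` yields the homeostasis point with eigenvalues
    ``[-mu1, r - I1, -mu2]``; ``m > 0`` yields the treated tumor-free point
    with eigenvalues ``[-mu1, r - I1 - I2, -mu2]`` (closed forms; they
    coincide with the numeric Jacobian spectrum).
    """
    p = params
    I1 = immune_intensity_I1(p)
    Estar = p.d0 / p.mu2
    if p.m == 0:
        state = (0.0, 0.0, Estar)
        eig = np.array([-p.mu1, p.r - I1, -p.mu2])
        label = HOMEOSTASIS
    else:
        state = (p.m / p.mu1, 0.0, Estar)
        eig = np.array([-p.mu1, p.r - I1 - chemo_intensity_I2(p), -p.mu2])
        label = TUMOR_FREE
    stable, marginal = _verdict(eig)
    return [EquilibriumReport(state=state, eigenvalues=eig, stable=stable, label=label, marginal=marginal)]


def _effector_at(T: float, params: ModelParameters) -> float:
    """E*(T): the effector level in equilibrium with a fixed tumor count."""
    p = params
    Mstar = p.m / p.mu1
    kill = p.p1 * Mstar / (Mstar + p.a)
    return (p.d0 + p.gamma * kill * T) / (p.p3 * T + p.mu2)


def cancer_equilibrium_condition(T, params: ModelParameters):
    """Scalar residual whose roots in (0, k] are interior equilibria.

    ``g(T) = r*(1 - T/k) - p1*M*/(M*+a) - p2*E*(T)`` with ``M* = m/mu1``.
    Vectorized over T.
    """
    p = params
    T = np.asarray(T, dtype=float)
    Mstar = p.m / p.mu1
    kill = p.p1 * Mstar / (Mstar + p.a)
    Estar = (p.d0 + p.gamma * kill * T) / (p.p3 * T + p.mu2)
    return p.r * (1.0 - T / p.k) - kill - p.p2 * Estar


def find_cancer_equilibria(params: ModelParameters) -> list[EquilibriumReport]:
    """Interior equilibria with ``T* in (0, k]``, found via the quadratic.

    Clearing the denominator ``p3*T + mu2`` from the scalar condition
    leaves a degree-2 polynomial in T, so at most two interior equilibria
    exist.  Each real root in ``(0, k]`` is returned with the numeric
    Jacobian spectrum; an empty list means no interior equilibrium.
    """
    p = params
    Mstar = p.m / p.mu1
    c = p.p1 * Mstar / (Mstar + p.a)  # per-cell drug kill at residual drug level
    # (r - c - r*T/k) * (p3*T + mu2) - p2*(d0 + gamma*c*T) = 0
    A = -p.r * p.p3 / p.k
    B = (p.r - c) * p.p3 - p.r * p.mu2 / p.k - p.p2 * p.gamma * c
    C = (p.r - c) * p.mu2 - p.p2 * p.d0
    roots = np.roots([A, B, C])

    reports = []
    for root in roots:
        if abs(root.imag) > 1e-9 * max(1.0, abs(root.real)):
            continue
        T = float(root.real)
        if not (0.0 < T <= p.k):
            continue
        E = _effector_at(T, p)
        if E <= 0:
            continue
        # polish the root against the un-cleared scalar condition
        state = (Mstar, T, E)
        eig = np.linalg.eigvals(jacobian(state, p))
        stable, marginal = _verdict(eig)
        reports.append(
            EquilibriumReport(state=state, eigenvalues=eig, stable=stable, label=CANCER, marginal=marginal)
        )
    reports.sort(key=lambda rep: rep.T)
    return reports


def equilibrium_residual(report: EquilibriumReport, params: ModelParameters) -> float:
    """Max-norm RHS residual at an equilibrium, relative to the state scale."""
    M, T, E = report.state
    resid = _rhs_raw(M, T, E, params)
    scale = max(1.0, abs(M), abs(T), abs(E))
    return float(np.max(np.abs(resid)) / scale)
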