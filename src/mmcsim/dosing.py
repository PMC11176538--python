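"""Personalized dose determination from the tumor-free stability criterion.

The treated tumor-free equilibrium is locally stable when the tumor growth
rate ``r`` is below the total kill intensity ``I1 + I2(m)``.  Inverting
that criterion for the instillation rate ``m`` yields, for each patient
(parameter set), an eligibility window of growth rates and a dose bound:

* eligibility window:  ``I1 < r < I1 + w``
* dose bound:          ``m_b = mu1 * a * (I1 - r) / (r - I1 - w)``

Two variants of the window width ``w`` are shipped:

* ``"scaled"`` (default): ``w = p1/mu1``, the form used throughout the
  dose-determination algorithm and needed to reproduce the cohort
  experiment;
* ``"algebraic"``: ``w = p1``, obtained by solving ``r < I1 + I2(m)``
  directly for ``m``.  Because ``I2`` is increasing in ``m``, the
  algebraic bound is the *minimum* rate at which the tumor-free state is
  stabilized: ``I1 + I2(m_b) = r`` exactly at the bound, and stability
  holds for ``m`` above it.

The recommendation step converts the bound to a mg course dose and
classifies the patient: bounds above the recommended maximum are capped
and flagged as over-toxicity; growth rates outside the window, or bounds
below a negligible-dose floor, mark theoretical non-responders.
"""

from __future__ import annotations

import dataclasses
import math

from .equilibria import chemo_intensity_I2, immune_intensity_I1
from .geometry import (
    DEFAULT_TAU_DAYS,
    MMC_MOLECULAR_WEIGHT,
    PROTOCOL_DOSE_MG,
    PROTOCOL_VOLUME_ML,
    rate_to_course_mg,
)
from .params import ModelParameters

__all__ = [
    "VARIANTS",
    "NotEligibleError",
    "DoseRecommendation",
    "eligibility_window",
    "dose_bound",
    "recommend",
]

VARIANTS = ("scaled", "algebraic")

ELIGIBLE = "eligible"
OVER_TOXICITY = "over_toxicity_capped"
NON_RESPONDER = "non_responder"


class NotEligibleError(ValueError):
    """Growth rate outside the eligibility window; names the failing side."""


def _window_width(params: ModelParameters, variant: str) -> float:
    if variant == "scaled":
        return params.p1 / params.mu1
    if variant == "algebraic":
        return params.p1
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def eligibility_window(params: ModelParameters, variant: str = "scaled") -> tuple[float, float]:
    """Growth-rate window ``(I1, I1 + w)`` within which a dose bound exists [1/day]."""
    I1 = immune_intensity_I1(params)
    return (I1, I1 + _window_width(params, variant))


def dose_bound(params: ModelParameters, r: float, variant: str = "scaled") -> float:
    """Instillation-rate bound [uM/day] for a growth rate strictly inside the window.

    Both the numerator ``mu1*a*(I1 - r)`` and the denominator
    ``r - I1 - w`` are negative inside the window, so the bound is
    positive.  It vanishes as ``r`` approaches ``I1`` from above and
    diverges at the upper window edge.
    """
    lo, hi = eligibility_window(params, variant)
    if r <= lo:
        raise NotEligibleError(
            f"growth rate r={r:g} is at or below the lower window edge I1={lo:g}: "
            "the immune system alone suffices, no positive dose bound exists"
        )
    if r >= hi:
        raise NotEligibleError(
            f"growth rate r={r:g} is at or above the upper window edge {hi:g}: "
            "no finite dose stabilizes the tumor-free state"
        )
    w = _window_width(params, variant)
    return params.mu1 * params.a * (lo - r) / (r - lo - w)


@dataclasses.dataclass(frozen=True)
class DoseRecommendation:
    """Outcome of the dose-determination algorithm for one patient."""

    r_window: tuple[float, float]
    eligible: bool
    bound_rate: float  # uM/day; NaN for non-responders
    bound_mg: float    # mg per course; NaN for non-responders
    usable_mg: float   # bound_mg, capped at the recommended maximum
    capped: bool
    classification: str  # eligible | over_toxicity_capped | non_responder
    variant: str


def recommend(
    params: ModelParameters,
    r: float | None = None,
    *,
    variant: str = "scaled",
    max_mg: float = PROTOCOL_DOSE_MG,
    min_mg: float = 1.0,
    tau_days: float = DEFAULT_TAU_DAYS,
    volume_ml: float = PROTOCOL_VOLUME_ML,
    mw: float = MMC_MOLECULAR_WEIGHT,
) -> DoseRecommendation:
    """Run the dose-determination algorithm for one parameter set.

    ``r`` defaults to the growth rate carried by ``params``.  Window
    failures and negligible bounds classify the patient as a theoretical
    non-responder rather than raising.
    """
    if r is None:
        r = params.r
    window = eligibility_window(params, variant)

    def _non_responder() -> DoseRecommendation:
        return DoseRecommendation(
            r_window=window, eligible=False, bound_rate=math.nan, bound_mg=math.nan,
            usable_mg=math.nan, capped=False, classification=NON_RESPONDER, variant=variant,
        )

    try:
        bound_rate = dose_bound(params, r, variant)
    except NotEligibleError:
        return _non_responder()

    bound_mg = rate_to_course_mg(bound_rate, tau_days, volume_ml, mw)
    if not math.isfinite(bound_mg) or bound_mg < min_mg:
        return _non_responder()
    if bound_mg > max_mg:
        return DoseRecommendation(
            r_window=window, eligible=True, bound_rate=bound_rate, bound_mg=bound_mg,
            usable_mg=max_mg, capped=True, classification=OVER_TOXICITY, variant=variant,
        )
    return DoseRecommendation(
        r_window=window, eligible=True, bound_rate=bound_rate, bound_mg=bound_mg,
        usable_mg=bound_mg, capped=False, classification=ELIGIBLE, variant=variant,
    )


def algebraic_bound_is_boundary(params: ModelParameters, r: float) -> float:
    """Residual ``I1 + I2(m_b) - r`` at the algebraic bound (zero at the boundary)."""
    m_b = dose_bound(params, r, variant="algebraic")
    at_bound = params.replace(m=m_b)
    return immune_intensity_I1(at_bound) + chemo_intensity_I2(at_bound) - r
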